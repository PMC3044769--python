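"""Nearest-neighbor thermodynamic parameters shared by every energy computation.

A single :class:`EnergyParameterSet` instance carries the stacking table, the
loop-length penalties, the intermolecular initiation and terminal-AU terms, the
linear multiloop cost, and the physical constants R and T.  The same instance
must be used for the duplex stage and the folding stage of one run: free-energy
differences are only meaningful when every term comes from one consistent rule.

The default table shipped with the package is a Turner-style 37 degC set
(kcal/mol).  It is the package's own normative default — no claim of
bit-compatibility with any particular published vintage is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, TextIO

__all__ = [
    "CANONICAL_PAIRS",
    "WC_PAIRS",
    "GU_PAIRS",
    "EnergyParameterSet",
    "ParameterFileError",
    "load_parameters",
    "write_parameters",
    "stack_energy",
    "loop_penalty",
]

#: canonical base pairs, Watson-Crick plus GU wobble
WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
GU_PAIRS = frozenset({"GU", "UG"})
CANONICAL_PAIRS = WC_PAIRS | GU_PAIRS

#: largest tabulated loop length; longer loops use logarithmic extrapolation
MAX_TABULATED_LOOP = 30

_LOOP_KINDS = ("hairpin", "bulge", "internal")


class ParameterFileError(ValueError):
    """Raised when a parameter table is missing, malformed, or incomplete."""


@dataclass(frozen=True)
class EnergyParameterSet:
    """One consistent nearest-neighbor energy rule.

    ``stack_table`` is keyed by ``(pair5, pair3)``: the 5'-side pair followed by
    the 3'-side pair, each written top-base-then-bottom-base (e.g. ``("CG",
    "GC")`` is 5'-CG-3' over 3'-GC-5').  Energies are kcal/mol at the set's
    temperature; loop penalties are indexed by loop length in nucleotides.
    """

    stack_table: Mapping[tuple[str, str], float]
    hairpin_penalty: Mapping[int, float]
    bulge_penalty: Mapping[int, float]
    internal_penalty: Mapping[int, float]
    duplex_initiation: float
    terminal_au_penalty: float
    multiloop_offset: float
    multiloop_branch: float
    multiloop_unpaired: float
    loop_extrapolation_c: float
    temperature: float = 310.15
    gas_constant: float = 0.001987
    version_tag: str = "default"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.gas_constant <= 0:
            raise ValueError(f"gas constant must be > 0, got {self.gas_constant}")
        for key, value in self.stack_table.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite stack energy for {key}")
        for kind in _LOOP_KINDS:
            table = getattr(self, f"{kind}_penalty")
            for length, value in table.items():
                if value < 0:
                    raise ValueError(f"{kind} penalty at length {length} is negative")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


def _is_pair(pair: str) -> bool:
    return pair in CANONICAL_PAIRS


def stack_energy(pair5: str, pair3: str, params: EnergyParameterSet) -> float:
    """Stacking free energy (kcal/mol) of ``pair3`` stacked 3' of ``pair5``.

    Both pairs must be canonical (AU/UA/CG/GC/GU/UG), written top strand base
    first.  The table obeys nearest-neighbor rotational symmetry:
    ``stack(p, q) == stack(reverse(q), reverse(p))``.
    """
    for pair in (pair5, pair3):
        if not _is_pair(pair):
            raise ValueError(f"{pair!r} is not a canonical base pair")
    return params.stack_table[(pair5, pair3)]


def loop_penalty(kind: str, length: int, params: EnergyParameterSet) -> float:
    """Destabilizing free energy (kcal/mol) of a loop of ``length`` nucleotides.

    Hairpin loops must be >= 3 nt (the minimum hairpin); bulge and internal
    loops >= 1 nt.  Lengths beyond the tabulated maximum (30) extrapolate
    logarithmically: ``value(30) + c * ln(length/30)``.
    """
    if kind not in _LOOP_KINDS:
        raise ValueError(f"unknown loop kind {kind!r}")
    if kind == "hairpin" and length < 3:
        raise ValueError(f"hairpin loop length must be >= 3, got {length}")
    if length < 1:
        raise ValueError(f"loop length must be positive, got {length}")
    table = getattr(params, f"{kind}_penalty")
    if length <= MAX_TABULATED_LOOP:
        return table[length]
    return table[MAX_TABULATED_LOOP] + params.loop_extrapolation_c * math.log(
        length / MAX_TABULATED_LOOP
    )


def _default_stream() -> TextIO:
    return (
        resources.files("mirneq.data").joinpath("default_params.tsv").open("r")
    )


_SCALARS = {
    "duplex_initiation",
    "terminal_au",
    "multiloop_offset",
    "multiloop_branch",
    "multiloop_unpaired",
    "loop_extrapolation_c",
    "temperature",
    "gas_constant",
}


def load_parameters(source: str | Path = "default") -> EnergyParameterSet:
    """Load an :class:`EnergyParameterSet` from a TSV table.

    ``source`` is either the literal string ``"default"`` (the shipped table)
    or a path to a file in the same dialect: three tab-separated columns
    ``kind``, ``key``, ``value_kcal_mol``; ``#`` lines are comments.  Stack keys
    are written ``XY/ZW`` (top strand 5'-XY-3' over bottom strand 3'-ZW-5').
    """
    if isinstance(source, str) and source == "default":
        handle = _default_stream()
        tag = "default"
    else:
        path = Path(source)
        if not path.is_file():
            raise ParameterFileError(f"parameter file not found: {path}")
        handle = path.open("r")
        tag = str(path)

    stacks: dict[tuple[str, str], float] = {}
    loops: dict[str, dict[int, float]] = {k: {} for k in _LOOP_KINDS}
    scalars: dict[str, float] = {}
    with handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParameterFileError(
                    f"{tag}:{lineno}: expected 3 tab-separated columns, got {line!r}"
                )
            kind, key, raw_value = fields
            try:
                value = float(raw_value)
            except ValueError:
                raise ParameterFileError(
                    f"{tag}:{lineno}: bad energy value {raw_value!r}"
                ) from None
            if kind == "stack":
                if len(key) != 5 or key[2] != "/":
                    raise ParameterFileError(f"{tag}:{lineno}: bad stack key {key!r}")
                pair5, pair3 = key[0] + key[3], key[1] + key[4]
                if not (_is_pair(pair5) and _is_pair(pair3)):
                    raise ParameterFileError(
                        f"{tag}:{lineno}: {key!r} does not describe canonical pairs"
                    )
                stacks[(pair5, pair3)] = value
            elif kind in _LOOP_KINDS:
                try:
                    length = int(key)
                except ValueError:
                    raise ParameterFileError(
                        f"{tag}:{lineno}: bad loop length {key!r}"
                    ) from None
                loops[kind][length] = value
            elif kind in _SCALARS:
                scalars[kind] = value
            else:
                raise ParameterFileError(f"{tag}:{lineno}: unknown kind {kind!r}")

    if len(stacks) != 36:
        missing = 36 - len(stacks)
        raise ParameterFileError(
            f"{tag}: stack table incomplete, {missing} of 36 entries missing"
        )
    for kind in _LOOP_KINDS:
        start = 3 if kind == "hairpin" else 1
        for length in range(start, MAX_TABULATED_LOOP + 1):
            if length not in loops[kind]:
                raise ParameterFileError(
                    f"{tag}: missing {kind} penalty for length {length}"
                )
    for name in _SCALARS:
        if name not in scalars:
            raise ParameterFileError(f"{tag}: missing scalar row {name!r}")

    return EnergyParameterSet(
        stack_table=stacks,
        hairpin_penalty=loops["hairpin"],
        bulge_penalty=loops["bulge"],
        internal_penalty=loops["internal"],
        duplex_initiation=scalars["duplex_initiation"],
        terminal_au_penalty=scalars["terminal_au"],
        multiloop_offset=scalars["multiloop_offset"],
        multiloop_branch=scalars["multiloop_branch"],
        multiloop_unpaired=scalars["multiloop_unpaired"],
        loop_extrapolation_c=scalars["loop_extrapolation_c"],
        temperature=scalars["temperature"],
        gas_constant=scalars["gas_constant"],
        version_tag=tag,
    )


def write_parameters(params: EnergyParameterSet, path: str | Path) -> None:
    """Serialize ``params`` back to the TSV dialect read by :func:`load_parameters`."""
    lines = ["# mirneq parameter table", "# columns: kind\tkey\tvalue_kcal_mol"]
    for (pair5, pair3) in sorted(params.stack_table):
        key = pair5[0] + pair3[0] + "/" + pair5[1] + pair3[1]
        lines.append(f"stack\t{key}\t{params.stack_table[(pair5, pair3)]:.2f}")
    for kind in _LOOP_KINDS:
        table = getattr(params, f"{kind}_penalty")
        for length in sorted(table):
            lines.append(f"{kind}\t{length}\t{table[length]:.2f}")
    lines.append(f"duplex_initiation\t-\t{params.duplex_initiation:g}")
    lines.append(f"terminal_au\t-\t{params.terminal_au_penalty:g}")
    lines.append(f"multiloop_offset\t-\t{params.multiloop_offset:g}")
    lines.append(f"multiloop_branch\t-\t{params.multiloop_branch:g}")
    lines.append(f"multiloop_unpaired\t-\t{params.multiloop_unpaired:g}")
    lines.append(f"loop_extrapolation_c\t-\t{params.loop_extrapolation_c:g}")
    lines.append(f"temperature\t-\t{params.temperature:g}")
    lines.append(f"gas_constant\t-\t{params.gas_constant:g}")
    Path(path).write_text("\n".join(lines) + "\n")
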