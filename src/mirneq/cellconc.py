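"""Copy-number-per-cell to cytoplasmic molar concentration, and back.

A species present in N copies in the cytoplasm of a single cell has molar
concentration C = N / (V_cyto * N_A), where V_cyto is the cytoplasmic volume
in liters and N_A is Avogadro's number.  Cell volumes are given in cubic
micrometers (1 um^3 = 1e-15 L under SI conversion) and the nucleus is assumed
to occupy a fixed fraction (default 25%) of the cell volume.

The ``paper_convention`` flag scales results by 1000, reproducing a family of
published example values whose SI prefixes are a consistent 1000x above what
the formula yields under strict SI volume conversion (the significands agree;
only the prefix differs).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AVOGADRO", "LITERS_PER_UM3", "CellSpec", "copies_to_molar", "molar_to_copies"]

AVOGADRO = 6.022e23  # 1/mol
LITERS_PER_UM3 = 1e-15


@dataclass(frozen=True)
class CellSpec:
    """One RNA species in one cell: copy count and cytoplasm geometry."""

    copies: float
    cell_volume: float  # um^3
    nucleus_fraction: float = 0.25
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copy number must be >= 0")
        if self.cell_volume <= 0:
            raise ValueError("cell volume must be > 0 um^3")
        if not (0 <= self.nucleus_fraction < 1):
            raise ValueError("nucleus fraction must lie in [0, 1)")

    @property
    def cytoplasm_liters(self) -> float:
        return (1.0 - self.nucleus_fraction) * self.cell_volume * LITERS_PER_UM3


def copies_to_molar(spec: CellSpec, paper_convention: bool = False) -> float:
    """Cytoplasmic molar concentration (mol/L) of ``spec.copies`` molecules."""
    conc = spec.copies / (spec.cytoplasm_liters * spec.avogadro)
    return conc * 1000.0 if paper_convention else conc


def molar_to_copies(
    concentration: float,
    cell_volume: float,
    nucleus_fraction: float = 0.25,
    paper_convention: bool = False,
) -> float:
    """Exact algebraic inverse of :func:`copies_to_molar` (real-valued copies)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    spec = CellSpec(copies=0, cell_volume=cell_volume, nucleus_fraction=nucleus_fraction)
    if paper_convention:
        concentration = concentration / 1000.0
    return concentration * spec.cytoplasm_liters * spec.avogadro
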