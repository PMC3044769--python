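"""Two-species mass-action hybridization equilibrium.

Given the net interaction energy ddg, temperature, and the total (initial)
concentrations [S0] of miRNA and [T0] of mRNA, solve

    [S] + [ST] = [S0]          (conservation of miRNA)
    [T] + [ST] = [T0]          (conservation of mRNA)
    [ST] / ([S][T]) = K        (mass action),  K = exp(-ddg / RT)

for the equilibrium concentrations of unbound miRNA [S], unbound mRNA [T] and
duplex [ST].  Eliminating variables gives a quadratic; the roots are evaluated
in cancellation-free form so that extreme K and strongly unequal
concentrations remain accurate to machine precision:

    [S]  = ( -(T0 - S0 + 1/K) + sqrt((T0 - S0 + 1/K)^2 + 4 S0/K) ) / 2
    [T]  =   symmetric with S0 and T0 exchanged
    [ST] =   2 S0 T0 / ( b + sqrt(b^2 - 4 S0 T0) ),   b = S0 + T0 + 1/K

The net ensemble free-energy change of the interaction is the total free
energy of the mixture at equilibrium minus that of the unmixed initial state.
Each species contributes [i] * (g_i0 + RT (ln([i]/1M) - 1)) per liter — the
ideal-dilute-solution Gibbs energy, whose minimum along the reaction
coordinate is exactly the mass-action root (the "-1" accounts for the change
in total molecule count when two strands condense into one duplex) — with the
convention [i] ln[i] -> 0 as [i] -> 0.  The net change is zero when no duplex
forms and strictly negative otherwise (binding is a spontaneous process).

Concentrations are mol/L against a 1 mol/L standard state; energies kcal/mol;
the net change is reported in kcal per liter of solution.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

from .energy_params import EnergyParameterSet

__all__ = [
    "ConcentrationPair",
    "EquilibriumState",
    "equilibrium_constant",
    "solve_equilibrium",
    "net_free_energy",
    "run_ensemble_batch",
    "EXPONENT_CLAMP",
]

logger = logging.getLogger(__name__)

#: |ddg/RT| beyond which the Boltzmann exponent is clamped to avoid overflow
EXPONENT_CLAMP = 700.0

_MASS_TOL = 1e-9


@dataclass(frozen=True)
class ConcentrationPair:
    """Total (initial) strand concentrations, mol/L."""

    s0: float
    t0: float

    def __post_init__(self) -> None:
        if self.s0 < 0 or self.t0 < 0:
            raise ValueError("initial concentrations must be >= 0")


@dataclass(frozen=True)
class EquilibriumState:
    s: float
    t: float
    st: float
    k: float
    fraction_mrna_bound: float
    dg_net: float = 0.0


def equilibrium_constant(ddg: float, params: EnergyParameterSet) -> float:
    """K = exp(-ddg / RT) against the 1 mol/L standard state (units L/mol)."""
    exponent = -ddg / params.rt
    if abs(exponent) > EXPONENT_CLAMP:
        logger.warning(
            "Boltzmann exponent %.1f clamped to +/-%g (ddg=%g kcal/mol)",
            exponent,
            EXPONENT_CLAMP,
            ddg,
        )
        exponent = math.copysign(EXPONENT_CLAMP, exponent)
    return math.exp(exponent)


def solve_equilibrium(conc: ConcentrationPair, k: float) -> EquilibriumState:
    """Solve the mass-action quadratic in numerically stable form.

    ``dg_net`` in the returned state is 0; use :func:`net_free_energy` to fill
    it in when the standard-state energies of the species are known.
    """
    if k <= 0:
        raise ValueError(f"equilibrium constant must be > 0, got {k}")
    s0, t0 = conc.s0, conc.t0
    inv_k = 1.0 / k

    if s0 == 0.0 or t0 == 0.0:
        st = 0.0
        s, t = s0, t0
    else:
        # each root in cancellation-free form: (-q + sqrt(q^2 + e))/2 is
        # rewritten as e / (2 (q + sqrt(q^2 + e))) whenever q > 0, so the
        # minority species keeps full relative precision in both the weak-
        # and strong-binding limits
        def stable_root(q: float, e: float) -> float:
            root = math.sqrt(q * q + e)
            if q > 0.0:
                return e / (2.0 * (q + root))
            return (root - q) / 2.0

        s = stable_root(t0 - s0 + inv_k, 4.0 * s0 * inv_k)
        t = stable_root(s0 - t0 + inv_k, 4.0 * t0 * inv_k)
        b = s0 + t0 + inv_k
        # discriminant expanded so no large squares cancel
        disc = (s0 - t0) ** 2 + inv_k * (2.0 * (s0 + t0) + inv_k)
        st = 2.0 * s0 * t0 / (b + math.sqrt(disc))
        # reconcile conservation while keeping every small quantity at the
        # full relative precision of its own cancellation-free formula
        if st <= s and st <= t:
            s, t = s0 - st, t0 - st
        elif s <= t:
            st = s0 - s
        else:
            st = t0 - t

    scale_s = max(s0, 1e-300)
    scale_t = max(t0, 1e-300)
    if abs(s + st - s0) > _MASS_TOL * scale_s or abs(t + st - t0) > _MASS_TOL * scale_t:
        raise AssertionError("mass-conservation residual exceeded tolerance")

    fraction = st / t0 if t0 > 0 else 0.0
    return EquilibriumState(s=s, t=t, st=st, k=k, fraction_mrna_bound=fraction)


def net_free_energy(
    state: EquilibriumState,
    g_s0: float,
    g_t0: float,
    g_st0: float,
    conc: ConcentrationPair,
    params: EnergyParameterSet,
) -> float:
    """Net ensemble free-energy change, kcal per liter of solution.

    ``g_s0``/``g_t0`` are the standard-state structural energies of free miRNA
    and mRNA; ``g_st0`` that of the bound complex (g_s0 + g_t0 + ddg).  The
    total free energy of a state is the sum over species of
    [i] * (g_i0 + RT (ln[i] - 1)); the net change is equilibrium minus the
    unmixed initial state (no duplex).  Always <= 0, and 0 exactly when
    [ST] = 0; the equilibrium concentrations minimize this total.
    """
    st = state.st
    if st == 0.0:
        return 0.0
    rt = params.rt
    ddg = g_st0 - g_s0 - g_t0
    s0, t0 = conc.s0, conc.t0
    # cancellation-free regrouping of G(eq) - G(init): every term carries a
    # factor of [ST], so weak binding keeps its (negative) sign exactly
    term_mix = st * (ddg + rt * (math.log(st) - math.log(s0) - math.log(t0)))

    def dilution(remaining: float, total: float) -> float:
        # remaining * ln(remaining/total); log1p keeps precision when the
        # bound fraction is far below the float epsilon
        if remaining <= 0.0:
            return 0.0
        if st <= 0.5 * total:
            return remaining * math.log1p(-st / total)
        return remaining * math.log(remaining / total)

    # +rt*st: the molecule-count term of the dilute-solution Gibbs energy
    # (two strands become one duplex)
    return term_mix + rt * (st + dilution(state.s, s0) + dilution(state.t, t0))


def run_ensemble_batch(
    in_path: str | Path,
    out_path: str | Path,
    params: EnergyParameterSet,
    g_s0: float = 0.0,
) -> int:
    """Batch equilibrium calculator: TSV (ddg, s0, t0 [, g_t0]) -> TSV.

    Each input row gives the interaction energy and initial concentrations;
    the optional fourth column is the mRNA structural energy used for the net
    free-energy bookkeeping (0 if absent).  Output columns: the inputs plus
    s, t, st, fraction_mrna_bound, dg_net.  Returns the number of rows.
    """
    in_path, out_path = Path(in_path), Path(out_path)
    rows = 0
    with in_path.open() as fin, out_path.open("w", newline="") as fout:
        writer = csv.writer(fout, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["ddg", "s0", "t0", "s", "t", "st", "fraction_mrna_bound", "dg_net"]
        )
        for raw in fin:
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("ddg"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise ValueError(f"expected 3 or 4 columns, got {line!r}")
            ddg, s0, t0 = (float(v) for v in fields[:3])
            g_t0 = float(fields[3]) if len(fields) == 4 else 0.0
            conc = ConcentrationPair(s0, t0)
            k = equilibrium_constant(ddg, params)
            state = solve_equilibrium(conc, k)
            dg_net = net_free_energy(
                state, g_s0, g_t0, g_s0 + g_t0 + ddg, conc, params
            )
            writer.writerow(
                [
                    f"{ddg:.2f}",
                    f"{s0:.6e}",
                    f"{t0:.6e}",
                    f"{state.s:.6e}",
                    f"{state.t:.6e}",
                    f"{state.st:.6e}",
                    f"{state.fraction_mrna_bound:.6f}",
                    f"{dg_net:.6e}",
                ]
            )
            rows += 1
    return rows
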