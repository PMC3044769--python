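"""The two-step free-energy change of a miRNA binding an mRNA site.

Binding proceeds in two steps: the folded mRNA opens its target site (cost
``dg_open >= 0``), then the duplex forms (gain ``dg_hybrid``).  The net change

    ddg = dg_hybrid + dg_open - dg_mirna_structure

drives the equilibrium constant K = exp(-ddg/RT).  The miRNA's own structural
energy is zero by default — the mature miRNA is presented unfolded by the
silencing complex — but a precomputed miRNA folding energy can be supplied and
is subtracted as an additional unfolding cost.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["InteractionEnergy", "interaction_ddg"]


@dataclass(frozen=True)
class InteractionEnergy:
    dg_hybrid: float
    dg_open: float
    dg_mirna_structure: float
    ddg: float


def interaction_ddg(
    dg_hybrid: float, dg_open: float, dg_mirna_structure: float = 0.0
) -> InteractionEnergy:
    """Combine hybridization and opening energies into the net change ddg.

    ``dg_open`` must be non-negative (a folding constraint can only cost
    energy).  ``ddg`` itself is unrestricted in sign: inaccessible sites can
    yield a net-unfavorable positive value.
    """
    if dg_open < 0:
        raise ValueError(f"opening energy must be >= 0 kcal/mol, got {dg_open}")
    ddg = dg_hybrid + dg_open - dg_mirna_structure
    return InteractionEnergy(
        dg_hybrid=dg_hybrid,
        dg_open=dg_open,
        dg_mirna_structure=dg_mirna_structure,
        ddg=ddg,
    )
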