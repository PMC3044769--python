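"""Candidate target-site discovery by intermolecular duplex free energy.

The first stage of the prediction: slide a window over the mRNA, compute the
minimum-free-energy miRNA:window duplex by dynamic programming (intermolecular
pairs only, antiparallel, no pseudoknots), keep sites at or below the energy
cutoff (default -8.5 kcal/mol) and within a suboptimality increment of the
best site, reduce overlapping hits to locally optimal ones, and demand a seed
match: Watson-Crick pairing at miRNA positions 2-7 (human mode), or the same
with at most one GU wobble tolerated (fly mode).

Duplex energies are the sum of stacking terms, bulge/internal-loop penalties
between consecutive pairs, the intermolecular initiation term, and terminal-AU
penalties — the same nearest-neighbor rule used for folding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy_params import EnergyParameterSet, GU_PAIRS, WC_PAIRS
from ._seq import normalize_rna

__all__ = [
    "DuplexAlignment",
    "CandidateSite",
    "duplex_mfe",
    "alignment_energy",
    "seed_match",
    "scan_candidate_sites",
    "ENERGY_CUTOFF",
    "SUBOPTIMAL_INCREMENT",
    "WINDOW_EXTENSION",
    "MAX_DUPLEX_LOOP",
]

INF = float("inf")
#: default hybridization-energy cutoff, kcal/mol ("at most" -8.5)
ENERGY_CUTOFF = -8.5
#: default retention band above the best site on an mRNA, kcal/mol
SUBOPTIMAL_INCREMENT = 5.0
#: scan window length = miRNA length + this many nt (room for mRNA-side loops)
WINDOW_EXTENSION = 15
#: largest bulge/internal loop allowed inside a duplex, nt
MAX_DUPLEX_LOOP = 15

_CANONICAL = WC_PAIRS | GU_PAIRS
_SEED_POSITIONS = range(1, 7)  # miRNA nt 2-7, 0-based indices 1..6


@dataclass(frozen=True)
class DuplexAlignment:
    """An intermolecular miRNA:mRNA duplex at one site.

    ``pairs`` holds (miRNA position, mRNA position) tuples, 0-based, sorted by
    miRNA position; the strands are antiparallel so mRNA positions decrease.
    ``site_interval`` is the half-open mRNA interval covered by the duplex.
    """

    pairs: tuple[tuple[int, int], ...]
    dg_hybrid: float
    site_interval: tuple[int, int]
    #: (miRNA base, mRNA base) for each entry of ``pairs``
    pair_bases: tuple[tuple[str, str], ...] = ()

    def shifted(self, offset: int) -> "DuplexAlignment":
        """The same alignment with mRNA coordinates shifted by ``offset``."""
        return DuplexAlignment(
            pairs=tuple((i, j + offset) for i, j in self.pairs),
            dg_hybrid=self.dg_hybrid,
            site_interval=(
                self.site_interval[0] + offset,
                self.site_interval[1] + offset,
            ),
            pair_bases=self.pair_bases,
        )


@dataclass(frozen=True)
class CandidateSite:
    mirna_id: str
    mrna_id: str
    alignment: DuplexAlignment
    seed_ok: bool
    seed_gu_count: int


_TERMINAL_PENALIZED = frozenset({"AU", "UA", "GU", "UG"})


def _terminal_penalty(a: str, b: str, params: EnergyParameterSet) -> float:
    return params.terminal_au_penalty if a + b in _TERMINAL_PENALIZED else 0.0


def duplex_mfe(
    mirna: str,
    window: str,
    params: EnergyParameterSet,
    *,
    _validate_lengths: bool = True,
) -> DuplexAlignment | None:
    """Minimum-free-energy intermolecular alignment of ``mirna`` with ``window``.

    Returns ``None`` when no alignment containing at least two stacked
    (adjacent) pairs exists; isolated pairs and stackless pair sets are not
    reportable duplexes.
    """
    x = normalize_rna(mirna, name="miRNA")
    y = normalize_rna(window, name="window")
    m, n = len(x), len(y)
    if _validate_lengths:
        if not (15 <= m <= 30):
            raise ValueError(f"miRNA length must be 15-30 nt, got {m}")
        if n > m + WINDOW_EXTENSION:
            raise ValueError("window longer than miRNA + extension")
    if m == 0 or n == 0:
        return None

    init = params.duplex_initiation
    stack = params.stack_table
    bulge = params.bulge_penalty
    internal = params.internal_penalty

    canon = [[x[i] + y[j] in _CANONICAL for j in range(n)] for i in range(m)]
    # H[s][i][j]: best partial duplex whose 3'-most miRNA pair is (i, j);
    # s = 1 once at least one stacked (adjacent) pair of pairs is present.
    H0 = [[INF] * n for _ in range(m)]
    H1 = [[INF] * n for _ in range(m)]
    back: dict[tuple[int, int, int], tuple[int, int, int] | None] = {}

    for i in range(m):
        xi = x[i]
        for j in range(n):
            if not canon[i][j]:
                continue
            best0 = init + _terminal_penalty(xi, y[j], params)
            back[(0, i, j)] = None
            best1 = INF
            pred1: tuple[int, int, int] | None = None
            pij_lo = x[i] + y[j]
            for ip in range(max(0, i - MAX_DUPLEX_LOOP - 1), i):
                g1 = i - ip - 1
                row0, row1 = H0[ip], H1[ip]
                jp_hi = min(n - 1, j + MAX_DUPLEX_LOOP + 1 - g1)
                for jp in range(j + 1, jp_hi + 1):
                    if row0[jp] >= INF and row1[jp] >= INF:
                        continue
                    g2 = jp - j - 1
                    if g1 == 0 and g2 == 0:
                        cost = stack[(x[ip] + y[jp], pij_lo)]
                        stacked = True
                    elif g1 == 0 or g2 == 0:
                        cost = bulge[g1 + g2]
                        stacked = False
                    else:
                        cost = internal[g1 + g2]
                        stacked = False
                    if stacked:
                        cand = row0[jp] + cost
                        if cand < best1:
                            best1, pred1 = cand, (0, ip, jp)
                        cand = row1[jp] + cost
                        if cand < best1:
                            best1, pred1 = cand, (1, ip, jp)
                    else:
                        cand = row0[jp] + cost
                        if cand < best0:
                            best0 = cand
                            back[(0, i, j)] = (0, ip, jp)
                        cand = row1[jp] + cost
                        if cand < best1:
                            best1, pred1 = cand, (1, ip, jp)
            H0[i][j] = best0
            if best1 < INF:
                H1[i][j] = best1
                back[(1, i, j)] = pred1

    best_total = INF
    best_end: tuple[int, int] | None = None
    for i in range(m):
        for j in range(n):
            if H1[i][j] >= INF:
                continue
            total = H1[i][j] + _terminal_penalty(x[i], y[j], params)
            if total < best_total or (
                total == best_total
                and best_end is not None
                and (i, j) < best_end
            ):
                best_total, best_end = total, (i, j)
    if best_end is None:
        return None

    pairs: list[tuple[int, int]] = []
    node: tuple[int, int, int] | None = (1, *best_end)
    while node is not None:
        _, i, j = node
        pairs.append((i, j))
        node = back[node]
    pairs.reverse()
    mrna_positions = [j for _, j in pairs]
    return DuplexAlignment(
        pairs=tuple(pairs),
        dg_hybrid=best_total,
        site_interval=(min(mrna_positions), max(mrna_positions) + 1),
        pair_bases=tuple((x[i], y[j]) for i, j in pairs),
    )


def alignment_energy(
    mirna: str, mrna: str, pairs: tuple[tuple[int, int], ...], params: EnergyParameterSet
) -> float:
    """Recompute a duplex energy from its pair list (consistency oracle)."""
    x, y = normalize_rna(mirna), normalize_rna(mrna)
    if not pairs:
        raise ValueError("empty alignment")
    total = params.duplex_initiation
    total += _terminal_penalty(x[pairs[0][0]], y[pairs[0][1]], params)
    total += _terminal_penalty(x[pairs[-1][0]], y[pairs[-1][1]], params)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 <= i1 or j2 >= j1:
            raise ValueError("alignment pairs are not monotone")
        g1, g2 = i2 - i1 - 1, j1 - j2 - 1
        if g1 == 0 and g2 == 0:
            total += params.stack_table[(x[i1] + y[j1], x[i2] + y[j2])]
        elif g1 == 0 or g2 == 0:
            total += params.bulge_penalty[g1 + g2]
        else:
            total += params.internal_penalty[g1 + g2]
    return total


def seed_match(
    mirna: str, alignment: DuplexAlignment, mode: str = "human"
) -> tuple[bool, int]:
    """Check Watson-Crick seed pairing at miRNA nt 2-7 against an alignment.

    Human mode demands all six seed positions Watson-Crick paired; fly mode
    tolerates one GU wobble among them.  Returns ``(seed_ok, gu_count)``.
    """
    if mode not in ("human", "fly"):
        raise ValueError(f"seed mode must be 'human' or 'fly', got {mode!r}")
    x = normalize_rna(mirna, name="miRNA")
    if len(x) < 8:
        raise ValueError("miRNA shorter than 8 nt has no defined seed")
    bases = {i: (xb, yb) for (i, _), (xb, yb) in zip(alignment.pairs, alignment.pair_bases)}
    gu = 0
    ok = True
    for pos in _SEED_POSITIONS:
        if pos not in bases:
            return False, gu
        xb, yb = bases[pos]
        pair = xb + yb
        if pair in GU_PAIRS:
            gu += 1
        elif pair not in WC_PAIRS:
            ok = False
    if gu > (1 if mode == "fly" else 0):
        ok = False
    return ok, gu


def scan_candidate_sites(
    mirna: str,
    mrna: str,
    params: EnergyParameterSet,
    energy_cutoff: float = ENERGY_CUTOFF,
    suboptimal_increment: float = SUBOPTIMAL_INCREMENT,
    mode: str = "human",
    mirna_id: str = "mirna",
    mrna_id: str = "mrna",
) -> list[CandidateSite]:
    """Scan an mRNA for seed-matched duplex sites at or below the energy cutoff.

    Slides a window of miRNA length + :data:`WINDOW_EXTENSION` nt in 1-nt
    steps, takes the duplex MFE per window, keeps alignments with
    ``dg_hybrid <= energy_cutoff`` that also lie within
    ``suboptimal_increment`` of the best alignment on this mRNA, reduces
    overlapping alignments to the locally optimal one (lowest energy, ties to
    the smaller start), and finally applies the seed filter.  Results are
    sorted by hybridization energy, most stable first; mRNA coordinates are
    global (0-based half-open internally).
    """
    x = normalize_rna(mirna, name="miRNA")
    y = normalize_rna(mrna, name="mRNA")
    if len(y) < len(x):
        raise ValueError("mRNA shorter than miRNA")
    width = len(x) + WINDOW_EXTENSION
    starts = range(0, max(1, len(y) - width + 1))

    seen: dict[tuple[tuple[int, int], ...], DuplexAlignment] = {}
    for start in starts:
        window = y[start : start + width]
        aln = duplex_mfe(x, window, params, _validate_lengths=False)
        if aln is None:
            continue
        aln = aln.shifted(start)
        seen.setdefault(aln.pairs, aln)
    alignments = list(seen.values())
    if not alignments:
        return []

    best = min(a.dg_hybrid for a in alignments)
    retained = [
        a
        for a in alignments
        if a.dg_hybrid <= energy_cutoff and a.dg_hybrid <= best + suboptimal_increment
    ]
    # overlapping alignments collapse to the locally optimal one
    retained.sort(key=lambda a: (a.dg_hybrid, a.site_interval[0]))
    kept: list[DuplexAlignment] = []
    for aln in retained:
        lo, hi = aln.site_interval
        if any(lo < k_hi and k_lo < hi for (k_lo, k_hi) in (k.site_interval for k in kept)):
            continue
        kept.append(aln)

    sites = []
    for aln in kept:
        ok, gu = seed_match(x, aln, mode)
        if ok:
            sites.append(
                CandidateSite(
                    mirna_id=mirna_id,
                    mrna_id=mrna_id,
                    alignment=aln,
                    seed_ok=True,
                    seed_gu_count=gu,
                )
            )
    sites.sort(key=lambda s: (s.alignment.dg_hybrid, s.alignment.site_interval[0]))
    return sites
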