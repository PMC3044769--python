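"""Minimum-free-energy mRNA folding, with optional forced-unpaired constraints.

This is the accessibility stage of the two-step hybridization model: fold the
mRNA once unconstrained, once with the candidate target site forced
single-stranded, and take the difference.  That difference — the opening
energy — is the thermodynamic cost of exposing the site, and is always >= 0.

The engine is a Zuker-style dynamic program over pseudoknot-free secondary
structures under the simplified nearest-neighbor rule of
:mod:`mirneq.energy_params`: helix stacking energies, length-dependent
hairpin/bulge/internal-loop penalties (interior loops capped at 30 unpaired
nucleotides, the standard restriction), and a linear multiloop cost
``a + b*branches + c*unpaired``.  The minimum hairpin loop is 3 nt; lonely
pairs are allowed.  The open chain is the reference state at 0 kcal/mol, so a
sequence whose best structure would be destabilizing folds to nothing.

Folding-region policy for long messages: transcripts up to 6000 nt are folded
whole; longer ones only over their 3'UTR; 3'UTRs beyond 6000 nt are split into
overlapping ~4000-nt sections folded separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy_params import EnergyParameterSet, loop_penalty
from ._seq import normalize_rna

__all__ = [
    "FoldResult",
    "AccessibilityResult",
    "fold_mfe",
    "opening_energy",
    "select_fold_region",
    "structure_energy",
    "MAX_INTERIOR_LOOP",
    "MIN_HAIRPIN",
    "WHOLE_MRNA_LIMIT",
]

INF = float("inf")
MIN_HAIRPIN = 3
MAX_INTERIOR_LOOP = 30
#: transcripts at most this long are folded in their entirety
WHOLE_MRNA_LIMIT = 6000

_CANONICAL = {"AU", "UA", "CG", "GC", "GU", "UG"}


@dataclass(frozen=True)
class FoldResult:
    """MFE and structure of one folded window."""

    dg: float
    structure: str
    constrained_interval: tuple[int, int] | None = None


@dataclass(frozen=True)
class AccessibilityResult:
    """Unconstrained vs site-open folding energies and their difference."""

    dg_unconstrained: float
    dg_constrained: float
    dg_open: float
    region_used: str = "whole"


def _loop_tables(params: EnergyParameterSet, n: int):
    """Loop penalties as flat lists indexed by length, extrapolated to n."""
    hp = [INF] * (n + 1)
    bg = [INF] * (n + 1)
    il = [INF] * (n + 1)
    for length in range(1, n + 1):
        if length >= MIN_HAIRPIN:
            hp[length] = loop_penalty("hairpin", length, params)
        bg[length] = loop_penalty("bulge", length, params)
        il[length] = loop_penalty("internal", length, params)
    return hp, bg, il


def fold_mfe(
    seq: str,
    params: EnergyParameterSet,
    constraint: tuple[int, int] | None = None,
) -> FoldResult:
    """Fold ``seq`` to its MFE structure; ``constraint`` forces an interval unpaired.

    ``constraint`` is a 0-based half-open interval.  Returns the open chain at
    0 kcal/mol whenever no structure with negative free energy exists.
    """
    seq = normalize_rna(seq)
    n = len(seq)
    if n == 0:
        raise ValueError("cannot fold an empty sequence")
    if constraint is not None:
        lo, hi = constraint
        if not (0 <= lo <= hi <= n):
            raise ValueError(
                f"constraint {constraint} outside sequence of length {n}"
            )
    blocked = [False] * n
    if constraint is not None:
        for i in range(constraint[0], constraint[1]):
            blocked[i] = True

    stack = params.stack_table
    a_ml = params.multiloop_offset
    b_ml = params.multiloop_branch
    c_ml = params.multiloop_unpaired
    hp, bg, il = _loop_tables(params, max(n, MIN_HAIRPIN))

    # pairability matrix
    can = [[False] * n for _ in range(n)]
    for i in range(n):
        if blocked[i]:
            continue
        si = seq[i]
        for j in range(i + MIN_HAIRPIN + 1, n):
            if not blocked[j] and si + seq[j] in _CANONICAL:
                can[i][j] = True

    V = [[INF] * n for _ in range(n)]
    WM = [[INF] * n for _ in range(n)]

    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: structure closed by pair (i, j)
            if can[i][j]:
                best = hp[j - i - 1]
                pij = seq[i] + seq[j]
                # stack / bulge / interior loop to inner pair (k, l)
                kmax = min(i + MAX_INTERIOR_LOOP + 1, j - MIN_HAIRPIN - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    row = V[k]
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR_LOOP - n1))
                    for l in range(lmin, j):
                        inner = row[l]
                        if inner >= INF or not can[k][l]:
                            continue
                        n2 = j - l - 1
                        if n1 == 0 and n2 == 0:
                            cand = stack[(pij, seq[k] + seq[l])] + inner
                        elif n1 == 0 or n2 == 0:
                            cand = bg[n1 + n2] + inner
                        else:
                            cand = il[n1 + n2] + inner
                        if cand < best:
                            best = cand
                # multiloop: closing pair + >=2 interior branches
                if j - i >= 2 * (MIN_HAIRPIN + 2) + 1:
                    wmi = WM[i + 1]
                    base = a_ml + b_ml
                    for s in range(i + 1, j - 1):
                        left = wmi[s]
                        if left >= INF:
                            continue
                        right = WM[s + 1][j - 1]
                        if right >= INF:
                            continue
                        cand = base + left + right
                        if cand < best:
                            best = cand
                V[i][j] = best
            # --- WM: >=1 branch inside a multiloop on [i, j]
            best = WM[i][j - 1] + c_ml if j - 1 >= i else INF
            for k in range(i, j - MIN_HAIRPIN):
                vkj = V[k][j]
                if vkj >= INF:
                    continue
                if k == i:
                    prefix = 0.0
                else:
                    prefix = c_ml * (k - i)
                    wmik = WM[i][k - 1]
                    if wmik < prefix:
                        prefix = wmik
                cand = vkj + b_ml + prefix
                if cand < best:
                    best = cand
            WM[i][j] = best

    # exterior loop
    W = [0.0] * (n + 1)  # W[j] = MFE of prefix seq[:j]
    for j in range(1, n + 1):
        best = W[j - 1]
        for k in range(0, j - MIN_HAIRPIN - 1):
            vkj = V[k][j - 1]
            if vkj >= INF:
                continue
            cand = W[k] + vkj
            if cand < best:
                best = cand
        W[j] = best

    dg = W[n]
    if dg >= 0.0:
        return FoldResult(0.0, "." * n, constraint)

    # deterministic traceback (first case that reproduces the stored optimum)
    struct = ["."] * n
    agenda: list[tuple] = [("W", n)]
    eps = 1e-9
    while agenda:
        state = agenda.pop()
        if state[0] == "W":
            j = state[1]
            while j > 0:
                if abs(W[j] - W[j - 1]) <= eps and W[j - 1] <= W[j] + eps:
                    j -= 1
                    continue
                hit = False
                for k in range(0, j - MIN_HAIRPIN - 1):
                    vkj = V[k][j - 1]
                    if vkj < INF and abs(W[k] + vkj - W[j]) <= eps:
                        agenda.append(("V", k, j - 1))
                        j = k
                        hit = True
                        break
                if not hit:  # numerical safety; prefer unpaired
                    j -= 1
        elif state[0] == "V":
            _, i, j = state
            struct[i], struct[j] = "(", ")"
            target = V[i][j]
            if abs(hp[j - i - 1] - target) <= eps:
                continue
            pij = seq[i] + seq[j]
            found = False
            kmax = min(i + MAX_INTERIOR_LOOP + 1, j - MIN_HAIRPIN - 1)
            for k in range(i + 1, kmax + 1):
                if found:
                    break
                n1 = k - i - 1
                lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERIOR_LOOP - n1))
                for l in range(lmin, j):
                    if not can[k][l] or V[k][l] >= INF:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        cand = stack[(pij, seq[k] + seq[l])] + V[k][l]
                    elif n1 == 0 or n2 == 0:
                        cand = bg[n1 + n2] + V[k][l]
                    else:
                        cand = il[n1 + n2] + V[k][l]
                    if abs(cand - target) <= eps:
                        agenda.append(("V", k, l))
                        found = True
                        break
            if found:
                continue
            base = a_ml + b_ml
            for s in range(i + 1, j - 1):
                left = WM[i + 1][s]
                right = WM[s + 1][j - 1] if left < INF else INF
                if left < INF and right < INF and abs(base + left + right - target) <= eps:
                    agenda.append(("WM", i + 1, s))
                    agenda.append(("WM", s + 1, j - 1))
                    break
        else:  # WM
            _, i, j = state
            target = WM[i][j]
            if target >= INF:
                continue
            if j - 1 >= i and abs(WM[i][j - 1] + c_ml - target) <= eps:
                agenda.append(("WM", i, j - 1))
                continue
            for k in range(i, j - MIN_HAIRPIN):
                vkj = V[k][j]
                if vkj >= INF:
                    continue
                if k == i:
                    if abs(vkj + b_ml - target) <= eps:
                        agenda.append(("V", k, j))
                        break
                else:
                    if abs(vkj + b_ml + c_ml * (k - i) - target) <= eps:
                        agenda.append(("V", k, j))
                        break
                    wmik = WM[i][k - 1]
                    if wmik < INF and abs(vkj + b_ml + wmik - target) <= eps:
                        agenda.append(("WM", i, k - 1))
                        agenda.append(("V", k, j))
                        break

    return FoldResult(dg, "".join(struct), constraint)


def structure_energy(seq: str, structure: str, params: EnergyParameterSet) -> float:
    """Free energy (kcal/mol) of a given dot-bracket structure on ``seq``.

    Scores by loop decomposition under the same rule as :func:`fold_mfe`; used
    to verify that reported structures re-score to their reported energies.
    """
    seq = normalize_rna(seq)
    if len(structure) != len(seq):
        raise ValueError("structure and sequence lengths differ")
    pairs: dict[int, int] = {}
    opens: list[int] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            opens.append(idx)
        elif ch == ")":
            if not opens:
                raise ValueError("unbalanced structure string")
            i = opens.pop()
            pairs[i] = idx
            pairs[idx] = i
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if opens:
        raise ValueError("unbalanced structure string")

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in pairs:
                kids.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    # outermost pairs of the exterior loop seed the recursion
    outer = []
    k = 0
    n = len(seq)
    while k < n:
        if k in pairs and pairs[k] > k:
            outer.append((k, pairs[k]))
            k = pairs[k] + 1
        else:
            k += 1
    agenda = list(outer)
    while agenda:
        i, j = agenda.pop()
        if seq[i] + seq[j] not in _CANONICAL:
            raise ValueError(f"non-canonical pair {seq[i]}{seq[j]} at ({i},{j})")
        kids, unpaired = children(i, j)
        if not kids:
            total += loop_penalty("hairpin", j - i - 1, params)
        elif len(kids) == 1:
            k1, l1 = kids[0]
            n1, n2 = k1 - i - 1, j - l1 - 1
            if n1 == 0 and n2 == 0:
                total += params.stack_table[(seq[i] + seq[j], seq[k1] + seq[l1])]
            elif n1 == 0 or n2 == 0:
                total += loop_penalty("bulge", n1 + n2, params)
            else:
                total += loop_penalty("internal", n1 + n2, params)
        else:
            total += (
                params.multiloop_offset
                + params.multiloop_branch * (len(kids) + 1)
                + params.multiloop_unpaired * unpaired
            )
        agenda.extend(kids)
    return total


def opening_energy(
    seq: str,
    site_interval: tuple[int, int],
    params: EnergyParameterSet,
    region_used: str = "whole",
) -> AccessibilityResult:
    """Cost of forcing ``site_interval`` single-stranded in the folded mRNA."""
    unconstrained = fold_mfe(seq, params)
    constrained = fold_mfe(seq, params, constraint=site_interval)
    dg_open = constrained.dg - unconstrained.dg
    if dg_open < 0:
        raise AssertionError(
            "constrained MFE below unconstrained MFE — folding engine defect"
        )
    return AccessibilityResult(
        dg_unconstrained=unconstrained.dg,
        dg_constrained=constrained.dg,
        dg_open=dg_open,
        region_used=region_used,
    )


class FoldRegionError(ValueError):
    """Raised when the folding-region policy cannot be applied."""


def select_fold_region(
    mrna_length: int,
    utr_interval: tuple[int, int] | None = None,
    section_length: int = 4000,
    overlap: int = 200,
) -> list[tuple[int, int]]:
    """Choose the window(s) to fold, absolute mRNA coordinates (0-based half-open).

    Up to :data:`WHOLE_MRNA_LIMIT` nt the whole transcript is folded.  Longer
    transcripts fold only their 3'UTR (annotation required); 3'UTRs longer than
    the limit are split into ``section_length`` windows overlapping by
    ``overlap`` nt.
    """
    if mrna_length <= 0:
        raise ValueError("mRNA length must be positive")
    if utr_interval is not None:
        lo, hi = utr_interval
        if not (0 <= lo < hi <= mrna_length):
            raise ValueError(f"UTR interval {utr_interval} outside mRNA")
    if mrna_length <= WHOLE_MRNA_LIMIT:
        return [(0, mrna_length)]
    if utr_interval is None:
        raise FoldRegionError(
            f"mRNA of {mrna_length} nt exceeds {WHOLE_MRNA_LIMIT} nt: supply a "
            "3'UTR annotation (BED) so only the UTR is folded"
        )
    lo, hi = utr_interval
    if hi - lo <= WHOLE_MRNA_LIMIT:
        return [(lo, hi)]
    step = section_length - overlap
    if step <= 0:
        raise ValueError("section overlap must be smaller than section length")
    windows = []
    start = lo
    while True:
        end = min(start + section_length, hi)
        windows.append((start, end))
        if end >= hi:
            break
        start += step
    return windows
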