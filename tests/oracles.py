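"""Independent oracles for the test suite.

Everything here deliberately avoids the package's dynamic programs and solver
algebra: secondary structures and duplex alignments are enumerated
exhaustively and scored by direct loop decomposition; equilibria are solved
with 50-digit arithmetic straight from the quadratic; the ensemble free
energy is evaluated as the literal species sum.  The shared nearest-neighbor
parameter table is the single source of energy values for both sides.
"""

from __future__ import annotations

import mpmath as mp

from mirneq.energy_params import EnergyParameterSet, loop_penalty

CANONICAL = {"AU", "UA", "CG", "GC", "GU", "UG"}
TERMINAL_PENALIZED = {"AU", "UA", "GU", "UG"}
MIN_HAIRPIN = 3
MAX_INTERIOR_LOOP = 30
MAX_DUPLEX_LOOP = 15


# ---------------------------------------------------------------- folding

def enumerate_structures(seq: str, blocked: frozenset[int] = frozenset()):
    """Yield every pseudoknot-free pair set (tuples of (i, j)) on ``seq``."""
    n = len(seq)

    def rec(i: int, j: int):
        if i >= j:
            yield ()
            return
        for rest in rec(i + 1, j):
            yield rest
        if i in blocked:
            return
        for k in range(i + MIN_HAIRPIN + 1, j):
            if k in blocked or seq[i] + seq[k] not in CANONICAL:
                continue
            for inner in rec(i + 1, k):
                for outer in rec(k + 1, j):
                    yield ((i, k),) + inner + outer

    yield from rec(0, n)


def score_structure(seq: str, pairs, params: EnergyParameterSet) -> float:
    """Loop-decomposition energy of one pair set; +inf if the model forbids it."""
    pair_map = dict(pairs)
    pair_map.update({j: i for i, j in pairs})

    def direct_children(i: int, j: int):
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if k in pair_map and pair_map[k] > k:
                kids.append((k, pair_map[k]))
                k = pair_map[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    total = 0.0
    for i, j in pairs:
        kids, unpaired = direct_children(i, j)
        if not kids:
            total += loop_penalty("hairpin", j - i - 1, params)
        elif len(kids) == 1:
            (k, l), = kids
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += params.stack_table[(seq[i] + seq[j], seq[k] + seq[l])]
            elif n1 == 0 or n2 == 0:
                if n1 + n2 > MAX_INTERIOR_LOOP:
                    return float("inf")
                total += params.bulge_penalty[n1 + n2]
            else:
                if n1 + n2 > MAX_INTERIOR_LOOP:
                    return float("inf")
                total += params.internal_penalty[n1 + n2]
        else:
            total += (
                params.multiloop_offset
                + params.multiloop_branch * (len(kids) + 1)
                + params.multiloop_unpaired * unpaired
            )
    return total


def mfe_by_enumeration(
    seq: str,
    params: EnergyParameterSet,
    blocked: frozenset[int] = frozenset(),
) -> float:
    """Exhaustive MFE with the open chain (0 kcal/mol) as the floor."""
    best = 0.0
    for pairs in enumerate_structures(seq, blocked):
        e = score_structure(seq, pairs, params)
        if e < best:
            best = e
    return best


def mfe_structure_by_enumeration(seq, params, blocked=frozenset()):
    """(energy, pair set) of the exhaustive minimum (ties: first encountered)."""
    best, best_pairs = 0.0, ()
    for pairs in enumerate_structures(seq, blocked):
        e = score_structure(seq, pairs, params)
        if e < best:
            best, best_pairs = e, pairs
    return best, best_pairs


# ----------------------------------------------------------------- duplex

def enumerate_duplexes(x: str, y: str):
    """Yield every monotone (antiparallel, non-crossing) intermolecular pair set."""
    m, n = len(x), len(y)

    def rec(i0: int, j0: int):
        yield ()
        for i in range(i0, m):
            for j in range(j0, -1, -1):
                if x[i] + y[j] in CANONICAL:
                    for rest in rec(i + 1, j - 1):
                        yield ((i, j),) + rest

    yield from rec(0, n - 1)


def score_duplex(x: str, y: str, pairs, params: EnergyParameterSet) -> float:
    """Direct duplex energy; +inf if no stacked pair or a loop exceeds the cap."""
    if len(pairs) < 2:
        return float("inf")

    def terminal(i, j):
        return (
            params.terminal_au_penalty
            if x[i] + y[j] in TERMINAL_PENALIZED
            else 0.0
        )

    total = params.duplex_initiation + terminal(*pairs[0]) + terminal(*pairs[-1])
    stacked = False
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        g1, g2 = i2 - i1 - 1, j1 - j2 - 1
        if g1 == 0 and g2 == 0:
            total += params.stack_table[(x[i1] + y[j1], x[i2] + y[j2])]
            stacked = True
        elif g1 + g2 > MAX_DUPLEX_LOOP:
            return float("inf")
        elif g1 == 0 or g2 == 0:
            total += params.bulge_penalty[g1 + g2]
        else:
            total += params.internal_penalty[g1 + g2]
    return total if stacked else float("inf")


def duplex_mfe_by_enumeration(x, y, params):
    """Minimum duplex energy over exhaustive enumeration, or None."""
    best = float("inf")
    for pairs in enumerate_duplexes(x, y):
        e = score_duplex(x, y, pairs, params)
        if e < best:
            best = e
    return None if best == float("inf") else best


# ------------------------------------------------------------ equilibrium

def solve_equilibrium_mp(s0, t0, k, dps: int = 150):
    """(s, t, st) from the mass-action quadratic at ``dps`` decimal digits.

    The textbook small-root form is used directly; the working precision is
    generous enough (150 digits) that the discriminant subtraction is exact
    over the whole tested range of K and concentrations.
    """
    with mp.workdps(dps):
        s0m, t0m, km = mp.mpf(s0), mp.mpf(t0), mp.mpf(k)
        if s0m == 0 or t0m == 0:
            return float(s0m), float(t0m), 0.0
        b = s0m + t0m + 1 / km
        st = (b - mp.sqrt(b * b - 4 * s0m * t0m)) / 2
        return float(s0m - st), float(t0m - st), float(st)


def _ensemble_g(st, s0, t0, g_s, g_t, g_st, rt):
    """Total ensemble free energy at duplex concentration ``st`` (mpf, kcal/L)."""
    st_m = mp.mpf(st)
    s, t = mp.mpf(s0) - st_m, mp.mpf(t0) - st_m

    def mix(v):
        # v * (ln v - 1): ideal-dilute-solution entropy + molecule-count term
        return v * (mp.log(v) - 1) if v > 0 else mp.mpf(0)

    return (
        s * g_s + t * g_t + st_m * g_st + mp.mpf(rt) * (mix(s) + mix(t) + mix(st_m))
    )


def ensemble_g_mp(st, s0, t0, g_s, g_t, g_st, rt, dps: int = 150):
    with mp.workdps(dps):
        return float(_ensemble_g(st, s0, t0, g_s, g_t, g_st, rt))


def dg_net_mp(st, s0, t0, g_s, g_t, g_st, rt, dps: int = 150):
    """G(st) - G(0), the difference taken inside arbitrary precision."""
    with mp.workdps(dps):
        return float(
            _ensemble_g(st, s0, t0, g_s, g_t, g_st, rt)
            - _ensemble_g(0, s0, t0, g_s, g_t, g_st, rt)
        )
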