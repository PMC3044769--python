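"""MFE folding, constrained folding, opening energies, and the region policy."""

import numpy as np
import pytest

from conftest import random_rna
from oracles import mfe_by_enumeration
from mirneq import fold_mfe, opening_energy, select_fold_region, structure_energy
from mirneq.folding import FoldRegionError


def test_unpairable_sequence_is_open_chain(params):
    res = fold_mfe("AAAAAAAAAA", params)
    assert res.dg == 0.0
    assert res.structure == "." * 10


def test_simple_hairpin_energy_and_structure(params):
    res = fold_mfe("GGGAAAACCC", params)
    expected = 2 * params.stack_table[("GC", "GC")] + params.hairpin_penalty[4]
    assert expected < 0  # the helix must beat the loop for this check to bite
    assert res.dg == pytest.approx(expected, abs=1e-9)
    assert res.structure == "(((....)))"


def test_whole_sequence_constraint_forces_open_chain(params):
    seq = "GGGAAAACCCGGGAAAACCC"
    res = fold_mfe(seq, params, constraint=(0, len(seq)))
    assert res.dg == 0.0
    assert res.structure == "." * len(seq)


def test_constraint_outside_sequence_rejected(params):
    with pytest.raises(ValueError, match="constraint"):
        fold_mfe("GGGAAAACCC", params, constraint=(5, 20))


def test_dp_matches_enumeration_with_and_without_constraints(params):
    rng = np.random.default_rng(7)
    for trial in range(40):
        n = int(rng.integers(8, 22))
        seq = random_rna(rng, n)
        constraint = None
        blocked = frozenset()
        if trial % 3 == 0:
            lo = int(rng.integers(0, n - 3))
            hi = lo + int(rng.integers(1, 5))
            constraint = (lo, min(hi, n))
            blocked = frozenset(range(*constraint))
        res = fold_mfe(seq, params, constraint)
        assert res.dg == pytest.approx(mfe_by_enumeration(seq, params, blocked), abs=1e-9)
        # reported structure re-scores to the reported energy
        assert structure_energy(seq, res.structure, params) == pytest.approx(
            res.dg, abs=1e-9
        )
        if constraint is not None:
            assert set(res.structure[constraint[0] : constraint[1]]) <= {"."}


def test_folding_is_deterministic(params):
    seq = "GCGCGAAAGCGCGCAAAGCGC"
    first = fold_mfe(seq, params)
    for _ in range(3):
        again = fold_mfe(seq, params)
        assert again.structure == first.structure
        assert again.dg == first.dg


def test_opening_energy_zero_for_unstructured_site(params):
    acc = opening_energy("A" * 40, (10, 20), params)
    assert acc.dg_unconstrained == 0.0
    assert acc.dg_open == 0.0


def test_opening_energy_abolishes_lone_hairpin(params):
    seq = "GGGGGAAAACCCCC"
    unconstrained = fold_mfe(seq, params)
    assert unconstrained.dg < 0
    acc = opening_energy(seq, (0, 5), params)  # one strand of the only helix
    assert acc.dg_constrained == 0.0
    assert acc.dg_open == pytest.approx(-unconstrained.dg, abs=1e-9)


def test_opening_energy_nonnegative_and_monotone_in_interval(params):
    rng = np.random.default_rng(12)
    for _ in range(25):
        seq = random_rna(rng, int(rng.integers(20, 40)))
        lo = int(rng.integers(0, len(seq) - 6))
        small = (lo, lo + 3)
        large = (max(0, lo - 2), min(len(seq), lo + 8))
        a = opening_energy(seq, small, params)
        b = opening_energy(seq, large, params)
        assert a.dg_open >= 0
        assert b.dg_open >= a.dg_open - 1e-9


@pytest.mark.parametrize(
    "length,utr,expected",
    [
        (5000, (3000, 5000), [(0, 5000)]),          # short mRNA: fold whole
        (8000, (6000, 8000), [(6000, 8000)]),       # long mRNA: fold 3'UTR only
        (
            10000,
            (1000, 10000),
            [(1000, 5000), (4800, 8800), (8600, 10000)],  # 9000-nt UTR sections
        ),
    ],
)
def test_fold_region_policy(length, utr, expected):
    assert select_fold_region(length, utr) == expected


def test_long_mrna_without_utr_annotation_is_a_configuration_error():
    with pytest.raises(FoldRegionError, match="UTR"):
        select_fold_region(8000, None)
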