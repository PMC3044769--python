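"""Duplex MFE search, seed filtering, and the site scanner."""

import numpy as np
import pytest

from conftest import random_rna
from oracles import duplex_mfe_by_enumeration
from mirneq import (
    DuplexAlignment,
    alignment_energy,
    duplex_mfe,
    scan_candidate_sites,
    seed_match,
)
from mirneq.fixtures import FixtureSpec, make_fixture

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def test_no_complementarity_gives_no_duplex(params):
    assert duplex_mfe("A" * 16, "A" * 16, params) is None


def test_perfect_gc_duplex_is_sum_of_stacks_plus_initiation(params):
    aln = duplex_mfe("GGGGG", "ACCCCC", params, _validate_lengths=False)
    expected = 4 * params.stack_table[("GC", "GC")] + params.duplex_initiation
    assert aln is not None
    assert aln.dg_hybrid == pytest.approx(expected, abs=1e-9)
    assert aln.pairs == ((0, 5), (1, 4), (2, 3), (3, 2), (4, 1))


def test_alphabet_violation_rejected(params):
    with pytest.raises(ValueError, match="non-RNA"):
        duplex_mfe("GGGGGNGGGGGGGGG", "CCCCC", params)


def test_dp_matches_enumeration_on_random_pairs(params):
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(80):
        x = random_rna(rng, int(rng.integers(5, 13)))
        y = random_rna(rng, int(rng.integers(5, 13)))
        aln = duplex_mfe(x, y, params, _validate_lengths=False)
        oracle = duplex_mfe_by_enumeration(x, y, params)
        if aln is None:
            assert oracle is None
        else:
            assert aln.dg_hybrid == pytest.approx(oracle, abs=1e-9)
            # energy is recomputable from the pair list
            assert alignment_energy(x, y, aln.pairs, params) == pytest.approx(
                aln.dg_hybrid, abs=1e-9
            )
            checked += 1
    assert checked > 20


def _wc_alignment(mirna: str) -> DuplexAlignment:
    """Full reverse-complement alignment of a miRNA against its perfect site."""
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    L = len(mirna)
    pairs = tuple((i, L - 1 - i) for i in range(L))
    return DuplexAlignment(
        pairs=pairs,
        dg_hybrid=-30.0,
        site_interval=(0, L),
        pair_bases=tuple((b, comp[b]) for b in mirna),
    )


def test_seed_fully_watson_crick_passes_both_modes():
    aln = _wc_alignment(LET7)
    assert seed_match(LET7, aln, "human") == (True, 0)
    assert seed_match(LET7, aln, "fly") == (True, 0)


def test_one_gu_in_seed_fails_human_passes_fly():
    aln = _wc_alignment(LET7)
    bases = list(aln.pair_bases)
    assert LET7[1] == "G"
    bases[1] = ("G", "U")  # wobble opposite seed position 2
    aln = DuplexAlignment(aln.pairs, aln.dg_hybrid, aln.site_interval, tuple(bases))
    assert seed_match(LET7, aln, "human") == (False, 1)
    assert seed_match(LET7, aln, "fly") == (True, 1)


def test_two_gu_in_seed_fail_both_modes():
    aln = _wc_alignment(LET7)
    bases = list(aln.pair_bases)
    bases[1] = ("G", "U")
    bases[4] = ("U", "G")
    aln = DuplexAlignment(aln.pairs, aln.dg_hybrid, aln.site_interval, tuple(bases))
    assert seed_match(LET7, aln, "human") == (False, 2)
    assert seed_match(LET7, aln, "fly") == (False, 2)


def test_bulged_seed_position_fails_both_modes():
    aln = _wc_alignment(LET7)
    keep = [k for k, (i, _) in enumerate(aln.pairs) if i != 2]
    aln = DuplexAlignment(
        tuple(aln.pairs[k] for k in keep),
        aln.dg_hybrid,
        aln.site_interval,
        tuple(aln.pair_bases[k] for k in keep),
    )
    assert seed_match(LET7, aln, "human")[0] is False
    assert seed_match(LET7, aln, "fly")[0] is False


def test_short_mirna_has_no_defined_seed():
    with pytest.raises(ValueError, match="shorter than 8"):
        seed_match("UGAGGUA", _wc_alignment(LET7), "human")


def test_scan_recovers_planted_site_exactly(params):
    mirna, mrna, truth = make_fixture(FixtureSpec(rng_seed=11))
    sites = scan_candidate_sites(mirna, mrna, params)
    assert len(sites) == 1
    assert sites[0].alignment.site_interval == truth
    assert sites[0].seed_gu_count == 0


def test_scan_poly_a_mrna_is_empty(params):
    assert scan_candidate_sites("UGAGGUAGUAGGUUGUAUAGUU", "A" * 60, params) == []


def test_energy_cutoff_is_inclusive_boundary(params):
    mirna, mrna, _ = make_fixture(FixtureSpec(rng_seed=11))
    [site] = scan_candidate_sites(mirna, mrna, params)
    dg = site.alignment.dg_hybrid
    assert scan_candidate_sites(mirna, mrna, params, energy_cutoff=dg)
    # a cutoff just below the site's energy excludes it ("at most" semantics)
    assert not scan_candidate_sites(mirna, mrna, params, energy_cutoff=dg - 0.01)


def test_cutoff_filter_is_monotone(params):
    mirna, mrna, _ = make_fixture(FixtureSpec(rng_seed=13))
    loose = {
        s.alignment.site_interval
        for s in scan_candidate_sites(mirna, mrna, params, energy_cutoff=-8.5)
    }
    tight = {
        s.alignment.site_interval
        for s in scan_candidate_sites(mirna, mrna, params, energy_cutoff=-25.0)
    }
    assert tight <= loose


def test_scan_output_shifts_with_coordinate_offset(params):
    mirna, mrna, truth = make_fixture(FixtureSpec(rng_seed=17))
    offset = 23
    shifted = "A" * offset + mrna
    base = scan_candidate_sites(mirna, mrna, params)
    moved = scan_candidate_sites(mirna, shifted, params)
    assert [s.alignment.site_interval for s in moved] == [
        (lo + offset, hi + offset)
        for lo, hi in (s.alignment.site_interval for s in base)
    ]
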