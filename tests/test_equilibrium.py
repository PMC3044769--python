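"""Mass-action equilibrium solver and the net ensemble free energy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dg_net_mp, ensemble_g_mp, solve_equilibrium_mp
from mirneq import (
    ConcentrationPair,
    equilibrium_constant,
    net_free_energy,
    run_ensemble_batch,
    solve_equilibrium,
)


def test_equilibrium_constant_basics(params):
    assert equilibrium_constant(0.0, params) == pytest.approx(1.0)
    k = equilibrium_constant(-10.0, params)
    assert k == pytest.approx(math.exp(10.0 / params.rt), rel=1e-12)
    assert equilibrium_constant(10.0, params) == pytest.approx(1.0 / k, rel=1e-12)


def test_equilibrium_constant_clamps_extreme_exponents(params, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="mirneq.equilibrium"):
        k = equilibrium_constant(-1000.0, params)
    assert k == pytest.approx(math.exp(700.0))
    assert "clamped" in caplog.text


def test_nothing_to_bind_when_mirna_absent():
    state = solve_equilibrium(ConcentrationPair(0.0, 1e-6), 1e9)
    assert state.s == 0.0
    assert state.t == 1e-6
    assert state.st == 0.0
    assert state.fraction_mrna_bound == 0.0


def test_nonpositive_k_rejected():
    with pytest.raises(ValueError, match="equilibrium constant"):
        solve_equilibrium(ConcentrationPair(1e-6, 1e-6), 0.0)


def test_micromolar_worked_example_matches_oracle():
    state = solve_equilibrium(ConcentrationPair(1e-6, 1e-6), 1e7)
    s, t, st = solve_equilibrium_mp(1e-6, 1e-6, 1e7)
    assert state.st == pytest.approx(st, rel=1e-9)
    assert state.s == pytest.approx(s, rel=1e-9)
    assert state.st == pytest.approx(7.2984e-7, rel=1e-4)
    assert state.fraction_mrna_bound == pytest.approx(0.730, abs=5e-4)


def test_saturating_k_gives_complete_binding_without_cancellation():
    state = solve_equilibrium(ConcentrationPair(2e-6, 1e-6), 1e30)
    assert state.st == pytest.approx(1e-6, rel=1e-9)
    assert state.s == pytest.approx(1e-6, rel=1e-9)


def test_symmetric_concentrations_give_equal_free_strands():
    for k in (1e3, 1e7, 1e12):
        state = solve_equilibrium(ConcentrationPair(5e-7, 5e-7), k)
        assert abs(state.s - state.t) <= 1e-12 * 5e-7


def test_solver_matches_oracle_on_coarse_grid(params):
    for ddg in np.linspace(-30, 30, 7):
        k = equilibrium_constant(float(ddg), params)
        for s0 in np.logspace(-11, -5, 4):
            for t0 in np.logspace(-11, -5, 4):
                state = solve_equilibrium(ConcentrationPair(s0, t0), k)
                s, t, stv = solve_equilibrium_mp(s0, t0, k)
                assert state.s == pytest.approx(s, rel=1e-9)
                assert state.t == pytest.approx(t, rel=1e-9)
                assert state.st == pytest.approx(stv, rel=1e-9)


@settings(max_examples=60, derandomize=True)
@given(
    log_s0=st.floats(-12, -4),
    log_t0=st.floats(-12, -4),
    log_k=st.floats(0, 20),
    factor=st.floats(1.1, 10.0),
)
def test_bound_fraction_monotone_in_inputs(log_s0, log_t0, log_k, factor):
    s0, t0, k = 10.0**log_s0, 10.0**log_t0, 10.0**log_k
    base = solve_equilibrium(ConcentrationPair(s0, t0), k)
    more_mirna = solve_equilibrium(ConcentrationPair(s0 * factor, t0), k)
    stronger = solve_equilibrium(ConcentrationPair(s0, t0), k * factor)
    assert more_mirna.st >= base.st * (1 - 1e-12)
    assert more_mirna.fraction_mrna_bound >= base.fraction_mrna_bound * (1 - 1e-12)
    assert stronger.st >= base.st * (1 - 1e-12)
    more_mrna = solve_equilibrium(ConcentrationPair(s0, t0 * factor), k)
    assert more_mrna.st >= base.st * (1 - 1e-12)


def test_net_free_energy_zero_without_duplex(params):
    state = solve_equilibrium(ConcentrationPair(0.0, 1e-6), 1e9)
    assert net_free_energy(state, 0, -5, -15, ConcentrationPair(0.0, 1e-6), params) == 0.0


def test_net_free_energy_negative_with_duplex_and_matches_oracle(params):
    conc = ConcentrationPair(1e-6, 1e-6)
    k = equilibrium_constant(-10.0, params)
    state = solve_equilibrium(conc, k)
    dg = net_free_energy(state, 0.0, -5.0, -15.0, conc, params)
    assert dg < 0
    _, _, st = solve_equilibrium_mp(1e-6, 1e-6, k)
    assert dg == pytest.approx(
        dg_net_mp(st, 1e-6, 1e-6, 0.0, -5.0, -15.0, params.rt), rel=1e-9
    )
    # frozen from the arbitrary-precision oracle under the package's
    # dilute-solution free-energy functional
    assert dg == pytest.approx(-1.2126e-6, rel=1e-4)


def test_equilibrium_state_minimizes_ensemble_free_energy(params):
    conc = ConcentrationPair(2e-7, 8e-7)
    for ddg in (-15.0, -8.0, -2.0):
        k = equilibrium_constant(ddg, params)
        state = solve_equilibrium(conc, k)
        g_star = ensemble_g_mp(state.st, conc.s0, conc.t0, 0.0, 0.0, ddg, params.rt)
        for factor in (0.999, 1.001):
            st = state.st * factor
            if 0 < st <= min(conc.s0, conc.t0):
                assert (
                    ensemble_g_mp(st, conc.s0, conc.t0, 0.0, 0.0, ddg, params.rt)
                    >= g_star
                )


def test_ensemble_batch_round_trip(params, tmp_path):
    src = tmp_path / "in.tsv"
    out = tmp_path / "out.tsv"
    src.write_text("ddg\ts0\tt0\n-10\t1e-6\t1e-6\n-2\t1e-7\t1e-8\t-3.5\n")
    n = run_ensemble_batch(src, out, params)
    assert n == 2
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["ddg", "s0", "t0"]
    first = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
    assert float(first["fraction_mrna_bound"]) == pytest.approx(0.742, abs=2e-3)
    assert float(first["dg_net"]) < 0
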