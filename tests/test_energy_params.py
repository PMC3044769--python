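"""The shipped nearest-neighbor table and its accessors."""

import math

import pytest

from mirneq import (
    ParameterFileError,
    load_parameters,
    loop_penalty,
    stack_energy,
    write_parameters,
)
from mirneq.energy_params import CANONICAL_PAIRS, MAX_TABULATED_LOOP


def test_default_set_physical_constants(params):
    assert params.temperature == pytest.approx(310.15)
    assert params.gas_constant == pytest.approx(0.001987)
    assert params.rt == pytest.approx(0.001987 * 310.15)


def test_stack_table_complete_and_rotationally_symmetric(params):
    count = 0
    for p5 in CANONICAL_PAIRS:
        for p3 in CANONICAL_PAIRS:
            value = stack_energy(p5, p3, params)
            assert math.isfinite(value)
            # 5'-XY-3'/3'-ZW-5' read from the other strand is WZ/YX
            partner = stack_energy(p3[::-1], p5[::-1], params)
            assert value == pytest.approx(partner, abs=1e-12)
            count += 1
    assert count == 36


def test_stack_rejects_non_canonical_pair(params):
    with pytest.raises(ValueError, match="not a canonical base pair"):
        stack_energy("AC", "GC", params)


@pytest.mark.parametrize("kind", ["hairpin", "bulge", "internal"])
def test_loop_penalties_nonnegative_and_monotone_beyond_table(params, kind):
    start = 3 if kind == "hairpin" else 1
    for length in range(start, 120):
        assert loop_penalty(kind, length, params) >= 0
    # logarithmic extrapolation: continuous at the table edge, then increasing
    edge = loop_penalty(kind, MAX_TABULATED_LOOP, params)
    just_beyond = loop_penalty(kind, MAX_TABULATED_LOOP + 1, params)
    assert 0 < just_beyond - edge < 0.1
    assert loop_penalty(kind, 60, params) > loop_penalty(kind, 30, params)


def test_minimum_hairpin_loop_enforced(params):
    with pytest.raises(ValueError, match="hairpin"):
        loop_penalty("hairpin", 2, params)
    assert loop_penalty("bulge", 1, params) == params.bulge_penalty[1]


def test_round_trip_preserves_every_entry(params, tmp_path):
    out = tmp_path / "params.tsv"
    write_parameters(params, out)
    reloaded = load_parameters(out)
    assert reloaded.stack_table == dict(params.stack_table)
    assert reloaded.hairpin_penalty == dict(params.hairpin_penalty)
    assert reloaded.bulge_penalty == dict(params.bulge_penalty)
    assert reloaded.internal_penalty == dict(params.internal_penalty)
    assert reloaded.duplex_initiation == params.duplex_initiation
    assert reloaded.temperature == params.temperature
    assert reloaded.gas_constant == params.gas_constant


def test_missing_stack_row_is_reported(params, tmp_path):
    out = tmp_path / "broken.tsv"
    write_parameters(params, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("stack\tAA")]
    out.write_text("\n".join(lines) + "\n")
    with pytest.raises(ParameterFileError, match="stack table incomplete"):
        load_parameters(out)


def test_garbled_value_names_offending_row(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("stack\tAA/UU\tnot-a-number\n")
    with pytest.raises(ParameterFileError, match="bad.tsv:1"):
        load_parameters(bad)


def test_missing_file_raises_parameter_error():
    with pytest.raises(ParameterFileError, match="not found"):
        load_parameters("/nonexistent/params.tsv")


def test_temperature_change_leaves_tabulated_energies_untouched(params):
    from dataclasses import replace

    hot = replace(params, temperature=350.0)
    assert hot.stack_table == params.stack_table
    assert hot.rt > params.rt
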