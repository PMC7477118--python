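import numpy as np
import pytest

import xylemflow as xf
from xylemflow import ModelTier, PercentConvention
from xylemflow.sweeps import (
    SweepError,
    SweepSpec,
    default_sweep,
    efficiency_table,
    linear_fit,
    run_sweep,
)


def monotone(xs, direction):
    d = np.diff(xs)
    return np.all(d < 0) if direction == "dec" else np.all(d > 0)


TREND_DIRECTIONS = {
    "membrane_permeability": "dec",
    "inner_diameter": "dec",
    "pit_depth": "inc",
    "plate_height": "inc",
    "plate_width": "inc",
}


def test_resistance_trend_directions(sweep_results):
    for pname, direction in TREND_DIRECTIONS.items():
        _, rs = sweep_results[pname].resistances()
        assert monotone(rs, direction), pname


def test_plate_height_dominates_plate_width(sweep_results):
    def span(pname):
        _, rs = sweep_results[pname].resistances()
        return rs[-1] - rs[0]

    assert span("plate_height") > span("plate_width") > 0


def test_linearity_of_resistance_in_each_parameter(sweep_results):
    for pname, result in sweep_results.items():
        _, _, r2 = linear_fit(result)
        assert r2 >= 0.95, pname


def test_diameter_sweep_has_negative_slope(sweep_results):
    slope, _, _ = linear_fit(sweep_results["inner_diameter"])
    assert slope < 0


def test_efficiency_trend_directions(sweep_results):
    expectations = {
        "inner_diameter": "dec",
        "pit_depth": "inc",
        "membrane_permeability": "inc",
    }
    for pname, direction in expectations.items():
        eff = sweep_results[pname].efficiencies()
        series = [eff[v] for v in sorted(eff)]
        assert monotone(series, direction), pname
        assert all(e >= 0 for e in series)


def test_efficiency_identically_zero_at_zero_permeability(sweep_results):
    eff = sweep_results["membrane_permeability"].efficiencies()
    assert eff[0.0] == 0.0


def test_endpoint_percent_change_consistency(sweep_results):
    result = sweep_results["pit_depth"]
    _, rs = result.resistances()
    expected = (rs[-1] - rs[0]) / rs[0]
    assert result.endpoint_percent_change(PercentConvention.BASELINE) == expected


def test_rows_carry_full_parameter_snapshot(sweep_results):
    frame = sweep_results["inner_diameter"].frame()
    assert list(frame.value) == sorted(frame.value)
    assert (frame.param_pit_depth == 4.6).all()
    assert (frame.value == frame.param_inner_diameter).all()


def test_efficiency_table_shape(sweep_results):
    table = efficiency_table(
        {p: sweep_results[p]
         for p in ("inner_diameter", "pit_depth", "membrane_permeability")}
    )
    assert len(table) == 12
    perm0 = table[(table.parameter == "membrane_permeability")
                  & (table.value == 0.0)].iloc[0]
    assert perm0.r_with_radial_pa_s_m3 == perm0.r_axial_only_pa_s_m3


def test_sweep_output_is_byte_deterministic():
    spec = SweepSpec(
        parameter_name="plate_width", values=(2.0, 5.0),
        tier=ModelTier.FULL, mesh_level=0,
    ).validate()
    assert run_sweep(spec).to_csv() == run_sweep(spec).to_csv()


def test_per_value_failures_do_not_abort_sweep():
    spec = SweepSpec(
        parameter_name="plate_height", values=(2.0, 26.0), mesh_level=0,
    )
    result = run_sweep(spec)
    assert 26.0 in result.failures
    assert 2.0 in result.summaries


def test_all_values_failing_raises():
    spec = SweepSpec(parameter_name="plate_height", values=(26.0, 27.0))
    with pytest.raises(SweepError):
        run_sweep(spec)


def test_linear_fit_trivial_cases(sweep_results):
    result = sweep_results["plate_width"]
    vals, rs = result.resistances()
    fit = np.polyfit(vals, rs, 1)
    slope, intercept, r2 = linear_fit(result)
    assert slope == pytest.approx(fit[0], rel=1e-9)
    with pytest.raises(SweepError):
        linear_fit(
            run_sweep(SweepSpec(parameter_name="plate_width",
                                values=(2.0, 5.0), mesh_level=0))
        )


def test_unknown_parameter_rejected():
    with pytest.raises(SweepError):
        SweepSpec(parameter_name="pit_diameter", values=(8.0,)).validate()
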