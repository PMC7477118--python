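import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import xylemflow as xf
from xylemflow import ModelTier, PercentConvention, VesselParams
from xylemflow.hydraulics import (
    HydraulicsError,
    decompose,
    network_oracle,
    percent_change,
    radial_efficiency,
    resistance,
)

positive_r = st.floats(min_value=1e9, max_value=1e15)


# -- resistance --------------------------------------------------------

@pytest.mark.parametrize(
    "dp, q, expected",
    [
        (0.849, 7.093e-13, 1.197e12),   # tier-1 reference triple
        (1.021, 5.858e-13, 1.743e12),   # tier-2
        (1.059, 5.858e-13, 1.808e12),   # tier-3
    ],
)
def test_resistance_reproduces_reference_triples(dp, q, expected):
    assert resistance(dp, q) == pytest.approx(expected, rel=5e-4)


def test_resistance_zero_pressure_drop():
    assert resistance(0.0, 1e-13) == 0.0


def test_resistance_rejects_nonpositive_flux():
    with pytest.raises(HydraulicsError):
        resistance(1.0, 0.0)


# -- decomposition -----------------------------------------------------

def test_decomposition_of_reference_resistances():
    d = decompose(1.197e12, 1.743e12, 1.808e12)
    assert 100 * d.frac_smooth == pytest.approx(66.20, abs=0.05)
    assert 100 * d.frac_wall == pytest.approx(30.20, abs=0.05)
    assert 100 * d.frac_plate == pytest.approx(3.60, abs=0.05)


@pytest.mark.parametrize(
    "r123, fractions",
    [
        ((2.0, 2.0, 2.0), (1.0, 0.0, 0.0)),
        ((1.0, 2.0, 4.0), (0.25, 0.25, 0.5)),
    ],
)
def test_decomposition_hand_examples(r123, fractions):
    d = decompose(*r123)
    assert (d.frac_smooth, d.frac_wall, d.frac_plate) == fractions


def test_decomposition_warns_on_nonmonotone_tiers():
    with pytest.warns(UserWarning, match="not monotone"):
        d = decompose(2.0, 1.0, 3.0)
    assert d.r_wall < 0


def test_decomposition_rejects_nonpositive():
    with pytest.raises(HydraulicsError):
        decompose(0.0, 1.0, 2.0)


@given(r1=positive_r, dr2=positive_r, dr3=positive_r)
def test_decomposition_is_exact_bookkeeping(r1, dr2, dr3):
    r2, r3 = r1 + dr2, r1 + dr2 + dr3
    d = decompose(r1, r2, r3)
    assert d.r_smooth + d.r_wall + d.r_plate == pytest.approx(
        d.r_total, rel=1e-14
    )
    assert d.frac_smooth + d.frac_wall + d.frac_plate == pytest.approx(
        1.0, abs=1e-12
    )
    assert min(d.r_smooth, d.r_wall, d.r_plate) >= 0


# -- percent change ----------------------------------------------------

@pytest.mark.parametrize(
    "base, comp, conv, expected_pct",
    [
        (0.849, 1.021, PercentConvention.BASELINE, 20.26),
        (7.093e-13, 5.858e-13, PercentConvention.COMPARISON, -21.08),
        (1.197e12, 1.743e12, PercentConvention.BASELINE, 45.61),
        (1.021, 1.059, PercentConvention.BASELINE, 3.72),
    ],
)
def test_percent_change_reference_claims(base, comp, conv, expected_pct):
    assert 100 * percent_change(base, comp, conv) == pytest.approx(
        expected_pct, abs=0.005
    )


def test_percent_change_identity_is_zero():
    assert percent_change(3.14, 3.14, PercentConvention.BASELINE) == 0.0


def test_percent_change_zero_denominator():
    with pytest.raises(HydraulicsError):
        percent_change(0.0, 1.0, PercentConvention.BASELINE)


@given(st.floats(min_value=0.1, max_value=10),
       st.floats(min_value=0.1, max_value=10))
def test_percent_conventions_are_reciprocal(a, b):
    """Swapping the denominator convention rescales by −(a/b)."""
    pb = percent_change(a, b, PercentConvention.BASELINE)
    pc = percent_change(a, b, PercentConvention.COMPARISON)
    assert pb * a == pytest.approx(pc * b, rel=1e-12)


# -- radial efficiency -------------------------------------------------

@pytest.mark.parametrize(
    "r_with, r_axial, expected_pct",
    [
        (2.198e12, 2.234e12, 1.64),
        (1.942e12, 1.974e12, 1.65),
        (1.592e12, 1.615e12, 1.44),
        (1.162e12, 1.178e12, 1.38),
        (1.748e12, 1.837e12, 5.09),
    ],
)
def test_radial_efficiency_reference_pairs(r_with, r_axial, expected_pct):
    res = radial_efficiency(r_with, r_axial)
    assert 100 * res.efficiency == pytest.approx(expected_pct, abs=0.01)


def test_radial_efficiency_zero_at_equal_resistance():
    assert radial_efficiency(1.837e12, 1.837e12).efficiency == 0.0


def test_radial_efficiency_rejects_nonpositive():
    with pytest.raises(HydraulicsError):
        radial_efficiency(-1.0, 1.0)


# -- network oracle ----------------------------------------------------

def test_oracle_smooth_equals_hagen_poiseuille(default_params):
    expected = xf.hagen_poiseuille_resistance(250.0, 27.5, 1.003e-3)
    assert network_oracle(default_params, ModelTier.SMOOTH) == pytest.approx(
        expected
    )
    assert expected == pytest.approx(1.12e12, rel=0.01)


def test_oracle_limits(default_params):
    p0 = default_params.replace(plate_height=0.0)
    assert network_oracle(p0, ModelTier.FULL) == network_oracle(
        p0, ModelTier.WALL_THICKENING
    )
    sealed = default_params.replace(membrane_permeability=0.0)
    open_ = network_oracle(default_params, ModelTier.WALL_THICKENING)
    axial = network_oracle(sealed, ModelTier.WALL_THICKENING)
    assert axial > open_  # sealing removes the parallel pathway


def test_oracle_reproduces_all_sweep_trend_signs(default_params):
    """The closed form and the discretized solver must agree on every
    parameter-sweep direction."""
    base = network_oracle(default_params, ModelTier.FULL)

    def oracle_at(**changes):
        return network_oracle(
            default_params.replace(**changes), ModelTier.FULL
        )

    assert oracle_at(inner_diameter=61.0) < base < oracle_at(inner_diameter=52.0)
    assert oracle_at(pit_depth=2.6) < base < oracle_at(pit_depth=5.6)
    assert oracle_at(plate_height=2.0) < base < oracle_at(plate_height=5.0)
    assert oracle_at(plate_width=2.0) < base < oracle_at(plate_width=5.0)
    assert oracle_at(membrane_permeability=0.30) < base < oracle_at(
        membrane_permeability=0.0
    )


# -- reference report helpers -----------------------------------------

def test_reference_percent_change_table_reproduces_printed_values():
    from xylemflow.hydraulics import reference_percent_changes

    table = reference_percent_changes()
    for row in table.itertuples():
        if not row.reproducible:
            continue
        assert abs(row.recomputed_pct) == pytest.approx(
            abs(row.printed_pct), abs=row.tolerance_pp
        ), row.claim


def test_reference_efficiency_table_matches_printed_percentages():
    from xylemflow.hydraulics import reference_efficiency_table
    from xylemflow.reference import PRINTED_EFFICIENCIES_PCT

    table = reference_efficiency_table()
    for (pname, value), printed in PRINTED_EFFICIENCIES_PCT.items():
        row = table[(table.parameter == pname) & (table.value == value)]
        assert row.efficiency_pct.iloc[0] == pytest.approx(printed, abs=0.01)
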