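import pytest
from hypothesis import given
from hypothesis import strategies as st

import xylemflow as xf
from xylemflow.fixtures import (
    PARAMETER_RANGES,
    build_fixture_set,
    degenerate_cases,
    generate_params,
    reference_smooth_solution,
)


@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_generation_is_deterministic_per_seed(seed):
    assert generate_params(seed, 5) == generate_params(seed, 5)


def test_generated_sets_respect_anatomical_ranges():
    for p in generate_params(seed=1, n=50):
        for name, (lo, hi) in PARAMETER_RANGES.items():
            assert lo <= getattr(p, name) <= hi, name


def test_hundred_seeded_sets_all_validate():
    sets = generate_params(seed=7, n=100)
    assert len(sets) == 100  # .validate() already ran inside the generator


def test_generator_rejects_empty_request():
    with pytest.raises(ValueError):
        generate_params(seed=1, n=0)


def test_reference_solution_closed_form(default_params):
    dp, q, r = reference_smooth_solution(default_params)
    assert r == pytest.approx(1.12e12, rel=0.01)
    assert dp == pytest.approx(r * q)
    # r⁻⁴ radius scaling and linear length scaling
    _, _, r_wide = reference_smooth_solution(
        default_params.replace(inner_diameter=110.0, pit_depth=4.6)
    )
    assert r / r_wide == pytest.approx(16.0)
    _, _, r_half = reference_smooth_solution(
        default_params.replace(vessel_length=75.0)  # halves the total length
    )
    assert r_half == pytest.approx(r / 2)


def test_solver_agrees_with_bundled_reference():
    """Any fixture smooth case matches its closed-form triple within 2 %."""
    params = generate_params(seed=3, n=1)[0]
    _, q_ref, r_ref = reference_smooth_solution(params)
    g = xf.build_vessel_geometry(params, xf.ModelTier.SMOOTH)
    mesh = xf.generate_mesh(g, 1)
    s = xf.summarize_flow(xf.solve_flow(mesh), mesh)
    assert s.flux == pytest.approx(q_ref, rel=1e-6)
    assert s.resistance == pytest.approx(r_ref, rel=0.02)


def test_degenerate_cases_flow_through_the_pipeline():
    for name, params in degenerate_cases().items():
        g = xf.build_vessel_geometry(params, xf.ModelTier.FULL)
        mesh = xf.generate_mesh(g, 0)
        s = xf.summarize_flow(xf.solve_flow(mesh), mesh)
        assert s.resistance > 0, name


def test_fixture_set_bundle():
    fs = build_fixture_set(seed=11, n=4)
    assert fs.seed == 11 and len(fs.parameter_sets) == 4
    frame = fs.references_frame()
    assert len(frame) == 4
    assert (frame.resistance_pa_s_m3 > 0).all()
    for _, dp, q, r in fs.reference_solutions:
        assert dp == pytest.approx(r * q)
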