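import dataclasses
import math

import numpy as np
import pytest

import xylemflow as xf
from xylemflow import BoundaryConditions, ModelTier, SolverConfig, VesselParams
from xylemflow.solver import InfeasibleDomainError, SolverError


def test_continuity_satisfied_cellwise(tier_solutions):
    for _, field, _ in tier_solutions.values():
        assert field.continuity_residual < 1e-6
        assert field.converged


def test_global_mass_conservation(tier_solutions):
    for _, _, summary in tier_solutions.values():
        assert summary.mass_balance_error < 1e-3


def test_axial_velocity_profile_is_poiseuille(smooth_converged):
    """Mid-length profile matches u(r) = 2·u_mean·(1 − (r/R)²) within 1 %."""
    mesh, field, _ = smooth_converged
    p = mesh.geometry.params
    r, uz = field.axial_profile(p.total_length / 2)
    R = p.lumen_radius
    u_mean = field.bc.inlet_velocity
    analytic = 2 * u_mean * (1 - (r / R) ** 2)
    assert np.max(np.abs(uz - analytic)) < 0.01 * 2 * u_mean


def test_smooth_pressure_drop_matches_hagen_poiseuille(smooth_converged):
    mesh, _, summary = smooth_converged
    p = mesh.geometry.params
    q = summary.flux
    mu = 1.003e-3
    r = p.lumen_radius * 1e-6
    dp_hp = 8 * mu * (p.total_length * 1e-6) * q / (math.pi * r**4)
    assert summary.pressure_drop == pytest.approx(dp_hp, rel=0.02)


def test_pressure_drop_linear_in_inlet_velocity(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.SMOOTH)
    mesh = xf.generate_mesh(g, 0)
    s1 = xf.summarize_flow(xf.solve_flow(mesh), mesh)
    bc2 = BoundaryConditions(inlet_velocity=6.0e-4)
    s2 = xf.summarize_flow(xf.solve_flow(mesh, bc2), mesh)
    assert s2.pressure_drop == pytest.approx(2 * s1.pressure_drop, rel=0.005)


def test_pressure_monotone_along_axis_for_smooth(tier_solutions):
    _, field, _ = tier_solutions[ModelTier.SMOOTH]
    centerline = field.p[:, 0]
    assert np.all(np.diff(centerline) < 1e-12)


def test_tier_resistance_ordering(tier_solutions):
    r = {t: s.resistance for t, (_, _, s) in tier_solutions.items()}
    assert r[ModelTier.SMOOTH] < r[ModelTier.WALL_THICKENING] < r[ModelTier.FULL]


def test_maximum_velocity_sits_in_the_plate_region(tier_solutions):
    _, field, _ = tier_solutions[ModelTier.FULL]
    assert field.max_speed_region() == "plate"


def test_pit_cavity_fluid_is_nearly_stagnant(tier_solutions):
    _, field, _ = tier_solutions[ModelTier.WALL_THICKENING]
    ratio = field.region_mean_speed("cavity") / field.region_mean_speed("lumen")
    assert ratio < 0.05


def test_membrane_efflux_direction_and_sealing(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.WALL_THICKENING)
    mesh = xf.generate_mesh(g, 0)
    open_ = xf.summarize_flow(xf.solve_flow(mesh), mesh)
    assert open_.flux_membrane > 0
    sealed = xf.summarize_flow(
        xf.solve_flow(mesh, config=SolverConfig(seal_membrane=True)), mesh
    )
    assert sealed.flux_membrane == 0.0
    # sealing the membrane raises the total resistance
    assert sealed.resistance > open_.resistance


def test_resistance_decreases_with_membrane_permeability(default_params):
    """More open membrane area → lower total resistance on the same mesh."""
    rs = []
    for phi in (0.15, 0.30):
        p = default_params.replace(membrane_permeability=phi)
        g = xf.build_vessel_geometry(p, ModelTier.WALL_THICKENING)
        mesh = xf.generate_mesh(g, 0)
        rs.append(xf.summarize_flow(xf.solve_flow(mesh), mesh).resistance)
    assert rs[1] < rs[0]


def test_orifice_conductance_matches_sampson_law():
    """A lone circular orifice reproduces Q = a³Δp/(3µ) (plus the finite
    thickness Poiseuille term) within 15 % on a locally refined mesh."""
    a, t = 2.0, 1.0  # hole radius / plate thickness, µm
    params = VesselParams(
        inner_diameter=40.0, vessel_length=40.0, extension_length=20.0,
        pit_depth=0.5, pit_rows=0, membrane_permeability=0.0,
        plate_width=t, plate_height=19.5 - a,
    ).validate()
    rs = {}
    for tier in (ModelTier.WALL_THICKENING, ModelTier.FULL):
        g = xf.build_vessel_geometry(params, tier)
        mesh = xf.generate_mesh(g, 2)
        rs[tier] = xf.summarize_flow(xf.solve_flow(mesh), mesh).resistance
    r_orifice = rs[ModelTier.FULL] - rs[ModelTier.WALL_THICKENING]
    expected = xf.sampson_pore_resistance(a, t, 1.003e-3)
    assert r_orifice == pytest.approx(expected, rel=0.15)


def test_uniform_inlet_profile_carries_entrance_excess(default_params):
    """The plug profile develops inside the extension and costs extra Δp."""
    g = xf.build_vessel_geometry(default_params, ModelTier.SMOOTH)
    mesh = xf.generate_mesh(g, 0)
    parabolic = xf.summarize_flow(xf.solve_flow(mesh), mesh)
    plug = xf.summarize_flow(
        xf.solve_flow(mesh, BoundaryConditions(inlet_profile="uniform")), mesh
    )
    assert plug.pressure_drop > parabolic.pressure_drop
    assert plug.flux == pytest.approx(parabolic.flux, rel=1e-9)
    # the vessel-proper drop is development-free and agrees between the two
    assert plug.pressure_drop_vessel == pytest.approx(
        parabolic.pressure_drop_vessel, rel=0.01
    )


def test_summary_resistance_is_exact_quotient(tier_solutions):
    for _, _, s in tier_solutions.values():
        assert s.resistance == s.pressure_drop / s.flux


def test_summarize_refuses_unconverged_field(tier_solutions):
    mesh, field, _ = tier_solutions[ModelTier.SMOOTH]
    broken = dataclasses.replace(field, converged=False)
    with pytest.raises(SolverError, match="unconverged"):
        xf.summarize_flow(broken, mesh)


def test_fully_blocked_domain_is_infeasible(default_params):
    p = default_params.replace(membrane_permeability=0.0)
    g = xf.build_vessel_geometry(p, ModelTier.WALL_THICKENING)
    mesh = xf.generate_mesh(g, 0)
    mesh.fluid[mesh.nz // 2, :] = False  # wall off the lumen entirely
    with pytest.raises(InfeasibleDomainError):
        xf.solve_flow(mesh)


def test_solver_is_deterministic(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.WALL_THICKENING)
    mesh = xf.generate_mesh(g, 0)
    f1 = xf.solve_flow(mesh)
    f2 = xf.solve_flow(mesh)
    assert np.array_equal(f1.u, f2.u)
    assert np.array_equal(f1.v, f2.v)
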