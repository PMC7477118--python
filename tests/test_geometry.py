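import math

import pytest

import xylemflow as xf
from xylemflow import ModelTier, Reduction, VesselParams
from xylemflow.geometry import membrane_pore_layout, pit_axial_positions
from xylemflow.params import ParameterError


def build(params, tier):
    return xf.build_vessel_geometry(params, tier)


def test_smooth_tier_has_no_pit_or_plate_features(default_params):
    g = build(default_params, ModelTier.SMOOTH)
    assert not g.solid_boxes and not g.carve_boxes
    assert not g.membrane_segments and not g.pit_placements
    assert g.plate_span is None
    assert "pit_cavity_wall" not in g.boundary_patches
    assert "plate_wall" not in g.boundary_patches
    assert g.lumen_radius == default_params.inner_diameter / 2


def test_full_tier_plate_constriction(default_params):
    g = build(default_params, ModelTier.FULL)
    z0, z1 = g.plate_span
    assert z1 - z0 == pytest.approx(default_params.plate_width)
    assert g.plate_inner_radius == pytest.approx(
        g.lumen_radius - default_params.plate_height
    )
    assert "plate_wall" in g.boundary_patches


def test_feature_sets_nest_across_tiers(default_params):
    """Each tier's features are contained in the next tier's feature set."""
    gs = build(default_params, ModelTier.SMOOTH)
    gw = build(default_params, ModelTier.WALL_THICKENING)
    gf = build(default_params, ModelTier.FULL)
    assert gs.boundary_patches <= gw.boundary_patches <= gf.boundary_patches
    assert set(gw.solid_boxes) <= set(gf.solid_boxes)
    # dropped rows aside, surviving full-tier pits coincide with tier-2 pits
    assert set(gf.pit_placements) <= set(gw.pit_placements)
    assert set(gf.dropped_pits) | set(gf.pit_placements) == set(gw.pit_placements)
    # extension/end-plane extent identical across tiers
    assert gs.total_length == gw.total_length == gf.total_length == 250.0


def test_pit_count_matches_spacing_rule(default_params):
    p = default_params
    pitch = p.pit_diameter + p.pit_axial_spacing
    expected = math.floor(p.vessel_length / pitch)
    positions = pit_axial_positions(p)
    assert len(positions) == expected == 12
    g = build(p, ModelTier.WALL_THICKENING)
    assert len(g.pit_placements) == expected


def test_pit_placements_strictly_inside_vessel(default_params):
    p = default_params
    lo = p.extension_length
    hi = p.extension_length + p.vessel_length
    for c in pit_axial_positions(p):
        assert lo < c - p.pit_diameter / 2
        assert c + p.pit_diameter / 2 < hi


def test_explicit_pit_rows_override():
    p = VesselParams(pit_rows=3)
    assert len(pit_axial_positions(p)) == 3
    assert pit_axial_positions(VesselParams(pit_rows=0)) == []


def test_geometry_is_deterministic(default_params):
    a = build(default_params, ModelTier.FULL)
    b = build(default_params, ModelTier.FULL)
    assert a == b


def test_invalid_params_rejected_with_field_name():
    with pytest.raises(ParameterError) as err:
        build(VesselParams(pit_aperture=10.0), ModelTier.SMOOTH)
    assert err.value.field_name == "pit_aperture"


@pytest.mark.parametrize(
    "phi, expected",
    [(0.0, 0.0), (0.15, 0.15), (0.30, 0.30)],
)
def test_membrane_pore_layout_open_fraction(default_params, phi, expected):
    layout = membrane_pore_layout(
        default_params.replace(membrane_permeability=phi)
    )
    assert layout.achieved_open_fraction == pytest.approx(expected, abs=0.01)
    if phi == 0.0:
        assert layout.pore_count == 0


def test_membrane_pore_layout_rejects_bad_fraction(default_params):
    with pytest.raises(ParameterError):
        membrane_pore_layout(
            default_params.replace(membrane_permeability=-0.05)
        )


def test_plate_plane_open_area_is_reduced_annulus(default_params):
    """Cross-section at the plate equals the thickened lumen disc minus
    the annular plate profile."""
    g = build(default_params, ModelTier.FULL)
    open_area = math.pi * g.plate_inner_radius**2
    full_area = math.pi * g.lumen_radius**2
    ring = math.pi * (g.lumen_radius**2 - g.plate_inner_radius**2)
    assert open_area + ring == pytest.approx(full_area)


def test_vanishing_plate_converges_to_wall_thickening(default_params):
    p = default_params.replace(plate_height=0.0)
    gf = build(p, ModelTier.FULL)
    gw = build(p, ModelTier.WALL_THICKENING)
    assert gf.solid_boxes == gw.solid_boxes
    assert gf.carve_boxes == gw.carve_boxes
    assert gf.plate_span is None


def test_sector_3d_geometry_described_but_not_meshed(default_params):
    g = xf.build_vessel_geometry(
        default_params, ModelTier.WALL_THICKENING, Reduction.SECTOR_3D
    )
    assert g.azimuthal_pit_count > 0
    assert 0 < g.circumferential_open_fraction <= 1
    with pytest.raises(NotImplementedError):
        xf.generate_mesh(g, 0)
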