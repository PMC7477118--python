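import math

import numpy as np
import pytest

import xylemflow as xf
from xylemflow import ModelTier
from xylemflow.mesh import MeshSizing, RefinementError


def test_smooth_mesh_volume_matches_cylinder(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.SMOOTH)
    mesh = xf.generate_mesh(g, 0)
    r = default_params.lumen_radius
    exact = math.pi * r**2 * default_params.total_length
    assert mesh.fluid_volume() == pytest.approx(exact, rel=0.005)


def test_cell_count_strictly_increases_with_level(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.FULL)
    counts = [xf.generate_mesh(g, lvl).cells for lvl in (0, 1, 2)]
    assert counts[0] < counts[1] < counts[2]


def test_membrane_adjacent_cells_resolve_membrane_thickness(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.WALL_THICKENING)
    for lvl in (0, 1):
        mesh = xf.generate_mesh(g, lvl)
        assert mesh.min_membrane_adjacent_size() <= default_params.membrane_thickness


def test_geometry_quantities_positive(default_params):
    mesh = xf.generate_mesh(
        xf.build_vessel_geometry(default_params, ModelTier.FULL), 0
    )
    assert np.all(mesh.cell_volumes() > 0)
    assert np.all(np.diff(mesh.z_edges) > 0)
    assert np.all(np.diff(mesh.r_edges) > 0)
    big, small = mesh.characteristic_sizes
    assert 0 < small <= big


def test_each_boundary_face_has_exactly_one_patch_label(default_params):
    mesh = xf.generate_mesh(
        xf.build_vessel_geometry(default_params, ModelTier.FULL), 0
    )
    seen = set()
    for faces in mesh.patch_faces.values():
        for face in faces:
            assert face not in seen
            seen.add(face)


def test_patch_areas_stable_under_refinement(default_params):
    """Patch boundary area is a geometric quantity: refinement cannot move it."""
    g = xf.build_vessel_geometry(default_params, ModelTier.FULL)
    a0 = xf.generate_mesh(g, 0).patch_areas()
    a1 = xf.generate_mesh(g, 1).patch_areas()
    for name, area in a0.items():
        assert a1[name] == pytest.approx(area, rel=0.005), name


def test_unresolvable_aperture_raises_named_error(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.WALL_THICKENING)
    with pytest.raises(RefinementError, match="aperture"):
        xf.generate_mesh(g, 0, MeshSizing(aperture_cells=1))


def test_grid_independence_smooth_converges(grid_report_smooth):
    report = grid_report_smooth
    assert report.converged
    assert report.final_relative_change < 0.005
    assert report.production_level is not None
    assert report.cell_counts == sorted(report.cell_counts)


def test_grid_independence_identical_level_changes_nothing(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.SMOOTH)
    report = xf.grid_independence_study(g, [0, 0])
    assert report.final_relative_change == 0.0
    assert report.converged


def test_grid_study_needs_two_levels(default_params):
    g = xf.build_vessel_geometry(default_params, ModelTier.SMOOTH)
    with pytest.raises(ValueError):
        xf.grid_independence_study(g, [0])
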