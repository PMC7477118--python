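import pytest
from hypothesis import settings

import xylemflow as xf
from xylemflow.sweeps import default_sweep, run_sweep

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return xf.default_jatropha_params()


@pytest.fixture(scope="session")
def tier_solutions(default_params):
    """Coarse-mesh solve of each model tier: tier → (mesh, field, summary)."""
    out = {}
    for tier in xf.ModelTier:
        geometry = xf.build_vessel_geometry(default_params, tier)
        mesh = xf.generate_mesh(geometry, 0)
        field = xf.solve_flow(mesh)
        out[tier] = (mesh, field, xf.summarize_flow(field, mesh))
    return out


@pytest.fixture(scope="session")
def smooth_converged(default_params):
    """Smooth tier at a grid-independent refinement level."""
    geometry = xf.build_vessel_geometry(default_params, xf.ModelTier.SMOOTH)
    mesh = xf.generate_mesh(geometry, 2)
    field = xf.solve_flow(mesh)
    return mesh, field, xf.summarize_flow(field, mesh)


@pytest.fixture(scope="session")
def sweep_results():
    """The five coarse-mesh parameter sweeps (efficiency where relevant)."""
    out = {}
    for pname in ("membrane_permeability", "inner_diameter", "pit_depth",
                  "plate_height", "plate_width"):
        eff = pname in ("membrane_permeability", "inner_diameter", "pit_depth")
        out[pname] = run_sweep(default_sweep(pname, compute_efficiency=eff))
    return out


@pytest.fixture(scope="session")
def grid_report_smooth(default_params):
    geometry = xf.build_vessel_geometry(default_params, xf.ModelTier.SMOOTH)
    return xf.grid_independence_study(geometry, [0, 1, 2, 3])
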