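"""One-parameter sweep orchestration: geometry → mesh → solve → reduce.

Each sweep varies exactly one anatomical parameter over an ordered grid
(defaults are the published four-value grids, endpoints included), solving
the full pipeline at every value.  When radial-transmission efficiency is
requested, each value is solved twice on the *same* mesh — once with the
stated membrane permeability and once with the membranes sealed — so the
efficiency difference is never contaminated by meshing differences.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ModelTier, Reduction, build_vessel_geometry
from .hydraulics import (
    PercentConvention,
    decompose,
    percent_change,
    radial_efficiency,
)
from .mesh import MeshSizing, generate_mesh
from .params import (
    BoundaryConditions,
    FluidProperties,
    SolverConfig,
    VesselParams,
)
from .solver import FlowSummary, solve_flow, summarize_flow

logger = logging.getLogger(__name__)

SWEEPABLE = (
    "membrane_permeability",
    "inner_diameter",
    "pit_depth",
    "plate_height",
    "plate_width",
)

#: documented default ranges of the five sweeps
DEFAULT_RANGES = {
    "membrane_permeability": (0.0, 0.30),
    "inner_diameter": (52.0, 61.0),
    "pit_depth": (2.6, 5.6),
    "plate_height": (2.0, 5.0),
    "plate_width": (2.0, 5.0),
}


class SweepError(RuntimeError):
    pass


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of a one-parameter sweep."""

    parameter_name: str
    values: tuple[float, ...]
    base_params: VesselParams = field(default_factory=VesselParams)
    tier: ModelTier = ModelTier.FULL
    mesh_level: int = 0
    compute_efficiency: bool = False
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    config: SolverConfig = field(default_factory=SolverConfig)
    sizing: MeshSizing | None = None

    def validate(self) -> "SweepSpec":
        if self.parameter_name not in SWEEPABLE:
            raise SweepError(
                f"parameter {self.parameter_name!r} is not sweepable; "
                f"choose one of {SWEEPABLE}"
            )
        if len(self.values) == 0:
            raise SweepError("sweep needs at least one value")
        lo, hi = DEFAULT_RANGES[self.parameter_name]
        for v in self.values:
            if not lo <= v <= hi:
                logger.warning(
                    "sweep value %s for %s lies outside the documented "
                    "range [%s, %s]", v, self.parameter_name, lo, hi,
                )
        self.base_params.validate()
        return self

    def params_at(self, value: float) -> VesselParams:
        return self.base_params.replace(**{self.parameter_name: value})


def default_sweep(
    parameter_name: str,
    compute_efficiency: bool = False,
    **kwargs,
) -> SweepSpec:
    """A sweep over the published four-value grid of one parameter."""
    from .reference import SWEEP_GRIDS

    return SweepSpec(
        parameter_name=parameter_name,
        values=tuple(SWEEP_GRIDS[parameter_name]),
        compute_efficiency=compute_efficiency,
        **kwargs,
    ).validate()


@dataclass
class SweepResult:
    """Per-value flow summaries plus derived quantities."""

    spec: SweepSpec
    summaries: dict[float, FlowSummary]
    axial_only: dict[float, FlowSummary]  # empty unless efficiency requested
    failures: dict[float, str]

    # -- tabular view --------------------------------------------------
    def frame(self) -> pd.DataFrame:
        rows = []
        for v in self.spec.values:
            if v in self.failures:
                continue
            s = self.summaries[v]
            row = {"parameter": self.spec.parameter_name, "value": v}
            row.update(s.to_dict())
            if v in self.axial_only:
                res = radial_efficiency(
                    s.resistance, self.axial_only[v].resistance
                )
                row["resistance_axial_only_pa_s_m3"] = res.r_axial_only
                row["radial_efficiency"] = res.efficiency
            rows.append(row)
        return pd.DataFrame(rows)

    def resistances(self) -> tuple[np.ndarray, np.ndarray]:
        vals = [v for v in self.spec.values if v not in self.failures]
        return (
            np.array(vals),
            np.array([self.summaries[v].resistance for v in vals]),
        )

    def efficiencies(self) -> dict[float, float]:
        out = {}
        for v, s in self.summaries.items():
            if v in self.axial_only:
                out[v] = radial_efficiency(
                    s.resistance, self.axial_only[v].resistance
                ).efficiency
        return out

    def endpoint_percent_change(
        self, convention: PercentConvention = PercentConvention.BASELINE
    ) -> float:
        vals, rs = self.resistances()
        if len(rs) < 2:
            raise SweepError("need at least two successful values")
        return percent_change(rs[0], rs[-1], convention)

    def to_csv(self) -> str:
        """Deterministic CSV serialization (stable byte output)."""
        buf = _io.StringIO()
        self.frame().to_csv(buf, index=False, float_format="%.12e",
                            lineterminator="\n")
        return buf.getvalue()


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Execute a sweep; per-value failures are recorded, not fatal."""
    spec.validate()
    summaries: dict[float, FlowSummary] = {}
    axial: dict[float, FlowSummary] = {}
    failures: dict[float, str] = {}
    for v in spec.values:
        try:
            params = spec.params_at(v).validate()
            geometry = build_vessel_geometry(params, spec.tier)
            mesh = generate_mesh(geometry, spec.mesh_level, spec.sizing)
            field_ = solve_flow(mesh, spec.bc, spec.fluid, spec.config)
            summaries[v] = summarize_flow(field_, mesh)
            if spec.compute_efficiency:
                sealed_cfg = replace(spec.config, seal_membrane=True)
                field0 = solve_flow(mesh, spec.bc, spec.fluid, sealed_cfg)
                axial[v] = summarize_flow(field0, mesh)
        except Exception as exc:  # noqa: BLE001 - per-value bookkeeping
            logger.error("sweep %s=%s failed: %s", spec.parameter_name, v, exc)
            failures[v] = f"{type(exc).__name__}: {exc}"
    if not summaries:
        raise SweepError(
            f"all values of the {spec.parameter_name} sweep failed: {failures}"
        )
    return SweepResult(spec=spec, summaries=summaries, axial_only=axial,
                       failures=failures)


def linear_fit(result: SweepResult) -> tuple[float, float, float]:
    """Ordinary least squares of resistance on the swept value.

    Returns (slope, intercept, r²).  Refuses fewer than three points.
    """
    vals, rs = result.resistances()
    if len(vals) < 3:
        raise SweepError("linear fit needs at least three successful values")
    if np.allclose(rs, rs[0]):
        return 0.0, float(rs[0]), 1.0
    fit = stats.linregress(vals, rs)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def efficiency_table(results: dict[str, SweepResult]) -> pd.DataFrame:
    """Paired (R_with_radial, R_axial_only, efficiency) rows per parameter."""
    rows = []
    for pname, result in results.items():
        for v in result.spec.values:
            if v in result.failures:
                rows.append({"parameter": pname, "value": v,
                             "error": result.failures[v]})
                continue
            s = result.summaries[v]
            res = radial_efficiency(
                s.resistance, result.axial_only[v].resistance
            )
            rows.append({
                "parameter": pname,
                "value": v,
                "r_with_radial_pa_s_m3": res.r_with_radial,
                "r_axial_only_pa_s_m3": res.r_axial_only,
                "efficiency_pct": 100 * res.efficiency,
            })
    return pd.DataFrame(rows)


def run_tier_decomposition(
    params: VesselParams | None = None,
    mesh_level: int = 0,
    bc: BoundaryConditions | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
    sizing: MeshSizing | None = None,
):
    """Solve all three tiers at one parameter set and decompose.

    Returns (dict tier-number → FlowSummary, ResistanceDecomposition).
    """
    params = (params or VesselParams()).validate()
    bc = bc or BoundaryConditions()
    fluid = fluid or FluidProperties()
    config = config or SolverConfig()
    summaries = {}
    for n, tier in ((1, ModelTier.SMOOTH), (2, ModelTier.WALL_THICKENING),
                    (3, ModelTier.FULL)):
        geometry = build_vessel_geometry(params, tier)
        mesh = generate_mesh(geometry, mesh_level, sizing)
        field_ = solve_flow(mesh, bc, fluid, config)
        summaries[n] = summarize_flow(field_, mesh)
    deco = decompose(
        summaries[1].resistance, summaries[2].resistance,
        summaries[3].resistance,
    )
    return summaries, deco


def plot_sweep(result: SweepResult, path=None):
    """Resistance (and efficiency, if present) against the swept value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals, rs = result.resistances()
    eff = result.efficiencies()
    ncols = 2 if eff else 1
    fig, axes = plt.subplots(1, ncols, figsize=(5 * ncols, 4), squeeze=False)
    ax = axes[0][0]
    ax.plot(vals, rs / 1e12, "o-")
    ax.set_xlabel(result.spec.parameter_name)
    ax.set_ylabel("total resistance (10$^{12}$ Pa s m$^{-3}$)")
    if eff:
        ax2 = axes[0][1]
        ev = sorted(eff)
        ax2.plot(ev, [100 * eff[v] for v in ev], "s-")
        ax2.set_xlabel(result.spec.parameter_name)
        ax2.set_ylabel("radial transmission efficiency (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
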