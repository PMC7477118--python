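"""Synthetic anatomical inputs and analytic reference solutions.

No external data accompanies the vessel model; every pipeline stage is
exercised on parameter sets generated here.  Randomized sets are drawn
uniformly within the documented anatomical ranges (the measured anatomy ±
the published sweep spans); degenerate sets probe the closed limits (sealed
membrane, vanishing plate, shallow pits).  Smooth-tier reference solutions
are the Hagen–Poiseuille closed form, the primary solver oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydraulics import hagen_poiseuille_resistance
from .params import MICRON, FluidProperties, VesselParams

__all__ = [
    "PARAMETER_RANGES",
    "FixtureSet",
    "generate_params",
    "reference_smooth_solution",
    "degenerate_cases",
    "build_fixture_set",
]

#: uniform sampling ranges (µm except the open-area fraction)
PARAMETER_RANGES = {
    "inner_diameter": (52.0, 61.0),
    "pit_depth": (2.6, 5.6),
    "membrane_permeability": (0.0, 0.30),
    "plate_height": (2.0, 5.0),
    "plate_width": (2.0, 5.0),
}


def generate_params(seed: int, n: int) -> list[VesselParams]:
    """Draw ``n`` valid anatomically plausible parameter sets.

    Deterministic per seed; every returned set passes validation.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        draws = {
            name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in PARAMETER_RANGES.items()
        }
        out.append(VesselParams(**draws).validate())
    return out


def reference_smooth_solution(
    params: VesselParams,
    fluid: FluidProperties | None = None,
    inlet_velocity: float = 3.0e-4,
) -> tuple[float, float, float]:
    """(Δp, q, R) of the smooth tier from the Hagen–Poiseuille closed form.

    q = u_in·πr², Δp = 8µL_total·q/(πr⁴), R = Δp/q; lengths include the two
    entrance/exit extensions.
    """
    fluid = fluid or FluidProperties()
    r = params.lumen_radius * MICRON
    q = inlet_velocity * np.pi * r**2
    R = hagen_poiseuille_resistance(
        params.total_length, params.lumen_radius, fluid.dynamic_viscosity
    )
    return R * q, q, R


def degenerate_cases() -> dict[str, VesselParams]:
    """Closed-limit parameter sets used to probe the solver's edge behaviour."""
    base = VesselParams()
    return {
        "sealed_membrane": base.replace(membrane_permeability=0.0).validate(),
        "vanishing_plate": base.replace(plate_height=0.0).validate(),
        # shallow pits: thinnest thickening the bordered-pit profile allows
        "shallow_pits": base.replace(pit_depth=0.5).validate(),
        "fully_open_membrane": base.replace(membrane_permeability=1.0).validate(),
    }


@dataclass(frozen=True)
class FixtureSet:
    """Reproducible bundle of parameter sets and analytic references."""

    seed: int
    parameter_sets: tuple[VesselParams, ...]
    reference_solutions: tuple[tuple[VesselParams, float, float, float], ...]
    degenerate: dict[str, VesselParams]

    def references_frame(self) -> pd.DataFrame:
        rows = []
        for params, dp, q, r in self.reference_solutions:
            row = {f"param_{k}": v for k, v in params.to_dict().items()}
            row.update({"pressure_drop_pa": dp, "flux_m3_s": q,
                        "resistance_pa_s_m3": r})
            rows.append(row)
        return pd.DataFrame(rows)


def build_fixture_set(
    seed: int,
    n: int,
    fluid: FluidProperties | None = None,
    inlet_velocity: float = 3.0e-4,
) -> FixtureSet:
    sets = generate_params(seed, n)
    refs = tuple(
        (p, *reference_smooth_solution(p, fluid, inlet_velocity)) for p in sets
    )
    return FixtureSet(
        seed=seed,
        parameter_sets=tuple(sets),
        reference_solutions=refs,
        degenerate=degenerate_cases(),
    )
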