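"""The resistance calculus of the vessel model.

Hydraulic resistance is R = Δp/q (Pa s m⁻³, additive in series).  The three
incremental model tiers decompose the total resistance into structural
components:

    R_s = R1            (smooth vessel)
    R_w = R2 − R1       (secondary wall thickening, pits included)
    R_p = R3 − R2       (perforation plate)
    R_tot = R3,         fractions F_i = component / R_tot.

Radial transmission efficiency compares the resistance with the pit
membranes sealed (axial-only transport) against the resistance with radial
transport open:

    efficiency = (R_axial_only − R_with_radial) / R_with_radial.

The published reference tables use the same symbol pair both for resistance
fractions and for the two efficiency resistances; this module deliberately
names the efficiency quantities ``r_axial_only`` / ``r_with_radial`` so a
fraction can never be confused with a resistance.

Percent-change statements about these quantities mix two denominator
conventions (the baseline value or the comparison value); the convention is
therefore an explicit required argument of :func:`percent_change`, and the
package ships a table mapping each published claim to the convention that
reproduces it (:data:`xylemflow.reference.PRINTED_COMPARISONS`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .geometry import ModelTier, pit_axial_positions, _azimuthal_pit_count
from .params import MICRON, FluidProperties, VesselParams

__all__ = [
    "PercentConvention",
    "ResistanceDecomposition",
    "RadialEfficiencyResult",
    "resistance",
    "decompose",
    "percent_change",
    "radial_efficiency",
    "network_oracle",
    "hagen_poiseuille_resistance",
    "sampson_pore_resistance",
]


class HydraulicsError(ValueError):
    pass


class PercentConvention(Enum):
    """Denominator convention of a percent change."""

    BASELINE = "baseline"
    COMPARISON = "comparison"


def resistance(pressure_drop: float, flux: float) -> float:
    """Hydraulic resistance Δp/q, Pa s m⁻³."""
    if flux <= 0:
        raise HydraulicsError(f"flux must be positive, got {flux!r}")
    return pressure_drop / flux


def percent_change(
    baseline: float,
    comparison: float,
    convention: PercentConvention,
) -> float:
    """Signed fractional change between two values.

    BASELINE: (comparison − baseline)/baseline.
    COMPARISON: (comparison − baseline)/comparison.
    """
    denom = baseline if convention is PercentConvention.BASELINE else comparison
    if denom == 0:
        raise HydraulicsError("zero denominator in percent change")
    return (comparison - baseline) / denom


@dataclass(frozen=True)
class ResistanceDecomposition:
    """Component resistances and fractions of the three-tier decomposition."""

    r1: float
    r2: float
    r3: float
    r_smooth: float
    r_wall: float
    r_plate: float
    r_total: float
    frac_smooth: float
    frac_wall: float
    frac_plate: float

    def summary(self) -> pd.DataFrame:
        """Component table in the publication style (×10¹², 4 digits)."""
        return pd.DataFrame(
            {
                "component": ["smooth vessel", "wall thickening",
                              "perforation plate", "total"],
                "resistance_1e12_pa_s_m3": [
                    round(self.r_smooth / 1e12, 4),
                    round(self.r_wall / 1e12, 4),
                    round(self.r_plate / 1e12, 4),
                    round(self.r_total / 1e12, 4),
                ],
                "fraction_pct": [
                    round(100 * self.frac_smooth, 2),
                    round(100 * self.frac_wall, 2),
                    round(100 * self.frac_plate, 2),
                    100.0,
                ],
            }
        )


def decompose(r1: float, r2: float, r3: float) -> ResistanceDecomposition:
    """Map the three tier resistances to structural components.

    Exact bookkeeping: the components sum to r3 bit-for-bit and the
    fractions sum to one.  Warns (does not fail) if the tiers are not
    monotone, which would produce a negative component.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r3", r3)):
        if not r > 0:
            raise HydraulicsError(f"{name} must be positive, got {r!r}")
    if r1 > r2 or r2 > r3:
        warnings.warn(
            "tier resistances are not monotone (r1 ≤ r2 ≤ r3); a component "
            "resistance will be negative",
            stacklevel=2,
        )
    r_wall = r2 - r1
    r_plate = r3 - r2
    return ResistanceDecomposition(
        r1=r1, r2=r2, r3=r3,
        r_smooth=r1, r_wall=r_wall, r_plate=r_plate, r_total=r3,
        frac_smooth=r1 / r3, frac_wall=r_wall / r3, frac_plate=r_plate / r3,
    )


@dataclass(frozen=True)
class RadialEfficiencyResult:
    """Radial transmission efficiency of a pitted vessel.

    ``r_axial_only`` is the total resistance with the pit membranes sealed
    (permeability 0); ``r_with_radial`` with radial transport open.  The
    efficiency is the fractional resistance relief provided by the radial
    pathway; it is identically zero at zero permeability.
    """

    r_with_radial: float
    r_axial_only: float
    efficiency: float


def radial_efficiency(
    r_with_radial: float, r_axial_only: float
) -> RadialEfficiencyResult:
    if r_with_radial <= 0 or r_axial_only <= 0:
        raise HydraulicsError("resistances must be positive")
    eff = (r_axial_only - r_with_radial) / r_with_radial
    return RadialEfficiencyResult(
        r_with_radial=r_with_radial,
        r_axial_only=r_axial_only,
        efficiency=eff,
    )


# -- closed-form network oracle ----------------------------------------

def hagen_poiseuille_resistance(
    length_um: float, radius_um: float, viscosity: float
) -> float:
    """Laminar pipe resistance 8µL/(πr⁴), Pa s m⁻³ (lengths in µm)."""
    L = length_um * MICRON
    r = radius_um * MICRON
    return 8 * viscosity * L / (math.pi * r**4)


def sampson_pore_resistance(
    radius_um: float, thickness_um: float, viscosity: float
) -> float:
    """Orifice resistance 3µ/a³ plus the Poiseuille thickness term."""
    a = radius_um * MICRON
    t = thickness_um * MICRON
    return 3 * viscosity / a**3 + 8 * viscosity * t / (math.pi * a**4)


def network_oracle(
    params: VesselParams,
    tier: ModelTier,
    fluid: FluidProperties | None = None,
) -> float:
    """Closed-form series/parallel estimate of the total resistance.

    The lumen is a chain of Hagen–Poiseuille segments (extensions at the
    primary diameter, the vessel proper at the thickened diameter, the plate
    as a short narrower segment with a Sampson end correction).  The pit
    pathway is lumped as a single shunt at mid-length to the outlet
    pressure: all pits in parallel, each an aperture pore in series with the
    membrane pores it feeds.  This is an order-of-magnitude cross-check of
    trends and scalings, not a replica of the discretized solution.
    """
    params.validate()
    fluid = fluid or FluidProperties()
    mu = fluid.dynamic_viscosity
    r_lumen = params.lumen_radius

    r_ext = hagen_poiseuille_resistance(
        2 * params.extension_length, r_lumen, mu
    )
    if tier is ModelTier.SMOOTH:
        return r_ext + hagen_poiseuille_resistance(
            params.vessel_length, r_lumen, mu
        )

    r_open = params.thickened_lumen_radius
    r_axial_vessel = hagen_poiseuille_resistance(
        params.vessel_length, r_open, mu
    )
    if tier is ModelTier.FULL and params.plate_height > 0:
        r_plate_open = r_open - params.plate_height
        if r_plate_open <= 0:
            raise HydraulicsError("plate closes the lumen in the oracle")
        extra = hagen_poiseuille_resistance(
            params.plate_width, r_plate_open, mu
        ) - hagen_poiseuille_resistance(params.plate_width, r_open, mu)
        # end correction for the sudden constriction (Sampson orifice)
        extra += 3 * mu / (r_plate_open * MICRON) ** 3
        r_axial_vessel += extra

    # pit shunt: aperture + membrane per pit, all pits in parallel
    n_pits = len(pit_axial_positions(params)) * _azimuthal_pit_count(params)
    if n_pits == 0 or params.membrane_permeability <= 0:
        r_shunt = math.inf
    else:
        r_aperture = sampson_pore_resistance(
            params.pit_aperture / 2, 0.3 * params.pit_depth, mu
        )
        a = params.membrane_pore_radius
        pore_r = sampson_pore_resistance(a, params.membrane_thickness, mu)
        pores = (
            params.membrane_permeability
            * (params.pit_diameter / 2) ** 2
            / a**2
        )
        r_membrane = pore_r / max(pores, 1e-300)
        r_shunt = (r_aperture + r_membrane) / n_pits

    # axial chain with the shunt tapping at mid-length
    r_first = r_ext / 2 + r_axial_vessel / 2
    r_second = r_axial_vessel / 2 + r_ext / 2
    if math.isinf(r_shunt):
        return r_first + r_second
    return r_first + 1.0 / (1.0 / r_second + 1.0 / r_shunt)


# -- publication-style tables ------------------------------------------

def tier_flow_table(summaries: dict[int, "object"] | None = None) -> pd.DataFrame:
    """(Δp, q, R) per model tier, publication layout.

    With no argument, rebuilds the table from the published reference
    triples; given a mapping tier-number → FlowSummary, uses this package's
    own solver results.
    """
    from . import reference

    rows = []
    if summaries is None:
        for tier, (dp, q, r) in reference.TIER_FLOW_TABLE.items():
            rows.append({"model": tier, "pressure_drop_pa": dp,
                         "flux_m3_s": q, "resistance_pa_s_m3": r})
    else:
        for tier, s in sorted(summaries.items()):
            rows.append({
                "model": tier,
                "pressure_drop_pa": s.pressure_drop,
                "flux_m3_s": s.flux,
                "resistance_pa_s_m3": s.resistance,
            })
    return pd.DataFrame(rows)


def reference_decomposition() -> ResistanceDecomposition:
    """Decomposition of the published tier triples via this calculus."""
    from . import reference

    rs = [
        resistance(dp, q) for dp, q, _ in (
            reference.TIER_FLOW_TABLE[1],
            reference.TIER_FLOW_TABLE[2],
            reference.TIER_FLOW_TABLE[3],
        )
    ]
    return decompose(*rs)


def reference_efficiency_table() -> pd.DataFrame:
    """Efficiency of every published (with-radial, axial-only) pair."""
    from . import reference

    rows = []
    for pname, table in reference.EFFICIENCY_TABLE.items():
        for value, (r_with, r_axial) in table.items():
            res = radial_efficiency(r_with, r_axial)
            rows.append({
                "parameter": pname,
                "value": value,
                "r_with_radial_pa_s_m3": r_with,
                "r_axial_only_pa_s_m3": r_axial,
                "efficiency_pct": 100 * res.efficiency,
            })
    return pd.DataFrame(rows)


def reference_percent_changes() -> pd.DataFrame:
    """Recompute every published percent-change claim from its endpoints."""
    from . import reference

    rows = []
    for label, base, comp, conv, printed, ok, tol in reference.PRINTED_COMPARISONS:
        value = 100 * percent_change(base, comp, conv)
        rows.append({
            "claim": label,
            "baseline": base,
            "comparison": comp,
            "convention": conv.value,
            "recomputed_pct": value,
            "printed_pct": printed,
            "reproducible": ok,
            "tolerance_pp": tol,
        })
    return pd.DataFrame(rows)
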