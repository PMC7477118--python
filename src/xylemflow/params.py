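"""Anatomical, fluid and solver parameter containers.

All anatomical lengths are stored in micrometres (the natural unit of vessel
anatomy); fluid properties and boundary conditions are SI.  Conversion to SI
happens only inside the flow solver.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

MICRON = 1e-6  # m

#: Fraction of the pit depth occupied by the aperture neck of a bordered pit
#: (the narrow channel through the overarching border on the lumen side).
APERTURE_NECK_FRACTION = 0.3


class ParameterError(ValueError):
    """A vessel parameter set violates an anatomical invariant.

    Carries the name of the offending field in :attr:`field_name`.
    """

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class VesselParams:
    """Anatomical dimensions of a single xylem vessel (µm unless noted).

    Defaults are the measured *Jatropha curcas* midrib-branch vessel anatomy:
    a circular vessel 200 µm long and 55 µm across with bordered pits
    (8 µm chamber, 2.6 µm aperture, 4.6 µm deep) in the pitted secondary wall
    thickening, a 0.2 µm thick pit membrane with 15 % open area, and a single
    perforation plate 3 µm wide and 3 µm high tilted at 45°.  Smooth 25 µm
    extensions are added at both ends so entrance and exit effects do not
    contaminate the vessel proper.

    ``inner_diameter`` is the smooth-tier lumen diameter.  In the tiers with
    secondary wall thickening the thickening layer (thickness = ``pit_depth``)
    narrows the open lumen to ``inner_diameter − 2·pit_depth``; the bordered
    pits pierce that layer, so the distance from the aperture mouth to the
    pit membrane equals ``pit_depth`` and the membrane lies at the primary
    wall.
    """

    vessel_length: float = 200.0
    inner_diameter: float = 55.0
    pit_diameter: float = 8.0
    pit_aperture: float = 2.6
    pit_depth: float = 4.6
    membrane_thickness: float = 0.2
    membrane_permeability: float = 0.15  # open-area fraction, [0, 1]
    plate_width: float = 3.0
    plate_height: float = 3.0
    plate_tilt_angle: float = 45.0  # degrees; only meaningful in 3-D sector mode
    extension_length: float = 25.0
    pit_axial_spacing: float = 8.0  # clear axial gap between pit chambers
    pit_rows: int | None = None  # None -> derived from spacing
    membrane_pore_radius: float = 0.3  # µm, pore radius of the porous membrane

    # -- validation ----------------------------------------------------
    def validate(self) -> "VesselParams":
        """Check all anatomical invariants; raise :class:`ParameterError`."""
        positive = (
            "vessel_length", "inner_diameter", "pit_diameter", "pit_aperture",
            "pit_depth", "membrane_thickness", "plate_width",
            "extension_length", "membrane_pore_radius",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(name, "must be strictly positive")
        if self.plate_height < 0:
            raise ParameterError("plate_height", "must be non-negative")
        if self.pit_axial_spacing < 0:
            raise ParameterError("pit_axial_spacing", "must be non-negative")
        if not 0.0 <= self.membrane_permeability <= 1.0:
            raise ParameterError(
                "membrane_permeability", "open-area fraction must lie in [0, 1]"
            )
        if self.pit_aperture >= self.pit_diameter:
            raise ParameterError(
                "pit_aperture", "must be smaller than pit_diameter"
            )
        if self.plate_height >= self.inner_diameter / 2:
            raise ParameterError(
                "plate_height", "must be smaller than the vessel radius"
            )
        # the bordered-pit profile reserves APERTURE_NECK_FRACTION of the depth
        # for the aperture neck; the chamber + membrane occupy the rest
        chamber = self.pit_depth * (1 - APERTURE_NECK_FRACTION)
        if chamber <= self.membrane_thickness:
            raise ParameterError(
                "pit_depth",
                "too shallow: chamber depth (pit_depth minus aperture neck) "
                "must exceed membrane_thickness",
            )
        if self.pit_depth >= self.inner_diameter / 2:
            raise ParameterError(
                "pit_depth", "thickening layer would close the lumen"
            )
        if self.pit_rows is not None and self.pit_rows < 0:
            raise ParameterError("pit_rows", "must be non-negative")
        if self.pit_rows is not None and self.pit_rows > 0:
            pitch = self.pit_diameter + self.pit_axial_spacing
            if self.pit_rows * pitch > self.vessel_length:
                raise ParameterError(
                    "pit_rows", "requested rows do not fit the vessel length"
                )
        return self

    # -- derived geometry ----------------------------------------------
    @property
    def total_length(self) -> float:
        """Axial extent of the modelled domain (µm), vessel + two extensions."""
        return self.vessel_length + 2 * self.extension_length

    @property
    def lumen_radius(self) -> float:
        """Smooth-tier (primary wall) lumen radius, µm."""
        return self.inner_diameter / 2

    @property
    def thickened_lumen_radius(self) -> float:
        """Open lumen radius inside the secondary wall thickening, µm."""
        return self.inner_diameter / 2 - self.pit_depth

    def replace(self, **changes: Any) -> "VesselParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid; defaults are water at 20 °C."""

    density: float = 998.2  # kg m^-3
    dynamic_viscosity: float = 1.003e-3  # Pa s

    def validate(self) -> "FluidProperties":
        if not self.density > 0:
            raise ParameterError("density", "must be strictly positive")
        if not self.dynamic_viscosity > 0:
            raise ParameterError("dynamic_viscosity", "must be strictly positive")
        return self


@dataclass(frozen=True)
class BoundaryConditions:
    """Axial velocity inlet and fixed-pressure outlet.

    ``inlet_velocity`` is the mean axial velocity through the inlet plane.
    The default ``parabolic`` profile is the fully developed laminar shape
    (the inlet extension then carries no entrance development and the
    measured pressure drop is grid-convergent); the ``uniform`` plug profile
    is also available but carries a stress singularity where the plug meets
    the no-slip wall, which makes the inlet-plane pressure refine without
    bound — use the vessel-proper pressure drop with it.
    """

    inlet_velocity: float = 3.0e-4  # m s^-1 (0.3 mm s^-1), mean over the inlet
    outlet_pressure: float = 0.0  # Pa
    inlet_profile: str = "parabolic"  # "parabolic" | "uniform"

    def validate(self) -> "BoundaryConditions":
        if not self.inlet_velocity > 0:
            raise ParameterError("inlet_velocity", "must be strictly positive")
        if self.inlet_profile not in ("parabolic", "uniform"):
            raise ParameterError(
                "inlet_profile", "must be 'parabolic' or 'uniform'"
            )
        return self


@dataclass(frozen=True)
class SolverConfig:
    """Numerical configuration of the flow solver.

    ``mode`` selects between the fully linear direct Stokes solve (default:
    deterministic, no iteration) and the SIMPLEC pressure–velocity coupling
    loop.  Convective terms matter only in SIMPLEC mode; at the study's
    Reynolds number (~0.016) they are negligible, which is itself a tested
    property.
    """

    mode: str = "stokes"  # "stokes" | "simplec"
    include_convection: bool = False
    tolerance: float = 1e-8  # normalized residual target (SIMPLEC)
    max_iterations: int = 600
    relax_velocity: float = 0.9
    relax_pressure: float = 1.0
    seal_membrane: bool = False  # force zero membrane conductance (axial-only)

    def validate(self) -> "SolverConfig":
        if self.mode not in ("stokes", "simplec"):
            raise ParameterError("mode", "must be 'stokes' or 'simplec'")
        if not 0 < self.relax_velocity <= 1:
            raise ParameterError("relax_velocity", "must lie in (0, 1]")
        return self


# -- flat key/value parameter files -----------------------------------

def params_to_yaml(params: VesselParams, path: str | Path) -> None:
    """Write a flat key/value parameter file (lengths in µm, no unit strings)."""
    data = {k: v for k, v in params.to_dict().items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def params_from_yaml(path: str | Path) -> VesselParams:
    """Read a flat key/value parameter file written by :func:`params_to_yaml`."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(VesselParams)}
    unknown = set(data) - known
    if unknown:
        raise ParameterError(sorted(unknown)[0], "unknown parameter key")
    return VesselParams(**data).validate()
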