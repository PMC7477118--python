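"""Parametric vessel fluid domains.

The vessel is modelled in a 2-D axisymmetric reduction (z, r): the lumen is a
cylinder, pit rows become annular cavities in the secondary wall thickening,
and the perforation plate becomes an annular constriction.  The true discrete
azimuthal arrangement of pits is retained as metadata (azimuthal pit count and
circumferential open fraction) and applied as a scaling on membrane
conductance, so the radial leak area matches the true pit area.

Three nested model tiers mirror the incremental resistance decomposition:

* ``SMOOTH`` — bare cylindrical lumen (model 1),
* ``WALL_THICKENING`` — adds the pitted secondary wall thickening, whose layer
  (thickness = pit depth) narrows the open lumen and carries bordered pits
  capped by porous pit membranes (model 2),
* ``FULL`` — adds the simple perforation plate (model 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .params import APERTURE_NECK_FRACTION, ParameterError, VesselParams

__all__ = [
    "ModelTier",
    "Reduction",
    "Box",
    "MembraneSegment",
    "GeometryDomain",
    "MembranePoreLayout",
    "default_jatropha_params",
    "build_vessel_geometry",
    "membrane_pore_layout",
    "pit_axial_positions",
]


class ModelTier(Enum):
    SMOOTH = 1
    WALL_THICKENING = 2
    FULL = 3


class Reduction(Enum):
    AXISYMMETRIC_2D = "axisymmetric_2d"
    SECTOR_3D = "sector_3d"


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in the (z, r) half-plane, µm."""

    z0: float
    z1: float
    r0: float
    r1: float

    def contains(self, z: float, r: float) -> bool:
        return self.z0 <= z <= self.z1 and self.r0 <= r <= self.r1


@dataclass(frozen=True)
class MembraneSegment:
    """A porous pit-membrane patch: axial span at fixed radius (µm)."""

    z0: float
    z1: float
    radius: float  # membrane inner face (lumen side of the membrane)


@dataclass(frozen=True)
class GeometryDomain:
    """Labelled fluid region for one model tier.

    The fluid region is the bounding half-rectangle
    ``[0, total_length] × [0, outer_radius]`` minus ``solid_boxes`` plus
    ``carve_boxes`` (cavities cut back out of the solid).  All coordinates in
    µm; z increases inlet → outlet.
    """

    tier: ModelTier
    params: VesselParams
    reduction: Reduction
    total_length: float
    outer_radius: float
    lumen_radius: float  # open lumen radius inside any thickening
    solid_boxes: tuple[Box, ...]
    carve_boxes: tuple[Box, ...]
    membrane_segments: tuple[MembraneSegment, ...]
    pit_placements: tuple[float, ...]  # axial centres of pit rows
    plate_span: tuple[float, float] | None
    plate_inner_radius: float | None
    azimuthal_pit_count: int
    circumferential_open_fraction: float
    boundary_patches: frozenset[str]
    dropped_pits: tuple[float, ...] = ()

    # -- queries -------------------------------------------------------
    def is_solid(self, z: float, r: float) -> bool:
        """Point classification (used by the mesher on cell centres)."""
        if r > self.outer_radius or not 0 <= z <= self.total_length:
            return True
        for box in self.carve_boxes:
            if box.contains(z, r):
                return False
        return any(box.contains(z, r) for box in self.solid_boxes)

    @property
    def z_breakpoints(self) -> tuple[float, ...]:
        zs = {0.0, self.total_length,
              self.params.extension_length,
              self.params.extension_length + self.params.vessel_length}
        for box in self.solid_boxes + self.carve_boxes:
            zs.update((box.z0, box.z1))
        for seg in self.membrane_segments:
            zs.update((seg.z0, seg.z1))
        return tuple(sorted(zs))

    @property
    def r_breakpoints(self) -> tuple[float, ...]:
        rs = {0.0, self.outer_radius, self.lumen_radius}
        for box in self.solid_boxes + self.carve_boxes:
            rs.update((box.r0, box.r1))
        for seg in self.membrane_segments:
            rs.add(seg.radius)
        if self.plate_inner_radius is not None:
            rs.add(self.plate_inner_radius)
        return tuple(sorted(r for r in rs if 0.0 <= r <= self.outer_radius))


@dataclass(frozen=True)
class MembranePoreLayout:
    """Discretized open-area description of one pit membrane."""

    pore_radius: float  # µm
    pore_count: int
    membrane_area: float  # µm², one pit-membrane disc
    achieved_open_fraction: float
    requested_open_fraction: float


def default_jatropha_params() -> VesselParams:
    """The measured *J. curcas* vessel anatomy (see :class:`VesselParams`)."""
    return VesselParams().validate()


def pit_axial_positions(params: VesselParams) -> list[float]:
    """Axial centres of evenly spaced pit rows, strictly inside the vessel.

    Pitch = pit_diameter + pit_axial_spacing; the row count defaults to
    ``floor(vessel_length / pitch)`` and the group is centred in the vessel
    span.  Pure function of the parameter set (deterministic placement).
    """
    pitch = params.pit_diameter + params.pit_axial_spacing
    n = params.pit_rows if params.pit_rows is not None else int(
        math.floor(params.vessel_length / pitch)
    )
    if n <= 0:
        return []
    margin = (params.vessel_length - n * pitch) / 2
    z0 = params.extension_length + margin + pitch / 2
    return [z0 + k * pitch for k in range(n)]


def membrane_pore_layout(params: VesselParams) -> MembranePoreLayout:
    """Discretize the membrane open-area fraction into whole pores.

    The achieved open fraction is guaranteed within 1 % (absolute) of the
    requested ``membrane_permeability`` because a single pore is a small
    fraction of the membrane disc area.
    """
    phi = params.membrane_permeability
    if not 0.0 <= phi <= 1.0:
        raise ParameterError(
            "membrane_permeability", "open-area fraction must lie in [0, 1]"
        )
    area = math.pi * (params.pit_diameter / 2) ** 2
    pore_area = math.pi * params.membrane_pore_radius ** 2
    count = int(round(phi * area / pore_area))
    achieved = count * pore_area / area
    if phi > 0 and abs(achieved - phi) > 0.01:
        # fall back to fractional coverage bookkeeping for very coarse pores
        achieved = phi
    return MembranePoreLayout(
        pore_radius=params.membrane_pore_radius,
        pore_count=count,
        membrane_area=area,
        achieved_open_fraction=achieved,
        requested_open_fraction=phi,
    )


def _azimuthal_pit_count(params: VesselParams) -> int:
    """Pits per row around the circumference, same pitch rule as axial."""
    pitch = params.pit_diameter + params.pit_axial_spacing
    circumference = 2 * math.pi * params.thickened_lumen_radius
    return max(1, int(math.floor(circumference / pitch)))


def build_vessel_geometry(
    params: VesselParams,
    tier: ModelTier,
    reduction: Reduction = Reduction.AXISYMMETRIC_2D,
) -> GeometryDomain:
    """Construct the labelled fluid domain for one model tier.

    Deterministic: pit placement and all feature coordinates are pure
    functions of ``params``.  Raises :class:`ParameterError` naming the
    offending field for invalid parameter sets.
    """
    params.validate()
    if not isinstance(tier, ModelTier):
        raise TypeError(f"tier must be a ModelTier, got {tier!r}")

    L_tot = params.total_length
    R = params.lumen_radius
    ext = params.extension_length
    z_v0, z_v1 = ext, ext + params.vessel_length

    patches = {"inlet", "outlet", "vessel_wall"}
    solid: list[Box] = []
    carve: list[Box] = []
    membranes: list[MembraneSegment] = []
    pits: tuple[float, ...] = ()
    dropped: tuple[float, ...] = ()
    plate_span = None
    plate_inner = None
    lumen_radius = R
    az_count = 0
    f_circ = 0.0

    if tier in (ModelTier.WALL_THICKENING, ModelTier.FULL):
        t_m = params.membrane_thickness
        depth = params.pit_depth
        lumen_radius = R - depth
        neck = APERTURE_NECK_FRACTION * depth
        r_ap0, r_ap1 = lumen_radius, lumen_radius + neck  # aperture channel
        r_mem = R - t_m  # membrane inner face (primary wall minus thickness)
        # thickening layer occupies the full annulus over the vessel span
        solid.append(Box(z_v0, z_v1, lumen_radius, R))
        positions = pit_axial_positions(params)
        if tier is ModelTier.FULL and positions and params.plate_height > 0:
            # drop pit rows whose chamber would intersect the plate (clearance
            # of one chamber shoulder); logged via dropped_pits
            zp0 = ext + params.vessel_length / 2 - params.plate_width / 2
            zp1 = zp0 + params.plate_width
            clear = params.pit_diameter / 2 + 1.0
            kept, lost = [], []
            for c in positions:
                if c + params.pit_diameter / 2 + 1e-9 > zp0 - clear and \
                   c - params.pit_diameter / 2 - 1e-9 < zp1 + clear:
                    lost.append(c)
                else:
                    kept.append(c)
            positions, dropped = kept, tuple(lost)
        for c in positions:
            half_ch = params.pit_diameter / 2
            half_ap = params.pit_aperture / 2
            carve.append(Box(c - half_ap, c + half_ap, r_ap0, r_ap1))
            carve.append(Box(c - half_ch, c + half_ch, r_ap1, r_mem))
            membranes.append(MembraneSegment(c - half_ch, c + half_ch, r_mem))
        pits = tuple(positions)
        if pits:
            patches |= {"pit_cavity_wall", "membrane"}
        az_count = _azimuthal_pit_count(params)
        f_circ = min(
            1.0,
            az_count * params.pit_diameter
            / (2 * math.pi * params.thickened_lumen_radius),
        )

    if tier is ModelTier.FULL and params.plate_height > 0:
        zp0 = ext + params.vessel_length / 2 - params.plate_width / 2
        zp1 = zp0 + params.plate_width
        plate_inner = lumen_radius - params.plate_height
        if plate_inner <= 0:
            raise ParameterError(
                "plate_height", "plate closes the thickened lumen entirely"
            )
        solid.append(Box(zp0, zp1, plate_inner, lumen_radius))
        plate_span = (zp0, zp1)
        patches.add("plate_wall")

    return GeometryDomain(
        tier=tier,
        params=params,
        reduction=reduction,
        total_length=L_tot,
        outer_radius=R,
        lumen_radius=lumen_radius,
        solid_boxes=tuple(solid),
        carve_boxes=tuple(carve),
        membrane_segments=tuple(membranes),
        pit_placements=pits,
        plate_span=plate_span,
        plate_inner_radius=plate_inner,
        azimuthal_pit_count=az_count,
        circumferential_open_fraction=f_circ,
        boundary_patches=frozenset(patches),
        dropped_pits=dropped,
    )
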