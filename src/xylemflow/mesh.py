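"""Structured axisymmetric meshing and the grid-independence procedure.

The mesh is a tensor-product (z, r) grid whose edge sets contain every
geometric feature coordinate, with cells blanked to solid where they fall
inside the thickening, membrane body or perforation plate.  Refinement is
graded toward pit apertures, pit membranes and the plate; level ``k+1``
halves every target cell size of level ``k`` (nested refinement by factor 2).

Cells adjacent to a pit membrane are never larger than the membrane
thickness, at any refinement level, so the porous jump is always resolved by
its neighbouring pressure cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import GeometryDomain, ModelTier, Reduction
from .params import MICRON, BoundaryConditions, FluidProperties, SolverConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Mesh",
    "RefinementError",
    "GridIndependenceReport",
    "generate_mesh",
    "grid_independence_study",
]

#: grid-independence criterion: successive relative pressure-drop change
CONVERGENCE_CRITERION = 0.005

#: cell aspect ratios beyond this bound trigger a quality warning (not error)
ASPECT_RATIO_WARN = 80.0


class RefinementError(RuntimeError):
    """A geometric feature cannot be resolved at the requested level."""


@dataclass(frozen=True)
class MeshSizing:
    """Target cell sizes (µm) at refinement level 0."""

    extension_z: float = 3.0
    lumen_z: float = 2.0
    shoulder_z_max: float = 0.8
    aperture_cells: int = 4  # cells across the pit aperture
    plate_cells: int = 6  # cells across the plate width
    core_r_cells: int = 14  # cells across the lumen core
    wall_band: float = 2.0  # µm of near-wall radial refinement
    wall_band_r: float = 0.5
    neck_r: float = 0.4
    chamber_r0: float = 0.5  # chamber radial size at the aperture side
    smooth_z: float = 4.0


def _subdivide(a: float, b: float, h: float) -> np.ndarray:
    """Uniform edges over [a, b] with size ≤ h (≥ 1 cell)."""
    n = max(1, int(math.ceil((b - a) / h - 1e-12)))
    return np.linspace(a, b, n + 1)


def _subdivide_graded(a: float, b: float, h0: float, h1: float) -> np.ndarray:
    """Edges over [a, b] with sizes grading geometrically from ~h0 to ≤ h1."""
    span = b - a
    if span <= h1:
        return np.array([a, b])
    if h1 >= h0:
        return _subdivide(a, b, h0)
    # choose cell count so the last (smallest) cell is ≤ h1
    for n in range(2, 10_000):
        ratio = (h1 / h0) ** (1.0 / (n - 1))
        sizes = h0 * ratio ** np.arange(n)
        scale = span / sizes.sum()
        if sizes[-1] * scale <= h1 * (1 + 1e-9):
            sizes *= scale
            return a + np.concatenate(([0.0], np.cumsum(sizes)))
    raise RefinementError("graded subdivision failed to satisfy the size cap")


def _merge_edges(segments: Sequence[np.ndarray]) -> np.ndarray:
    edges = np.concatenate(segments)
    edges = np.unique(np.round(edges, 9))
    return edges


@dataclass
class Mesh:
    """Axisymmetric structured mesh on a :class:`GeometryDomain`.

    ``fluid[i, j]`` marks cell (z-index i, r-index j) as fluid.  Patch faces
    are stored as ``(orientation, i, j)`` with orientation ``"z"`` for faces
    normal to z (face index i ∈ [0, nz]) and ``"r"`` for faces normal to r
    (face index j ∈ [0, nr]).
    """

    geometry: GeometryDomain
    refinement_level: int
    z_edges: np.ndarray  # µm, length nz+1
    r_edges: np.ndarray  # µm, length nr+1
    fluid: np.ndarray  # bool, (nz, nr)
    patch_faces: dict[str, list[tuple[str, int, int]]]
    membrane_faces: list[tuple[int, int, int]]  # (i, j_face, segment index)
    cell_region: np.ndarray  # (nz, nr) int8: -1 solid, 0 lumen, 1 ext, 2 cavity, 3 plate

    REGIONS = {"lumen": 0, "extension": 1, "cavity": 2, "plate": 3}

    # -- basic metrics -------------------------------------------------
    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def nr(self) -> int:
        return len(self.r_edges) - 1

    @property
    def cells(self) -> int:
        return int(self.fluid.sum())

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    def cell_sizes(self) -> tuple[np.ndarray, np.ndarray]:
        return np.diff(self.z_edges), np.diff(self.r_edges)

    @property
    def characteristic_sizes(self) -> tuple[float, float]:
        """(max, min) cell edge length over fluid cells, in metres."""
        dz, dr = self.cell_sizes()
        zz = np.repeat(dz[:, None], self.nr, axis=1)[self.fluid]
        rr = np.repeat(dr[None, :], self.nz, axis=0)[self.fluid]
        sizes = np.concatenate([zz, rr])
        return float(sizes.max() * MICRON), float(sizes.min() * MICRON)

    def cell_volumes(self) -> np.ndarray:
        """Full-annulus cell volumes, µm³, (nz, nr)."""
        dz = np.diff(self.z_edges)
        ring = math.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)
        return dz[:, None] * ring[None, :]

    def fluid_volume(self) -> float:
        """Total fluid volume, µm³."""
        return float(self.cell_volumes()[self.fluid].sum())

    def z_face_areas(self) -> np.ndarray:
        """Annular areas of z-normal faces per radial index, µm²."""
        return math.pi * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2)

    def r_face_area(self, i: int, j: int) -> float:
        """Area of the r-normal face at radius r_edges[j] in column i, µm²."""
        return 2 * math.pi * self.r_edges[j] * (self.z_edges[i + 1] - self.z_edges[i])

    def patch_areas(self) -> dict[str, float]:
        areas: dict[str, float] = {}
        az = self.z_face_areas()
        for name, faces in self.patch_faces.items():
            total = 0.0
            for orient, i, j in faces:
                total += az[j] if orient == "z" else self.r_face_area(i, j)
            areas[name] = total
        return areas

    def max_aspect_ratio(self) -> float:
        dz, dr = self.cell_sizes()
        ar = np.maximum(dz[:, None] / dr[None, :], dr[None, :] / dz[:, None])
        return float(ar[self.fluid].max())

    def min_membrane_adjacent_size(self) -> float | None:
        """Radial size (µm) of the largest cell adjacent to a membrane face."""
        if not self.membrane_faces:
            return None
        dr = np.diff(self.r_edges)
        return float(max(dr[j - 1] for _, j, _ in self.membrane_faces))


def _z_edges(geometry: GeometryDomain, sizing: MeshSizing, scale: float) -> np.ndarray:
    p = geometry.params
    has_features = bool(geometry.carve_boxes) or geometry.plate_span is not None
    aperture_spans = [
        (b.z0, b.z1) for b in geometry.carve_boxes if b.r0 == geometry.lumen_radius
    ]
    chamber_spans = [
        (b.z0, b.z1) for b in geometry.carve_boxes if b.r0 > geometry.lumen_radius
    ]
    plate = geometry.plate_span
    segments = []
    bps = list(geometry.z_breakpoints)
    for a, b in zip(bps[:-1], bps[1:]):
        mid = 0.5 * (a + b)
        if any(z0 <= mid <= z1 for z0, z1 in aperture_spans):
            h = p.pit_aperture / sizing.aperture_cells
        elif any(z0 <= mid <= z1 for z0, z1 in chamber_spans):
            h = min(sizing.shoulder_z_max, (b - a) / 2)
        elif plate is not None and plate[0] <= mid <= plate[1]:
            h = p.plate_width / sizing.plate_cells
        elif p.extension_length <= mid <= p.extension_length + p.vessel_length:
            h = sizing.lumen_z if has_features else sizing.smooth_z
        else:
            h = sizing.extension_z if has_features else sizing.smooth_z
        segments.append(_subdivide(a, b, h * scale))
    return _merge_edges(segments)


def _r_edges(geometry: GeometryDomain, sizing: MeshSizing, scale: float) -> np.ndarray:
    p = geometry.params
    lr = geometry.lumen_radius
    t_m = p.membrane_thickness
    bps = set(geometry.r_breakpoints)
    band = max(0.0, lr - sizing.wall_band)
    if 0.0 < band < lr:
        bps.add(band)
    bps = sorted(bps)
    thickened = geometry.tier is not ModelTier.SMOOTH
    neck_top = lr + 0.3 * p.pit_depth if thickened else None
    r_mem = p.lumen_radius - t_m if thickened else None
    segments = []
    for a, b in zip(bps[:-1], bps[1:]):
        mid = 0.5 * (a + b)
        if mid < band:
            h = max(lr / sizing.core_r_cells, 0.25) * scale
            segments.append(_subdivide(a, b, h))
        elif mid < lr:
            segments.append(_subdivide(a, b, sizing.wall_band_r * scale))
        elif neck_top is not None and mid < neck_top:
            segments.append(_subdivide(a, b, sizing.neck_r * scale))
        elif r_mem is not None and mid < r_mem:
            # chamber: grade toward the membrane; adjacent cell ≤ t_m always
            segments.append(
                _subdivide_graded(a, b, sizing.chamber_r0 * scale,
                                  min(t_m, t_m * scale))
            )
        else:
            segments.append(_subdivide(a, b, max(t_m, (b - a)) * scale))
    return _merge_edges(segments)


def generate_mesh(
    geometry: GeometryDomain,
    refinement_level: int = 0,
    sizing: MeshSizing | None = None,
) -> Mesh:
    """Generate a structured, feature-aligned mesh at the given level.

    Cell count strictly increases with ``refinement_level``.  Raises
    :class:`RefinementError` naming the feature if an aperture or the plate
    opening would be resolved by fewer than two cells.
    """
    if geometry.reduction is not Reduction.AXISYMMETRIC_2D:
        raise NotImplementedError(
            "meshing is implemented for the axisymmetric reduction only"
        )
    if refinement_level < 0:
        raise ValueError("refinement_level must be ≥ 0")
    sizing = sizing or MeshSizing()
    scale = 0.5 ** refinement_level
    z_edges = _z_edges(geometry, sizing, scale)
    r_edges = _r_edges(geometry, sizing, scale)

    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    nz, nr = len(zc), len(rc)

    fluid = np.ones((nz, nr), dtype=bool)
    for j, r in enumerate(rc):
        for i, z in enumerate(zc):
            if geometry.is_solid(z, r):
                fluid[i, j] = False

    # feature resolvability checks
    for box in geometry.carve_boxes:
        if box.r0 == geometry.lumen_radius:  # aperture channel
            inside = np.sum((zc > box.z0) & (zc < box.z1))
            if inside < 2:
                raise RefinementError(
                    f"pit aperture at z∈[{box.z0:.2f},{box.z1:.2f}] µm resolved "
                    f"by {inside} cells (< 2) at level {refinement_level}"
                )
    if geometry.plate_inner_radius is not None:
        below = np.sum(rc < geometry.plate_inner_radius)
        if below < 2:
            raise RefinementError(
                "perforation plate opening resolved by fewer than 2 radial "
                f"cells at level {refinement_level}"
            )

    region = np.full((nz, nr), -1, dtype=np.int8)
    p = geometry.params
    z_v0, z_v1 = p.extension_length, p.extension_length + p.vessel_length
    for i, z in enumerate(zc):
        for j, r in enumerate(rc):
            if not fluid[i, j]:
                continue
            if geometry.plate_span and geometry.plate_span[0] <= z <= geometry.plate_span[1]:
                region[i, j] = Mesh.REGIONS["plate"]
            elif z < z_v0 or z > z_v1:
                region[i, j] = Mesh.REGIONS["extension"]
            elif r > geometry.lumen_radius:
                region[i, j] = Mesh.REGIONS["cavity"]
            else:
                region[i, j] = Mesh.REGIONS["lumen"]

    patches, membrane_faces = _classify_faces(geometry, z_edges, r_edges, fluid)

    mesh = Mesh(
        geometry=geometry,
        refinement_level=refinement_level,
        z_edges=z_edges,
        r_edges=r_edges,
        fluid=fluid,
        patch_faces=patches,
        membrane_faces=membrane_faces,
        cell_region=region,
    )
    ar = mesh.max_aspect_ratio()
    if ar > ASPECT_RATIO_WARN:
        logger.warning(
            "mesh quality: max cell aspect ratio %.1f exceeds %.0f", ar,
            ASPECT_RATIO_WARN,
        )
    logger.info(
        "mesh level %d: %d x %d grid, %d fluid cells, %d membrane faces",
        refinement_level, nz, nr, mesh.cells, len(membrane_faces),
    )
    return mesh


def _classify_faces(geometry, z_edges, r_edges, fluid):
    nz, nr = fluid.shape
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    patches: dict[str, list[tuple[str, int, int]]] = {
        name: [] for name in geometry.boundary_patches
    }
    membrane_faces: list[tuple[int, int, int]] = []
    mem_r = {}
    for k, seg in enumerate(geometry.membrane_segments):
        mem_r.setdefault(round(seg.radius, 9), []).append((k, seg))
    plate = geometry.plate_span
    plate_inner = geometry.plate_inner_radius

    def in_plate(z, r):
        return (
            plate is not None
            and plate[0] - 1e-9 <= z <= plate[1] + 1e-9
            and (plate_inner or 0.0) - 1e-9 <= r <= geometry.lumen_radius + 1e-9
        )

    def in_carve(z, r):
        return any(b.contains(z, r) for b in geometry.carve_boxes)

    def wall_label(z_fluid, r_fluid, z_solid, r_solid):
        """Label a wall face by its solid side (fluid side as fallback)."""
        if z_solid is not None and in_plate(z_solid, r_solid):
            return "plate_wall"
        if in_carve(z_fluid, r_fluid):
            return "pit_cavity_wall"
        return "vessel_wall"

    # z-normal faces
    for j in range(nr):
        for i in range(nz + 1):
            left = fluid[i - 1, j] if i > 0 else None
            right = fluid[i, j] if i < nz else None
            if i == 0 and right:
                patches["inlet"].append(("z", 0, j))
            elif i == nz and left:
                patches["outlet"].append(("z", nz, j))
            elif i not in (0, nz) and left != right:
                fi = i - 1 if left else i  # fluid cell index
                si = i if left else i - 1  # solid cell index
                lbl = wall_label(zc[fi], rc[j], zc[si], rc[j])
                patches[lbl].append(("z", i, j))
    # r-normal faces
    for i in range(nz):
        for j in range(1, nr + 1):
            below = fluid[i, j - 1]
            above = fluid[i, j] if j < nr else False
            if below == above:
                continue
            if not below:  # solid below, fluid above (e.g. cavity floor)
                lbl = wall_label(zc[i], rc[j], zc[i], rc[j - 1])
                patches[lbl].append(("r", i, j))
                continue
            # fluid below, solid (or outer boundary) above
            key = round(r_edges[j], 9)
            seg_hit = None
            for k, seg in mem_r.get(key, []):
                if seg.z0 - 1e-9 <= zc[i] <= seg.z1 + 1e-9:
                    seg_hit = k
                    break
            if seg_hit is not None:
                membrane_faces.append((i, j, seg_hit))
                patches["membrane"].append(("r", i, j))
            else:
                z_s = zc[i] if j < nr else None
                r_s = rc[j] if j < nr else None
                lbl = wall_label(zc[i], rc[j - 1], z_s, r_s)
                patches[lbl].append(("r", i, j))
    return patches, membrane_faces


# -- grid independence -------------------------------------------------

@dataclass
class GridIndependenceReport:
    """Pressure-drop convergence under nested refinement.

    ``converged`` is true iff the last successive relative change in Δp is
    below the 0.5 % criterion; ``production_level`` is the first level at
    which that criterion is met.
    """

    levels: list[int]
    cell_counts: list[int]
    pressure_drops: list[float]  # Pa
    final_relative_change: float
    converged: bool
    production_level: int | None

    def to_records(self) -> list[dict]:
        rows = []
        prev = None
        for lvl, n, dp in zip(self.levels, self.cell_counts, self.pressure_drops):
            change = abs(dp - prev) / abs(dp) if prev is not None else math.nan
            rows.append(
                {"level": lvl, "cells": n, "pressure_drop_pa": dp,
                 "relative_change": change}
            )
            prev = dp
        return rows


def grid_independence_study(
    geometry: GeometryDomain,
    levels: Sequence[int],
    bc: BoundaryConditions | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
    sizing: MeshSizing | None = None,
) -> GridIndependenceReport:
    """Solve the flow at each refinement level and test Δp convergence."""
    from .solver import solve_flow, summarize_flow  # deferred: avoids cycle

    if len(levels) < 2:
        raise ValueError("grid independence needs at least 2 levels")
    bc = bc or BoundaryConditions()
    fluid_props = fluid or FluidProperties()
    config = config or SolverConfig()
    counts, drops = [], []
    for lvl in levels:
        mesh = generate_mesh(geometry, lvl, sizing)
        try:
            field = solve_flow(mesh, bc, fluid_props, config)
        except Exception as exc:  # noqa: BLE001 - annotate with level
            raise RuntimeError(f"solver failed at refinement level {lvl}") from exc
        summary = summarize_flow(field, mesh)
        counts.append(int(mesh.cells))
        drops.append(float(summary.pressure_drop))
        logger.info("grid study level %d: %d cells, Δp = %.6g Pa", lvl,
                    mesh.cells, summary.pressure_drop)
    changes = [
        abs(b - a) / abs(b) for a, b in zip(drops[:-1], drops[1:])
    ]
    production = None
    for k, ch in enumerate(changes):
        if ch < CONVERGENCE_CRITERION:
            production = levels[k + 1]
            break
    return GridIndependenceReport(
        levels=list(levels),
        cell_counts=counts,
        pressure_drops=drops,
        final_relative_change=float(changes[-1]),
        converged=bool(changes[-1] < CONVERGENCE_CRITERION),
        production_level=production,
    )
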