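"""Plain-text exports: legacy-VTK fields/outlines, CSV/JSON reports.

The field writer emits an ASCII legacy-VTK rectilinear grid with cell data
(fluid mask, pressure, velocity), readable by ParaView and friends; the
geometry writer emits a polydata outline of the solid features for quick
inspection.  Both are deliberately minimal single-purpose writers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .geometry import GeometryDomain
from .mesh import GridIndependenceReport, Mesh
from .solver import FlowField

__all__ = [
    "write_field_vtk",
    "write_mesh_vtk",
    "write_geometry_outline_vtk",
    "write_json",
    "write_grid_report",
]


def _vtk_header(title: str) -> list[str]:
    return ["# vtk DataFile Version 3.0", title, "ASCII"]


def _rectilinear(mesh: Mesh) -> list[str]:
    lines = [
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {mesh.nz + 1} {mesh.nr + 1} 1",
        f"X_COORDINATES {mesh.nz + 1} double",
        " ".join(f"{z:.9g}" for z in mesh.z_edges),
        f"Y_COORDINATES {mesh.nr + 1} double",
        " ".join(f"{r:.9g}" for r in mesh.r_edges),
        "Z_COORDINATES 1 double",
        "0",
    ]
    return lines


def _cell_scalar(name: str, values: np.ndarray) -> list[str]:
    flat = values.T.ravel()  # VTK runs x fastest
    return [
        f"SCALARS {name} double 1",
        "LOOKUP_TABLE default",
        " ".join("0" if not np.isfinite(x) else f"{x:.9g}" for x in flat),
    ]


def write_mesh_vtk(mesh: Mesh, path: str | Path) -> None:
    lines = _vtk_header("xylemflow mesh (lengths in micrometres)")
    lines += _rectilinear(mesh)
    lines.append(f"CELL_DATA {mesh.nz * mesh.nr}")
    lines += _cell_scalar("fluid", mesh.fluid.astype(float))
    lines += _cell_scalar("region", mesh.cell_region.astype(float))
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_vtk(field: FlowField, path: str | Path) -> None:
    """Velocity (m/s) and pressure (Pa) as cell data on the mesh grid."""
    mesh = field.mesh
    lines = _vtk_header("xylemflow flow field (SI units, lengths in µm)")
    lines += _rectilinear(mesh)
    lines.append(f"CELL_DATA {mesh.nz * mesh.nr}")
    lines += _cell_scalar("fluid", mesh.fluid.astype(float))
    p = np.where(mesh.fluid, field.p_si, 0.0)
    lines += _cell_scalar("pressure", p)
    uz, ur = field.cell_velocity_si()
    uz = np.where(mesh.fluid, uz, 0.0)
    ur = np.where(mesh.fluid, ur, 0.0)
    flat = np.stack([uz.T.ravel(), ur.T.ravel(), np.zeros(uz.size)], axis=1)
    lines.append("VECTORS velocity double")
    lines.append(
        "\n".join(f"{a:.9g} {b:.9g} {c:.9g}" for a, b, c in flat)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def write_geometry_outline_vtk(domain: GeometryDomain, path: str | Path) -> None:
    """Feature outline (domain boundary, solid boxes, membranes) as polylines."""
    points: list[tuple[float, float]] = []
    lines: list[list[int]] = []

    def add_rect(z0, z1, r0, r1):
        base = len(points)
        points.extend([(z0, r0), (z1, r0), (z1, r1), (z0, r1)])
        lines.append([base, base + 1, base + 2, base + 3, base])

    add_rect(0.0, domain.total_length, 0.0, domain.outer_radius)
    for box in domain.solid_boxes + domain.carve_boxes:
        add_rect(box.z0, box.z1, box.r0, box.r1)
    for seg in domain.membrane_segments:
        base = len(points)
        points.extend([(seg.z0, seg.radius), (seg.z1, seg.radius)])
        lines.append([base, base + 1])

    out = _vtk_header(f"xylemflow geometry outline ({domain.tier.name})")
    out.append("DATASET POLYDATA")
    out.append(f"POINTS {len(points)} double")
    out += [f"{z:.9g} {r:.9g} 0" for z, r in points]
    total = sum(len(l) + 1 for l in lines)
    out.append(f"LINES {len(lines)} {total}")
    out += [" ".join(str(x) for x in [len(l), *l]) for l in lines]
    Path(path).write_text("\n".join(out) + "\n")


def write_json(obj, path: str | Path) -> None:
    if is_dataclass(obj) and not isinstance(obj, type):
        obj = asdict(obj)
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def write_grid_report(report: GridIndependenceReport, path: str | Path) -> None:
    """Grid-independence report as JSON (CSV via pandas on .to_records())."""
    payload = {
        "levels": report.levels,
        "cell_counts": report.cell_counts,
        "pressure_drops_pa": report.pressure_drops,
        "final_relative_change": report.final_relative_change,
        "converged": report.converged,
        "production_level": report.production_level,
        "rows": report.to_records(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
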