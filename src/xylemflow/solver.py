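"""Steady incompressible creeping flow through the vessel.

Discretization: finite volumes on the staggered (MAC) arrangement of the
axisymmetric tensor mesh — axial velocity u on z-normal faces, radial
velocity v on r-normal faces, pressure at cell centres.  Boundary
conditions are the study conditions: an axial velocity inlet (developed
profile by default; see :class:`xylemflow.params.BoundaryConditions`),
fixed pressure at the outlet, no-slip walls, symmetry at the axis, and a
porous-jump (Robin) condition on pit-membrane faces whose conductance scales
with the membrane open-area fraction.

Two solution modes share the same discrete operators:

* ``stokes`` (default) — the fully linear Stokes saddle-point system solved
  directly with a sparse LU; deterministic, iteration-free.  At the study's
  Reynolds number (≈ 0.016) the neglected convective terms are negligible,
  which the test-suite checks against the SIMPLEC mode.
* ``simplec`` — SIMPLEC pressure–velocity coupling (see
  :mod:`xylemflow.simplec`), optionally retaining convective terms.

The solver works in nondimensional variables (lengths in µm, velocity in
units of the inlet velocity, pressure in units of µ·u_in/1 µm) so that the
linear system is well conditioned; summaries convert back to SI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .geometry import GeometryDomain, ModelTier
from .mesh import Mesh
from .params import (
    MICRON,
    BoundaryConditions,
    FluidProperties,
    SolverConfig,
    VesselParams,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SolverError",
    "DivergenceError",
    "InfeasibleDomainError",
    "FlowField",
    "FlowSummary",
    "membrane_area_conductance",
    "membrane_face_coefficients",
    "solve_flow",
    "summarize_flow",
]

L_REF = MICRON  # reference length: 1 µm


class SolverError(RuntimeError):
    pass


class DivergenceError(SolverError):
    """Iterative solve failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


class InfeasibleDomainError(SolverError):
    """No open flow path connects the inlet to any outlet."""


# -- membrane porous-jump law ------------------------------------------

def membrane_area_conductance(params: VesselParams, fluid: FluidProperties) -> float:
    """Per-area conductance of the pit membrane, m s⁻¹ Pa⁻¹.

    Sampson–Dagan law for a short circular pore of radius a through a plate
    of thickness t: per-pore resistance 3µ/a³ + 8µt/(πa⁴); pores per unit
    area φ/(πa²).  Multiplying gives the normal face velocity per unit
    pressure jump.  Zero open area gives a sealed (wall) membrane.
    """
    phi = params.membrane_permeability
    if phi <= 0:
        return 0.0
    mu = fluid.dynamic_viscosity
    a = params.membrane_pore_radius * MICRON
    t = params.membrane_thickness * MICRON
    per_pore_resistance = 3 * mu / a**3 + 8 * mu * t / (math.pi * a**4)
    pores_per_area = phi / (math.pi * a**2)
    return pores_per_area / per_pore_resistance


def membrane_face_coefficients(
    mesh: Mesh,
    fluid: FluidProperties,
    seal: bool = False,
) -> np.ndarray:
    """Nondimensional Robin coefficients κ* for every membrane face.

    The porous-jump velocity is v* = κ*·(p*_cell − p*_ext).  The conductance
    is scaled by the circumferential open fraction of the annularised pit
    row so the radial leak area matches the true (discrete) pit area.
    """
    n = len(mesh.membrane_faces)
    if n == 0:
        return np.zeros(0)
    if seal:
        return np.zeros(n)
    params = mesh.geometry.params
    kappa = membrane_area_conductance(params, fluid)
    kappa *= mesh.geometry.circumferential_open_fraction
    # nondimensionalize: v* = (κ µ / L_ref) p*
    return np.full(n, kappa * fluid.dynamic_viscosity / L_REF)


def inlet_profile_values(mesh: Mesh, bc: BoundaryConditions) -> np.ndarray:
    """Nondimensional inlet face velocities per radial cell index.

    Mean over the inlet plane is exactly 1 (units of the inlet velocity).
    The parabolic option uses the exact cell-average of the developed
    profile, 2 − (r_j² + r_{j+1}²)/R², so the discrete inlet flux equals
    u_in·πR² identically.
    """
    fluid_in = mesh.fluid[0, :]
    vals = np.zeros(mesh.nr)
    if bc.inlet_profile == "uniform":
        vals[fluid_in] = 1.0
        return vals
    j_top = int(np.max(np.nonzero(fluid_in)))
    R_in = mesh.r_edges[j_top + 1]
    rE = mesh.r_edges
    vals[fluid_in] = (
        2.0 - (rE[:-1] ** 2 + rE[1:] ** 2)[fluid_in] / R_in**2
    )
    return vals


# -- discrete field ----------------------------------------------------

@dataclass
class FlowField:
    """Discrete velocity/pressure solution on a :class:`Mesh`.

    Velocities are stored nondimensionally (units of the inlet velocity) on
    the staggered faces; SI accessors are provided.  ``converged`` reflects
    the discrete continuity residual (direct mode) or the iteration history
    (SIMPLEC mode).
    """

    mesh: Mesh
    u: np.ndarray  # (nz+1, nr) axial face velocity / u_ref
    v: np.ndarray  # (nz, nr+1) radial face velocity / u_ref
    p: np.ndarray  # (nz, nr) pressure / p_ref, NaN in solid
    u_ref: float  # m s^-1
    p_ref: float  # Pa
    bc: BoundaryConditions
    fluid_props: FluidProperties
    config: SolverConfig
    iterations: int
    residual_history: list[float]
    continuity_residual: float  # max cell imbalance / inlet flux
    converged: bool

    # -- SI views ------------------------------------------------------
    @property
    def u_si(self) -> np.ndarray:
        return self.u * self.u_ref

    @property
    def v_si(self) -> np.ndarray:
        return self.v * self.u_ref

    @property
    def p_si(self) -> np.ndarray:
        return self.p * self.p_ref

    def cell_velocity_si(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centred (u_z, u_r) in m/s, NaN in solid cells."""
        uz = 0.5 * (self.u[:-1, :] + self.u[1:, :]) * self.u_ref
        ur = 0.5 * (self.v[:, :-1] + self.v[:, 1:]) * self.u_ref
        solid = ~self.mesh.fluid
        uz[solid] = np.nan
        ur[solid] = np.nan
        return uz, ur

    def cell_speed_si(self) -> np.ndarray:
        uz, ur = self.cell_velocity_si()
        return np.hypot(uz, ur)

    def region_mean_speed(self, region: str) -> float:
        """Volume-weighted mean speed (m/s) over a mesh region label."""
        code = Mesh.REGIONS[region]
        mask = self.mesh.cell_region == code
        if not mask.any():
            raise ValueError(f"region {region!r} is empty on this mesh")
        speed = self.cell_speed_si()
        vol = self.mesh.cell_volumes()
        return float(np.nansum(speed[mask] * vol[mask]) / vol[mask].sum())

    def max_speed_region(self) -> str:
        """Region label of the cell with the largest speed magnitude."""
        speed = self.cell_speed_si()
        speed = np.where(self.mesh.fluid, speed, -np.inf)
        i, j = np.unravel_index(np.argmax(speed), speed.shape)
        code = int(self.mesh.cell_region[i, j])
        inv = {v: k for k, v in Mesh.REGIONS.items()}
        return inv[code]

    def axial_profile(self, z: float) -> tuple[np.ndarray, np.ndarray]:
        """(r_centers µm, axial velocity m/s) at the column nearest ``z``."""
        i = int(np.argmin(np.abs(self.mesh.z_centers - z)))
        uz = 0.5 * (self.u[i, :] + self.u[i + 1, :]) * self.u_ref
        keep = self.mesh.fluid[i, :]
        return self.mesh.r_centers[keep], uz[keep]


# -- assembly ----------------------------------------------------------

@dataclass
class Assembly:
    """Discrete Stokes operators in block form (all nondimensional).

    Momentum rows are written as  A·vel + G·p = b; continuity rows as
    D_u·u + D_v·v = b_c.  Membrane faces appear as v-unknowns whose
    "momentum" row is the Robin jump condition v − κ*·p_cell = κ*·p_ext.
    """

    mesh: Mesh
    u_index: np.ndarray  # (nz+1, nr) int, -1 if not an unknown
    v_index: np.ndarray  # (nz, nr+1)
    p_index: np.ndarray  # (nz, nr)
    n_u: int
    n_v: int
    n_p: int
    A_uu: sp.csr_matrix
    G_u: sp.csr_matrix
    b_u: np.ndarray
    A_vv: sp.csr_matrix
    G_v: sp.csr_matrix
    b_v: np.ndarray
    D_u: sp.csr_matrix
    D_v: sp.csr_matrix
    b_c: np.ndarray
    membrane_v: np.ndarray  # indices into v unknowns that are membrane faces
    membrane_kappa: np.ndarray
    inlet_values: np.ndarray  # nondimensional inlet face velocity per j
    p_out: float  # nondimensional outlet pressure
    u_ref: float
    p_ref: float


def _check_feasible(mesh: Mesh, kappa: np.ndarray) -> None:
    fluid = mesh.fluid
    if not fluid[0, :].any():
        raise InfeasibleDomainError("no fluid cells at the inlet plane")
    labels, _ = ndimage.label(fluid)
    inlet_labels = set(np.unique(labels[0, :][fluid[0, :]]))
    outlet_ok = bool(inlet_labels & set(np.unique(labels[-1, :][fluid[-1, :]])))
    mem_ok = any(
        labels[i, j - 1] in inlet_labels and k > 0
        for (i, j, _), k in zip(mesh.membrane_faces, kappa)
    )
    if not (outlet_ok or mem_ok):
        raise InfeasibleDomainError(
            "domain is fully blocked: no open axial path and no open membrane"
        )


def assemble(
    mesh: Mesh,
    bc: BoundaryConditions,
    fluid_props: FluidProperties,
    config: SolverConfig,
) -> Assembly:
    """Assemble the nondimensional Stokes blocks on a mesh."""
    bc.validate()
    fluid_props.validate()
    config.validate()
    kappa = membrane_face_coefficients(mesh, fluid_props,
                                       seal=config.seal_membrane)
    _check_feasible(mesh, kappa)

    fluid = mesh.fluid
    nz, nr = fluid.shape
    zE, rE = mesh.z_edges, mesh.r_edges
    zc, rc = mesh.z_centers, mesh.r_centers
    dz = np.diff(zE)
    Az = mesh.z_face_areas()  # annulus areas per radial index

    u_ref = bc.inlet_velocity
    p_ref = fluid_props.dynamic_viscosity * u_ref / L_REF
    p_out = bc.outlet_pressure / p_ref

    mem_lookup = {(i, j): k for k, (i, j, _) in enumerate(mesh.membrane_faces)}
    inflow = inlet_profile_values(mesh, bc)

    # unknown numbering
    u_index = np.full((nz + 1, nr), -1, dtype=np.int64)
    for j in range(nr):
        for i in range(1, nz):
            if fluid[i - 1, j] and fluid[i, j]:
                u_index[i, j] = 0
        if fluid[nz - 1, j]:
            u_index[nz, j] = 0
    n_u = int((u_index == 0).sum())
    u_index[u_index == 0] = np.arange(n_u)
    u_index[u_index < 0] = -1

    v_index = np.full((nz, nr + 1), -1, dtype=np.int64)
    mem_v_ids = np.full(len(mesh.membrane_faces), -1, dtype=np.int64)
    count = 0
    for i in range(nz):
        for j in range(1, nr):
            if fluid[i, j - 1] and fluid[i, j]:
                v_index[i, j] = count
                count += 1
            elif fluid[i, j - 1] and (i, j) in mem_lookup \
                    and kappa[mem_lookup[(i, j)]] != 0.0:
                # sealed membrane faces (κ = 0) stay exact walls
                v_index[i, j] = count
                mem_v_ids[mem_lookup[(i, j)]] = count
                count += 1
        # j == nr membrane faces cannot occur (membrane lies below the
        # outer boundary by construction)
    n_v = count

    p_index = np.full((nz, nr), -1, dtype=np.int64)
    p_index[fluid] = np.arange(int(fluid.sum()))
    n_p = int(fluid.sum())

    def ustate(i: int, j: int):
        """('unk', idx) | ('val', value) for the u point at face (i, j)."""
        if j < 0 or j >= nr:
            return ("val", 0.0)
        if i == 0:
            return ("val", float(inflow[j]))
        idx = u_index[i, j]
        if idx >= 0:
            return ("unk", idx)
        return ("val", 0.0)

    def vstate(i: int, j: int):
        if j <= 0 or j >= nr + 1 or i < 0 or i >= nz:
            return ("val", 0.0)
        idx = v_index[i, j]
        if idx >= 0:
            return ("unk", idx)
        return ("val", 0.0)

    Auu_r, Auu_c, Auu_x = [], [], []
    Gu_r, Gu_c, Gu_x = [], [], []
    b_u = np.zeros(n_u)
    Avv_r, Avv_c, Avv_x = [], [], []
    Gv_r, Gv_c, Gv_x = [], [], []
    b_v = np.zeros(n_v)

    # ---- u momentum ----
    for j in range(nr):
        for i in range(1, nz + 1):
            row = u_index[i, j]
            if row < 0:
                continue
            dzu = (zc[i] - zc[i - 1]) if i < nz else (zE[nz] - zc[nz - 1])
            aP = 0.0

            def couple(state, coef):
                nonlocal aP
                aP += coef
                kind, val = state
                if kind == "unk":
                    Auu_r.append(row)
                    Auu_c.append(val)
                    Auu_x.append(-coef)
                else:
                    b_u[row] += coef * val

            # east / west diffusion (z-direction)
            if i < nz:
                couple(ustate(i + 1, j), Az[j] / (zE[i + 1] - zE[i]))
            couple(ustate(i - 1, j), Az[j] / (zE[i] - zE[i - 1]))
            # north (j+1)
            if j + 1 < nr:
                An = 2 * math.pi * rE[j + 1] * dzu
                nb = ustate(i, j + 1)
                if nb[0] == "unk":
                    couple(nb, An / (rc[j + 1] - rc[j]))
                else:
                    cells_solid = (
                        (not fluid[min(i, nz - 1), j + 1])
                        and (not fluid[max(i - 1, 0), j + 1])
                    )
                    dist = (rE[j + 1] - rc[j]) if cells_solid else (rc[j + 1] - rc[j])
                    couple(("val", 0.0), An / dist)
            else:
                An = 2 * math.pi * rE[nr] * dzu
                couple(("val", 0.0), An / (rE[nr] - rc[j]))  # outer wall
            # south (j-1)
            if j > 0:
                As = 2 * math.pi * rE[j] * dzu
                nb = ustate(i, j - 1)
                if nb[0] == "unk":
                    couple(nb, As / (rc[j] - rc[j - 1]))
                else:
                    cells_solid = (
                        (not fluid[min(i, nz - 1), j - 1])
                        and (not fluid[max(i - 1, 0), j - 1])
                    )
                    dist = (rc[j] - rE[j]) if cells_solid else (rc[j] - rc[j - 1])
                    couple(("val", 0.0), As / dist)
            # (j == 0: axis, zero-area south face, no flux)

            Auu_r.append(row)
            Auu_c.append(row)
            Auu_x.append(aP)
            # pressure gradient: +Az (pE - pW)
            if i < nz:
                Gu_r.append(row)
                Gu_c.append(p_index[i, j])
                Gu_x.append(Az[j])
            else:
                b_u[row] += -Az[j] * p_out  # outlet face pressure
            Gu_r.append(row)
            Gu_c.append(p_index[i - 1, j])
            Gu_x.append(-Az[j])

    # ---- v momentum ----
    mem_rows = set(int(k) for k in mem_v_ids if k >= 0)
    for i in range(nz):
        for j in range(1, nr):
            row = v_index[i, j]
            if row < 0 or row in mem_rows:
                continue
            drv = rc[j] - rc[j - 1]
            dzv = dz[i]
            aP = 0.0

            def couple(state, coef):
                nonlocal aP
                aP += coef
                kind, val = state
                if kind == "unk":
                    Avv_r.append(row)
                    Avv_c.append(val)
                    Avv_x.append(-coef)
                else:
                    b_v[row] += coef * val

            # north / south diffusion (r-direction)
            An = 2 * math.pi * rc[j] * dzv
            couple(vstate(i, j + 1), An / (rE[min(j + 1, nr)] - rE[j]))
            As = 2 * math.pi * rc[j - 1] * dzv
            couple(vstate(i, j - 1), As / (rE[j] - rE[j - 1]))
            # east / west diffusion (z-direction)
            Aew = math.pi * (rc[j] ** 2 - rc[j - 1] ** 2)
            if i + 1 < nz:
                nb = vstate(i + 1, j)
                if nb[0] == "unk":
                    couple(nb, Aew / (zc[i + 1] - zc[i]))
                else:
                    cells_solid = (not fluid[i + 1, j - 1]) and (
                        j >= nr or not fluid[i + 1, min(j, nr - 1)]
                    )
                    dist = (zE[i + 1] - zc[i]) if cells_solid else (zc[i + 1] - zc[i])
                    couple(("val", 0.0), Aew / dist)
            # i + 1 == nz: outlet, zero normal gradient — no flux
            if i > 0:
                nb = vstate(i - 1, j)
                if nb[0] == "unk":
                    couple(nb, Aew / (zc[i] - zc[i - 1]))
                else:
                    cells_solid = (not fluid[i - 1, j - 1]) and (
                        j >= nr or not fluid[i - 1, min(j, nr - 1)]
                    )
                    dist = (zc[i] - zE[i]) if cells_solid else (zc[i] - zc[i - 1])
                    couple(("val", 0.0), Aew / dist)
            else:
                # inlet plane: purely axial inflow, v = 0 on the plane
                couple(("val", 0.0), Aew / (zc[0] - zE[0]))
            # curvature sink  -v / r²
            vol = 2 * math.pi * rE[j] * drv * dzv
            aP += vol / rE[j] ** 2

            Avv_r.append(row)
            Avv_c.append(row)
            Avv_x.append(aP)
            Af = 2 * math.pi * rE[j] * dzv
            Gv_r.append(row)
            Gv_c.append(p_index[i, j])
            Gv_x.append(Af)
            Gv_r.append(row)
            Gv_c.append(p_index[i, j - 1])
            Gv_x.append(-Af)

    # membrane Robin rows: v − κ p_cell = κ p_ext
    for k, (i, j, _) in enumerate(mesh.membrane_faces):
        row = int(mem_v_ids[k])
        if row < 0:
            continue
        Avv_r.append(row)
        Avv_c.append(row)
        Avv_x.append(1.0)
        Gv_r.append(row)
        Gv_c.append(p_index[i, j - 1])
        Gv_x.append(-float(kappa[k]))
        b_v[row] += float(kappa[k]) * p_out

    # ---- continuity ----
    Du_r, Du_c, Du_x = [], [], []
    Dv_r, Dv_c, Dv_x = [], [], []
    b_c = np.zeros(n_p)
    for i in range(nz):
        for j in range(nr):
            if not fluid[i, j]:
                continue
            row = p_index[i, j]

            def add_u(state, coef):
                kind, val = state
                if kind == "unk":
                    Du_r.append(row)
                    Du_c.append(val)
                    Du_x.append(coef)
                else:
                    b_c[row] -= coef * val

            def add_v(state, coef):
                kind, val = state
                if kind == "unk":
                    Dv_r.append(row)
                    Dv_c.append(val)
                    Dv_x.append(coef)
                else:
                    b_c[row] -= coef * val

            add_u(ustate(i + 1, j), Az[j])
            add_u(ustate(i, j), -Az[j])
            add_v(vstate(i, j + 1), 2 * math.pi * rE[j + 1] * dz[i])
            add_v(vstate(i, j), -2 * math.pi * rE[j] * dz[i])

    shape_u = (n_u, n_u)
    return Assembly(
        mesh=mesh,
        u_index=u_index,
        v_index=v_index,
        p_index=p_index,
        n_u=n_u,
        n_v=n_v,
        n_p=n_p,
        A_uu=sp.csr_matrix(sp.coo_matrix((Auu_x, (Auu_r, Auu_c)), shape=shape_u)),
        G_u=sp.csr_matrix(sp.coo_matrix((Gu_x, (Gu_r, Gu_c)), shape=(n_u, n_p))),
        b_u=b_u,
        A_vv=sp.csr_matrix(sp.coo_matrix((Avv_x, (Avv_r, Avv_c)), shape=(n_v, n_v))),
        G_v=sp.csr_matrix(sp.coo_matrix((Gv_x, (Gv_r, Gv_c)), shape=(n_v, n_p))),
        b_v=b_v,
        D_u=sp.csr_matrix(sp.coo_matrix((Du_x, (Du_r, Du_c)), shape=(n_p, n_u))),
        D_v=sp.csr_matrix(sp.coo_matrix((Dv_x, (Dv_r, Dv_c)), shape=(n_p, n_v))),
        b_c=b_c,
        membrane_v=mem_v_ids,
        membrane_kappa=kappa,
        inlet_values=inflow,
        p_out=p_out,
        u_ref=u_ref,
        p_ref=p_ref,
    )


def _field_from_solution(
    asm: Assembly,
    u_sol: np.ndarray,
    v_sol: np.ndarray,
    p_sol: np.ndarray,
    bc: BoundaryConditions,
    fluid_props: FluidProperties,
    config: SolverConfig,
    iterations: int,
    history: list[float],
) -> FlowField:
    mesh = asm.mesh
    nz, nr = mesh.fluid.shape
    u = np.zeros((nz + 1, nr))
    u[0, :] = asm.inlet_values
    mask = asm.u_index >= 0
    u[mask] = u_sol[asm.u_index[mask]]
    v = np.zeros((nz, nr + 1))
    maskv = asm.v_index >= 0
    v[maskv] = v_sol[asm.v_index[maskv]]
    p = np.full((nz, nr), np.nan)
    p[mesh.fluid] = p_sol

    # discrete continuity residual per cell, relative to inlet flux
    div = asm.D_u @ u_sol + asm.D_v @ v_sol - asm.b_c
    Az_in = mesh.z_face_areas()
    q_in = float(np.sum(asm.inlet_values * Az_in * mesh.fluid[0, :]))
    resid = float(np.max(np.abs(div)) / q_in)

    return FlowField(
        mesh=mesh,
        u=u,
        v=v,
        p=p,
        u_ref=asm.u_ref,
        p_ref=asm.p_ref,
        bc=bc,
        fluid_props=fluid_props,
        config=config,
        iterations=iterations,
        residual_history=history,
        continuity_residual=resid,
        converged=resid < 1e-6,
    )


def solve_flow(
    mesh: Mesh,
    bc: BoundaryConditions | None = None,
    fluid: FluidProperties | None = None,
    config: SolverConfig | None = None,
) -> FlowField:
    """Solve the steady flow on a mesh and return the discrete field.

    Deterministic for identical inputs: the direct Stokes path performs a
    single sparse LU factorization with no randomness; the SIMPLEC path uses
    a fixed iteration scheme.
    """
    bc = (bc or BoundaryConditions()).validate()
    fluid_props = (fluid or FluidProperties()).validate()
    config = (config or SolverConfig()).validate()
    asm = assemble(mesh, bc, fluid_props, config)
    if config.mode == "simplec":
        from .simplec import solve_simplec

        u_sol, v_sol, p_sol, iters, history = solve_simplec(
            asm, fluid_props, config
        )
        field = _field_from_solution(
            asm, u_sol, v_sol, p_sol, bc, fluid_props, config, iters, history
        )
        field.converged = field.converged and history[-1] < config.tolerance
        if not field.converged:
            raise DivergenceError(
                f"SIMPLEC did not reach tolerance {config.tolerance:g} in "
                f"{iters} iterations (last residual {history[-1]:.3e})",
                history,
            )
        return field

    K = sp.bmat(
        [
            [asm.A_uu, None, asm.G_u],
            [None, asm.A_vv, asm.G_v],
            [asm.D_u, asm.D_v, None],
        ],
        format="csc",
    )
    rhs = np.concatenate([asm.b_u, asm.b_v, asm.b_c])
    sol = spla.spsolve(K, rhs)
    if not np.all(np.isfinite(sol)):
        raise SolverError("direct Stokes solve produced non-finite values")
    u_sol = sol[: asm.n_u]
    v_sol = sol[asm.n_u : asm.n_u + asm.n_v]
    p_sol = sol[asm.n_u + asm.n_v :]
    field = _field_from_solution(
        asm, u_sol, v_sol, p_sol, bc, fluid_props, config, 1,
        [0.0],
    )
    logger.info(
        "stokes solve: %d unknowns, continuity residual %.2e",
        asm.n_u + asm.n_v + asm.n_p, field.continuity_residual,
    )
    return field


# -- reduction to (Δp, q, R) -------------------------------------------

@dataclass(frozen=True)
class FlowSummary:
    """Reduction of a flow field to pressure drop, flux and resistance.

    ``flux`` is the total delivered volumetric flux (axial outlet flux plus
    membrane efflux to the neighbouring conduit, which sits at the outlet
    pressure); by mass conservation it equals the inlet flux.  The axial and
    membrane components are reported separately because their split is a
    material modelling distinction for pitted vessels.

    ``pressure_drop`` is measured between the extended-domain inlet and
    outlet planes (the extensions exist precisely so entrance and exit
    effects stay out of the vessel proper); ``pressure_drop_vessel`` is the
    same quantity between the vessel-proper end planes.
    """

    pressure_drop: float  # Pa, extended-domain planes
    pressure_drop_vessel: float  # Pa, vessel-proper planes
    flux: float  # m³ s⁻¹, total delivered (axial + membrane)
    flux_axial: float
    flux_membrane: float
    flux_inlet: float
    resistance: float  # Pa s m⁻³ = pressure_drop / flux
    mass_balance_error: float  # |q_in − q_axial − q_mem| / q_in
    tier: ModelTier
    params: VesselParams
    refinement_level: int
    measurement_planes: str = "extended_domain"

    def to_dict(self) -> dict[str, Any]:
        d = {
            "tier": self.tier.name,
            "pressure_drop_pa": self.pressure_drop,
            "pressure_drop_vessel_pa": self.pressure_drop_vessel,
            "flux_m3_s": self.flux,
            "flux_axial_m3_s": self.flux_axial,
            "flux_membrane_m3_s": self.flux_membrane,
            "flux_inlet_m3_s": self.flux_inlet,
            "resistance_pa_s_m3": self.resistance,
            "mass_balance_error": self.mass_balance_error,
            "refinement_level": self.refinement_level,
            "measurement_planes": self.measurement_planes,
        }
        d.update({f"param_{k}": v for k, v in self.params.to_dict().items()})
        return d


def _plane_pressure(field: FlowField, z_plane: float) -> float:
    """Area-averaged pressure (nondim) interpolated to an axial plane."""
    mesh = field.mesh
    zc = mesh.z_centers
    Az = mesh.z_face_areas()
    i1 = int(np.searchsorted(zc, z_plane))
    i0 = i1 - 1
    i0 = max(i0, 0)
    i1 = min(i1, mesh.nz - 1)
    total_a = 0.0
    total_pa = 0.0
    for j in range(mesh.nr):
        if not (mesh.fluid[i0, j] and mesh.fluid[i1, j]):
            continue
        if i0 == i1:
            pj = field.p[i0, j]
        else:
            w = (z_plane - zc[i0]) / (zc[i1] - zc[i0])
            pj = (1 - w) * field.p[i0, j] + w * field.p[i1, j]
        total_a += Az[j]
        total_pa += pj * Az[j]
    return total_pa / total_a


def summarize_flow(field: FlowField, mesh: Mesh | None = None) -> FlowSummary:
    """Reduce a converged field to (Δp, q, R); refuses unconverged fields."""
    mesh = mesh or field.mesh
    if not field.converged:
        raise SolverError(
            "refusing to summarize an unconverged field "
            f"(continuity residual {field.continuity_residual:.3e})"
        )
    Az = mesh.z_face_areas()
    inlet_mask = mesh.fluid[0, :]
    outlet_mask = mesh.fluid[-1, :]
    q_scale = field.u_ref * MICRON**2  # u* · µm² → m³/s
    q_in = float(np.sum(field.u[0, inlet_mask] * Az[inlet_mask])) * q_scale
    q_axial = float(np.sum(field.u[-1, outlet_mask] * Az[outlet_mask])) * q_scale
    q_mem = 0.0
    for i, j, _ in mesh.membrane_faces:
        area = 2 * math.pi * mesh.r_edges[j] * (mesh.z_edges[i + 1] - mesh.z_edges[i])
        q_mem += float(field.v[i, j]) * area
    q_mem *= q_scale
    q_total = q_axial + q_mem

    # inlet-plane pressure: extrapolate cell-centre pressures to z = 0
    zc = mesh.z_centers
    total_a = total_pa = 0.0
    for j in range(mesh.nr):
        if not inlet_mask[j]:
            continue
        if mesh.fluid[1, j]:
            slope = (field.p[1, j] - field.p[0, j]) / (zc[1] - zc[0])
        else:
            slope = 0.0
        pj = field.p[0, j] - slope * (zc[0] - mesh.z_edges[0])
        total_a += Az[j]
        total_pa += pj * Az[j]
    p_in = total_pa / total_a
    dp = (p_in - field.bc.outlet_pressure / field.p_ref) * field.p_ref

    ext = field.mesh.geometry.params.extension_length
    L = field.mesh.geometry.params.vessel_length
    dp_vessel = (
        _plane_pressure(field, ext) - _plane_pressure(field, ext + L)
    ) * field.p_ref

    mass_err = abs(q_in - q_total) / q_in
    if q_total <= 0:
        raise SolverError("non-positive delivered flux; domain may be blocked")
    return FlowSummary(
        pressure_drop=dp,
        pressure_drop_vessel=dp_vessel,
        flux=q_total,
        flux_axial=q_axial,
        flux_membrane=q_mem,
        flux_inlet=q_in,
        resistance=dp / q_total,
        mass_balance_error=mass_err,
        tier=mesh.geometry.tier,
        params=mesh.geometry.params,
        refinement_level=mesh.refinement_level,
    )
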