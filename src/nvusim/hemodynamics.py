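"""Velocity and pressure fields of the phantom.

Lumen: axially developed, axisymmetric generalized Stokes flow of a
Carreau shear-thinning fluid driven by the inlet/outlet pressure
difference.  At capillary scale the Reynolds number is ~1e-3, so the
default solver drops the inertial terms (quasi-steady); a transient
option retains the time derivative for fidelity checks.  The nonlinear
viscosity is converged by damped fixed-point iteration.

Parenchyma: Darcy percolation u = -(kappa/mu_ISF) grad p, with the
pressure solving the incompressibility (Laplace) problem on the tissue
annulus.  Endothelium and basal lamina carry no flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .config import RheologyParams, ISFParams, ScenarioParams
from .mesh import Mesh, LUMEN, TISSUE
from .protocol import smooth_step


class SolverError(RuntimeError):
    """A flow solve failed to converge or was ill-posed."""


# ---------------------------------------------------------------------------
# constitutive law

def carreau_viscosity(shear_rate, rheo: RheologyParams):
    """Carreau dynamic viscosity mu(|gamma_dot|), Pa s.

    mu = mu_inf + (mu_0 - mu_inf) * [1 + (lambda*gd)^2]^((n-1)/2),
    bounded in (mu_inf, mu_0] and non-increasing in shear for n < 1.
    """
    gd = np.asarray(shear_rate, dtype=float)
    if np.any(gd < 0.0):
        raise ValueError("shear rate must be non-negative")
    mu = rheo.mu_inf + (rheo.mu_0 - rheo.mu_inf) * (
        1.0 + (rheo.lambda_c * gd) ** 2) ** ((rheo.n_idx - 1.0) / 2.0)
    return float(mu) if np.ndim(shear_rate) == 0 else mu


def shear_rate_magnitude(dur_dr, dur_dz, duz_dr, duz_dz, ur_over_r):
    """Scalar shear-rate magnitude |gamma_dot| = sqrt(2 eps:eps).

    ``eps`` is the strain-rate tensor of an axisymmetric velocity field
    (u_r(r,z), u_z(r,z)); the hoop component is u_r/r.  In simple shear
    (only du_z/dr = g nonzero) this reduces to |g|.
    """
    e_rr = np.asarray(dur_dr, dtype=float)
    e_zz = np.asarray(duz_dz, dtype=float)
    e_tt = np.asarray(ur_over_r, dtype=float)
    e_rz = 0.5 * (np.asarray(dur_dz, dtype=float) + np.asarray(duz_dr, dtype=float))
    ee = e_rr ** 2 + e_zz ** 2 + e_tt ** 2 + 2.0 * e_rz ** 2
    out = np.sqrt(2.0 * ee)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# pressure protocol

@dataclass(frozen=True)
class PressureDrive:
    """Boundary pressures of the capillary at one instant."""

    t: float
    p_inlet: float
    p_outlet: float
    f_shift: float

    @property
    def drop(self) -> float:
        return self.p_inlet - self.p_outlet


def pressure_driver(t: float, scenario: ScenarioParams) -> PressureDrive:
    """Inlet/outlet pressures under the smoothed step protocol.

    p_in = (p0 + dp) f(t), p_out = (p0 - dp) f(t); the drop 2*dp*f(t)
    is what drives the flow.
    """
    f = smooth_step(t, scenario.t0, scenario.dt_smooth,
                    scenario.amplitude_a, scenario.direction)
    return PressureDrive(t=float(t),
                         p_inlet=(scenario.p0 + scenario.dp) * f,
                         p_outlet=(scenario.p0 - scenario.dp) * f,
                         f_shift=float(f))


# ---------------------------------------------------------------------------
# flow field container

@dataclass
class FlowField:
    """Cell-centred velocity/pressure on the full mesh.

    Velocities are nonzero only in the lumen and parenchyma; the
    endothelium and basal lamina are convection-free.
    """

    u_r: np.ndarray            # (nr, nz), m/s
    u_z: np.ndarray            # (nr, nz), m/s
    p: np.ndarray              # (nr, nz), Pa
    timestamp: float = 0.0
    drive: PressureDrive | None = None
    lumen_profile: np.ndarray | None = None   # u_z per lumen ring
    fp_iterations: int = 0

    def speed(self) -> np.ndarray:
        return np.hypot(self.u_r, self.u_z)


def empty_flow(mesh: Mesh, timestamp: float = 0.0) -> FlowField:
    shape = (mesh.nr, mesh.nz)
    return FlowField(u_r=np.zeros(shape), u_z=np.zeros(shape),
                     p=np.zeros(shape), timestamp=timestamp)


def merge_flow(mesh: Mesh, lumen: FlowField, darcy: FlowField,
               timestamp: float = 0.0) -> FlowField:
    """Combine a lumen solve and a parenchymal solve into one field."""
    out = empty_flow(mesh, timestamp)
    for region, src in ((LUMEN, lumen), (TISSUE, darcy)):
        m = mesh.region_mask(region)
        out.u_r[m] = src.u_r[m]
        out.u_z[m] = src.u_z[m]
        out.p[m] = src.p[m]
    out.drive = lumen.drive
    out.lumen_profile = lumen.lumen_profile
    return out


def lumen_mean_speed(flow: FlowField, mesh: Mesh) -> float:
    """Volume-weighted mean |u| over the lumen."""
    m = mesh.region_mask(LUMEN)
    v = mesh.cell_volumes[m]
    return float((flow.speed()[m] * v).sum() / v.sum())


# ---------------------------------------------------------------------------
# lumen solver

def _lumen_radial_solve(r_faces, r_centers, mu_faces, G, rho=None, dt=None,
                        u_prev=None):
    """One linear solve of the radial momentum balance.

    -(1/r) d/dr (r mu du/dr) = G  (+ optional backward-Euler inertia),
    u(R0) = 0 (no slip), du/dr(0) = 0 (axis symmetry).
    """
    n = len(r_centers)
    cell_meas = 0.5 * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)  # int r dr
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = G * cell_meas
    # interior faces f = 1..n-1 join cells f-1 and f
    dr_c = r_centers[1:] - r_centers[:-1]
    t_int = r_faces[1:n] * mu_faces[1:n] / dr_c          # transmissibility
    diag[:-1] += t_int
    diag[1:] += t_int
    upper[1:] = -t_int     # coefficient of u_{i+1} in row i (banded layout)
    lower[:-1] = -t_int    # coefficient of u_{i-1} in row i
    # wall face: gradient over the half cell to the no-slip boundary
    t_wall = r_faces[n] * mu_faces[n] / (r_faces[n] - r_centers[-1])
    diag[-1] += t_wall
    if rho is not None:
        diag += rho * cell_meas / dt
        rhs = rhs + rho * cell_meas / dt * u_prev
    ab = np.zeros((3, n))
    ab[0, 1:] = upper[1:]
    ab[1, :] = diag
    ab[2, :-1] = lower[:-1]
    return solve_banded((1, 1), ab, rhs)


def _face_shear(r_faces, r_centers, u):
    """|du/dr| at radial faces (axis face 0, wall face one-sided)."""
    n = len(u)
    g = np.zeros(n + 1)
    g[1:n] = np.abs(np.diff(u) / np.diff(r_centers))
    g[n] = np.abs((0.0 - u[-1]) / (r_faces[n] - r_centers[-1]))
    return g


def solve_lumen_flow(mesh: Mesh, rheo: RheologyParams, drive: PressureDrive,
                     mode: str = "quasi_steady", fp_tol: float = 1e-8,
                     fp_max_iter: int = 200, fp_relax: float = 0.7,
                     dt: float = 1e-4, n_steps: int = 200,
                     u0: np.ndarray | None = None) -> FlowField:
    """Axial velocity profile in the lumen under the given drive.

    ``quasi_steady`` converges the Carreau viscosity by damped
    fixed-point iteration on the steady Stokes balance; ``transient``
    time-steps the momentum equation (backward Euler, ``n_steps`` of
    ``dt``) from ``u0`` (rest by default).  The axial pressure is the
    linear interpolant between the drive pressures.
    """
    sl = mesh.ring_slice(LUMEN)
    if sl.stop - sl.start < 8:
        raise SolverError("lumen must be resolved by at least 8 radial cells")
    r_faces = mesh.r_faces[sl.start:sl.stop + 1]
    r_centers = mesh.r_centers[sl]
    L = mesh.geometry.L_capillary
    G = drive.drop / L

    def converge(u, rho=None, dtv=None, u_prev=None):
        if abs(G) < 1e-300:
            return np.zeros_like(r_centers), 1
        for it in range(1, fp_max_iter + 1):
            mu_f = carreau_viscosity(_face_shear(r_faces, r_centers, u), rheo)
            u_new = _lumen_radial_solve(r_faces, r_centers, mu_f, G,
                                        rho=rho, dt=dtv, u_prev=u_prev)
            du = np.max(np.abs(u_new - u))
            scale = max(np.max(np.abs(u_new)), 1e-300)
            u = fp_relax * u_new + (1.0 - fp_relax) * u
            if du / scale < fp_tol:
                return u, it
        raise SolverError(
            f"viscosity fixed point did not converge in {fp_max_iter} "
            f"iterations (relative residual {du / scale:.3e})")

    if mode == "quasi_steady":
        u_start = np.zeros_like(r_centers) if u0 is None else np.array(u0)
        u, its = converge(u_start)
    elif mode == "transient":
        u = np.zeros_like(r_centers) if u0 is None else np.array(u0)
        its = 0
        for _ in range(n_steps):
            u, k = converge(u, rho=rheo.rho_blood, dtv=dt, u_prev=u.copy())
            its += k
    else:
        raise ValueError(f"unknown lumen solver mode '{mode}'")

    flow = empty_flow(mesh, timestamp=drive.t)
    flow.u_z[sl, :] = u[:, None]
    zc = mesh.z_centers
    p_axial = drive.p_inlet + (drive.p_outlet - drive.p_inlet) * zc / L
    flow.p[sl, :] = p_axial[None, :]
    flow.drive = drive
    flow.lumen_profile = u
    flow.fp_iterations = its
    return flow


def generalized_poiseuille_profile(dp_total: float, L: float, R: float,
                                   rheo: RheologyParams, n: int = 600):
    """Independent 1-D reference for fully developed Carreau pipe flow.

    Uses the statically determinate stress profile tau_rz = dp*r/(2L):
    at each radius the shear rate solves mu(g)*g = |tau| (bracketed
    root find), and the velocity is the inward integral of the shear
    rate from the no-slip wall.  Returns (r, u, mean_velocity).
    """
    r = np.linspace(0.0, R, n)
    tau = abs(dp_total) * r / (2.0 * L)

    def gamma_of_tau(tv):
        if tv == 0.0:
            return 0.0
        hi = tv / rheo.mu_inf
        return brentq(lambda g: carreau_viscosity(g, rheo) * g - tv,
                      0.0, hi * 1.0000001, xtol=1e-300, rtol=1e-14)

    gam = np.array([gamma_of_tau(tv) for tv in tau])
    # u(r) = int_r^R gamma ds, cumulative trapezoid from the wall inward
    du = 0.5 * (gam[1:] + gam[:-1]) * np.diff(r)
    cum = np.concatenate([[0.0], np.cumsum(du)])   # int_0^r gamma
    u = cum[-1] - cum                              # int_r^R gamma, u(R) = 0
    mean = 2.0 / R ** 2 * np.trapezoid(u * r, r)
    if dp_total < 0:
        u, mean = -u, -mean
    return r, u, mean


# ---------------------------------------------------------------------------
# parenchymal Darcy flow

def solve_darcy_flow(mesh: Mesh, isf: ISFParams, p_cap_in: float,
                     p_cap_out: float, timestamp: float = 0.0) -> FlowField:
    """Darcy percolation through the parenchyma annulus.

    The pressure solves the axisymmetric Laplace problem with Dirichlet
    values on the two end caps (z = 0 and z = L) and no-flux on the
    inner and outer cylindrical surfaces; the filtration velocity is
    u = -(kappa/mu_ISF) grad p.
    """
    st = mesh.ring_slice(TISSUE)
    nt = st.stop - st.start
    nz = mesh.nz
    if nt == 0:
        raise SolverError("mesh has no parenchyma cells")
    mob = isf.kappa / isf.mu_isf
    rc = mesh.r_centers[st]
    dz = float(np.diff(mesh.z_faces)[0])
    a_rad = mesh.radial_face_areas[st.start:st.stop + 1, :]   # (nt+1, nz)
    a_ax = mesh.axial_face_areas[st]                          # (nt,)

    def idx(i, j):
        return i * nz + j

    rows, cols, vals = [], [], []
    rhs = np.zeros(nt * nz)
    dr_c = np.diff(rc)
    for i in range(nt):
        for j in range(nz):
            me = idx(i, j)
            diag = 0.0
            if i + 1 < nt:
                t = mob * a_rad[i + 1, j] / dr_c[i]
                rows += [me]; cols += [idx(i + 1, j)]; vals += [-t]
                diag += t
            if i > 0:
                t = mob * a_rad[i, j] / dr_c[i - 1]
                rows += [me]; cols += [idx(i - 1, j)]; vals += [-t]
                diag += t
            if j + 1 < nz:
                t = mob * a_ax[i] / dz
                rows += [me]; cols += [idx(i, j + 1)]; vals += [-t]
                diag += t
            else:
                t = mob * a_ax[i] / (dz / 2.0)
                diag += t
                rhs[me] += t * p_cap_out
            if j > 0:
                t = mob * a_ax[i] / dz
                rows += [me]; cols += [idx(i, j - 1)]; vals += [-t]
                diag += t
            else:
                t = mob * a_ax[i] / (dz / 2.0)
                diag += t
                rhs[me] += t * p_cap_in
            rows += [me]; cols += [me]; vals += [diag]
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(nt * nz, nt * nz))
    try:
        p = spsolve(A, rhs).reshape(nt, nz)
    except Exception as exc:  # pragma: no cover - scipy raises rarely here
        raise SolverError(f"Darcy pressure solve failed: {exc}") from exc
    if not np.all(np.isfinite(p)):
        raise SolverError("Darcy pressure solve produced non-finite values "
                          "(incompatible boundary setup)")

    # face fluxes -> cell-centred velocities
    u_z_face = np.zeros((nt, nz + 1))
    u_z_face[:, 1:nz] = -mob * (p[:, 1:] - p[:, :-1]) / dz
    u_z_face[:, 0] = -mob * (p[:, 0] - p_cap_in) / (dz / 2.0)
    u_z_face[:, nz] = -mob * (p_cap_out - p[:, -1]) / (dz / 2.0)
    u_r_face = np.zeros((nt + 1, nz))
    u_r_face[1:nt, :] = -mob * (p[1:, :] - p[:-1, :]) / dr_c[:, None]

    flow = empty_flow(mesh, timestamp)
    flow.u_z[st, :] = 0.5 * (u_z_face[:, 1:] + u_z_face[:, :-1])
    flow.u_r[st, :] = 0.5 * (u_r_face[1:, :] + u_r_face[:-1, :])
    flow.p[st, :] = p
    return flow
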