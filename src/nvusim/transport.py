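"""Glucose advection-diffusion-reaction in the four-region phantom.

Finite-volume, cell-centred, axisymmetric.  The scheme is backward
Euler with first-order upwind advection, both implicit; the saturable
carrier (GLUT1) interface fluxes and the hexokinase-phosphofructokinase
sink are linearised per step by lagging their Michaelis-Menten
denominators, which keeps the system matrix an M-matrix: the update is
unconditionally stable, positivity-preserving and discretely
conservative to solver round-off.

Region physics:

* lumen / endothelium / basal lamina: free-medium diffusion tensor
  Dc * diag(sigma_trans, sigma_long), advection only in the lumen;
* parenchyma: porous medium - stored mass alpha*c, effective tensor
  (Dc/tau)(1 + alpha) * diag(sigma), Darcy advection;
* lumen|endothelium and endothelium|basal-lamina interfaces carry
  GLUT1 flux everywhere; the basal-lamina|parenchyma interface carries
  GLUT1 flux on end-foot facets and free diffusive continuity in the
  clefts (the "flux dysconnectivity" of the blood-brain barrier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .config import PhantomConfig, TransportParams, ISFParams
from .constants import AVOGADRO
from .hemodynamics import FlowField
from .mesh import Mesh, LUMEN, ENDO, BL, TISSUE, REGION_CODES


class DomainError(ValueError):
    """Physically inadmissible argument (e.g. negative concentration)."""


class AssemblyError(RuntimeError):
    """Inconsistent mesh/facet labelling during operator assembly."""


class StabilityError(RuntimeError):
    """Requested step violates the explicit boundary-closure constraint."""


@dataclass
class ConcentrationField:
    """Glucose concentration per cell, mol/m^3 (= mM)."""

    c: np.ndarray          # (nr, nz)
    timestamp: float = 0.0

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(c=self.c.copy(), timestamp=self.timestamp)


@dataclass(frozen=True)
class DiffusionModel:
    """Effective diagonal diffusion tensor of one region."""

    D_rr: float
    D_zz: float
    porous: bool = False

    def __post_init__(self):
        if self.D_rr <= 0 or self.D_zz <= 0:
            raise DomainError("diffusion tensor entries must be positive")


@dataclass(frozen=True)
class CarrierSurface:
    """A membrane bearing saturable (Michaelis-Menten) carriers."""

    label: str
    N_glut: float    # 1/m^2
    k_cat: float     # 1/s
    Km: float        # mol/m^3
    mode: str = "symmetric"   # or "one_sided"

    @property
    def vmax_area(self) -> float:
        """Per-area maximal flux, mol/m^2/s."""
        return self.N_glut * self.k_cat / AVOGADRO


def effective_diffusion(region, params: TransportParams,
                        isf: ISFParams) -> DiffusionModel:
    """Effective diffusion tensor for one region.

    Lumen, endothelium and basal lamina use their free-medium
    coefficient; parenchyma combines tortuosity-reduced dispersion
    (Dc/tau) with porosity-weighted porous diffusion (alpha*Dc/tau).
    The anisotropy factors map sigma_long to the capillary axis (z)
    and sigma_trans to the radial direction.
    """
    if isinstance(region, str):
        if region not in REGION_CODES:
            raise AssemblyError(f"unknown region label '{region}'")
        region = REGION_CODES[region]
    if region == LUMEN:
        dc = params.D_lumen
        porous = False
    elif region == ENDO:
        dc = params.D_endothelium
        porous = False
    elif region == BL:
        dc = params.D_bl
        porous = False
    elif region == TISSUE:
        dc = params.D_tissue * (1.0 + isf.alpha_icf) / isf.tau
        porous = True
    else:
        raise AssemblyError(f"unknown region code {region!r}")
    return DiffusionModel(D_rr=dc * params.sigma_trans,
                          D_zz=dc * params.sigma_long, porous=porous)


def consumption_rate(c, region, params: TransportParams):
    """Hexokinase-PFK glucose sink, mol/m^3/s (non-positive).

    rate = -eps * c/(c + K_glc) with eps = k*c_ATP/(1+(c_ATP/K_I)^nH);
    the rate constant k differs per region (blood << endothelium ~
    parenchyma) and the basal lamina is acellular (no consumption).
    """
    carr = np.asarray(c, dtype=float)
    if np.any(carr < 0.0):
        raise DomainError("concentration must be non-negative")
    if isinstance(region, str):
        region = REGION_CODES.get(region)
        if region is None:
            raise AssemblyError("unknown region label")
    k = {LUMEN: params.k_glc_I, ENDO: params.k_glc_E,
         BL: 0.0, TISSUE: params.k_glc_II}.get(region)
    if k is None:
        raise AssemblyError(f"unknown region code {region!r}")
    eps = params.epsilon(k)
    out = -eps * carr / (carr + params.K_glc)
    return float(out) if np.ndim(c) == 0 else out


def glut_flux(c_cis, c_trans, surf: CarrierSurface):
    """Carrier-mediated normal flux (mol/m^2/s), positive cis -> trans.

    ``one_sided`` evaluates a single saturable term on the cis side;
    ``symmetric`` (default) is the net flux of a bidirectional carrier,
    the difference of the two one-sided terms.  Bounded by vmax_area.
    """
    cc = np.asarray(c_cis, dtype=float)
    ct = np.asarray(c_trans, dtype=float)
    if np.any(cc < 0.0) or np.any(ct < 0.0):
        raise DomainError("concentration must be non-negative")
    vma = surf.vmax_area
    f = vma * cc / (surf.Km + cc)
    if surf.mode == "symmetric":
        f = f - vma * ct / (surf.Km + ct)
    elif surf.mode != "one_sided":
        raise DomainError(f"unknown carrier mode '{surf.mode}'")
    return float(f) if np.ndim(c_cis) == 0 and np.ndim(c_trans) == 0 else f


# ---------------------------------------------------------------------------


@dataclass
class StepRecord:
    """Per-step discrete mass accounting (mol)."""

    mass_before: float
    mass_after: float
    influx: float        # boundary advective + Dirichlet inflow, mol
    outflux: float       # boundary advective outflow, mol
    consumed: float      # reaction sink, mol (non-negative)
    residual: float      # |dM - (in - out - consumed)|

    @property
    def relative_residual(self) -> float:
        scale = max(abs(self.mass_before), abs(self.mass_after), 1e-300)
        return self.residual / scale


class TransportSystem:
    """Assembled finite-volume operators for one mesh + parameter set."""

    def __init__(self, mesh: Mesh, config: PhantomConfig,
                 endfeet_mask: np.ndarray):
        self.mesh = mesh
        self.config = config
        self.params = config.transport
        self.isf = config.isf
        self.endfeet_mask = np.asarray(endfeet_mask, dtype=bool)
        if self.endfeet_mask.shape != (mesh.nz,):
            raise AssemblyError("end-feet mask must label every facet of the "
                                "BL|parenchyma interface")
        nr, nz = mesh.nr, mesh.nz
        self.n = nr * nz
        self.region = np.repeat(mesh.region_of_ring, nz)   # flattened (i*nz+j)
        self.volumes = mesh.cell_volumes.reshape(-1)
        storage_coef = np.where(self.region == TISSUE,
                                config.isf.alpha_icf, 1.0)
        self.storage = storage_coef * self.volumes
        self.diff_models = {reg: effective_diffusion(reg, self.params, self.isf)
                            for reg in (LUMEN, ENDO, BL, TISSUE)}
        self._build_carriers()
        self._build_diffusion()
        self._build_consumption()
        self._flow: FlowField | None = None
        self._L_adv = sparse.csr_matrix((self.n, self.n))
        self._b_inlet = np.zeros(self.n)
        self._outflow_cells = np.array([], dtype=int)
        self._outflow_coefs = np.array([])
        self._explicit_in_cells = np.array([], dtype=int)
        self._explicit_in_coefs = np.array([])
        self._lin = None      # lagged MM linearisation (carrier + sink)
        self._lu = None       # cached LU factorisation
        self._step_count = 0

    # -- assembly ----------------------------------------------------------

    def _idx(self, i, j):
        return i * self.mesh.nz + j

    def _build_carriers(self):
        mesh, p = self.mesh, self.params
        mode = self.config.numerics.carrier_mode
        self.surfaces = {
            "lumen|endo": CarrierSurface("lumen|endo", p.N_glut_endo_inner,
                                         p.k_cat, p.Km_glut, mode),
            "endo|bl": CarrierSurface("endo|bl", p.N_glut_endo_outer,
                                      p.k_cat, p.Km_glut, mode),
            "bl|tissue:end_foot": CarrierSurface(
                "bl|tissue:end_foot", p.N_glut_endfeet, p.k_cat, p.Km_glut, mode),
        }
        nz = mesh.nz
        jj = np.arange(nz)
        faces = []   # (cis_cells, trans_cells, areas, surface)
        for inner, label in ((LUMEN, "lumen|endo"), (ENDO, "endo|bl")):
            fi = mesh.interface_face_index(inner)
            cis = self._idx(fi - 1, jj)
            trans = self._idx(fi, jj)
            faces.append((cis, trans, mesh.radial_face_areas[fi, jj],
                          self.surfaces[label]))
        fi = mesh.interface_face_index(BL)
        ef = np.where(self.endfeet_mask)[0]
        faces.append((self._idx(fi - 1, ef), self._idx(fi, ef),
                      mesh.radial_face_areas[fi, ef],
                      self.surfaces["bl|tissue:end_foot"]))
        self._car_cis = np.concatenate([f[0] for f in faces])
        self._car_trans = np.concatenate([f[1] for f in faces])
        self._car_area = np.concatenate([f[2] for f in faces])
        self._car_vma = np.concatenate(
            [np.full(len(f[0]), f[3].vmax_area) for f in faces])
        self._car_km = np.concatenate(
            [np.full(len(f[0]), f[3].Km) for f in faces])
        self._car_mode = mode
        # fixed COO pattern for the per-step carrier operator
        n_f = len(self._car_cis)
        self._car_rows = np.concatenate(
            [self._car_cis, self._car_trans, self._car_cis, self._car_trans])
        self._car_cols = np.concatenate(
            [self._car_cis, self._car_cis, self._car_trans, self._car_trans])
        self._car_slices = n_f

    def _build_diffusion(self):
        mesh = self.mesh
        nr, nz = mesh.nr, mesh.nz
        reg = mesh.region_of_ring
        d_rr = np.array([self.diff_models[r].D_rr for r in reg])
        d_zz = np.array([self.diff_models[r].D_zz for r in reg])
        rows, cols, vals = [], [], []

        def add_face(a, b, t):
            rows.extend([a, a, b, b])
            cols.extend([a, b, b, a])
            vals.extend([t, -t, t, -t])

        jj = np.arange(nz)
        carrier_ifaces = {mesh.interface_face_index(LUMEN),
                          mesh.interface_face_index(ENDO)}
        bl_iface = mesh.interface_face_index(BL)
        for fi in range(1, nr):
            i_a, i_b = fi - 1, fi
            if fi in carrier_ifaces:
                continue
            d_a = mesh.r_faces[fi] - mesh.r_centers[i_a]
            d_b = mesh.r_centers[i_b] - mesh.r_faces[fi]
            t = mesh.radial_face_areas[fi, :] / (d_a / d_rr[i_a] + d_b / d_rr[i_b])
            if fi == bl_iface:
                sel = ~self.endfeet_mask      # clefts: free diffusion
                if not sel.any():
                    continue
                for j, tv in zip(jj[sel], t[sel]):
                    add_face(self._idx(i_a, j), self._idx(i_b, j), tv)
            else:
                for j, tv in zip(jj, t):
                    add_face(self._idx(i_a, j), self._idx(i_b, j), tv)
        dz = float(np.diff(mesh.z_faces)[0])
        for i in range(nr):
            t = mesh.axial_face_areas[i] * d_zz[i] / dz
            for j in range(nz - 1):
                add_face(self._idx(i, j), self._idx(i, j + 1), t)
        L = sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        # optional fixed-concentration end caps on endothelium/basal lamina
        self._dir_cells = np.array([], dtype=int)
        self._dir_coefs = np.array([])
        c0 = self.config.numerics.fixed_endcap_concentration
        if c0 is not None:
            cells, coefs = [], []
            for i in range(nr):
                if reg[i] in (ENDO, BL):
                    t = mesh.axial_face_areas[i] * d_zz[i] / (dz / 2.0)
                    cells += [self._idx(i, 0), self._idx(i, nz - 1)]
                    coefs += [t, t]
            self._dir_cells = np.array(cells, dtype=int)
            self._dir_coefs = np.array(coefs)
            L = L + sparse.coo_matrix(
                (self._dir_coefs, (self._dir_cells, self._dir_cells)),
                shape=(self.n, self.n))
            self._dir_c0 = float(c0)
        self._L_diff = L.tocsr()

    def _build_consumption(self):
        p = self.params
        eps_by_region = {LUMEN: p.epsilon(p.k_glc_I),
                         ENDO: p.epsilon(p.k_glc_E),
                         BL: 0.0,
                         TISSUE: p.epsilon(p.k_glc_II)}
        self._eps = np.array([eps_by_region[r] for r in self.region])

    # -- advection ---------------------------------------------------------

    def set_flow(self, flow: FlowField):
        """Rebuild the advection operator for a new velocity field.

        Interior faces use implicit first-order upwind.  Open
        boundaries carry zero diffusive flux; their advective closure
        is: Danckwerts feed at the upstream lumen cap (total flux =
        u*c_inlet), implicit upwind outflow where the velocity leaves
        the domain, and an explicit zero-gradient influx elsewhere.
        """
        mesh = self.mesh
        nr, nz = mesh.nr, mesh.nz
        reg = mesh.region_of_ring
        u_z = flow.u_z
        u_r = flow.u_r
        face_a, face_b, face_q = [], [], []   # interior faces, q from a to b

        # axial interior faces of the convective regions
        conv = np.where((reg == LUMEN) | (reg == TISSUE))[0]
        jj = np.arange(nz - 1)
        for i in conv:
            q = mesh.axial_face_areas[i] * 0.5 * (u_z[i, :-1] + u_z[i, 1:])
            face_a.append(self._idx(i, jj))
            face_b.append(self._idx(i, jj + 1))
            face_q.append(q)
        # radial interior faces (zero across region interfaces by
        # construction: no slip at the wall, no convection in E/BL)
        jz = np.arange(nz)
        for fi in range(1, nr):
            if reg[fi - 1] != reg[fi] or reg[fi] in (ENDO, BL):
                continue
            q = mesh.radial_face_areas[fi, :] * 0.5 * (u_r[fi - 1, :]
                                                       + u_r[fi, :])
            face_a.append(self._idx(fi - 1, jz))
            face_b.append(self._idx(fi, jz))
            face_q.append(q)
        a = np.concatenate(face_a)
        b = np.concatenate(face_b)
        q = np.concatenate(face_q)
        up = np.where(q >= 0.0, a, b)      # upwind cell of each face
        dn = np.where(q >= 0.0, b, a)
        qa = np.abs(q)
        rows = np.concatenate([up, dn])
        cols = np.concatenate([up, up])
        vals = np.concatenate([qa, -qa])

        # boundary faces: outward flux per boundary cell
        out_cells, out_coefs = [], []
        in_cells, in_coefs = [], []
        inlet_cells, inlet_coefs = [], []

        def classify(cells, flux_out, feed):
            pos = flux_out > 0.0
            neg = flux_out < 0.0
            out_cells.append(cells[pos]); out_coefs.append(flux_out[pos])
            fin = -flux_out[neg]
            if feed or self.config.numerics.venous_inflow:
                inlet_cells.append(cells[neg]); inlet_coefs.append(fin)
            else:
                in_cells.append(cells[neg]); in_coefs.append(fin)

        for j, sgn in ((0, -1.0), (nz - 1, +1.0)):
            for region, feed in ((LUMEN, True), (TISSUE, False)):
                ii = np.where(reg == region)[0]
                classify(self._idx(ii, j),
                         sgn * u_z[ii, j] * mesh.axial_face_areas[ii], feed)
        # outer radial boundary of the parenchyma
        classify(self._idx(nr - 1, jz),
                 u_r[nr - 1, :] * mesh.radial_face_areas[nr, :], False)

        self._out_cells_b = np.concatenate(out_cells).astype(int)
        self._out_coefs_b = np.concatenate(out_coefs)
        rows = np.concatenate([rows, self._out_cells_b])
        cols = np.concatenate([cols, self._out_cells_b])
        vals = np.concatenate([vals, self._out_coefs_b])
        self._L_adv = sparse.coo_matrix((vals, (rows, cols)),
                                        shape=(self.n, self.n)).tocsr()
        self._inlet_cells = np.concatenate(inlet_cells).astype(int)
        self._inlet_coefs = np.concatenate(inlet_coefs)
        self._b_inlet = np.zeros(self.n)
        feed_vals = np.where(self.region[self._inlet_cells] == LUMEN,
                             self.config.scenario.c_inlet,
                             self.config.scenario.c_init_tissue)
        np.add.at(self._b_inlet, self._inlet_cells,
                  self._inlet_coefs * feed_vals)
        self._explicit_in_cells = np.concatenate(in_cells).astype(int)
        self._explicit_in_coefs = np.concatenate(in_coefs)
        self._flow = flow
        self._lu = None   # advection changed: drop the cached factorisation

    # -- stepping ----------------------------------------------------------

    def max_stable_dt(self) -> float:
        """Upper bound imposed by the explicit zero-gradient inflow closure."""
        if len(self._explicit_in_cells) == 0:
            return np.inf
        return float(np.min(self.storage[self._explicit_in_cells]
                            / self._explicit_in_coefs))

    def mass(self, c: np.ndarray) -> float:
        """Discrete stored mass (mol); parenchyma stores alpha*c."""
        return float(self.storage @ c.reshape(-1))

    def carrier_operator(self, c_flat: np.ndarray) -> sparse.csr_matrix:
        """Linearised carrier exchange with lagged MM denominators."""
        a_cis = self._car_area * self._car_vma / (self._car_km
                                                  + c_flat[self._car_cis])
        if self._car_mode == "symmetric":
            a_trans = self._car_area * self._car_vma / (self._car_km
                                                        + c_flat[self._car_trans])
        else:
            a_trans = np.zeros_like(a_cis)
        data = np.concatenate([a_cis, -a_cis, -a_trans, a_trans])
        return sparse.coo_matrix((data, (self._car_rows, self._car_cols)),
                                 shape=(self.n, self.n)).tocsr()

    def step(self, field: ConcentrationField, dt: float
             ) -> tuple[ConcentrationField, StepRecord]:
        """Advance one backward-Euler step of length ``dt``."""
        if dt <= 0.0:
            raise StabilityError("dt must be positive")
        dt_max = self.max_stable_dt()
        if dt > dt_max:
            raise StabilityError(
                f"dt={dt:g} s exceeds the boundary-closure limit; "
                f"use dt <= {dt_max:g} s")
        if self._flow is None:
            raise AssemblyError("set_flow() must be called before stepping")
        c0 = field.c.reshape(-1)
        if np.any(c0 < 0.0):
            raise DomainError("concentration must be non-negative")
        # The MM linearisation is lagged: it is refreshed on a fixed
        # step schedule (every `relinearize_every` steps, counted from
        # construction) so the LU factorisation can be reused in
        # between.  The schedule is tied to the absolute step index,
        # not to flow updates, so runs that differ only in the pressure
        # protocol share identical linearisation points and differ
        # purely through the physics.  The M-matrix structure,
        # conservation and positivity are unaffected by the lag.
        every = self.config.numerics.relinearize_every
        if (self._lin is None or self._lin["dt"] != dt
                or self._step_count % every == 0):
            self._lin = {"cons_coef": self.volumes * self._eps
                         / (c0 + self.params.K_glc),
                         "car": self.carrier_operator(c0), "dt": dt}
            self._lu = None
        if self._lu is None:
            A = (sparse.diags(self.storage / dt) + self._L_diff + self._L_adv
                 + self._lin["car"] + sparse.diags(self._lin["cons_coef"]))
            self._lu = splu(A.tocsc())
        self._step_count += 1
        cons_coef = self._lin["cons_coef"]
        b = self.storage / dt * c0 + self._b_inlet
        if len(self._explicit_in_cells):
            np.add.at(b, self._explicit_in_cells,
                      self._explicit_in_coefs * c0[self._explicit_in_cells])
        if len(self._dir_cells):
            np.add.at(b, self._dir_cells, self._dir_coefs * self._dir_c0)
        c1 = self._lu.solve(b)
        if np.any(c1 < -1e-10 * max(c1.max(), 1e-300)):
            raise DomainError("negative concentration beyond tolerance; "
                              "the scheme should be positivity-preserving")
        # discrete mass accounting (interior fluxes telescope by construction)
        influx = float(self._b_inlet.sum()) * dt
        if len(self._explicit_in_cells):
            influx += dt * float(self._explicit_in_coefs
                                 @ c0[self._explicit_in_cells])
        if len(self._dir_cells):
            influx += dt * float(self._dir_coefs @ (self._dir_c0
                                                    - c1[self._dir_cells]))
        outflux = dt * float(self._out_coefs_b @ c1[self._out_cells_b]) \
            if len(self._out_cells_b) else 0.0
        consumed = dt * float(cons_coef @ c1)
        m0, m1 = self.mass(field.c), float(self.storage @ c1)
        residual = abs((m1 - m0) - (influx - outflux - consumed))
        rec = StepRecord(mass_before=m0, mass_after=m1, influx=influx,
                         outflux=outflux, consumed=consumed, residual=residual)
        return ConcentrationField(c=c1.reshape(field.c.shape),
                                  timestamp=field.timestamp + dt), rec

    # -- diagnostics -------------------------------------------------------

    def interface_fluxes(self, field: ConcentrationField,
                         facet: str) -> np.ndarray:
        """Normal flux density (mol/m^2/s, positive outward) per facet.

        ``facet`` is one of ``lumen|endo``, ``endo|bl``,
        ``bl|tissue:end_foot``, ``bl|tissue:cleft``.
        """
        mesh = self.mesh
        c = field.c
        if facet in ("lumen|endo", "endo|bl", "bl|tissue:end_foot"):
            surf = self.surfaces[facet]
            inner = {"lumen|endo": LUMEN, "endo|bl": ENDO,
                     "bl|tissue:end_foot": BL}[facet]
            fi = mesh.interface_face_index(inner)
            jj = (np.where(self.endfeet_mask)[0]
                  if facet == "bl|tissue:end_foot" else np.arange(mesh.nz))
            return glut_flux(c[fi - 1, jj], c[fi, jj], surf)
        if facet == "bl|tissue:cleft":
            fi = mesh.interface_face_index(BL)
            jj = np.where(~self.endfeet_mask)[0]
            d_a = mesh.r_faces[fi] - mesh.r_centers[fi - 1]
            d_b = mesh.r_centers[fi] - mesh.r_faces[fi]
            d1 = self.diff_models[BL].D_rr
            d2 = self.diff_models[TISSUE].D_rr
            t_per_area = 1.0 / (d_a / d1 + d_b / d2)
            return t_per_area * (c[fi - 1, jj] - c[fi, jj])
        raise AssemblyError(f"unlabelled facet '{facet}'")


def initial_concentration(mesh: Mesh, config: PhantomConfig
                          ) -> ConcentrationField:
    """Region-wise initial condition (lumen at feed level, tissue lower)."""
    s = config.scenario
    per_region = {LUMEN: s.c_init_lumen, ENDO: s.c_init_endo,
                  BL: s.c_init_bl, TISSUE: s.c_init_tissue}
    c = np.empty((mesh.nr, mesh.nz))
    for reg, val in per_region.items():
        c[mesh.region_of_ring == reg, :] = val
    return ConcentrationField(c=c, timestamp=0.0)


def advance_transport(field: ConcentrationField, flow: FlowField, dt: float,
                      system: TransportSystem) -> ConcentrationField:
    """One transport step under ``flow`` (convenience wrapper)."""
    if system._flow is not flow:
        system.set_flow(flow)
    new, _ = system.step(field, dt)
    return new
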