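"""Diffusion tensors, kinetics, carrier fluxes and the FV transport step."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import nvusim as nv
from nvusim.constants import AVOGADRO
from nvusim.mesh import LUMEN, ENDO, BL, TISSUE
from nvusim.transport import (TransportSystem, CarrierSurface,
                              initial_concentration, DomainError,
                              AssemblyError)
from nvusim.hemodynamics import PressureDrive


class TestEffectiveDiffusion:
    def test_lumen_axial_coefficient(self, config):
        d = nv.effective_diffusion("lumen", config.transport, config.isf)
        assert d.D_zz == pytest.approx(3.1e-10)

    def test_parenchyma_combines_porosity_and_tortuosity(self, config):
        """(Dc/tau)(1 + alpha): tortuosity-reduced dispersion plus
        porosity-weighted porous diffusion."""
        iso = config.replace(transport={"sigma_trans": 1.0}).transport
        d = nv.effective_diffusion("parenchyma", iso, config.isf)
        assert d.D_zz == pytest.approx(8.7e-10 * 1.36 / 1.635, rel=1e-6)
        assert d.D_zz == pytest.approx(7.24e-10, rel=1e-3)
        assert d.porous

    @pytest.mark.parametrize("region", ["lumen", "endothelium",
                                        "basal_lamina", "parenchyma"])
    def test_anisotropy_ratio_in_every_region(self, config, region):
        d = nv.effective_diffusion(region, config.transport, config.isf)
        assert d.D_rr / d.D_zz == pytest.approx(0.33)

    def test_unknown_region_rejected(self, config):
        with pytest.raises(AssemblyError):
            nv.effective_diffusion("plasma", config.transport, config.isf)


class TestConsumption:
    def test_saturated_plateau_from_table_arithmetic(self, config):
        """eps = 0.12*1/(1+1^4) = 0.06 mol/m^3/s in parenchyma."""
        p = config.transport
        assert p.epsilon(p.k_glc_II) == pytest.approx(0.06, rel=1e-12)
        rate = nv.consumption_rate(1e3, "parenchyma", p)
        assert rate == pytest.approx(-0.06, rel=1e-4)

    def test_half_saturation_at_K_glc(self, config):
        eps = config.transport.epsilon(config.transport.k_glc_II)
        assert nv.consumption_rate(0.05, "parenchyma", config.transport) \
            == pytest.approx(-eps / 2)

    def test_zero_at_zero_and_acellular_basal_lamina(self, config):
        assert nv.consumption_rate(0.0, "parenchyma", config.transport) == 0.0
        assert nv.consumption_rate(5.0, "basal_lamina", config.transport) == 0.0

    def test_negative_concentration_rejected(self, config):
        with pytest.raises(DomainError):
            nv.consumption_rate(-1.0, "parenchyma", config.transport)


class TestGlutFlux:
    def test_endothelial_vmax_area_arithmetic(self, config):
        surf = CarrierSurface("endo", 1e15, 1.166e3, 8.0)
        assert surf.vmax_area == pytest.approx(1e15 * 1.166e3 / AVOGADRO)
        assert surf.vmax_area == pytest.approx(1.94e-6, rel=1e-2)

    def test_half_saturation_at_Km(self, config):
        surf = CarrierSurface("endo", 1e15, 1.166e3, 8.0, mode="symmetric")
        assert nv.glut_flux(8.0, 0.0, surf) == pytest.approx(surf.vmax_area / 2)

    def test_symmetric_carrier_has_no_net_flux_at_equilibrium(self):
        surf = CarrierSurface("s", 1e15, 1.166e3, 8.0, mode="symmetric")
        assert nv.glut_flux(3.3, 3.3, surf) == 0.0

    def test_end_feet_half_saturated_flux(self):
        surf = CarrierSurface("ef", 1.8e13, 1.166e3, 8.0, mode="symmetric")
        expected = (18e12 * 1166 / 6.022e23) / 2
        assert nv.glut_flux(8.0, 0.0, surf) == pytest.approx(expected, rel=1e-3)

    def test_one_sided_mode_ignores_trans_side(self):
        surf = CarrierSurface("s", 1e15, 1.166e3, 8.0, mode="one_sided")
        assert nv.glut_flux(8.0, 100.0, surf) == nv.glut_flux(8.0, 0.0, surf)

    @given(cc=st.floats(0.0, 1e3), ct=st.floats(0.0, 1e3))
    def test_saturation_bound_property(self, cc, ct):
        surf = CarrierSurface("s", 1e15, 1.166e3, 8.0, mode="symmetric")
        assert abs(nv.glut_flux(cc, ct, surf)) <= surf.vmax_area

    def test_negative_concentration_rejected(self):
        surf = CarrierSurface("s", 1e15, 1.166e3, 8.0)
        with pytest.raises(DomainError):
            nv.glut_flux(-0.1, 0.0, surf)


def _static_system(config, nr=24, nz=40, **overrides):
    cfg = config.replace(numerics={"nr": nr, "nz": nz}, **overrides)
    mesh = nv.build_mesh(cfg.geometry, nr, nz)
    mask = nv.make_endfeet_mask(cfg.endfeet, mesh)
    system = TransportSystem(mesh, cfg, mask)
    zero = nv.solve_darcy_flow(mesh, cfg.isf, 0.0, 0.0)
    system.set_flow(zero)
    return cfg, mesh, system


class TestTransportStep:
    def test_uniform_equilibrium_is_stationary(self, config):
        """No flow, no consumption, no carriers, uniform field: the
        step must reproduce the field exactly."""
        cfg, mesh, system = _static_system(
            config,
            transport={"N_glut_endo_inner": 0.0, "N_glut_endo_outer": 0.0,
                       "N_glut_endfeet": 0.0, "k_glc_E": 0.0,
                       "k_glc_II": 0.0, "k_glc_I": 0.0},
            scenario={"c_init_lumen": 1.0, "c_init_endo": 1.0,
                      "c_init_bl": 1.0, "c_init_tissue": 1.0, "c_inlet": 1.0})
        c = initial_concentration(mesh, cfg)
        for _ in range(5):
            c, rec = system.step(c, 0.05)
        assert np.allclose(c.c, 1.0, rtol=1e-12)

    def test_sealed_parenchyma_consumption_matches_ode_oracle(self, config):
        """Volume-average of a sealed, well-mixed parenchyma must follow
        dc/dt = -(eps/alpha) c/(c+K), integrated by a stiff ODE solver."""
        kin = {"N_glut_endo_inner": 0.0, "N_glut_endo_outer": 0.0,
               "N_glut_endfeet": 0.0}
        cfg, mesh, system = _static_system(config, transport=kin)
        c = initial_concentration(mesh, cfg)
        t_end, dt = 2.0, 2e-3
        for _ in range(int(t_end / dt)):
            c, _ = system.step(c, dt)
        got = nv.region_average(c, mesh, "parenchyma").mean
        p = cfg.transport
        eps = p.epsilon(p.k_glc_II)
        alpha = cfg.isf.alpha_icf

        def rhs(t, y):
            return -eps / alpha * y / (y + p.K_glc)

        ode = solve_ivp(rhs, (0.0, t_end), [1.0], method="Radau",
                        rtol=1e-10, atol=1e-12)
        assert got == pytest.approx(float(ode.y[0, -1]), rel=5e-3)

    def test_pure_advection_translates_a_pulse(self, config):
        """A passive axial pulse in the lumen moves at the flow speed
        (first-order upwind: correct centroid, diffused shape)."""
        kin = {"N_glut_endo_inner": 0.0, "N_glut_endo_outer": 0.0,
               "N_glut_endfeet": 0.0,
               "D_lumen": 1e-14, "k_glc_E": 0.0}
        cfg = config.replace(
            transport=kin,
            scenario={"c_init_lumen": 0.0, "c_inlet": 0.0},
            numerics={"nr": 24, "nz": 80, "dt": 1e-4})
        cfg = cfg.replace(transport={"k_glc_I": 0.0, "k_glc_II": 0.0,
                                     "k_glc_E": 0.0})
        mesh = nv.build_mesh(cfg.geometry, 24, 80)
        mask = nv.make_endfeet_mask(cfg.endfeet, mesh)
        system = TransportSystem(mesh, cfg, mask)
        u0 = 1.0e-3
        flow = nv.solve_darcy_flow(mesh, cfg.isf, 0.0, 0.0)
        flow.u_z[mesh.region_mask(LUMEN)] = u0   # uniform plug flow
        system.set_flow(flow)
        c = initial_concentration(mesh, cfg)
        sl = mesh.ring_slice(LUMEN)
        j0 = 20
        c.c[sl, j0 - 2:j0 + 3] = 1.0
        n_steps, dt = 60, 1e-4
        for _ in range(n_steps):
            c, _ = system.step(c, dt)
        lum = c.c[sl, :].mean(axis=0)
        centroid = float((lum * mesh.z_centers).sum() / lum.sum())
        start = float(mesh.z_centers[j0])
        dz = float(np.diff(mesh.z_faces)[0])
        assert centroid - start == pytest.approx(u0 * n_steps * dt, abs=dz)

    def test_mass_balance_residual_per_step(self, coarse_config):
        cfg = coarse_config
        mesh = nv.build_mesh(cfg.geometry, cfg.numerics.nr, cfg.numerics.nz)
        mask = nv.make_endfeet_mask(cfg.endfeet, mesh)
        system = TransportSystem(mesh, cfg, mask)
        drive = nv.pressure_driver(0.0, cfg.scenario)
        lum = nv.solve_lumen_flow(mesh, cfg.rheology, drive)
        dar = nv.solve_darcy_flow(mesh, cfg.isf, cfg.scenario.dp_isf, 0.0)
        system.set_flow(nv.merge_flow(mesh, lum, dar))
        c = initial_concentration(mesh, cfg)
        for _ in range(20):
            c, rec = system.step(c, cfg.numerics.dt)
            assert rec.relative_residual < 1e-10
            assert c.c.min() >= 0.0

    def test_carrier_interface_fluxes_bounded_by_vmax(self, config):
        cfg, mesh, system = _static_system(config)
        c = initial_concentration(mesh, cfg)
        for _ in range(10):
            c, _ = system.step(c, 1e-2)
        for facet in ("lumen|endo", "endo|bl", "bl|tissue:end_foot"):
            flux = system.interface_fluxes(c, facet)
            vma = system.surfaces[facet].vmax_area
            assert np.all(np.abs(flux) <= vma * (1 + 1e-12))

    def test_cleft_facet_equal_concentrations_zero_flux(self, config):
        cfg, mesh, system = _static_system(config)
        c = initial_concentration(mesh, cfg)   # BL and tissue both 1 mM
        flux = system.interface_fluxes(c, "bl|tissue:cleft")
        assert np.allclose(flux, 0.0)

    def test_unlabelled_facet_rejected(self, config):
        cfg, mesh, system = _static_system(config)
        c = initial_concentration(mesh, cfg)
        with pytest.raises(AssemblyError):
            system.interface_fluxes(c, "lumen|tissue")

    def test_dense_carriers_approach_concentration_continuity(self, config):
        """Scaling every carrier density x10, x100 must monotonically
        shrink the concentration jump across the lumen|endothelium
        interface (symmetric carriers approach continuity)."""
        jumps = []
        for scale in (1.0, 10.0, 100.0):
            tr = {"N_glut_endo_inner": 1e15 * scale,
                  "N_glut_endo_outer": 1e15 * scale,
                  "N_glut_endfeet": 1.8e13 * scale}
            cfg, mesh, system = _static_system(config, transport=tr)
            c = initial_concentration(mesh, cfg)
            for _ in range(40):
                c, _ = system.step(c, 5e-3)
            fi = mesh.interface_face_index(LUMEN)
            jumps.append(float(np.mean(c.c[fi - 1, :] - c.c[fi, :])))
        assert jumps[0] > jumps[1] > jumps[2] >= 0.0

    def test_porous_storage_uses_porosity(self, config):
        """Stored parenchymal mass is alpha*c*V."""
        cfg, mesh, system = _static_system(config)
        c = initial_concentration(mesh, cfg)
        m = system.mass(c.c)
        vols = mesh.cell_volumes
        expected = 0.0
        for reg, cini in ((LUMEN, 5.0), (ENDO, 1.0), (BL, 1.0)):
            expected += cini * vols[mesh.region_mask(reg)].sum()
        expected += cfg.isf.alpha_icf * 1.0 * vols[mesh.region_mask(TISSUE)].sum()
        assert m == pytest.approx(expected, rel=1e-12)

    def test_invalid_dt_rejected(self, config):
        cfg, mesh, system = _static_system(config)
        c = initial_concentration(mesh, cfg)
        with pytest.raises(Exception):
            system.step(c, 0.0)
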