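"""Carreau rheology, lumen flow, Darcy percolation and the drive."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import nvusim as nv
from nvusim.hemodynamics import (PressureDrive, _face_shear,
                                 generalized_poiseuille_profile)
from nvusim.mesh import TISSUE


class TestCarreau:
    def test_zero_shear_limit_is_mu0(self, config):
        assert nv.carreau_viscosity(0.0, config.rheology) == pytest.approx(5.6e-2)

    def test_infinite_shear_asymptote_is_mu_inf(self, config):
        assert nv.carreau_viscosity(1e9, config.rheology) == pytest.approx(
            3.45e-3, rel=1e-4)

    def test_value_at_inverse_time_constant(self, config):
        r = config.rheology
        expected = r.mu_inf + (r.mu_0 - r.mu_inf) * 2 ** ((r.n_idx - 1) / 2)
        assert nv.carreau_viscosity(1.0 / r.lambda_c, r) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_shear_rejected(self, config):
        with pytest.raises(ValueError):
            nv.carreau_viscosity(-1.0, config.rheology)

    @given(mu_inf=st.floats(1e-4, 1e-2), ratio=st.floats(1.5, 100.0),
           lam=st.floats(1e-3, 10.0), n=st.floats(0.1, 0.99),
           g=st.floats(0.0, 1e5))
    def test_bounded_and_monotone_property(self, mu_inf, ratio, lam, n, g):
        rheo = nv.RheologyParams(rho_blood=1060.0, mu_0=mu_inf * ratio,
                                 mu_inf=mu_inf, lambda_c=lam, n_idx=n)
        mu = nv.carreau_viscosity(g, rheo)
        assert mu_inf < mu <= rheo.mu_0
        assert nv.carreau_viscosity(g * 2 + 1e-6, rheo) <= mu + 1e-18


class TestShearRateMagnitude:
    def test_simple_shear_recovers_gradient(self):
        g = 123.0
        assert nv.shear_rate_magnitude(0, 0, g, 0, 0) == pytest.approx(g)

    def test_rigid_translation_is_zero(self):
        assert nv.shear_rate_magnitude(0, 0, 0, 0, 0) == 0.0

    def test_quadratic_axial_profile(self):
        # u_z = c r^2 -> du_z/dr = 2 c r, pure shear
        c, r = 7.0, np.linspace(0.1, 1.0, 5)
        duz_dr = 2 * c * r
        out = nv.shear_rate_magnitude(np.zeros_like(r), np.zeros_like(r),
                                      duz_dr, np.zeros_like(r),
                                      np.zeros_like(r))
        assert np.allclose(out, 2 * c * r)


class TestPressureDriver:
    def test_initial_time_is_unshifted(self, config):
        d = nv.pressure_driver(0.0, config.scenario)
        s = config.scenario
        assert d.f_shift == 1.0
        assert d.p_inlet == pytest.approx(s.p0 + s.dp)
        assert d.p_outlet == pytest.approx(s.p0 - s.dp)

    def test_terminal_decrease_and_increase_levels(self, config):
        dec = config.scenario
        assert nv.pressure_driver(4.0, dec).f_shift == pytest.approx(0.3)
        inc = config.replace(scenario={"direction": "increase",
                                       "amplitude_a": 0.5}).scenario
        assert nv.pressure_driver(4.0, inc).f_shift == pytest.approx(1.5)

    def test_baseline_never_shifts(self, config):
        base = config.replace(scenario={"direction": "baseline"}).scenario
        for t in (0.0, 2.0, 4.0):
            assert nv.pressure_driver(t, base).f_shift == 1.0


class TestLumenFlow:
    def test_newtonian_limit_matches_poiseuille(self, mesh, config,
                                                newtonian_rheology):
        drive = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        flow = nv.solve_lumen_flow(mesh, newtonian_rheology, drive)
        g = config.geometry
        mean_exact = g.R0 ** 2 * drive.drop / (8 * 3.45e-3 * g.L_capillary)
        assert nv.lumen_mean_speed(flow, mesh) == pytest.approx(
            mean_exact, rel=5e-3)

    def test_zero_drop_gives_zero_field(self, mesh, config):
        drive = PressureDrive(0.0, 2466.0, 2466.0, 1.0)
        flow = nv.solve_lumen_flow(mesh, config.rheology, drive)
        assert np.all(flow.u_z == 0.0)

    def test_carreau_profile_matches_radial_shooting_oracle(self, mesh, config):
        """FV solver vs an independent stress-inversion quadrature.

        The oracle solves tau_rz = dp*r/(2L) pointwise for the shear
        rate and integrates the velocity from the no-slip wall; it
        shares no code path with the finite-volume fixed point.
        """
        drive = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        flow = nv.solve_lumen_flow(mesh, config.rheology, drive)
        g = config.geometry
        _, _, mean_oracle = generalized_poiseuille_profile(
            drive.drop, g.L_capillary, g.R0, config.rheology)
        assert nv.lumen_mean_speed(flow, mesh) == pytest.approx(
            mean_oracle, rel=5e-3)

    def test_grid_convergence_toward_oracle(self, config):
        drive = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        g = config.geometry
        _, _, mean_oracle = generalized_poiseuille_profile(
            drive.drop, g.L_capillary, g.R0, config.rheology)
        errs = []
        for nr in (24, 48, 96):
            m = nv.build_mesh(g, nr, 8)
            f = nv.solve_lumen_flow(m, config.rheology, drive)
            errs.append(abs(nv.lumen_mean_speed(f, m) / mean_oracle - 1.0))
        assert errs[2] < errs[1] < errs[0]

    def test_no_slip_and_axis_symmetry(self, mesh, config):
        drive = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        flow = nv.solve_lumen_flow(mesh, config.rheology, drive)
        u = flow.lumen_profile
        sl = mesh.ring_slice(0)
        r_faces = mesh.r_faces[sl.start:sl.stop + 1]
        shear = _face_shear(r_faces, mesh.r_centers[sl], u)
        assert shear[0] == 0.0                      # symmetry at the axis
        assert u[-1] < u[0]                         # wall-adjacent slowest
        assert np.all(np.diff(u) <= 0.0)            # monotone profile
        # extrapolated wall velocity is zero by construction of the scheme
        assert abs(u[-1]) < abs(u[0])

    def test_quasi_steady_linearity_at_frozen_viscosity(self, mesh,
                                                        newtonian_rheology):
        d1 = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        d2 = PressureDrive(0.0, 2471.0, 2461.0, 1.0)
        f1 = nv.solve_lumen_flow(mesh, newtonian_rheology, d1)
        f2 = nv.solve_lumen_flow(mesh, newtonian_rheology, d2)
        assert nv.lumen_mean_speed(f2, mesh) == pytest.approx(
            nv.lumen_mean_speed(f1, mesh) / 2.0, rel=1e-6)

    def test_transient_relaxes_to_quasi_steady(self, mesh, config):
        """After the viscous time scale (~rho R^2/mu ~ 15 us) the
        transient solution must sit on the quasi-steady one."""
        drive = PressureDrive(0.0, 2476.0, 2456.0, 1.0)
        qs = nv.solve_lumen_flow(mesh, config.rheology, drive)
        tr = nv.solve_lumen_flow(mesh, config.rheology, drive,
                                 mode="transient", dt=5e-6, n_steps=40)
        assert nv.lumen_mean_speed(tr, mesh) == pytest.approx(
            nv.lumen_mean_speed(qs, mesh), rel=1e-2)

    def test_baseline_reynolds_number_is_small(self, mesh, config):
        drive = nv.pressure_driver(0.0, config.scenario)
        flow = nv.solve_lumen_flow(mesh, config.rheology, drive)
        g = config.geometry
        u = nv.lumen_mean_speed(flow, mesh)
        mu_wall = nv.carreau_viscosity(4 * u / g.R0, config.rheology)
        re = config.rheology.rho_blood * u * 2 * g.R0 / mu_wall
        assert re < 1e-2


class TestDarcy:
    def test_uniform_gradient_closed_form(self, mesh, config):
        """1 Pa/m axial gradient gives |u| = kappa/mu = 9.29e-12 m/s."""
        L = config.geometry.L_capillary
        flow = nv.solve_darcy_flow(mesh, config.isf, p_cap_in=L * 1.0,
                                   p_cap_out=0.0)
        m = mesh.region_mask(TISSUE)
        expected = config.isf.kappa / config.isf.mu_isf
        assert expected == pytest.approx(9.2857e-12, rel=1e-4)
        assert np.allclose(flow.u_z[m], expected, rtol=1e-8)
        assert np.allclose(flow.u_r[m], 0.0, atol=1e-20)

    def test_zero_gradient_gives_zero_velocity(self, mesh, config):
        flow = nv.solve_darcy_flow(mesh, config.isf, 5.0, 5.0)
        assert np.allclose(flow.u_z, 0.0, atol=1e-18)

    def test_darcy_linearity(self, mesh, config):
        f1 = nv.solve_darcy_flow(mesh, config.isf, 1.0, 0.0)
        f2 = nv.solve_darcy_flow(mesh, config.isf, 2.0, 0.0)
        assert np.allclose(f2.u_z, 2.0 * f1.u_z, rtol=1e-10, atol=1e-25)

    def test_default_drive_gives_literature_percolation_speed(self, mesh,
                                                              config):
        flow = nv.solve_darcy_flow(mesh, config.isf,
                                   config.scenario.dp_isf, 0.0)
        mean, _ = nv.velocity_stats(flow, mesh, "parenchyma")
        assert mean == pytest.approx(5e-7, rel=2e-2)
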