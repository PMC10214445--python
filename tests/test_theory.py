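"""Analytical dumbbell-engulfment model: geometry, energy, kinetics, fits."""

import numpy as np
import pytest
from scipy.integrate import quad

from vesiwrap import theory
from vesiwrap.theory import (DumbbellGeometry, EnergyParams, KineticParams,
                             barrier_fluctuation_scale, energy_derivative,
                             fit_wrap_time, front_velocity, time_to_wrap,
                             wrapped_area, wrapping_energy)
from vesiwrap.units import KBT_REF

D_S = 0.98e-6
KAPPA = 20.0 * KBT_REF
GEO = DumbbellGeometry.conformal(D_S)
GEO_K = DumbbellGeometry.catenoid_neck(D_S)
PAPER_PARAMS = EnergyParams(W=0.76e-6, sigma=100e-9, kappa=KAPPA)


class TestGeometry:
    def test_area_limits(self):
        assert wrapped_area(0.0, GEO) == 0.0
        # rho_n -> 0: full area approaches two complete spheres, 8 pi a^2
        a = GEO.a
        for rho_frac, tol in [(0.05, 0.06), (0.005, 0.006)]:
            g = DumbbellGeometry(a=a, rho_n=rho_frac * a)
            assert wrapped_area(g.s_max, g) == pytest.approx(
                8 * np.pi * a**2, rel=tol)

    def test_area_matches_quadrature(self):
        # independent oracle: numeric surface-of-revolution quadrature of
        # 2 pi r(s) against the analytic piecewise expression
        for geo in (GEO, GEO_K):
            for s_end in np.linspace(0.05, 0.999, 20) * geo.s_max:
                oracle, err = quad(
                    lambda s: 2 * np.pi * geo.profile(s)[0], 0.0, s_end,
                    limit=200, epsabs=1e-22, epsrel=1e-10,
                    points=[geo.s_lobe1, geo.s_fillet])
                assert wrapped_area(s_end, geo) == pytest.approx(
                    oracle, rel=1e-6)

    def test_area_strictly_increasing(self):
        s = np.linspace(0, GEO.s_max, 2000)
        assert np.all(np.diff(wrapped_area(s, GEO)) > 0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            wrapped_area(-0.1 * GEO.a, GEO)
        with pytest.raises(ValueError):
            wrapped_area(1.01 * GEO.s_max, GEO)

    def test_profile_continuity(self):
        s = np.linspace(1e-9, GEO.s_max - 1e-9, 50000)
        r, psi, km, kphi = GEO.profile(s)
        # r and psi are continuous across the segment joints
        assert np.max(np.abs(np.diff(r))) < 1e-3 * GEO.a
        assert np.max(np.abs(np.diff(psi))) < 1e-2

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            DumbbellGeometry(a=1e-6, rho_n=2e-6)
        with pytest.raises(ValueError):
            DumbbellGeometry(a=-1.0, rho_n=0.1)


class TestEnergy:
    def test_zero_params_zero_energy(self):
        g = DumbbellGeometry(GEO.a, GEO.rho_n, single_lobe=True)
        p = EnergyParams(W=0.0, sigma=0.0, kappa=0.0)
        s = np.linspace(0, g.s_max, 100)
        assert np.allclose(wrapping_energy(s, p, g), 0.0)

    def test_single_sphere_closed_form(self):
        # classical sphere wrapping: E(phi) = (-W + sigma (1-cos phi)/2)
        #                                     * 2 pi a^2 (1 - cos phi)
        g = DumbbellGeometry(GEO.a, GEO.rho_n, single_lobe=True)
        p = EnergyParams(W=0.5e-6, sigma=80e-9, kappa=0.0)
        phi = np.linspace(0, np.pi, 57)
        e = wrapping_energy(phi * g.a, p, g)
        closed = ((-p.W + p.sigma * (1 - np.cos(phi)) / 2)
                  * 2 * np.pi * g.a**2 * (1 - np.cos(phi)))
        scale = p.W * 2 * np.pi * g.a**2
        assert np.allclose(e, closed, atol=1e-8 * scale)

    def test_energy_derivative_consistent(self):
        # analytic dE/ds matches central differences of E(s)
        s = np.linspace(0.05, 0.95, 40) * GEO.s_max
        h = 1e-6 * GEO.s_max
        de = energy_derivative(s, PAPER_PARAMS, GEO)
        num = (wrapping_energy(s + h, PAPER_PARAMS, GEO)
               - wrapping_energy(s - h, PAPER_PARAMS, GEO)) / (2 * h)
        assert np.allclose(de, num, rtol=5e-4, atol=1e-10)

    def test_waist_dominates_energy_cost(self):
        # the steepest energy cost per wrapped area lies in the neck region
        s = np.linspace(1e-3, 1 - 1e-3, 30000) * GEO.s_max
        de = energy_derivative(s, PAPER_PARAMS, GEO)
        r = GEO.profile(s)[0]
        de_daw = de / (2 * np.pi * r)
        s_star = s[np.argmax(de_daw)]
        lo = GEO.s_waist - GEO.rho_n * np.pi / 2
        hi = GEO.s_waist + GEO.rho_n * np.pi / 2
        assert lo <= s_star <= hi


class TestKinetics:
    def test_stall_contract(self):
        # wherever the drive is non-positive the front speed is zero
        kin = KineticParams(eta_eff=0.8)
        s = np.linspace(0.01, 0.99, 500) * GEO.s_max
        v = front_velocity(s, PAPER_PARAMS, kin, GEO)
        drive = -energy_derivative(s, PAPER_PARAMS, GEO)
        assert np.all(v[drive <= 0] == 0.0)
        assert np.all(v >= 0.0)

    def test_velocity_inverse_in_viscosity(self):
        s = np.linspace(0.01, 0.5, 50) * GEO_K.s_max
        p = EnergyParams(W=0.76e-6, sigma=5e-9, kappa=KAPPA)
        v1 = front_velocity(s, p, KineticParams(eta_eff=0.8), GEO_K)
        v2 = front_velocity(s, p, KineticParams(eta_eff=1.6), GEO_K)
        assert np.allclose(v2, v1 / 2)

    def test_sphere_constant_drive_speed(self):
        # sphere limit, kappa = sigma = 0: drive and drag are both
        # proportional to the circumference, so v = W / (alpha eta) exactly
        g = DumbbellGeometry(GEO.a, GEO.rho_n, single_lobe=True)
        p = EnergyParams(W=0.5e-6, sigma=0.0, kappa=0.0)
        kin = KineticParams(eta_eff=0.8, alpha=1.0)
        s = np.linspace(0.1, 0.9, 20) * g.s_max
        v = front_velocity(s, p, kin, g)
        assert np.allclose(v, p.W / (kin.alpha * kin.eta_eff), rtol=1e-12)

    def test_sphere_wrap_time_closed_form(self):
        # independent oracle: quadrature of the closed-form sphere integrand
        g = DumbbellGeometry(GEO.a, GEO.rho_n, single_lobe=True)
        p = EnergyParams(W=0.5e-6, sigma=60e-9, kappa=0.0)
        kin = KineticParams(eta_eff=0.8)
        res = time_to_wrap(p.sigma, p, kin, g, n_grid=200001)
        assert not res.stalled
        a = g.a
        s_lo = a * np.arcsin(0.05)

        # closed-form drive: dE/ds for the sphere with kappa = 0
        def t_integrand(s):
            phi = s / a
            r = a * np.sin(phi)
            aw = 2 * np.pi * a**2 * (1 - np.cos(phi))
            de = (2 * np.pi * r * (-p.W + p.sigma * (1 - np.cos(phi)) / 2)
                  + p.sigma * aw * np.sin(phi) / (2 * a))
            L = 2 * np.pi * max(r, 0.05 * a)
            return kin.alpha * kin.eta_eff * L / (-de)

        oracle, _ = quad(t_integrand, s_lo, g.s_max - s_lo, limit=400,
                         epsrel=1e-12)
        assert res.time == pytest.approx(oracle, rel=1e-8)

    def test_stall_at_first_contact_when_adhesion_too_weak(self):
        # W below the bending floor 2 kappa / a^2 stalls immediately
        p = EnergyParams(W=0.2e-6, sigma=0.0, kappa=KAPPA)
        res = time_to_wrap(0.0, p, KineticParams(eta_eff=0.8), GEO_K)
        assert res.stalled and res.s_stall == 0.0

    def test_stall_location_at_waist_for_tense_membranes(self):
        # in the conformal-neck geometry the neck's bending cost stalls the
        # front in the waist region once the first lobe completes
        kin = KineticParams(eta_eff=0.8)
        lo = GEO.s_waist - GEO.rho_n * np.pi / 2
        hi = GEO.s_waist + GEO.rho_n * np.pi / 2
        for sigma in (5e-9, 15e-9, 30e-9):
            res = time_to_wrap(sigma, PAPER_PARAMS, kin, GEO)
            assert res.stalled
            assert lo <= res.s_stall <= hi

    def test_wrap_time_monotone_convex_in_tension(self):
        ep = EnergyParams(W=0.76e-6, sigma=0.0, kappa=KAPPA)
        kin = KineticParams(eta_eff=0.8)
        sig = np.linspace(2e-9, 22e-9, 9)
        t = np.array([time_to_wrap(s, ep, kin, GEO_K).time for s in sig])
        assert np.all(np.isfinite(t))
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(t, 2) > 0)

    def test_wrap_time_decreases_with_adhesion(self):
        kin = KineticParams(eta_eff=0.8)
        times = []
        for w in (0.69e-6, 0.76e-6, 0.79e-6):
            ep = EnergyParams(W=w, sigma=0.0, kappa=KAPPA)
            times.append(time_to_wrap(10e-9, ep, kin, GEO_K).time)
        assert times[0] > times[1] > times[2]


class TestFit:
    def test_noiseless_self_consistency(self):
        ep = EnergyParams(W=0.76e-6, sigma=0.0, kappa=KAPPA)
        kin = KineticParams(eta_eff=0.8)
        sig = np.linspace(2e-9, 22e-9, 8)
        t = np.array([time_to_wrap(s, ep, kin, GEO_K).time for s in sig])
        fit = fit_wrap_time(sig, t, GEO_K, kappa=KAPPA)
        assert fit.W == pytest.approx(0.76e-6, rel=1e-4)
        assert fit.eta_eff == pytest.approx(0.8, rel=1e-4)

    def test_duplicate_conflicting_points_still_fit(self):
        ep = EnergyParams(W=0.76e-6, sigma=0.0, kappa=KAPPA)
        kin = KineticParams(eta_eff=0.8)
        sig = np.array([5e-9, 5e-9, 10e-9, 15e-9])
        t = np.array([time_to_wrap(s, ep, kin, GEO_K).time for s in sig])
        t[1] *= 1.4  # conflicting duplicate
        fit = fit_wrap_time(sig, t, GEO_K, kappa=KAPPA)
        assert np.isfinite(fit.W) and np.isfinite(fit.eta_eff)
        assert fit.residuals.shape == (4,)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_wrap_time([1e-9, 2e-9], [10.0, 12.0], GEO_K, kappa=KAPPA)
        with pytest.raises(ValueError):
            fit_wrap_time([1e-9, 2e-9, 3e-9], [np.inf] * 3, GEO_K, kappa=KAPPA)

    def test_time_rescaling_maps_to_viscosity(self):
        # T_i -> lam T_i must rescale eta_eff by lam and leave W unchanged
        ep = EnergyParams(W=0.76e-6, sigma=0.0, kappa=KAPPA)
        kin = KineticParams(eta_eff=0.8)
        sig = np.linspace(2e-9, 22e-9, 8)
        t = np.array([time_to_wrap(s, ep, kin, GEO_K).time for s in sig])
        fit1 = fit_wrap_time(sig, t, GEO_K, kappa=KAPPA)
        fit2 = fit_wrap_time(sig, 3.0 * t, GEO_K, kappa=KAPPA)
        assert fit2.eta_eff == pytest.approx(3.0 * fit1.eta_eff, rel=1e-6)
        assert fit2.W == pytest.approx(fit1.W, rel=1e-6)


class TestBarrier:
    def test_no_barrier_returns_zero(self):
        # strong adhesion, relaxed neck: E decreases monotonically
        p = EnergyParams(W=2e-6, sigma=1e-9, kappa=KAPPA)
        assert barrier_fluctuation_scale(p, GEO_K) == 0.0

    def test_barrier_shrinks_with_adhesion(self):
        sigma = 100e-9
        hs = [barrier_fluctuation_scale(
            EnergyParams(W=w, sigma=sigma, kappa=KAPPA), GEO)
            for w in np.linspace(0.5e-6, 6.0e-6, 12)]
        hs = np.array(hs)
        nz = hs > 0
        assert np.all(np.diff(hs[nz]) < 0)
        assert hs[-1] == 0.0  # no-barrier threshold reached

    def test_order_100nm_for_lab_scale_parameters(self):
        for w in (0.69e-6, 0.76e-6, 0.79e-6):
            for sigma in (50e-9, 100e-9, 200e-9):
                h = barrier_fluctuation_scale(
                    EnergyParams(W=w, sigma=sigma, kappa=KAPPA), GEO)
                assert 30e-9 <= h <= 300e-9
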