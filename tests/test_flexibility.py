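"""Swollen-coil and worm-like-chain flexibility fits, bending forces,
SEC calibration."""

import numpy as np
import pytest

from quadflex import datasets
from quadflex.flexibility import (Environment, WLCParams, bending_force,
                                  equivalent_radii, fit_swollen, force_curve,
                                  hydfit_minimize, rg_benoit_doty, rg_swollen,
                                  sec_calibration, wlc_theory)
from quadflex.io import PropertyRecord
from quadflex.synthetic import simulate_property_table

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestRgSwollen:
    def test_closed_form_n1(self):
        # N=1, v=0.5: Rg = lp / sqrt(6)
        assert rg_swollen(1, 10.0, 0.5) == pytest.approx(10.0 / np.sqrt(6.0))

    def test_value_near_measured_trimer(self):
        assert rg_swollen(3, 34.8, 0.69) == pytest.approx(26.2, abs=0.1)

    def test_monotonic_in_n_and_lp(self):
        n = np.arange(1, 6)
        base = rg_swollen(n, 30.0, 0.6)
        assert np.all(np.diff(base) > 0)
        assert np.all(rg_swollen(n, 31.0, 0.6) > base)

    def test_monotonic_in_v_for_long_chains(self):
        # stiffening (larger v) swells long chains; for N near 1 the
        # (2v+1)(2v+2) prefactor dominates and the trend reverses
        n = np.arange(6, 12)
        assert np.all(rg_swollen(n, 30.0, 0.62) > rg_swollen(n, 30.0, 0.6))

    def test_scaling_limits(self):
        # v = 1, large N: linear growth; v = 0.5: sqrt(N) growth
        big = np.array([50.0, 100.0, 200.0])
        rod = rg_swollen(big, 10.0, 1.0)
        np.testing.assert_allclose(rod[1:] / rod[:-1], 2.0, rtol=0.02)
        coil = rg_swollen(big, 10.0, 0.5)
        np.testing.assert_allclose(coil[1:] / coil[:-1], np.sqrt(2.0),
                                   rtol=0.01)


class TestFitSwollen:
    def test_noise_free_exact_recovery(self):
        n = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        rg = rg_swollen(n, 30.0, 0.6)
        fit = fit_swollen(n, rg)
        assert fit.lp == pytest.approx(30.0, rel=1e-4)
        assert fit.v == pytest.approx(0.6, rel=1e-4)

    def test_matches_dense_grid_oracle(self):
        n = np.array([1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(2)
        rg = rg_swollen(n, 28.0, 0.65) * (1 + rng.normal(0, 0.01, 4))
        fit = fit_swollen(n, rg, 0.02 * rg)
        best = (np.inf, None, None)
        for lp in np.arange(20.0, 40.01, 0.1):
            for v in np.arange(0.5, 1.0001, 0.001):
                ss = np.sum(((rg - rg_swollen(n, lp, v)) / (0.02 * rg)) ** 2)
                if ss < best[0]:
                    best = (ss, lp, v)
        assert fit.lp == pytest.approx(best[1], abs=0.1)
        assert fit.v == pytest.approx(best[2], abs=0.002)

    def test_study_rg_series_gives_reference_parameters(self):
        """The four-construct Rg(N) series returns lp ~= 34.8 A and
        v ~= 0.69, the reference swollen-coil flexibility estimate."""
        n, rg, sig = datasets.swollen_fit_points()
        fit = fit_swollen(n, rg, sig)
        assert fit.lp == pytest.approx(34.8, abs=0.4)
        assert fit.v == pytest.approx(0.69, abs=0.02)
        assert fit.r2 > 0.999

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_swollen([1, 2], [10, 15])


class TestWLCTheory:
    def test_rod_limit(self):
        # lp >> L: Rg -> L / sqrt(12)
        L = 100.0
        assert rg_benoit_doty(L, 1e6) == pytest.approx(L / np.sqrt(12.0),
                                                       rel=1e-3)

    def test_coil_limit(self):
        # L >> lp: Rg^2 -> lp L / 3
        L, lp = 1e6, 10.0
        assert rg_benoit_doty(L, lp) ** 2 == pytest.approx(lp * L / 3.0,
                                                           rel=1e-3)

    def test_sub_bead_chain_rejected(self):
        with pytest.raises(ValueError, match="bead"):
            wlc_theory(500.0, WLCParams(lp=30.0, ml=160.0, d=40.0))

    def test_dt_between_rod_and_sphere_bounds(self):
        # Kirkwood Dt of a flexible chain must lie between the Dt of the
        # fully extended rod of the same beads and a single bead
        env = Environment()
        params = WLCParams(lp=33.0, ml=163.0, d=40.0)
        mw = 30000.0
        _, dt, _ = wlc_theory(mw, params, env, n_mc=100)
        kb = 1.380649e-16
        dt_bead = kb * env.T / (6 * np.pi * env.eta * 20.0e-8)
        n_seg = round(mw / 163.0 / 40.0)
        # straight rod of the same beads
        from quadflex.modeling import kirkwood_friction
        xyz = np.zeros((n_seg, 3))
        xyz[:, 2] = 40.0 * np.arange(n_seg)
        dt_rod = kb * env.T / kirkwood_friction(xyz * 1e-8, 20.0e-8, env.eta)
        assert dt_rod <= dt <= dt_bead

    def test_svedberg_relation(self):
        env = Environment()
        params = WLCParams(lp=33.0, ml=163.0, d=40.0)
        mw = 22849.0
        rg, dt, s = wlc_theory(mw, params, env)
        na, kb = 6.02214076e23, 1.380649e-16
        s_expected = mw * (1 - env.vbar * env.rho) * dt / (na * kb * env.T)
        assert s == pytest.approx(s_expected / 1e-13, rel=1e-12)


class TestEquivalentRadii:
    def test_rg_radius_closed_form(self):
        rec = PropertyRecord(name="x", mw=1e4, rg=19.69)
        r = equivalent_radii(rec)
        assert r.a_g == pytest.approx(np.sqrt(5.0 / 3.0) * 19.69, rel=1e-12)
        assert r.a_g == pytest.approx(25.42, abs=0.01)

    def test_sphere_self_consistency(self):
        # an ideal sphere: all three equivalent radii coincide
        env = Environment()
        a_cm = 20.0e-8
        kb, na = 1.380649e-16, 6.02214076e23
        dt = kb * env.T / (6 * np.pi * env.eta * a_cm)
        mw = 20000.0
        f = 6 * np.pi * env.eta * a_cm
        s = mw * (1 - env.vbar * env.rho) / (na * f) / 1e-13
        rec = PropertyRecord(name="sphere", mw=mw,
                             rg=np.sqrt(3.0 / 5.0) * 20.0, dt=dt, s20w=s)
        r = equivalent_radii(rec, env)
        assert r.a_g == pytest.approx(20.0, rel=1e-9)
        assert r.a_t == pytest.approx(20.0, rel=1e-9)
        assert r.a_s == pytest.approx(20.0, rel=1e-9)

    def test_at_halves_when_dt_doubles(self):
        r1 = equivalent_radii(PropertyRecord(name="a", mw=1e4, dt=1e-6))
        r2 = equivalent_radii(PropertyRecord(name="b", mw=1e4, dt=2e-6))
        assert r2.a_t == pytest.approx(r1.a_t / 2.0, rel=1e-12)


class TestHydfit:
    def test_noiseless_self_consistency(self):
        """A table generated by the WLC theory at (33, 163, 40) is
        recovered to grid/refinement resolution with 100*Delta ~ 0."""
        truth = WLCParams(lp=33.0, ml=163.0, d=40.0)
        mws = sorted(datasets.construct_mws_da().values())
        table = simulate_property_table(truth, mws, cv=0.0)
        fit = hydfit_minimize(table)
        assert fit.lp == pytest.approx(33.0, abs=0.5)
        assert fit.ml == pytest.approx(163.0, abs=2.0)
        assert fit.d == pytest.approx(40.0, abs=1.0)
        assert fit.pct_dev < 0.5
        assert not fit.on_boundary

    def test_scale_consistency_mw_and_ml(self):
        """Multiplying all MW and the true ML by one constant leaves the
        recovered persistence length unchanged (same contour lengths)."""
        mws = [8000.0, 16000.0, 24000.0, 32000.0]
        t1 = simulate_property_table(WLCParams(33.0, 163.0, 40.0), mws,
                                     cv=0.0)
        t2 = simulate_property_table(WLCParams(33.0, 2 * 163.0, 40.0),
                                     [2 * m for m in mws], cv=0.0)
        f1 = hydfit_minimize(t1)
        f2 = hydfit_minimize(t2, ranges={"ml": (10.0, 600.0)})
        assert f2.lp == pytest.approx(f1.lp, abs=1.0)
        assert f2.ml == pytest.approx(2 * f1.ml, rel=0.02)

    def test_noisy_recovery_study(self):
        """With 3% relative property noise the persistence-length estimate
        is unbiased to < 5% at the median.  (Individual replicates scatter
        by ~5 A: the Delta^2 surface has a shallow lp-ML ridge, so the
        single-replicate lp is less precise than its median.  Replicate
        count is scaled down to keep the suite fast.)"""
        truth = WLCParams(lp=33.0, ml=163.0, d=40.0)
        mws = sorted(datasets.construct_mws_da().values())
        lps = []
        for rep in range(12):
            table = simulate_property_table(truth, mws, cv=0.03,
                                            seed=100 + rep)
            fit = hydfit_minimize(table, grid_shape=(7, 10, 5))
            lps.append(fit.lp)
        median_lp = float(np.median(lps))
        assert abs(median_lp - 33.0) / 33.0 < 0.05

    def test_zero_weights_rejected(self):
        rec = PropertyRecord(name="a", mw=1e4, rg=20.0,
                             weights={"rg": 0.0})
        with pytest.raises(ValueError, match="weights"):
            hydfit_minimize([rec, rec])


class TestBendingForce:
    def test_reference_value(self):
        # lp = 22 A, contour 330 A bent on a semicircle: R = 105 A,
        # F = 1/2 kB T lp / R^2 ~ 0.040 pN at 293.15 K
        f = bending_force(22.0, 330.0, T=293.15)
        R = 330.0 / np.pi
        assert R == pytest.approx(105.04, abs=0.01)
        assert f == pytest.approx(0.040, abs=0.002)

    def test_scaling_laws(self):
        f1 = bending_force(30.0, 200.0)
        assert bending_force(60.0, 200.0) == pytest.approx(2 * f1, rel=1e-12)
        # doubling the arc radius quarters the force
        assert bending_force(30.0, 400.0) == pytest.approx(f1 / 4.0,
                                                           rel=1e-12)

    def test_ss_to_folded_force_ratio(self):
        # ssDNA (lp 22 A, 200 A) vs folded multimer (lp 34.8 A, 100 A)
        ratio = bending_force(34.8, 100.0) / bending_force(22.0, 200.0)
        assert ratio == pytest.approx(6.33, abs=0.05)

    def test_geometry_modes(self):
        f_contour = bending_force(30.0, 314.159265, geometry="contour")
        f_ee = bending_force(30.0, 200.0, geometry="end-to-end")
        assert f_contour == pytest.approx(bending_force(30.0, 200.0 * np.pi
                                                        / 2.0,
                                                        geometry="contour"))
        assert f_ee == pytest.approx(0.5 * 1.380649e-23 * 293.15 * 30e-10
                                     / (100e-10) ** 2 * 1e12, rel=1e-9)

    def test_force_curve_monotone_and_lp_ordered(self):
        grid = np.linspace(60.0, 400.0, 35)
        ss = force_curve(22.0, grid)[:, 1]
        g4 = force_curve(34.8, grid)[:, 1]
        ds = force_curve(550.0, grid)[:, 1]
        assert np.all(np.diff(ss) < 0)
        assert np.all(ss < g4) and np.all(g4 < ds)


class TestSecCalibration:
    def test_exact_log_linear_recovery(self):
        kd = np.linspace(0.1, 0.8, 6)
        rs = 10.0 ** (1.8 - 1.2 * kd)
        out = sec_calibration(kd, rs, 0.45)
        assert out["slope"] == pytest.approx(-1.2, rel=1e-9)
        assert out["intercept"] == pytest.approx(1.8, rel=1e-9)
        assert out["rs"] == pytest.approx(10 ** (1.8 - 1.2 * 0.45), rel=1e-9)

    def test_standard_kd_returns_standard_rs(self):
        kd = np.array([0.2, 0.4, 0.6, 0.8])
        rs = 10.0 ** (1.5 - 1.0 * kd)
        out = sec_calibration(kd, rs, 0.4)
        assert out["rs"] == pytest.approx(rs[1], rel=1e-9)

    def test_stokes_einstein_dt(self):
        kd = np.linspace(0.1, 0.9, 5)
        rs = np.full(5, 20.0)
        env = Environment(eta=0.01002)  # water at 20 C
        out = sec_calibration(kd, rs, 0.5, env=env)
        assert out["dt"] == pytest.approx(1.07e-6, rel=0.01)

    def test_extrapolation_warns(self):
        kd = np.linspace(0.2, 0.6, 4)
        rs = 10.0 ** (1.5 - kd)
        with pytest.warns(UserWarning, match="extrapolation"):
            sec_calibration(kd, rs, 0.9)
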