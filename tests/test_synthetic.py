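"""Synthetic-data generators: WLC chains, tandem G4 models, noisy SAXS,
property tables and CD spectra, plus the end-to-end pipeline check."""

import numpy as np
import pytest

from quadflex.ensemble import GAConfig, build_pool, gajoe_select
from quadflex.flexibility import WLCParams
from quadflex.io import ScatteringProfile
from quadflex.modeling import debye_intensity, kirkwood_hydro, \
    SolventEnvironment
from quadflex.saxs import dimensionless_kratky, guinier_fit, ift_pr
from quadflex.synthetic import (G4_STACK_GAP, G4_UNIT_HEIGHT, JunctionSpec,
                                build_g4_multimer, sample_wlc_chain,
                                simulate_cd, simulate_property_table,
                                simulate_saxs)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestWLCChainSampler:
    def test_rigid_limit_is_straight_rod(self):
        chain = sample_wlc_chain(L=200.0, lp=1e9, l_seg=10.0, seed=1)
        assert chain.end_to_end() == pytest.approx(200.0, rel=1e-6)

    def test_tangent_correlation_matches_theory(self):
        # <cos theta> over many joints = exp(-l_seg / lp) within 3 SE
        lp, l_seg = 33.0, 10.0
        chains = sample_wlc_chain(L=200.0, lp=lp, l_seg=l_seg, seed=2,
                                  n_chains=6000)
        cosines = []
        for ch in chains:
            t = np.diff(ch.positions, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            cosines.extend(np.sum(t[1:] * t[:-1], axis=1))
        cosines = np.array(cosines)
        expected = np.exp(-l_seg / lp)
        se = cosines.std(ddof=1) / np.sqrt(cosines.size)
        assert abs(cosines.mean() - expected) < 3 * se

    def test_mean_square_end_to_end_matches_closed_form(self):
        # <R^2> = 2 lp L - 2 lp^2 (1 - exp(-L/lp)) within 3 SE
        lp, L, l_seg = 40.0, 400.0, 4.0
        chains = sample_wlc_chain(L=L, lp=lp, l_seg=l_seg, seed=3,
                                  n_chains=10000)
        r2 = np.array([ch.end_to_end() ** 2 for ch in chains])
        expected = 2 * lp * L - 2 * lp ** 2 * (1 - np.exp(-L / lp))
        se = r2.std(ddof=1) / np.sqrt(r2.size)
        assert abs(r2.mean() - expected) < 3 * se

    def test_reproducible_given_seed(self):
        c1 = sample_wlc_chain(100.0, 30.0, 10.0, seed=7)
        c2 = sample_wlc_chain(100.0, 30.0, 10.0, seed=7)
        np.testing.assert_array_equal(c1.positions, c2.positions)


class TestG4Multimer:
    def test_stacked_dimer_geometry_calibration(self):
        m = build_g4_multimer("22").model
        assert 19.0 <= m.rg() <= 20.0
        assert m.dmax() == pytest.approx(2 * G4_UNIT_HEIGHT + G4_STACK_GAP,
                                         abs=1.0)

    def test_stacked_sediments_faster_than_hinged(self):
        env = SolventEnvironment()
        stacked = build_g4_multimer("212").model
        hinged = build_g4_multimer(
            "212", junctions=[JunctionSpec("hinge", angle_deg=90)] * 2,
            seed=1).model
        s_stacked = kirkwood_hydro(stacked, env, mw=22849.0).s20w
        s_hinged = kirkwood_hydro(hinged, env, mw=22849.0).s20w
        assert s_stacked > s_hinged

    def test_single_unit_globular_kratky(self):
        q = np.linspace(0.006, 0.4, 200)
        m = build_g4_multimer("2").model
        prof = simulate_saxs(m, q, i0_scale=100.0, noise_b=0.0)
        g = guinier_fit(prof)
        _, _, flag = dimensionless_kratky(prof, g.rg, g.i0)
        assert flag == "globular"

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            build_g4_multimer("2x1")


class TestSimulateSaxs:
    def test_zero_noise_is_exact_debye(self):
        q = np.linspace(0.01, 0.3, 80)
        m = build_g4_multimer("22").model
        prof = simulate_saxs(m, q, i0_scale=50.0, noise_b=0.0)
        curve = debye_intensity(m, q).i_model
        np.testing.assert_allclose(prof.i, curve / m.f.sum() ** 2 * 50.0,
                                   rtol=1e-9)

    def test_guinier_recovery_across_seeds(self):
        """Mean Guinier Rg of repeated noisy simulations recovers the
        noise-free value to 0.1% (the ln-transform of noisy intensities
        carries a small but non-zero bias at 2% noise)."""
        q = np.linspace(0.006, 0.25, 150)
        m = build_g4_multimer("2").model
        prof0 = simulate_saxs(m, q, i0_scale=100.0, noise_b=0.0)
        rg_ref = guinier_fit(prof0).rg
        rgs = np.array([guinier_fit(simulate_saxs(m, q, 100.0, noise_b=0.02,
                                                  seed=s)).rg
                        for s in range(60)])
        assert abs(rgs.mean() - rg_ref) / rg_ref < 1e-3
        assert rgs.std(ddof=1) / rg_ref < 0.01

    def test_generating_model_chi2_near_one(self):
        q = np.linspace(0.006, 0.3, 150)
        m = build_g4_multimer("22").model
        prof = simulate_saxs(m, q, i0_scale=100.0, noise_b=0.02, seed=5)
        from quadflex.modeling import fit_single_model
        fit = fit_single_model(prof, m, inflation_grid=[1.0],
                               shell_grid=[0.0])
        assert fit.chi2 == pytest.approx(1.0, abs=3 * np.sqrt(2 / len(q)))


class TestSimulatePropertyTable:
    def test_noiseless_matches_theory(self):
        from quadflex.flexibility import wlc_theory, Environment
        params = WLCParams(lp=33.0, ml=163.0, d=40.0)
        table = simulate_property_table(params, [15000.0, 30000.0], cv=0.0)
        rg, dt, s = wlc_theory(15000.0, params, Environment())
        assert table[0].rg == pytest.approx(rg, rel=1e-12)
        assert table[0].dt == pytest.approx(dt, rel=1e-12)
        assert table[0].s20w == pytest.approx(s, rel=1e-12)

    def test_study_design_mws(self):
        from quadflex import datasets
        mws = datasets.construct_mws_da()
        # the four-construct design: ~7.9, 15.2, 22.8, 30.5 kDa
        assert [round(v / 1000, 1) for v in sorted(mws.values())] == \
            [7.9, 15.2, 22.8, 30.5]

    def test_noise_scale(self):
        params = WLCParams(lp=33.0, ml=163.0, d=40.0)
        ref = simulate_property_table(params, [20000.0], cv=0.0)[0]
        vals = []
        for s in range(200):
            rec = simulate_property_table(params, [20000.0], cv=0.03,
                                          seed=s)[0]
            vals.append(rec.rg / ref.rg - 1.0)
        assert np.std(vals) == pytest.approx(0.03, rel=0.25)


class TestSimulateCD:
    def test_zero_noise_decomposition_roundtrip(self):
        from quadflex.cd import builtin_basis, fit_combinations
        basis = builtin_basis()
        comps = {3: ("hybrid-1", "hybrid-2", "hybrid-2")}
        spec = simulate_cd(comps, basis)[3]
        ranked = fit_combinations(spec, basis, n_units=3)
        assert ranked[0].multiset == tuple(sorted(comps[3]))
        assert ranked[0].rss == pytest.approx(0.0, abs=1e-16)

    def test_planted_slope_recovered(self):
        from quadflex.cd import builtin_basis, correct_and_regress, \
            derive_junction_spectrum, compose_spectrum
        basis = builtin_basis()
        comps = {n: ("hybrid-2",) * n for n in (2, 3, 4)}
        spectra = simulate_cd(comps, basis, junction_scale=0.0,
                              noise_sd=1.0, seed=4)
        zero_j = derive_junction_spectrum(
            [(compose_spectrum(c, basis), c) for c in comps.values()], basis)
        out = correct_and_regress(spectra, zero_j)
        slope_truth = basis.spectra["hybrid-2"][
            np.argmin(np.abs(basis.wavelength - 290.0))]
        assert out["regression_raw"]["slope"] == pytest.approx(slope_truth,
                                                               abs=3.0)


class TestEndToEndPipeline:
    def test_planted_mixture_recovered_and_trimer_pr_triphasic(self):
        """Simulate scattering from a planted 70/30 two-conformer mixture,
        recover the composition by ensemble selection, and verify the
        3-unit stacked model's P(r) is tri-phasic (three local maxima)."""
        q = np.linspace(0.006, 0.3, 120)
        stacked = build_g4_multimer("212").model
        bent = build_g4_multimer(
            "212", junctions=[JunctionSpec("hinge", angle_deg=110)] * 2,
            seed=2).model
        extra = [build_g4_multimer(
            "221", junctions=[JunctionSpec("hinge", angle_deg=a)] * 2,
            seed=s).model for a, s in ((40, 3), (70, 4), (150, 5))]
        pool = build_pool([stacked, bent] + extra, q)
        ia = pool.curves[0] / pool.curves[0][0]
        ib = pool.curves[1] / pool.curves[1][0]
        i_mix = 100.0 * (0.7 * ia + 0.3 * ib)
        sig = 0.005 * np.sqrt(i_mix * 100.0)
        rng = np.random.default_rng(6)
        prof = ScatteringProfile(q, i_mix + rng.normal(0, sig), sig)
        sol = gajoe_select(pool, prof,
                           GAConfig(repeats=20, max_ensemble=10, seed=9))
        assert sol.weights.get(0, 0.0) == pytest.approx(0.7, abs=0.1)
        assert sol.weights.get(1, 0.0) == pytest.approx(0.3, abs=0.1)
        # trimer P(r): three local maxima (tri-phasic)
        prof3 = simulate_saxs(stacked, np.linspace(0.006, 0.4, 250),
                              i0_scale=100.0, noise_b=0.0)
        pd = ift_pr(prof3, dmax=1.05 * stacked.dmax(), alpha="auto")
        p = pd.p
        interior = np.flatnonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:]))
        # merge plateau-adjacent maxima
        peaks = []
        for idx in interior + 1:
            if not peaks or idx - peaks[-1] > 3:
                peaks.append(idx)
        assert len([k for k in peaks if p[k] > 0.05 * p.max()]) == 3
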