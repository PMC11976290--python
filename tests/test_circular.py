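"""Circular statistics: means, Rayleigh, von Mises fits, V_ex machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetaseq.circular import (PhaseSampleSet, bootstrap_proportion,
                               circular_mean, fit_von_mises, hedges_g,
                               rate_matched_subsample, rayleigh_test,
                               simes_correct, trial_mean_phases, vex,
                               vex_permutation_test)
from tests.conftest import vex_bruteforce


class TestCircularMean:
    def test_degenerate_and_hand_computed_cases(self):
        m, r = circular_mean([0.0, 0.0, 0.0])
        assert m == pytest.approx(0.0) and r == pytest.approx(1.0)
        m, r = circular_mean([0.0, np.pi / 2])
        assert m == pytest.approx(np.pi / 4)
        assert r == pytest.approx(np.cos(np.pi / 4))

    def test_antipodal_cancellation_flags_undefined_mean(self):
        m, r = circular_mean([0.0, np.pi])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ph = rng.vonmises(1.0, 2.0, size=200) % (2 * np.pi)
        m, r = circular_mean(ph)
        assert m == pytest.approx(pingouin.circ_mean(ph) % (2 * np.pi))
        assert r == pytest.approx(pingouin.circ_r(ph))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            circular_mean([])


class TestRayleigh:
    def test_perfect_concentration_gives_z_equal_n(self):
        z, p = rayleigh_test(np.zeros(10))
        assert z == pytest.approx(10.0)
        assert p < 1e-3

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ph = rng.vonmises(0.5, 1.0, size=80) % (2 * np.pi)
        z, p = rayleigh_test(ph)
        z2, p2 = pingouin.circ_rayleigh(ph)
        assert z == pytest.approx(z2, rel=1e-6)
        assert p == pytest.approx(p2, rel=1e-3)

    def test_uniform_calibration(self, rng):
        # ~95% of uniform samples should be non-significant at alpha=0.05
        rejections = sum(rayleigh_test(rng.uniform(0, 2 * np.pi, 1000))[1] < 0.05
                         for _ in range(400))
        assert rejections / 400 < 0.10

    def test_small_sample_falls_back_to_monte_carlo(self):
        with pytest.warns(UserWarning, match="Monte-Carlo"):
            _, p = rayleigh_test(np.array([0.1, 0.2, 0.3]))
        assert 0 < p <= 1

    def test_power_matches_monte_carlo_oracle(self, rng):
        # brute-force MC power of the Rayleigh test at kappa=1, n=100
        n_rep = 300
        power = np.mean([rayleigh_test(rng.vonmises(0, 1.0, 100))[1] < 0.05
                         for _ in range(n_rep)])
        assert power > 0.99  # kappa=1 at n=100 is essentially always detected


class TestVonMisesFit:
    def test_uniform_limit_kappa_near_zero(self, rng):
        fit = fit_von_mises(rng.uniform(0, 2 * np.pi, 10_000))
        assert fit.kappa < 0.1

    def test_recovers_planted_kappa_and_mu(self, rng):
        kappas, mus = [], []
        for _ in range(200):
            ph = rng.vonmises(np.pi / 2, 2.0, size=500)
            fit = fit_von_mises(ph)
            kappas.append(fit.kappa)
            mus.append(fit.mu)
        assert 1.7 <= np.median(kappas) <= 2.3
        err = np.angle(np.exp(1j * (np.array(mus) - np.pi / 2)))
        assert abs(np.median(err)) < np.deg2rad(5)

    def test_matches_scipy_mle(self, rng):
        ph = rng.vonmises(1.0, 3.0, size=400)
        fit = fit_von_mises(ph)
        kappa_sp, mu_sp, _ = __import__("scipy.stats", fromlist=["vonmises"]
                                        ).vonmises.fit(ph, fscale=1)
        assert fit.mu == pytest.approx(mu_sp % (2 * np.pi), abs=1e-3)
        assert fit.kappa == pytest.approx(kappa_sp, rel=0.02)

    def test_kappa_bias_shrinks_with_n(self, rng):
        bias = []
        for n in (50, 500, 5000):
            k = np.median([fit_von_mises(rng.vonmises(0, 2.0, n)).kappa
                           for _ in range(60)])
            bias.append(abs(k - 2.0))
        assert bias[2] < bias[0]
        assert bias[2] < 0.1

    def test_identical_phases_cap_flagged(self):
        fit = fit_von_mises(np.full(10, 1.0))
        assert fit.capped and fit.kappa >= 1e3

    def test_binned_fit_close_to_raw(self, rng):
        ph = rng.vonmises(2.0, 2.0, size=2000)
        raw = fit_von_mises(ph)
        binned = fit_von_mises(ph, n_bins=20)
        assert binned.kappa == pytest.approx(raw.kappa, rel=0.15)


class TestVex:
    def test_perfect_separation(self):
        ph = np.repeat([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 4)
        cond = np.repeat([1, 2, 3, 4], 4)
        res = vex(PhaseSampleSet(ph, cond))
        assert res.v_w == pytest.approx(0.0, abs=1e-12)
        assert res.v_ex == pytest.approx(1.0)

    def test_null_limit_near_zero(self, rng):
        ph = rng.uniform(0, 2 * np.pi, 4000)
        cond = np.repeat([1, 2, 3, 4], 1000)
        res = vex(PhaseSampleSet(ph, cond))
        # small positive finite-sample bias is expected; it vanishes as
        # the per-condition trial count grows
        assert abs(res.v_ex) < 0.02

    def test_matches_bruteforce_on_toy_set(self):
        ph = np.array([0.1, 0.4, 0.2, 0.6, 2.0, 2.5, 2.2, 2.8])
        cond = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        res = vex(PhaseSampleSet(ph, cond))
        v_ex, v_w, v_a = vex_bruteforce(ph, cond)
        assert res.v_ex == pytest.approx(v_ex)
        assert res.v_w == pytest.approx(v_w)
        assert res.v_a == pytest.approx(v_a)

    def test_identical_phases_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            vex(PhaseSampleSet(np.full(8, 1.0), np.repeat([1, 2], 4)))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 2 * np.pi), st.integers(0, 2**31 - 1))
    def test_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(0, 2 * np.pi, 24)
        cond = np.repeat([1, 2, 3], 8)
        a = vex(PhaseSampleSet(ph, cond)).v_ex
        b = vex(PhaseSampleSet((ph + rot) % (2 * np.pi), cond)).v_ex
        assert a == pytest.approx(b, abs=1e-9)


class TestVexPermutation:
    def test_pvalue_floor(self, rng):
        # strongly separated conditions: observed beats the whole null
        ph = np.concatenate([rng.vonmises(m, 50.0, 20) % (2 * np.pi)
                             for m in (0, np.pi / 2, np.pi, 3 * np.pi / 2)])
        cond = np.repeat([1, 2, 3, 4], 20)
        res = vex_permutation_test(PhaseSampleSet(ph, cond), n_perm=199, rng=rng)
        assert res.p_value == pytest.approx(1 / 200)

    def test_null_matches_slow_loop(self, rng):
        # the vectorized null agrees in distribution with an explicit
        # label-shuffling loop (compare means and spread)
        ph = rng.uniform(0, 2 * np.pi, 32)
        cond = np.repeat([1, 2, 3, 4], 8)
        res = vex_permutation_test(PhaseSampleSet(ph, cond), n_perm=2000, rng=rng)
        slow = []
        for _ in range(2000):
            res2 = vex(PhaseSampleSet(ph, rng.permutation(cond)))
            slow.append(res2.v_ex)
        assert np.mean(res.null) == pytest.approx(np.mean(slow), abs=0.02)
        assert np.std(res.null) == pytest.approx(np.std(slow), rel=0.15)

    def test_null_pvalues_uniform(self, rng):
        # p-values under the null should be ~Uniform(0,1)
        pvals = []
        for _ in range(300):
            ph = rng.uniform(0, 2 * np.pi, 40)
            cond = np.repeat([1, 2, 3, 4], 10)
            pvals.append(vex_permutation_test(PhaseSampleSet(ph, cond),
                                              n_perm=199, rng=rng).p_value)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_with_planted_separation(self, rng):
        hits = 0
        for _ in range(40):
            ph = np.concatenate([rng.vonmises(m, 2.0, 28) % (2 * np.pi)
                                 for m in np.deg2rad([0, 60, 120, 180])])
            cond = np.repeat([1, 2, 3, 4], 28)
            res = vex_permutation_test(PhaseSampleSet(ph, cond), n_perm=199,
                                       rng=rng)
            hits += res.p_value < 0.05
        assert hits / 40 > 0.5


class TestKappaVexTradeoff:
    def test_pooled_concentration_anticorrelates_with_vex(self, rng):
        # as planted between-position separation grows, V_ex rises while
        # the concentration of the pooled phase distribution falls
        from scipy import stats as sps
        kappas, vexs = [], []
        for _ in range(120):
            spacing = rng.uniform(0, np.pi / 2)
            mus = spacing * np.arange(4)
            ph = np.concatenate([rng.vonmises(m, 4.0, 28) % (2 * np.pi)
                                 for m in mus])
            cond = np.repeat([1, 2, 3, 4], 28)
            kappas.append(fit_von_mises(ph).kappa)
            vexs.append(vex(PhaseSampleSet(ph, cond)).v_ex)
        rho = sps.spearmanr(kappas, vexs).statistic
        assert rho < 0


class TestEffectSizesAndCorrections:
    def test_hedges_g_hand_computed(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        # pooled sd = 1, raw d = -1, small-sample correction 1 - 3/(4*6-9)
        expected = -1.0 * (1 - 3 / 15)
        assert hedges_g(a, b) == pytest.approx(expected)
        assert hedges_g(b, a) == pytest.approx(-expected)
        assert hedges_g(a, a) == pytest.approx(0.0)

    def test_hedges_g_zero_variance_raises(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [1.0, 1.0])

    def test_simes_hand_cases(self):
        gp, rej = simes_correct([0.01, 0.02, 0.03], alpha=0.05)
        assert rej.all()
        assert gp == pytest.approx(0.03)  # min(3*.01/1, 3*.02/2, 3*.03/3)
        _, rej = simes_correct([1.0, 1.0, 1.0])
        assert not rej.any()
        gp, rej = simes_correct([0.03])
        assert gp == pytest.approx(0.03) and rej.all()
        with pytest.raises(ValueError):
            simes_correct([0.0, 0.5])

    def test_bootstrap_proportion_degenerate_and_coverage(self, rng):
        prop, ci, _ = bootstrap_proportion(np.ones(20, bool), n_boot=99, rng=rng)
        assert prop == 1.0 and ci == (1.0, 1.0)
        # coverage: CI should include p_true=0.3 in ~95% of meta-replicates
        cover = 0
        for _ in range(200):
            flags = rng.random(100) < 0.3
            _, (lo, hi), _ = bootstrap_proportion(flags, n_boot=499, rng=rng)
            cover += lo <= 0.3 <= hi
        assert 0.88 <= cover / 200 <= 1.0


class TestRateControl:
    def test_counts_equalized(self, rng):
        a, b = rng.random(100), rng.random(40)
        aa, bb = rate_matched_subsample(a, b, rng=rng)
        assert aa.size == bb.size == 40
        assert set(aa) <= set(a)

    def test_equal_counts_identity(self, rng):
        a, b = rng.random(10), rng.random(10)
        aa, bb = rate_matched_subsample(a, b, rng=rng)
        assert np.array_equal(aa, a) and np.array_equal(bb, b)

    def test_uniform_phases_stay_uniform(self, rng):
        # subsampling must not introduce phase structure
        from scipy import stats
        ph = rng.uniform(0, 2 * np.pi, 5000)
        other = rng.uniform(0, 2 * np.pi, 500)
        sub, _ = rate_matched_subsample(ph, other, rng=rng)
        assert stats.kstest(sub / (2 * np.pi), "uniform").pvalue > 0.01


class TestTrialMeanPhases:
    def test_zero_spike_trials_dropped(self, rng):
        phases = np.array([0.1, 0.2, 1.0, 1.1, 1.2])
        trials = np.array([0, 0, 1, 1, 1])
        conds = {0: 1, 1: 2, 2: 3}  # trial 2 has no spikes
        s = trial_mean_phases(phases, trials, conds)
        assert s.n_trials == 2
        assert set(s.conditions.tolist()) == {1, 2}
        assert s.phases[0] == pytest.approx(circular_mean([0.1, 0.2])[0])
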