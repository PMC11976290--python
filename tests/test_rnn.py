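"""Rate RNN: dynamics, Dale constraint, loss terms, gradients, analysis."""

import numpy as np
import pytest

from thetaseq.rnn import (RnnParams, accuracy, build_network, dale_project,
                          gradients, lfp_peak_frequency, lfp_proxy, loss,
                          make_task_batch, model_phase_analysis,
                          model_reference_oscillation, oscillation_spectrum,
                          phi, reg_osc, sample_spikes_from_rates, simulate,
                          stimulus_selective_units)


class TestTaskBatch:
    def test_evaluation_mode_exact_half_match_and_unique(self):
        b = make_task_batch(224, seed=0, evaluation=True)
        assert b.is_match.sum() == 112
        assert len({tuple(s) for s in b.sequences}) == 224

    def test_one_hot_inputs(self):
        b = make_task_batch(3, seed=1)
        sums = b.u.sum(axis=2)
        assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_input_zero_outside_stimulus_and_probe(self):
        b = make_task_batch(2, seed=2)
        t = b.times
        quiet = (t >= b.delay_window[0]) & (t < b.delay_window[1])
        assert np.all(b.u[:, quiet, :] == 0)
        assert np.all(b.u[:, t < b.stim_onsets[0], :] == 0)

    def test_non_match_probe_differs(self):
        b = make_task_batch(50, seed=3)
        for i in np.where(~b.is_match)[0]:
            assert not np.array_equal(b.sequences[i], b.probe_orders[i])
            assert sorted(b.sequences[i]) == sorted(b.probe_orders[i])

    def test_overlapping_stimuli_rejected(self):
        with pytest.raises(ValueError):
            make_task_batch(1, soa=0.1, stim_dur=0.2)


class TestNetwork:
    def test_dale_invariant_and_reproducibility(self):
        p1 = build_network(n=50, seed=7)
        p2 = build_network(n=50, seed=7)
        assert np.array_equal(p1.J, p2.J) and np.array_equal(p1.I, p2.I)
        for j in range(50):
            col = p1.J[:, j]
            assert np.all(col * p1.sign[j] >= 0)

    def test_spectral_radius_at_target(self):
        p = build_network(n=80, spectral_radius=1.2, seed=1)
        rho = np.abs(np.linalg.eigvals(p.J)).max()
        assert rho == pytest.approx(1.2, rel=1e-6)

    def test_dale_project_clips_wrong_signs(self):
        rng = np.random.default_rng(0)
        J = rng.standard_normal((10, 10))
        sign = np.where(np.arange(10) < 5, 1.0, -1.0)
        P = dale_project(J, sign)
        assert np.all(P[:, :5] >= 0) and np.all(P[:, 5:] <= 0)
        kept = J * sign[None, :] >= 0
        assert np.array_equal(P[kept], J[kept])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            build_network(n=10, frac_excitatory=1.5)


class TestSimulate:
    def test_leak_only_exponential_decay(self):
        n = 4
        p = RnnParams(tau=np.full(n, 0.1), J=np.zeros((n, n)),
                      I=np.zeros((n, 8)), w=np.zeros(n),
                      sign=np.ones(n), sigma_xi=0.0, dt=0.02)
        b = make_task_batch(1, delay=0.5, dt=0.02, seed=0)
        b.u[:] = 0.0
        traj = simulate(p, b, zero_noise=True)
        # x starts at 0 and receives no input: stays 0; drive one step in
        x0 = np.ones(n)
        alpha = p.alpha
        expected = x0 * (1 - alpha) ** 10
        state = x0.copy()
        for _ in range(10):
            state = (1 - alpha) * state
        assert np.allclose(state, expected)
        assert np.allclose(traj.x, 0.0)

    def test_one_step_hand_computed(self):
        # N=2 with hand-set numbers: x1 = (1-a)x0 + a(J phi(x0) + I u0)
        J = np.array([[0.5, -0.3], [0.2, 0.0]])
        I = np.zeros((2, 8))
        I[0, 0] = 1.0
        p = RnnParams(tau=np.array([0.1, 0.2]), J=J, I=I,
                      w=np.array([1.0, -1.0]), sign=np.array([1.0, -1.0]),
                      sigma_xi=0.0, dt=0.02)
        b = make_task_batch(1, delay=0.5, dt=0.02, seed=0)
        b.u[:] = 0.0
        b.u[0, 0, 0] = 1.0  # drive channel 0 at step 0
        traj = simulate(p, b, zero_noise=True)
        alpha = p.alpha
        x1_expected = alpha * (I @ b.u[0, 0])  # x0 = 0 so phi(x0) = 0
        assert np.allclose(traj.x[0, 1], x1_expected)
        x2_expected = ((1 - alpha) * x1_expected
                       + alpha * (J @ phi(x1_expected) + I @ b.u[0, 1]))
        assert np.allclose(traj.x[0, 2], x2_expected)

    def test_zero_noise_deterministic(self):
        p = build_network(n=30, seed=0)
        b = make_task_batch(2, delay=0.5, dt=0.02, seed=1)
        t1 = simulate(p, b, zero_noise=True)
        t2 = simulate(p, b, zero_noise=True)
        assert np.array_equal(t1.x, t2.x)

    def test_noise_reproducible_given_seed(self):
        p = build_network(n=30, seed=0)
        b = make_task_batch(2, delay=0.5, dt=0.02, seed=1)
        t1 = simulate(p, b, noise_seed=5)
        t2 = simulate(p, b, noise_seed=5)
        assert np.array_equal(t1.x, t2.x)


class TestLfpAndRegularizers:
    def test_lfp_zero_rates_and_linearity(self):
        J = np.array([[0.5, -1.0], [0.25, 0.0]])
        rates = np.zeros((1, 5, 2))
        assert np.allclose(lfp_proxy(rates, J), 0.0)
        rates = np.abs(np.random.default_rng(0).standard_normal((1, 5, 2)))
        assert np.allclose(lfp_proxy(rates, 2 * J), 2 * lfp_proxy(rates, J))
        # hand value: a = column sums of |J|
        a = np.array([0.75, 1.0])
        assert np.allclose(lfp_proxy(rates, J), rates @ a)

    def test_reg_osc_pure_sinusoid_is_minus_half(self):
        dt, f = 0.01, 2.0
        t = np.arange(500) * dt  # 5 s = 10 cycles exactly
        assert reg_osc(4.2 * np.sin(2 * np.pi * f * t + 1.0) + 7.0, f, dt) \
            == pytest.approx(-0.5, abs=1e-12)

    def test_reg_osc_amplitude_invariant(self, rng):
        dt, f = 0.01, 2.0
        x = rng.standard_normal(400) + np.sin(2 * np.pi * f * np.arange(400) * dt)
        assert reg_osc(x, f, dt) == pytest.approx(reg_osc(10 * x, f, dt))

    def test_reg_osc_white_noise_near_zero(self, rng):
        vals = [reg_osc(rng.standard_normal(2000), 2.0, 0.01)
                for _ in range(50)]
        assert abs(np.mean(vals)) < 0.05

    def test_reg_osc_constant_lfp_raises(self):
        with pytest.raises(ValueError):
            reg_osc(np.ones(100), 2.0, 0.01)

    def test_loss_components(self):
        p = build_network(n=20, seed=0)
        b = make_task_batch(2, delay=0.5, dt=0.02, seed=1)
        traj = simulate(p, b, zero_noise=True)
        # perfect readout: zero masked error
        traj.y = np.tile(b.targets[:, None], (1, b.n_steps)).astype(float)
        comps = loss(traj, b, lam_fr=0.0, lam_osc=0.0)
        assert comps["mse"] == pytest.approx(0.0)
        # zero readout against +/-1 targets: unit masked error
        traj.y = np.zeros_like(traj.y)
        assert loss(traj, b)["mse"] == pytest.approx(1.0)
        # rate penalty equals the hand formula (1/NT) sum phi^2
        comps = loss(traj, b, lam_fr=0.5, lam_osc=0.0)
        hand = np.mean([np.sum(traj.rates[i] ** 2)
                        / traj.rates[i].size for i in range(2)])
        assert comps["reg_fr"] == pytest.approx(hand)

    def test_all_zero_mask_rejected(self):
        p = build_network(n=10, seed=0)
        b = make_task_batch(1, delay=0.5, dt=0.02, seed=1)
        traj = simulate(p, b, zero_noise=True)
        b.mask[:] = 0.0
        with pytest.raises(ValueError):
            loss(traj, b)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        p = build_network(n=6, frac_excitatory=0.5, dt=0.05, tau=0.1,
                          sigma_xi=0.0, seed=0)
        b = make_task_batch(3, soa=0.2, stim_dur=0.1, delay=0.3,
                            decision_dur=0.2, pre=0.1, dt=0.05, seed=1)
        lam_fr, lam_osc, f_osc = 0.3, 0.7, 2.0

        def total(pp):
            t = simulate(pp, b, zero_noise=True)
            return loss(t, b, lam_fr, lam_osc, f_osc)["total"]

        traj = simulate(p, b, zero_noise=True)
        _, g = gradients(p, traj, b, lam_fr, lam_osc, f_osc)
        rng = np.random.default_rng(2)
        eps = 1e-6
        for name in ("J", "I", "w"):
            arr = getattr(p, name)
            for flat in rng.choice(arr.size, 5, replace=False):
                ix = np.unravel_index(flat, arr.shape)
                p_hi, p_lo = p.copy(), p.copy()
                getattr(p_hi, name)[ix] += eps
                getattr(p_lo, name)[ix] -= eps
                fd = (total(p_hi) - total(p_lo)) / (2 * eps)
                assert g[name][ix] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestAnalysis:
    def test_spike_sampling_poisson_count(self, rng):
        dt, rate, dur = 0.001, 30.0, 50.0
        spikes = sample_spikes_from_rates(np.full(int(dur / dt), rate), dt,
                                          rng=rng)
        expected = rate * dur
        assert abs(spikes.size - expected) < 4 * np.sqrt(expected)
        assert np.all(np.diff(spikes) > 0)
        assert sample_spikes_from_rates(np.zeros(100), dt, rng=rng).size == 0

    def test_spike_sampling_gain_doubles_count(self, rng):
        r = np.full(200_000, 10.0)
        n1 = sample_spikes_from_rates(r, 0.001, gain=1.0, rng=rng).size
        n2 = sample_spikes_from_rates(r, 0.001, gain=2.0, rng=rng).size
        assert n2 / n1 == pytest.approx(2.0, rel=0.1)

    def test_reference_oscillation_conventions(self):
        t = np.linspace(0, 2, 2001)
        ph = model_reference_oscillation(2.0, anchor_time=0.5, times=t)
        assert ph[np.argmin(np.abs(t - 0.5))] == pytest.approx(0.0, abs=1e-9)
        # advances 2 pi per period; anchor shift by half period flips by pi
        ph2 = model_reference_oscillation(2.0, anchor_time=0.75, times=t)
        d = np.angle(np.exp(1j * (ph - ph2)))
        assert np.allclose(np.abs(d), np.pi, atol=1e-6)

    def test_oscillation_spectrum_peaks_at_tone(self, rng):
        dt = 0.02
        t = np.arange(300) * dt
        lfp = np.sin(2 * np.pi * 2.75 * t) + 0.3 * rng.standard_normal((5, 300))
        peak, spec, freqs = lfp_peak_frequency(lfp, dt)
        assert abs(peak - 2.75) < 0.15

    def test_sinusoidal_rates_give_lfp_peak_at_their_frequency(self):
        # LFP proxy of sinusoidally modulated rates inherits the rhythm
        dt = 0.02
        t = np.arange(400) * dt
        J = np.abs(np.random.default_rng(0).standard_normal((3, 3)))
        rates = 0.5 + 0.4 * np.sin(2 * np.pi * 2.0 * t)[None, :, None] \
            * np.ones((1, 1, 3))
        lfp = lfp_proxy(rates, J)
        peak, _, _ = lfp_peak_frequency(lfp, dt)
        assert abs(peak - 2.0) < 0.1

    def test_selective_units_detect_driven_subset(self):
        p = build_network(n=40, input_scale=3.0, seed=3)
        b = make_task_batch(40, delay=1.0, dt=0.02, seed=4)
        traj = simulate(p, b, noise_seed=5)
        units, preferred, pvals = stimulus_selective_units(traj, b)
        assert units.size > 0
        assert np.all((preferred >= 0) & (preferred < 8))

    def test_phase_analysis_recovers_planted_position_phases(self):
        # craft a trajectory whose delay rates oscillate with a
        # position-dependent phase offset; V_ex machinery must see it
        from thetaseq.circular import vex_permutation_test
        b = make_task_batch(64, delay=2.0, dt=0.02, seed=6)
        t = b.times
        n_units = 2
        rates = np.full((b.n_trials, b.n_steps, n_units), 0.1)
        f = 2.5
        preferred = np.array([b.sequences[0][0], b.sequences[1][0]])
        anchor = b.stim_onsets[-1]
        for un in range(n_units):
            for i in range(b.n_trials):
                pos = np.nonzero(b.sequences[i] == preferred[un])[0]
                if not pos.size:
                    continue
                mu = np.pi / 2 * pos[0]
                rates[i, :, un] = 1.0 + np.cos(
                    2 * np.pi * f * (t - anchor) - mu)
        traj = type("T", (), {})()
        traj.rates = rates
        sets, empty = model_phase_analysis(traj, b, f, np.arange(n_units),
                                           preferred)
        assert len(sets) == n_units
        for s in sets:
            res = vex_permutation_test(s, n_perm=199, rng=0)
            assert res.p_value < 0.05

    def test_degenerate_percentile_flags_units(self):
        b = make_task_batch(8, delay=1.0, dt=0.02, seed=7)
        traj = type("T", (), {})()
        traj.rates = np.zeros((8, b.n_steps, 1))
        sets, empty = model_phase_analysis(traj, b, 2.0, np.array([0]),
                                           np.array([b.sequences[0][0]]),
                                           percentile=100.0)
        assert sets == [] and empty == [0]


class TestAccuracy:
    def test_sign_rule(self):
        b = make_task_batch(4, delay=0.5, dt=0.02, seed=8)
        traj = type("T", (), {})()
        traj.y = np.tile((b.targets * 2)[:, None], (1, b.n_steps))
        assert accuracy(traj, b) == 1.0
        traj.y = -traj.y
        assert accuracy(traj, b) == 0.0
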