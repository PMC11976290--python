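"""Phase analyses of trained networks.

Bridges network trajectories to the same circular-statistics and
phase-order machinery applied to recorded units: spikes sampled from
rates, a sinusoidal reference oscillation phase-anchored at the last
stimulus onset, LFP spectra of the normalized LFP, stimulus-selective
unit detection, and rate-weighted per-trial phase samples thresholded at
the per-unit 50th percentile.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..circular import PhaseSampleSet, circular_mean
from .network import Trajectory

__all__ = ["sample_spikes_from_rates", "model_reference_oscillation",
           "oscillation_spectrum", "lfp_peak_frequency",
           "stimulus_selective_units", "model_phase_analysis"]


def sample_spikes_from_rates(rates, dt: float, gain: float = 1.0, rng=None):
    """Inhomogeneous Poisson spikes from a nonnegative rate series.

    ``gain`` rescales rate to spikes/s per unit rate. One Bernoulli draw
    per time bin (p = gain * rate * dt, clipped to 1); spike times get
    uniform sub-bin jitter so they are strictly increasing.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("negative rate")
    rng = np.random.default_rng(rng)
    p = np.clip(gain * rates * dt, 0.0, 1.0)
    hits = np.nonzero(rng.random(rates.size) < p)[0]
    return (hits + rng.random(hits.size)) * dt


def model_reference_oscillation(f_peak: float, anchor_time: float, times):
    """Phase of the reference sinusoid at each time.

    The reference is a sine of frequency ``f_peak`` with phase fixed to 0
    at ``anchor_time`` (the last stimulus onset), advancing by 2*pi per
    1/f_peak seconds.
    """
    if f_peak <= 0:
        raise ValueError("f_peak must be positive")
    times = np.asarray(times, dtype=float)
    return np.mod(2.0 * np.pi * f_peak * (times - anchor_time), 2.0 * np.pi)


def oscillation_spectrum(lfp, dt: float, freqs, window_mask=None):
    """Mean amplitude of the standardized LFP at each frequency.

    The LFP is standardized per trial ((LFP - mean) / std, so a pure
    sinusoid has amplitude sqrt(2) and spectral magnitude 1/sqrt(2) ~
    0.707); the reported value at f is |(1/T) sum_n LFPstd_n
    exp(-i 2 pi f n dt)| averaged over trials. This is sqrt(2) times the
    magnitude inside the training regularizer.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if window_mask is not None:
        lfp = lfp[:, window_mask]
    mu = lfp.mean(axis=1, keepdims=True)
    sd = lfp.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (lfp - mu) / sd
    T = z.shape[1]
    n = np.arange(T)
    freqs = np.asarray(freqs, dtype=float)
    e = np.exp(-2j * np.pi * freqs[None, :] * n[:, None] * dt)  # (T, F)
    return np.abs(z @ e).mean(axis=0) / T


def lfp_peak_frequency(lfp, dt: float, band=(0.5, 6.0), df: float = 0.05,
                       window_mask=None):
    """Peak of the delay-window LFP amplitude spectrum on a fine grid.

    Returns ``(peak_frequency, spectrum, freqs)``; ties break toward the
    lower frequency.
    """
    freqs = np.arange(band[0], band[1] + df / 2, df)
    spec = oscillation_spectrum(lfp, dt, freqs, window_mask)
    return float(freqs[np.argmax(spec)]), spec, freqs


def stimulus_selective_units(traj: Trajectory, batch, alpha: float = 0.001):
    """Stimulus-responsive units and their preferred stimulus.

    A unit is responsive if its per-trial mean rate during the stimulus
    period exceeds the pre-stimulus baseline (Wilcoxon signed-rank,
    one-sided, p < alpha). The preferred stimulus maximizes the mean
    evoked rate during that stimulus's presentation windows.
    """
    times = batch.times
    base_mask = (times >= batch.baseline_window[0]) & (times < batch.baseline_window[1])
    stim_start = batch.stim_onsets[0]
    stim_end = batch.delay_window[0]
    stim_mask = (times >= stim_start) & (times < stim_end)
    base = traj.rates[:, base_mask, :].mean(axis=1)   # (B, N)
    stim = traj.rates[:, stim_mask, :].mean(axis=1)
    n_units = traj.rates.shape[2]
    pvals = np.ones(n_units)
    for i in range(n_units):
        diff = stim[:, i] - base[:, i]
        if np.allclose(diff, 0):
            continue
        pvals[i] = stats.wilcoxon(diff, alternative="greater").pvalue
    responsive = np.nonzero(pvals < alpha)[0]

    n_stim = batch.u.shape[2]
    evoked = np.zeros((n_stim, n_units))
    stim_dur = batch.delay_window[0] - batch.stim_onsets[-1]
    for s in range(n_stim):
        acc, count = np.zeros(n_units), 0
        for b in range(batch.n_trials):
            pos = np.nonzero(batch.sequences[b] == s)[0]
            if not pos.size:
                continue
            on = batch.stim_onsets[pos[0]]
            m = (times >= on) & (times < on + stim_dur)
            acc += traj.rates[b][m].mean(axis=0) - base[b]
            count += 1
        if count:
            evoked[s] = acc / count
    preferred = evoked.argmax(axis=0)
    return responsive, preferred, pvals


def model_phase_analysis(traj: Trajectory, batch, f_peak: float, units,
                         preferred, percentile: float = 50.0):
    """Rate-weighted per-trial phase samples for selected units.

    For each unit, delay-period rates are pooled across trials to set a
    per-unit rate threshold at the given percentile; on each trial where
    the unit's preferred stimulus appeared, the mean phase is the
    circular mean of the reference-oscillation phase weighted by the
    suprathreshold rate. The condition label is the sequence position
    (1..4) of the preferred stimulus. Returns ``(sample_sets,
    empty_units)``; units with no suprathreshold samples or no preferred-
    stimulus trials land in ``empty_units``.
    """
    units = np.asarray(units)
    if units.size == 0:
        return [], []
    times = batch.times
    delay_mask = (times >= batch.delay_window[0]) & (times < batch.delay_window[1])
    phases = model_reference_oscillation(f_peak, batch.stim_onsets[-1],
                                         times[delay_mask])
    sample_sets, empty = [], []
    for u in units:
        r = traj.rates[:, delay_mask, u]           # (B, T_delay)
        thresh = np.percentile(r, percentile)
        trial_phases, conds = [], []
        for b in range(batch.n_trials):
            pos = np.nonzero(batch.sequences[b] == preferred[u])[0]
            if not pos.size:
                continue
            w = np.where(r[b] > thresh, r[b], 0.0)
            if w.sum() <= 0:
                continue
            mean, _ = circular_mean(phases, weights=w)
            if not np.isfinite(mean):
                continue
            trial_phases.append(mean)
            conds.append(int(pos[0]) + 1)
        if len(trial_phases) < 8 or len(set(conds)) < 2:
            empty.append(int(u))
            continue
        sample_sets.append(PhaseSampleSet(np.asarray(trial_phases),
                                          np.asarray(conds), unit_id=int(u),
                                          frequency=f_peak))
    return sample_sets, empty
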