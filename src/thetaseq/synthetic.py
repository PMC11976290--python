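"""Synthetic session generator with planted, recoverable structure.

Emulates a Sternberg-style sequence working-memory session: on each trial
four of eight stimuli are shown in sequence (400 ms onset asynchrony),
followed by a ~2.5 s delay and a probe. The generator plants the three
empirical signatures every downstream stage must recover:

* theta-band LFP whose power rises from baseline to delay,
* spikes phase-locked (von Mises) to theta during the delay, with a
  preferred phase that depends on the sequence position of the unit's
  preferred stimulus,
* stimulus-evoked rate responses with a primacy gradient during encoding
  and no position effect on delay rates (rate and phase coding are
  decoupled by construction: the phase modulation is normalized by
  I0(kappa) so the mean rate is kappa-independent).

All randomness flows from one session seed through named substreams
(ground truth, trials, lfp, spikes), so each component is independently
reproducible. Time is in seconds with 0 at fixation onset; event windows
are closed-open [on, off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special

from . import order as order_analysis

__all__ = [
    "LfpTrace",
    "GroundTruth",
    "SessionConfig",
    "Session",
    "generate_trial_table",
    "generate_lfp",
    "generate_spikes",
    "generate_session",
]

N_STIMULI = 8
N_POSITIONS = 4


@dataclass
class LfpTrace:
    """Regularly sampled voltage-like series for one trial."""

    channel_id: int
    trial_id: int
    samples: np.ndarray
    fs: float            # Hz
    t0: float = 0.0      # s, relative to fixation onset

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite LFP samples")


@dataclass
class GroundTruth:
    """Planted per-unit coding parameters (what the analyses must recover)."""

    preferred_stimulus: np.ndarray   # (n_units,) int in 0..7
    baseline_rate: np.ndarray        # (n_units,) Hz
    selectivity_gain: np.ndarray     # (n_units,) dimensionless
    primacy: np.ndarray              # (4,) evoked gain multiplier per position
    kappa: np.ndarray                # (n_units, 4) delay phase-locking per position
    mu: np.ndarray                   # (n_units, 4) preferred phase per position, [0, 2*pi)
    kappa_nps: np.ndarray            # (n_units,) locking when PS absent
    ordering_mode: str               # forward | reverse | arbitrary | reset_model
    theta_freq: float                # Hz
    theta_phase0: np.ndarray         # (n_trials,) planted LFP phase at t=0 per trial

    def __post_init__(self) -> None:
        if np.any(self.kappa < 0) or np.any(self.kappa_nps < 0):
            raise ValueError("kappa must be nonnegative")
        self.mu = np.mod(self.mu, 2 * np.pi)


@dataclass
class SessionConfig:
    """Generator parameters. Defaults mirror the recorded task structure."""

    n_trials: int = 224
    n_units: int = 20
    soa: float = 0.4                # s between stimulus onsets
    stim_dur: float = 0.2           # s stimulus on screen
    fix_dur: float = 1.0            # s fixation before first stimulus
    delay_mean: float = 2.5         # s
    delay_jitter: float = 0.1       # s, uniform +/- around the mean
    post_probe: float = 0.3         # s of trace retained after probe onset
    p_match: float = 0.5
    p_correct: float = 0.85         # behavioural accuracy of the synthetic subject
    balanced: bool = True           # every stimulus equally often at every position
    fs: float = 1000.0              # Hz LFP sampling rate
    theta_freq: float = 2.8         # Hz planted oscillation
    theta_amp: float = 1.0
    delay_power_boost: float = 3.0  # theta amplitude multiplier during delay
    noise_amp: float = 1.0          # 1/f background std
    noise_exponent: float = 1.0     # spectral slope of the background
    baseline_rate: float = 5.0      # Hz
    selectivity_gain: float = 4.0   # evoked gain at the preferred stimulus
    nonpref_gain_frac: float = 0.2  # evoked response to non-preferred stimuli
    primacy: tuple = (1.0, 0.85, 0.7, 0.55)
    kappa: float = 2.0              # delay phase locking on PS trials
    kappa_nps: float = 0.5          # locking when the PS is absent
    mu_spacing: float = float(np.deg2rad(60.0))  # phase separation between positions
    ordering_mode: str = "forward"  # forward | reverse | arbitrary | reset_model
    seed: int | None = None


@dataclass
class Session:
    trials: pd.DataFrame
    lfp: list            # list[LfpTrace], one per trial
    spikes: pd.DataFrame  # columns unit_id, trial_id, time
    ground_truth: GroundTruth
    config: SessionConfig

    def delay_window(self, trial_row) -> tuple:
        return float(trial_row.delay_on), float(trial_row.probe_on)


# ---------------------------------------------------------------------------
# trials

def _balanced_position_matrix(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """(n_trials, 4) stimulus matrix: each stimulus exactly n/8 times per
    position, all four entries distinct within a trial."""
    if n_trials % N_STIMULI:
        raise ValueError("balanced design needs n_trials divisible by 8")
    per = n_trials // N_STIMULI
    cols = [rng.permutation(np.repeat(np.arange(N_STIMULI), per))
            for _ in range(N_POSITIONS)]
    m = np.stack(cols, axis=1)
    # repair rows with duplicate stimuli by swapping within a column
    for _ in range(100 * n_trials):
        dup_rows = [i for i in range(n_trials) if len(set(m[i])) < N_POSITIONS]
        if not dup_rows:
            return m
        for i in dup_rows:
            seen = {}
            for c in range(N_POSITIONS):
                s = m[i, c]
                if s in seen:
                    j = int(rng.integers(n_trials))
                    m[i, c], m[j, c] = m[j, c], m[i, c]
                    break
                seen[s] = c
    raise RuntimeError("balanced design repair did not converge")


def generate_trial_table(n_trials: int, soa: float = 0.4, delay_mean: float = 2.5,
                         delay_jitter: float = 0.1, p_match: float = 0.5,
                         seed=None, balanced: bool = False, stim_dur: float = 0.2,
                         fix_dur: float = 1.0, p_correct: float = 0.85) -> pd.DataFrame:
    """Random trial table.

    In balanced mode (requires ``n_trials`` divisible by 8) each of the 8
    stimuli appears exactly ``n_trials/8`` times at each of the 4
    positions. Probe order equals the sample order on match trials and a
    random non-identical permutation otherwise.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0.0 <= p_match <= 1.0):
        raise ValueError("p_match must lie in [0, 1]")
    if soa <= 0:
        raise ValueError("soa must be positive")
    if stim_dur > soa:
        raise ValueError("stimulus duration cannot exceed the soa")
    rng = np.random.default_rng(seed)
    if balanced:
        seqs = _balanced_position_matrix(n_trials, rng)
    else:
        seqs = np.stack([rng.permutation(N_STIMULI)[:N_POSITIONS]
                         for _ in range(n_trials)])
    is_match = rng.random(n_trials) < p_match
    probes = seqs.copy()
    for i in np.where(~is_match)[0]:
        perm = rng.permutation(N_POSITIONS)
        while np.all(perm == np.arange(N_POSITIONS)):
            perm = rng.permutation(N_POSITIONS)
        probes[i] = seqs[i, perm]
    delay = delay_mean + rng.uniform(-delay_jitter, delay_jitter, size=n_trials)
    stim_on = fix_dur + soa * np.arange(N_POSITIONS)
    delay_on = fix_dur + soa * (N_POSITIONS - 1) + soa  # last stimulus slot ends
    rows = {
        "trial_id": np.arange(n_trials),
        **{f"seq{k}": seqs[:, k] for k in range(N_POSITIONS)},
        **{f"probe{k}": probes[:, k] for k in range(N_POSITIONS)},
        "is_match": is_match,
        "correct": rng.random(n_trials) < p_correct,
        "fixation_on": np.zeros(n_trials),
        **{f"stim_on_{k}": np.full(n_trials, stim_on[k]) for k in range(N_POSITIONS)},
        "delay_on": np.full(n_trials, delay_on),
        "probe_on": delay_on + delay,
        "soa": np.full(n_trials, soa),
    }
    return pd.DataFrame(rows)


def sequences(trials: pd.DataFrame) -> np.ndarray:
    return trials[[f"seq{k}" for k in range(N_POSITIONS)]].to_numpy()


# ---------------------------------------------------------------------------
# LFP

def _one_over_f_noise(n: int, exponent: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _amplitude_envelope(t: np.ndarray, delay_on: float, probe_on: float,
                        boost: float, ramp: float = 0.1) -> np.ndarray:
    """1 outside the delay, ``boost`` inside, cosine ramps at the borders."""
    env = np.ones_like(t)
    if boost != 1.0:
        rise = np.clip((t - (delay_on - ramp)) / ramp, 0.0, 1.0)
        fall = np.clip((probe_on - t) / ramp, 0.0, 1.0)
        w = 0.5 * (1 - np.cos(np.pi * rise)) * 0.5 * (1 - np.cos(np.pi * fall))
        env = 1.0 + (boost - 1.0) * w
    return env


def generate_lfp(trials: pd.DataFrame, theta_freq: float = 2.8,
                 delay_power_boost: float = 3.0, theta_amp: float = 1.0,
                 noise_amp: float = 1.0, noise_exponent: float = 1.0,
                 fs: float = 1000.0, seed=None, post_probe: float = 0.3,
                 phase0=None):
    """Per-trial LFP: 1/f background plus a theta tone whose amplitude is
    multiplied by ``delay_power_boost`` during the delay window.

    Returns ``(traces, phase0)`` where ``phase0[i]`` is the planted theta
    phase at t = 0 of trial i (drawn uniformly unless supplied). Setting
    ``noise_amp = 0`` gives pure-tone traces for convention checks.
    """
    if not (0 < theta_freq < fs / 2):
        raise ValueError("theta_freq must lie in (0, fs/2)")
    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    if phase0 is None:
        phase0 = rng.uniform(0, 2 * np.pi, size=n_trials)
    phase0 = np.asarray(phase0, dtype=float)
    traces = []
    for i, row in enumerate(trials.itertuples(index=False)):
        dur = row.probe_on + post_probe
        n = int(np.round(dur * fs))
        t = np.arange(n) / fs
        env = _amplitude_envelope(t, row.delay_on, row.probe_on, delay_power_boost)
        theta = theta_amp * env * np.cos(2 * np.pi * theta_freq * t + phase0[i])
        noise = noise_amp * _one_over_f_noise(n, noise_exponent, fs, rng) if noise_amp else 0.0
        traces.append(LfpTrace(channel_id=0, trial_id=int(row.trial_id),
                               samples=theta + noise, fs=fs, t0=0.0))
    return traces, phase0


# ---------------------------------------------------------------------------
# ground truth and spikes

def _make_ground_truth(config: SessionConfig, n_trials: int,
                       rng: np.random.Generator) -> GroundTruth:
    n = config.n_units
    preferred = rng.integers(0, N_STIMULI, size=n)
    mu = np.zeros((n, N_POSITIONS))
    mode = config.ordering_mode
    for u in range(n):
        base = rng.uniform(0, 2 * np.pi)
        if mode == "forward":
            mu[u] = base + config.mu_spacing * np.arange(N_POSITIONS)
        elif mode == "reverse":
            mu[u] = base - config.mu_spacing * np.arange(N_POSITIONS)
        elif mode == "arbitrary":
            mu[u] = base + config.mu_spacing * rng.permutation(N_POSITIONS)
        elif mode == "reset_model":
            pred = order_analysis.predict_reset_phases(
                config.theta_freq, config.soa, phi0=base)
            mu[u] = pred.phases
        else:
            raise ValueError(f"unknown ordering_mode {mode!r}")
    return GroundTruth(
        preferred_stimulus=preferred,
        baseline_rate=np.full(n, config.baseline_rate),
        selectivity_gain=np.full(n, config.selectivity_gain),
        primacy=np.asarray(config.primacy, dtype=float),
        kappa=np.full((n, N_POSITIONS), config.kappa),
        mu=np.mod(mu, 2 * np.pi),
        kappa_nps=np.full(n, config.kappa_nps),
        ordering_mode=mode,
        theta_freq=config.theta_freq,
        theta_phase0=np.zeros(0),  # filled once the LFP phases are drawn
    )


def generate_spikes(trials: pd.DataFrame, lfp: list, ground_truth: GroundTruth,
                    seed=None, stim_latency: float = 0.05,
                    resp_dur: float = 0.25, nonpref_gain_frac: float = 0.2,
                    selectivity_gain=None) -> pd.DataFrame:
    """Inhomogeneous Poisson spikes with planted rate and phase coding.

    Rate on a 1 ms grid: r(t) = r_base * g_stim(t) * vm(t) where
    g_stim applies the evoked gain (scaled by the primacy coefficient of
    the stimulus position, full gain for the preferred stimulus and
    ``nonpref_gain_frac`` of it otherwise) during [onset + latency,
    onset + latency + resp_dur), and vm(t) = exp(kappa cos(theta(t) - mu))
    / I0(kappa) during the delay. The I0 normalization keeps the mean
    delay rate independent of kappa, decoupling rate and phase coding.
    """
    gt = ground_truth
    if np.any(gt.baseline_rate < 0):
        raise ValueError("negative baseline rate")
    rng = np.random.default_rng(seed)
    fs = lfp[0].fs
    dt = 1.0 / fs
    n_units = gt.preferred_stimulus.size
    seqs = sequences(trials)
    records_unit, records_trial, records_time = [], [], []
    for i, row in enumerate(trials.itertuples(index=False)):
        n = lfp[i].samples.size
        t = np.arange(n) * dt
        theta_phase = 2 * np.pi * gt.theta_freq * t + gt.theta_phase0[i]
        delay_mask = (t >= row.delay_on) & (t < row.probe_on)
        stim_windows = []
        for k in range(N_POSITIONS):
            on = getattr(row, f"stim_on_{k}") + stim_latency
            stim_windows.append((t >= on) & (t < on + resp_dur))
        for u in range(n_units):
            gain = np.ones(n)
            for k in range(N_POSITIONS):
                sg = gt.selectivity_gain[u] * gt.primacy[k]
                if seqs[i, k] != gt.preferred_stimulus[u]:
                    sg *= nonpref_gain_frac
                gain[stim_windows[k]] += sg
            pos = np.where(seqs[i] == gt.preferred_stimulus[u])[0]
            if pos.size:  # PS trial: position-specific locking
                k = int(pos[0])
                kap, mu = gt.kappa[u, k], gt.mu[u, k]
            else:         # NPS trial: weak locking at the unit's mean phase
                kap = gt.kappa_nps[u]
                mu = np.angle(np.mean(np.exp(1j * gt.mu[u])))
            if kap > 0:
                vm = np.exp(kap * np.cos(theta_phase - mu)) / special.i0(kap)
                gain[delay_mask] *= vm[delay_mask]
            rate = gt.baseline_rate[u] * gain
            p = np.clip(rate * dt, 0.0, 1.0)
            hits = np.nonzero(rng.random(n) < p)[0]
            if hits.size:
                times = (hits + rng.random(hits.size)) * dt
                records_unit.append(np.full(hits.size, u))
                records_trial.append(np.full(hits.size, int(row.trial_id)))
                records_time.append(times)
    if records_unit:
        spikes = pd.DataFrame({
            "unit_id": np.concatenate(records_unit),
            "trial_id": np.concatenate(records_trial),
            "time": np.concatenate(records_time),
        })
    else:
        spikes = pd.DataFrame({"unit_id": [], "trial_id": [], "time": []})
    return spikes.sort_values(["unit_id", "trial_id", "time"]).reset_index(drop=True)


def generate_session(config: SessionConfig | None = None, seed=None) -> Session:
    """Generate a full self-consistent session bundle.

    The session seed (argument, falling back to ``config.seed``) is split
    into named substreams in fixed order: ground truth, trials, lfp,
    spikes — so each component is reproducible on its own.
    """
    config = config or SessionConfig()
    if seed is None:
        seed = config.seed
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    ss_gt, ss_trials, ss_lfp, ss_spikes = ss.spawn(4)
    trials = generate_trial_table(
        config.n_trials, soa=config.soa, delay_mean=config.delay_mean,
        delay_jitter=config.delay_jitter, p_match=config.p_match,
        seed=np.random.default_rng(ss_trials), balanced=config.balanced,
        stim_dur=config.stim_dur, fix_dur=config.fix_dur,
        p_correct=config.p_correct)
    gt = _make_ground_truth(config, config.n_trials, np.random.default_rng(ss_gt))
    lfp, phase0 = generate_lfp(
        trials, theta_freq=config.theta_freq,
        delay_power_boost=config.delay_power_boost, theta_amp=config.theta_amp,
        noise_amp=config.noise_amp, noise_exponent=config.noise_exponent,
        fs=config.fs, seed=np.random.default_rng(ss_lfp),
        post_probe=config.post_probe)
    gt.theta_phase0 = phase0
    spikes = generate_spikes(trials, lfp, gt, seed=np.random.default_rng(ss_spikes),
                             nonpref_gain_frac=config.nonpref_gain_frac)
    return Session(trials=trials, lfp=lfp, spikes=spikes, ground_truth=gt,
                   config=config)
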