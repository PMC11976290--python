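"""Gradient-descent training of the rate RNN by backprop through time.

The loss (masked MSE + rate penalty + oscillation regularizer) is
differentiated analytically through the Euler recursion; the noise is
treated pathwise (gradients flow through the stored noisy states).
Weights are updated with Adam under global-norm gradient clipping, and
the recurrent matrix is projected back onto the Dale sign pattern after
every step. Training stops once validation accuracy reaches criterion
(95% by default) or the iteration budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (RnnParams, Trajectory, dale_project, dphi, loss,
                      simulate)
from .task import make_task_batch

__all__ = ["RnnTrainConfig", "gradients", "accuracy", "train"]


@dataclass
class RnnTrainConfig:
    lam_fr: float = 0.01          # rate penalty weight
    lam_osc: float = 1.0          # oscillation regularizer weight
    f_osc: float = 2.75           # Hz target oscillation
    lr: float = 2e-3              # Adam learning rate
    lr_final: float | None = None  # decayed target (None: constant lr)
    lr_decay_start: int = 0       # iteration at which lr decay begins
    lr_decay_iters: int = 3000    # linear decay duration
    batch_size: int = 32
    max_iters: int = 3000
    eval_every: int = 25
    target_accuracy: float = 0.95
    clip: float = 5.0             # global gradient-norm clip
    dtype: str = "float32"        # training precision (casts params/batches)
    soa: float = 0.4              # s, task timing
    stim_dur: float = 0.2
    delay: float = 2.5
    decision_dur: float = 0.4
    pre: float = 0.2
    n_val_trials: int = 112       # evaluation-mode validation set
    curriculum_iters: int = 0     # iterations with set-mismatch non-matches
    curriculum_frac: float = 0.0  # their fraction; annealed to 0 afterwards
    curriculum_anneal: int = 1000  # iterations over which to anneal
    hard_negative_frac: float = 0.3   # oversampled head-permuted non-matches
    hard_negative_start: int = 2500  # iteration at which oversampling begins
    match_so_far_shaping: bool = False
    shaping_weight: float = 0.25
    # With shaping on, training trials additionally carry a time-resolved
    # teaching signal during the probe: the target is +1 while the probe
    # has matched the sample so far and switches to -1 once the first
    # mismatching item has been fully presented. Probe steps enter the
    # masked MSE with weight ``shaping_weight`` relative to decision
    # steps, teaching the network to latch mismatches detected early
    # without displacing the decision-window objective. Validation
    # always uses the plain task (final +/-1 target in the post-probe
    # decision window only).
    lam_aux: float = 8.0          # auxiliary memory-shaping loss weight
    lam_aux_final: float | None = None   # anneal target (None: constant)
    aux_anneal_start: int = 0     # iteration at which annealing begins
    aux_anneal_iters: int = 2000  # annealing duration
    # With lam_aux > 0, 32 auxiliary linear readouts are trained to report
    # which stimulus occupied each sequence position (4 positions x 8
    # stimuli, one-hot targets) from delay onset onward. This shapes the
    # network to carry an order-bound memory of the sample into the probe
    # period -- the prerequisite for the match comparison -- and is a
    # training aid only: the auxiliary readouts play no role in task
    # evaluation and are discarded afterwards.


def _match_so_far(batch, stim_dur: float, dtype, probe_weight: float = 0.25):
    """Blend the probe-period teaching signal into mask and targets.

    Decision steps keep weight 1; probe steps (from the end of the first
    probe item) enter with ``probe_weight``. Targets become
    (n_trials, n_steps): the final label everywhere except probe steps
    before the first mismatch has been fully shown, where they are +1.
    """
    times = batch.times
    decision = batch.mask.astype(bool)
    probe = ((times >= batch.probe_onsets[0] + stim_dur) & ~decision
             & (times < times[np.nonzero(decision)[0][-1]]))
    mask = decision.astype(dtype) + probe_weight * probe.astype(dtype)
    targets = np.repeat(batch.targets[:, None], batch.n_steps, axis=1).astype(dtype)
    diverged = batch.probe_orders != batch.sequences
    for i in np.where(diverged.any(axis=1))[0]:
        k = int(np.argmax(diverged[i]))
        switch = batch.probe_onsets[k] + stim_dur
        targets[i, probe & (times < switch)] = 1.0
    batch.mask = mask
    batch.targets = targets
    return batch


def _decision_readout(traj: Trajectory, batch) -> np.ndarray:
    m = batch.mask
    return (traj.y * m[None, :]).sum(axis=1) / m.sum()


def accuracy(traj: Trajectory, batch) -> float:
    """Fraction of trials whose masked-mean readout has the target sign."""
    pred = np.sign(_decision_readout(traj, batch))
    return float(np.mean(pred == batch.targets))


def _osc_grad_z(lfp: np.ndarray, f_osc: float, dt: float) -> np.ndarray:
    """d reg_osc / d LFP for each trial (backprop through the per-trial
    standardization and the Fourier magnitude)."""
    lfp = np.atleast_2d(lfp)
    T = lfp.shape[1]
    mu = lfp.mean(axis=1, keepdims=True)
    sd = lfp.std(axis=1, keepdims=True)
    zbar = (lfp - mu) / (np.sqrt(2.0) * sd)
    e = np.exp(-2j * np.pi * f_osc * np.arange(T) * dt)
    F = (zbar @ e) / T                           # (B,)
    mag = np.maximum(np.abs(F), 1e-12)
    gbar = -np.real((np.conj(F) / mag)[:, None] * e[None, :]) / T
    # backprop through zbar = (z - mu) / (sqrt(2) sd)
    ztil = (lfp - mu) / sd
    inner = (gbar * ztil).mean(axis=1, keepdims=True)
    gz = (gbar - gbar.mean(axis=1, keepdims=True) - ztil * inner) / (np.sqrt(2.0) * sd)
    return gz


N_AUX = 36  # 32 item-at-position memory channels + 4 match-verdict channels


def _aux_targets(batch, stim_dur: float, dtype=float):
    """Time-resolved auxiliary teaching targets, (n_trials, n_steps, 36).

    Channels 0..31 hold the one-hot (position, stimulus) code of the
    sample throughout (memory teacher). Channels 32..35 are per-position
    match verdicts: 0 until probe item k has been fully presented, then
    +1 if it matched the sample's item k and -1 otherwise (comparison
    and latch teacher).
    """
    n_trials, n_steps = batch.n_trials, batch.n_steps
    times = batch.times
    t = np.zeros((n_trials, n_steps, N_AUX), dtype=dtype)
    for k in range(4):
        t[np.arange(n_trials), :, k * 8 + batch.sequences[:, k]] = 1.0
        verdict = np.where(batch.probe_orders[:, k] == batch.sequences[:, k],
                           1.0, -1.0).astype(dtype)
        after = times >= batch.probe_onsets[k] + stim_dur
        t[:, after, 32 + k] = verdict[:, None]
    return t


def gradients(params: RnnParams, traj: Trajectory, batch,
              lam_fr: float, lam_osc: float, f_osc: float,
              aux: "tuple | None" = None):
    """Analytic gradients of the batch-mean loss w.r.t. J, I and w.

    ``aux = (w_aux, mask_aux, targets_aux, lam_aux)`` adds the
    memory-shaping loss and returns a ``w_aux`` gradient alongside.
    """
    x, rates, u = traj.x, traj.rates, batch.u
    n_trials, n_steps, n = x.shape
    alpha = params.alpha
    m = batch.mask
    msum = m.sum()
    comps = loss(traj, batch, lam_fr, lam_osc, f_osc)

    # d(mse)/dy, averaged over trials; targets may be per-trial scalars
    # or full (n_trials, n_steps) teaching signals
    targets = np.asarray(batch.targets)
    if targets.ndim == 1:
        targets = targets[:, None]
    e = 2.0 * (traj.y - targets) * m[None, :] / (msum * n_trials)
    rp = dphi(x)
    if params.readout == "rates":
        gw = np.einsum("bt,btn->n", e, rates)
        direct = e[:, :, None] * params.w[None, None, :] * rp
    else:
        gw = np.einsum("bt,btn->n", e, x)
        direct = e[:, :, None] * params.w[None, None, :]
    direct += (2.0 * lam_fr / (n * n_steps * n_trials)) * rates * rp
    if lam_osc:
        gz = (lam_osc / n_trials) * _osc_grad_z(traj.lfp, f_osc, traj.dt)
        a = np.abs(params.J).sum(axis=0)
        direct += gz[:, :, None] * (a[None, None, :] * rp)
        s = np.einsum("bt,btn->n", gz, rates)
    else:
        s = None

    g_aux = None
    if aux is not None:
        w_aux, m_aux, t_aux, lam_aux = aux
        if t_aux.ndim == 2:                               # constant-in-time
            t_aux = t_aux[:, None, :]
        norm = m_aux.sum() * t_aux.shape[-1] * n_trials
        y_aux = rates @ w_aux                              # (B, T, K)
        resid = m_aux[None, :, None] * (y_aux - t_aux)
        e_aux = (2.0 * lam_aux / norm) * resid
        comps = dict(comps)
        comps["aux"] = float(lam_aux / norm
                             * np.sum(resid * (y_aux - t_aux)))
        comps["total"] += comps["aux"]
        g_aux = np.einsum("btk,btn->nk", e_aux, rates)
        direct += (e_aux @ w_aux.T) * rp

    dJ = np.zeros_like(params.J)
    dI = np.zeros_like(params.I)
    lam_next = direct[:, n_steps - 1]
    for t in range(n_steps - 2, -1, -1):
        a_lam = alpha[None, :] * lam_next
        dJ += a_lam.T @ rates[:, t]
        dI += a_lam.T @ u[:, t]
        lam_next = direct[:, t] + (1.0 - alpha) * lam_next + rp[:, t] * (a_lam @ params.J)
    if s is not None:
        dJ += np.sign(params.J) * s[None, :]
    grads = {"J": dJ, "I": dI, "w": gw}
    if g_aux is not None:
        grads["w_aux"] = g_aux
    return comps, grads


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = {}
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _clip_global(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        return {k: g * scale for k, g in grads.items()}
    return grads


def train(params: RnnParams, config: RnnTrainConfig, seed=None, log_fn=None):
    """Train to criterion; returns ``(trained_params, history)``.

    ``history`` holds per-evaluation loss components, validation accuracy
    and the iteration at which criterion was reached (-1 if never). The
    validation set is a fixed evaluation-mode batch (unique sequences,
    half match) simulated with noise on.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    ss_batch, ss_noise, ss_val = ss.spawn(3)
    rng_batch = np.random.default_rng(ss_batch)
    rng_noise = np.random.default_rng(ss_noise)
    params = params.copy()
    dtype = np.dtype(config.dtype)
    for name in ("tau", "J", "I", "w", "sign"):
        setattr(params, name, getattr(params, name).astype(dtype))
    params.J = dale_project(params.J, params.sign)

    def cast_batch(b):
        b.u = b.u.astype(dtype)
        b.mask = b.mask.astype(dtype)
        b.targets = b.targets.astype(dtype)
        return b
    val_batch = cast_batch(make_task_batch(
        config.n_val_trials, soa=config.soa, stim_dur=config.stim_dur,
        delay=config.delay, decision_dur=config.decision_dur, pre=config.pre,
        dt=params.dt, seed=np.random.default_rng(ss_val), evaluation=True))
    shapes = {"J": params.J.shape, "I": params.I.shape, "w": params.w.shape}
    w_aux = None
    if config.lam_aux > 0:
        rng_aux = np.random.default_rng(ss_val.spawn(1)[0])
        w_aux = (rng_aux.standard_normal((params.n, N_AUX))
                 / np.sqrt(params.n)).astype(dtype)
        shapes["w_aux"] = w_aux.shape
    opt = _Adam(shapes, config.lr)
    history = {"iteration": [], "loss": [], "mse": [], "reg_fr": [],
               "reg_osc": [], "val_accuracy": [], "criterion_iteration": -1}
    for it in range(config.max_iters):
        if config.curriculum_iters and it >= config.curriculum_iters:
            frac = config.curriculum_frac * max(
                1.0 - (it - config.curriculum_iters) / config.curriculum_anneal,
                0.0)
        else:
            frac = config.curriculum_frac
        hard = (config.hard_negative_frac
                if it >= config.hard_negative_start else 0.0)
        batch = cast_batch(make_task_batch(
            config.batch_size, soa=config.soa, stim_dur=config.stim_dur,
            delay=config.delay, decision_dur=config.decision_dur,
            pre=config.pre, dt=params.dt, seed=rng_batch,
            set_mismatch_frac=frac, hard_negative_frac=hard))
        if config.match_so_far_shaping:
            batch = _match_so_far(batch, config.stim_dur, dtype,
                                  config.shaping_weight)
        traj = simulate(params, batch, noise_seed=rng_noise)
        aux = None
        if w_aux is not None:
            lam_aux = config.lam_aux
            if config.lam_aux_final is not None and it >= config.aux_anneal_start:
                frac_a = min((it - config.aux_anneal_start)
                             / max(config.aux_anneal_iters, 1), 1.0)
                lam_aux = (config.lam_aux
                           + frac_a * (config.lam_aux_final - config.lam_aux))
            times = np.arange(batch.n_steps) * params.dt
            m_aux = (times >= batch.delay_window[0]).astype(dtype)
            aux = (w_aux, m_aux, _aux_targets(batch, config.stim_dur, dtype),
                   lam_aux)
        comps, grads = gradients(params, traj, batch, config.lam_fr,
                                 config.lam_osc, config.f_osc, aux=aux)
        if not np.isfinite(comps["total"]):
            raise FloatingPointError(f"loss diverged at iteration {it}")
        if config.lr_final is not None and it >= config.lr_decay_start:
            frac_lr = min((it - config.lr_decay_start)
                          / max(config.lr_decay_iters, 1), 1.0)
            opt.lr = config.lr + frac_lr * (config.lr_final - config.lr)
        updates = opt.step(_clip_global(grads, config.clip))
        params.J = dale_project(params.J - updates["J"], params.sign)
        params.I = params.I - updates["I"]
        params.w = params.w - updates["w"]
        if w_aux is not None:
            w_aux = w_aux - updates["w_aux"]
        if (it + 1) % config.eval_every == 0 or it == 0:
            vtraj = simulate(params, val_batch, noise_seed=rng_noise)
            vacc = accuracy(vtraj, val_batch)
            history["iteration"].append(it)
            history["loss"].append(comps["total"])
            history["mse"].append(comps["mse"])
            history["reg_fr"].append(comps["reg_fr"])
            history["reg_osc"].append(comps["reg_osc"])
            history["val_accuracy"].append(vacc)
            if log_fn is not None:
                log_fn(it, comps, vacc)
            if vacc >= config.target_accuracy:
                history["criterion_iteration"] = it
                break
    return params, history
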