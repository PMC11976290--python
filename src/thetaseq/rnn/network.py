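"""Dale-constrained rate network: construction, simulation, LFP, loss.

Dynamics (Euler discretization with step dt, alpha_i = dt / tau_i):

    x[n+1] = (1 - alpha) * x[n] + alpha * (J phi(x[n]) + I u[n])
             + sqrt(2 * alpha * sigma_xi**2) * eps[n]

with eps ~ N(0, 1) i.i.d. The readout is linear, y[n] = w . x[n]. The
LFP proxy is the summed absolute synaptic input,
LFP[n] = sum_ij |J_ij| phi(x_j[n]), nonnegative because phi >= 0.

The activation is a rectified tanh (0 below zero, tanh above): rates are
nonnegative and saturate, which the L2 rate penalty keeps away from the
saturated regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RnnParams", "Trajectory", "phi", "dphi", "dale_project",
           "build_network", "simulate", "lfp_proxy", "reg_osc", "loss"]


def phi(x: np.ndarray) -> np.ndarray:
    """Rectified tanh activation."""
    return np.where(x > 0, np.tanh(x), 0.0)


def dphi(x: np.ndarray) -> np.ndarray:
    t = np.tanh(x)
    return np.where(x > 0, 1.0 - t * t, 0.0)


@dataclass
class RnnParams:
    tau: np.ndarray          # (N,) time constants, s
    J: np.ndarray            # (N, N) recurrent weights, Dale-signed columns
    I: np.ndarray            # (N, n_in) input weights
    w: np.ndarray            # (N,) readout weights
    sign: np.ndarray         # (N,) +1 excitatory / -1 inhibitory
    sigma_xi: float          # intrinsic noise scale
    dt: float                # Euler step, s
    readout: str = "rates"   # 'rates': y = w . phi(x); 'currents': y = w . x

    @property
    def n(self) -> int:
        return self.J.shape[0]

    @property
    def n_in(self) -> int:
        return self.I.shape[1]

    @property
    def alpha(self) -> np.ndarray:
        return self.dt / self.tau

    def copy(self) -> "RnnParams":
        return replace(self, tau=self.tau.copy(), J=self.J.copy(),
                       I=self.I.copy(), w=self.w.copy(), sign=self.sign.copy())


@dataclass
class Trajectory:
    x: np.ndarray            # (n_trials, T, N) unit currents
    rates: np.ndarray        # (n_trials, T, N) phi(x)
    y: np.ndarray            # (n_trials, T) linear readout
    lfp: np.ndarray          # (n_trials, T) summed absolute synaptic input
    dt: float
    noise_seed: object = None


def dale_project(J: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Project each column of J onto its unit's allowed output sign.

    Column j carries the outgoing weights of unit j; entries with the
    wrong sign are clipped to zero, leaving magnitudes free.
    """
    allowed = sign[None, :]
    return np.where(J * allowed >= 0, J, 0.0)


def build_network(n: int = 200, n_in: int = 8, frac_excitatory: float = 0.8,
                  spectral_radius: float = 1.5, tau: "float | tuple" = 0.05,
                  sigma_xi: float = 0.05, dt: float = 0.02,
                  input_scale: float = 1.0, readout: str = "rates",
                  seed=None) -> RnnParams:
    """Random Dale-respecting initialization.

    |J| entries are folded Gaussians scaled by 1/sqrt(n); inhibitory
    columns are scaled by the E/I count ratio so the expected net
    recurrent input is balanced, and J is finally rescaled to the target
    spectral radius. ``tau`` may be a scalar (uniform time constants) or
    a (lo, hi) pair for log-uniform per-unit time constants — a mix of
    fast and slow units supports both rapid stimulus responses and
    passive retention over hundreds of milliseconds.
    """
    if not (0.0 < frac_excitatory < 1.0):
        raise ValueError("frac_excitatory must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_exc = int(round(frac_excitatory * n))
    if n_exc in (0, n):
        raise ValueError("need at least one unit of each sign")
    sign = np.where(np.arange(n) < n_exc, 1.0, -1.0)
    J = np.abs(rng.standard_normal((n, n))) / np.sqrt(n)
    J[:, sign < 0] *= n_exc / (n - n_exc)   # balance E and I drive
    J = J * sign[None, :]
    eigs = np.linalg.eigvals(J)
    rho = np.abs(eigs).max()
    if rho > 0:
        J *= spectral_radius / rho
    I = rng.standard_normal((n, n_in)) * input_scale / np.sqrt(n_in)
    w = rng.standard_normal(n) / np.sqrt(n)
    if np.ndim(tau) == 0:
        tau_vec = np.full(n, float(tau))
    else:
        lo, hi = tau
        tau_vec = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    return RnnParams(tau=tau_vec, J=J, I=I, w=w, sign=sign,
                     sigma_xi=float(sigma_xi), dt=float(dt), readout=readout)


def simulate(params: RnnParams, batch, noise_seed=None,
             zero_noise: bool = False) -> Trajectory:
    """Integrate the network over a task batch.

    x[.,0,.] = 0; step n uses input u[n]. Raises on divergence with the
    offending step index.
    """
    rng = np.random.default_rng(noise_seed)
    u = batch.u
    n_trials, n_steps, _ = u.shape
    n = params.n
    alpha = params.alpha
    dtype = params.J.dtype
    noise_scale = np.sqrt(2.0 * alpha * params.sigma_xi**2).astype(dtype)
    x = np.zeros((n_trials, n_steps, n), dtype=dtype)
    state = np.zeros((n_trials, n), dtype=dtype)
    noise_dtype = dtype if dtype in (np.dtype("float32"), np.dtype("float64")) \
        else np.dtype("float64")
    for t in range(n_steps - 1):
        rate = phi(state)
        drive = rate @ params.J.T + u[:, t] @ params.I.T
        state = ((1.0 - alpha) * state + alpha * drive).astype(dtype, copy=False)
        if not zero_noise and params.sigma_xi > 0:
            state = state + noise_scale * rng.standard_normal(
                (n_trials, n), dtype=noise_dtype)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"state diverged at step {t + 1}")
        x[:, t + 1] = state
    rates = phi(x)
    y = (rates if params.readout == "rates" else x) @ params.w
    return Trajectory(x=x, rates=rates, y=y, lfp=lfp_proxy(rates, params.J),
                      dt=params.dt, noise_seed=noise_seed)


def lfp_proxy(rates: np.ndarray, J: np.ndarray) -> np.ndarray:
    """LFP[n] = sum_ij |J_ij| phi(x_j[n]) (linear in |J|, nonnegative)."""
    a = np.abs(J).sum(axis=0)
    return rates @ a


def _normalize_lfp(lfp: np.ndarray):
    """Amplitude-invariant normalization (LFP - mean) / (sqrt(2) * std),
    per trial over time."""
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    mu = lfp.mean(axis=1, keepdims=True)
    sd = lfp.std(axis=1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("constant LFP: normalization degenerate")
    return (lfp - mu) / (np.sqrt(2.0) * sd)


def reg_osc(lfp: np.ndarray, f_osc: float, dt: float) -> float:
    """Oscillation regularizer: minus the magnitude of the normalized
    LFP's Fourier component at ``f_osc``.

    A pure sinusoid at ``f_osc`` spanning an integer number of cycles
    gives exactly -0.5 (the normalization makes its amplitude 1 and the
    one-sided Fourier magnitude of a unit sinusoid is 1/2); incoherent
    noise gives values near 0. Averaged over trials when given a 2-D
    array.
    """
    z = _normalize_lfp(lfp)
    T = z.shape[1]
    e = np.exp(-2j * np.pi * f_osc * np.arange(T) * dt)
    F = (z @ e) / T
    return float(np.mean(-np.abs(F)))


def loss(traj: Trajectory, batch, lam_fr: float = 0.0, lam_osc: float = 0.0,
         f_osc: float | None = None) -> dict:
    """Masked MSE + lam_fr * rate penalty + lam_osc * oscillation term.

    The MSE is normalized by the mask mass; the rate penalty is the mean
    squared rate (1/(N T) sum phi(x)^2). Components are reported
    separately; all terms are trial means.
    """
    m = batch.mask
    msum = m.sum()
    if msum == 0:
        raise ValueError("all-zero decision mask")
    targets = np.asarray(batch.targets)
    if targets.ndim == 1:
        targets = targets[:, None]
    err = (traj.y - targets) ** 2
    mse = float(np.mean((err * m[None, :]).sum(axis=1) / msum))
    fr = float(np.mean(traj.rates**2))
    osc = reg_osc(traj.lfp, f_osc, traj.dt) if lam_osc else 0.0
    total = mse + lam_fr * fr + lam_osc * osc
    return {"total": total, "mse": mse, "reg_fr": fr, "reg_osc": osc}
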