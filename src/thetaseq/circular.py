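"""Circular statistics for spike-phase analyses.

Implements the machinery used to quantify phase-of-firing coding:
per-trial mean phases, Rayleigh's test of uniformity, maximum-likelihood
von Mises fits, the circular variance explained (V_ex) between conditions
with its label-permutation null, Hedges' g effect sizes, bootstrap
confidence intervals on proportions, Simes multiple-testing correction,
and a spike-count-matched subsampling control.

All phases are radians. Phase 0 is the peak of the reference cosine and
phase increases with time; angles are reported in [0, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "PhaseSampleSet",
    "VonMisesFit",
    "VexResult",
    "circular_mean",
    "rayleigh_test",
    "fit_von_mises",
    "vex",
    "vex_permutation_test",
    "significant_across_frequencies",
    "hedges_g",
    "bootstrap_proportion",
    "simes_correct",
    "rate_matched_subsample",
    "trial_mean_phases",
]

KAPPA_MAX = 1e3


def _wrap(phases: np.ndarray) -> np.ndarray:
    return np.mod(phases, 2.0 * np.pi)


@dataclass
class PhaseSampleSet:
    """Per-trial mean phases labelled by condition (sequence position).

    Trials in which no spikes occurred carry no mean-phase estimate and
    must simply be absent from ``phases``/``conditions``.
    """

    phases: np.ndarray          # (n_trials,) radians in [0, 2*pi)
    conditions: np.ndarray      # (n_trials,) integer labels, e.g. position 1..4
    weights: np.ndarray | None = None   # optional per-trial spike counts
    unit_id: int | None = None
    frequency: float | None = None      # Hz of the phase-providing oscillation
    correct: np.ndarray | None = None   # optional per-trial correctness flags

    def __post_init__(self) -> None:
        self.phases = _wrap(np.asarray(self.phases, dtype=float))
        self.conditions = np.asarray(self.conditions)
        if self.phases.shape != self.conditions.shape:
            raise ValueError("phases and conditions must have equal length")

    @property
    def n_trials(self) -> int:
        return self.phases.size

    def condition_labels(self) -> np.ndarray:
        return np.unique(self.conditions)

    def select(self, mask: np.ndarray) -> "PhaseSampleSet":
        return PhaseSampleSet(
            self.phases[mask],
            self.conditions[mask],
            None if self.weights is None else self.weights[mask],
            self.unit_id,
            self.frequency,
            None if self.correct is None else self.correct[mask],
        )


@dataclass
class VonMisesFit:
    mu: float               # preferred direction, radians in [0, 2*pi)
    kappa: float            # concentration (>= 0)
    r: float                # resultant length of the sample
    n: int
    capped: bool = False    # kappa hit KAPPA_MAX (R ~ 1)


@dataclass
class VexResult:
    """Circular variance explained for one unit-frequency pair."""

    v_within: np.ndarray            # V_j^w per condition
    v_w: float                      # trial-count-weighted mean of V_j^w
    v_a: float                      # circular variance across all trials
    v_ex: float                     # 1 - V^w / V^a
    n_per_condition: np.ndarray
    labels: np.ndarray
    null: np.ndarray | None = None  # permutation null of V_ex
    p_value: float | None = None
    unit_id: int | None = None
    frequency: float | None = None


def circular_mean(phases, weights=None, axis=None):
    """Circular mean direction and resultant length R.

    Returns ``(mean_angle, R)`` with the mean in [0, 2*pi). With perfectly
    antipodal samples (R == 0) the direction is undefined and NaN is
    returned for the angle.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular_mean of an empty sample")
    z = np.exp(1j * phases)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        m = np.sum(w * z, axis=axis) / np.sum(w, axis=axis)
    else:
        m = np.mean(z, axis=axis)
    r = np.abs(m)
    ang = _wrap(np.angle(m))
    ang = np.where(r < 1e-12, np.nan, ang)
    if np.ndim(ang) == 0:
        return float(ang), float(r)
    return ang, r


def rayleigh_test(phases, rng: np.random.Generator | None = None):
    """Rayleigh's test of circular uniformity.

    Returns ``(Z, p)`` with Z = n * R**2 and the standard asymptotic
    approximation for p. For n < 5 the asymptotic p is unreliable; a
    Monte-Carlo null (10,000 draws) is used instead and a warning issued.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("rayleigh_test of an empty sample")
    _, r = circular_mean(phases)
    z = n * r**2
    if n >= 5:
        # Zar (1999) approximation, as in the common circular toolboxes;
        # (n*r)**2 = n*z is the squared resultant-sum length.
        p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - n * z)) - (1.0 + 2.0 * n))
        p = float(min(max(p, np.finfo(float).tiny), 1.0))
    else:
        import warnings

        warnings.warn(
            f"Rayleigh test with n={n} < 5: using Monte-Carlo null", stacklevel=2
        )
        rng = np.random.default_rng(0) if rng is None else rng
        null = rng.uniform(0, 2 * np.pi, size=(10_000, n))
        rnull = np.abs(np.mean(np.exp(1j * null), axis=1))
        p = float((1 + np.sum(n * rnull**2 >= z)) / (1 + 10_000))
    return float(z), p


def _a1inv(r: float) -> float:
    """Invert A(kappa) = I1(kappa)/I0(kappa) = R (Best & Fisher 1981)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def fit_von_mises(phases, weights=None, n_bins: int | None = None) -> VonMisesFit:
    """Maximum-likelihood von Mises fit (mu, kappa).

    kappa solves A(kappa) = R via the Best-Fisher piecewise inversion
    followed by a few Newton steps on A(kappa) - R. With ``n_bins`` the
    sample is first histogrammed and the fit performed on bin centers
    weighted by counts (the binned variant used for display histograms).
    """
    phases = _wrap(np.asarray(phases, dtype=float))
    if phases.size < 2:
        raise ValueError("need at least 2 phases to fit")
    if n_bins is not None:
        counts, edges = np.histogram(phases, bins=n_bins, range=(0, 2 * np.pi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        phases, weights = centers, counts.astype(float)
    mu, r = circular_mean(phases, weights=weights)
    capped = False
    if r >= 1.0 - 1e-12:
        return VonMisesFit(mu=mu, kappa=KAPPA_MAX, r=r, n=int(np.size(phases)), capped=True)
    kappa = min(_a1inv(r), KAPPA_MAX)
    for _ in range(25):  # Newton refinement of A(kappa) = R
        # exponentially scaled Bessels: same ratio, no overflow
        a = special.i1e(kappa) / special.i0e(kappa)
        da = 1.0 - a / kappa - a**2 if kappa > 0 else 0.5
        if da <= 0:
            break
        step = (a - r) / da
        kappa = kappa - step
        if kappa <= 0:
            kappa = 1e-8
        if abs(step) < 1e-10:
            break
    if kappa > KAPPA_MAX:
        kappa, capped = KAPPA_MAX, True
    return VonMisesFit(mu=mu, kappa=float(max(kappa, 0.0)), r=r, n=int(np.size(phases)), capped=capped)


def _group_stats(phases: np.ndarray, conditions: np.ndarray):
    labels, inverse = np.unique(conditions, return_inverse=True)
    n_j = np.bincount(inverse, minlength=labels.size).astype(float)
    z = np.exp(1j * phases)
    sums = np.zeros(labels.size, dtype=complex)
    np.add.at(sums, inverse, z)
    return labels, n_j, sums, z


def vex(samples: PhaseSampleSet) -> VexResult:
    """Circular variance explained by condition labels (point estimate).

    V_j^w = 1 - |mean_k exp(i theta_k)| within condition j;
    V^w   = (1/N) sum_j N_j V_j^w;
    V^a   = 1 - |mean over all trials of exp(i theta_k)|;
    V_ex  = 1 - V^w / V^a.
    """
    phases, conditions = samples.phases, samples.conditions
    labels, n_j, sums, z = _group_stats(phases, conditions)
    if labels.size < 2 or np.any(n_j < 2):
        raise ValueError("vex needs >= 2 conditions with >= 2 trials each")
    n = phases.size
    v_j = 1.0 - np.abs(sums) / n_j
    v_w = float(np.sum(n_j * v_j) / n)
    v_a = float(1.0 - np.abs(np.sum(z)) / n)
    if v_a <= 1e-12:
        raise ValueError("V^a = 0 (all trial phases identical): V_ex undefined")
    return VexResult(
        v_within=v_j,
        v_w=v_w,
        v_a=v_a,
        v_ex=float(1.0 - v_w / v_a),
        n_per_condition=n_j.astype(int),
        labels=labels,
        unit_id=samples.unit_id,
        frequency=samples.frequency,
    )


def _null_vex(phases: np.ndarray, group_sizes: np.ndarray, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """Vectorized permutation null of V_ex for balanced or unbalanced groups.

    Shuffling condition labels over trials is equivalent to shuffling the
    phase vector and cutting it into contiguous blocks of the observed
    group sizes.
    """
    n = phases.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    z = np.exp(1j * phases)[order]                       # (n_perm, n)
    edges = np.concatenate([[0], np.cumsum(group_sizes)]).astype(int)
    v_w = np.zeros(n_perm)
    for j in range(group_sizes.size):
        block = z[:, edges[j]:edges[j + 1]]
        v_j = 1.0 - np.abs(block.sum(axis=1)) / group_sizes[j]
        v_w += group_sizes[j] * v_j
    v_w /= n
    v_a = 1.0 - np.abs(z.sum(axis=1)) / n                # invariant to shuffling
    return 1.0 - v_w / v_a


def vex_permutation_test(samples: PhaseSampleSet, n_perm: int = 1999,
                         rng: np.random.Generator | int | None = None) -> VexResult:
    """V_ex with a label-permutation null.

    Trial labels are shuffled between conditions ``n_perm`` times; the
    p-value uses the add-one convention
    p = (1 + #{null >= observed}) / (1 + n_perm), so the smallest
    attainable p is 1/(1 + n_perm).
    """
    rng = np.random.default_rng(rng)
    result = vex(samples)
    null = _null_vex(samples.phases, result.n_per_condition.astype(float), n_perm, rng)
    result.null = null
    result.p_value = float((1 + np.sum(null >= result.v_ex)) / (1 + n_perm))
    return result


def significant_across_frequencies(p_values, alpha: float = 0.05, min_freqs: int = 2) -> bool:
    """Unit-level significance rule over a frequency grid.

    A unit counts as phase-coding if its observed V_ex beats the
    permutation null (p < alpha) at ``min_freqs`` or more frequencies.
    """
    p_values = np.asarray(p_values, dtype=float)
    return int(np.sum(p_values < alpha)) >= min_freqs


def hedges_g(sample_a, sample_b) -> float:
    """Bias-corrected standardized mean difference (Hedges' g), a - b."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    correction = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(d * correction)


def bootstrap_proportion(flags, n_boot: int = 1999,
                         rng: np.random.Generator | int | None = None,
                         ci: float = 0.95):
    """Proportion of True flags with a percentile bootstrap CI.

    Returns ``(proportion, (lo, hi), boot_samples)``. A single unit yields
    the degenerate CI {0 or 1}; callers should treat it as uninformative.
    """
    rng = np.random.default_rng(rng)
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise ValueError("no units")
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    boots = flags[idx].mean(axis=1)
    q = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [q, 1.0 - q])
    return float(flags.mean()), (float(lo), float(hi)), boots


def simes_correct(p_values, alpha: float = 0.05):
    """Simes procedure over a family of p-values.

    Returns ``(global_p, reject)``: the Simes global p-value
    min_i (n * p_(i) / i), and per-test decisions from the step-up rule
    (reject all p <= p_(k) where k is the largest index with
    p_(k) <= k * alpha / n).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p)
    ps = p[order]
    ranks = np.arange(1, n + 1)
    global_p = float(np.min(n * ps / ranks))
    passing = np.nonzero(ps <= ranks * alpha / n)[0]
    reject = np.zeros(n, dtype=bool)
    if passing.size:
        k = passing.max()
        reject[order[: k + 1]] = True
    return global_p, reject


def rate_matched_subsample(spikes_a, spikes_b,
                           rng: np.random.Generator | int | None = None,
                           n_draws: int = 1):
    """Equalize spike counts between two samples by random subsampling.

    The larger sample is subsampled without replacement to the size of
    the smaller one; the smaller passes through unchanged. With
    ``n_draws > 1`` a list of (a, b) pairs is returned for averaging
    statistics over repeated draws.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(spikes_a)
    b = np.asarray(spikes_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty spike sample")
    m = min(a.size, b.size)

    def draw():
        aa = a if a.size == m else rng.choice(a, size=m, replace=False)
        bb = b if b.size == m else rng.choice(b, size=m, replace=False)
        return aa, bb

    if n_draws == 1:
        return draw()
    return [draw() for _ in range(n_draws)]


def trial_mean_phases(spike_phases, trial_ids, trial_conditions: dict,
                      min_spikes: int = 1, unit_id=None, frequency=None) -> PhaseSampleSet:
    """Collapse spike phases to one circular mean per trial.

    ``trial_conditions`` maps trial id -> condition label; trials with
    fewer than ``min_spikes`` spikes contribute no estimate (they are
    dropped, mirroring the treatment of zero-spike trials).
    """
    spike_phases = np.asarray(spike_phases, dtype=float)
    trial_ids = np.asarray(trial_ids)
    means, labels, counts = [], [], []
    for tid in np.unique(trial_ids):
        if tid not in trial_conditions:
            continue
        ph = spike_phases[trial_ids == tid]
        if ph.size < min_spikes:
            continue
        mean, _ = circular_mean(ph)
        if np.isnan(mean):
            continue
        means.append(mean)
        labels.append(trial_conditions[tid])
        counts.append(ph.size)
    return PhaseSampleSet(
        np.asarray(means), np.asarray(labels), np.asarray(counts, dtype=float),
        unit_id=unit_id, frequency=frequency,
    )
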