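"""Sequence match/non-match working-memory task for the rate RNN.

Four of eight input channels pulse on sequentially (0.2 s each, one
onset per SOA), a constant delay follows, then the same four stimuli
reappear either in the same order (match, target +1) or a shuffled order
(non-match, target -1). The target applies only during a decision window
after the probe; inputs are zero everywhere outside stimulus and probe
periods.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaskBatch", "make_task_batch"]

N_IN = 8
SEQ_LEN = 4


@dataclass
class TaskBatch:
    u: np.ndarray            # (n_trials, T, 8) one-hot input pulses
    targets: np.ndarray      # (n_trials,) +1 match / -1 non-match
    mask: np.ndarray         # (T,) 1 during the decision period
    dt: float                # s
    sequences: np.ndarray    # (n_trials, 4) stimulus ids in sample order
    probe_orders: np.ndarray  # (n_trials, 4) stimulus ids in probe order
    is_match: np.ndarray     # (n_trials,)
    soa: float
    stim_onsets: np.ndarray  # (4,) s
    probe_onsets: np.ndarray  # (4,) s
    delay_window: tuple      # (start, stop) s of the memory delay
    baseline_window: tuple   # (start, stop) s before the first stimulus

    @property
    def n_trials(self) -> int:
        return self.u.shape[0]

    @property
    def n_steps(self) -> int:
        return self.u.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


def _non_identity_perm(rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(SEQ_LEN)
    while np.all(perm == np.arange(SEQ_LEN)):
        perm = rng.permutation(SEQ_LEN)
    return perm


def make_task_batch(n_trials: int, soa: float = 0.4, stim_dur: float = 0.2,
                    delay: float = 2.5, decision_dur: float = 0.4,
                    pre: float = 0.2, dt: float = 0.02, p_match: float = 0.5,
                    seed=None, evaluation: bool = False,
                    set_mismatch_frac: float = 0.0,
                    hard_negative_frac: float = 0.0) -> TaskBatch:
    """Build a batch of task trials on a discrete time grid.

    ``evaluation=True`` draws ``n_trials`` *unique* stimulus combinations
    with exactly half assigned to be match trials (the evaluation-set
    convention); otherwise sequences are drawn independently and match
    trials occur with probability ``p_match``.

    ``set_mismatch_frac`` is a curriculum aid for training: that fraction
    of non-match trials swap one probe item for a stimulus absent from
    the sample, giving an item-identity (rather than order-only)
    mismatch signal. ``hard_negative_frac`` draws that fraction of
    non-match trials as permutations of the first three positions only
    (last item unchanged) — the mismatch class networks find hardest.
    Evaluation batches always use uniform order-only mismatches (the
    task proper).
    """
    if stim_dur > soa:
        raise ValueError("stimulus duration exceeds the onset asynchrony")
    rng = np.random.default_rng(seed)
    stim_onsets = pre + soa * np.arange(SEQ_LEN)
    stim_end = pre + soa * (SEQ_LEN - 1) + stim_dur
    probe_start = stim_end + delay
    probe_onsets = probe_start + soa * np.arange(SEQ_LEN)
    probe_end = probe_start + soa * (SEQ_LEN - 1) + stim_dur
    total = probe_end + decision_dur
    n_steps = int(np.round(total / dt))
    times = np.arange(n_steps) * dt

    if evaluation:
        if n_trials % 2:
            raise ValueError("evaluation mode needs an even trial count")
        combos = set()
        seqs = []
        while len(seqs) < n_trials:
            s = tuple(rng.permutation(N_IN)[:SEQ_LEN])
            if s not in combos:
                combos.add(s)
                seqs.append(s)
        sequences = np.array(seqs)
        is_match = np.zeros(n_trials, dtype=bool)
        is_match[rng.permutation(n_trials)[: n_trials // 2]] = True
    else:
        sequences = np.stack([rng.permutation(N_IN)[:SEQ_LEN]
                              for _ in range(n_trials)])
        is_match = rng.random(n_trials) < p_match

    probe_orders = sequences.copy()
    for i in np.where(~is_match)[0]:
        r = rng.random()
        if not evaluation and r < set_mismatch_frac:
            absent = np.setdiff1d(np.arange(N_IN), sequences[i])
            probe = sequences[i].copy()
            probe[rng.integers(SEQ_LEN)] = rng.choice(absent)
            probe_orders[i] = probe
        elif not evaluation and r < set_mismatch_frac + hard_negative_frac:
            head = rng.permutation(3)
            while np.all(head == np.arange(3)):
                head = rng.permutation(3)
            probe_orders[i, :3] = sequences[i, head]
        else:
            probe_orders[i] = sequences[i, _non_identity_perm(rng)]

    u = np.zeros((n_trials, n_steps, N_IN))
    for k in range(SEQ_LEN):
        s_on = (times >= stim_onsets[k]) & (times < stim_onsets[k] + stim_dur)
        p_on = (times >= probe_onsets[k]) & (times < probe_onsets[k] + stim_dur)
        for i in range(n_trials):
            u[i, s_on, sequences[i, k]] = 1.0
            u[i, p_on, probe_orders[i, k]] = 1.0

    mask = ((times >= probe_end) & (times < probe_end + decision_dur)).astype(float)
    targets = np.where(is_match, 1.0, -1.0)
    return TaskBatch(u=u, targets=targets, mask=mask, dt=dt,
                     sequences=sequences, probe_orders=probe_orders,
                     is_match=is_match, soa=soa, stim_onsets=stim_onsets,
                     probe_onsets=probe_onsets,
                     delay_window=(stim_end, probe_start),
                     baseline_window=(0.0, pre))
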