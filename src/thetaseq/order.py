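"""Phase-order analysis and the phase-reset prediction.

A unit that fires at a different preferred theta phase for each sequence
position defines an ordering of positions around the oscillation cycle.
Because phase is circular, orderings that are rotations of one another
(1,2,3,4 == 4,1,2,3 == 3,4,1,2 == 2,3,4,1) are equivalent: 4 positions
yield 24/4 = 6 rotation classes. This module anchors per-position phases,
extracts the counter-clockwise order, classifies it as forward / reverse
/ other, computes chance probabilities by exhaustive enumeration, and
implements the phase-reset model in which each stimulus resets its
unit's phase to a constant, so the phase of position k relative to an
ongoing reference oscillation at f_osc advances by 2*pi*f_osc*soa per
position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .circular import circular_mean

__all__ = [
    "PhaseOrder",
    "ResetPrediction",
    "anchor_phases",
    "canonical_class",
    "phase_order",
    "classify_phases",
    "chance_probabilities",
    "predict_reset_phases",
    "order_match_rate",
]

FORWARD_4 = (1, 2, 3, 4)
REVERSE_4 = (1, 4, 3, 2)  # canonical rotation of (4, 3, 2, 1)


def _wrap_pi(x):
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x, dtype=float), 2.0 * np.pi)


@dataclass
class PhaseOrder:
    anchored: np.ndarray        # per-position phase, circular mean removed, (-pi, pi]
    order: tuple                # positions (1-based) sorted counter-clockwise
    canonical: tuple            # rotation-invariant label (rotation starting at 1)
    category: str               # 'forward' | 'reverse' | 'other'
    tied: bool = False          # exact phase ties broken toward lower position


@dataclass
class ResetPrediction:
    f_osc: float                # reference oscillation frequency, Hz
    soa: float                  # stimulus onset asynchrony, s
    phi0: float                 # phase of the reference at the first stimulus onset
    phases: np.ndarray          # predicted phase per position, [0, 2*pi)
    order: "PhaseOrder | None"  # None when the prediction is degenerate
    degenerate: bool            # f_osc * soa integral: all phases coincide


def anchor_phases(mean_phase_per_position):
    """Remove the circular mean across positions from each position's phase.

    Anchors the phase pattern relative to 0 so that units with different
    absolute preferred phases become comparable. Returns phases wrapped to
    (-pi, pi]. Raises if the across-position resultant vanishes (the mean
    direction, and hence the anchoring, is undefined).
    """
    phases = np.asarray(mean_phase_per_position, dtype=float)
    mean, r = circular_mean(phases)
    if not np.isfinite(mean) or r < 1e-12:
        raise ValueError("across-position resultant is zero: anchoring undefined")
    return _wrap_pi(phases - mean)


def canonical_class(order) -> tuple:
    """Rotation-invariant label of a cyclic ordering of positions.

    The cycle is rotated so that position 1 comes first; all rotations of
    the same cyclic order share this label.
    """
    order = tuple(int(o) for o in order)
    i = order.index(min(order))
    return order[i:] + order[:i]


def phase_order(anchored_phases) -> PhaseOrder:
    """Sort positions counter-clockwise by phase and classify the order.

    Category is 'forward' when the rotation class equals that of
    (1,2,3,4), 'reverse' for (4,3,2,1), else 'other'. Exact phase ties
    are broken toward the lower position index and flagged.
    """
    anchored = np.asarray(anchored_phases, dtype=float)
    n = anchored.size
    positions = np.arange(1, n + 1)
    # stable lexsort: primary key phase, ties resolved by position index
    idx = np.lexsort((positions, anchored))
    order = tuple(int(p) for p in positions[idx])
    tied = bool(np.unique(anchored).size < n)
    canon = canonical_class(order)
    if canon == canonical_class(tuple(range(1, n + 1))):
        category = "forward"
    elif canon == canonical_class(tuple(range(n, 0, -1))):
        category = "reverse"
    else:
        category = "other"
    return PhaseOrder(anchored=anchored, order=order, canonical=canon,
                      category=category, tied=tied)


def classify_phases(phases) -> PhaseOrder:
    """Anchor then classify; if the across-position resultant vanishes
    (anchoring undefined) classify the unanchored pattern — the cyclic
    class is rotation-invariant so the category is unaffected."""
    try:
        anchored = anchor_phases(phases)
    except ValueError:
        anchored = _wrap_pi(phases)
    return phase_order(anchored)


def chance_probabilities(seq_len: int = 4) -> dict:
    """Chance level of each order category by exhaustive enumeration.

    All ``seq_len!`` orderings of distinct phases are equally likely;
    rotation equivalence partitions them into ``(seq_len-1)!`` classes.
    Under the mutually exclusive partition {forward, reverse, other} the
    probabilities sum to 1; the complementary reading 'not forward' is
    reported alongside.
    """
    if seq_len < 3:
        raise ValueError("need seq_len >= 3 for a non-degenerate partition")
    fwd = canonical_class(tuple(range(1, seq_len + 1)))
    rev = canonical_class(tuple(range(seq_len, 0, -1)))
    counts = {"forward": 0, "reverse": 0, "other": 0}
    total = 0
    for perm in itertools.permutations(range(1, seq_len + 1)):
        total += 1
        c = canonical_class(perm)
        if c == fwd:
            counts["forward"] += 1
        elif c == rev:
            counts["reverse"] += 1
        else:
            counts["other"] += 1
    probs = {k: v / total for k, v in counts.items()}
    probs["not_forward"] = 1.0 - probs["forward"]
    probs["n_classes"] = total // seq_len
    return probs


def predict_reset_phases(f_osc: float, soa: float, phi0: float = 0.0,
                         n_positions: int = 4) -> ResetPrediction:
    """Phase order predicted by stimulus-locked phase resets.

    If each stimulus resets its unit's oscillation phase to a constant,
    the phase of position k (0-based) relative to a free-running reference
    at ``f_osc`` is ``phi0 + 2*pi*f_osc*k*soa`` (mod 2*pi). When
    ``f_osc * soa`` is an integer all positions land on the same phase and
    the prediction is degenerate.
    """
    if f_osc <= 0 or soa <= 0:
        raise ValueError("f_osc and soa must be positive")
    k = np.arange(n_positions)
    phases = np.mod(phi0 + 2.0 * np.pi * f_osc * soa * k, 2.0 * np.pi)
    frac = np.mod(f_osc * soa, 1.0)
    degenerate = bool(min(frac, 1.0 - frac) < 1e-9)
    order = None
    if not degenerate:
        order = classify_phases(phases)
    return ResetPrediction(f_osc=f_osc, soa=soa, phi0=phi0, phases=phases,
                           order=order, degenerate=degenerate)


def order_match_rate(observed, predicted, n_shuffles: int = 1999,
                     rng: np.random.Generator | int | None = None):
    """Proportion of units whose observed rotation class matches prediction.

    ``observed`` and ``predicted`` are paired sequences of canonical
    class tuples (or PhaseOrder objects). The null shuffles the
    prediction-to-unit assignment, breaking the link between each unit's
    oscillation frequency / SOA and its observed order; p uses the
    add-one convention.
    """
    def to_class(x):
        return x.canonical if isinstance(x, PhaseOrder) else tuple(x)

    obs = [to_class(o) for o in observed]
    pred = [to_class(p) for p in predicted]
    if len(obs) != len(pred):
        raise ValueError("observed and predicted must be paired")
    n = len(obs)
    matches = np.array([o == p for o, p in zip(obs, pred)])
    rate = float(matches.mean())
    rng = np.random.default_rng(rng)
    null = np.empty(n_shuffles)
    pred_arr = np.array(pred, dtype=object)
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        null[s] = np.mean([obs[i] == pred_arr[perm[i]] for i in range(n)])
    p = float((1 + np.sum(null >= rate)) / (1 + n_shuffles))
    return rate, p, null
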