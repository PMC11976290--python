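import numpy as np
import pytest

from thetaseq import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """Compact forward-ordered session shared by pipeline-level tests."""
    cfg = synthetic.SessionConfig(
        n_trials=64, n_units=6, balanced=True, kappa=3.0,
        baseline_rate=8.0, ordering_mode="forward")
    return synthetic.generate_session(cfg, seed=777)


def vex_bruteforce(phases, conditions):
    """Straight-line reimplementation of the circular-variance-explained
    formulas, independent of the package's vectorized path."""
    import numpy as np
    phases = np.asarray(phases, float)
    conditions = np.asarray(conditions)
    n = len(phases)
    labels = sorted(set(conditions.tolist()))
    v_w = 0.0
    for j in labels:
        ph = phases[conditions == j]
        nj = len(ph)
        vj = 1 - abs(sum(np.exp(1j * p) for p in ph) / nj)
        v_w += nj * vj
    v_w /= n
    v_a = 1 - abs(sum(np.exp(1j * p) for p in phases) / n)
    return 1 - v_w / v_a, v_w, v_a
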