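# thetaseq

Analysis toolkit for **phase-of-firing coding of sequence position** in
working memory: does the theta phase at which a neuron fires during a
memory delay depend on *where* in a remembered sequence its preferred
stimulus appeared?

The package is aimed at systems/computational neuroscientists working
with simultaneous spike + LFP recordings (or rate-network models of
them). It provides, end to end:

* a **synthetic session generator** for a Sternberg-style task (4 of 8
  stimuli per trial at 400 ms SOA, ~2.5 s delay, match/non-match
  probe) that plants theta LFP with a delay power increase, von
  Mises phase-locked spiking whose preferred phase depends on sequence
  position, and primacy-graded evoked responses — so every stage of the
  chain can be validated against known ground truth;
* **Morlet-wavelet phase extraction** (c = 7 cycles, log-spaced
  1.5–8 Hz grid) with baseline-z-scored power, delay spectra, and
  spike-phase assignment;
* **circular statistics**, centred on the circular variance explained

  V_j^w = 1 − |(1/N_j) Σ_k e^{iθ_k}|,  V^w = (1/N) Σ_j N_j V_j^w,
  V^a = 1 − |(1/N) Σ_k e^{iθ_k}|,  **V_ex = 1 − V^w / V^a**,

  with a 1,999-permutation label-shuffle null, Rayleigh tests, von Mises
  ML fits, Hedges' g, bootstrap CIs and Simes correction;
* **phase-order analysis**: anchoring per-position phases, classifying
  orders up to circular rotation (6 classes for 4 items; forward and
  reverse each have chance 1/6, computed by enumeration), and the
  **phase-reset model** predicting the order from oscillation frequency
  and SOA via φ_k = φ0 + 2π·f·k·SOA;
* **position decoding** from phase with an RBF SVM (one-vs-one, 85/15
  stratified splits, label-shuffle null; chance 25%), including
  pseudo-populations across units;
* a **Dale-constrained rate RNN** trained on the same task with an
  oscillation regularizer (minus the normalized LFP's Fourier magnitude
  at a target frequency), simulated by the Euler method and trained by
  analytic backpropagation through time in plain numpy.

## Worked example

```python
import numpy as np
from thetaseq import synthetic
from thetaseq.pipeline import AnalysisConfig, analyze_session

cfg = synthetic.SessionConfig(n_trials=64, n_units=6, balanced=True,
                              kappa=3.0, baseline_rate=8.0,
                              ordering_mode="forward")
session = synthetic.generate_session(cfg, seed=777)
report = analyze_session(session, AnalysisConfig(n_perm=199), seed=0)
print(f"phase-coding units: {report['proportion_significant']:.2f} "
      f"(CI {report['proportion_ci'][0]:.2f}-{report['proportion_ci'][1]:.2f})")
print("order categories:", report["order_counts"])
print(report["unit_table"][["unit", "frequency", "v_ex", "p_value"]]
      .to_string(index=False))
```

prints

```
phase-coding units: 1.00 (CI 1.00-1.00)
order categories: {'forward': 6}
 unit  frequency     v_ex  p_value
    0        2.8 0.967367    0.005
    1        3.2 0.959158    0.005
    2        3.2 0.974047    0.005
    3        3.7 0.956171    0.005
    4        2.8 0.961446    0.005
    5        3.7 0.970097    0.005
```

All six synthetic units (planted with position-dependent preferred
phases, 60° apart, locked to the planted 2.8 Hz theta) are detected as
phase-coding (permutation p = 1/200, the add-one floor at 199
permutations), V_ex is large, and every unit's recovered phase order is
the planted forward order. The reported frequency is each unit's
V_ex-maximizing grid frequency; neighbouring grid points of 2.8 Hz
capture the same locking. With `mu_spacing=0` (no planted effect) the
significant fraction falls to the false-positive rate ≈ 5% and decoding
accuracy to chance (25%).

The same pipeline is available from the shell:

```bash
thetaseq generate --seed 3 --out session.h5 --csv trials.csv
thetaseq analyze --session session.h5 --outdir results/
thetaseq train-rnn --outdir model/ --f-osc 2.75
```

## Layout

```
src/thetaseq/
  synthetic.py   session generator (trials, LFP, spikes, ground truth)
  spectral.py    Morlet decomposition, z-scored power, spike phases
  circular.py    circular stats: V_ex, permutation null, fits, tests
  order.py       phase anchoring, rotation classes, reset prediction
  decoding.py    SVM position decoding, shuffle nulls, pseudo-populations
  rnn/           task, Dale network, BPTT training, model phase analysis
  pipeline.py    end-to-end empirical and model pipelines
  io.py          HDF5 session bundles, CSV/YAML
  cli.py         `thetaseq` command-line interface
docs/methods.md  model and statistics documentation
```
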