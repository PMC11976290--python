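"""End-to-end analysis pipelines and report generation.

``run_empirical_pipeline`` chains session generation -> Morlet phase
extraction -> circular variance explained with permutation nulls ->
phase-order classification -> position decoding, and writes unit-level
CSV tables plus a JSON/Markdown summary. ``run_model_pipeline`` trains
an oscillation-regularized RNN, checks the trained LFP peak, runs the
model phase analysis and compares observed phase orders with the
phase-reset prediction, optionally over an SOA sweep. Every number in a
report is regenerable from the stored config and seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, decoding, order, spectral, synthetic
from .rnn import (RnnTrainConfig, build_network, lfp_peak_frequency,
                  make_task_batch, model_phase_analysis, simulate,
                  stimulus_selective_units, train)

__all__ = ["AnalysisConfig", "analyze_session", "run_empirical_pipeline",
           "ModelRunConfig", "run_model_pipeline"]

BASELINE_WINDOW = 1.0   # s before the first stimulus
DELAY_WINDOW = 2.0      # s before probe onset used for spike phases


@dataclass
class AnalysisConfig:
    n_perm: int = 499            # label permutations for the V_ex null
    n_shuffles: int = 101        # label shuffles for the decoding null
    n_repeats: int = 5           # train/test splits per decoding estimate
    n_boot: int = 1999           # bootstrap draws for proportion CIs
    alpha: float = 0.05
    min_freqs: int = 2           # frequencies needed for unit significance
    frequencies: tuple = tuple(spectral.THETA_GRID)


def _unit_phase_samples(session: synthetic.Session, freqs, min_spikes=1):
    """Per-unit, per-frequency PhaseSampleSets from delay spike phases.

    Only trials containing the unit's preferred stimulus contribute; the
    condition label is that stimulus's sequence position (1..4). Returns
    ``(samples[unit][freq_index], excluded_trial_fraction)``.
    """
    trials = session.trials
    seqs = synthetic.sequences(trials)
    gt = session.ground_truth
    freqs = np.asarray(freqs, dtype=float)
    decs = [spectral.morlet_transform(tr, freqs=freqs) for tr in session.lfp]
    n_units = gt.preferred_stimulus.size
    samples = [[None] * freqs.size for _ in range(n_units)]
    n_used = n_dropped = 0
    for u in range(n_units):
        unit_spikes = session.spikes[session.spikes.unit_id == u]
        cond_by_trial, window_by_trial = {}, {}
        for i, row in enumerate(trials.itertuples(index=False)):
            pos = np.nonzero(seqs[i] == gt.preferred_stimulus[u])[0]
            if pos.size:
                cond_by_trial[int(row.trial_id)] = int(pos[0]) + 1
                window_by_trial[int(row.trial_id)] = (
                    row.probe_on - DELAY_WINDOW, row.probe_on)
        for fi, f in enumerate(freqs):
            ph_all, tid_all = [], []
            for tid, cond in cond_by_trial.items():
                sp = unit_spikes[unit_spikes.trial_id == tid]["time"].to_numpy()
                ph, _ = spectral.spike_phases(sp, decs[tid], f,
                                              window=window_by_trial[tid])
                ph_all.append(ph)
                tid_all.append(np.full(ph.size, tid))
            if not ph_all:
                continue
            sset = circular.trial_mean_phases(
                np.concatenate(ph_all), np.concatenate(tid_all), cond_by_trial,
                min_spikes=min_spikes, unit_id=u, frequency=f)
            samples[u][fi] = sset
            if fi == 0:
                n_used += sset.n_trials
                n_dropped += len(cond_by_trial) - sset.n_trials
    frac_dropped = n_dropped / max(n_used + n_dropped, 1)
    return samples, frac_dropped


def analyze_session(session: synthetic.Session, config: AnalysisConfig,
                    seed=None) -> dict:
    """Full circular / order / decoding analysis of one session."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng_perm, rng_dec, rng_boot, rng_pop = [np.random.default_rng(s)
                                            for s in ss.spawn(4)]
    freqs = np.asarray(config.frequencies)
    samples, frac_dropped = _unit_phase_samples(session, freqs)
    n_units = len(samples)

    unit_rows, order_rows = [], []
    significant = []
    best_sets = []
    for u in range(n_units):
        pvals = np.ones(freqs.size)
        vexs = np.full(freqs.size, np.nan)
        results = [None] * freqs.size
        for fi in range(freqs.size):
            sset = samples[u][fi]
            if sset is None or sset.n_trials < 8:
                continue
            labels, counts = np.unique(sset.conditions, return_counts=True)
            if labels.size < 2 or counts.min() < 2:
                continue
            res = circular.vex_permutation_test(sset, config.n_perm, rng_perm)
            pvals[fi], vexs[fi] = res.p_value, res.v_ex
            results[fi] = res
        sig = circular.significant_across_frequencies(pvals, config.alpha,
                                                      config.min_freqs)
        significant.append(sig)
        if np.all(np.isnan(vexs)):
            best_sets.append(None)
            continue
        best = int(np.nanargmax(vexs))
        sset = samples[u][best]
        best_sets.append(sset)
        mus, kappas = {}, {}
        for c in sorted(np.unique(sset.conditions)):
            ph = sset.phases[sset.conditions == c]
            fit = circular.fit_von_mises(ph) if ph.size >= 2 else None
            mus[c] = fit.mu if fit else np.nan
            kappas[c] = fit.kappa if fit else np.nan
        unit_rows.append({
            "unit": u, "frequency": freqs[best], "v_ex": vexs[best],
            "p_value": pvals[best], "significant": bool(sig),
            "n_significant_freqs": int(np.sum(pvals < config.alpha)),
            **{f"kappa_pos{c}": kappas[c] for c in kappas},
            **{f"mu_pos{c}": mus[c] for c in mus},
        })
        if len(mus) == 4 and not any(np.isnan(list(mus.values()))):
            mean_by_pos = np.array([mus[c] for c in sorted(mus)])
            try:
                po = order.phase_order(order.anchor_phases(mean_by_pos))
            except ValueError:
                continue
            pred = order.predict_reset_phases(session.ground_truth.theta_freq,
                                              session.config.soa)
            order_rows.append({
                "unit": u, "frequency": freqs[best],
                "order": "".join(map(str, po.order)),
                "canonical": "".join(map(str, po.canonical)),
                "category": po.category,
                "predicted": "".join(map(str, pred.order.canonical))
                if pred.order else "degenerate",
                "match": bool(pred.order and po.canonical == pred.order.canonical),
            })

    prop, ci, _ = circular.bootstrap_proportion(significant, config.n_boot,
                                                rng_boot)
    categories = pd.Series([r["category"] for r in order_rows])
    chance = order.chance_probabilities(4)

    # decoding: per-unit at the best frequency, plus a pseudo-population
    unit_dec = []
    for sset in best_sets:
        if sset is None:
            continue
        labels, counts = np.unique(sset.conditions, return_counts=True)
        if labels.size < 4 or counts.min() < 3:
            continue
        res = decoding.shuffle_null(sset.phases, sset.conditions,
                                    n_shuffles=config.n_shuffles,
                                    n_repeats=config.n_repeats, rng=rng_dec)
        unit_dec.append({"unit": sset.unit_id, "accuracy": res.mean_accuracy,
                         "null_mean": float(res.null.mean()),
                         "p_value": res.p_value})
    pop_row = None
    usable = [s for s in best_sets if s is not None]
    if len(usable) >= 2:
        try:
            X, ylab, kept = decoding.pseudo_population(usable, rng=rng_pop)
            res = decoding.decode_position(X, ylab, n_repeats=config.n_repeats,
                                           rng=rng_dec,
                                           scope="pseudo_population")
            pop_row = {"n_units": len(kept), "accuracy": res.mean_accuracy}
        except ValueError:
            pop_row = None

    return {
        "n_units": n_units,
        "excluded_zero_spike_trial_fraction": frac_dropped,
        "proportion_significant": prop,
        "proportion_ci": ci,
        "order_counts": categories.value_counts().to_dict(),
        "order_chance": {k: chance[k] for k in ("forward", "reverse", "other",
                                                "not_forward")},
        "reset_match_rate": (float(np.mean([r["match"] for r in order_rows]))
                             if order_rows else None),
        "unit_table": pd.DataFrame(unit_rows),
        "order_table": pd.DataFrame(order_rows),
        "decoding_table": pd.DataFrame(unit_dec),
        "population_decoding": pop_row,
    }


def run_empirical_pipeline(session_config: synthetic.SessionConfig,
                           analysis_config: AnalysisConfig, outdir,
                           seed=None) -> dict:
    """Generate a session, analyze it, write tables and a summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ss_gen, ss_an = ss.spawn(2)
    session = synthetic.generate_session(session_config, seed=ss_gen)
    report = analyze_session(session, analysis_config, seed=ss_an)
    for key in ("unit_table", "order_table", "decoding_table"):
        report[key].to_csv(outdir / f"{key}.csv", index=False)
    summary = {k: v for k, v in report.items()
               if not isinstance(v, pd.DataFrame)}
    summary["seed"] = seed
    summary["session_config"] = asdict(session_config)
    summary["analysis_config"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in asdict(analysis_config).items()}
    with open(outdir / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, default=float)
    lines = ["# Session analysis summary", "",
             f"- units analyzed: {report['n_units']}",
             f"- zero-spike trials excluded: "
             f"{report['excluded_zero_spike_trial_fraction']:.1%}",
             f"- proportion of phase-coding units: "
             f"{report['proportion_significant']:.2f} "
             f"(95% CI {report['proportion_ci'][0]:.2f}-"
             f"{report['proportion_ci'][1]:.2f})",
             f"- phase-order categories: {report['order_counts']}",
             f"- reset-prediction match rate: {report['reset_match_rate']}"]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    return report


@dataclass
class ModelRunConfig:
    n_units: int = 100
    frac_excitatory: float = 0.8
    spectral_radius: float = 1.5
    tau: tuple = (0.05, 0.7)     # s, log-uniform per-unit range
    sigma_xi: float = 0.02
    dt: float = 0.02             # s
    input_scale: float = 2.0
    readout: str = "rates"
    train: RnnTrainConfig = field(default_factory=RnnTrainConfig)
    n_eval_trials: int = 224     # evaluation set size (unique sequences)
    soa_sweep: tuple = ()        # extra SOAs (s) for the order map
    success_tolerance: float = 0.5   # Hz: LFP peak must land this close
    n_perm: int = 499
    alpha: float = 0.05


def _model_order_analysis(params, batch, f_ref, n_perm, alpha, rng):
    """V_ex + phase order of selective units against the reset prediction."""
    traj = simulate(params, batch, noise_seed=rng)
    times = batch.times
    delay_mask = (times >= batch.delay_window[0]) & (times < batch.delay_window[1])
    units, preferred, _ = stimulus_selective_units(traj, batch)
    sets, _ = model_phase_analysis(traj, batch, f_ref, units, preferred)
    phi0 = float(np.mod(2 * np.pi * f_ref *
                        (batch.stim_onsets[0] - batch.stim_onsets[-1]),
                        2 * np.pi))
    pred = order.predict_reset_phases(f_ref, batch.soa, phi0=phi0)
    rows = []
    for sset in sets:
        try:
            res = circular.vex_permutation_test(sset, n_perm, rng)
        except ValueError:
            continue
        mean_by_pos = []
        ok = True
        for c in (1, 2, 3, 4):
            ph = sset.phases[sset.conditions == c]
            if ph.size == 0:
                ok = False
                break
            mean_by_pos.append(circular.circular_mean(ph)[0])
        if not ok:
            continue
        try:
            po = order.phase_order(order.anchor_phases(np.array(mean_by_pos)))
        except ValueError:
            continue
        rows.append({
            "unit": sset.unit_id, "v_ex": res.v_ex, "p_value": res.p_value,
            "significant": res.p_value < alpha,
            "canonical": "".join(map(str, po.canonical)),
            "category": po.category,
            "predicted": ("".join(map(str, pred.order.canonical))
                          if pred.order else "degenerate"),
            "match": bool(pred.order and po.canonical == pred.order.canonical),
        })
    return pd.DataFrame(rows), traj, delay_mask


def run_model_pipeline(config: ModelRunConfig, outdir, seed=None) -> dict:
    """Train one model, check the oscillation criterion, analyze phases."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ss_build, ss_train, ss_eval, ss_an = ss.spawn(4)
    params = build_network(n=config.n_units,
                           frac_excitatory=config.frac_excitatory,
                           spectral_radius=config.spectral_radius,
                           tau=config.tau, sigma_xi=config.sigma_xi,
                           dt=config.dt, input_scale=config.input_scale,
                           readout=config.readout, seed=ss_build)
    params, history = train(params, config.train, seed=ss_train)
    tc = config.train
    batch = make_task_batch(config.n_eval_trials, soa=tc.soa,
                            stim_dur=tc.stim_dur, delay=tc.delay,
                            decision_dur=tc.decision_dur, pre=tc.pre,
                            dt=params.dt, seed=ss_eval, evaluation=True)
    rng_an = np.random.default_rng(ss_an)
    traj = simulate(params, batch, noise_seed=rng_an)
    times = batch.times
    delay_mask = (times >= batch.delay_window[0]) & (times < batch.delay_window[1])
    peak, spec, freqs = lfp_peak_frequency(traj.lfp, params.dt,
                                           window_mask=delay_mask)
    success = abs(peak - tc.f_osc) <= config.success_tolerance
    f_ref = tc.f_osc if success else peak
    soas = (tc.soa,) + tuple(config.soa_sweep)
    sweeps = {}
    for soa in soas:
        b = (batch if soa == tc.soa else
             make_task_batch(config.n_eval_trials, soa=soa,
                             stim_dur=tc.stim_dur, delay=tc.delay,
                             decision_dur=tc.decision_dur, pre=tc.pre,
                             dt=params.dt, seed=ss_eval, evaluation=True))
        table, _, _ = _model_order_analysis(params, b, f_ref, config.n_perm,
                                            config.alpha, rng_an)
        sweeps[soa] = table
    main = sweeps[tc.soa]
    main.to_csv(outdir / "model_order_table.csv", index=False)
    report = {
        "lfp_peak_hz": peak,
        "f_osc": tc.f_osc,
        "success": bool(success),
        "final_val_accuracy": (history["val_accuracy"][-1]
                               if history["val_accuracy"] else None),
        "criterion_iteration": history["criterion_iteration"],
        "n_selective_units": int(len(main)),
        "prop_vex_significant": (float(main["significant"].mean())
                                 if len(main) else None),
        "reset_match_rate": (float(main["match"].mean()) if len(main) else None),
        "order_map": {f"{soa:g}": (sweeps[soa]["canonical"].mode().iloc[0]
                                   if len(sweeps[soa]) else None)
                      for soa in soas},
        "history": history,
        "seed": seed,
    }
    with open(outdir / "model_summary.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
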