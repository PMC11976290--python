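"""Session bundle serialization: HDF5 round-trip, CSV export, YAML config."""

from __future__ import annotations

from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import GroundTruth, LfpTrace, Session, SessionConfig

__all__ = ["save_session", "load_session", "export_trials_csv",
           "load_config", "save_config"]


def _config_dict(config: SessionConfig) -> dict:
    def clean(v):
        if isinstance(v, (tuple, list)):
            return [clean(x) for x in v]
        if isinstance(v, np.integer):
            return int(v)
        if isinstance(v, np.floating):
            return float(v)
        return v

    return {k: clean(v) for k, v in asdict(config).items()}


def save_session(session: Session, path) -> None:
    """Write a session to HDF5 (groups /trials, /lfp, /spikes, /ground_truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("trials")
        g.attrs["columns"] = list(session.trials.columns)
        for col in session.trials.columns:
            g.create_dataset(col, data=session.trials[col].to_numpy())
        g = f.create_group("lfp")
        for tr in session.lfp:
            d = g.create_dataset(f"trial_{tr.trial_id}", data=tr.samples)
            d.attrs["fs"] = tr.fs
            d.attrs["t0"] = tr.t0
            d.attrs["channel_id"] = tr.channel_id
            d.attrs["trial_id"] = tr.trial_id
        g = f.create_group("spikes")
        for col in ("unit_id", "trial_id", "time"):
            g.create_dataset(col, data=session.spikes[col].to_numpy())
        g = f.create_group("ground_truth")
        gt = session.ground_truth
        for name in ("preferred_stimulus", "baseline_rate", "selectivity_gain",
                     "primacy", "kappa", "mu", "kappa_nps", "theta_phase0"):
            g.create_dataset(name, data=getattr(gt, name))
        g.attrs["ordering_mode"] = gt.ordering_mode
        g.attrs["theta_freq"] = gt.theta_freq
        f.attrs["config"] = yaml.safe_dump(_config_dict(session.config))


def load_session(path) -> Session:
    with h5py.File(path, "r") as f:
        cols = list(f["trials"].attrs["columns"])
        trials = pd.DataFrame({col: f["trials"][col][()] for col in cols})
        trials = trials.sort_values("trial_id").reset_index(drop=True)
        lfp = []
        for name in f["lfp"]:
            d = f["lfp"][name]
            lfp.append(LfpTrace(channel_id=int(d.attrs["channel_id"]),
                                trial_id=int(d.attrs["trial_id"]),
                                samples=d[()], fs=float(d.attrs["fs"]),
                                t0=float(d.attrs["t0"])))
        lfp.sort(key=lambda tr: tr.trial_id)
        spikes = pd.DataFrame({col: f["spikes"][col][()]
                               for col in ("unit_id", "trial_id", "time")})
        g = f["ground_truth"]
        gt = GroundTruth(
            preferred_stimulus=g["preferred_stimulus"][()],
            baseline_rate=g["baseline_rate"][()],
            selectivity_gain=g["selectivity_gain"][()],
            primacy=g["primacy"][()],
            kappa=g["kappa"][()],
            mu=g["mu"][()],
            kappa_nps=g["kappa_nps"][()],
            ordering_mode=str(g.attrs["ordering_mode"]),
            theta_freq=float(g.attrs["theta_freq"]),
            theta_phase0=g["theta_phase0"][()],
        )
        config = SessionConfig(**yaml.safe_load(f.attrs["config"]))
    return Session(trials=trials, lfp=lfp, spikes=spikes, ground_truth=gt,
                   config=config)


def export_trials_csv(session: Session, path) -> None:
    session.trials.to_csv(path, index=False)


def load_config(path) -> SessionConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    try:
        return SessionConfig(**data)
    except TypeError as e:
        raise ValueError(f"config schema violation: {e}") from e


def save_config(config: SessionConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_config_dict(config), f)
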