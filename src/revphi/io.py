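"""File formats: HDF5 and tidy CSV for stimuli, responses and trial data."""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .pipeline import TrialSet
from .stimuli import SpaceTimeStimulus, StimulusSpec

__all__ = [
    "save_stimulus_h5",
    "load_stimulus_h5",
    "stimulus_to_frame",
    "trialset_to_frame",
    "trialset_from_frame",
    "save_cohort_csv",
    "load_cohort_csv",
]


def save_stimulus_h5(stim: SpaceTimeStimulus, path) -> None:
    """Write a stimulus (luminance grid + spec attributes) to HDF5."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("luminance", data=stim.luminance)
        d.attrs["receptor_spacing_deg"] = stim.receptor_spacing_deg
        d.attrs["dt_s"] = stim.dt_s
        if stim.spec is not None:
            f.attrs["spec_json"] = json.dumps(asdict(stim.spec))
        if stim.meta:
            f.attrs["meta_json"] = json.dumps(stim.meta)


def load_stimulus_h5(path) -> SpaceTimeStimulus:
    with h5py.File(path, "r") as f:
        d = f["luminance"]
        spec = None
        if "spec_json" in f.attrs:
            raw = json.loads(f.attrs["spec_json"])
            raw["luminance_levels"] = tuple(raw["luminance_levels"])
            spec = StimulusSpec(**raw)
        meta = json.loads(f.attrs["meta_json"]) if "meta_json" in f.attrs else {}
        return SpaceTimeStimulus(
            luminance=d[...],
            receptor_spacing_deg=float(d.attrs["receptor_spacing_deg"]),
            dt_s=float(d.attrs["dt_s"]),
            spec=spec,
            meta=meta,
        )


def stimulus_to_frame(stim: SpaceTimeStimulus) -> pd.DataFrame:
    """Long-format table: one row per (receptor, time) sample."""
    r, t = np.meshgrid(
        np.arange(stim.n_receptors), stim.times, indexing="ij"
    )
    return pd.DataFrame(
        {
            "receptor": r.ravel(),
            "time_s": t.ravel(),
            "luminance": stim.luminance.ravel(),
        }
    )


def trialset_to_frame(trials: TrialSet) -> pd.DataFrame:
    """Tidy table: fly, trial, condition, direction, time, turning, speed."""
    n_trials, n_t = trials.turning.shape
    idx = np.repeat(np.arange(n_trials), n_t)
    return pd.DataFrame(
        {
            "fly": trials.fly_id,
            "trial": idx,
            "condition": np.asarray(trials.condition)[idx],
            "direction": np.asarray(trials.direction)[idx],
            "time_s": np.tile(trials.times, n_trials),
            "turning_deg_s": trials.turning.ravel(),
            "speed_mm_s": trials.walking_speed.ravel(),
        }
    )


def trialset_from_frame(df: pd.DataFrame, rate_hz: float = 20.0) -> TrialSet:
    fly_ids = df["fly"].unique()
    if len(fly_ids) != 1:
        raise ValueError("frame holds more than one fly; split it first")
    n_t = df["trial"].value_counts().iloc[0]
    pivot = df.sort_values(["trial", "time_s"])
    n_trials = df["trial"].nunique()
    per_trial = pivot.groupby("trial").first()
    return TrialSet(
        turning=pivot["turning_deg_s"].to_numpy().reshape(n_trials, n_t),
        walking_speed=pivot["speed_mm_s"].to_numpy().reshape(n_trials, n_t),
        direction=per_trial["direction"].to_numpy(),
        condition=per_trial["condition"].to_numpy(),
        fly_id=str(fly_ids[0]),
        rate_hz=rate_hz,
    )


def save_cohort_csv(flies: list[TrialSet], path) -> None:
    pd.concat([trialset_to_frame(f) for f in flies]).to_csv(path, index=False)


def load_cohort_csv(path, rate_hz: float = 20.0) -> list[TrialSet]:
    df = pd.read_csv(path)
    return [
        trialset_from_frame(g, rate_hz=rate_hz) for _, g in df.groupby("fly", sort=False)
    ]
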