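"""Summarization procedures for behavioral and physiological traces.

Behavioral trials are turning-velocity traces sampled at 20 Hz over 3.5 s,
presented in mirrored (leftward/rightward) pairs per condition; the
direction-selective response is isolated by subtracting mirrored trials,
which cancels any direction-independent turning bias exactly.  Flies are
retained post hoc only if a contiguous block of 40 of their 70 trials
satisfies a walking-speed and turning-bias criterion.  Membrane-potential
traces are summarized as mean depolarization over the first 2 s of
stimulation (cells below 6 mV for the preferred-direction phi condition are
discarded), and calcium traces as dF/F against a 15 s sliding-minimum
baseline, summarized as the PD - ND difference 1-4 s after stimulation
onset.  Confidence intervals are percentile bootstraps of the mean over
1,000 resamplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

__all__ = [
    "TrialSet",
    "PhysioTrace",
    "FlySelection",
    "mirror_subtract",
    "summarize_turning",
    "select_flies",
    "summarize_voltage",
    "include_cell",
    "delta_f_over_f",
    "summarize_imaging",
    "bootstrap_ci",
    "downsample",
]

VOLTAGE_INCLUSION_MV = 6.0
SPEED_THRESHOLD_MM_S = 4.0
TRIAL_WINDOW = 40


@dataclass
class TrialSet:
    """Behavioral trials of one fly.

    ``turning`` and ``walking_speed`` are (n_trials, n_samples) arrays at
    ``rate_hz``; ``direction`` holds +1/-1 for the mirrored presentations
    and ``condition`` the stimulus label of each trial.
    """

    turning: np.ndarray
    walking_speed: np.ndarray
    direction: np.ndarray
    condition: np.ndarray
    fly_id: str = "fly0"
    rate_hz: float = 20.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.turning = np.asarray(self.turning, dtype=float)
        self.walking_speed = np.asarray(self.walking_speed, dtype=float)
        self.direction = np.asarray(self.direction)
        self.condition = np.asarray(self.condition)
        n = self.turning.shape[0]
        if not (
            self.walking_speed.shape[0] == n
            and self.direction.shape == (n,)
            and self.condition.shape == (n,)
        ):
            raise ValueError("trial axes of TrialSet fields do not match")

    @property
    def n_trials(self) -> int:
        return self.turning.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.turning.shape[1]) / self.rate_hz

    def subset(self, idx) -> "TrialSet":
        return TrialSet(
            turning=self.turning[idx],
            walking_speed=self.walking_speed[idx],
            direction=self.direction[idx],
            condition=self.condition[idx],
            fly_id=self.fly_id,
            rate_hz=self.rate_hz,
            meta=dict(self.meta),
        )


@dataclass
class PhysioTrace:
    """A physiological time series (membrane potential or fluorescence)."""

    samples: np.ndarray
    rate_hz: float
    stimulus_onset_s: float
    kind: str = "membrane_mV"  # or "fluorescence_au"
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not (0 <= self.stimulus_onset_s <= self.samples.size / self.rate_hz):
            raise ValueError("stimulus onset outside the record")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate_hz


def mirror_subtract(trials: TrialSet) -> dict[str, np.ndarray]:
    """Per-condition mean turning trace with turning bias removed.

    For each condition, half the difference between the trial-average
    response to the rightward and the leftward presentation; any additive
    direction-independent component cancels exactly.
    """
    out: dict[str, np.ndarray] = {}
    for cond in np.unique(trials.condition):
        sel = trials.condition == cond
        pos = sel & (trials.direction == 1)
        neg = sel & (trials.direction == -1)
        if not pos.any() or not neg.any():
            raise ValueError(
                f"condition {cond!r} lacks one mirrored direction; "
                "cannot remove turning bias"
            )
        out[str(cond)] = 0.5 * (
            trials.turning[pos].mean(axis=0) - trials.turning[neg].mean(axis=0)
        )
    return out


def summarize_turning(
    trace: np.ndarray,
    rate_hz: float = 20.0,
    window_s: tuple[float, float] = (1.5, 3.0),
) -> float:
    """Mean turning velocity over a window (seconds from trial onset)."""
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(window_s[0] * rate_hz))
    i1 = int(round(window_s[1] * rate_hz))
    if i0 < 0 or i1 > trace.size or i1 <= i0:
        raise ValueError(f"window {window_s} s outside the {trace.size / rate_hz} s trial")
    return float(trace[i0:i1].mean())


@dataclass
class FlySelection:
    """Outcome of post-hoc fly selection."""

    retained: list[TrialSet]
    windows: dict[str, tuple[int, int]]
    excluded: list[str]
    bias_tol: float


def _cohort_response_scale(flies: list[TrialSet]) -> float:
    """Largest absolute condition summary across the cohort; used to anchor
    the default turning-bias tolerance."""
    best = 0.0
    for fly in flies:
        for trace in mirror_subtract(fly).values():
            best = max(best, abs(summarize_turning(trace, fly.rate_hz)))
    return best


def select_flies(
    flies: list[TrialSet],
    speed_threshold_mm_s: float = SPEED_THRESHOLD_MM_S,
    window_trials: int = TRIAL_WINDOW,
    bias_tol: float | None = None,
) -> FlySelection:
    """Post-hoc selection of flies with a qualifying contiguous trial block.

    For each fly, the earliest contiguous window of ``window_trials`` trials
    whose mean walking speed exceeds ``speed_threshold_mm_s`` and whose mean
    turning is within ``bias_tol`` of zero is chosen; flies without one are
    excluded.  ``bias_tol`` defaults to 10% of the cohort's response scale
    (the largest absolute condition summary across flies).
    """
    if bias_tol is None:
        bias_tol = 0.1 * _cohort_response_scale(flies)
    retained: list[TrialSet] = []
    windows: dict[str, tuple[int, int]] = {}
    excluded: list[str] = []
    for fly in flies:
        if fly.n_trials < window_trials:
            excluded.append(fly.fly_id)
            continue
        chosen = None
        for start in range(fly.n_trials - window_trials + 1):
            stop = start + window_trials
            if fly.walking_speed[start:stop].mean() <= speed_threshold_mm_s:
                continue
            if abs(fly.turning[start:stop].mean()) >= bias_tol:
                continue
            chosen = (start, stop)
            break
        if chosen is None:
            excluded.append(fly.fly_id)
        else:
            windows[fly.fly_id] = chosen
            retained.append(fly.subset(slice(*chosen)))
    return FlySelection(
        retained=retained, windows=windows, excluded=excluded, bias_tol=bias_tol
    )


def summarize_voltage(
    trace: PhysioTrace,
    window_s: float = 2.0,
    baseline_window_s: float = 0.5,
) -> float:
    """Mean depolarization (mV) over the first ``window_s`` of stimulation.

    The resting baseline is the mean over the ``baseline_window_s`` directly
    preceding stimulus onset.
    """
    if trace.kind != "membrane_mV":
        raise ValueError("summarize_voltage expects a membrane-potential trace")
    n = trace.samples.size
    onset = int(round(trace.stimulus_onset_s * trace.rate_hz))
    b0 = max(0, onset - int(round(baseline_window_s * trace.rate_hz)))
    i1 = onset + int(round(window_s * trace.rate_hz))
    if i1 > n:
        raise ValueError("summary window extends past the end of the record")
    if onset <= b0:
        raise ValueError("no pre-stimulus samples available for the baseline")
    baseline = trace.samples[b0:onset].mean()
    return float(trace.samples[onset:i1].mean() - baseline)


def include_cell(pd_phi_depolarization_mv: float) -> bool:
    """Cell-inclusion rule: preferred-direction phi depolarization of at
    least 6 mV."""
    return pd_phi_depolarization_mv >= VOLTAGE_INCLUSION_MV


def delta_f_over_f(trace: PhysioTrace, window_s: float = 15.0) -> np.ndarray:
    """dF/F against a sliding-minimum baseline.

    The baseline B(t) is the minimum fluorescence within a centered
    ``window_s`` window (truncated at the edges); the result is
    (F - B) / B, invariant to multiplicative rescaling of F.
    """
    f = np.asarray(trace.samples, dtype=float)
    size = int(round(window_s * trace.rate_hz))
    if size < 1:
        raise ValueError("sliding window shorter than one sample")
    baseline = minimum_filter1d(f, size=size, mode="nearest")
    if np.any(baseline <= 0):
        raise ValueError("nonpositive baseline; dF/F undefined")
    return (f - baseline) / baseline


def summarize_imaging(
    dff_pd: np.ndarray,
    dff_nd: np.ndarray,
    rate_hz: float,
    stimulus_onset_s: float,
    window_s: tuple[float, float] = (1.0, 4.0),
) -> float:
    """PD - ND difference of time-averaged dF/F in a window after
    stimulation onset (both traces must share one timebase)."""
    dff_pd = np.asarray(dff_pd, dtype=float)
    dff_nd = np.asarray(dff_nd, dtype=float)
    if dff_pd.shape != dff_nd.shape:
        raise ValueError("PD and ND traces are not on the same timebase")
    i0 = int(round((stimulus_onset_s + window_s[0]) * rate_hz))
    i1 = int(round((stimulus_onset_s + window_s[1]) * rate_hz))
    if i0 < 0 or i1 > dff_pd.size or i1 <= i0:
        raise ValueError("summary window outside the record")
    return float(dff_pd[i0:i1].mean() - dff_nd[i0:i1].mean())


def bootstrap_ci(
    samples,
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the mean.

    Deterministic given ``seed``; requires at least two samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples for a bootstrap CI")
    if seed is None:
        raise ValueError("seed is required for a reproducible interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def downsample(samples: np.ndarray, rate_hz: float, target_hz: float) -> np.ndarray:
    """Decimate by non-overlapping block averaging.

    ``rate_hz`` must be an integer multiple of ``target_hz`` (e.g. 2 kHz to
    50 Hz averages blocks of 40 samples); a trailing partial block is
    dropped.
    """
    factor = rate_hz / target_hz
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target rate {target_hz} Hz must evenly divide the source rate {rate_hz} Hz"
        )
    factor = int(round(factor))
    x = np.asarray(samples, dtype=float)
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)
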