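"""Seeded generators of synthetic behavioral and physiological traces.

These emulate the structure of the real recordings — 3.5 s treadmill trials
at 20 Hz with motion between 1.0 and 2.0 s, membrane potential at 2 kHz,
calcium fluorescence at 7.51 Hz — with planted direction-dependent
responses, per-fly turning bias, baseline drift and Gaussian noise, so that
every pipeline stage can be validated by plant-and-recover.  Response
kernels are first-order rise/decay transients scaled so that the pipeline's
own summary window recovers the planted amplitude exactly in the noiseless
limit.  All generators are pure functions of their spec (seed included).

The noise model is deliberately simple: additive white Gaussian noise on
turning and voltage, multiplicative-plus-additive on calcium.  It emulates
trial-to-trial variability and per-fly bias, not saccadic structure,
correlated noise, or indicator kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import PhysioTrace, TrialSet

__all__ = [
    "CohortSpec",
    "PhysioSpec",
    "DEFAULT_TUNING_PROFILE",
    "gen_behavior",
    "gen_voltage",
    "gen_calcium",
    "t4_like_profile",
    "t5_like_profile",
    "response_kernel",
]

#: Planted mean turning (deg/s) per reverse-phi velocity condition, shaped
#: like the bilobed 2Q reverse-phi tuning: syn-directional turning is
#: negative (inverted) at low pattern velocities and re-inverts at high
#: velocities.
DEFAULT_TUNING_PROFILE: dict[str, float] = {
    "rp_v16": -8.0,
    "rp_v32": -12.0,
    "rp_v64": -6.0,
    "rp_v128": 4.0,
    "rp_v256": 7.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic behavioral cohort.

    Amplitudes are in deg/s of turning velocity; the per-fly bias is a
    constant additive turning offset drawn once per fly; walking speed is
    drawn per fly (mm/s) with white within-trial fluctuation.
    """

    n_flies: int = 10
    trials_per_fly: int = 70
    tuning_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TUNING_PROFILE)
    )
    turning_noise_sd: float = 20.0
    bias_mean: float = 0.0
    bias_sd: float = 0.5
    speed_mean_mm_s: float = 8.0
    speed_sd_mm_s: float = 1.5
    speed_noise_sd: float = 1.0
    rise_tau_s: float = 0.25
    decay_tau_s: float = 1.0
    rate_hz: float = 20.0
    trial_duration_s: float = 3.5
    motion_onset_s: float = 1.0
    motion_offset_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_fly < 40:
            raise ValueError("need at least 40 trials per fly")
        if min(self.turning_noise_sd, self.bias_sd, self.speed_sd_mm_s) < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class PhysioSpec:
    """Parameters of synthetic physiological traces.

    ``amplitudes`` maps a condition label to the planted sustained response
    amplitude (mV for voltage, fluorescence units for calcium) on top of
    ``baseline``.  ``bleach_tau_s`` applies an exponential baseline decay
    (calcium only); it must be slow enough to keep fluorescence positive.
    """

    baseline: float = -50.0
    amplitudes: dict[str, float] = field(default_factory=dict)
    rise_tau_s: float = 0.1
    decay_tau_s: float = 0.3
    noise_sd: float = 0.0
    bleach_tau_s: float = np.inf
    rate_hz: float = 2000.0
    duration_s: float = 4.5
    stimulus_onset_s: float = 1.0
    stimulus_duration_s: float = 2.5
    seed: int = 0


def response_kernel(
    times: np.ndarray,
    onset_s: float,
    offset_s: float,
    rise_tau_s: float,
    decay_tau_s: float,
    normalize_window: tuple[float, float] | None = None,
    rate_hz: float | None = None,
) -> np.ndarray:
    """First-order rise during [onset, offset), exponential decay after.

    With ``normalize_window`` the kernel is rescaled so its mean over that
    window (sampled at ``rate_hz``) is exactly 1, making the corresponding
    pipeline summary recover planted amplitudes exactly when noise-free.
    """
    t = np.asarray(times, dtype=float)
    k = np.zeros_like(t)
    during = (t >= onset_s) & (t < offset_s)
    k[during] = 1.0 - np.exp(-(t[during] - onset_s) / rise_tau_s)
    k_off = 1.0 - np.exp(-(offset_s - onset_s) / rise_tau_s)
    after = t >= offset_s
    k[after] = k_off * np.exp(-(t[after] - offset_s) / decay_tau_s)
    if normalize_window is not None:
        i0 = int(round(normalize_window[0] * rate_hz))
        i1 = int(round(normalize_window[1] * rate_hz))
        m = k[i0:i1].mean()
        if m <= 0:
            raise ValueError("kernel vanishes inside the normalization window")
        k = k / m
    return k


def gen_behavior(spec: CohortSpec) -> list[TrialSet]:
    """Synthetic behavioral cohort with known ground truth.

    Per trial, turning = fly bias + direction x planted amplitude x response
    kernel + white noise; mirrored directions are generated in pairs so
    every condition is balanced.  Ground truth (planted amplitudes, per-fly
    bias and walking speed) is stored in each TrialSet's ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.trial_duration_s * spec.rate_hz))
    times = np.arange(n_t) / spec.rate_hz
    kernel = response_kernel(
        times,
        spec.motion_onset_s,
        spec.motion_offset_s,
        spec.rise_tau_s,
        spec.decay_tau_s,
        normalize_window=(1.5, 3.0),
        rate_hz=spec.rate_hz,
    )
    conditions = list(spec.tuning_profile)
    base_schedule = [(c, d) for c in conditions for d in (1, -1)]
    flies: list[TrialSet] = []
    for f in range(spec.n_flies):
        bias = rng.normal(spec.bias_mean, spec.bias_sd)
        speed = rng.normal(spec.speed_mean_mm_s, spec.speed_sd_mm_s)
        # repeat the balanced block, then truncate to trials_per_fly in
        # whole mirrored pairs so both directions stay present
        reps = -(-spec.trials_per_fly // len(base_schedule))
        schedule = (base_schedule * reps)[: 2 * (spec.trials_per_fly // 2)]
        turning = np.empty((len(schedule), n_t))
        walking = np.empty_like(turning)
        direction = np.empty(len(schedule), dtype=int)
        condition = np.empty(len(schedule), dtype=object)
        for i, (cond, d) in enumerate(schedule):
            amp = spec.tuning_profile[cond]
            turning[i] = bias + d * amp * kernel + rng.normal(
                0.0, spec.turning_noise_sd, n_t
            )
            walking[i] = np.maximum(
                speed + rng.normal(0.0, spec.speed_noise_sd, n_t), 0.0
            )
            direction[i] = d
            condition[i] = cond
        flies.append(
            TrialSet(
                turning=turning,
                walking_speed=walking,
                direction=direction,
                condition=condition,
                fly_id=f"fly{f}",
                rate_hz=spec.rate_hz,
                meta={
                    "ground_truth": {
                        "tuning_profile": dict(spec.tuning_profile),
                        "bias": float(bias),
                        "walking_speed_mm_s": float(speed),
                    }
                },
            )
        )
    return flies


def _physio_traces(
    spec: PhysioSpec, kind: str, normalize_window: tuple[float, float] | None
) -> dict[str, PhysioTrace]:
    rng = np.random.default_rng(spec.seed)
    n_t = int(round(spec.duration_s * spec.rate_hz))
    times = np.arange(n_t) / spec.rate_hz
    kernel = response_kernel(
        times,
        spec.stimulus_onset_s,
        spec.stimulus_onset_s + spec.stimulus_duration_s,
        spec.rise_tau_s,
        spec.decay_tau_s,
        normalize_window=normalize_window,
        rate_hz=spec.rate_hz,
    )
    if kind == "fluorescence_au":
        kernel = kernel / kernel.max()  # unit peak: dF/F peak == amp / baseline
    if np.isfinite(spec.bleach_tau_s):
        baseline = spec.baseline * np.exp(-times / spec.bleach_tau_s)
    else:
        baseline = np.full(n_t, spec.baseline)
    out: dict[str, PhysioTrace] = {}
    for label, amp in spec.amplitudes.items():
        samples = baseline + amp * kernel
        if spec.noise_sd > 0:
            samples = samples + rng.normal(0.0, spec.noise_sd, n_t)
            if kind == "fluorescence_au":
                # multiplicative shot-noise-like component
                samples = samples * (1.0 + rng.normal(0.0, 0.005, n_t))
        out[label] = PhysioTrace(
            samples=samples,
            rate_hz=spec.rate_hz,
            stimulus_onset_s=spec.stimulus_onset_s,
            kind=kind,
            condition={"label": label, "planted_amplitude": float(amp)},
        )
    return out


def gen_voltage(spec: PhysioSpec) -> dict[str, PhysioTrace]:
    """Synthetic tangential-cell membrane-potential traces (2 kHz).

    The response kernel is normalized over the first 2 s of stimulation, so
    ``summarize_voltage`` returns the planted amplitude exactly on
    noise-free traces.  Typical condition labels: ``"phi_PD"``,
    ``"phi_ND"``, ``"rp_PD"``, ``"rp_ND"``.
    """
    window = (spec.stimulus_onset_s, spec.stimulus_onset_s + 2.0)
    return _physio_traces(spec, "membrane_mV", window)


def gen_calcium(spec: PhysioSpec) -> dict[str, PhysioTrace]:
    """Synthetic calcium fluorescence traces (7.51 Hz, positive baseline
    with slow exponential bleaching).

    The kernel is normalized to unit peak, so a planted amplitude ``a`` on
    baseline ``b`` gives a dF/F peak of approximately ``a / b``.
    """
    if spec.baseline <= 0:
        raise ValueError("calcium baseline must be positive")
    traces = _physio_traces(spec, "fluorescence_au", None)
    for tr in traces.values():
        if np.any(tr.samples <= 0):
            raise ValueError(
                "fluorescence went nonpositive; reduce noise/bleaching"
            )
    return traces


def t4_like_profile(
    velocities=(16, 32, 64, 128, 256),
    nd_low: float = 0.6,
    pd_high: float = 0.5,
    pd_base: float = 0.1,
    nd_base: float = 0.1,
) -> dict[str, float]:
    """Reverse-phi amplitude profile of an ON-pathway (T4-like) unit:
    null-direction dominant at low velocities, preferred-direction dominant
    at high velocities.  Labels are ``"rp_v{v}_PD"`` / ``"rp_v{v}_ND"``."""
    velocities = list(velocities)
    mid = len(velocities) // 2
    out: dict[str, float] = {}
    for i, v in enumerate(velocities):
        if i < mid:
            pd, nd = pd_base, nd_low
        else:
            pd, nd = pd_high, nd_base
        out[f"rp_v{v}_PD"] = pd
        out[f"rp_v{v}_ND"] = nd
    return out


def t5_like_profile(velocities=(16, 32, 64, 128, 256)) -> dict[str, float]:
    """OFF-pathway (T5-like) reverse-phi profile: same shape as the T4-like
    profile but with strongly attenuated inversion."""
    return t4_like_profile(velocities, nd_low=0.25, pd_high=0.4)
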