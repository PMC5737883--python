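"""Correlation-type elementary motion detector (EMD) arrays.

Two architectures are implemented over a one-dimensional array of detectors,
each reading a pair of neighboring photoreceptors separated by ``Delta_phi``:

* the four-quadrant (4Q) detector — the classical non-rectified
  Hassenstein-Reichardt correlator: each input is high-pass filtered, the
  delayed (low-pass filtered) signal of one receptor is multiplied with the
  undelayed signal of its neighbor, and the mirror-symmetric product is
  subtracted;
* the two-quadrant (2Q) detector — each input is high-pass filtered, a
  tonic fraction of the raw luminance (the DC component) is added, and the
  sum is half-wave rectified into a positive ON and a positive OFF signal.
  ON and OFF channels each feed their own mirror-symmetric correlator
  (modelling the T4 and T5 pathways) whose outputs are summed after the
  subtraction stage.

All temporal filters are first-order RC stages integrated with the Euler
forward method; the high-pass is realized as the input minus its own
low-pass, which makes ``HP + LP`` reconstruct the input exactly.  Filter
states start at the first input sample so a static lead-in produces no
onset transient.  Positive summed output signals motion toward increasing
receptor index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal import lfilter

from .stimuli import SpaceTimeStimulus

__all__ = [
    "DetectorConfig",
    "DetectorOutput",
    "lowpass",
    "highpass",
    "half_wave",
    "simulate",
    "simulate_4q",
    "simulate_2q",
    "mean_response",
    "smooth_display",
    "isolate_subunit",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Full parameter set of a detector array.

    Defaults follow the standard configuration: ``tau_hp_s`` = 250 ms input
    high-pass, ``tau_lp_s`` = 50 ms delay-arm low-pass, 10% tonic (DC)
    luminance admitted into both subunits, unit subunit weights, 60
    detectors at 4 deg receptor spacing (240 deg of visual space), 1 ms
    integration step, and 200 ms display smoothing for time-resolved output.
    """

    tau_hp_s: float = 0.250
    tau_lp_s: float = 0.050
    dc_frac_on: float = 0.10
    dc_frac_off: float = 0.10
    w_on: float = 1.0
    w_off: float = 1.0
    model: Literal["4Q", "2Q"] = "2Q"
    n_detectors: int = 60
    receptor_spacing_deg: float = 4.0
    dt_s: float = 0.001
    display_tau_s: float = 0.200

    def __post_init__(self):
        if self.tau_hp_s <= 0 or self.tau_lp_s <= 0:
            raise ValueError("filter time constants must be positive")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.dt_s >= min(self.tau_hp_s, self.tau_lp_s):
            raise ValueError(
                "dt_s must be smaller than both time constants "
                "(Euler forward is unstable otherwise)"
            )
        if self.model not in ("4Q", "2Q"):
            raise ValueError("model must be '4Q' or '2Q'")
        if self.n_detectors < 1:
            raise ValueError("need at least one detector")


@dataclass
class DetectorOutput:
    """Time-resolved output of a detector array simulation."""

    summed: np.ndarray
    config: DetectorConfig
    stimulus_spec: object = None
    per_detector: np.ndarray | None = None
    dt_s: float = 0.001
    motion_window: tuple[float, float] | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.summed.shape[-1]) * self.dt_s


def lowpass(signal: np.ndarray, tau_s: float, dt_s: float) -> np.ndarray:
    """First-order RC low-pass, Euler forward integration.

    ``y[n+1] = y[n] + (dt/tau) * (x[n] - y[n])`` with ``y[0] = x[0]``;
    applied along the last axis.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if dt_s >= tau_s:
        raise ValueError("dt_s >= tau_s: Euler forward step is unstable")
    x = np.asarray(signal, dtype=float)
    a = dt_s / tau_s
    # y[n] = (1 - a) y[n-1] + a x[n-1]  ==  lfilter([0, a], [1, -(1-a)], x)
    zi = x[..., :1].copy()
    y, _ = lfilter([0.0, a], [1.0, -(1.0 - a)], x, axis=-1, zi=zi)
    return y


def highpass(signal: np.ndarray, tau_s: float, dt_s: float) -> np.ndarray:
    """First-order high-pass: the input minus its own low-pass.

    ``HP(x) + LP(x) == x`` pointwise by construction; a constant input maps
    to zero because the low-pass state starts at the first sample.
    """
    x = np.asarray(signal, dtype=float)
    return x - lowpass(x, tau_s, dt_s)


def half_wave(signal: np.ndarray, polarity: str) -> np.ndarray:
    """Half-wave rectification at zero: ON keeps positive excursions,
    OFF returns positive-valued negative excursions.  ``ON(x) - OFF(x) == x``
    and ``ON(-x) == OFF(x)``; exact zeros stay zero."""
    x = np.asarray(signal, dtype=float)
    if polarity == "ON":
        return np.maximum(x, 0.0)
    if polarity == "OFF":
        return np.maximum(-x, 0.0)
    raise ValueError("polarity must be 'ON' or 'OFF'")


def _check_stimulus(stim: SpaceTimeStimulus, cfg: DetectorConfig) -> np.ndarray:
    needed = cfg.n_detectors + 1
    if stim.n_receptors < needed:
        raise ValueError(
            f"{cfg.model} array of {cfg.n_detectors} detectors needs "
            f"{needed} receptors; stimulus provides {stim.n_receptors}"
        )
    if not np.isclose(stim.receptor_spacing_deg, cfg.receptor_spacing_deg):
        raise ValueError(
            "stimulus receptor spacing "
            f"({stim.receptor_spacing_deg} deg) does not match the detector "
            f"spacing ({cfg.receptor_spacing_deg} deg)"
        )
    if not np.isclose(stim.dt_s, cfg.dt_s):
        raise ValueError("stimulus dt_s does not match detector dt_s")
    return np.asarray(stim.luminance[:needed], dtype=float)


def _correlate_pairs(x: np.ndarray, tau_lp_s: float, dt_s: float) -> np.ndarray:
    """Mirror-symmetric correlator outputs for neighboring receptor rows.

    Detector i computes ``LP(x_i) * x_{i+1} - x_i * LP(x_{i+1})``; positive
    output indicates motion toward increasing receptor index.
    """
    d = lowpass(x, tau_lp_s, dt_s)
    return d[:-1] * x[1:] - x[:-1] * d[1:]


def simulate_4q(
    stim: SpaceTimeStimulus, cfg: DetectorConfig, keep_per_detector: bool = False
) -> DetectorOutput:
    """Simulate the non-rectified four-quadrant correlator array.

    Each arm carries ``HP(s) + dc * s``; with zero DC this is the plain
    Hassenstein-Reichardt detector.  The DC fraction for the (single,
    non-rectified) arm is ``dc_frac_on``; configure ``dc_frac_on = 0`` for
    the canonical DC-free 4Q model.
    """
    if cfg.model != "4Q":
        raise ValueError("config.model must be '4Q'")
    s = _check_stimulus(stim, cfg)
    x = highpass(s, cfg.tau_hp_s, cfg.dt_s)
    if cfg.dc_frac_on != 0.0:
        x = x + cfg.dc_frac_on * s
    per = _correlate_pairs(x, cfg.tau_lp_s, cfg.dt_s)
    return DetectorOutput(
        summed=per.sum(axis=0),
        per_detector=per if keep_per_detector else None,
        config=cfg,
        stimulus_spec=stim.spec,
        dt_s=cfg.dt_s,
        motion_window=stim.motion_window(),
    )


def simulate_2q(
    stim: SpaceTimeStimulus, cfg: DetectorConfig, keep_per_detector: bool = False
) -> DetectorOutput:
    """Simulate the rectified two-quadrant (ON/OFF) correlator array.

    Per receptor, the subunit input is ``HP(s) + dc * s`` with a
    subunit-specific DC fraction, half-wave rectified into a positive ON and
    a positive OFF signal.  Each polarity channel runs its own
    mirror-symmetric correlator; channel outputs are combined after the
    subtraction stage with weights ``w_on`` and ``w_off`` (set one weight to
    zero to isolate a subunit).
    """
    if cfg.model != "2Q":
        raise ValueError("config.model must be '2Q'")
    s = _check_stimulus(stim, cfg)
    hp = highpass(s, cfg.tau_hp_s, cfg.dt_s)
    per_channels = []
    for dc, w, pol in (
        (cfg.dc_frac_on, cfg.w_on, "ON"),
        (cfg.dc_frac_off, cfg.w_off, "OFF"),
    ):
        if w == 0.0:
            continue
        ch = half_wave(hp + dc * s, pol)
        per_channels.append(w * _correlate_pairs(ch, cfg.tau_lp_s, cfg.dt_s))
    if not per_channels:
        raise ValueError("both subunit weights are zero")
    per = sum(per_channels)
    return DetectorOutput(
        summed=per.sum(axis=0),
        per_detector=per if keep_per_detector else None,
        config=cfg,
        stimulus_spec=stim.spec,
        dt_s=cfg.dt_s,
        motion_window=stim.motion_window(),
    )


def simulate(
    stim: SpaceTimeStimulus, cfg: DetectorConfig, keep_per_detector: bool = False
) -> DetectorOutput:
    """Dispatch to :func:`simulate_4q` or :func:`simulate_2q` per config."""
    fn = simulate_4q if cfg.model == "4Q" else simulate_2q
    return fn(stim, cfg, keep_per_detector=keep_per_detector)


def mean_response(
    out: DetectorOutput, window: tuple[float, float] | None = None
) -> float:
    """Time-mean of the summed array output over a window (seconds).

    Defaults to the stimulus motion interval when the simulation recorded
    one, else the full simulation.
    """
    if window is None:
        window = out.motion_window
    if window is None:
        window = (0.0, out.summed.shape[-1] * out.dt_s)
    t0, t1 = window
    i0 = int(round(t0 / out.dt_s))
    i1 = int(round(t1 / out.dt_s))
    i0 = max(i0, 0)
    i1 = min(i1, out.summed.shape[-1])
    if i1 <= i0:
        raise ValueError(f"empty averaging window {window}")
    return float(out.summed[i0:i1].mean())


def smooth_display(out: DetectorOutput) -> np.ndarray:
    """Lightly low-pass filtered summed output for time-resolved display
    and analysis of biphasic dynamics (tau = ``display_tau_s``)."""
    if out.config.display_tau_s <= 0:
        raise ValueError("display_tau_s must be positive")
    return lowpass(out.summed, out.config.display_tau_s, out.dt_s)


def isolate_subunit(cfg: DetectorConfig, subunit: str) -> DetectorConfig:
    """2Q config with the other pathway's weight set to zero."""
    if subunit == "ON":
        return replace(cfg, model="2Q", w_off=0.0)
    if subunit == "OFF":
        return replace(cfg, model="2Q", w_on=0.0)
    raise ValueError("subunit must be 'ON' or 'OFF'")
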