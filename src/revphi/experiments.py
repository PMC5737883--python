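"""Model experiment battery: velocity tuning, parameter scans and
flicker x motion response matrices.

Every experiment runs one simulation per stimulus condition, averages the
summed detector output over the motion interval, and averages the result
over both initial contrast polarities of the grating (bright-first and
dark-first), mirroring trial randomization in behavioral experiments.
Velocities and update frequencies are interchangeable through
``v = f_motion * step``; the default velocity grid is 20 log-spaced points
between 1 and 1000 deg/s and the default frequency grids are
{0, 8, 16, 32, 64} Hz at a 4 deg step.  All experiments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import emd
from .emd import DetectorConfig, isolate_subunit, mean_response, simulate
from .stimuli import SpaceTimeStimulus, StimulusSpec, make_decoupled_stimulus

__all__ = [
    "TuningCurve",
    "ResponseMatrix",
    "DEFAULT_VELOCITIES",
    "DEFAULT_FREQUENCIES",
    "velocity_tuning",
    "peak_velocity",
    "trough_velocity",
    "sign_change_velocities",
    "tau_scan",
    "dc_scan",
    "flicker_motion_matrix",
    "normalize_curve",
    "normalize_jointly",
]

DEFAULT_VELOCITIES = np.logspace(0, 3, 20)
DEFAULT_FREQUENCIES = (0.0, 8.0, 16.0, 32.0, 64.0)


@dataclass
class TuningCurve:
    """Mean model response as a function of pattern velocity."""

    velocities_deg_s: np.ndarray
    responses: np.ndarray
    normalized: bool = False
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.velocities_deg_s = np.asarray(self.velocities_deg_s, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.velocities_deg_s.ndim != 1 or (
            self.velocities_deg_s.shape != self.responses.shape
        ):
            raise ValueError("velocities and responses must be matching 1D arrays")
        if np.any(np.diff(self.velocities_deg_s) <= 0):
            raise ValueError("velocities must be strictly increasing")


@dataclass
class ResponseMatrix:
    """Mean responses over a flicker x motion update-frequency grid.

    ``responses[i, j]`` is the response at ``flicker_hz[i]``,
    ``motion_hz[j]``; the first row (flicker 0) reproduces phi tuning over
    the matching velocities and the diagonal reproduces reverse-phi tuning.
    """

    flicker_hz: np.ndarray
    motion_hz: np.ndarray
    responses: np.ndarray
    step_deg: float
    normalization: float = 1.0
    condition: dict = field(default_factory=dict)

    @property
    def velocities_deg_s(self) -> np.ndarray:
        return np.asarray(self.motion_hz) * self.step_deg


def _condition_response(
    cfg: DetectorConfig,
    wavelength_deg: float,
    motion_hz: float,
    flicker_hz: float,
    step_deg: float,
    phase_offset_frac: float = 0.0,
    duration_s: float = 10.0,
    motion_onset_s: float = 0.5,
    motion_offset_s: float = 9.5,
) -> float:
    """Mean response averaged over both initial polarities of the grating."""
    total = 0.0
    for p0 in (1, -1):
        if flicker_hz > 0:
            mode, init = "reverse-phi", p0
        else:
            mode, init = ("phi-bright" if p0 > 0 else "phi-dark"), 1
        spec = StimulusSpec(
            wavelength_deg=wavelength_deg,
            step_deg=step_deg,
            polarity_mode=mode,
            motion_hz=motion_hz,
            flicker_hz=flicker_hz,
            phase_offset_frac=phase_offset_frac,
            initial_polarity=init,
            duration_s=duration_s,
            motion_onset_s=motion_onset_s,
            motion_offset_s=motion_offset_s,
        )
        stim = make_decoupled_stimulus(
            spec,
            n_receptors=cfg.n_detectors + 1,
            receptor_spacing_deg=cfg.receptor_spacing_deg,
            dt_s=cfg.dt_s,
        )
        total += mean_response(simulate(stim, cfg))
    return total / 2.0


def velocity_tuning(
    cfg: DetectorConfig,
    wavelength_deg: float = 90.0,
    polarity_mode: str = "reverse-phi",
    velocities_deg_s: np.ndarray | None = None,
    step_deg: float | None = None,
    phase_offset_frac: float = 0.0,
    duration_s: float = 10.0,
) -> TuningCurve:
    """Velocity tuning curve of a detector model for phi or reverse-phi
    gratings (step defaults to one receptor spacing).

    ``polarity_mode`` is ``"phi"`` (responses averaged over bright and dark
    stripe polarity) or ``"reverse-phi"`` (averaged over initial polarity).
    """
    if velocities_deg_s is None:
        velocities_deg_s = DEFAULT_VELOCITIES
    velocities_deg_s = np.asarray(velocities_deg_s, dtype=float)
    if step_deg is None:
        step_deg = cfg.receptor_spacing_deg
    reverse = polarity_mode == "reverse-phi"
    if not reverse and polarity_mode not in ("phi", "phi-bright", "phi-dark"):
        raise ValueError(f"unknown polarity_mode {polarity_mode!r}")
    responses = np.empty_like(velocities_deg_s)
    for i, v in enumerate(velocities_deg_s):
        f_motion = v / step_deg
        try:
            responses[i] = _condition_response(
                cfg,
                wavelength_deg,
                motion_hz=f_motion,
                flicker_hz=f_motion if reverse else 0.0,
                step_deg=step_deg,
                phase_offset_frac=phase_offset_frac,
                duration_s=duration_s,
                motion_onset_s=0.5,
                motion_offset_s=duration_s - 0.5,
            )
        except Exception as exc:  # annotate which grid point failed
            raise RuntimeError(f"simulation failed at v={v} deg/s: {exc}") from exc
    return TuningCurve(
        velocities_deg_s=velocities_deg_s,
        responses=responses,
        condition={
            "model": cfg.model,
            "wavelength_deg": wavelength_deg,
            "polarity_mode": polarity_mode,
            "dc_frac_on": cfg.dc_frac_on,
            "dc_frac_off": cfg.dc_frac_off,
            "w_on": cfg.w_on,
            "w_off": cfg.w_off,
            "phase_offset_frac": phase_offset_frac,
        },
    )


def peak_velocity(curve: TuningCurve, kind: str = "abs") -> float:
    """Velocity at the response extremum.

    ``kind='abs'`` locates the maximum of ``|response|``, ``'positive'`` the
    maximum response and ``'negative'`` the minimum.  Ties break toward the
    lower velocity.
    """
    r = curve.responses
    if np.allclose(r, 0.0):
        raise ValueError("curve is identically zero; no peak defined")
    if kind == "abs":
        score = np.abs(r)
    elif kind == "positive":
        score = r
    elif kind == "negative":
        score = -r
    else:
        raise ValueError("kind must be 'abs', 'positive' or 'negative'")
    return float(curve.velocities_deg_s[int(np.argmax(score))])


def trough_velocity(curve: TuningCurve) -> float:
    """Velocity of the most negative response (reverse-phi inversion)."""
    return peak_velocity(curve, kind="negative")


def sign_change_velocities(curve: TuningCurve, atol: float = 0.0) -> np.ndarray:
    """Velocities (geometric midpoint of the bracketing grid points) at which
    the tuning curve changes sign; responses within ``atol`` of zero are
    treated as keeping the previous sign."""
    v, r = curve.velocities_deg_s, curve.responses.copy()
    signs = np.sign(np.where(np.abs(r) <= atol, 0.0, r))
    # carry previous nonzero sign through near-zero samples
    last = 0.0
    seq = []
    for s in signs:
        if s != 0:
            last = s
        seq.append(last)
    seq = np.asarray(seq)
    changes = []
    for i in range(1, len(seq)):
        if seq[i] != 0 and seq[i - 1] != 0 and seq[i] != seq[i - 1]:
            changes.append(np.sqrt(v[i - 1] * v[i]))
    return np.asarray(changes)


def tau_scan(
    cfg: DetectorConfig,
    which_filter: str,
    taus_s,
    wavelength_deg: float = 90.0,
    velocities_deg_s: np.ndarray | None = None,
) -> dict[float, dict[str, TuningCurve]]:
    """Tuning-curve family over a grid of one filter time constant.

    ``which_filter`` is ``'LP'`` or ``'HP'``; the other time constant stays
    at its configured value.  Returns ``{tau: {'phi': curve,
    'reverse-phi': curve}}``.
    """
    if which_filter not in ("LP", "HP"):
        raise ValueError("which_filter must be 'LP' or 'HP'")
    out: dict[float, dict[str, TuningCurve]] = {}
    for tau in taus_s:
        if tau <= cfg.dt_s:
            raise ValueError(f"tau={tau} s must exceed the time step {cfg.dt_s} s")
        scan_cfg = replace(
            cfg, **{"tau_lp_s" if which_filter == "LP" else "tau_hp_s": float(tau)}
        )
        out[float(tau)] = {
            mode: velocity_tuning(
                scan_cfg, wavelength_deg, mode, velocities_deg_s
            )
            for mode in ("phi", "reverse-phi")
        }
    return out


def dc_scan(
    cfg: DetectorConfig,
    subunit: str,
    dc_fracs,
    wavelength_deg: float = 90.0,
    velocities_deg_s: np.ndarray | None = None,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse-phi response of one isolated 2Q subunit over a DC grid.

    Returns ``(dc_fracs, velocities, responses)`` with ``responses[i, j]``
    the mean response at DC fraction i and velocity j; the other subunit's
    weight is zero.  With ``normalize`` the map is scaled to a maximum
    absolute response of one.
    """
    if velocities_deg_s is None:
        velocities_deg_s = DEFAULT_VELOCITIES
    dc_fracs = np.asarray(list(dc_fracs), dtype=float)
    base = isolate_subunit(cfg, subunit)
    dc_field = "dc_frac_on" if subunit == "ON" else "dc_frac_off"
    rows = []
    for dc in dc_fracs:
        curve = velocity_tuning(
            replace(base, **{dc_field: float(dc)}),
            wavelength_deg,
            "reverse-phi",
            velocities_deg_s,
        )
        rows.append(curve.responses)
    responses = np.asarray(rows)
    if normalize:
        responses = responses / np.abs(responses).max()
    return dc_fracs, np.asarray(velocities_deg_s, dtype=float), responses


def flicker_motion_matrix(
    cfg: DetectorConfig,
    flicker_hz=DEFAULT_FREQUENCIES,
    motion_hz=DEFAULT_FREQUENCIES,
    wavelength_deg: float = 90.0,
    step_deg: float = 4.0,
    normalize: bool = False,
) -> ResponseMatrix:
    """Mean responses for all combinations of flicker and motion update
    frequencies (default 5 x 5 grid of {0, 8, 16, 32, 64} Hz, step 4 deg).

    The flicker clock runs during the motion interval even when the motion
    rate is zero (stationary flickering grating)."""
    flicker_hz = np.asarray(list(flicker_hz), dtype=float)
    motion_hz = np.asarray(list(motion_hz), dtype=float)
    responses = np.empty((flicker_hz.size, motion_hz.size))
    for i, ff in enumerate(flicker_hz):
        for j, fm in enumerate(motion_hz):
            responses[i, j] = _condition_response(
                cfg, wavelength_deg, motion_hz=fm, flicker_hz=ff, step_deg=step_deg
            )
    norm = 1.0
    if normalize:
        norm = float(responses.max())
        if norm == 0.0:
            raise ValueError("cannot normalize an all-nonpositive matrix by its max")
        responses = responses / norm
    return ResponseMatrix(
        flicker_hz=flicker_hz,
        motion_hz=motion_hz,
        responses=responses,
        step_deg=step_deg,
        normalization=norm,
        condition={"model": cfg.model, "wavelength_deg": wavelength_deg},
    )


def normalize_curve(curve: TuningCurve) -> TuningCurve:
    """Scale a tuning curve to unit maximum absolute response."""
    m = np.abs(curve.responses).max()
    if m == 0.0:
        raise ValueError("cannot normalize an all-zero curve")
    return TuningCurve(
        velocities_deg_s=curve.velocities_deg_s,
        responses=curve.responses / m,
        normalized=True,
        condition=dict(curve.condition),
    )


def normalize_jointly(curves: list[TuningCurve]) -> list[TuningCurve]:
    """Normalize a panel of curves by their shared maximum absolute value
    (per-panel convention: curves displayed together share one scale)."""
    m = max(np.abs(c.responses).max() for c in curves)
    if m == 0.0:
        raise ValueError("cannot normalize all-zero curves")
    return [
        TuningCurve(
            velocities_deg_s=c.velocities_deg_s,
            responses=c.responses / m,
            normalized=True,
            condition=dict(c.condition),
        )
        for c in curves
    ]
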