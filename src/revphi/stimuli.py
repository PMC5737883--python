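"""One-dimensional space-time luminance stimuli for motion-detector modelling.

Stimuli are square-wave gratings sampled on a row of photoreceptors: half of
each spatial period is "gray" (intermediate luminance), the other half carries
the contrast and is either bright or dark.  During the motion interval the
pattern jumps by a fixed step at the motion update rate; in reverse-phi mode
the non-gray stripes additionally flip between bright and dark at the flicker
rate.  Flicker and motion clocks may also run at independent rates
(decoupled stimuli).  Translating-noise and drifting-sinusoid stimuli are
provided for spectral and analytic checks.

Coordinates: receptor index is 0-based, space is degrees of azimuth, time is
the half-open interval [0, duration).  The pattern phase is tracked as a
continuous offset in degrees, so wavelengths need not be commensurate with
the receptor array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "StimulusSpec",
    "SpaceTimeStimulus",
    "make_grating_stimulus",
    "make_decoupled_stimulus",
    "make_translating_noise",
    "make_drifting_sinusoid",
    "rectify_stimulus",
    "mirror_stimulus",
    "DEFAULT_LUMINANCE",
]

#: dark / intermediate / bright luminance triplet (arbitrary units), symmetric
#: about the gray level so both contrast polarities have the same Michelson
#: contrast against gray.
DEFAULT_LUMINANCE: tuple[float, float, float] = (1.05, 1.3, 1.55)

PolarityMode = Literal["phi-bright", "phi-dark", "reverse-phi"]

# guard against floating-point jitter when update times coincide with samples
_CLOCK_EPS = 1e-9


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a discretized grating stimulus.

    ``motion_hz`` is the displacement-update rate and ``flicker_hz`` the
    contrast-reversal rate; for a stimulus specified by velocity,
    ``motion_hz = velocity_deg_s / step_deg`` exactly.  ``phase_offset_frac``
    shifts the flicker clock relative to the motion clock by that fraction of
    a flicker period (0.5 puts reversals midway between displacements).
    """

    wavelength_deg: float
    step_deg: float = 4.0
    polarity_mode: PolarityMode = "phi-bright"
    velocity_deg_s: float | None = None
    flicker_hz: float = 0.0
    motion_hz: float | None = None
    phase_offset_frac: float = 0.0
    luminance_levels: tuple[float, float, float] = DEFAULT_LUMINANCE
    duration_s: float = 10.0
    motion_onset_s: float = 0.5
    motion_offset_s: float = 9.5
    direction: int = 1
    initial_polarity: int = 1  # +1 bright non-gray stripes, -1 dark

    def __post_init__(self):
        if self.wavelength_deg <= 0:
            raise ValueError("wavelength_deg must be positive")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be positive")
        ld, lm, lb = self.luminance_levels
        if not (ld < lm < lb):
            raise ValueError("luminance levels must satisfy dark < mid < bright")
        if not (0 <= self.motion_onset_s < self.motion_offset_s <= self.duration_s):
            raise ValueError("need motion_onset_s < motion_offset_s <= duration_s")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.initial_polarity not in (1, -1):
            raise ValueError("initial_polarity must be +1 or -1")
        if self.flicker_hz < 0:
            raise ValueError("flicker_hz must be nonnegative")
        if self.motion_hz is None:
            if self.velocity_deg_s is None:
                raise ValueError("give either velocity_deg_s or motion_hz")
            object.__setattr__(
                self, "motion_hz", abs(self.velocity_deg_s) / self.step_deg
            )
        if self.motion_hz < 0:
            raise ValueError("motion_hz must be nonnegative")
        if self.velocity_deg_s is None:
            object.__setattr__(
                self, "velocity_deg_s", self.motion_hz * self.step_deg
            )

    @classmethod
    def from_velocity(
        cls,
        wavelength_deg: float,
        velocity_deg_s: float,
        step_deg: float = 4.0,
        polarity_mode: PolarityMode = "phi-bright",
        **kwargs,
    ) -> "StimulusSpec":
        """Spec for a grating moving at ``velocity_deg_s``; in reverse-phi
        mode the flicker clock is locked to the motion clock."""
        motion_hz = abs(velocity_deg_s) / step_deg
        flicker_hz = motion_hz if polarity_mode == "reverse-phi" else 0.0
        return cls(
            wavelength_deg=wavelength_deg,
            step_deg=step_deg,
            polarity_mode=polarity_mode,
            velocity_deg_s=abs(velocity_deg_s),
            motion_hz=motion_hz,
            flicker_hz=flicker_hz,
            direction=1 if velocity_deg_s >= 0 else -1,
            **kwargs,
        )


@dataclass
class SpaceTimeStimulus:
    """Luminance sampled on a receptor grid x time grid.

    ``luminance`` has shape (n_receptors, n_time); receptor i sits at azimuth
    ``i * receptor_spacing_deg`` and time sample n at ``n * dt_s``.
    """

    luminance: np.ndarray
    receptor_spacing_deg: float
    dt_s: float
    spec: StimulusSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_receptors(self) -> int:
        return self.luminance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.luminance.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_s

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt_s

    def motion_window(self) -> tuple[float, float]:
        """Time interval during which the stimulus is updating."""
        if self.spec is not None:
            return (self.spec.motion_onset_s, self.spec.motion_offset_s)
        return (0.0, self.duration_s)


def _n_samples(duration_s: float, dt_s: float) -> int:
    return int(round(duration_s / dt_s))


def _grating_profile(
    positions_deg: np.ndarray,
    offsets_deg: np.ndarray,
    polarity: np.ndarray,
    spec: StimulusSpec,
) -> np.ndarray:
    """Evaluate the square-wave pattern at given positions/offsets.

    The non-gray half-period starts at phase 0 (stripe boundary at receptor
    0 for zero offset); ``polarity`` (+1/-1 per time sample) selects bright
    or dark for the non-gray stripes.
    """
    ld, lm, lb = spec.luminance_levels
    lam = spec.wavelength_deg
    # phase in [0, 1) of each (receptor, time) sample
    u = np.mod(positions_deg[:, None] - offsets_deg[None, :], lam) / lam
    nongray = u < 0.5
    lum = np.full(u.shape, lm, dtype=float)
    bright = polarity[None, :] > 0
    lum[nongray & bright] = lb
    lum[nongray & ~bright] = ld
    return lum


def _update_counts(times: np.ndarray, spec: StimulusSpec) -> tuple[np.ndarray, np.ndarray]:
    """Number of displacement steps and contrast reversals elapsed per sample.

    Both clocks are gated by the motion interval: they start at
    ``motion_onset_s`` and freeze at ``motion_offset_s``.  Update events are
    centered in their cycles: the k-th displacement occurs at
    onset + (k - 1/2) / motion_hz and the k-th reversal at
    onset + (k - 1/2 + phase_offset_frac) / flicker_hz, so with zero offset
    reversals coincide with displacements whenever the two rates are equal,
    and a half-period offset puts reversals midway between displacements.
    Centering (rather than firing both clocks at multiples of their period
    from onset) keeps harmonically related clocks decoupled: otherwise every
    displacement of an f_flicker = 2 f_motion stimulus would ride on a
    reversal, turning it into a de facto reverse-phi stimulus.
    """
    t = np.clip(times, spec.motion_onset_s, spec.motion_offset_s) - spec.motion_onset_s
    if spec.motion_hz > 0:
        n_steps = np.floor(t * spec.motion_hz + 0.5 + _CLOCK_EPS).astype(np.int64)
    else:
        n_steps = np.zeros(t.shape, dtype=np.int64)
    if spec.flicker_hz > 0:
        n_flips = np.floor(
            t * spec.flicker_hz + 0.5 - spec.phase_offset_frac + _CLOCK_EPS
        ).astype(np.int64)
        n_flips = np.maximum(n_flips, 0)
    else:
        n_flips = np.zeros(t.shape, dtype=np.int64)
    return n_steps, n_flips


def make_decoupled_stimulus(
    spec: StimulusSpec,
    n_receptors: int = 61,
    receptor_spacing_deg: float = 4.0,
    dt_s: float = 0.001,
) -> SpaceTimeStimulus:
    """Grating with independent displacement and contrast-reversal clocks.

    ``flicker_hz = 0`` reduces to phi motion; ``flicker_hz = motion_hz`` with
    zero phase offset reduces to reverse-phi.  Either rate may be zero
    (``motion_hz = 0`` with flicker gives a stationary flickering grating).
    """
    if n_receptors < 2:
        raise ValueError("need at least 2 receptors")
    max_rate = max(spec.motion_hz, spec.flicker_hz)
    if max_rate > 0 and dt_s > 0.5 / max_rate:
        raise ValueError(
            f"dt_s={dt_s} exceeds half the update interval ({0.5 / max_rate:.4g} s); "
            "stimulus would be temporally aliased"
        )
    n_t = _n_samples(spec.duration_s, dt_s)
    times = np.arange(n_t) * dt_s
    n_steps, n_flips = _update_counts(times, spec)

    if spec.polarity_mode == "phi-bright":
        p0 = 1
        n_flips = np.zeros_like(n_flips)
    elif spec.polarity_mode == "phi-dark":
        p0 = -1
        n_flips = np.zeros_like(n_flips)
    else:
        p0 = spec.initial_polarity
    polarity = p0 * np.where(n_flips % 2 == 0, 1, -1)

    offsets = spec.direction * spec.step_deg * n_steps.astype(float)
    positions = np.arange(n_receptors) * receptor_spacing_deg
    lum = _grating_profile(positions, offsets, polarity, spec)
    return SpaceTimeStimulus(
        luminance=lum,
        receptor_spacing_deg=receptor_spacing_deg,
        dt_s=dt_s,
        spec=spec,
    )


def make_grating_stimulus(
    spec: StimulusSpec,
    n_receptors: int = 61,
    receptor_spacing_deg: float = 4.0,
    dt_s: float = 0.001,
) -> SpaceTimeStimulus:
    """Square-wave phi or reverse-phi grating (flicker locked to motion).

    In reverse-phi mode the flicker clock is forced to the motion rate with
    zero phase offset so that contrast reversals co-occur with displacements.
    """
    if spec.polarity_mode == "reverse-phi" and (
        spec.flicker_hz != spec.motion_hz or spec.phase_offset_frac != 0.0
    ):
        spec = replace(spec, flicker_hz=spec.motion_hz, phase_offset_frac=0.0)
    return make_decoupled_stimulus(spec, n_receptors, receptor_spacing_deg, dt_s)


def make_translating_noise(
    velocity_deg_s: float,
    n_receptors: int = 64,
    dt_s: float = 0.001,
    seed: int = 0,
    receptor_spacing_deg: float = 1.0,
    duration_s: float = 1.0,
    upsample: int = 16,
    luminance_range: tuple[float, float] = (1.05, 1.55),
) -> SpaceTimeStimulus:
    """Random 1D luminance profile rigidly translating at constant velocity.

    The master pattern is drawn once per receptor-sized cell (its
    correlation length, so that translation produces a coherent space-time
    structure) and held on a grid of ``upsample`` sub-samples per receptor
    spacing; each time step it is shifted by the nearest sub-sample
    (periodic wrap-around), resolving displacements to
    ``receptor_spacing_deg / upsample`` degrees.
    """
    if n_receptors < 1:
        raise ValueError("need at least one receptor")
    rng = np.random.default_rng(seed)
    n_master = n_receptors * upsample
    lo, hi = luminance_range
    master = np.repeat(rng.uniform(lo, hi, size=n_receptors), upsample)
    n_t = _n_samples(duration_s, dt_s)
    times = np.arange(n_t) * dt_s
    sub_deg = receptor_spacing_deg / upsample
    shifts = np.round(velocity_deg_s * times / sub_deg).astype(np.int64)
    idx = (np.arange(n_receptors)[:, None] * upsample - shifts[None, :]) % n_master
    lum = master[idx]
    return SpaceTimeStimulus(
        luminance=lum,
        receptor_spacing_deg=receptor_spacing_deg,
        dt_s=dt_s,
        spec=None,
        meta={
            "kind": "translating-noise",
            "velocity_deg_s": velocity_deg_s,
            "seed": seed,
            "upsample": upsample,
        },
    )


def make_drifting_sinusoid(
    wavelength_deg: float,
    temporal_frequency_hz: float,
    n_receptors: int = 61,
    receptor_spacing_deg: float = 4.0,
    dt_s: float = 0.001,
    duration_s: float = 10.0,
    mean_luminance: float = 1.3,
    amplitude: float = 0.25,
    direction: int = 1,
) -> SpaceTimeStimulus:
    """Smoothly drifting sinusoidal luminance grating.

    ``L(x, t) = mean + amplitude * cos(2*pi*(x/lambda - direction*f*t))``;
    positive ``direction`` drifts toward increasing receptor index.  Used for
    analytic steady-state checks and as the spectral-convention reference.
    """
    n_t = _n_samples(duration_s, dt_s)
    times = np.arange(n_t) * dt_s
    positions = np.arange(n_receptors) * receptor_spacing_deg
    phase = 2 * np.pi * (
        positions[:, None] / wavelength_deg
        - direction * temporal_frequency_hz * times[None, :]
    )
    lum = mean_luminance + amplitude * np.cos(phase)
    return SpaceTimeStimulus(
        luminance=lum,
        receptor_spacing_deg=receptor_spacing_deg,
        dt_s=dt_s,
        spec=None,
        meta={
            "kind": "drifting-sinusoid",
            "wavelength_deg": wavelength_deg,
            "temporal_frequency_hz": temporal_frequency_hz,
            "direction": direction,
        },
    )


def rectify_stimulus(stim: SpaceTimeStimulus, polarity: str) -> SpaceTimeStimulus:
    """Half-wave rectify a stimulus about its mean luminance.

    ON keeps excursions above the mean (values below it are replaced by the
    mean); OFF keeps excursions below the mean.  Equivalently the demeaned
    pattern is half-wave rectified and the mean restored.  The mean is the
    grand mean over the full space-time grid.
    """
    if polarity not in ("ON", "OFF"):
        raise ValueError("polarity must be 'ON' or 'OFF'")
    m = stim.luminance.mean()
    if polarity == "ON":
        lum = np.maximum(stim.luminance, m)
    else:
        lum = np.minimum(stim.luminance, m)
    out = SpaceTimeStimulus(
        luminance=lum,
        receptor_spacing_deg=stim.receptor_spacing_deg,
        dt_s=stim.dt_s,
        spec=stim.spec,
        meta={**stim.meta, "rectified": polarity},
    )
    return out


def mirror_stimulus(stim: SpaceTimeStimulus) -> SpaceTimeStimulus:
    """Reverse the receptor axis, turning rightward motion into leftward."""
    spec = stim.spec
    if spec is not None:
        spec = replace(spec, direction=-spec.direction)
    meta = dict(stim.meta)
    if "velocity_deg_s" in meta:
        meta["velocity_deg_s"] = -meta["velocity_deg_s"]
    if "direction" in meta:
        meta["direction"] = -meta["direction"]
    return SpaceTimeStimulus(
        luminance=stim.luminance[::-1].copy(),
        receptor_spacing_deg=stim.receptor_spacing_deg,
        dt_s=stim.dt_s,
        spec=spec,
        meta=meta,
    )
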