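"""Construction of phi / reverse-phi / decoupled gratings and noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revphi.stimuli import (
    DEFAULT_LUMINANCE,
    SpaceTimeStimulus,
    StimulusSpec,
    make_decoupled_stimulus,
    make_drifting_sinusoid,
    make_grating_stimulus,
    make_translating_noise,
    mirror_stimulus,
    rectify_stimulus,
)


def test_default_luminance_triplet_symmetric_about_gray():
    ld, lm, lb = DEFAULT_LUMINANCE
    assert lb - lm == pytest.approx(lm - ld)
    # both contrast polarities have the same Michelson contrast against gray
    assert (lb - lm) / (lb + lm) == pytest.approx((lm - ld) / (lm + ld), rel=0.2)


def test_zero_update_rate_is_static():
    spec = StimulusSpec(wavelength_deg=90, motion_hz=0.0, duration_s=2.0,
                        motion_onset_s=0.5, motion_offset_s=1.5)
    stim = make_grating_stimulus(spec, n_receptors=10, dt_s=0.01)
    assert np.all(stim.luminance == stim.luminance[:, :1])


def test_sample_count_and_value_set():
    spec = StimulusSpec.from_velocity(90, 64, 4, "reverse-phi", duration_s=3.0,
                                      motion_onset_s=0.5, motion_offset_s=2.5)
    stim = make_grating_stimulus(spec, n_receptors=31, dt_s=0.001)
    assert stim.n_samples == 3000
    assert set(np.unique(stim.luminance)) <= set(DEFAULT_LUMINANCE)


def test_reverse_phi_updates_displace_and_flip_together():
    # lambda=90, v=60, step=4 -> joint displacement + reversal every 66.7 ms
    spec = StimulusSpec.from_velocity(90, 60, 4, "reverse-phi", duration_s=2.0,
                                      motion_onset_s=0.0, motion_offset_s=2.0)
    stim = make_grating_stimulus(spec, n_receptors=61, dt_s=0.001)
    changed = np.any(np.diff(stim.luminance, axis=1) != 0, axis=0)
    change_times = stim.times[1:][changed]
    intervals = np.diff(change_times)
    assert np.allclose(intervals, 1 / 15.0, atol=2e-3)
    # at every update the brightest stripes swap polarity: both dark and
    # bright values present just before and after with swapped positions
    i = np.flatnonzero(changed)[3]
    before, after = stim.luminance[:, i], stim.luminance[:, i + 1]
    ld, lm, lb = DEFAULT_LUMINANCE
    assert (before == lb).any() != (after == lb).any() or (
        not np.array_equal(before == lb, after == lb)
    )


def test_phi_dark_is_phi_bright_with_swapped_contrast():
    kw = dict(wavelength_deg=90, velocity_deg_s=64, step_deg=4, duration_s=2.0,
              motion_onset_s=0.2, motion_offset_s=1.8)
    bright = make_grating_stimulus(StimulusSpec.from_velocity(polarity_mode="phi-bright", **kw))
    dark = make_grating_stimulus(StimulusSpec.from_velocity(polarity_mode="phi-dark", **kw))
    ld, lm, lb = DEFAULT_LUMINANCE
    swapped = bright.luminance.copy()
    swapped[bright.luminance == lb] = ld
    assert np.array_equal(swapped, dark.luminance)


def test_static_lead_in_and_lead_out_are_frozen():
    spec = StimulusSpec.from_velocity(90, 128, 4, "reverse-phi", duration_s=3.0,
                                      motion_onset_s=1.0, motion_offset_s=2.0)
    stim = make_grating_stimulus(spec, n_receptors=31, dt_s=0.001)
    pre = stim.luminance[:, stim.times < 1.0]
    post = stim.luminance[:, stim.times >= 2.0]
    assert np.all(pre == pre[:, :1])
    assert np.all(post == post[:, :1])


def test_dt_aliasing_rejected():
    spec = StimulusSpec.from_velocity(90, 256, 4, "reverse-phi")
    with pytest.raises(ValueError, match="alias"):
        make_grating_stimulus(spec, dt_s=0.02)  # update at 64 Hz


def test_decoupled_flicker_zero_reduces_to_phi():
    dec = make_decoupled_stimulus(
        StimulusSpec(wavelength_deg=90, flicker_hz=0.0, motion_hz=16.0, duration_s=3.0,
                     motion_onset_s=0.5, motion_offset_s=2.5)
    )
    phi = make_grating_stimulus(
        StimulusSpec.from_velocity(90, 64, 4, "phi-bright", duration_s=3.0,
                                   motion_onset_s=0.5, motion_offset_s=2.5)
    )
    assert np.array_equal(dec.luminance, phi.luminance)


def test_decoupled_equal_rates_reduce_to_reverse_phi():
    dec = make_decoupled_stimulus(
        StimulusSpec(wavelength_deg=90, polarity_mode="reverse-phi",
                     flicker_hz=8.0, motion_hz=8.0, duration_s=3.0,
                     motion_onset_s=0.5, motion_offset_s=2.5)
    )
    rp = make_grating_stimulus(
        StimulusSpec.from_velocity(90, 32, 4, "reverse-phi", duration_s=3.0,
                                   motion_onset_s=0.5, motion_offset_s=2.5)
    )
    assert np.array_equal(dec.luminance, rp.luminance)


def test_out_of_phase_reversals_fall_midway_between_displacements():
    spec = StimulusSpec(wavelength_deg=90, polarity_mode="reverse-phi",
                        flicker_hz=8.0, motion_hz=8.0, phase_offset_frac=0.5,
                        duration_s=3.0, motion_onset_s=0.5, motion_offset_s=2.5)
    stim = make_decoupled_stimulus(spec, n_receptors=61, dt_s=0.001)
    ld, lm, lb = DEFAULT_LUMINANCE
    # polarity trace: does the pattern currently contain bright stripes?
    has_bright = (stim.luminance == lb).any(axis=0)
    flips = stim.times[1:][np.diff(has_bright.astype(int)) != 0]
    # displacement events: luminance changes that do not flip polarity
    changed = np.any(np.diff(stim.luminance, axis=1) != 0, axis=0)
    all_events = stim.times[1:][changed]
    steps = np.array([t for t in all_events if not np.any(np.isclose(flips, t))])
    assert len(flips) > 5 and len(steps) > 5
    # each reversal sits halfway between neighboring displacements
    for f in flips[1:-1]:
        before = steps[steps < f].max()
        after = steps[steps > f].min()
        assert f - before == pytest.approx(after - f, abs=2e-3)


def test_negative_frequencies_rejected():
    with pytest.raises(ValueError):
        StimulusSpec(wavelength_deg=90, flicker_hz=-1.0, motion_hz=8.0)
    with pytest.raises(ValueError):
        StimulusSpec(wavelength_deg=90, motion_hz=-8.0)


def test_translating_noise_static_and_deterministic():
    still = make_translating_noise(0.0, n_receptors=16, dt_s=0.01, seed=3, duration_s=0.5)
    assert np.all(still.luminance == still.luminance[:, :1])
    a = make_translating_noise(60.0, n_receptors=16, dt_s=0.01, seed=7, duration_s=0.5)
    b = make_translating_noise(60.0, n_receptors=16, dt_s=0.01, seed=7, duration_s=0.5)
    assert np.array_equal(a.luminance, b.luminance)
    c = make_translating_noise(60.0, n_receptors=16, dt_s=0.01, seed=8, duration_s=0.5)
    assert not np.array_equal(a.luminance, c.luminance)
    with pytest.raises(ValueError):
        make_translating_noise(60.0, n_receptors=0, dt_s=0.01, seed=0)


def test_rectification_identity_and_constant():
    stim = make_translating_noise(60.0, n_receptors=16, dt_s=0.01, seed=1, duration_s=0.5)
    on = rectify_stimulus(stim, "ON")
    off = rectify_stimulus(stim, "OFF")
    m = stim.luminance.mean()
    assert np.allclose(on.luminance + off.luminance - m, stim.luminance)
    const = SpaceTimeStimulus(np.full((4, 10), 1.3), 4.0, 0.01)
    assert np.array_equal(rectify_stimulus(const, "ON").luminance, const.luminance)


def test_mirror_is_an_involution_and_flips_direction():
    spec = StimulusSpec.from_velocity(90, 64, 4, "reverse-phi", duration_s=2.0,
                                      motion_onset_s=0.2, motion_offset_s=1.8)
    stim = make_grating_stimulus(spec)
    back = mirror_stimulus(mirror_stimulus(stim))
    assert np.array_equal(back.luminance, stim.luminance)
    assert mirror_stimulus(stim).spec.direction == -spec.direction


def test_drifting_sinusoid_phase_velocity():
    stim = make_drifting_sinusoid(90.0, 2.0, n_receptors=31, dt_s=0.001, duration_s=1.0)
    # the pattern at t + 1/(2 Hz * lambda/deg) equals a shift by one wavelength
    shift_samples = 500  # 0.5 s = one temporal period
    assert np.allclose(stim.luminance[:, 0], stim.luminance[:, shift_samples], atol=1e-9)


@settings(deadline=None, max_examples=20)
@given(
    wavelength=st.floats(20.0, 120.0),
    velocity=st.floats(8.0, 256.0),
    initial=st.sampled_from([1, -1]),
)
def test_grating_values_always_in_triplet(wavelength, velocity, initial):
    spec = StimulusSpec.from_velocity(
        wavelength, velocity, 4, "reverse-phi", duration_s=1.0,
        motion_onset_s=0.1, motion_offset_s=0.9, initial_polarity=initial,
    )
    stim = make_grating_stimulus(spec, n_receptors=61, dt_s=0.002)
    assert set(np.unique(stim.luminance)) <= set(DEFAULT_LUMINANCE)
    # gray stripes cover half of each period; with >= 2 periods inside the
    # aperture the sampled gray fraction stays near one half
    frac_gray = (stim.luminance == DEFAULT_LUMINANCE[1]).mean()
    assert 0.25 < frac_gray < 0.75
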