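"""First-order filters and the 4Q/2Q correlator arrays."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from revphi.emd import (
    DetectorConfig,
    half_wave,
    highpass,
    isolate_subunit,
    lowpass,
    mean_response,
    simulate,
    simulate_2q,
    simulate_4q,
    smooth_display,
)
from revphi.stimuli import (
    SpaceTimeStimulus,
    StimulusSpec,
    make_drifting_sinusoid,
    make_grating_stimulus,
    mirror_stimulus,
)

# ---------------------------------------------------------------- filters


def test_lowpass_constant_is_fixed_point():
    x = np.full(200, 3.7)
    assert np.allclose(lowpass(x, 0.05, 0.001), x)


def test_lowpass_step_matches_direct_recursion():
    dt, tau = 0.001, 0.05
    x = np.zeros(100)
    x[1:] = 1.0
    y = lowpass(x, tau, dt)
    # independent oracle: evaluate the recursion sample by sample
    a = dt / tau
    expect = np.empty_like(x)
    expect[0] = x[0]
    for n in range(len(x) - 1):
        expect[n + 1] = expect[n] + a * (x[n] - expect[n])
    assert np.allclose(y, expect, atol=1e-14)
    # the charging value after 50 steps of a unit step
    assert y[51] == pytest.approx(1 - (1 - a) ** 50, rel=1e-12)


def test_lowpass_frozen_for_huge_tau():
    x = np.sin(np.linspace(0, 20, 500)) + 2.0
    y = lowpass(x, 1e4, 0.001)
    assert np.allclose(y, x[0], atol=1e-3)


def test_unstable_step_rejected():
    with pytest.raises(ValueError):
        lowpass(np.ones(10), 0.001, 0.01)


def test_highpass_constant_is_zero_and_reconstruction_exact():
    x = np.full(100, 5.0)
    assert np.allclose(highpass(x, 0.25, 0.001), 0.0)
    rng = np.random.default_rng(0)
    x = rng.normal(size=300)
    assert np.allclose(highpass(x, 0.25, 0.001) + lowpass(x, 0.25, 0.001), x,
                       atol=1e-12)


def test_highpass_attenuates_slow_sinusoid():
    # discrete transfer-function oracle for the complement-form high-pass
    dt, tau, f = 0.001, 0.05, 0.5  # period 2 s >> tau
    t = np.arange(0, 20, dt)
    x = np.sin(2 * np.pi * f * t)
    y = highpass(x, tau, dt)
    a = dt / tau
    z = np.exp(-2j * np.pi * f * dt)
    h = 1 - a * z / (1 - (1 - a) * z)
    steady = y[len(y) // 2:]
    assert steady.max() == pytest.approx(abs(h), rel=0.02)
    assert abs(h) < 0.2  # strong attenuation in the pass-through sense


@settings(deadline=None, max_examples=30)
@given(arrays(float, st.integers(1, 50),
              elements=st.floats(-1e6, 1e6, allow_nan=False)))
def test_half_wave_identities(x):
    on, off = half_wave(x, "ON"), half_wave(x, "OFF")
    assert (on >= 0).all() and (off >= 0).all()
    assert np.array_equal(on - off, x)
    assert np.array_equal(half_wave(-x, "ON"), off)


# ------------------------------------------------------- detector arrays


def _random_stimulus(n_receptors, n_t, seed, cfg):
    rng = np.random.default_rng(seed)
    lum = 1.3 + 0.25 * rng.standard_normal((n_receptors, n_t))
    return SpaceTimeStimulus(lum, cfg.receptor_spacing_deg, cfg.dt_s)


def test_four_quadrant_decomposition_oracle():
    """The non-rectified multiplication equals the signed sum of the four
    rectified quadrant products a+b+ + a-b- - a+b- - a-b+, to machine
    precision: this pins down the 'four-quadrant' semantics."""
    cfg = DetectorConfig(model="4Q", n_detectors=6, dc_frac_on=0.0)
    stim = _random_stimulus(7, 400, 42, cfg)
    ref = simulate_4q(stim, cfg, keep_per_detector=True)

    x = highpass(stim.luminance.astype(float), cfg.tau_hp_s, cfg.dt_s)
    d = lowpass(x, cfg.tau_lp_s, cfg.dt_s)

    def quad_product(p, q):
        pp, pm = half_wave(p, "ON"), half_wave(p, "OFF")
        qp, qm = half_wave(q, "ON"), half_wave(q, "OFF")
        return pp * qp + pm * qm - pp * qm - pm * qp

    per = quad_product(d[:-1], x[1:]) - quad_product(x[:-1], d[1:])
    assert np.array_equal(per, ref.per_detector)
    assert np.allclose(per.sum(axis=0), ref.summed, atol=1e-13)


def test_static_grating_mean_output_is_zero(small_cfg_4q):
    spec = StimulusSpec(wavelength_deg=90, motion_hz=0.0, duration_s=2.0,
                        motion_onset_s=0.5, motion_offset_s=1.5)
    stim = make_grating_stimulus(spec, n_receptors=13, dt_s=0.001)
    out = simulate_4q(stim, small_cfg_4q)
    assert mean_response(out, (0.0, 2.0)) == pytest.approx(0.0, abs=1e-12)


def test_zero_contrast_output_is_constant(small_cfg_2q):
    stim = SpaceTimeStimulus(np.full((13, 2000), 1.3), 4.0, 0.001)
    out = simulate_2q(stim, small_cfg_2q)
    assert np.allclose(out.summed, out.summed[0], atol=1e-12)


def test_summed_equals_per_detector_sum(small_cfg_2q):
    spec = StimulusSpec.from_velocity(90, 64, 4, "reverse-phi", duration_s=2.0,
                                      motion_onset_s=0.5, motion_offset_s=1.5)
    stim = make_grating_stimulus(spec, n_receptors=13, dt_s=0.001)
    out = simulate_2q(stim, small_cfg_2q, keep_per_detector=True)
    assert np.allclose(out.summed, out.per_detector.sum(axis=0), atol=1e-12)


@pytest.mark.parametrize("model", ["2Q", "4Q"])
def test_mirror_antisymmetry(model):
    cfg = DetectorConfig(model=model, n_detectors=20)
    spec = StimulusSpec.from_velocity(90, 64, 4, "phi-bright", duration_s=4.0,
                                      motion_onset_s=0.5, motion_offset_s=3.5)
    stim = make_grating_stimulus(spec, n_receptors=21, dt_s=0.001)
    r = mean_response(simulate(stim, cfg))
    r_m = mean_response(simulate(mirror_stimulus(stim), cfg))
    assert r_m == pytest.approx(-r, rel=0.05)


def test_4q_sinusoid_matches_closed_form_steady_state():
    """Time-averaged 4Q response to a drifting sinusoid against the
    analytically derived correlator steady state (discrete transfer
    functions of the Euler-forward filters)."""
    cfg = DetectorConfig(model="4Q", n_detectors=30, dc_frac_on=0.0)
    amp, lam, tf = 0.25, 90.0, 2.0
    stim = make_drifting_sinusoid(lam, tf, 31, 4.0, 0.001, duration_s=6.0)
    sim = mean_response(simulate(stim, cfg), window=(2.0, 6.0))

    def h_lp(tau):
        a = cfg.dt_s / tau
        z = np.exp(-2j * np.pi * tf * cfg.dt_s)
        return a * z / (1 - (1 - a) * z)

    hhp = 1 - h_lp(cfg.tau_hp_s)
    k = 2 * np.pi / lam
    pred = -cfg.n_detectors * amp**2 * abs(hhp) ** 2 * np.imag(
        h_lp(cfg.tau_lp_s)
    ) * np.sin(k * cfg.receptor_spacing_deg)
    assert sim == pytest.approx(pred, rel=0.05)
    assert pred > 0  # rightward drift, positive response


def test_2q_without_dc_tracks_4q_for_phi():
    velocities = np.logspace(0.5, 2.8, 10)
    c2 = DetectorConfig(model="2Q", n_detectors=20, dc_frac_on=0.0, dc_frac_off=0.0)
    c4 = DetectorConfig(model="4Q", n_detectors=20, dc_frac_on=0.0)
    from revphi.experiments import velocity_tuning

    t2 = velocity_tuning(c2, 90.0, "phi", velocities, duration_s=4.0)
    t4 = velocity_tuning(c4, 90.0, "phi", velocities, duration_s=4.0)
    assert np.all(np.sign(t2.responses) == np.sign(t4.responses))
    rho = spearmanr(t2.responses, t4.responses).statistic
    assert rho > 0.9


def test_mean_response_window_semantics(small_cfg_2q):
    out = simulate_2q(
        SpaceTimeStimulus(np.full((13, 1000), 1.3), 4.0, 0.001), small_cfg_2q
    )
    out.summed = np.linspace(0, 1, 1000)
    full = mean_response(out, (0.0, 1.0))
    a = mean_response(out, (0.0, 0.5))
    b = mean_response(out, (0.5, 1.0))
    assert 0.5 * (a + b) == pytest.approx(full, rel=1e-9)
    with pytest.raises(ValueError):
        mean_response(out, (0.7, 0.7))


def test_smooth_display_constant_unchanged(small_cfg_2q):
    out = simulate_2q(
        SpaceTimeStimulus(np.full((13, 500), 1.3), 4.0, 0.001), small_cfg_2q
    )
    out.summed = np.full(500, 2.5)
    assert np.allclose(smooth_display(out), 2.5)


def test_config_validation_and_stimulus_checks():
    with pytest.raises(ValueError):
        DetectorConfig(tau_lp_s=-0.1)
    with pytest.raises(ValueError):
        DetectorConfig(dt_s=0.1)  # larger than tau_lp
    cfg = DetectorConfig(model="2Q", n_detectors=12)
    short = SpaceTimeStimulus(np.ones((5, 100)), 4.0, 0.001)
    with pytest.raises(ValueError, match="receptors"):
        simulate_2q(short, cfg)
    wrong_spacing = SpaceTimeStimulus(np.ones((13, 100)), 2.0, 0.001)
    with pytest.raises(ValueError, match="spacing"):
        simulate_2q(wrong_spacing, cfg)
    with pytest.raises(ValueError):
        simulate_4q(SpaceTimeStimulus(np.ones((13, 100)), 4.0, 0.001), cfg)


def test_isolate_subunit():
    cfg = DetectorConfig(model="2Q")
    assert isolate_subunit(cfg, "ON").w_off == 0.0
    assert isolate_subunit(cfg, "OFF").w_on == 0.0
    with pytest.raises(ValueError):
        isolate_subunit(cfg, "BOTH")
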