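# Methods

This note records the modelling conventions, parameter choices and
numerical decisions behind `revphi`, and what the synthetic-data tests do
and do not establish about real data.

## Stimulus construction

Stimuli are luminance arrays sampled on a row of photoreceptors
(receptor index 0-based, positions `i * receptor_spacing_deg` degrees of
azimuth) over a half-open time interval `[0, duration)` at step `dt_s`.

Gratings are square waves of wavelength λ: half of each period is gray
(intermediate luminance `L_mid`), the other half carries contrast and is
bright or dark according to the current polarity state. The default
luminance triplet is 1.05 / 1.3 / 1.55 (dark / gray / bright), symmetric
about the gray level so both polarities present the same Michelson
contrast against gray. The pattern phase is tracked as a continuous offset
in degrees and discretized per receptor, so λ need not be commensurate
with the array.

Two clocks drive the stimulus during the motion interval
`[motion_onset, motion_offset)`:

- the **motion clock** displaces the pattern by `step_deg` at
  `motion_hz` (with `v = motion_hz * step_deg` as the single source of
  velocity/frequency conversion);
- the **flicker clock** swaps the non-gray stripes between bright and dark
  at `flicker_hz`.

Both clocks are *gated* by the motion interval (the lead-in and lead-out
display the pattern frozen; no reversals occur while motion is off) and
both are *centered in their cycles*: the k-th event of a clock at rate f
occurs at `onset + (k − 1/2) / f`. Centering preserves the defining cases —
equal rates with zero phase offset make every reversal coincide with a
displacement (reverse-phi), and a half-period flicker offset puts
reversals exactly midway between displacements (the out-of-phase
control) — while keeping harmonically related clocks decoupled. Had both
clocks fired at integer multiples of their period from onset, every
displacement of a stimulus with flicker at twice the motion rate would
ride on a contrast reversal, silently turning an intended
flicker-augmented phi stimulus into a reverse-phi one; with centered
events this coupling arises only on the frequency diagonal, where it
belongs. Event times are compared with a 1 ns guard so updates falling
exactly on a sample boundary are applied at that sample.

`phi-bright` and `phi-dark` fix the polarity state; reverse-phi and
decoupled stimuli start from a configurable `initial_polarity`. All
experiment drivers average responses over both initial polarities,
mirroring the trial-randomized polarity of behavioral experiments and
removing polarity-dependent transients.

Translating noise draws one random luminance value per receptor-sized cell
(the pattern's correlation length; finer-grained noise has no coherent
space-time structure at the receptor scale), holds it on a 16x upsampled
grid, and shifts it by the nearest sub-sample each time step with periodic
wrap-around, resolving `spacing / 16` displacements.

Half-wave rectification of a *stimulus* (for the motion-energy analysis)
replaces values below (ON) or above (OFF) the grand space-time mean with
that mean — equivalently, the demeaned pattern is half-wave rectified and
the mean restored.

## Motion-energy analysis

The magnitude spectrum is the centered 2D FFT of the demeaned stimulus, no
taper (stimulus durations are long relative to the pattern periods).
Quadrant energy is the **squared** magnitude averaged per quadrant pair —
energy, not magnitude, being the standard motion-energy quantity. The
`k = 0` row (full-field flicker) and `ω = 0` column (static pattern) are
excluded because they signal no direction; for even grid sizes the
Nyquist rows are excluded as well, since +f and −f alias onto the same bin
and their sign is undefined (this also makes the mirror-swap identity
exact). Which diagonal quadrant pair signals rightward motion depends only
on the FFT sign convention; it is fixed once by probing with a rightward
reference sinusoid (`calibrate_convention`), and `quadrant_energy` refuses
to run without a calibrated convention.

## Detector models

Filters are first-order RC stages integrated by Euler forward,
`y[n+1] = y[n] + (dt/τ)(x[n] − y[n])`, with the initial state set to the
first input sample so a static lead-in produces no onset transient. The
high-pass is realized as the input minus its own low-pass (complement
form), which guarantees `HP + LP = input` exactly. Steps with `dt ≥ τ`
are rejected as unstable.

Defaults (shared by both architectures): τ_HP = 250 ms, τ_LP = 50 ms,
DC = 10% in both subunits, unit subunit weights, 60 detectors at
Δφ = 4° (240° of visual space), dt = 1 ms, 200 ms display smoothing.
Presentations run 10 s with motion from 0.5 to 9.5 s; responses are the
time-mean of the spatially summed output over the motion interval.
Stimulus steps equal one receptor distance; velocity grids are 20
log-spaced points from 1 to 1000 °/s (40 points where peak-position
ratios are measured).

The receptor row has `n_detectors + 1` receptors with no periodic
wrap-around (λ = 90° is incommensurate with 240°, so wrap-around would
be ill-defined); detector *i* reads receptors *(i, i+1)* and positive
output signals motion toward increasing receptor index. The 4Q detector
admits an optional DC fraction on its (single, non-rectified) arm — used
by the 4Q + DC control — taken from `dc_frac_on`. In the 2Q detector the
DC fraction is added *before* rectification, subunit-specifically;
subunit isolation sets the other pathway's output weight to zero.
Half-wave rectification keeps exact zeros (no epsilon, no rectification
offset, no preferred–null imbalance).

## Sign classification of tuning curves

Time-averaged responses carry opposite-sign residue of a few percent of
the curve peak, originating in onset transients and step discretization
(the DC-free 2Q reverse-phi curve, for instance, dips to about −3% of its
peak at mid velocities; the OFF-subunit curve, which resembles it, shows
the same dip). Normalized tuning figures would not resolve these lobes.
All sign-structure assertions therefore classify a response as positive or
negative only beyond a floor of 5% of the curve's maximum absolute
response — the same relative tolerance used for the mirror-antisymmetry
check, where boundary effects set the scale. Zero-crossing velocities are
reported as the geometric midpoint of the bracketing grid points.

## Empirical pipeline conventions

- Mirror subtraction: per condition, half the difference between the
  trial-averaged rightward and leftward responses; any additive
  direction-independent trace cancels exactly.
- Turning summaries: mean over 1.5–3.0 s after trial onset (trials are
  3.5 s at 20 Hz, motion 1.0–2.0 s).
- Fly selection: earliest contiguous 40-of-70-trial window with mean
  walking speed strictly above 4 mm/s and absolute mean turning below a
  bias tolerance; the tolerance defaults to 10% of the cohort's response
  scale (the largest absolute condition summary across flies), since
  "stable and close to zero" is not otherwise quantified. Flies without a
  qualifying window are excluded.
- Voltage: baseline is the mean over the 0.5 s preceding stimulus onset
  (configurable); the summary is mean depolarization over the first 2 s of
  stimulation; cells below 6 mV for the preferred-direction phi condition
  are flagged for exclusion.
- Calcium: dF/F against a sliding-minimum baseline over a *centered* 15 s
  window, truncated at the record edges (centering avoids a systematic
  lag; the alignment is not otherwise specified). Imaging summaries are
  PD − ND differences of window means 1–4 s after stimulation onset.
- Bootstrap: percentile interval of the mean from 1,000 resamplings,
  seeded. Note that percentile bootstrap intervals under-cover at small
  sample sizes: with ~10 units per group a nominal 95% interval covers
  about 90% in Gaussian Monte-Carlo, and the synthetic-cohort
  plant-and-recover rate sits at that level by construction, not because
  the estimator is biased (its mean error is ~0.01 °/s).
- Down-sampling is non-overlapping block averaging; the target rate must
  divide the source rate, and a trailing partial block is dropped.

## Synthetic data

The generators emulate the *structure* of the recordings — trial counts
and durations, sampling rates (20 Hz turning, 2 kHz voltage, 7.51 Hz
calcium), mirrored condition pairs, per-fly constant turning bias,
per-fly walking speed, positive fluorescence with slow exponential
bleaching — with planted response amplitudes and first-order rise/decay
response kernels (rise τ = 250 ms for behavior, so the 1.5–3.0 s window
captures a sustained component). Kernels are rescaled so the pipeline's
own summary window integrates to exactly the planted amplitude, making
noiseless recovery exact and noisy recovery unbiased.

The default planted turning profile is bilobed like the 2Q reverse-phi
tuning (−8, −12, −6, +4, +7 °/s over 16–256 °/s), with 20 °/s white
turning noise per 50 ms sample, 0.5 °/s per-fly bias spread and
8 ± 1.5 mm/s walking speeds; the defaults retain ~90–95% of flies under
the selection rule, in line with the reported ~10% discard rate. Noise is
additive white Gaussian on turning and voltage and
multiplicative-plus-additive on calcium — the simplest defensible
choices. The generators do **not** model saccadic structure, temporally
correlated noise, indicator kinetics, adaptation, or sensorimotor
nonlinearities, so passing plant-and-recover tests demonstrates the
correctness of the pipeline's arithmetic and selection logic on data of
realistic shape, not robustness to every pathology of real recordings.

## Problem sizes

The test suite runs the full default configuration (60 detectors, 10 s,
dt = 1 ms) for all acceptance-level checks; unit tests use shorter arrays
(12–20 detectors, 2–4 s) where only correctness of the operation is at
stake. Analytic-limit checks use ten temporal frequencies whose periods
divide the 10 s averaging window exactly. Plant-and-recover uses 100
cohorts of 10 flies x 70 trials; bootstrap coverage uses 1,000 Gaussian
experiments of n = 50.

## Known limitations

- The 4Q-with-DC variant applies one DC fraction to both arms; pathway-
  asymmetric DC in a non-rectified detector has no biological reading.
- Detector arrays have open boundaries; edge detectors see the pattern
  enter and leave, which is the main source of the mirror-antisymmetry
  tolerance.
- The decoupled-stimulus clock-phase convention (centered events) is one
  of several defensible choices; off-diagonal matrix cells at harmonic
  rate ratios are sensitive to it, the first row and the diagonal are not.
- Hybrid nonlinearities (preferred-direction enhancement plus
  null-direction suppression), conductance-based units, adaptation and 2D
  retinal geometry are out of scope.
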