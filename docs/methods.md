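# Methods

This note documents the models, estimators and numerical choices behind
`ergflick`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Response model

The electroretinogram (ERG) to a periodic flicker is treated as a
steady-state evoked response: all information used downstream is the
amplitude of the recording's Fourier component at the stimulation
frequency.  The underlying intensity–response law is the classic V–log I
line,

    V(I, f) = clip(m · (log10 I − log10 i0), 0, v_max) · |H(f)|,

with slope `m` (µV per log10 unit of irradiance), zero-response intensity
`i0` (µW cm⁻²) and a hard saturation `v_max` (40 µV by default).  A
clamped line was chosen over a Naka–Rushton saturation because it keeps
criterion-intensity interpolation linear and matches the
proportional-to-log-intensity behaviour the analysis assumes; the clamp
only matters at the top of an intensity series, where the fit's saturation
guard discards points anyway.

Temporal summation enters through a low-pass filter |H(f)| whose −3 dB
corner `fc` is the temporal-resolution knob: dark adaptation lowers `fc`,
lengthening integration times and dragging the flicker fusion frequency
(FFF) down.  **The filter is a two-pole cascade**,
|H(f)| = (1 + (f/f₁)²)⁻¹ with f₁ chosen so |H(fc)| = 1/√2.  A single pole
was considered and rejected on arithmetic grounds: with the fusion
experiment's per-individual normalisation (stimulus intensity set to evoke
3.2 µV at 10 Hz) and a 0.6 µV fusion criterion, a first-order skirt can
never place the criterion crossing below ≈53 Hz, so dark-adapted fusion
frequencies near 35–40 Hz would be unreachable.  Photoreceptor impulse
responses are multi-stage low-pass systems; two poles is the minimal model
steep enough to express both light- and dark-adapted fusion behaviour.

Default per-condition parameters are calibrated so that the *pipeline*
(not a formula shortcut) recovers the intended study conditions: 1 µV
criterion intensities in ratio ≈5.8 between light-adapted day and night
and ≈4.5×10⁴ between light-adapted day and dark-adapted night (with the
dark-adapted day/night gap at three log units), and fusion frequencies
near 73.6 / 58.8 / 34.5 / 39.8 Hz for LA-day / LA-night / DA-day /
DA-night at the 0.6 µV criterion.  The corresponding corners are
24.9 / 18.5 / 8.3 / 10.6 Hz and slopes 6 / 6 / 9 / 27 µV per log10 unit
(the steep dark-adapted-night slope follows from requiring ≈15.6 µV to a
3.84×10⁻⁴ µW cm⁻² test light at full dark adaptation).

## Recording synthesis

A recording is 21 s at 5 kHz.  The square-wave drive (ON-first at t = 0,
duty 0.5) is filtered by the two-pole cascade and rescaled so its
fundamental equals V(I, f); to this are added Gaussian baseline noise
(SD 2 µV), a heartbeat sinusoid (1 µV at 1.5 Hz — the artifact is named in
ERG practice but its rate is a free choice), a mains sinusoid (0.5 µV at
50 Hz), and Poisson movement spikes (0.05 s⁻¹, 20 ms half-cosine bumps at
8× the noise SD — sized to be removable by the 5-SD rule yet disruptive if
not removed).  Everything then passes through the acquisition chain: a
first-order high-pass at 1 Hz cascaded with a first-order low-pass at
100 Hz, emulating an AC differential amplifier's band-pass.  The measured
fundamental is therefore V(I, f)·g(f) with g the analytic band-pass gain
(g(10 Hz) ≈ 0.990; a 100 Hz tone loses ≈29.3% to the low-pass alone), and
the ground-truth tables the simulator emits define criterion intensities
on this *measured* scale, which is what the estimators see.

All randomness flows from one `numpy` Generator passed explicitly; the
same seed reproduces a dataset bit-for-bit.

## Dark-adaptation state dynamics

Adaptation state is a scalar s ∈ [0, 1]: 0 is the fully light-adapted eye,
1 the fully dark-adapted (night-type) eye.  Effective parameters
interpolate between the light-adapted set of the current time of day and
the fully dark-adapted set — linearly in slope, corner and saturation,
log-linearly in i0 (sensitivity shifts are multiplicative).  Using a
*single* dark endpoint with time-of-day ceilings, rather than separate
day/night dark endpoints, is deliberate: daytime dark adaptation is a
partial, circadian-gated approach to the same anatomical end state, and a
static daytime "dark-adapted" parameter set (three log units less
sensitive) cannot produce any response to the dim exp-3 test light even
after an hour of darkness, contradicting the behaviour the experiment is
built around.  The static DA-day set remains in force for the
steady-state experiments (1 and 2), where it describes eyes with a
different adaptation history.

Unperturbed, s relaxes as a fast-plus-slow double exponential toward the
ceiling: night τ_fast = 2 min, τ_slow = 15 min, weight 0.85, ceiling 1.0;
day τ = 6/25 min, weight 0.7, ceiling 0.892 (set so an uninterrupted
daytime hour ends near 3.8 µV).  Each probe whose noise-free response
exceeds 0.5 µV light-adapts the eye: s loses `gain · response`
(gain 0.009 per µV), and the loss decays with an 8 min recovery constant.
This feedback reproduces the three-period night time course — fast rise,
a dip inside the 12–24 min window while accumulated probe losses outrun
the slowing baseline, then a renewed climb — and leaves endpoint-only
control runs strictly darker-adapted at 60 min than probed runs.  The
dip's depth and the detectability trigger are calibrated qualitatively
(no quantitative anchor exists for them); per-crab random effects make
individual dips range from pronounced to marginal, so cohort-level
assertions are made on the mean time course.

## Preprocessing

Order: 11 ms running median, then 5-SD amplitude rejection — the median
window (55 samples, forced odd, mirror-reflected edges) passes monotone
segments exactly, so the piecewise-monotone flicker response loses little
while impulsive artifacts vanish; the rejection rule masks samples at
least k·SD from the trace mean (mean/SD computed once on the full
filtered trace; an iterative re-estimation variant exists but is off by
default).  Masked samples are bridged by linear interpolation because the
transform needs contiguous samples; the mask is preserved so rejected
samples never enter time-domain statistics.  Recordings with >20% masked
log a warning; >50% raises and aborts the pipeline run with the recording
id.  Note the 11 ms window materially attenuates components above
~60 Hz; fusion-frequency analyses on noiseless fixtures therefore measure
raw traces, and noisy full-pipeline fusion estimates are systematically
low but order-preserving across conditions.

## Spectral measurement and the noise-floor test

Records are transformed whole with no window: on 21 s records every
integer stimulus frequency is exactly bin-aligned (resolution 1/21 Hz),
and a taper would leak amplitude and break the square-wave 2A/π check.
The single-sided amplitude spectrum is normalised so a sinusoid of
amplitude A yields A at its bin.  The response measure collects K = 20
noise bins per side, walking outward from the signal bin and skipping
±2 bins around the signal, each of its harmonics, and 50 Hz (mains is
always excluded); keeping the count at 2K fixes the test's degrees of
freedom.  Significance is the steady-state evoked-potential F statistic:
signal-bin power over mean noise-bin power referred to F(2, 4K) — exact
for white Gaussian noise because distinct rectangular-window DFT bins are
independent complex Gaussians.  The suite verifies the 5% nominal level
empirically on ≥2000 noise-only records.  A nonparametric alternative
(`method="rank"`: rank of the signal power among the noise-bin powers)
exists for sensitivity analysis; its level floor is 1/(2K+1).  A
segment-averaged (Welch-style) amplitude option was considered and left
out: the full-record transform is the interpretation adopted for "mean
response amplitude over the recording".

## Sensitivity metrics

**V–log I fit.** Ordinary least squares of amplitude on log10 intensity
over selected points.  Selection: significant, amplitude ≥ 3× the mean
noise-bin amplitude, amplitude ≤ 0.9× the series maximum (saturation
guard), and membership in the contiguous selectable run walking down from
the brightest unsaturated point.  The last two refinements exist because
a 5%-level test run over 15 presentations *will* occasionally flag a
noise-floor point significant, and an isolated far-left false positive
has enough leverage to corrupt a steep line badly; requiring clear
noise-floor clearance and run-contiguity reflects the physical structure
of an intensity series (the response sinks monotonically into the noise)
and restores per-individual threshold recovery to ~0.01 log10 units.
All three knobs are configurable.

**Criterion intensity.** The fitted line inverted at the criterion
(1 µV for treatment comparisons, 3.2 µV for the fusion-experiment
normalisation): I = 10^((criterion − intercept)/slope).  Estimates outside
the fitted range are returned but flagged extrapolated.

**FFF.** Amplitude falls with flicker frequency, so the fusion point is
taken as the *final downward crossing* of the criterion: linear
interpolation between the highest tested frequency still producing a
significant response at or above 0.6 µV and the next tested frequency.
(A literal "lowest frequency above the criterion" reading is
self-contradictory for a decreasing curve.)  Excluded frequencies
(default 50 Hz) never participate; all-above and all-below cases are
flagged rather than extrapolated.

**Dark-adaptation features.** From probe amplitudes over 60 min:
initial slope (OLS over 0–12 min), mean amplitude over (12, 24] min,
final amplitude, and the dip (deepest shortfall below the running maximum
within (12, 28], with its time).

## Group statistics

The repeated-measures structure (every crab in every treatment) is
handled by a random-intercept linear model estimated by REML through a
one-dimensional profile over the variance ratio λ = τ²/σ², with
generalised least squares at each candidate — closed-form per-subject
block algebra keeps it stable even on the 3-subject designs used for
exhaustive permutation checks (it is cross-checked against statsmodels
MixedLM on well-conditioned fixtures).  Fixed-effect terms are tested by
permutation: the statistic is the residual-sum-of-squares reduction
between null and full models on the GLS-whitened scale, variance
components plugged in from the observed full-model fit and held fixed
across permutations; labels shuffle within subject (the exchangeable unit
under a random intercept), and p = (r+1)/(N+1) with a default of 10,000
permutations.  Whitening subtracts a fixed multiple of each subject
block's column sum, which within-subject permutation leaves invariant, so
designs are whitened once and only the tested term's columns are
re-shuffled.  An exhaustive mode enumerates every within-subject
relabelling on tiny designs.

Pairwise treatment contrasts are within-subject sign-flip permutation
tests on per-subject mean differences (exhaustive up to 16 subjects),
Holm-adjusted across the six pairs — a permutation-native, conservative
replacement for parametric multivariate-t (Tukey-style) contrasts, which
would demand distributional machinery the permutation framework makes
unnecessary.  With eight subjects the sign-flip floor is 2/256, so
Holm-adjusted significance at 0.05 is attainable.  Welch's t-test (with
Welch–Satterthwaite degrees of freedom; the degenerate all-constant case
returns p = 1 by convention) covers the unpaired comparisons of the
dark-adaptation experiment.

The real study's likelihood-ratio χ² statistics depend on the original
raw data and a specific ML implementation; they are context, not targets.

## What the synthetic tests show — and what they don't

The generator reproduces the *statistical structure* the pipeline
assumes: log-linear intensity coding, low-pass temporal filtering,
band-limited acquisition, stationary Gaussian noise with named artifact
types, and a smooth scalar adaptation state.  Real ERGs violate most of
these in the small: response waveforms carry harmonics with
intensity-dependent shape, noise is non-stationary, heartbeat and
movement artifacts are irregular, adaptation interacts with stimulus
history in ways a scalar state cannot capture, and electrode drift exists.
Passing recovery tests therefore demonstrates that the estimators are
correct and well-calibrated *under the stated model*, not that they are
robust to every pathology of live recordings.  The published biological
means from the eight real animals serve here as calibration anchors and
ordering constraints only; they are not reproducible quantities.

## Numerical choices and problem sizes

Bin-grid alignment for spectral measurement is enforced at 1% of a bin
width (integer frequencies on 21 s records are exact).  The FFF
interpolation returns the node frequency on exact ties.  Degenerate
inputs raise typed errors (`ProtocolError`, `FitError`, `DesignError`,
...) rather than returning sentinels.  Dataset containers are HDF5 with
per-recording SHA-256 checksums verified on read and a format-version
gate; the index table rides along as CSV inside the file and as a sidecar.
Test problem sizes are chosen to exercise the statistics at study scale
while staying quick: 8 crabs × 4 conditions × 15 intensities for
threshold recovery, 2000 noise-only records for significance-test
calibration, 200 replicate datasets × 99 permutations for permutation
calibration, exhaustive enumeration on 3-subject designs.
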