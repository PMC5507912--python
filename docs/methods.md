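# Methods

This note documents the models, estimators, and design choices behind
`bistable_alpha`: what the synthetic data emulate, how every spectral and
statistical quantity is defined, and where genuinely open choices were
resolved.

## The analysis in one paragraph

During continuous viewing of an ambiguous figure (a Necker cube), the two
perceptual interpretations alternate spontaneously; each button press marks
the onset of a new percept, and the percept's duration is the interval to
the next press. The analysis asks whether posterior alpha-band power
(7–11 Hz, peak 9 Hz) during a percept predicts how long that percept
survives, whether the prediction is already present in the first second
after percept onset, where in the brain the coupling is expressed, and
whether an experimental increase in alpha power (total sleep deprivation)
lengthens percepts *through* its effect on alpha. Log alpha power and log
duration enter linear mixed-effects models (LMEMs) with nested random
intercepts for subject, day, and session; the sleep-deprivation mediation
is a Sobel test assembled from LMEM path coefficients.

## Synthetic data generator

There is no public recording to analyse, so the package ships a generator
(`synthdata`) that realizes the statistical structure the analysis
assumes. It is first-class, tested code: every downstream stage is
validated against data whose ground truth is known exactly.

**Percept durations.** Baseline durations are gamma distributed. The
default shape is 2.5 — a typical positive-skew value for bistable percept
durations — and the scale is calibrated numerically (incomplete-gamma
identities, Brent root) so the mean of the distribution truncated to the
1.5–60 s inclusion window is 8.87 s. With this pair only ~3% of draws fall
outside the window, so the analysis-side exclusion rule barely distorts
the generative coupling. Calibrating shape *and* scale to hit the reported
median (5.94 s) as well would force a shape near 0.5, placing over a third
of the mass below 1.5 s; the resulting response truncation attenuates every
duration regression substantially, so the median is deliberately left
free (the generated truncated median is ≈7.7 s).

**Alpha–duration coupling (causal direction alpha → duration).** Each
percept carries a latent log alpha power
`x ~ Normal(μ_α + a·SD, σ_α²)` with `μ_α = 3.0` log(µV²) (≈20 µV², a
plausible eyes-open posterior alpha level), `σ_α = 0.8`, and `a = 0.202`,
the sleep-deprivation shift. Durations are

    d = G · exp( b·(x − μ_α) + c·SD + u_subject + u_day + u_session − ½σ²_noise ),

with `G ~ Gamma(shape, scale)`, coupling `b = 0.111` log(s)/log(µV²) (the
condition-adjusted path, so the mediated effect has the exact
product-of-paths ground truth `a·b = 0.0224`), direct condition effect
`c = 0.222` log(s), and independent Gaussian random intercepts. The
`−½σ²_noise` term centres the noise part of the multiplier on the natural
scale, so the calibrated truncated mean survives coupling and random
effects in expectation.

**Random-effect scales.** The study does not report variance components,
so these are free parameters (flagged in the config): subject 0.3, day
0.1, session 0.1 log(s). 0.3 log(s) spans roughly a factor 0.55–1.8
between a slow and a fast subject at ±2 SD, in line with the
between-observer spread usual for bistable alternation rates. Two
consequences worth knowing: with 8 subjects the pooled duration mean
wanders ±1–2 s around its expectation from seed to seed, and because a
fixed-length session yields fewer percepts for slow subjects, pooled
per-percept means slightly under-weight them (an inverse-weighting effect
real fixed-length experiments share).

**Sessions.** Percepts tile each 240 s session (five per day, two days,
eight subjects by default); the percept whose onset falls before the
session end completes, so observed durations carry no length bias from
the boundary. Condition order is counterbalanced across subjects. Labels
alternate, with i.i.d. return transitions at probability 0.09.

**EEG synthesis.** Each percept contributes a narrowband alpha carrier
(Gaussian spectral envelope, SD 0.5 Hz around 9 Hz; a pure random-phase
tone when the width is 0), normalized to unit variance per percept and
scaled so the oscillation's variance — hence its 7–11 Hz band power — is
exactly `exp(x)`. The source projects to the scalp with a cosine-falloff
topography from an occipital pole (gain normalized to mean 1 over the
posterior channel set; schematic, not physiological). Within ±0.5 s of
every press the alpha *power* is reduced by `dip_depth` (default 0.5,
i.e. amplitude × √(1−dip)), reproducing the transient reversal-locked
alpha dip. Channels carry independent 1/f noise scaled so the alpha-band
signal-to-noise ratio is `snr` (default 5). What the generator does *not*
emulate: eye blinks, EMG, saccades, line noise, non-stationary alpha peak
frequency, volume-conducted correlated noise. Tests passing on this data
therefore validate the estimators and their contracts, not robustness to
real-world artifacts.

**Toy leadfields.** Source analyses need a forward model; BEM head
modelling is out of scope. `gen_toy_leadfield` provides a cubic grid
(10 mm default spacing) with either quasi-dipolar gains (current dipole
in an infinite homogeneous conductor, random tangential orientation) or
unit-norm random gain rows. The random mode has no depth bias, which is
why the localization oracle uses it. User-supplied leadfields (TSV matrix
+ JSON header) are accepted in the same container.

## Percept epoching

A percept is the interval between two subsequent presses; the last press
of a session opens no percept. Durations exactly 1.5 or 60 s are kept
("less than"/"more than" read literally); a 1 ns slack absorbs float
accumulation in onset arithmetic. A reversal whose label repeats the
previous percept is a *return*; session-initial percepts have no defined
transition, and return rates are reported both with and without them in
the denominator. Stable-interval windows are 1 s, 50% overlap, half-open
`[start, start+width)`, starting 1 s after the opening press; as many
full windows as fit are placed subject to the last window ending at least
1 s before the closing press, so the tail guard varies between 1 and
1.5 s.

## Spectral estimation

* **Welch PSD** — mean-detrended, Hanning-tapered periodograms averaged
  over windows (`scipy.signal.periodogram` per window), one-sided density
  normalized so the integral equals the variance. Band power integrates
  bins whose centre frequency lies in [7, 11] Hz inclusive; logs are
  natural throughout.
* **Per-percept alpha power** — band power averaged over the 14 posterior
  channels and the percept's stable-interval windows, then logged.
  Percepts too short for a single window (< ~3 s with default guards)
  yield NaN and are dropped (with a count) by the regression stage.
* **Early sliding windows** — 500 ms windows advancing in 50 ms steps
  from the reported onset, fully inside the first second (11 windows);
  timestamps are window centres, so the trace starts at 0.25 s and the
  value "at 400 ms" is the window [0.15, 0.65] s.
* **Reversal-locked TFR** — per-frequency windows of 5 cycles (1250 ms at
  4 Hz, ~167 ms at 30 Hz, rounded to samples), Hanning-tapered single-bin
  Fourier power on a −1…1 s grid around each press, 1 Hz frequency steps,
  averaged over presses and posterior channels; presses too close to the
  recording edge are skipped and counted.
* **Multitaper CSD** — DPSS tapers with half-bandwidth 2 Hz around 9 Hz,
  `floor(2·T·W) − 1` tapers (3 for 1 s segments), cross-spectra averaged
  over tapers/segments and integrated over the band, so the diagonal is
  each channel's band power in µV². Hermitian and positive semi-definite
  by construction; both are asserted in tests on every input.
* **Pre-reversal time course** — 1 s, 50% overlapping segments anchored
  at the *end* of each percept (the session-level description anchors at
  the start, but the reported timestamps −1.5, −2, −2.5 s relative to the
  reversal are only exactly realizable with end-anchored segments, so
  that is the implementation). Log alpha per segment is baseline-corrected
  by the percept's first available segment (default) or by the 1–2 s
  before percept onset (`baseline="preonset"`, the figure-caption variant);
  values within 25 s of the reversal are averaged across percepts, with
  SEM.

## Beamformer

Frequency-domain (DICS-style) spatial filters per voxel:
`C' = Re(C) + λ·(tr Re(C)/n)·I` with λ = 0.05, and
`w = C'⁻¹l / (lᵀC'⁻¹l)`, which is the closed form of the constrained
problem min `wᵀC'w` s.t. `wᵀl = 1` (verified in tests against an
independent KKT solve to 1e−8, and unit gain to 1e−10). Only the real
part of the CSD enters (standard power variant); scaling the CSD leaves
the weights unchanged because the regularization is proportional to mean
sensor power. Free-orientation leadfields are reduced to the dominant
orientation (the eigenvector minimizing `lᵀC'⁻¹l`) before filtering. The
*common filter* is computed from all of a session's stable-interval
segments and reapplied to each percept's own CSD:
`power_v = Re(wᵀ C_epoch w̄) ≥ 0` (tiny negative round-off clipped;
negative beyond 1e−6 relative raises a conditioning error). Per-voxel
LMEMs of log duration on log source power produce the z-map, masked
one-sided at z ≥ 2.326 (p = 0.01); non-convergent voxels are reported as
missing, never silently filled.

## Inference

`fit_lmem` fits `response ~ fixed effects` with random intercepts for
subject, day-in-subject, and session-in-day (the percept level is the
residual — the study's "four nested levels"), by maximum likelihood (not
REML) through `statsmodels.MixedLM`, with an optimizer fallback chain
(L-BFGS, then Powell, then CG) and an honest `converged` flag; singular
or degenerate fits are reported, never silently accepted. Wald z =
estimate/SE against the standard normal, two-sided p everywhere except
the voxel maps (one-sided at 2.326 as reported). Inner nesting levels
with as many units as their parents (e.g. day when each subject has one
day) carry no separable variance and are dropped from the random
structure. r² is the squared correlation between conditional fitted
values (fixed effects + predicted random effects) and the observations.
No multiple-testing correction is applied across voxels or sliding
windows, matching the original analysis; reports carry the raw counts.

One identifiability note: with two days per subject and one condition per
day, the day-level variance and the condition effect compete; the day
variance is often estimated near zero and the condition SE then
understates day-to-day noise. This is a property of the design (condition
is identified from 16 subject-days), and is why the package's recovery
tests scale tolerances by replicate Monte-Carlo SDs rather than by
single-fit model SEs.

**Mediation.** Path a from `log_alpha ~ condition`; paths b (alpha,
adjusted) and c (condition, unmediated) from the joint model
`log_duration ~ log_alpha + condition`; mediated effect `ab = a·b` with
`se_ab = √(a²σ_b² + b²σ_a²)` and Sobel `z = ab/se_ab`. The identities are
asserted on every result; if either fit fails to converge the Sobel z is
withheld. The two-sample Kolmogorov–Smirnov comparison of condition-wise
duration distributions uses `scipy.stats.ks_2samp` (exact p below 5 per
side, with a warning).

Because the inclusion filter truncates the response, the estimands the
analysis can recover differ slightly from the untruncated generative
parameters (b ≈ 0.098 rather than 0.111 under defaults). The test suite
therefore carries a model-free oracle — a vectorized large-n draw of the
generative equations with plain moment/OLS estimands on the filtered
sample — and checks the LMEM machinery for *unbiasedness against that
oracle*, while single-run checks use replicate-based Monte-Carlo SDs.

## Preprocessing and pipeline

Average reference over good channels; zero-phase 4th-order Butterworth
high-pass at 0.5 Hz and a Q = 30 notch at 50 Hz (forward–backward, so the
effective order doubles — chosen so press-locked windows suffer no group
delay). Bad channels are interpolated from their three nearest montage
neighbours for scalp analyses or dropped for source analyses. ICA-based
artifact rejection is a no-op hook: the synthetic data are artifact-free,
and the interface is reserved for real recordings. All window lengths
convert to samples by rounding half-up at the 1024 Hz default rate.

`run_pipeline` sequences simulate → preprocess → epochs → power →
regression → sliding prediction → TFR → time course → (optional
beamformer) → KS → mediation, processing one session at a time to bound
memory, and writes a manifest JSON with every statistic, the seed, the
full configuration, and SHA-256 hashes of the TSV outputs; two runs with
the same seed produce byte-identical manifests. Recordings are stored in
a documented NPZ container (data in µV, sampling rate, channel names,
JSON metadata); EDF files are read via `mne` when available. Without a
leadfield the source stage is skipped with an explicit notice.

## Problem sizes and numerical conventions

Default test and acceptance runs use 16-channel montages, 256 Hz
synthesis, sessions of 70–560 s, and ~1000–5500 percepts per study —
sizes chosen so the full validation suite completes in a few minutes on
one CPU while keeping every Monte-Carlo check at 3-SD resolution.
Tie-breaks and tolerances: band edges inclusive; windows half-open;
sample indices rounded half-up; CSD PSD-ness checked at 1e−8 relative;
unit gain at 1e−10; beamformer power clipped at −1e−6 relative.

## Known limitations

* The generator's lognormal multiplier makes SD durations
  gamma-lognormal rather than exactly gamma; the KS statistic between
  conditions is therefore larger than the published one (whose
  heavier-tailed empirical distribution dilutes the same mean shift).
* Day-level variance is weakly identified (see above).
* The toy leadfields are not head models; localization results validate
  the filter algebra, not anatomical accuracy.
* Sliding-window and voxel analyses are mass-univariate with no
  multiplicity control, mirroring the original design.
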