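# Methods

This note documents the models, estimator conventions and design choices
behind `ratqeeg`, in enough detail to reproduce or audit any stage.

## Synthetic recording model

Each channel is a superposition of independent components, all in µV:

* **Band-limited sources.** One unit-variance white-noise source per channel
  and band, shaped by a 4th-order Butterworth bandpass at the band edges and
  scaled so the component's RMS equals the configured band amplitude.
  Defaults (delta 30, theta 25, alpha 15, beta 10, high beta 6, gamma 5 µV
  RMS) give a total background of roughly ±150 µV peak, typical of rat
  skull-screw recordings.
* **1/f background** (10 µV RMS, flat below 1 Hz) generated by FFT shaping,
  plus white sensor noise (2 µV RMS).
* **Pairwise coupling** is a *delayed shared source*: a receiver's band
  source is `w·s(t−τ) + sqrt(1−w²)·s_own(t)`, keeping unit variance.  The
  pure delay (τ > 0, shorter than the band's shortest period) makes the
  imaginary cross-spectrum nonzero, so the phase-lagged coherence target is
  available in closed form.  Default couplings connect the six homologous
  pairs and a fronto-temporal network {F3, F4, T3, T4} in theta/alpha/beta
  (weights 0.35–0.6, lags 8–17 ms).
* **Common drive.** Real rodent cortex is broadly coherent; with only a few
  coupled pairs the 396-cell GFC average would be dominated by noise-floor
  coherence estimates.  Every band therefore also carries a weak common
  source (weight 0.55) delivered to each channel with a channel-specific
  conduction delay (0–20 ms in 4-ms steps), giving all electrode pairs a
  small true lagged coherence.
* **Drug effects** are per-epoch multiplicative factors: `power_gain`
  multiplies band power (amplitude × √gain) and `coupling_gain` multiplies
  every coupling weight, with the receiver's own-source residual
  re-normalised so channel variance is unchanged — disconnection without a
  power confound.
* **Behavioural activity** adds EMG-like noise (white noise high-passed at
  40 Hz, 40 µV RMS) during active intervals plus ~2 movement transients per
  active minute (0.25-s pulses, ~400 µV, 5–10× background RMS).  These
  exercise the inactivity filter and the amplitude criterion.

Ground truth is derived from the generative transfer functions, never
measured from the signal.  Band powers integrate the analytic one-sided PSD;
pair coherences follow from enumerating shared source terms (including the
common drive) in the cross-spectrum, with lags rounded to the sample grid
exactly as the generator applies them.

**Estimator-aligned binning.** The Welch estimator's 1-Hz bin labelled *f*
sums the 0.5-Hz native bins at *f* and *f*+0.5, whose nominal coverage is
[*f*−0.25, *f*+0.75).  Ground-truth integrals use the same coverage so the
oracle and the estimator measure the same quantity; otherwise a spurious
±10% "bias" appears wherever the PSD slopes across a band edge.

**Quantization.** The recording model's quantizer uses step =
half_range/2^bits, which for ±500 µV at 16 bits reproduces the acquisition
hardware's printed 7.63 nV/bit.  The conventional full-range/2^bits step
would be twice as large; the half-range convention is deliberate.  The EDF
container itself stores int16 at ±500 µV physical range (15.26 nV LSB), and
round-trip fidelity is asserted against that container step.

## Preprocessing

* **Filtering.** Linear-phase FIR bandpass, 111 taps, 0.5–40 Hz, applied by
  same-length convolution (exact group-delay compensation).  The
  per-channel mean is removed first: at 250 Hz a 111-tap kernel has a
  multi-hertz transition band and cannot itself null sub-hertz components,
  while amplifier DC carries no physiological information here.
* **Epochs.** Post-treatment windows are derived from the per-recording
  administration time; windows extending beyond the recording are flagged
  missing, never truncated.
* **Segment selection** replaces two manual steps with deterministic rules:
  the visually chosen 10-s exemplar becomes the ten eligible seconds with
  the lowest cross-channel peak amplitude, and the proprietary reliability
  metrics become symmetric variance-agreement ratios
  `1 − |v₁−v₂|/(v₁+v₂)` on per-second blocks (interleaved seconds for
  split-half, sequential halves for test–retest), compared against the same
  ≥ 0.9 thresholds.  Both are documented stand-ins: the originals are
  unpublished, and the ratio form reproduces their threshold semantics (a
  10× amplitude change yields ≈ 0.02).  Acceptance is per second, in
  temporal order, against per-channel ceilings of 1.25× the exemplar's
  per-channel maximum; seconds whose variance is farthest from the median
  are dropped until reliability passes; epochs with < 30 s accepted are
  rejected.  Unmarked time counts as inactive (activity is what gets
  flagged during co-registration); handling, artifact and sleep-suspect
  intervals are excluded like activity.

## Spectral and connectivity estimators

Welch averaging uses 2-s Hann windows at 50% overlap, tiled inside each
accepted segment so windows never span splices.  Absolute power (µV²) is
the primitive; band edges shared by two bands resolve half-open
[low, high), with the topmost band closed at 40 Hz, so band powers add
without double counting.

Lagged coherence is computed per 1-Hz bin from bin-integrated spectra, with
an ε = 10⁻¹² denominator guard (LC ≔ 0 at degeneracy), then aggregated to
bands by a power-weighted mean (weights: geometric mean of the two
auto-powers) so negligible-power bins cannot dominate.  The vendor software
that popularised the metric publishes no formula; the standard form above
removes the zero-lag component by construction, which is the metric's
stated intent.

Connectivity change is the per-cell log ratio to the subject's own baseline
(Box-Cox λ = 0); cells with LC below 10⁻³ in either epoch are masked rather
than producing extreme logs.  An alternative reading — differencing the
logs of group-mean coherences — would lose the per-subject GFC scalar and
is not used.  GFC is the unweighted mean of unmasked cells and requires
≥ 50% coverage.  The KDE uses a Gaussian kernel whose *standard deviation*
is the configured width (0.5), on a grid spanning the data ± 3 bandwidths.

## Statistics

The mixed repeated-measures ANOVA is implemented from explicit sums of
squares (between: treatment, subjects-within-groups; within: time,
treatment × time, subject × time error) and verified to 10⁻⁸ against a
brute-force least-squares oracle and against `pingouin.mixed_anova`.
Greenhouse–Geisser ε̂ comes from the double-centered pooled within-group
covariance, `(Σλ)² / ((t−1)Σλ²)`, clamped to [1/(t−1), 1]; within-subject
p-values use ε̂-scaled degrees of freedom.  Under true sphericity the
corrected interaction test is mildly conservative (empirical type-I ≈ 0.042
at k = 2, t = 3, n = 8/group) — a property of the correction, not of the
implementation.

qEEG responses enter the ANOVA baseline-normalised (log ratio to the
subject's own baseline), so the within factor has three levels (E1–E3) and
a four-arm design carries interaction df = 6.  The behaviour ANOVA keeps
the baseline as a fourth level, since inactivity durations are compared
across all four epochs directly.  Bonferroni post-hocs (pooled-variance
pairwise group contrasts at each time level, family = comparisons actually
performed, clipped at 1) run only when the interaction is significant at
α = 0.05.  The GFC rule: significant interaction → per-time post-hocs;
otherwise a significant treatment main effect → time-collapsed contrasts
read as an overall connectivity change; otherwise no effect.  Shapiro–Wilk
normality is reported but does not gate the parametric tests.  Unbalanced
groups are accepted; achieved dfs are reported.

## Topographic maps

"3-D spline mapping" is implemented as an exact 2-D thin-plate spline
(linear polynomial tail, smoothing 0) over flattened skull coordinates —
exact at electrodes, affine-reproducing, linear in the data.  Grid points
beyond the electrode convex hull plus a 1-mm margin are masked.  Pointwise
maps interpolate each subject × epoch and run the same vectorised ANOVA at
every grid point, binning p at 0.05/0.01/0.001.  No multiplicity correction
is applied across pixels (corrections apply to planned comparisons, not map
points); this is configurable and recorded in the output metadata.

## Problem sizes and what the tests show

Recovery studies use the study's arm sizes (8 subjects/group) with a
compressed epoch schedule — four back-to-back epochs of 60 s (power
recovery; 50-s selection targets) or 130 s (connectivity recovery; 120-s
targets, the full selection length) — keeping a complete 20-replicate study
within minutes on one CPU while preserving the per-epoch effect structure.
The type-I calibration uses 500 replicates of spherical null data.

Passing these suites shows the pipeline recovers known effects from signals
with the right second-order statistics (band structure, 1/f background,
lagged coupling, movement artifacts).  The generator does not model
non-stationary vigilance drift, electrode impedance changes, chewing/EMG
spectra beyond high-passed white noise, volume-conduction head geometry, or
sleep — so the tests cannot certify behaviour under those real-data
features, and selection thresholds may need re-tuning on real recordings.

## Numerical and degenerate-input conventions

Zero-variance designs are flagged, not tested; all-zero signals get
reliability 1 (degenerate, logged); coherence denominators below 10⁻¹²
yield LC = 0 with a degeneracy flag; Box-Cox inputs must be strictly
positive (masking happens upstream at the coherence floor); EDF signals
clip at the ±500 µV dynamic range exactly as the acquisition hardware
would.  Selection ties (equal per-second peaks) resolve by temporal order
via a stable sort, making the whole pipeline deterministic under a fixed
seed; a global seed fans out to per-subject streams keyed by subject id, so
adding subjects never perturbs existing ones.

## Known limitations

EDF storage quantises at 15.26 nV (int16 over ±1000 µV span), slightly
coarser than the modelled 7.63 nV acquisition step; markers live in a YAML
sidecar rather than EDF+ annotations; the reliability and exemplar rules
are principled stand-ins for unpublished procedures; and the KDE "width"
is interpreted as the kernel standard deviation.
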