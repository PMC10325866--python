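# ratqeeg

Quantitative EEG analysis of drug-induced broadband desynchronization and
disconnection in freely moving rats.

Serotonergic psychedelics such as psilocin produce two robust signatures in
the rodent cortical EEG: a broadband drop in absolute spectral power
(desynchronization) and a drop in long-range phase-lagged coupling
(disconnection).  `ratqeeg` implements the full resting-state qEEG pipeline
used to quantify these effects and their reversal by receptor antagonists —
from raw 12-channel skull-electrode recordings through artifact-free segment
selection, spectral power, phase-lagged coherence, a per-subject global
functional connectivity (GFC) scalar, Box-Cox-normalized mixed
repeated-measures statistics, and topographic significance maps.  Because
such animal recordings are rarely shared, the package ships a synthetic-data
generator with analytically known ground truth, so that every stage is
verifiable by parameter recovery.

It is intended for neurophysiologists analysing pharmaco-EEG studies in
rodents, and for methodologists who need a fully testable reference
implementation of this analysis chain.

## The analysis in brief

* **Recording model.** 12 cortical sites (F3/F4, C3/C4, P3/P4, P5/P6, T3/T4,
  T5/T6) at 250 Hz, 16-bit depth over a ±500 µV dynamic range (7.63 nV/bit).
  Four analysis epochs: a 10-min baseline and 20–30, 50–60, 80–90 min after
  substance administration.
* **Segment selection.** Only behavioural-inactivity signal enters the
  resting-state analysis.  Within each epoch a 10-s low-amplitude exemplar
  sets per-channel ceilings; seconds are accepted while every channel stays
  within 1.25× the exemplar maximum, targeting ~120 s, requiring split-half
  and test–retest reliability ≥ 0.9 and at least 30 s.
* **Spectra.** FIR bandpass (111 taps, 0.5–40 Hz), Welch FFT in 2-s Hann
  windows, absolute power per 1-Hz bin and per band: delta 1–4, theta 4–8,
  alpha 8–12, beta 12–25, high beta 25–30, gamma 30–40 Hz.
* **Connectivity.** Phase-lagged coherence per electrode pair and band,

      LC(f) = Im(S_xy)² / (S_xx·S_yy − Re(S_xy)²),

  insensitive to zero-lag (volume-conducted) coupling.  The GFC scalar is
  the per-subject mean of baseline-relative lagged-coherence changes
  (log ratio, Box-Cox λ = 0) over all 66 pairs × 6 bands; distribution
  shifts are summarised by a Gaussian KDE of kernel width 0.5.
* **Statistics.** Responses are normalised to each subject's baseline
  (log ratio), then tested with a mixed repeated-measures ANOVA
  (between = treatment, within = epoch) with the Greenhouse–Geisser
  correction; Bonferroni post-hocs run only on significant interactions.
  A treatment main effect without interaction is read as an overall GFC
  change.
* **Maps.** Per-electrode statistics are interpolated by exact thin-plate
  splines over flattened skull coordinates with pointwise three-level
  significance overlays.

## Worked example

`examples/study.yaml` defines a two-arm synthetic study (4 saline controls
vs 4 subjects with a psilocin-like effect: band powers ×0.6 and coupling
weights ×0.7 in the first two post-treatment epochs), with compressed 60-s
epochs so it runs in seconds:

```bash
ratqeeg run --config examples/study.yaml --out demo_out
# GFC decision branch: interaction
# results written to demo_out
```

The mean-power ANOVA table (`demo_out/anova_mean_power.csv`,
treatment:time rows) shows the drug × time interaction in every band —
the desynchronization is time-locked to the dosed epochs:

```
     band          F  df_num  df_den  gg_epsilon         p_gg
    delta  76.457814     2.0    12.0    0.853259 1.054855e-06
    theta  78.654353     2.0    12.0    0.934500 3.070290e-07
    alpha 122.033768     2.0    12.0    0.811141 2.170036e-07
     beta 180.044386     2.0    12.0    0.645996 7.218151e-07
high_beta  25.629416     2.0    12.0    0.979455 5.458930e-05
    gamma 175.259869     2.0    12.0    0.913169 6.302558e-09
```

`df_num = 2` is (groups−1)×(epochs−1) for this 2-arm design; with the
study's four arms it is 6.  The per-subject GFC values
(`demo_out/gfc.csv`, group × epoch means) recover the simulated
disconnection and its partial recovery in E3:

```
PSI  E1  -0.653      SAL  E1   0.070
PSI  E2  -0.681      SAL  E2  -0.063
PSI  E3  -0.269      SAL  E3   0.018
```

A GFC of −0.65 is a mean log-ratio, i.e. lagged coherence at ~52% of each
subject's own baseline.  The same pipeline is scriptable from Python via
`ratqeeg.run_study(StudyConfig(...))`, and the individual stages
(`spectral.power_spectrum`, `connectivity.lagged_coherence_matrix`,
`stats.rm_anova`, `topomap.spline_interpolate`, …) are importable directly.

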