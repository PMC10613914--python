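# Methods

This note documents the models, parameter choices and known limitations
of `pdscreen`, in the spirit of a statistical software appendix.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Facial feature extraction

Input is a 68-point landmark trajectory in image coordinates (origin
top-left, y down; iBUG ordering, 1-based: jaw 1–17, brows 18–27, nose
28–36, eyes 37–48, mouth 49–68) at a fixed frame rate (25 FPS default).

**Head-motion normalization.** "Face length" is defined as the distance
from landmark 28 (top of the nose bridge) to landmark 9 (chin tip),
per frame.  The published catalog this reimplements never defines the
term; this choice spans a rigid part of the face and is robust to
expression.  Distances and vertical offsets are divided by face length,
polygon areas by face length squared (a package choice for dimensional
consistency; whether the original analysis normalized areas at all is
unknown).  Angles and ratios are dimensionless.  Every normalized
measure is therefore exactly invariant to per-frame translation plus
uniform scaling (tested at 1e-9); rotation is *not* in the invariance
contract — the vertical brow measures are y-differences and rotate by
construction.

**Catalog.** 55 measures: 13 distances, 5 brow measures (3 angles, 2
verticals), 22 eye distances, 8 mouth distances, 2 mouth ratios, 3 areas
(inner-lip loop 61–68, eye loops 37–42 and 43–48, by the shoelace
formula), a face ratio and 2 mouth-skew ratios.  Two brow entries
(EYEBROW2/EYEBROW3) are published with identical definitions; both
names are kept (one aliases the other) and a warning is logged, so the
55-name surface stays stable without inventing a definition.  Angles are
unsigned degrees in [0°, 180°); a zero-length segment yields NaN via the
arccos guard; a ratio with zero denominator yields NaN rather than an
exception; a degenerate polygon has area 0.

**Detector gaps.** Missing frames are linearly interpolated on raw
coordinates when the gap is ≤ 0.5 s; longer gaps are dropped from all
feature series consistently.  Fewer than two usable frames is an error.

**Per-series summaries.** Ten statistics per measure: mean; population
std; rsd = std/|mean| (0 for a constant series); min; max;
range = max − min (exact); var = std² (exact); the OLS slope of value
against time *in seconds*, making slopes frame-rate independent;
Shannon entropy over a 16-bin equal-width histogram spanning [min, max]
(bits, 0 when min = max); and approximate entropy ApEn(m = 2,
r = 0.2·std) in the original regularity-statistic form — Chebyshev
distance, self-matches included, ApEn = Φᵐ − Φᵐ⁺¹ — which is
non-negative up to rounding.  Entropy statistics require ≥ 8 samples and
are NaN below that.  The binning (16) and ApEn defaults (m = 2,
r = 0.2·std) are standard conventions; the source analysis is silent on
both.  Both entropies are verified against brute-force reference
implementations on 100 seeded series at 1e-9.

## 2. Acoustic feature extraction

All analyses use 40 ms frames with a 10 ms hop.  Energy thresholds are
relative, so every measure is invariant to a global gain change
(tested at 1e-6).

**Pitch and voicing.** Normalized autocorrelation of the mean-removed
frame, searched in 60–500 Hz.  The peak lag is picked on the raw
(biased) estimator, whose lag taper naturally suppresses the
octave-down ambiguity, and the peak *height* is bias-corrected by
N/(N−lag) so a periodic frame scores ≈ 1 regardless of period; parabolic
interpolation refines the lag.  A frame is voiced when the corrected
peak ≥ 0.45 and its RMS exceeds a relative silence floor (2% of the
95th-percentile RMS).  The threshold is exposed for low-harmonicity
analyses.  DUV is the unvoiced fraction of frames; relF0SD the
population std of voiced F0 over its mean.

**Jitter and shimmer.** Cycle segmentation is guided by the tracker:
the median voiced F0 predicts the cycle length and waveform peaks at
least 0.7 predicted periods apart mark cycle boundaries; intervals
outside 0.5–2× the predicted period are discarded as tracking slips.
The five-point perturbation quotients
100·mean|xᵢ − (1/5)Σ_{k=i−2..i+2} x_k| / mean(x) are then applied to the
period and peak-amplitude sequences.  The quotient itself matches a
direct formula evaluation at 1e-9; estimated values rank-order perfectly
with injected perturbation levels in synthesis sweeps (note that the
PPQ5 of i.i.d. period noise is a fixed fraction ≈ 0.71 of the injected
sd — the quotient measures deviation from a local mean, not the raw sd).

**HNR.** Per voiced frame, HNR = 10·log₁₀(r′/(1−r′)) with r′ the
corrected autocorrelation peak at the pitch lag, clipped so perfect
periodicity saturates at 60 dB; the mean over voiced frames is reported.

**Formants.** Resample to 10 kHz, pre-emphasis 0.97, Hamming window,
order-12 autocorrelation LPC per voiced frame
(Levinson via `solve_toeplitz`).  Pole frequencies with bandwidth
< 700 Hz are formant candidates; F1 is the lowest in 200–1200 Hz, F2 the
next above it in 600–3200 Hz.  Frames missing either formant are
skipped; fewer than five usable frames yields NaN.

**Energy, syllables, pauses.** relSEOSD is the rel. std of short-time
energy over speech-active frames (energy above 1% of its 95th
percentile).  Syllable nuclei are smoothed energy-envelope peaks at
least 6 dB above the median envelope, ≥ 60 ms apart, with a ≥ 3 dB dip
between (enforced as peak prominence).  Pauses are internal runs
≥ 60 ms where frame energy falls 25 dB below the median speech level
(median of frames within 30 dB of the maximum), with leading/trailing
silence excluded; SPIR = pauses per recording minute; net speech time
NST = duration − pauses − edge silences; NSR = nuclei/NST.  NSR uses
syllable nuclei as the countable unit because phone counting would
require transcription; it is a proxy and is flagged as such.  MPT is the
longest voiced stretch.  The −25 dB / 60 ms pause convention and the
nucleus rules are package choices; the original analysis used external
tools whose settings are unpublished.

**Task applicability.** Expiration tasks (TSK1–2): MPT plus the
phonation set; sustained vowels (TSK3–17): relF0SD, jitter, shimmer,
relF1SD, relF2SD, mean HNR, DUV; the diadochokinetic task (TSK18): DDK
rate (onsets over first-to-last span plus one mean interval, so k
evenly spaced onsets at interval d give exactly 1/d) and DDK regularity
(population std of inter-onset intervals); connected-speech tasks
(TSK19–43): relF0SD, relF1SD, relF2SD, relSEOSD, with SPIR on TSK20–26
and TSK37–42 and NSR on TSK20–41, following the published task lists.
All other measures are NaN for a given task.

## 3. Synthetic cohort

The generator reproduces the *structure* of a two-group clinical
recording study, not its content.  Defaults mirror the study design:
73 PD / 46 HC, 25 FPS video, 48 kHz/16-bit mono audio, and one task from
each family (TSK3 vowel, TSK18 DDK, TSK41 sentence proxy, TSK42 reading
proxy).  No quantitative PD-vs-HC effect sizes are published for any of
these features — only directions (smaller mouth excursion, altered blink
rate, raised jitter/shimmer, lowered HNR, irregular and slowed DDK).
The reference profile therefore sets magnitudes once, chosen so that
the planted signal clearly dominates subject-level variability
(log-normal, sd 0.15 on the log scale):

| parameter | HC | PD |
|---|---|---|
| mouth amplitude multiplier | 1.0 | 0.45 |
| blink rate (Hz) | 0.35 | 0.15 |
| mouth-corner drift (face-lengths/s) | 0.0005 | 0.004 |
| corner asymmetry (face-lengths) | 0.005 | 0.03 |
| jitter (%) | 0.7 | 2.5 |
| shimmer (%) | 3.0 | 9.0 |
| HNR (dB) | 22 | 10 |
| relative F0 wander | 0.015 | 0.06 |
| DDK rate (Hz) | 6.0 | 4.5 |
| DDK regularity sd (s) | 0.012 | 0.05 |

A null profile sets PD = HC everywhere.  Faces animate from a canonical
neutral template (face length exactly 100 units): sinusoidal mouth
opening at 0.8 Hz, 120 ms triangular blinks with exponential inter-blink
times, brow noise, linear corner drift, static asymmetry, plus rigid
head translation and uniform scale drift applied last (and therefore
invisible to normalized features).  Vowels are source–filter synthesized
(perturbed glottal pulse train through formant resonators, white noise
scaled to the exact target HNR, optional slow F0 wander); DDK is a tone
burst train with Gaussian inter-onset intervals; connected speech
alternates syllabically gated vowel stretches with silent pauses and
returns its ground-truth segment table for oracle tests.

**Confounds** enter additively and linearly on *extracted* features
(age and male-gender shifts in units of each feature's sd), which makes
OLS residualization exactly correct by construction — the property the
confound tests exploit.  A direct feature-table simulator
(`synthesize_feature_table`) provides the same post-extraction path for
many-seed statistical checks (null false-positive rates, permutation
nulls) where full signal synthesis would add nothing but runtime.

What the generator does **not** emulate: photorealistic appearance,
real articulation or language content, landmark-detector noise
statistics, correlated effect structure across features, disease
severity gradation.  Passing tests therefore demonstrate that the
*pipeline* recovers planted effects and stays at chance under nulls —
not that the reference effect sizes match any real cohort.

## 4. Statistics, selection, classification

**Regression-out.** Each feature is replaced by its residual from an
OLS fit on [1, age, gender] (gender coded male = 1, age in years,
uncentered).  The default `fit_all` mode fits on all subjects, mirroring
the original order in which residualized values exist before any
train/test split; this leaks distributional information into
preprocessing, so a `fit_train` mode (coefficients from training folds
only) is provided as the clean alternative and the leakage is measured,
not silently fixed (see the null anti-leakage test).  Residuals of a
`fit_all` fit are exactly orthogonal to the confounds, mean-zero, and
the operation is idempotent (all tested at 1e-10).  Negative feature
values after residualization are expected and preserved.

**Univariate tests.** Two-sided Mann-Whitney U per feature (exact
enumeration when both groups ≤ 8 and tie-free, otherwise the tie- and
continuity-corrected normal approximation), Benjamini-Hochberg
adjustment across features, medians and IQRs per group.  Test results
are reported but do not gate selection — the published analysis retains
features whose FDR-adjusted p exceeds 0.05, so selection is driven by
mRMR alone.

**mRMR.** Greedy MID variant: relevance = MI(feature, label),
redundancy = mean MI with the already-selected set, both on 3-bin
equal-frequency discretizations (NaNs form their own bin); first pick is
the max-relevance feature; ties break on column order; k = 50 by
default.  The exact variant and discretization of the original analysis
are unpublished; MID with equal-frequency bins is the common default.
The greedy trace equals an independently implemented brute-force trace
on small tables.

**Classifier and CV.** XGBoost, 200 trees, depth 3, learning rate 0.1,
L2 = 1.0, `scale_pos_weight` = majority/minority training count ratio
(the original hyperparameters are unpublished; these are conservative
defaults for ~100 subjects, and balanced accuracy is the score for any
hyperparameter search).  Stratified 10-fold CV, single run, metrics
aggregated as mean (std) — matching the "mean (std)" reporting
convention.  Imputation (training medians) and z-scoring (training
statistics) are fold-local.  mRMR runs once on the full table before CV
by default (`outer`, mirroring the published order) or inside each
training fold (`per_fold`); on null cohorts the per-fold variant stays
at chance while the outer variant may exceed it, and the suite asserts
per_fold ≤ outer + 0.05.  MCC with a zero denominator factor is
reported as 0 with an explicit undefined flag.

**Attribution.** Exact TreeSHAP from the boosted-tree library
(`pred_contribs`); per sample the attributions plus base value equal the
margin output.  The identity is algebraically exact; the library emits
float32, so the suite asserts 1e-6 on a 50-tree ensemble and 1e-5 on the
default 200-tree ensemble, where float32 accumulation across trees sets
the floor.  Feature sign is the sign of the correlation between feature
value and attribution.

## 5. Problem sizes in the test suite

Signal-level checks run on short recordings (0.8–2.5 s audio, 3–8 s
video) and the end-to-end separation check on a 26-subject cohort with
three tasks — sizes chosen so the whole suite documents the pipeline's
behavior at desk scale; the acceptance script re-runs the cohort
analysis at the full 73/46 design.  Many-seed chance-level checks (20
permutations / 20 null seeds) use the post-extraction table simulator.

## 6. Known limitations

* Jitter/shimmer are estimated from tracker-guided peak picking, not
  from glottal-closure instants; absolute values are comparable within
  the pipeline but not calibrated to any external voice-analysis tool
  (the original study's tool chain and settings are unpublished, and its
  data are confidential, so numeric equivalence cannot be verified).
* The synthesizers are validation instruments: effect magnitudes are
  free parameters, so cohort-level classification numbers characterize
  the pipeline under the reference profile, not clinical performance.
* NSR counts syllable nuclei, not phones.
* The published catalog's duplicated brow entry is preserved as an
  alias, so two of the 550 video features are identical by design.
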