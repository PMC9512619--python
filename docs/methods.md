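# Methods

This note documents the models, parameters and design choices behind
`fidgetlab`, in the spirit of a methods supplement: what each stage
assumes, what the synthetic generator does and does not emulate, and
where genuinely open choices were resolved.

## The synthetic generator

The generator (`fidgetlab.synthdata`) emulates one session of a
head-fixed passive-viewing experiment at 30 Hz: a behavior video, a
per-frame annotation track, ΔF/F traces, a drifting-grating stimulus
table, and a running-speed trace.  All ground truth (event times and
amplitudes, per-neuron response types, tuning, running gains) is stored
in a separate `truth` record that no analysis stage reads, so every
stage can be scored against information it could not have used.

**Video.**  The animal is a textured elliptical blob on a static
textured background — deliberately not a rendered mouse.  The detector
consumes gradient structure, not anatomy, so what matters is that the
body carries internal texture that moves and deforms with it.  During a
fidget the body lifts vertically and contracts horizontally with a
Hann-shaped time course (peak lift 7 px by default, ~5% of the frame);
"movement" epochs are a slow 2-Hz horizontal sway; a small amount of
per-frame sensor noise (SD 0.003) keeps frames from being bit-identical.
Event durations are uniform on 15–45 frames (0.5–1.5 s) and peak
amplitudes are drawn with a configurable coefficient of variation
(`fidget_amplitude_cv`, default 0.10).  No published quantitative
kinematics exist for fidgets; these values are stated defaults, not
inferred ones.

**Event scheduling.**  Events are placed one per equal time slot, away
from the session edges, and — when the slot geometry allows — at least
`min_event_gap_frames` (default 300, i.e. one full 100-pre/200-post
analysis window) apart.  The gap matters: without it, a dense synthetic
session lets neighboring events bleed into each other's trial windows,
which stamps a session-specific event-spacing signature onto every
responsive neuron's trial average.  Real inter-fidget intervals (tens of
seconds) rarely violate a 10-s window, so the gap is the realistic
regime, not a convenience.

**Traces.**  Each neuron draws one of four response types
(neutral / phasic / active / depressed) at configurable prevalences,
defaulting to the observed population mix (52.8 / 13.9 / 12.0 / 21.3%).
The archetype waveforms are causal indicator-kinetics shapes with decay
constant `indicator_tau` (default 0.7 s, GCaMP6f-like): phasic is an
instantaneous rise with exponential decay, active a saturating rise held
through the post window, depressed its negative.  Peak ΔF/F amplitudes
are 0.30 / 0.20 / 0.12 for phasic / active / depressed, with
neuron-to-neuron lognormal variability `amp_cv` (default 0.05).  The
default is deliberately small: the cluster-count recovery analyses
presuppose well-separated archetype clusters, and amplitude CVs ≳ 0.2
stretch each type into a ray in z-space, a geometry in which *any*
within-dispersion criterion over-counts clusters.  Visual responses are
von Mises direction tuning (κ = 2) × one-octave log-Gaussian temporal
frequency tuning, peak amplitude 0.15 ΔF/F, convolved with the indicator
kinetics; a `running_fraction` (default 0.3) of neurons multiplies its
visual response by `1 + running_gain` (default gain 0.5) during running
frames.  I.i.d. Gaussian noise (SD 0.06 ΔF/F per frame) is added last.

**Cohorts.**  `generate_cohort` cycles sessions through the requested
areas, depths and Cre-lines.  `area_effect = 0` produces the null cohort
(identical generating prevalences everywhere).  `area_effect > 0` makes
the first three areas each boost one non-neutral type (phasic, active,
depressed respectively) at neutral's expense.  A single-area,
single-type shift was considered and rejected: with four areas it caps
Bayes-optimal decoding accuracy near 0.33, too weak to serve as a
positive control for the decoder; the cyclic shift makes the same scalar
produce mutually distinguishable areas while preserving "the first
area's phasic prevalence rises by `area_effect`" as its observable
signature.

**What the generator does not emulate.**  Anatomically realistic video
(pose, fur, limbs), eye/pupil state, non-grating stimuli, slow drift and
bleaching in ΔF/F, correlated (shared-noise) population variability, and
spatial structure within a field of view.  Passing tests therefore show
that the *algorithms* recover known structure under controlled
conditions; they do not certify performance on real video or real
calcium traces.

## Detection pipeline choices

- Power-law exponent γ = 0.5 by default (only "compression" is standard;
  the exact exponent is a free choice, configurable).
- Blocks are non-overlapping 1-s tiles (stride = one block).  A block is
  labeled fidget for training when more than 25% of its frames are
  fidget-annotated.  A strict majority rule was evaluated and rejected:
  a 0.5-s event split across two 1-s blocks can never occupy more than
  half of either block, so a >50% rule silently discards every short
  event and caps achievable event-level recall near 60%.  The 0.25
  threshold keeps sub-second events trainable; at the event level,
  any-overlap matching makes the resulting block-granularity predictions
  score correctly.
- The classifier is a 3-class RBF SVM (`class_weight="balanced"` to
  counter the dominance of resting blocks), C ∈ {1, 10, 100} ×
  γ ∈ {scale, 10⁻², 10⁻³} by default, 5-fold stratified CV.  The SVM is
  trained with the standard soft-margin hinge objective.
- Event extraction: runs separated by ≤ 5 frames are merged, runs
  shorter than 10 frames (~300 ms) are dropped as label jitter.
- The PCA basis is fit on training frames only and serialized with the
  model; inference never refits it (guard-tested).

## Optical flow

OpenCV is not a dependency; the Farnebäck two-frame polynomial-expansion
estimator is implemented in `fidgetlab._farneback`: quadratic polynomial
fits under a Gaussian applicability (poly_n = 7, poly_sigma = 1.5),
displacement from the averaged normal equations over a 30-px box window,
3 pyramid levels at scale 0.5, 3 iterations per level.  Only the 30-px
window is a scientifically fixed parameter; the rest are implementation
constants.  Validation: exact recovery of integer translations
(±0.5 px), zero flow on identical frames, invariance to additive
intensity offsets, linear scaling with displacement, and agreement with
scikit-image's iLK estimator on known shifts.

Event magnitude is the *unnormalized* sum of per-pixel flow norms over
all within-event frame pairs — no division by duration or area.  Because
that sum approximates the total path length swept by the body, it tracks
movement excursion rather than duration, which is what makes a
10%-amplitude-CV population produce magnitudes clustered near the
maximum.  "Within 30% of the maximum" is read one-sided: m ≥ 0.7·max.

## Alignment, clustering, naming

Trials are z-scored per trial with the 100 pre-onset samples only;
trials with zero baseline SD are excluded (ε-stabilization available).
Neurons need ≥ 3 valid trials to enter clustering.  Trials whose windows
overlap a neighboring event are kept (configurable at the generator, not
silently dropped at analysis).

The gap statistic uses uniform reference data drawn over the bounding
box in the data's principal-component frame, n_ref = 20 reference draws,
with s(k) inflated by √(1 + 1/n_ref).  Cluster count is the smallest k
whose gap is within one s of the global gap maximum (the `globalSEmax`
rule of R's `cluster::clusGap`).  Tibshirani's first-crossing rule is
available but not the default: when one dominant compact cluster (the
neutral majority) coexists with small distant clusters, the gap curve
dips at k = 2 before its true maximum and the first-crossing rule
terminates at k = 1 regardless of noise level.  `globalSEmax` returns
k = 4 on archetype mixtures and k = 1 on single Gaussians (both
300-dimensional and low-dimensional), which is the behavior the analysis
needs.

Cluster naming is a heuristic on the centroid: with M the post-onset
mean, P the signed extremum and L the fraction of the post window above
P/2 — small |M| and |P| ⇒ neutral; M < −0.25 ⇒ depressed; M > 0.25 and
L < 0.5 ⇒ phasic, L ≥ 0.5 ⇒ active; anything else falls back to the
nearest archetype with a warning.  Threshold criteria are applied to
|mean| and |extremum| of the raw-ΔF/F post window so that suppressed
(negative-going) cells can satisfy them; re-labeling is one-directional
(non-neutral → "criteria neutral"), which guarantees that a stricter
threshold's modulated set is a subset of a looser one's.

Imaging depth maps to layer as 175 µm → L2/3, 275 µm → L4, 375 µm → L5;
350 µm sessions (present in some acquisitions but absent from the
three-depth decoding scheme) are merged into the L4 class.

## Decoding

Embedding variants: UMAP 2-D (min_dist = 0, n_neighbors = 20; also 5 and
200), UMAP 3-D, and PCA-10.  Classes are balanced by subsampling to the
least prevalent class *after* the stratified 85–15 split, independently
in train and test (pre-split balancing available).  The classifier grid
is depth {2, 4, 6} × learning rate {0.1, 0.3} × {100, 300} rounds,
5-fold CV; 20 shuffled-label repetitions by default.

A caveat discovered with the synthetic cohorts and worth knowing for
real data: per-neuron train/test splits leak session identity.  Neurons
from one session share event times, and therefore share the pattern of
stimulus and running epochs falling inside their trial windows; a
decoder can memorize these session signatures and, when few sessions
feed each anatomical class, convert them into spurious area/layer
decodability.  The packaged null-cohort analyses use 48 sessions (12 per
area, 16 per layer) of 400 s each, which empirically brings the null
within ±0.03 of the shuffled baseline while a prevalence-shifted
positive control stays ~0.23 above it.

## State modulation

The Cohen's d denominator is the Euclidean norm √(s₁² + s₂²) — the plain
reading of "the norm of the two SDs"; the pooled form √((s₁²+s₂²)/2) is
available via `norm="pooled"`.  Responses are measured over stimulus-on
frames of the preferred condition only; preferred-condition ties break
to the lowest direction, then the lowest temporal frequency.  Fidget and
running masks are mutually exclusive by default (each state's contrast
excludes the other state's frames).  Running means speed > 1 cm/s
sustained ≥ 1 s.  Per-cell tests are two-sided two-sample KS with BH
correction at q = 0.05; cells with fewer than two samples in either
state are flagged untestable and excluded from the BH family.  DSI uses
(R_pref − R_null)/(R_pref + R_null) at the preferred temporal frequency
and is undefined when the denominator is non-positive.  `tuning_metrics`
accepts an exclusion mask so tuning can be estimated from trials free of
fidget-evoked activity; sustained post-fidget responses otherwise bias
per-type tuning estimates (strongly so in short, fidget-dense synthetic
sessions).

## Problem sizes and determinism

All analyses are deterministic given their seeds (k-means, UMAP, XGBoost
and every generator stream are seeded; the pipeline fans one global seed
out to fixed per-stage offsets).  The packaged test and acceptance runs
use scaled-down cohorts chosen as the smallest sizes at which each
recovery is stable: 2,000 neurons for cluster-count recovery, 5,000 for
prevalence recovery, six 3–10-minute video sessions for detector
train/test, 200 events for the stereotypy statistic, and the 48 × 75
cohort above for decoding.  The methods themselves carry no dependence
on these sizes.

## Known limitations

- The detector and flow stages are validated on blob-kinematics video;
  real fur, lighting and pose variation will lower performance toward
  the published real-video figures rather than the near-perfect
  synthetic ones.
- The gap-statistic default rule is tailored to the
  dominant-cluster-plus-satellites geometry; data without a dominant
  cluster are served equally well, but heavy-tailed amplitude
  distributions (ray-like clusters) will inflate the selected k under
  any uniform-reference gap variant.
- Frame-level significance tests on autocorrelated ΔF/F treat frames as
  exchangeable samples, as is common practice; their false-positive
  rates are anti-conservative for slow indicators.
- `modulation.state_modulation` requires the preferred-condition trials
  to actually contain frames of both states; in short sessions many
  cells are flagged undefined for the fidget contrast.
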