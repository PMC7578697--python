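# Methods

## The analysis this package implements

`citnirs` models a two-group fNIRS study of auditory attention in chronic
liver disease: patients (CL, n = 30, of whom 10 carry a minimal-hepatic-
encephalopathy sub-label) and healthy controls (HC, n = 25) perform three
melodic contour identification task (CIT) blocks while 16 prefrontal
channels record oxygenated-hemoglobin (HbO₂) changes at one sample per
0.65 s. The pipeline turns each recording into one 16-channel feature
vector per subject × CIT and asks which channel subsets best separate the
groups with a linear support-vector machine.

The classifier is the L1 soft-margin SVM

    min_{w,b}  ½‖w‖² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b)),

with CL encoded +1 and a decision value of exactly 0 classified as
positive. Performance is summarised from the fold-level confusion matrix
by sensitivity, specificity, accuracy, the Matthews correlation
coefficient (MCC) and balanced accuracy (bACC = (sens + spec)/2); MCC and
bACC are the ranking measures because the cohort is imbalanced. A zero
factor in the MCC denominator defines MCC = 0.

Cross-validation is stratified 5-fold repeated 20 times (100 fold-level
metric sets). Fold partitions are a pure function of (master seed, repeat
index), and **every channel subset is evaluated on the identical
partitions**, so subset scores are directly comparable. An optional
subject-grouped mode keeps a subject's CIT1 and CIT2 rows in the same
fold; the default row-level mode mirrors the original design, in which
same-subject rows can straddle train and test (a known source of
optimism — see Limitations).

The subset search enumerates every non-empty subset of a grouping —
right hemisphere CH1–CH8 (255 subsets), left hemisphere CH9–CH16 (255),
bilateral CH1–CH16 (65,535) — and ranks by mean MCC, with ties broken by
mean bACC, then smaller subset, then lexicographic order. A
`max_subset_size` cap bounds the bilateral enumeration for desk-scale
runs (all reported best subsets have ≤ 7 channels). The weight-sign
matrix refits the SVM on the full table for each top subset and records
each channel's signed weight: positive = HbO₂ higher in patients.

## Preprocessing

1. **MBLL** — optical-density change relative to the baseline-window mean
   intensity, inverted through the 2×2 extinction system. Defaults:
   wavelengths 770/840 nm, tabulated extinction coefficients in
   1/(mM·cm), DPF 6.0 at both wavelengths, 3.0 cm separation; output in
   µM. All configurable; the instrument class this emulates does not
   publish its constants.
2. **Zero-phase band-pass** — 3rd-order Butterworth, 0.01–0.09 Hz,
   applied forward–backward (`sosfiltfilt`), reflection padding of one
   impulse-response length (≈ 1/f_lo seconds). Removes drift below the
   band and cardiac pulsation above it with zero net phase shift.
3. **Baseline standardization** — subtract each channel's mean over the
   20-s pre-stimulus window ("mean" mode, the default reading of
   "standardized"); "z" mode additionally divides by the baseline SD.
4. **Block features** — mean HbO₂ per channel over each CIT block after
   discarding the first 10 s (configurable in [0, block length); the
   source description of the exclusion, "first 3–10 s", is ambiguous
   between a 3-to-10-s window and a choice in that range — both are
   expressible via `onset_exclusion_s`). Only HbO₂ enters features; HHb
   is retained in `HbSeries` for diagnostics.

The classification table keeps CIT1 + CIT2 rows by default (110 rows =
55 subjects × 2 CITs); CIT3 is excluded because the hardest block floors
patient performance and its hemodynamics no longer reflect a comparable
load. Including all CITs gives 165 rows.

## Synthetic cohorts

Each channel's signal is a boxcar over the CIT blocks convolved with a
delayed double-gamma HRF (response peak 6 s, undershoot 16 s, ratio 1/6,
onset delay 5 s; kernel normalised to unit area so a long block
plateaus at its amplitude). An optional larger delay can be applied to
MHE-flagged subjects. Noise comprises cardiac pulsation at ~1.1 Hz —
generated on an 8× finer grid and decimated without anti-aliasing, so it
folds into the sampled band exactly as in a real recording — ~0.1 Hz
vasomotion, linear drift plus a slow random walk, and white noise.

Response amplitude varies at three levels: per subject (SD 2.0, shared
across channels — a global "responder" factor), per channel within
subject (SD 0.5), and per block × channel (SD 1.0). The planted group
effect adds δ × √(2.0² + 1.0²) to the CL amplitude on CH6, CH7, CH10 and
subtracts it on CH13, CH14, CH16. Because the amplitude jitters dominate
post-filter feature noise, the realised per-channel feature effect size
is ≈ δ; the default δ = 0.5 puts six-channel subsets in a mid-range MCC
regime where the search is exercised but not saturated.

Signal units are a generator convention: amplitudes are fixed so that
baseline-standardized features come out at order 0.3. With the
soft-margin penalty fixed at C = 1 across all subsets (required for
comparability), the feature scale is what places the SVM in its working
regime; below roughly a tenth of the default scale the margin term
dominates and the classifier degenerates to the majority class. The MCC
of the planted subset is flat across several-fold scale changes around
the default.

The 216-s blocks are long relative to the 0.01 Hz high-pass corner, so
the filter removes most of the sustained plateau (deterministic block
gain ≈ 0.13). This attenuates signal and amplitude jitter equally and
therefore leaves δ interpretable; it is a faithful property of applying
this band to long blocks, not an artifact.

Behavioural tables use a Gaussian copula: a per-subject latent ability
z ~ N(0,1) loads positively (default 0.6) on accuracy and digit-span
scores and negatively on reaction time and number-connection times,
reproducing the observed correlation sign structure. Marginals are
moment-matched so group means/SDs equal the configured parameters
exactly: Beta distributions for accuracy (the observed (mean, SD) pairs
— e.g. 0.75 ± 0.28 — exceed what any truncated normal on [0,1] can
reach), truncated normals on (0, ∞) for times and spans. Accuracy and RT
parameters default to the observed group statistics; NCT/DST levels are
plausible clinical values (only their correlations were reported).

What the generator does **not** emulate: motion artifacts, superficial
(scalp) hemodynamics, spatially correlated noise beyond the common-mode
amplitude factor, heteroscedastic per-channel noise, non-Gaussian
behavioural outliers. Passing tests therefore show the pipeline is
correct and the search recovers planted structure under clean
block-design assumptions — not that it would survive motion-contaminated
real recordings.

## Solver

Training is SMO on the dual with second-order working-pair selection,
an unregularized bias recovered from the KKT conditions of free support
vectors (midpoint of the feasible interval when none are free), and
libsvm-style shrinking of the selection scans; convergence on a shrunk
active set is always re-verified against the full variable set, so
shrinking changes speed, not solutions. The public training entry point
uses dual tolerance 1e-6; the search engine uses 1e-3, ample for
fold-level confusion counts. The engine works in kernel space with
per-channel Gram matrices (a subset's Gram is their sum), warm-starts
each fold's dual solution from the previous subset in size-then-
lexicographic order, and never materialises weight vectors in the hot
loop. Optimality is checked in tests against an independent brute-force
active-set enumeration on ≤ 10-point instances and against a reference
library solver on larger ones.

## Problem sizes used in the shipped checks

The acceptance script runs the bilateral search capped at subset size 6
(14,892 subsets × 100 folds) plus the full 255-subset per-hemisphere
searches on one cohort. The test suite's 20-seed recovery study uses the
per-hemisphere searches, taking the union of the right and left winners
as the selected channel set; the capped bilateral variant gives the same
verdict (≥ 4 of 6 planted channels recovered in ≥ 80% of seeds) and is
the script's single-cohort configuration. The uncapped 65,535-subset
bilateral search is supported but is a long-running batch job. These
sizes are the package's desk-scale defaults.

## Limitations

- Row-level CV lets two rows of the same subject co-occur in train and
  test; with per-subject amplitude jitter this inflates absolute MCC.
  The subject-grouped mode quantifies the effect; rankings of subsets
  are much less sensitive than absolute scores.
- C is fixed at 1 and no per-feature rescaling is applied before the
  SVM; real recordings in physical units may need a different C.
- The best-subset selection performs no multiple-comparison correction
  over the 10³–10⁴ subsets scored; top MCCs are selection-biased upward
  (the permutation-null check bounds this at ≈ ±0.1 for a single subset).
- SNIRF support is a minimal continuous-wave reader/writer (one
  source–detector pair per channel), not a full implementation of the
  standard.
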