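# Methods

## The modelling problem

Short peptides released by enzymatic hydrolysis of food or algal
proteins can scavenge free radicals, and their potency depends on which
residues sit at the chain termini. Given a small database of peptides
with measured antioxidant activity (here an ORAC-scale activity for 26
hydrolysate peptides of length 2–26), the goal is a regression that maps
sequence to activity and can rank untested candidate sequences. The
package also implements the deterministic arithmetic of the assays used
to verify such predictions in vitro and in cell culture.

## Sequence encoding

Peptides vary in length, so a fixed-length representation is imposed by
two-terminal position numbering: positions 1..k_n counted from the
N-terminus and 1..k_c counted from the C-terminus are each encoded by a
d-dimensional amino-acid property vector and concatenated in that order,
giving p = (k_n + k_c)·d features for every peptide.

Choices, all configurable via `EncodingSpec`:

* **k_n = k_c = 5 (default).** Ten encoded positions cover the shortest
  database peptide (length 2, with overlap) fully and the termini of the
  longest (length 26), and keep p = 50 modest relative to a ~17-sample
  calibration set. Two-terminal schemes conventionally window both ends.
* **Zero fill.** Positions beyond the peptide length receive 0 in every
  descriptor dimension, applied *before* autoscaling, so after column
  centring the fill is effectively a shift to the column mean. This is
  the most common convention in peptide QSAR encodings; mean-fill can be
  emulated by supplying a different `fill_value`.
* **Overlap for short peptides.** When len < k_n + k_c the two windows
  reuse residues rather than truncating; this preserves the fixed-length
  contract with no third rule.
* **Descriptor scale.** The default is the five-dimensional z-scale of
  Sandberg et al. (1998), a principal-component summary of 26 measured
  physicochemical properties (lipophilicity, steric bulk/polarisability,
  electronic and NMR-derived properties) of the coded amino acids,
  bundled as `data/scales/z5.tsv`. Any 20-row tabular scale can be
  loaded instead. Scales are validated (all 20 residues, d finite values
  each, no duplicates) and immutable after load.

A documented limitation: residues in the middle of long peptides are
invisible to the encoding by construction.

## PLS regression and validation

The activity model is single-response partial least squares fitted by
NIPALS on autoscaled data (columns of X and y centred and scaled to unit
variance on the calibration set; constant columns get scale 1 and
receive zero weight automatically). Per component: w ∝ Xᵀy normalised,
t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X and y are deflated. The
coefficient vector is back-transformed to original units, so prediction
is one affine map; nested sub-models (fewer components) are recoverable
from the same weight sequence.

* **Component count A.** Chosen to maximise leave-one-out Q², with
  A capped at min(10, n − 2, p) by default. LOO folds refit everything,
  including the autoscaling. Ties break to the smaller A. The cap and
  the criterion are standard chemometrics practice; nothing in the
  source database documents the original choice.
* **Q² = 1 − PRESS/SS_tot** with SS_tot about the calibration mean.
  Q² ≤ 1 always; negative values mean LOO prediction is worse than
  predicting the mean.
* **Split.** A random 2:1 calibration:prediction partition; the
  calibration count is round(2N/3) (17 of 26). The seed is a required,
  logged parameter, and validation claims are evaluated as distributions
  over ≥ 20 seeds, because a single random split of a 26-row database is
  not reproducible and its statistics are strongly split-dependent.
* **Acceptance rule.** `pass_flag` is R > 0.6 and Q > 0.5 on the
  correlation scale (strict inequalities); the report also exposes R²
  and Q² directly so squared-scale thresholds can be applied.
* **Numerics.** NIPALS stops early if the response residual vanishes
  (‖Xᵀy‖ < 1e-12) — extra components would be numerical noise. At full
  rank the fit coincides with OLS (tested to 1e-8), and the engine is
  cross-checked against an independent PLS implementation and against a
  literal delete-one-refit LOO loop in the test suite.

Negative activities are legal and kept untransformed; PLS needs no
positivity.

## Assay arithmetic

* **Composition.** HAA = {Ala, Val, Ile, Leu, Tyr, Phe, Pro, Met, Cys},
  NCAA = {Asp, Glu}, AAA = {Phe, Tyr}; Phe and Tyr belong to both HAA
  and AAA, so class sums may overlap and need not partition the total.
  Fractions are 100·class/grand-total with the grand total the exact sum
  of the listed residues; undetected residues (ND) count as zero.
* **ABTS.** Implemented as [1 − (As − Ac)/Ab]·100. The formula is
  sometimes typeset as 1 − [(As − Ac)/Ab] × 100, which evaluates to ≈ 1
  for no scavenging and cannot be a percentage; the bracketed form
  restores the 0%/100% boundary identities.
* **CAA.** Areas under the fluorescence–time curves are trapezoidal on
  the recorded grid (reads every 10 min within 1 h), the standard rule
  for sparse kinetic reads. CAA is invariant to rescaling both curves.
* **EC50.** Unweighted least squares through (log₁₀ dose,
  log₁₀(CAA/(100 − CAA))); EC50 = 10^(−b/m), the dose where the line
  crosses zero (CAA = 50). Doses with CAA ≤ 0 or ≥ 100 are excluded
  (the transform is undefined there; clipping would bias the line) and
  at least two usable doses are required. Log base is immaterial for the
  EC50 and fixed at 10 for reportable slopes.

## Synthetic generators

Both generators are pure functions of their spec, seed included.

* **Peptide datasets** draw sequences uniformly over the 20-letter
  alphabet with lengths uniform in [2, 26] (the database's range) and
  set activity = β·encode(seq) + ε, ε ~ N(0, noise_sd·sd(signal)), with
  default n = 60 and noise_sd = 0.1. Ground truth (β, signal, noise) is
  returned alongside the records. What this emulates is the *shape* of
  a real activity database and an exactly descriptor-linear
  structure–activity law; real activities are not linear in any fixed
  descriptor set, contain measurement error in y beyond i.i.d. Gaussian,
  and their sequences are not uniform random — so recovery tests
  demonstrate the estimator works when its assumptions hold, not that
  the assumptions hold for real peptides.
* **Fluorescence experiments** use the kinetic read schedule 0–60 min in
  10-min steps, an exponentially decaying control (F₀ = 10⁴, rate
  0.02/min), and impose the median-effect law analytically on the AUC
  ratio: the sample curve at dose D is the control scaled by
  1 − CAA(D)/100, then multiplied pointwise by unit-mean lognormal noise
  (default 2%). Because the law is imposed on the ratio, the EC50 ground
  truth is exact regardless of the control-curve shape. Defaults centre
  five two-fold-spaced doses on EC50 = 0.04 mg/mL with slope 1.5 — the
  potency scale of the strongest verified peptide — so recovery is
  tested where the assay actually operates.

## Problem sizes and design choices

Validation sweeps use 20 seeds throughout; recovery experiments use
n = 60 peptides and 5-dose curve experiments. These sizes make every
statistic a distribution rather than an anecdote while keeping the full
suite fast.

Where the analysis protocol was genuinely open, the package fixes one
documented choice rather than many silent ones: the z5 default scale,
k = 5 + 5 zero-filled windows, Q²-maximising component selection, and
seed-parameterised splits. On the bundled 26-peptide database this
protocol yields split-dependent validation statistics (median
calibration R² ≈ 0.7 and median LOO Q² < 0 over 20 seeds, while a
full-data high-component fit approaches R² ≈ 1): small homologous
peptide databases simply do not cross-validate stably, which is the
reason the package reports distributions over seeds and flags the
R > 0.6 / Q > 0.5 rule per split instead of quoting one split's numbers.

## Known limitations

* Only the 20 standard residues; no modified amino acids, no
  three-letter sequence parsing, no structure-based descriptors.
* Middle residues of long peptides do not enter the encoding.
* No variable selection, applicability-domain analysis, or
  y-randomisation beyond the property tests.
* The EC50 fit is the classical two-parameter median-effect
  linearisation; no four-parameter logistic alternative.
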