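# Methods

## Problem setting and model

The package classifies pharmacogenomic missense variants as
*deleterious* (reduced gene-product function — decreased- or
loss-of-function clinical annotation, or measured intrinsic clearance
below 50% of wild type) versus *functionally neutral*, and quantifies
the expected magnitude of the effect. "Deleterious" here is a
functional notion, deliberately distinct from disease pathogenicity:
predictors trained on pathogenic/benign labels systematically
mis-handle common, weakly conserved pharmacogene variants, which is the
motivation for re-parametrizing and ensembling them.

The pipeline has four statistical stages.

### 1. Benchmarking with explicit missingness

For each predictor, raw scores are thresholded at the predictor's
conventional published cutoff, honouring the printed comparison
operator exactly (SIFT ≤ 0.05 is inclusive, CADD > 15 exclusive, and so
on — boundary scores are classified accordingly). Confusion counts are
accumulated over the variants the predictor actually scored; unscored
variants enter only the missingness count and percentage. No imputation
is performed anywhere: a predictor with high accuracy on 50% coverage
is reported as exactly that. Ratios with an empty denominator are
UNDEFINED (`None`, JSON `null`), never zero, so empty classes cannot
silently inflate a metric.

ROC curves are oriented by each predictor's deleterious direction (the
curve sweeps "more deleterious" thresholds), computed via
scikit-learn's `roc_curve` without intermediate-point dropping, and AUC
is the trapezoidal area — equal to the Mann-Whitney pairwise
concordance probability with ties counted ½. The test suite verifies
this equality against an independent exhaustive pair-counting oracle.

The built-in registry carries one entry per benchmarked predictor
release (29 entries covering 28 distinct algorithms — VEST ships in two
scored versions, VEST3 and VEST4, under the shared family `VEST`), each
with its direction, operator strictness and conventional cutoff.

### 2. Youden-J threshold re-parametrization

For a cutoff `t`, informedness is `J(t) = SEN(t) + SPE(t) − 1`. The
candidate grid consists of the midpoints between consecutive distinct
observed scores plus one candidate a half-gap beyond each extreme —
`n` distinct scores give `n + 1` candidates, covering every partition a
threshold can induce while never colliding with an observed score (so
operator strictness cannot flip a fitted result). The optimizer
evaluates all candidates by vectorized binary search and returns the
argmax; ties in J are broken toward higher specificity (false-positive
calls carry the larger clinical cost in dose-adjustment settings), then
toward the smallest candidate, making the result deterministic. By
construction the optimized J on the fitting data is at least the J at
the conventional cutoff.

Cross-validation uses a hand-rolled label-stratified k-fold partition
(greedy deal of each shuffled class into the currently smallest fold):
unlike off-the-shelf stratified splitters, this guarantees overall fold
sizes differ by at most one while keeping per-class counts balanced,
and is reproducible from an explicit seed. Per fold, the cutoff is
fitted on the other k−1 folds and ΔJ (optimized minus conventional) is
evaluated on both the training portion and the held-out fold; held-out
ΔJ may legitimately be negative. The final reported cutoff is refit on
the full set — cross-validation exists to report the generalization of
the gain, not to average thresholds.

### 3. Weighted binary-vote ensemble

The shipped model aggregates five re-parametrized components
(AlphaMissense ≥ 0.152, PROVEAN < −3.2925, MutationAssessor > 2.08,
PolyPhen-2 > 0.42, VEST4 > 0.2905). Each available component casts a
binary vote `v_i ∈ {0, 1}` (1 = functional); the score is
`Σ w_i v_i` with weights renormalized over the available components,
so it always lies in [0, 1] and is monotone in every vote. Scores at or
below the fixed cutoff 0.367 are classified deleterious; the cutoff is
a stored constant of the shipped model, not re-derived at fit time
(refits may recompute it as the J-optimal cutoff on ensemble scores).

Two genuinely open design points are resolved as follows and recorded
in the serialized model:

* **Weighting.** Weights are proportional to each component's
  cross-validated mean validation-fold J (the same objective the
  thresholds optimize, measured where it generalizes), normalized to
  sum to one. `uniform` and user-supplied schemes are also available.
  The shipped default model uses the components' combined-set optimized
  J values (0.46, 0.44, 0.38, 0.42, 0.37) as fixed constants.
* **Vote encoding.** Binary thresholded votes rather than rescaled
  continuous scores, because components are individually re-calibrated
  cutoffs; the orientation (1 = functional, deleterious at *low*
  scores) makes the score correlate positively with residual enzyme
  activity. A continuous encoding was considered and rejected for the
  default because component scores live on incommensurable scales.

`min_components = 3` of 5: a call with a minority of components is
withheld as NO_CALL rather than scored — tolerant of partial
missingness (a third of AlphaMissense predictions can be absent)
without letting one or two tools masquerade as an ensemble.

### 4. Activity regression and population aggregation

Ensemble scores are binned into 7 equal-width bins over [0, 1]
(configurable, recorded with the fitted map); ordinary least squares of
bin-mean activity on bin midpoint gives slope, intercept, R² and the
two-sided p-value of the slope (scipy `linregress`). At least 3
non-empty bins are required. Predictions are clamped to [0, max
activity observed at fit time]. Binning stabilizes the regression
against the coarse, clumped distribution of a 5-component vote score;
the regression is unweighted by bin occupancy.

Population aggregation assumes Hardy-Weinberg equilibrium and
independence across sites and genes (linkage is ignored — a stated
limitation; no genotype data are used). For deleterious allele
frequencies `p_v`:

* expected variants per individual: `Σ_v 2 p_v` (the only reading of
  "aggregating variant frequencies" that yields a per-individual
  *count* without genotypes; the carrier probability
  `1 − Π_v (1 − p_v)²` is emitted alongside);
* rare/common split at MAF 1%: rare is strictly `p < 0.01`, the
  boundary counts as common; fractions are of the `Σ 2p` burden;
* per-drug risk: per rule gene, `q = 1 − Π_v (1 − p_v)`; an
  any-variant-allele trigger yields `1 − (1 − q)²`, a
  two-variant-alleles trigger `q²`; multi-gene rules combine
  independently as `1 − Π_g (1 − f_g)`; reported ×1000.

Actionability is expressed as small, auditable JSON rules
(drug, genes, trigger) rather than a hard-coded guideline engine, since
diplotype-level guideline logic is gene- and drug-specific and should
be user-visible. Both trigger types are supported because published
dose-adjustment guidance mixes dominant-style (any allele) and
recessive-style (two alleles) criteria.

## Synthetic data: what it emulates and what it does not

`simulate_labeled_scores` draws a combined fitting set of 530 variants
(285 deleterious / 245 neutral — the ~54% deleterious prevalence
consistent with the balanced accuracy figures of the benchmarked
predictors), of which 145 carry consortium-style labels without
activity and 385 carry in-vitro activities consistent with their label
(deleterious < 50% of wild type). Each of the five components draws
class-conditional Gaussian scores on its native scale, tuned to
analytic AUCs of about 0.74–0.80 — the observed performance band —
with the observed missing-prediction rates (33%, 4%, 22%, 25%, 1%)
injected completely at random. Gaussians are the default because they
admit closed-form oracles used throughout the tests: the analytic AUC
`Φ(Δμ / √(σ₁² + σ₂²))` and the density-intersection optimal threshold
(midpoint of means for equal scales; for unequal scales the root of the
quadratic log-density equation lying between the means, which is the
large-n limit of the J-optimal cutoff for equal class sizes). A
heavy-tailed Student-t option stresses tie-breaking.

`simulate_frequency_table` draws per-population allele frequencies as
a mixture of rare (log-uniform below 1%) and common (log-uniform in
[1%, 50%]) variants at a configurable rare proportion (default 90%).

What the generator does **not** emulate: correlation between predictor
scores (real tools share training data and features, so real ensembles
gain less than independent-noise simulations suggest), informative
missingness, per-gene score idiosyncrasies, realistic mutation spectra,
and linkage between variants. Passing tests therefore demonstrate the
correctness and calibration of the machinery — metric identities,
oracle equivalence of the optimizer, parameter recovery, HWE closed
forms — not field performance on real pharmacogenomic data, which
requires externally computed predictor scores.

## Numerical choices

* Missing scores are `NaN` in memory, `.` or empty on disk; never a
  sentinel number.
* J ties are compared with a 1e-12 absolute tolerance (counts are
  ratios of small integers; genuinely equal values are exactly equal).
* AUC ties contribute ½ (Mann-Whitney convention).
* The empirical J-argmax has cube-root-rate sampling noise proportional
  to the score scale, so parameter-recovery checks assert the mean
  fitted threshold over seeded replicates (20 × 10⁴ variants per class)
  against the analytic optimum at 0.05 absolute tolerance, with a
  per-draw sanity bound of a quarter score-scale.
* Degenerate inputs: single-class label sets raise for ROC and
  threshold fitting; a single distinct score yields two candidates at
  ±0.5; folds that lose a class to missingness report zero ΔJ rather
  than failing; empty-denominator metrics are UNDEFINED.
* `scripts/acceptance.py` and all simulations derive every random
  stream from the single `--seed`/config seed (kept below 2³¹).

## Problem sizes

The default test suite and the acceptance script run at the study-scale
defaults (530-variant fitting set, 146-variant test set, 600-variant
frequency table per population) plus 10⁴-per-class draws for oracle
recovery and 5000-variant null-calibration checks; the whole suite
completes in well under a minute of CPU apart from the replicated
recovery test (~20 s).

## Known limitations

* Gain-of-function, substrate-specific, combinatorial-haplotype and
  non-missense effects are out of scope by construction of a
  single-score missense ensemble.
* Scores for the component predictors are inputs; the package does not
  run AlphaMissense/ANNOVAR annotation, liftover or transcript
  collapsing (multi-transcript variants must be pre-collapsed).
* Population figures inherit the HWE-plus-independence assumptions and
  treat the deleterious set as fixed and error-free.
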