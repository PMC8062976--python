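# Methods

## Problem and model

oral2gut regresses a person's stool microbiome composition, summarized as 12
bacterial families plus a residual "Other" category (13 features, percent,
closed to 100), on their oral microbiome profile at the genus level. The
predictor is a small fully-connected feed-forward network:

    input (retained genera, standardized)
      → dense 50, ReLU, dropout
      → dense 50, ReLU, dropout
      → dense 13, linear (no activation)

The loss is mean squared error on the percent scale plus an L2 penalty on
all weight matrices; mean absolute error (percentage points per feature) is
the monitoring metric. Optimization is Adam on shuffled mini-batches.
Because the output layer is linear, raw predictions are unconstrained; a
post-processing step sets negatives to zero and rescales each sample to sum
to 100%, which is what turns the regression into a composition.

The stopping epoch is selected by k-fold cross-validation: the training set
is partitioned into k shuffled folds, each fold serves once as validation,
the validation MAE is recorded after every epoch, and the fold-averaged
curve's earliest argmin is taken as the best epoch. The final model is then
refitted on all training samples for exactly that many epochs. This refit
protocol uses all data while keeping the epoch choice honest.

A final training-set calibration handles families the network systematically
over- or under-estimates: for each family the mean signed training error is
compared against a fraction (default 0.25) of that family's training
standard deviation; flagged families receive a multiplicative factor
`mean(true) / mean(pred)`, all others keep factor 1, and corrected rows are
re-closed to 100%. A multiplicative mean-matching rule was chosen because it
is training-data-only, serializes with the model as 13 scalars, and cannot
produce negative abundances. A binned-misclassification variant would be a
legitimate alternative realization; the correction sits behind its own
estimate/apply interface so it can be swapped.

## Preprocessing

* **Genus filter.** A genus is retained iff its relative abundance exceeds
  `min_abundance` (default 0.001, i.e. 0.1%) in strictly more than
  `min_samples` (default 4) samples. Both inequalities are strict. The
  filter is monotone: raising either threshold never enlarges the set.
* **Standardization.** Each retained genus is centered on its training mean
  and divided by its training standard deviation, computed with the n−1
  (sample) denominator. Zero-variance genera map to 0 rather than erroring,
  so constant features are inert. Numerically, fitted standard deviations at
  or below 1e−12 are snapped to exact zero so float dust in constant columns
  cannot explode the z-scores.
* **Missing genera.** A new table (typically a partial/ancient profile) may
  lack model genera; they are imputed as zero abundance before
  standardization and listed in a warning. Zero is the minimal-assumption
  choice: absence of evidence is treated as absence, and the warning makes
  the imputation auditable.
* **Targets.** The 12-family schema is fixed by default (the list in the
  README, in that order). `Other = 100 − Σ families`, clamped at 0. For
  retraining on a new cohort the schema can instead be re-derived as the k
  families with the largest median relative abundance (ties broken by input
  order).
* **Input sums.** Oral tables may sum to less than 1 per sample (unassigned
  reads); they are not renormalized at read time, since standardization
  makes the network insensitive to a consistent shortfall.

## Default hyperparameters

| parameter | default | notes |
|---|---|---|
| hidden sizes | 50, 50 | fixed architecture; configurable for experiments |
| dropout rate | 0.5 | on both hidden layers only |
| L2 coefficient | 0.001 | per-entry squared-weight penalty |
| epochs | 500 | CV horizon; best epoch ≤ 500 |
| k folds | 4 | shuffled, seeded |
| learning rate | 0.001 | Adam |
| batch size | 16 | |
| genus filter | >4 samples, >0.1% | strict inequalities |
| bias flag threshold | 0.25 × family sd | |
| train fraction | 0.8 | subject-level disjoint split |

All randomness — weight initialization, batch shuffling, dropout masks, fold
assignment, subject splits, mock draws, simulation — is a pure function of
the integer seeds in the corresponding configs; identical seeds give
bit-identical bundles, predictions and cohorts.

## Evaluation metrics

* **maes** (per family): mean absolute error divided by the sample standard
  deviation of the *real* data; the mean over families summarizes a run.
  maes < 1 means the prediction error is smaller than the natural spread of
  the truth. Families with zero real-data sd have an undefined entry,
  flagged and excluded from the mean. maes is invariant under jointly
  scaling predictions and truth by a positive constant.
* **Per-sample Spearman quality bins**: Spearman r (average-rank ties) over
  the 13 paired features, binned with right-closed boundaries — excellent
  (r > 0.8), good (0.7 < r ≤ 0.8), discrete (0.4 < r ≤ 0.7), incorrect
  (r ≤ 0.4). Boundaries are contiguous on the unrounded r; a constant
  profile has undefined r and is conservatively binned incorrect with a
  warning. All 13 features (including "Other") enter the correlation.
* **Family-wise rank-sum comparison**: two-sided unpaired Wilcoxon /
  Mann-Whitney per family between two groups of compositions (exact for
  small tie-free groups, normal approximation with tie correction
  otherwise; a family constant and identical across groups gets p = 1). No
  multiple-testing correction is applied; reports say so.

## Baselines

* **Random Forest**: one regression forest per family (500 trees, library
  default split rules; a single multi-output forest is available behind a
  flag) on the same standardized features and percent targets, predictions
  closed by the same clip-and-rescale (no bias correction).
* **Stochastic mock profiles**: each family drawn uniformly within its
  per-family [min, max] observed in the training stool table, independently
  per sample and family, then closed to a composition. Uniform is the
  minimal assumption for "within the training range"; the draw is a floor
  any informative predictor must beat.

## The paired-cohort simulator

Real paired oral/stool cohorts require controlled-access downloads and
upstream read processing, so the package ships a generative stand-in with a
*known* shared structure. Each subject has a latent state z ~ N(0, I) of
dimension 5 (default). Oral genus and stool family log-intensities are
linear readouts of the same z — `coupling · A z + a0` and
`coupling · B z + b0` — plus independent Gaussian log-scale noise (default
sd 0.3 on both sides), pushed through a softmax (× 100 on the stool side).
`coupling` (default 2) scales the shared signal: 0 makes the niches
independent; increasing it makes the oral table increasingly informative.

Loading and intercept scales (A ~ N(0, 0.35), B ~ N(0, 0.25),
a0 ~ N(0, 1.75), b0 ~ N(0, 1.25)) are calibrated for compositional realism:
at the default coupling the per-taxon logit sd is ~1.6 (oral) / ~1.1
(stool), taxon mean shares span roughly 0.5–25%, and the median top-family
share is ~38% — persistent dominant taxa rather than winner-takes-all rows.
A fraction of genera (default 30%) is made sporadically present, with
per-genus presence probabilities spanning ~0.005–0.6, so prevalence varies
and some genera genuinely fail the default filter, exercising both the
filter and the zero-imputation path. Genus labels mix real oral genera
(rendered as full Greengenes paths) with synthetic placeholders so parsers
see realistic strings.

The simulator emulates: compositional closure, dominance structure, a
tunable cross-niche dependence, sporadic prevalence, and (via
`degrade_to_ancient`, which randomly drops whole genus rows without
renormalizing) partial ancient-style inputs. It does **not** emulate
sequencing depth or read-level noise, phylogenetic correlation between
taxa, population structure across cohorts, or ancient-DNA damage.
Consequently, passing recovery tests show the pipeline's machinery is
correct and can extract a genuine cross-niche signal at realistic
compositional scales — they do not certify performance on real cohorts.

Reference study conditions (the defaults): 380 subjects, 60 genera,
12 + 1 families, coupling 2, noise sd 0.3, split 300/80 at the subject
level. These sizes keep a full end-to-end run (4-fold CV × 500 epochs plus
baselines) around a minute on one CPU.

## Numerical and degenerate-input choices

* Closure snaps the float residue of each row into the last ("Other")
  column so row sums are exactly 100 to tolerance 1e−6; clip-and-rescale is
  idempotent and preserves the ranking of strictly positive entries.
* A prediction row with no positive entry cannot be rescaled; it falls back
  to the uniform composition (100/13 each) with a warning instead of
  failing the batch.
* Best-epoch ties resolve to the earliest epoch; the CV curve is used raw
  (no smoothing).
* Taxonomy parsing normalizes whitespace around `;`, requires canonical
  prefix order (k, p, c, o, f, g), and keeps genus-unresolved rows under a
  synthetic `unclassified:<deepest rank>` label so they stay addressable.
* Model bundles are plain text: a JSON manifest (config, retained genera,
  scaler statistics, schema, best epoch, bias factors, tool version), JSON
  weights, and the CV curve as TSV. Manifests are key-sorted so determinism
  can be checked at the file level.

## Known limitations

* The network's advantage over Random Forest is regime-dependent. Under the
  simulator's reference conditions — a smooth, low-dimensional latent map
  with moderate noise — the Random Forest baseline is extremely strong and
  can reach a lower mean maes than the dropout-regularized network (the
  acceptance script reports both, computed on the same split). The
  network's edge on real cross-niche data, which is noisier and more
  heterogeneous than this generator class, is not reproduced at desk scale.
* The bias correction is a mean-matching heuristic; it provably reduces the
  flagged family's mean signed training error but is not guaranteed to help
  on covariate-shifted inputs.
* Quality-bin boundaries are a convention on unrounded r; samples near a
  boundary are sensitive to tie handling.
* The predictor assumes the input taxonomy is Greengenes-compatible at the
  genus level; no name translation between reference databases is
  attempted.
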