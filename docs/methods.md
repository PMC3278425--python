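# Methods

`stratcorr` implements three ways of removing nuisance-covariate
variability from tabular biomarker data before two-group classification,
plus the machinery needed to compare them fairly. This note records the
models, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## The problem

A classification feature `c` (a regional brain volume, a cognitive test
score) depends not only on disease status but on nuisance features
`s_1..s_k` (age, gender, education, ...). Left in place, this variability
widens the within-group distributions and erodes the separation between
study groups. The package assumes a *reference group* — subjects free of
disease-related variability, typically healthy controls — is available,
possibly outside the pair of groups being discriminated.

## Regression correction

For each classification feature, an ordinary least-squares regression on
the chosen nuisance features is fitted **on the reference group only**:

    c_i(n) = a_i1 s_1(n) + ... + a_ik s_k(n) + b_i + e(n),

and the fitted effect, intercept included, is subtracted from **all**
subjects of all groups:

    c_i'(n) = c_i(n) - (a_i · s(n) + b_i).

Because OLS residuals average to zero, the corrected reference-group
values of every feature have exactly zero mean; the package keeps the
values as residuals rather than re-adding the reference mean, since the
downstream classifier is translation-invariant and the zero-mean identity
then becomes directly testable.

Choices:

* **Multiple nuisances** are handled by one joint multiple regression per
  feature (intercept + one coefficient per nuisance), not by sequential
  single-nuisance corrections. Joint OLS is order-independent and matches
  the ANCOVA adjustment this method descends from; the two coincide
  exactly when the nuisances are uncorrelated in the reference sample.
* **Complete-case fitting**: reference subjects missing the feature or any
  involved nuisance are dropped from that feature's fit, so no imputed
  value can bias the slopes. The per-feature fit requires at least
  `k + 2` complete cases and every nuisance to vary in the reference group.
* **Binary/ordinal nuisances** (gender, smoking) enter as numeric 0/1 or
  integer regressors.
* A subject with a missing nuisance value receives a missing corrected
  value; imputation happens later, at classification time, from training
  data only.
* In cross-validation the model is always fitted on the training split's
  reference subjects and applied unchanged to the test split, so held-out
  subjects never influence the fit.

## Stratification

For a target subject `n`, the training set is restricted to subjects `m`
with

    |s_j(m) - s_j(n)| <= th_j   for every used nuisance j,

with `th_j = alpha * std(s_j)` computed over the whole dataset
(sample standard deviation, `n-1` denominator). `alpha` defaults to 1.
Boundary ties are included (the rule is `<=`). A fresh classifier is
trained on the selected subset for each test subject.

* **Thresholds are global scale parameters.** They are computed once from
  the whole dataset, not per CV training split, mirroring the method's
  definition; the target's own nuisance values enter only through the
  window centre, never the width.
* **Small-sample fallback**: if after selection *either* study group has
  fewer than `min_group_size` subjects (default 10), the full training set
  is used — a classifier needs both groups populated. The alternative
  reading (fall back only when *both* groups are small) is available via
  `fallback="both"`.
* Non-ordered categorical nuisances are not supported in the rule; binary
  features must be 0/1-coded (for a balanced binary nuisance the default
  threshold is below 1, so only same-category subjects are kept).

## Combination

Stratify first, then correct the selected subset — but the regression
model is fitted on the **full** training set's reference group, not the
stratified subset. Stratified reference samples can be too small for
stable slope estimates, and under the linearity assumption the same
coefficients apply in every stratum. The target subject's own features are
corrected with the same model before prediction.

## Classifier stack

1. **Pre-selection.** A feature is dropped if more than 10% of its values
   are missing or if a two-sided, pooled-variance two-sample t-test
   between the study groups exceeds a p-threshold (suggested 1e-5 for an
   easy pair, 0.01 for a hard one; Welch variant available). Pre-selection
   is run once on the full dataset, not per CV split — a deliberate,
   documented optimistic-bias choice that keeps the retained feature set
   fixed across all method comparisons.
2. **Imputation.** Remaining missing values are filled with training-set
   column means (never test-set information).
3. **SMOTE.** The minority study group is oversampled to parity: each
   synthetic sample is `x + u (x_nn - x)` for a random minority subject
   `x`, one of its `k = 5` nearest minority neighbours `x_nn` (Euclidean
   distance on the imputed feature block) and `u ~ U(0,1)`. Balancing
   happens inside the training set only, after correction/stratification
   and before feature selection.
4. **Stepwise selection.** From the empty model, the candidate with the
   smallest partial-F p-value is added while below `p_enter = 0.05`; then
   the included feature with the largest partial-F p-value is removed if
   above `p_remove = 0.10` (one removal per iteration, largest first),
   until a fixed point. Constant and collinear candidates are skipped; a
   residual-sum-of-squares floor of 1e-12 guards the F denominator on
   perfectly separable toys.
5. **Regression classifier.** OLS of the 0/1 class indicator on the
   selected features; predict class 1 when the score is >= 0.5 (ties to
   class 1). With SMOTE balance, 0.5 equals the balanced prior. If nothing
   is selected the classifier degrades to intercept-only and predicts a
   constant (logged).

## Evaluation harness

* Repeated leave-N-out CV: 90% train / 10% test, drawn at random from the
  pair-eligible subjects (default 100 repeats; the synthetic benchmarks in
  this repository use 20 to keep runtimes in seconds-to-minutes at 300
  subjects per group). The identical splits are reused for every method
  and nuisance subset, so per-repeat accuracies are positionally paired.
  Out-of-pair subjects (e.g. controls in a stable-vs-progressive MCI
  comparison) join every training set and are never classified.
* Accuracy is the fraction of test subjects assigned the true label.
* Method comparison uses a two-sided paired t-test on per-repeat accuracy
  differences at p < 0.05. Repeated-CV accuracies are not independent, so
  this test's nominal level is approximate; it is reported as defined. A
  zero-variance difference vector leaves p undefined (NaN), never 0 or 1.
* The nuisance-subset search enumerates all `2^k - 1` non-empty subsets
  (guarded at k <= 12) per method on the shared plan and reports the best
  subset per method and the best accuracy per subset size.
* Stratification retrains one classifier per test subject per repeat;
  classifiers are cached per repeat by the identity of the stratified
  subset, which cannot change results because training is deterministic
  given the subset and the per-repeat seed.
* Classifier randomness (SMOTE draws) derives from a per-repeat seed
  sequence, so method runs are reproducible bit-for-bit and the reduction
  identities (empty-subset correction == original; alpha -> infinity
  stratification == original) hold exactly.

## Synthetic data

The generators produce the four canonical nuisance-feature interaction
types plus an age/gender hippocampal-volume scenario; all noise is
Gaussian, group labels are `A`/`B` with an optional disease-free `REF`
group drawn like `A`.

* Type 0: no relation (`c = shift·1[B] + e`); neither method should help.
* Type 1: group label drawn with log-odds of `B` linear in `s`; `c`
  independent of `s` within groups. Such a nuisance is really a
  classification feature and must not be corrected or stratified on.
* Type 2: `c = slope·s + shift·1[B] + e`, identical slope in both groups —
  exactly the structure regression correction removes.
* Type 3: reference and `A` flat in `s`; `B`'s shift grows linearly from 0
  at the bottom of the nuisance range to its maximum at the top. The
  reference fit learns nothing (slope 0 by construction), isolating the
  mechanism only stratification can exploit.

No canonical numeric parameters exist for these schematic types, so the
defaults are this package's calibration, chosen once: nuisance `s1`
uniform on [55, 90] (age-like), `noise_sd = 1` as the unit of the group
shift, `group_separation = 1.5`, and Type-2 `slope = 0.1` so the nuisance
effect `slope·std(s) ≈ 1.0` within-group noise SD. This places unadjusted
Type-2 accuracy near 0.70–0.80 with measurable headroom. Type-3
experiments use `group_separation = 3` so the top-of-range separation is
large while the pooled relation between `c` and `s` in the reference group
stays null. The hippocampal scenario uses mm³-scale magnitudes (baseline
4200, −25/yr age slope, −350 gender offset, −700 disease shift, noise SD
450) resembling published atrophy effect sizes.

What the generators do **not** emulate: real marginal distributions of
clinical variables, correlated nuisances, non-linear trends, informative
missingness, or measurement floors/ceilings of test scores. Passing
benchmarks therefore demonstrate that each method removes the interaction
structure it targets under its own assumptions — not that the same gains
transfer to any particular clinical dataset.

## Benchmark sizes and tolerances

The repository's end-to-end checks run 20-repeat CV at 300 subjects per
group, 20 replicate experiments for the Type-2 ordering, 200 replicates
for OLS parameter recovery and 100 random toys for the stratification
brute-force audit — sizes at which every comparison resolves in seconds to
a few minutes on one CPU. "Within Monte-Carlo error" for paired accuracy
comparisons means within three standard errors of the paired per-repeat
difference. Exact identities (zero reference mean, reduction identities)
are asserted at 1e-10 or bit-for-bit.

## Known limitations

* Correction assumes linearity of the nuisance effect and suits continuous
  features; large corrections are needed to flip a binary/ordinal feature.
* Stratification trades nuisance homogeneity against training-set size;
  with many nuisances the fallback fires often and the method degrades
  toward the original classifier.
* The interaction type is assumed known (or irrelevant); detecting types
  from data is out of scope.
* Pre-selection outside CV and the paired t-test on repeated-CV folds are
  replicated design choices with known optimistic bias, kept for
  comparability and flagged here.
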