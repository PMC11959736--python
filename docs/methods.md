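# Methods

## The quantity being measured

A random forest trained twice on identical data with different seeds gives
different outputs; `foreststab` treats the *R* repeated runs as raters
scoring the same subjects and quantifies their agreement.

For a **metric response**, the *n*<sub>test</sub> × *R* prediction matrix is
scored with the intraclass correlation ICC(1,1): the one-way random-effects,
single-measures form, computed from explicit sums of squares,

    MSB = R · Σᵢ (m̄ᵢ − m̄)² / (n − 1)
    MSW = Σᵢⱼ (mᵢⱼ − m̄ᵢ)² / (n (R − 1))
    ICC(1,1) = (MSB − MSW) / (MSB + (R − 1) · MSW)

rather than from a fitted mixed model, so the single-measures definition is
guaranteed and the statistic is exact at perfect agreement. For a
**categorical response** the statistic is Fleiss' κ over the class labels.
Variable-importance stability is the ICC(1,1) of the *p* × *R* importance
matrix (importances are continuous regardless of the task). Selection
stability is Fleiss' κ over the binary matrix obtained by marking, in each
repetition, the top k = round(α·n) subjects (k ≥ 1; ties broken by subject
index — random tie-breaking would inject artificial instability into the
very quantity being measured). Defaults: α = 0.15 for individuals with
criterion `high` (also `low`, `zero` = closest to zero, or an explicit class
set for categorical predictions), α = 0.05 for variables (always
highest-importance).

Degenerate matrices — all cells identical (ICC), or one single category
everywhere (κ) — raise a typed `UndefinedStabilityError` instead of
returning NaN, so the trial runner can flag "stability undefined at t trees"
per grid point; a curve needs at least 3 defined points to be modelled.
Subjects with a missing repetition (possible in out-of-bag mode) are dropped
from the ratings matrix with a logged count; the alternative (imputing them)
would mix prediction error into an agreement statistic.

## The forest backend

scikit-learn's `RandomForestRegressor`/`Classifier` stand behind the
`ForestSpec`/`fit_forest` contract. Bootstrap is with replacement at sample
fraction 1.0, so each individual is out of bag for a fraction → e⁻¹ ≈ 0.368
of trees. Split-candidate and node-size defaults follow the conventions of
the forest implementations used in quantitative genetics — regression:
p/3 candidate variables, minimum leaf 5; classification: √p and 1 — not
scikit-learn's legacy regression default of considering all p variables,
which is both atypical for high-dimensional marker data and needlessly slow.
All passthroughs (`max_features`, `min_node_size`, `sample_fraction`) remain
settable; tuning them is out of scope here.

Out-of-bag predictions use the per-tree in-bag records
(`estimators_samples_`): the mean (regression) or modal class
(classification, ties to the first class in sorted order) over the trees
that did not see the individual. Individuals in-bag for every tree get a
missing entry plus a warning, not an error.

**Importance.** Default is permutation importance — the standard
recommendation when split-selection bias matters — computed as the drop in
forest-level score (negative MSE, or accuracy) on the training data when one
variable's column is permuted once; the permutation RNG derives from the
forest seed, so importances are bit-reproducible. The evaluation is
vectorised by stacking permuted copies of X and predicting in bounded-memory
chunks; a naive per-feature loop with the identical draws is the test
oracle. Mean-decrease-in-impurity is available via
`importance_kind="impurity"`. A single permutation round (rather than
averaging several) deliberately leaves the estimator noisy — run-to-run
spread of the importance vector is exactly the signal being measured.

## Seeding and reproducibility

Repetition r at grid position g uses seed (base_seed + g·R + r) mod 2³¹.
A stability curve is therefore a pure function of (data, config); grid
points can be reproduced in isolation, and the end-to-end tests assert
bit-identical curves on repeated runs.

## The 2PL stability model

Measured points (t_j, s_j) are fitted with ŝ(t) = 1/(1 + (θ₁/t)^θ₂):
a logistic in log t rising from 0 to the natural asymptote 1 of the
agreement statistics; θ₁ is the tree count at ŝ = 0.5, θ₂ the slope there.
Fitting is Levenberg–Marquardt least squares on the log-parameterisation
(ln θ₁, ln θ₂), which keeps both parameters positive without bounded
optimisation. Initial values come from the closed-form linearisation
logit(s) = θ₂ (ln t − ln θ₁): an OLS line through (ln t, logit s) is robust
even for s near 1. Residuals are unweighted by default (a `weights` option
exists). Points with s ≤ 0 carry no information under the model and are
excluded with a warning; s ≥ 1 is clipped just below 1. A fit whose usable
stabilities have no spread cannot identify θ₁ and is flagged `degenerate_`.

**Recommendation.** Scanning t = 10, 20, …, 10 000 000, the recommendation
is the first t at which ŝ(t+10) − ŝ(t) ≤ `rec_thresh` (default 10⁻⁶),
rounded **up** to the next multiple of 1 000 — the granularity at which
such recommendations are meaningfully quoted; the rounding is a `round_to`
option. If the threshold is never met the upper interval end is returned
with a saturation flag. The scan is vectorised in chunks; the test oracle is
a literal 10-step loop. For curves with θ₂ > 1 the gain is small near t = 10
as well, so "first qualifying t" is a definition, not merely an
implementation detail; it is applied consistently in scan and oracle.
`estimate_numtrees` inverts the curve in closed form,
t = θ₁ (1/s* − 1)^(−1/θ₂) (ceiled); `estimate_runtime` extrapolates the
per-forest wall time linearly in t (slope clamped ≥ 0), which matches how
ensemble training cost scales.

The recommendation basis is the prediction stability for the prediction
workflow and the importance stability for the importance workflow; passing
`basis="selection"` fits a separate 2PL to the selection-stability column
and recommends from that.

## Synthetic data

`SimSpec` emulates genomic-selection data: p independent SNPs with
per-marker allele frequencies uniform on a MAF range (default 0.05–0.5),
genotypes Binomial(2, f) per individual, and an additive phenotype
y = Σ β_q g_q + ε. Architectures: `few_strong` (5 QTLs), `many_weak`
(p/4 QTLs), `null` (no signal); effects have equal magnitude and random
sign, which keeps the realised heritability controllable: ε is scaled so
var(genetic)/var(total) equals h² (default 0.5) in the generated sample.
Classification thresholds y at a quantile into "low"/"high".

Deliberate omissions: no linkage disequilibrium, population structure,
dominance or epistasis. The mechanism under study — sampling noise of the
forest itself — does not depend on them, so passing tests demonstrate the
stability machinery, not robustness to confounding in real data.

## Problem sizes used by the test suite

The desk-scale end-to-end checks run n = 120 training individuals
(40 test), p = 600 markers, tree grid 50/100/200/400/800, R = 5
repetitions, 5 replicate curves per workflow; the mechanism comparisons
(architecture effect, sample-size effect) use p = 240 with
grid 25/50/100/200/400, R = 4, n = 60–150, 5 replicates — sizes chosen so
the full suite runs comfortably on a laptop while the qualitative effects
(stability non-decreasing in t, many-weak ≥ few-strong recommendations,
larger n → fewer trees) are reproducible in the replicate means.
Single replicate curves can and do wiggle; only means are asserted.

## Known limitations

- Real genomic data recommendations (tens to hundreds of thousands of
  trees) require forest sizes far beyond the desk-scale grids exercised
  here; the extrapolation is validated on model-generated data.
- Missing genotypes are mean-imputed per column after filtering; k-nearest-
  neighbour imputation, common in genomic QC pipelines, is intentionally
  left to upstream tools — supply pre-imputed data for parity with such
  pipelines.
- Out-of-bag mode with very small forests can drop many subjects
  (never-OOB), shrinking the ratings matrix; warnings report the counts.
- The permutation importance is evaluated on the training data; its
  absolute scale is optimistic, but the stability of the estimates — the
  quantity modelled — is unaffected by that bias.
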