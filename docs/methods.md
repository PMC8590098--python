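# Methods

## What the package models

Epigenetic clocks are sparse linear predictors of chronological age built
from DNA methylation beta values (methylated / total signal, in [0, 1]) at
CpG loci. On large multi-tissue array compendia they raise questions this
package is built to probe with fully known ground truth: how many distinct
loci carry age information (iterative knockout), whether clock sites
transfer across tissues and across age ranges, whether age effects interact
with tissue, what trajectory shapes the loci follow, which genomic features
clock sites occupy, and whether "age acceleration" (predicted minus
chronological age) separates planted disease groups.

Because every analysis here runs on simulated cohorts, each recovery claim
is checked against a planted truth table rather than against an external
dataset.

## The cohort simulator

Each locus gets a baseline beta drawn from a low/intermediate/high mixture
(0.05–0.20, 0.35–0.65, 0.80–0.95), reproducing the bimodal marginal
distribution of array betas. A planted mean structure is added per locus
class, the mean is clipped to (0, 1), and Gaussian noise is added on the
logit scale with a per-locus scale of `noise_sd / (m0 (1 - m0))`, so that
the beta-scale residual spread near the baseline is about `noise_sd` while
values respect [0, 1] without hard clipping.

Locus classes and their mean structures (ages in years, `a*` is age plus
any planted condition shift):

- **age_linear** — slope × (a* − mean age). The slope is calibrated so the
  expected beta difference between the aged (65–100) and young (25–35)
  sample windows equals `lifespan_delta` (default 0.015, i.e. ~1.5% of the
  beta scale), matching how "change over a lifetime" is measured by the
  young-vs-aged delta metric. Under uniform ages on 25–100 this makes the
  full-range extremes differ by ~1.43 × `lifespan_delta`. Slopes default to
  positive (hypermethylating); `hyper_fraction` mixes in losses.
- **age_parabolic** — amplitude × (1 − ((a* − peak)/w)²) with
  w = max distance from the peak to either end of the age range; value
  equals baseline at the far end and baseline + amplitude (default 0.02) at
  the peak (default 62.5, the midpoint of 25–100, which makes the planted
  curve exactly linearly uncorrelated with age under a symmetric design).
- **age_variance** — constant mean; the logit-noise variance is multiplied
  by 1 + `variance_slope` × (a − min)/(max − min) (default slope 8, i.e. a
  3× sd ratio old vs young).
- **tissue_identity** — one randomly chosen tissue is offset by
  ±`tissue_delta` (default 0.40, the blood-vs-brain scale contrast); sign
  chosen to stay inside [0, 1].
- **interaction** — one tissue's age slope differs by `interaction_slope`
  (default 0.001 beta/year); centred at the mean age so the tissue *main*
  effect is ~0 and the signal is purely a slope difference.
- **null** — baseline plus noise only.

Ages are uniform over `age_range` by default; an explicit per-sample age
design can be supplied (`ages=`), used e.g. for symmetric age grids. Batch
shifts are additive per (locus, batch) draws of N(0, `batch_shift_sd`),
clipped and recorded in the truth table. Missing entries are Bernoulli with
the mask returned for oracle tests. Disease groups are appended to the
`n_samples` controls; their planted "acceleration" substitutes an effective
age = age + shift into every age-responsive locus, so the shift is
recoverable by a clock trained on controls.

What the simulator deliberately omits: probe chemistry (Type I/II bias),
SNP-affected probes, cell-type composition shifts, and correlated noise
between loci. Passing recovery tests therefore demonstrates correctness of
the analysis machinery under the stated statistical structure, not
robustness to those real-data artefacts.

## Genomic coordinates and planted enrichments

Loci are placed ~20 kb apart on one synthetic chromosome, far enough that
the structures planted around one locus (gene + promoter, CpG island with
shores/shelves) cannot touch a neighbour. Each locus draws a genic context
(gene body / promoter / intergenic), an island context (island / shore /
shelf / open sea) and point-feature memberships from base probabilities;
an enrichment spec multiplies the odds of one feature for one locus class,
and the generator then lays intervals so that re-deriving features from
the emitted BED tracks reproduces the planted memberships. Derivations
follow array-annotation conventions: promoters are the 2 kb strand-aware
window upstream of the TSS; shores are the 2 kb island flanks minus
bodies; shelves the next 2 kb minus both; intergenic is the complement of
genes plus promoters; point features use a ±500 bp window (parameter).
All coordinates are 0-based half-open.

## Preprocessing

- **Adult filter**: keep age ≥ 25 (development excluded; boundary kept).
- **Age transform**: forward(a) = log(a+1) − log(adult+1) for a ≤ adult,
  else (a − adult)/(adult+1), with adult = 20 — continuous, differentiable
  at the knot, exactly invertible. Clocks fit on the transformed scale and
  report years after inversion.
- **KNN imputation**: per chunk of loci (default 120,000), each missing
  entry is the uniform mean of the k = 10 nearest loci by NaN-aware
  Euclidean distance over samples, taken among loci observed in that
  sample. Chunking bounds memory only. Metric and k are design choices;
  tests pin the unchunked result to a brute-force all-pairs oracle.
- **Batch correction**: parametric empirical-Bayes location/scale
  adjustment (the ComBat model) applied to logit-transformed betas and
  back-transformed, with protected covariates (default age) in the
  standardisation design. The implementation matches Bioconductor
  `sva::ComBat` to < 1e-4 on a shared fixture. A batch structure that
  perfectly determines a protected covariate is rejected.
- **Outlier flagging**: per-sample Kolmogorov–Smirnov distance to the
  cohort's median beta profile; the default threshold is cohort-relative
  (median + 10 × IQR of the distances), so homogeneous cohorts yield no
  flags. Flags are advisory; nothing is dropped.

## Feature selection

Four per-locus screens: univariate F statistic of beta on age
(F = (n−2)r²/(1−r²)); continuous-target mutual information with the
Kraskov-family nearest-neighbour estimator (k = 3), computed a quarter of
the loci at a time for memory; and |aged − young| differences of mean or
variance between the 25–35 and 65–100 windows. `top_fraction` keeps
ceil(fraction·n) loci with ties broken lexicographically by locus id. A
symmetric parabolic trajectory is invisible to the F screen (its linear
correlation with age is ~0, and the trajectory variance further dilutes
the noise-driven correlation) but scores high MI — the core argument for
non-linear selection.

## Clock training

Elastic net on transformed age with l1_ratio 0.5, α chosen by 10-fold CV
(folds seeded, stratified by age quartile) over a log-spaced path of 20
values spanning 3 decades. **Selection rule**: the default is the 1-SE
rule (largest α whose CV error is within one standard error of the
minimum, glmnet's `lambda.1se` convention); plain minimum-CV-error is
available (`selection_rule="min"`). The 1-SE default was chosen because
minimum-CV on cohorts with many null loci admits hundreds of tiny spurious
coefficients that a one-standard-error relaxation removes, while on
high-signal cohorts the CV curve is steep and both rules coincide; a
sparse site set is the object of interest in every downstream experiment
(knockout, overlap, concordance, enrichment). Models are refit at the
chosen α on the full training set and stored sparsely with provenance
(seed, α, sample hash, tissues, age range). The penalty is applied on the
raw beta scale — all features share the same units and range, so
per-feature standardisation (glmnet's default) is not performed; this
weights high-variance loci (e.g. tissue-identity sites) more heavily into
the penalty, which is the desired behaviour when the features are
physically commensurate fractions.

Evaluation reports Pearson r, RMSE in years, and the median absolute
error in years ("median absolute deviation" of predictions); constant
predictions get r = 0 with a flag rather than NaN.

## Clock experiments

- **Knockout**: train/test split fixed before round 1; each round fits 5
  clocks differing by CV-fold seed, records the mean of their test metrics
  (best-of-5 by flag), removes the union of their loci from the pool, and
  stops on pool exhaustion, an empty round, or `max_rounds`.
- **Transfer matrices**: one clock per tissue or per age bin (young 25–50,
  middle 50–75, aged 75–100; right-open except the last), every train/test
  pair evaluated, diagonal on held-out samples only. Per-group splits are
  seeded from the group label, so results are independent of processing
  order. Undersized groups are dropped with a warning.
- **Concordance**: restrict to loci nonzero in ≥ `min_models_shared`
  models; Pearson correlation of coefficient values over each pair's
  mutually nonzero subset; pairs with < 3 shared loci are flagged NaN.
- **Overlap counts**: exclusive intersection sizes over every model
  subset; they sum to the union size by construction.

## Locus-wise association

All loci share one design, so `beta ~ age + tissue + age:tissue` is fit to
every locus at once via QR decompositions of the four nested designs.
Term p-values are type-II partial F-tests (each term against the model
without it, interactions excluded from main-effect comparisons; the
full-model residual is the denominator), verified to 1e-8 against
`statsmodels` `anova_lm(typ=2)`. Each term forms its own BH family
(decision rule q ≤ α, the step-up convention). Classification is
hierarchical: a significant interaction implies both factors are involved
(`both_interaction`); otherwise two significant mains give
`both_no_interaction`, one gives `age_only`/`tissue_only`, none gives
`none`. The default classification threshold is q ≤ 0.05; 0.10 is used
where an analysis reports at 10% FDR.

Trajectories: lowess (span 0.5) on a 1-year age grid; turning points are
smoothed-curve extrema with prominence above the noise tolerance — an
extremum must rise above the noise floor on both flanks. The default
tolerance is 6 × resid_sd / √(span·n), the standard-error scale of the
*smoothed* curve (a lowess window averages ~span·n points); a tolerance on
the per-sample residual scale was tried first and classed every realistic
trajectory flat, because smoothing shrinks the curve's noise floor by
~√(span·n). "flat" if the whole smoothed range is below tolerance,
"linear" if no qualifying turning point, else "non_monotone".
An "inflection" in the rise-then-fall sense is an extremum, not a
curvature sign change; a curvature-based definition was considered and
rejected because the planted parabola has exactly one extremum but two
curvature-neutral flanks.

## Enrichment statistics

For a locus set against the array background: hypergeometric
over/under-representation tails, two-sided p = 2·min(tails) capped at 1,
and the log odds ratio of feature odds in the set vs the background with
0.5 continuity corrections (this form is exactly 0 when set = background
and flips sign exactly under feature complementation). BH across features
within a set at q = 0.10. Depletion is the under tail with negative log
OR, not a separate test.

## Age acceleration

Difference mode (predicted − actual, the default) and residual mode
(residual of predicted on actual) are both implemented and labelled;
difference mode is the default because the planted shift is defined in
years of effective age. Clock shrinkage (regression toward the training
mean) attenuates recovered shifts by roughly 5–15% at the default SNR —
a +5-year planted shift is typically recovered as ~4.3–4.7 years.
External clocks load from JSON (intercept, coefficients, calibration:
identity, linear a·x+b, or the inverse age transform); spec loci missing
from a matrix (≤ 10%) are imputed at the per-sample mean beta. Group
comparison: one-way ANOVA F over groups, then per-group pooled-variance t
tests vs pooled controls with Holm step-down at α = 0.05; singleton groups
are excluded with a warning.

One design point matters for calibration: the clock must be trained on a
*subset* of controls and all groups — including controls — compared on
held-out samples. In-sample control acceleration is biased toward zero
with deflated variance by the fit itself, and comparing out-of-sample
disease groups against in-sample controls inflates the false-flag rate of
unshifted groups roughly threefold in our replicate studies. The bundled
acceleration analyses therefore train on 120 of 200 controls and compare
every group against the held-out 80.

## Problem sizes and numerical choices

The bundled analyses and checks use cohorts of 150–800 samples and
200–5,500 loci with 20–200 replicates per stochastic claim — sizes at
which every planted effect is recoverable with comfortable margins and
the full suite runs in minutes on one CPU. Tolerances: oracle equalities
to 1e-8–1e-12; recovery claims at the planted-effect scale (e.g. the
young/aged contrast to ±0.003 beta at n = 2000). Ties in `top_fraction`
break lexicographically; CV folds, train/test splits and all generators
take explicit seeds, and identical configurations reproduce byte-identical
pipeline artifacts (the manifest records SHA-256 hashes).

## Known limitations

- The simulator's independence between loci understates the correlation
  structure of real arrays; elastic-net behaviour on correlated blocks
  (site swapping along the path) is only lightly exercised.
- The enrichment generator controls marginal feature odds per class, not
  joint odds across features; joint structure (e.g. promoter ∩ island) is
  whatever the independent axes imply.
- Holm post hocs use pooled-variance t tests; strongly heteroscedastic
  group comparisons would warrant Welch, available trivially but not the
  default.
- The 1-SE selection rule makes sparsity, not prediction, the tiebreaker;
  reported r/RMSE are marginally conservative relative to minimum-CV.
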