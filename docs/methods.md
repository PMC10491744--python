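# Methods

## The model

Connectome-based predictive modeling (CPM) predicts a scalar clinical score
from a subject's functional connectome.  A connectome is a symmetric
`n_nodes x n_nodes` matrix of Fisher z-transformed Pearson correlations
between node time courses; only the `n(n-1)/2` upper-triangle edges carry
information (the diagonal is undefined and stored as NaN).

Given a training sample of edge vectors `x_i` and scores `y_i`:

1. **Edge selection.**  Every edge is correlated with the score; edges with
   two-tailed `p < alpha` (default `alpha = 0.001`) are kept and split by the
   sign of the correlation into a *positive* and a *negative* network.
   p-values use the exact transform `t = r sqrt((n-2)/(1-r^2))` with `n-2`
   degrees of freedom; the inequality is strict, and an edge that is constant
   across subjects carries `(r, p) = (0, 1)` and can never be selected.
2. **Network strength.**  A subject's strength on a network is the plain sum
   of their edge weights over the network's mask (0 for an empty mask).
3. **Linear models.**  Ordinary least squares relates strength to score:
   one univariate model per network plus a bivariate *combined* model with
   both strengths as regressors.  A strength column with zero variance is
   dropped (slope 0) and absorbed into the intercept, so an empty-mask model
   degrades gracefully to predicting the training mean.
4. **Leave-one-out cross-validation.**  For each subject, steps 1–3 run on
   the other `n-1` subjects only, and the held-out subject is predicted from
   the resulting model.  Fold order is subject order; nothing is random.
   Model fit is summarized by the Pearson concordance `r` between the `n`
   held-out predictions and observed scores, and by the RMSE.
5. **Consensus.**  Edges selected in *every* fold (a strict intersection)
   form the consensus networks used for interpretation.

The combined model is a bivariate least-squares fit on (positive strength,
negative strength).  A univariate fit on the summed strengths is the main
alternative reading of the protocol; the bivariate form nests both
single-network models and is the default here.

## Permutation inference

LOOCV folds share `n-2` subjects, so parametric p-values on the concordance
overstate the degrees of freedom.  Significance is therefore assessed by
permutation: the score vector is shuffled over subjects (covariates stay
attached to their subjects), the complete LOOCV — including per-fold edge
selection — is rerun on each shuffle, and

    p_perm = (1 + #{null r >= observed r}) / (n_perm + 1)

with `n_perm = 5000` by default.  The add-one convention avoids `p = 0`;
the raw proportion is also reported.  Ties count toward the numerator
(conservative).  When held-out predictions are constant (every fold's masks
empty), the concordance is defined as 0 — no predictive signal.  An
exhaustive mode enumerates all `n!` orderings for tiny samples and returns
the exact rank-based `p = c / n!` (identity ordering included).

## Numerical organisation of the LOOCV

Per-fold leave-one-out statistics are assembled from prefix/suffix
cumulative sums, so fold `i`'s selection statistics never numerically
involve subject `i`'s score: perturbing a held-out score leaves that fold's
masks and prediction *bitwise* unchanged, which the test suite asserts as
an exact no-leakage guarantee.  The score-independent parts (per-fold edge
sums and variances) are computed once per cohort and reused across all
permutations.  Inside the engine the selection threshold `p < alpha` is
applied as the algebraically equivalent `r^2 > t_c^2 / (t_c^2 + df)` with
`t_c` the two-tailed t critical value — one quantile evaluation per run
instead of per-edge p-values in every fold.  A fold variance below
`1e-12` of the largest edge variance is treated as zero (constant edge).
With fewer than 4 training subjects per fold the selection t-statistic has
no degrees of freedom; such folds select nothing and predict the training
mean.

## Covariate-adjusted concordance and confound checks

Partial Pearson correlations residualize both vectors on the covariates
(plus intercept) by least squares; the residual correlation is tested with
`n - 2 - n_covariates` degrees of freedom.  The standard report controls
predicted-observed concordance for age and gender (female = 1 indicator —
any full-rank coding gives the same partial correlation).  A confound check
correlates mean framewise displacement with each target, and the targets
with each other.

## Quality control

A subject's connectome similarity score is the Pearson correlation between
their edge vector and the elementwise median edge vector of all *other*
subjects.  Subjects below `Q1 - 1.5 IQR` are flagged (never silently
dropped).  The fence is evaluated on the Fisher-z transform of the scores:
similarity correlations are left-skewed, and the variance-stabilized scale
keeps the fence from flagging the natural lower tail while still isolating
genuinely aberrant subjects.

## Clinical targets

The depressed-mood target (HDRS-5) is the sum of the five Hamilton
Depression Rating Scale items loading highest on depression: depressed
mood, work and interests, guilt, psychomotor retardation, suicide.  The
elevated-mood target is the Young Mania Rating Scale total (sum of its 11
items); the 29-item HDRS total is available for exploratory runs.  Items
are opaque non-negative integers keyed by canonical lower-case names — the
item names, not positional indices, are the contract.  Subjects missing a
target score are excluded from that target's analysis (and logged), never
imputed.

## Frozen models and transfer

`train_full_model` selects edges and fits all three models on the complete
training sample and freezes the result — masks as sorted edge-index lists
plus coefficients — in a JSON artifact.  Applying it to a new cohort uses
the frozen masks and coefficients with no re-selection or re-fitting, so
applying it back to its own training sample reproduces the in-sample
fitted values exactly.  Transfer evaluation refuses cohorts sharing subject
ids with the training sample (`enforce_disjoint=False` exists for
deliberate closure checks) and reports plain and covariate-adjusted
concordance; the plain correlation uses `n-2` degrees of freedom, the
adjusted one the partial-correlation convention above.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not fMRI physics:

* **Scores.**  Integer severity ratings from a clipped, rounded normal.
  The latent normal's `(mu, sigma)` are calibrated (by solving the discrete
  moment equations) so the clipped-rounded distribution matches the target
  moments exactly — HDRS-5-like mean 3.4, SD 3.4 on 0–13; YMRS-like mean
  6.5, SD 6.1 on 0–23.  A plainly truncated normal cannot reach SD ≈ mean
  with a floor at 0; clipping piles mass at the scale minimum, as real
  severity ratings do.
* **Edges.**  A shared group-mean connectome (`N(0.25, 0.15)` per edge in
  Fisher-z units) scaled per subject by a loading `N(1, 0.05)` — individual
  differences in global connectivity expression, without which
  between-subject similarity is unrealistically uniform — plus i.i.d. edge
  noise (`SD 0.15`).
* **Planted networks.**  Disjoint positive and negative edge sets (default
  40 + 40) drawn without replacement; with probability `hub_bias` (default
  0.5) an edge is forced to touch one of `n_hubs` designated hub nodes so
  degree analysis has signal.  Planted edges gain `±beta` times the
  standardized observed score, with
  `beta = noise_sd * r / sqrt(1 - r^2)` so the per-edge edge–score
  correlation matches the requested `effect_r` (default 0.3, a modest
  clinical-scale effect) in expectation.
* **Covariates.**  Age `N(29.3, 11.1)`, 63% female, mean framewise
  displacement folded-normal around 0.12 mm — drawn independently of the
  edges unless the age-confounding switch couples age to the score.
  A per-subject log-normal noise-scale multiplier
  (`subject_noise_scale_sd`, default off) emulates heterogeneous
  acquisition in validation samples.

Everything is reproducible from the seed, and a validation cohort can be
drawn from the same generative process as a training cohort (same planted
masks, fresh subjects) by passing the training ground truth's masks.

What the generator does **not** emulate: task structure, hemodynamics,
spatial autocorrelation between edges, site effects beyond noise scale,
medication or comorbidity heterogeneity.  Passing tests therefore
demonstrate that the *pipeline* recovers planted linear structure and is
calibrated under its assumed data model — not that the assumptions hold in
real fMRI cohorts.

## Problem sizes used in the shipped checks

The test suite and the acceptance script scale the connectome down — 60 to
120 nodes rather than 368 — and run the cohort-level analyses at n = 40 to
150 subjects; these sizes were chosen so the full distributional checks
(100 null cohorts at 200 permutations each; 20 planted-signal seeds) are
routine to run while leaving every algorithmic path identical to the
full-scale setting.  The acceptance script keeps the study-scale quantities
where they are cheap: the full 368-node atlas bookkeeping, an 81-subject
training roster with one planted aberrant subject, a 43-subject validation
roster with two missing elevated-mood scores, and 5000 permutations.

## Known limitations

* Consensus-by-strict-intersection is conservative: a single unstable fold
  empties the consensus.  Per-fold masks are retained so laxer summaries
  can be computed downstream.
* The LOOCV concordance of planted-signal synthetic cohorts is far higher
  than real-data values; synthetic noise is i.i.d. and the effect exactly
  linear, so these runs are implementation checks, not performance
  forecasts.
* `alpha` is a selection hyperparameter, not an error-rate guarantee; no
  multiplicity correction is applied across edges (the permutation test
  carries whole-model inference).
* With integer scores, permutations can produce tied score vectors; ties
  in the null distribution are counted conservatively.
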