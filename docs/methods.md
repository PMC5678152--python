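# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Text featurization

Tokenization is deliberately primitive and fully deterministic: sentences
split on runs of `.?!`; tokens are maximal runs of Unicode letters
(hyphen-joined compounds kept whole), lowercased; numerals and punctuation
are never tokens. This trades linguistic sophistication for exact
reproducibility — the features downstream are counts and pooled rating
statistics, which do not benefit from smarter segmentation.

Lexicon matching has two stages. A token that is itself a rated lexicon
entry matches *raw* (counted in `n_bawl_pre`). A token whose row in the
lexicon carries no ratings (a baseform-conversion row, standing in for an
online lemmatization service) matches via its baseform when that resolves
to a rated entry. `n_bawl` counts both stages, so `n_bawl ≥ n_bawl_pre`
always: baseform conversion can only add matches. Tokens without any
lexicon row are unclassifiable misses — no morphological guessing is
attempted. Word-class counts prefer the surface form's own row (the
conversion table classifies inflected forms); rating statistics always use
the matched (rated) entry.

Rating summaries are occurrence-level: every matched token occurrence
contributes once to the means, sample variances (ddof = 1; a single match
leaves the variance undefined) and the frequency median. The median is
used for frequency because per-million word frequencies are heavily
right-skewed. Undefined statistics propagate as NaN and are mean-imputed
only at matrix assembly (with a logged count), keeping the subject count
fixed; zero-variance columns are dropped there with a warning.

Dictionary category counting follows the standard word-count convention:
every pattern (exact word or `stem*` prefix) that matches a token
increments *all* of its categories; no longest-match precedence. Counts
are divided by total words, giving proportions in [0, 1] rather than
percent; multi-membership means the proportions need not sum to one.

## Regression

All four estimators z-score the predictors on the training data inside
`fit` (count features and rating means live on wildly different scales)
and back-transform coefficients, so `predict` operates on raw features.
Constant training columns get unit scale — they are inert in the fit —
with a warning; the standalone `pca()` helper instead raises, naming the
column, since an undefined z-score in an explicit PCA request is a user
error.

* **PCR**: SVD of the standardized training block; components ordered by
  variance with the sign convention that each component's
  largest-magnitude loading is positive; OLS (statsmodels) of y on the
  first n scores provides normal-theory 95% CIs on the component
  coefficients. `n_components = 0` is the intercept-only baseline.
* **Supervised PCR**: the screening score is the absolute standardized
  univariate coefficient of y on each column — equivalently |Pearson r| —
  so θ lives on a [0, 1] scale regardless of predictor units. Screening
  is re-estimated inside every CV fold.
* **PLS**: SIMPLS with the usual basis-deflation recursion; for a single
  response this coincides with NIPALS PLS1 (verified against
  scikit-learn's implementation in the tests).
* **Ridge**: closed-form solve of (XᵀX + λI)b = Xᵀy on standardized
  data, intercept unpenalized; λ = 0 on rank-deficient data falls back to
  the minimum-norm solution with a warning.

At their limits the methods collapse onto each other — PCR and PLS with
all components, ridge at λ = 0, and sPCR at θ = 0 all reproduce OLS — and
the tests pin these equivalences to 1e-6.

**Cross-validation.** Leave-one-out; for every hyperparameter grid point
and fold, standardization, PCA/PLS directions and screening are
re-estimated on the n−1 training subjects only (fold purity is asserted
by corrupting the held-out target and checking the prediction is
unchanged). Exact RMSE ties resolve toward parsimony: fewer components,
then larger λ, then larger θ. Grid points infeasible in some fold (e.g. a
θ that removes every column) score +∞ rather than aborting the sweep.
Default grids: components 0–10, λ log-spaced over [1e−3, 1e4] (50
points), θ ∈ {0, 0.05, …, 0.3} × components 0–5.

Two analysis modes exist on purpose. CV mode (above) is the only source
of reported prediction accuracy. *Report mode* fits one PCA on the full
data set and regresses each target on the same component basis — this is
what makes component coefficients comparable across targets (internal vs.
semantic vs. √k), at the price of in-sample optimism, which is why it is
never used for accuracy claims.

## Temporal discounting

The adaptive task offers 20 units now against a larger-later amount at
delays {2, 7, 14, 30, 90, 180} days; each delay runs an independent
staircase (two successive smaller-sooner choices raise the later amount
by 10% of its current value, two successive larger-later choices lower it
likewise, floored at 20.5; initial amount 40; 12 trials per delay). These
staircase constants are simulator plumbing, chosen so the staircase
brackets the indifference point for discount rates in the realistic
0.001–0.2 range; all are configurable.

The choice likelihood is the field-standard logistic (softmax) rule on
the hyperbolic value difference, P(LL) = 1/(1 + e^(−β·(SV_LL − SV_SS))).
This likelihood is a modeling choice of this package, stated here
explicitly; alternative choice kernels are out of scope. Fitting
maximizes the Bernoulli log-likelihood over (log k, log β) — the log
parameterization enforces positivity — by Nelder–Mead from a 5 × 5
multistart grid (k ∈ [1e−4, 1], β ∈ [0.05, 20], log-spaced); the returned
optimum is verified in tests to beat every start. One-sided choice data
yield a boundary-flagged fit. Because fitted k are right-skewed across
subjects, analyses use √k.

## Synthetic study generator

The generator is the weakest structure consistent with the findings the
pipeline is meant to recover — linear-Gaussian latents on transformed
scales, with every coupling configurable so null cases are testable:

* Two independent subject-level factors: **verbosity** (quantity) and
  **richness** (quality). Condition-specific realizations share
  correlation ρ = 0.7 across AM/EFT.
* Text: cue word counts are lognormal with mean shifted by 0.5·verbosity;
  sentence lengths and the sampling weight of adjectives also grow with
  verbosity (longer narratives carry relatively more adjectives and
  longer sentences, as real feature matrices show); word sampling weights
  tilt toward high-imageability/high-valence words by 0.45·richness.
  Inflected variants (35%) exercise baseform matching; out-of-vocabulary
  fillers (12%) exercise misses.
* The synthetic category dictionary is affect-*balanced*: each category
  pairs words from the high and low ends of the valence/imageability
  axis, emulating topic-organized content categories. This keeps
  dictionary proportions nearly uncorrelated with the manual affective
  features and makes the quantity factor clearly dominate the first
  principal component, as in real data.
* Scores (rounded to nonnegative integers): internal = 40 + 12·quantity +
  7·quality + N(0, 5) with a +3 AM shift; semantic = 20 + 6·quantity +
  N(0, 6) with a +1.5 EFT shift — the quality loading of zero on semantic
  is the dissociation the regression stage should expose. External
  details get only a weak quantity coupling and are not prediction
  targets. Effect sizes were chosen so that LOO prediction error of
  internal details lands near 0.5 SD at n = 150, the accuracy scale
  reported for feature-based AI prediction.
* √k = 0.12 − 0.02·verbosity − 0.015·richness + N(0, 0.03), floored at
  0.01 (a weak negative coupling: more and richer narration goes with
  shallower discounting); choices are then simulated from the implied
  hyperbolic agent at β = 5.

**What passing tests show — and don't.** The generator produces
letter-salad tokens, not German; there is no discourse structure, no
interviewer speech, no disfluency, and category membership is random
rather than semantic. Recovery results therefore validate the *pipeline*
(featurization arithmetic, fold hygiene, model selection, inference
calibration under a known truth), not the linguistic claim that real AI
scores are predictable — that depends on real transcripts. Default sizes
(n = 150 subjects, 5 cues × 2 conditions, ~70 words per cue, 400-word
lexicon, 64 categories) are the package's standard study conditions; the
multi-seed recovery checks run 20 replicates at these sizes.

## Test-set-size analysis

Per-cue features use the same sufficient statistics as pooled features
(counts add; rating occurrences concatenate), so pooling any cue subset
is exact, not approximate. For each held-out subject and size m, all
C(n_cues, m) subsets are enumerated; the per-subject error at m is the
mean of *squared* subset errors, and the curve is the square root of the
across-subject mean. Averaging squared (rather than absolute) errors is
the choice that makes the curve collapse exactly onto the ordinary
pooled-feature LOO RMSE at m = n_cues, which the tests assert to 1e−12.
This analysis uses manual features only and condition-specific models
(AM features → AM target, EFT → EFT), unlike the main analyses, which
always use the full two-condition matrix.

## Known limitations

* The baseform table is finite: out-of-vocabulary inflected forms are
  misses, whereas an online lemmatizer might resolve them.
* Normal-theory CIs on component coefficients ignore selection of the
  component count; they are reporting devices, not selective inference.
* θ for supervised PCR is on the |r| scale of this implementation's
  screening score; thresholds from implementations using other screening
  statistics are not transferable.
* The subsample analysis is exhaustive over cue subsets and is therefore
  exponential in the cue count; it is intended for the single-digit cue
  counts typical of interview protocols.
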