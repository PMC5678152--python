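# aitext

Quantitative text-feature analysis of Autobiographical Interview (AI)
narratives.

In the AI, participants verbally elaborate cued past events
(autobiographical memory, AM) or imagined future events (episodic future
thinking, EFT). Transcripts are conventionally scored by hand into
*internal* (episodic), *semantic* and *external* detail sum scores — a slow
and subjective procedure. `aitext` implements an automatic alternative:
low-level linguistic features are extracted from the transcripts and used
to predict the detail sum scores, and, via the known EFT–impulsivity link,
square-root-transformed hyperbolic discount rates, with out-of-sample
accuracy measured by leave-one-out cross-validation (LOO-CV).

The package is aimed at researchers working with interview-style narrative
corpora who want a reproducible, fully offline featurization + prediction
pipeline, including a synthetic-data generator that emulates the latent
structure of real AI datasets (no raw interview data are redistributable).

## What it computes

**Features.** Per subject and condition, pooling all event cues:

* 19 *manual* features: word/sentence counts, noun/verb/adjective counts
  and proportions, words-per-sentence, counts of words matched to an
  affective word lexicon pre- and post-baseform (lemma) conversion, mean
  and sample variance of the matched words' valence, arousal and
  imageability ratings, and the median word frequency (median because
  word-frequency distributions are heavily right-skewed).
* 64 dictionary category proportions (LIWC-style wildcard word counting,
  counts normalized by text length).

Stacked over both conditions this gives the predictor matrix
**X** ∈ ℝ^(n × 166) = (19 + 64) × 2.

**Models.** Narrative features are strongly collinear, so **y** (a detail
sum score or √k) is regressed on **X** with four collinearity-robust
methods, all as scikit-learn-style estimators:

* `PCR(n_components)` — principal component regression: OLS of y on the
  first n PCA scores of the standardized predictors, with normal-theory
  95% CIs on the component coefficients;
* `SupervisedPCR(theta, n_components)` — PCR after univariate screening:
  columns with |standardized univariate coefficient| < θ are dropped
  before the PCA;
* `PLSRegressor(n_components)` — single-response partial least squares
  (SIMPLS);
* `RidgeRegressor(lam)` — L2 shrinkage with unpenalized intercept.

Hyperparameters are tuned by LOO-CV RMSE,
RMSE = √(Σᵢ(ŷᵢ − yᵢ)²/n), with all preprocessing re-estimated inside each
fold.

**Discounting.** An adaptive intertemporal-choice task (20 now vs. a
larger amount at 2–180 days; staircase on two successive identical
choices) is simulated per subject, and choices are fit by maximum
likelihood under a hyperbolic value function SV = A/(1 + k·D) with a
logistic choice rule; downstream analyses use √k.

## Worked example

```python
import aitext as at

study = at.generate_corpus(at.GeneratorConfig(n_subjects=40, seed=1))
X = at.assemble_matrix(study.transcripts, study.lexicon, study.dictionary)
y = (study.scores.query("condition == 'AM'")
     .set_index("subject_id")["internal"].loc[X.index].to_numpy(float))

res = at.loo_cv(X.to_numpy(), y, at.PCR(),
                [{"n_components": k} for k in range(6)])
print(X.shape, res.best_params, round(res.best_rmse, 2), round(res.rmse[0], 2))
```

prints

```
(40, 166) {'n_components': 4} 10.15 14.54
```

i.e. the assembled matrix has 40 subjects × 166 predictors; among 0–5
components the 4-component PCR predicts held-out AM internal-detail scores
best, with LOO RMSE 10.15 versus 14.54 for the intercept-only baseline
(the score SD is 14.2, so prediction error is ≈ 0.72 SD at this small n;
at the default n = 150 it is ≈ 0.5 SD).

The same stages are scriptable from the shell:

```bash
aitext simulate --n-subjects 40 --seed 1 --out study/
aitext assemble --corpus study/transcripts.jsonl --lexicon study/lexicon.tsv \
       --dictionary study/categories.dic --out X.csv
aitext cv --matrix X.csv --scores study/scores.csv --target internal_AM \
       --method pcr --out curve.csv
```

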