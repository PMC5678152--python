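"""End-to-end orchestration: matrix assembly, condition comparisons,
correlation structure, full-data PCA/PCR reporting and CV model
comparison.

The central object is the feature matrix X: one row per subject, columns
ordered manual-AM, manual-EFT, dictionary-AM, dictionary-EFT (so a
64-category dictionary yields (19 + 64) x 2 = 166 predictors).
Prediction models for the main analyses always use this full
two-condition matrix; only the test-set-size analysis
(:mod:`aitext.subsample`) switches to condition-specific features.

Two analysis modes exist on purpose.  *CV mode* re-estimates every
preprocessing step (standardization, PCA directions, screening) inside
each leave-one-out fold and is the only mode used for model selection
and reported prediction accuracy.  *Report mode* fits one PCA/PCR on the
full data set and is used solely to display component loadings and
component-coefficient confidence intervals, where a single common basis
across prediction targets is what makes the coefficients comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .categories import category_proportions
from .features import (MANUAL_FEATURE_NAMES, Condition, TokenizedNarrative,
                       Transcript, manual_features, tokenize)
from .lexicon import CategoryDictionary, Lexicon
from .regression import (DEFAULT_COMPONENT_GRID, CVResult, PCR, PLSRegressor,
                         loo_cv)

logger = logging.getLogger(__name__)

__all__ = [
    "assemble_matrix",
    "correlation_heatmap_data",
    "compare_conditions",
    "run_feature_set_comparison",
    "select_feature_set",
    "report_pca_regression",
    "provenance_record",
]

FEATURE_SETS = ("all", "manual_only", "liwc_only")


def _pooled_tokens(transcripts: Sequence[Transcript]) -> TokenizedNarrative:
    sentences: list = []
    for t in transcripts:
        sentences.extend(tokenize(t.text).sentences)
    return TokenizedNarrative(sentences=tuple(sentences))


def assemble_matrix(transcripts: Sequence[Transcript], lex: Lexicon,
                    dic: CategoryDictionary | None = None,
                    feature_set: str = "all",
                    drop_zero_variance: bool = True) -> pd.DataFrame:
    """Assemble the subjects x predictors matrix X.

    Every subject must appear in both conditions.  Column blocks are
    ordered manual-AM, manual-EFT, liwc-AM, liwc-EFT, names suffixed by
    condition; dictionary columns are proportions in [0, 1] and carry the
    ``liwc_`` prefix.  Missing feature values (undefined statistics of
    sparse narratives) are mean-imputed with a logged count; zero-
    variance columns are dropped with a warning.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    if dic is None and feature_set != "manual_only":
        raise ValueError("a category dictionary is required unless manual_only")

    by_subject: dict[str, dict[Condition, list[Transcript]]] = {}
    for t in sorted(transcripts, key=lambda t: (t.subject_id, t.condition.value, t.cue_id)):
        by_subject.setdefault(t.subject_id, {}).setdefault(t.condition, []).append(t)
    if not by_subject:
        raise ValueError("no transcripts")
    incomplete = [s for s, conds in by_subject.items() if len(conds) < 2]
    if incomplete:
        raise ValueError(f"subjects missing a condition: {incomplete}")

    rows = {}
    for subject, conds in by_subject.items():
        parts = []
        if feature_set in ("all", "manual_only"):
            for cond in (Condition.AM, Condition.EFT):
                feats = manual_features(conds[cond], lex)
                parts.append(feats.add_suffix(f"_{cond.value}"))
        if feature_set in ("all", "liwc_only"):
            for cond in (Condition.AM, Condition.EFT):
                props = category_proportions(_pooled_tokens(conds[cond]), dic)
                props.index = [f"liwc_{c}_{cond.value}" for c in props.index]
                parts.append(props)
        rows[subject] = pd.concat(parts)
    X = pd.DataFrame(rows).T
    X.index.name = "subject_id"

    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputing %d missing feature value(s)", n_missing)
        X = X.fillna(X.mean())
    if drop_zero_variance:
        variances = X.var(ddof=1)
        dead = list(variances.index[(variances == 0) | variances.isna()])
        if dead:
            logger.warning("dropping %d zero-variance column(s): %s", len(dead), dead)
            X = X.drop(columns=dead)
    return X


def correlation_heatmap_data(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of all predictors (symmetric, unit
    diagonal); zero-variance columns yield flagged NaN entries."""
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for correlations")
    corr = X.corr(method="pearson")
    dead = corr.columns[corr.isna().all()]
    if len(dead):
        logger.warning("zero-variance column(s) give undefined correlations: %s", list(dead))
    return corr


def compare_conditions(scores: pd.DataFrame) -> pd.DataFrame:
    """Paired AM-vs-EFT comparison per detail type.

    ``scores`` is tidy: subject_id, condition, then one column per
    detail type.  Returns, per detail type: paired t (df = n-1),
    two-sided p, the AM and EFT means and the across-condition Pearson
    r.  A zero-variance paired difference is flagged degenerate instead
    of reporting an infinite t.
    """
    wide = scores.pivot(index="subject_id", columns="condition")
    detail_types = sorted({c[0] for c in wide.columns})
    n = wide.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    rows = []
    for detail in detail_types:
        am = wide[(detail, "AM")].to_numpy(dtype=float)
        eft = wide[(detail, "EFT")].to_numpy(dtype=float)
        diff = am - eft
        degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
        if degenerate and np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        elif degenerate:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_rel(am, eft)
        if am.std(ddof=1) > 0 and eft.std(ddof=1) > 0:
            r = float(stats.pearsonr(am, eft)[0])
        else:
            r = np.nan
        rows.append({"detail_type": detail, "t": float(t), "df": n - 1,
                     "p": float(p), "mean_AM": am.mean(), "mean_EFT": eft.mean(),
                     "r_AM_EFT": r, "degenerate": degenerate})
    return pd.DataFrame(rows)


def select_feature_set(X: pd.DataFrame, feature_set: str) -> pd.DataFrame:
    """Column subset of an assembled matrix by feature family."""
    if feature_set == "all":
        return X
    liwc = X.columns.str.startswith("liwc_")
    if feature_set == "manual_only":
        return X.loc[:, ~liwc]
    if feature_set == "liwc_only":
        return X.loc[:, liwc]
    raise ValueError(f"unknown feature set {feature_set!r}")


def run_feature_set_comparison(X: pd.DataFrame, y: Sequence[float],
                               grid: Sequence[dict] | None = None) -> dict[str, CVResult]:
    """PLS LOO-CV curves for the three feature sets {all, manual_only,
    liwc_only} under identical (leave-one-out) fold assignments."""
    grid = list(grid) if grid is not None else [g for g in DEFAULT_COMPONENT_GRID]
    results = {}
    for feature_set in FEATURE_SETS:
        sub = select_feature_set(X, feature_set)
        results[feature_set] = loo_cv(sub.to_numpy(), np.asarray(y, dtype=float),
                                      PLSRegressor(), grid)
    return results


@dataclass
class PCAReport:
    """Full-data ('report mode') PCA + per-target PCR coefficients."""

    loadings: pd.DataFrame               # predictors x components
    explained_variance_ratio: np.ndarray
    coefficients: dict[str, pd.DataFrame]  # target -> (coef, ci_low, ci_high) per comp


def report_pca_regression(X: pd.DataFrame, targets: Mapping[str, Sequence[float]],
                          n_components: int = 10) -> PCAReport:
    """One common full-data PCA basis; per target, OLS coefficients of y
    on the first ``n_components`` scores with 95% CIs.  Because the
    basis is shared, coefficient patterns are directly comparable across
    targets (e.g. internal vs. semantic details)."""
    coefficients = {}
    loadings = None
    ratio = None
    for name, y in targets.items():
        model = PCR(n_components=n_components).fit(X.to_numpy(), np.asarray(y, dtype=float))
        if loadings is None:
            loadings = pd.DataFrame(
                model.loadings_[:, :n_components], index=X.columns,
                columns=[f"PC{i + 1}" for i in range(n_components)])
            ratio = model.explained_variance_ratio_
        coefficients[name] = pd.DataFrame({
            "coef": model.score_coef_,
            "ci_low": model.score_coef_ci_[:, 0],
            "ci_high": model.score_coef_ci_[:, 1],
        }, index=[f"PC{i + 1}" for i in range(model.score_coef_.size)])
    return PCAReport(loadings=loadings, explained_variance_ratio=ratio,
                     coefficients=coefficients)


def provenance_record(config: Mapping, seed: int) -> dict:
    """Machine-readable provenance: config hash, seed and versions."""
    import aitext
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "python": platform.python_version(),
        "aitext": aitext.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
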