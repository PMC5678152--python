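"""Effect of test-data size (number of event cues) on prediction accuracy.

Real interview sessions are long; this analysis asks how much test
material a trained model actually needs.  Condition-specific 2-component
PLS models are trained, under leave-one-out CV, on the pooled manual
features of the training subjects (always using *all* their cues).  For
the held-out subject, prediction is repeated on every possible subset of
m of their event cues (features re-pooled from exactly those cues), for
m = 1 .. n_cues.  The per-subject error at size m is the mean *squared*
error over all C(n_cues, m) subsets; the curve reports, per m, the
square root of the across-subject mean of these — so at m = n_cues the
curve equals the ordinary pooled-feature LOO RMSE exactly.

Only the 19 manual features enter this analysis (no dictionary
features), and AM features predict AM targets, EFT features EFT targets.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .features import (MANUAL_FEATURE_NAMES, Condition, CueStats, Transcript,
                       cue_stats, features_from_stats, merge_stats, tokenize)
from .lexicon import Lexicon
from .regression import PLSRegressor

logger = logging.getLogger(__name__)

__all__ = ["per_cue_features", "subset_size_curve"]


def _cue_stats_table(transcripts: Sequence[Transcript], lex: Lexicon,
                     condition: Condition) -> dict[str, dict[str, CueStats]]:
    """subject -> cue -> CueStats for one condition, cues in sorted order."""
    table: dict[str, dict[str, CueStats]] = {}
    for t in sorted(transcripts, key=lambda t: (t.subject_id, t.cue_id)):
        if t.condition is not condition:
            continue
        table.setdefault(t.subject_id, {})[t.cue_id] = cue_stats(tokenize(t.text), lex)
    return table


def per_cue_features(transcripts: Sequence[Transcript], lex: Lexicon) -> pd.DataFrame:
    """The 19 manual features computed separately for every
    subject x condition x cue (one row each)."""
    rows = []
    for t in sorted(transcripts, key=lambda t: (t.subject_id, t.condition.value, t.cue_id)):
        feats = features_from_stats(cue_stats(tokenize(t.text), lex))
        row = {"subject_id": t.subject_id, "condition": t.condition.value,
               "cue_id": t.cue_id}
        row.update(feats.to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "condition", "cue_id",
                                       *MANUAL_FEATURE_NAMES])


def _impute(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute both blocks with the training-fold column means."""
    means = np.nanmean(train, axis=0)
    means = np.nan_to_num(means)
    train = np.where(np.isnan(train), means, train)
    test = np.where(np.isnan(test), means, test)
    return train, test


def subset_size_curve(transcripts: Sequence[Transcript], lex: Lexicon,
                      y: Mapping[str, float], condition: Condition,
                      max_cues: int | None = None,
                      estimator: PLSRegressor | None = None) -> pd.DataFrame:
    """LOO RMSE as a function of test-set size m = 1 .. max_cues.

    ``y`` maps subject id to the condition-specific target value.
    Subjects with fewer than ``max_cues`` cues are excluded with a
    warning.  Returns a frame with columns m, rmse, n_subsets.
    """
    estimator = estimator if estimator is not None else PLSRegressor(n_components=2)
    table = _cue_stats_table(transcripts, lex, condition)
    n_cues = {s: len(cues) for s, cues in table.items()}
    if max_cues is None:
        max_cues = max(n_cues.values())
    subjects = [s for s in sorted(table) if s in y]
    dropped = [s for s in subjects if n_cues[s] < max_cues]
    if dropped:
        logger.warning("excluding %d subject(s) with fewer than %d cues: %s",
                       len(dropped), max_cues, dropped)
        subjects = [s for s in subjects if s not in set(dropped)]
    if len(subjects) < 4:
        raise ValueError("need at least 4 usable subjects")

    pooled = {s: features_from_stats(merge_stats(table[s].values())).to_numpy()
              for s in subjects}
    X_pooled = np.vstack([pooled[s] for s in subjects])
    y_vec = np.array([float(y[s]) for s in subjects])

    n = len(subjects)
    sq_err = np.zeros((max_cues, n))   # [m-1, subject] mean squared error
    mask = np.ones(n, dtype=bool)
    for i, subject in enumerate(subjects):
        mask[i] = False
        X_train, _ = _impute(X_pooled[mask], X_pooled[mask])
        model = clone(estimator).fit(X_train, y_vec[mask])
        train_means = np.nanmean(X_pooled[mask], axis=0)
        cue_ids = sorted(table[subject])
        for m in range(1, max_cues + 1):
            errors = []
            for subset in combinations(cue_ids, m):
                feats = features_from_stats(
                    merge_stats(table[subject][c] for c in subset)).to_numpy()
                feats = np.where(np.isnan(feats), np.nan_to_num(train_means), feats)
                pred = model.predict(feats[None, :])[0]
                errors.append((pred - y_vec[i]) ** 2)
            assert len(errors) == comb(len(cue_ids), m)
            sq_err[m - 1, i] = float(np.mean(errors))
        mask[i] = True

    return pd.DataFrame({
        "m": np.arange(1, max_cues + 1),
        "condition": condition.value,
        "rmse": np.sqrt(sq_err.mean(axis=1)),
        "n_subsets": [comb(max_cues, m) for m in range(1, max_cues + 1)],
    })
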