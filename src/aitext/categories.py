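"""Dictionary-based category proportions (LIWC-style word counting).

Each token is checked against every dictionary pattern (exact word or
``stem*`` prefix); every category of every matching pattern is
incremented once per token occurrence.  Counts are normalized by the
total word count, giving proportions in [0, 1] (not LIWC's percent —
recorded in the column metadata written by the pipeline).  A word may
belong to several categories, so the proportions need not sum to 1.
"""

from __future__ import annotations

import math

import pandas as pd

from .features import TokenizedNarrative
from .lexicon import CategoryDictionary

__all__ = ["category_proportions"]


def category_proportions(tok: TokenizedNarrative, dic: CategoryDictionary) -> pd.Series:
    """Category proportions of a (pooled) tokenized narrative.

    Returns one entry per dictionary category, in dictionary order.
    With zero words every proportion is undefined (NaN), never zero.
    """
    counts = {c: 0 for c in dic.categories}
    n_words = tok.n_words
    if n_words == 0:
        return pd.Series({c: math.nan for c in dic.categories}, index=dic.categories, dtype=float)
    for token in tok.tokens:
        for cat in dic.match(token):
            counts[cat] += 1
    return pd.Series({c: counts[c] / n_words for c in dic.categories},
                     index=dic.categories, dtype=float)
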