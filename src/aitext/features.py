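"""Tokenization and the 19 manually derived narrative features.

One Autobiographical Interview narrative (one subject, one condition, one
event cue) is tokenized into sentences and lowercase word tokens; tokens
are cross-referenced with the lexicon pre- and post-baseform conversion.
The 19 features per subject x condition pool the token statistics over
all cues of that condition:

==============  =========================================================
n_words         total number of words
n_sentences     total number of sentences
total_classified_words  words classified as noun/verb/adjective
n_adjectives / n_verbs / n_nouns  class counts
p_adjectives / p_verbs / p_nouns  class counts / n_words
n_bawl          words matched to a rated lexicon entry post-baseform
n_bawl_pre      words matched pre-baseform (always <= n_bawl)
wps             words per sentence
m_emo / m_arousal / m_image  mean valence / arousal / imageability
v_emo / v_arousal / v_image  sample variance of the same
med_freq        median frequency-per-million over matched occurrences
==============  =========================================================

Means, variances and the median are occurrence-level: every matched token
occurrence contributes once.  Undefined statistics (no matches, a single
match for a variance, zero denominators) are NaN; imputation happens only
at matrix assembly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, MatchStage, WordClass

__all__ = [
    "Condition",
    "Transcript",
    "TokenizedNarrative",
    "MANUAL_FEATURE_NAMES",
    "tokenize",
    "CueStats",
    "cue_stats",
    "merge_stats",
    "features_from_stats",
    "manual_features",
]


class Condition(str, Enum):
    AM = "AM"    # autobiographical memory (past events)
    EFT = "EFT"  # episodic future thinking (imagined future events)


@dataclass(frozen=True)
class Transcript:
    subject_id: str
    condition: Condition
    cue_id: str
    text: str


@dataclass(frozen=True)
class TokenizedNarrative:
    sentences: tuple[tuple[str, ...], ...]

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]


#: Fixed feature order of the manual feature set.
MANUAL_FEATURE_NAMES = [
    "n_words", "n_sentences", "total_classified_words",
    "n_adjectives", "n_verbs", "n_nouns",
    "p_adjectives", "p_verbs", "p_nouns",
    "n_bawl", "n_bawl_pre", "wps",
    "m_emo", "m_arousal", "m_image",
    "v_emo", "v_arousal", "v_image",
    "med_freq",
]

_SENTENCE_SPLIT = re.compile(r"[.?!]+")
# Maximal runs of Unicode letters; hyphen-joined compounds kept whole.
_TOKEN = re.compile(r"[^\W\d_]+(?:-[^\W\d_]+)*", re.UNICODE)


def tokenize(text: str) -> TokenizedNarrative:
    """Split a narrative into sentences (on ``.?!`` runs) and lowercase
    letter-run tokens.  Empty sentences are dropped; numerals and
    punctuation are not tokens."""
    sentences = []
    for chunk in _SENTENCE_SPLIT.split(text):
        tokens = tuple(m.group(0).lower() for m in _TOKEN.finditer(chunk))
        if tokens:
            sentences.append(tokens)
    return TokenizedNarrative(sentences=tuple(sentences))


@dataclass
class CueStats:
    """Pooling-safe sufficient statistics of one or more narratives.

    Pooling cues is list concatenation / count addition, so features of a
    cue subset computed from merged ``CueStats`` agree exactly with
    features computed on the concatenated text.
    """

    n_words: int = 0
    n_sentences: int = 0
    n_adjectives: int = 0
    n_verbs: int = 0
    n_nouns: int = 0
    n_bawl: int = 0
    n_bawl_pre: int = 0
    valence: list[float] = field(default_factory=list)
    arousal: list[float] = field(default_factory=list)
    imageability: list[float] = field(default_factory=list)
    freq: list[float] = field(default_factory=list)


def cue_stats(tok: TokenizedNarrative, lex: Lexicon) -> CueStats:
    """Token-level lexicon statistics of a single tokenized narrative."""
    st = CueStats(n_words=tok.n_words, n_sentences=tok.n_sentences)
    for token in tok.tokens:
        entry, stage = lex.lookup(token)
        # Word class: prefer the surface form's own row (the conversion
        # table classifies inflected forms), fall back to the matched entry.
        own = lex.get(token)
        classifier = own if own is not None else entry
        if classifier is not None:
            if classifier.word_class is WordClass.ADJECTIVE:
                st.n_adjectives += 1
            elif classifier.word_class is WordClass.VERB:
                st.n_verbs += 1
            elif classifier.word_class is WordClass.NOUN:
                st.n_nouns += 1
        if stage is MatchStage.MISS:
            continue
        st.n_bawl += 1
        if stage is MatchStage.RAW:
            st.n_bawl_pre += 1
        if not math.isnan(entry.valence):
            st.valence.append(entry.valence)
        if not math.isnan(entry.arousal):
            st.arousal.append(entry.arousal)
        if not math.isnan(entry.imageability):
            st.imageability.append(entry.imageability)
        if not math.isnan(entry.freq_per_million):
            st.freq.append(entry.freq_per_million)
    return st


def merge_stats(parts: Iterable[CueStats]) -> CueStats:
    out = CueStats()
    for p in parts:
        out.n_words += p.n_words
        out.n_sentences += p.n_sentences
        out.n_adjectives += p.n_adjectives
        out.n_verbs += p.n_verbs
        out.n_nouns += p.n_nouns
        out.n_bawl += p.n_bawl
        out.n_bawl_pre += p.n_bawl_pre
        out.valence += p.valence
        out.arousal += p.arousal
        out.imageability += p.imageability
        out.freq += p.freq
    return out


def _mean_var(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    var = float(arr.var(ddof=1)) if arr.size >= 2 else math.nan
    return mean, var


def features_from_stats(st: CueStats) -> pd.Series:
    """The 19-feature vector, in fixed order, from pooled statistics."""
    n = st.n_words
    m_emo, v_emo = _mean_var(st.valence)
    m_arousal, v_arousal = _mean_var(st.arousal)
    m_image, v_image = _mean_var(st.imageability)
    values = {
        "n_words": float(n),
        "n_sentences": float(st.n_sentences),
        "total_classified_words": float(st.n_adjectives + st.n_verbs + st.n_nouns),
        "n_adjectives": float(st.n_adjectives),
        "n_verbs": float(st.n_verbs),
        "n_nouns": float(st.n_nouns),
        "p_adjectives": st.n_adjectives / n if n else math.nan,
        "p_verbs": st.n_verbs / n if n else math.nan,
        "p_nouns": st.n_nouns / n if n else math.nan,
        "n_bawl": float(st.n_bawl),
        "n_bawl_pre": float(st.n_bawl_pre),
        "wps": n / st.n_sentences if st.n_sentences else math.nan,
        "m_emo": m_emo,
        "m_arousal": m_arousal,
        "m_image": m_image,
        "v_emo": v_emo,
        "v_arousal": v_arousal,
        "v_image": v_image,
        "med_freq": float(np.median(st.freq)) if st.freq else math.nan,
    }
    return pd.Series(values, index=MANUAL_FEATURE_NAMES, dtype=float)


def manual_features(transcripts: Sequence[Transcript], lex: Lexicon) -> pd.Series:
    """Pooled 19-feature set for one subject x condition.

    All transcripts must share the subject and condition; statistics pool
    over every cue of that condition.
    """
    if not transcripts:
        raise ValueError("no transcripts given")
    subjects = {t.subject_id for t in transcripts}
    conditions = {t.condition for t in transcripts}
    if len(subjects) > 1 or len(conditions) > 1:
        raise ValueError(
            f"transcripts mix subjects {subjects} / conditions {conditions}; "
            "pass one subject x condition at a time"
        )
    pooled = merge_stats(cue_stats(tokenize(t.text), lex) for t in transcripts)
    return features_from_stats(pooled)
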