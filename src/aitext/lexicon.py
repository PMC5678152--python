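"""Normative word lexicon and category dictionary I/O.

The lexicon emulates an affective word list of the BAWL-R kind: every row
carries a surface form, its baseform (lemma), a word class and — for rows
that are proper lexicon entries — normative ratings for valence, arousal
and imageability plus a corpus frequency.  Rows whose ratings are missing
act as a baseform-conversion table only (an offline stand-in for a
lemmatization webservice): they let an inflected surface form be resolved
to its rated base entry.

The category dictionary is a LIWC-style word-category dictionary: an
ordered set of content categories and a list of patterns (exact words or
``stem*`` prefixes), each mapping to one or more categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WordClass",
    "MatchStage",
    "LexiconEntry",
    "Lexicon",
    "CategoryDictionary",
    "LexiconFormatError",
    "LexiconValidationError",
    "load_lexicon",
    "save_lexicon",
    "load_category_dictionary",
    "save_category_dictionary",
]

#: Valid ranges of the normative rating scales.
RATING_RANGES = {
    "valence": (-3.0, 3.0),
    "arousal": (1.0, 5.0),
    "imageability": (1.0, 7.0),
}

LEXICON_COLUMNS = ["word", "baseform", "class", "valence", "arousal", "imageability", "freq"]


class LexiconFormatError(ValueError):
    """Raised when a lexicon or dictionary file is structurally malformed."""


class LexiconValidationError(ValueError):
    """Raised when a lexicon row violates a rating-scale or field invariant."""


class WordClass(str, Enum):
    NOUN = "noun"
    VERB = "verb"
    ADJECTIVE = "adjective"
    OTHER = "other"


class MatchStage(str, Enum):
    """How a token was resolved against the lexicon."""

    RAW = "raw"          # the token itself is a rated entry
    BASEFORM = "baseform"  # resolved to a rated entry via its baseform
    MISS = "miss"


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    baseform: str
    word_class: WordClass
    valence: float = math.nan
    arousal: float = math.nan
    imageability: float = math.nan
    freq_per_million: float = math.nan

    @property
    def has_ratings(self) -> bool:
        """Whether this row is a rated lexicon entry (vs. conversion-only)."""
        return not (math.isnan(self.valence) and math.isnan(self.arousal)
                    and math.isnan(self.imageability))

    def validate(self, row: object = "?") -> None:
        if not self.word:
            raise LexiconValidationError(f"row {row}: empty word")
        if not self.baseform:
            raise LexiconValidationError(f"row {row}: empty baseform for {self.word!r}")
        for name in ("valence", "arousal", "imageability"):
            value = getattr(self, name)
            lo, hi = RATING_RANGES[name]
            if not math.isnan(value) and not (lo <= value <= hi):
                raise LexiconValidationError(
                    f"row {row}: {name}={value} outside [{lo}, {hi}] for word {self.word!r}"
                )
        if not math.isnan(self.freq_per_million) and self.freq_per_million < 0:
            raise LexiconValidationError(
                f"row {row}: negative frequency for word {self.word!r}"
            )


class Lexicon:
    """Case-insensitive word lexicon with baseform resolution.

    ``entries`` maps every surface form (lowercased) to its row.
    ``baseform_index`` maps each baseform to the rated entry it resolves
    to: the entry whose own word equals the baseform when present,
    otherwise the first rated entry sharing that baseform.
    """

    def __init__(self, entries: list[LexiconEntry]):
        self.entries: dict[str, LexiconEntry] = {}
        for entry in entries:
            key = entry.word.lower()
            if key in self.entries:
                logger.warning("duplicate lexicon word %r: keeping first occurrence", key)
                continue
            self.entries[key] = entry

        self.baseform_index: dict[str, LexiconEntry] = {}
        # Prefer the self-named entry, then any rated entry with that baseform.
        for entry in self.entries.values():
            bf = entry.baseform.lower()
            current = self.baseform_index.get(bf)
            if entry.word.lower() == bf:
                self.baseform_index[bf] = entry
            elif current is None and entry.has_ratings:
                self.baseform_index[bf] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, token: str) -> Optional[LexiconEntry]:
        """The token's own row, if any (case-insensitive)."""
        return self.entries.get(token.lower())

    def lookup(self, token: str) -> tuple[Optional[LexiconEntry], MatchStage]:
        """Resolve a token to a rated entry, pre- or post-baseform.

        Stage ``raw``: the token itself is a rated entry.  Stage
        ``baseform``: the token's row exists but carries no ratings
        (conversion-table row) and its baseform resolves, via the
        baseform index, to a rated entry.  Tokens without a row of their
        own have no known baseform and are misses.
        """
        if not token:
            raise ValueError("empty token")
        own = self.entries.get(token.lower())
        if own is not None and own.has_ratings:
            return own, MatchStage.RAW
        if own is not None:
            base = self.baseform_index.get(own.baseform.lower())
            if base is not None and base.has_ratings:
                return base, MatchStage.BASEFORM
        return None, MatchStage.MISS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.word, e.baseform, e.word_class.value, e.valence, e.arousal,
             e.imageability, e.freq_per_million)
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=LEXICON_COLUMNS)


def lookup(lex: Lexicon, token: str) -> tuple[Optional[LexiconEntry], MatchStage]:
    """Functional form of :meth:`Lexicon.lookup`."""
    return lex.lookup(token)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a UTF-8 TSV with the canonical 7-column header.

    Ratings may be blank or ``NA`` (conversion-table rows).  Duplicate
    surface forms keep the first occurrence with a warning.  Out-of-range
    ratings raise :class:`LexiconValidationError` naming the row.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"word": str, "baseform": str, "class": str},
                        keep_default_na=True, na_values=["NA", ""])
    missing = [c for c in LEXICON_COLUMNS if c not in frame.columns]
    if missing:
        raise LexiconFormatError(f"{path}: missing column(s) {missing}")

    entries = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            word_class = WordClass(str(row[2]).lower())
        except ValueError as exc:
            raise LexiconValidationError(f"row {i}: unknown word class {row[2]!r}") from exc
        entry = LexiconEntry(
            word=str(row[0]).lower(),
            baseform=str(row[1]).lower(),
            word_class=word_class,
            valence=float(row[3]) if pd.notna(row[3]) else math.nan,
            arousal=float(row[4]) if pd.notna(row[4]) else math.nan,
            imageability=float(row[5]) if pd.notna(row[5]) else math.nan,
            freq_per_million=float(row[6]) if pd.notna(row[6]) else math.nan,
        )
        entry.validate(row=i)
        entries.append(entry)
    return Lexicon(entries)


def save_lexicon(lex: Lexicon, path: str | Path) -> None:
    lex.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class CategoryDictionary:
    """LIWC-style category dictionary.

    ``categories`` fixes the feature-column order; ``patterns`` maps each
    pattern (exact word, or prefix ending in ``*``) to the set of
    category names it increments.  A token matching several patterns
    increments every category of every matching pattern (multi-category
    membership is the norm, so category proportions need not sum to 1).
    """

    categories: list[str]
    patterns: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categories:
            raise LexiconFormatError("category dictionary needs at least one category")
        known = set(self.categories)
        for pattern, cats in self.patterns.items():
            if not cats:
                raise LexiconFormatError(f"pattern {pattern!r} maps to no category")
            unknown = cats - known
            if unknown:
                raise LexiconFormatError(f"pattern {pattern!r} references unknown {unknown}")
        self._exact = {p: cats for p, cats in self.patterns.items() if not p.endswith("*")}
        self._prefixes = [(p[:-1], cats) for p, cats in self.patterns.items() if p.endswith("*")]

    def match(self, token: str) -> set[str]:
        """All categories incremented by this token (union over patterns)."""
        token = token.lower()
        cats: set[str] = set()
        cats |= self._exact.get(token, set())
        for prefix, pcats in self._prefixes:
            if token.startswith(prefix):
                cats |= pcats
        return cats


def load_category_dictionary(path: str | Path) -> CategoryDictionary:
    """Parse a LIWC-style ``.dic`` file.

    Format: a header delimited by lines containing only ``%`` that maps
    integer category ids to names (``id<TAB>name``), followed by pattern
    lines ``pattern id id ...``.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.strip() for ln in text.splitlines()]
    delimiters = [i for i, ln in enumerate(lines) if ln == "%"]
    if len(delimiters) < 2:
        raise LexiconFormatError(f"{path}: expected a %%-delimited header")
    start, end = delimiters[0], delimiters[1]

    id_to_name: dict[int, str] = {}
    for ln in lines[start + 1:end]:
        if not ln:
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise LexiconFormatError(f"{path}: malformed header line {ln!r}")
        id_to_name[int(parts[0])] = parts[1]
    categories = [id_to_name[i] for i in sorted(id_to_name)]

    patterns: dict[str, set[str]] = {}
    for ln in lines[end + 1:]:
        if not ln:
            continue
        parts = ln.split()
        pattern, ids = parts[0].lower(), parts[1:]
        cats = set()
        for cid in ids:
            if int(cid) not in id_to_name:
                raise LexiconFormatError(
                    f"{path}: pattern {pattern!r} references unknown category id {cid}"
                )
            cats.add(id_to_name[int(cid)])
        patterns[pattern] = patterns.get(pattern, set()) | cats
    return CategoryDictionary(categories=categories, patterns=patterns)


def save_category_dictionary(dic: CategoryDictionary, path: str | Path) -> None:
    name_to_id = {name: i + 1 for i, name in enumerate(dic.categories)}
    out = ["%"]
    out += [f"{i}\t{name}" for name, i in name_to_id.items()]
    out.append("%")
    for pattern in sorted(dic.patterns):
        ids = sorted(name_to_id[c] for c in dic.patterns[pattern])
        out.append(pattern + "\t" + "\t".join(str(i) for i in ids))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
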