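"""Synthetic study generator: lexicon, category dictionary, two-condition
narrative corpus, detail scores and intertemporal-choice data.

No raw interview data are publicly available for this kind of study, so
every stage of the pipeline is exercised on synthetic data built to carry
the statistical structure the real data are reported to have:

* Each subject has two independent latent factors — *verbosity* (how much
  text they produce; the quantity axis that dominates the first principal
  component of real feature matrices) and *richness* (how strongly their
  word choice tilts toward imageable, positively valenced words; the
  quality axis).  Condition-specific realizations of each factor share a
  configurable cross-condition correlation ``rho``, mirroring the
  observed AM/EFT consistency of both quantitative and qualitative
  features.
* Internal (episodic) detail scores load on both quantity and quality;
  semantic detail scores load on quantity only.  That dissociation is
  what the regression stage should recover.
* sqrt-transformed discount rates are negatively coupled to both factors
  (weakly, as reported), and choice data are simulated from the implied
  hyperbolic agent on the adaptive task.

The generated text is letter-salad, not German: narratives are bags of
synthetic lexicon words (plus inflected variants and out-of-vocabulary
fillers) chopped into sentences.  Everything is deterministic given the
mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .discounting import StaircaseConfig, simulate_adaptive_task, trials_to_frame
from .features import Condition, Transcript
from .lexicon import (CategoryDictionary, Lexicon, LexiconEntry, WordClass,
                      save_category_dictionary, save_lexicon)

__all__ = ["GeneratorConfig", "SyntheticStudy", "make_lexicon",
           "make_category_dictionary", "generate_corpus", "write_study"]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_SUFFIXES = ("e", "en", "er", "es", "st")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-generation parameters.

    Effect sizes are on the detail-score scale (points per 1 SD of the
    latent factor); ``rho`` is the cross-condition correlation of the
    latent factors; discount couplings are on the sqrt(k) scale.
    """

    n_subjects: int = 150
    cues_per_condition: int = 5
    lexicon_size: int = 400          # base (rated) entries
    n_categories: int = 64
    rho: float = 0.7                 # cross-condition latent correlation
    words_per_cue: float = 70.0      # median words per narrative
    word_count_spread: float = 0.25  # lognormal sigma of cue word counts
    verbosity_effect: float = 0.5    # log word-count units per SD verbosity
    sentence_length_effect: float = 0.15  # log words-per-sentence per SD verbosity
    adjective_tilt: float = 0.3      # adjective sampling tilt per SD verbosity
    richness_tilt: float = 0.45      # sampling-weight tilt per SD richness
    p_inflected: float = 0.35        # emit an inflected (unrated) variant
    p_oov: float = 0.12              # emit an out-of-vocabulary token
    internal_base: float = 40.0
    internal_quantity: float = 12.0  # a1
    internal_quality: float = 7.0    # a2
    internal_noise: float = 5.0
    internal_am_shift: float = 3.0   # internal details higher for AM
    semantic_base: float = 20.0
    semantic_quantity: float = 6.0   # b1 (no quality loading: b2 = 0)
    semantic_noise: float = 6.0
    semantic_eft_shift: float = 1.5  # semantic details higher for EFT
    external_base: float = 15.0
    external_noise: float = 5.0
    external_am_shift: float = 1.0
    sqrt_k_base: float = 0.12
    sqrt_k_quantity: float = -0.02   # coupling to verbosity
    sqrt_k_quality: float = -0.015   # coupling to richness
    sqrt_k_noise: float = 0.03
    sqrt_k_floor: float = 0.01
    choice_beta: float = 5.0
    seed: int = 0


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    lexicon: Lexicon
    dictionary: CategoryDictionary
    transcripts: list[Transcript]
    scores: pd.DataFrame    # subject_id, condition, internal, semantic, external
    choices: pd.DataFrame   # subject_id, delay_days, amount_ss, amount_ll, choice
    truth: pd.DataFrame     # subject-level latents and true discount parameters

    @property
    def subjects(self) -> list[str]:
        return list(self.truth["subject_id"])


def _make_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
                   for _ in range(n_syllables))


def make_lexicon(size: int = 400, seed: int | np.random.Generator = 0) -> Lexicon:
    """Synthetic affective word lexicon with ``size`` rated base entries.

    Class proportions approximate an affective word database (~0.70 noun,
    0.17 verb, 0.10 adjective, 0.03 other); valence in [-3, 3], arousal
    in [1, 5], imageability in [1, 7]; frequencies lognormal (right-
    skewed, which is why features use the median).  Each base entry gets
    1-2 inflected surface variants carrying no ratings — conversion-table
    rows that resolve to the base entry.
    """
    if size < 50:
        raise ValueError("lexicon size must be >= 50")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    words: set[str] = set()
    entries: list[LexiconEntry] = []
    classes = rng.choice(["noun", "verb", "adjective", "other"],
                         size=size, p=[0.70, 0.17, 0.10, 0.03])
    while len(words) < size:
        words.add(_make_word(rng, int(rng.integers(2, 5))))
    base_words = sorted(words)
    rng.shuffle(base_words)

    variants: list[LexiconEntry] = []
    taken = set(base_words)
    for word, word_class in zip(base_words, classes):
        entries.append(LexiconEntry(
            word=word, baseform=word, word_class=WordClass(word_class),
            valence=float(np.clip(rng.normal(0.0, 1.2), -3, 3)),
            arousal=float(np.clip(rng.normal(2.8, 0.8), 1, 5)),
            imageability=float(np.clip(rng.normal(4.0, 1.4), 1, 7)),
            freq_per_million=float(rng.lognormal(2.5, 1.2)),
        ))
        for suffix in rng.choice(_SUFFIXES, size=int(rng.integers(1, 3)), replace=False):
            variant = word + suffix
            if variant in taken:
                continue
            taken.add(variant)
            variants.append(LexiconEntry(word=variant, baseform=word,
                                         word_class=WordClass(word_class)))
    return Lexicon(entries + variants)


def make_category_dictionary(lexicon: Lexicon, n_categories: int = 64,
                             seed: int | np.random.Generator = 0) -> CategoryDictionary:
    """Wildcard category dictionary whose patterns are stems and exact
    forms of lexicon words, each mapping to 1-2 of ``n_categories``.

    Category membership is balanced along the valence/imageability axis
    (each category pairs affectively high and low words), emulating real
    content categories, which are organized by topic rather than affect
    — dictionary proportions then correlate only weakly with the manual
    affective features.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    categories = [f"cat{i + 1:02d}" for i in range(n_categories)]
    rated = sorted((e for e in lexicon.entries.values() if e.has_ratings),
                   key=lambda e: e.word)
    quality = np.array([0.5 * (e.imageability + e.valence) for e in rated])
    order = list(np.argsort(quality))
    # interleave affect extremes so consecutive pairs are balanced
    interleaved = []
    while order:
        interleaved.append(order.pop(0))
        if order:
            interleaved.append(order.pop(-1))
    patterns: dict[str, set[str]] = {}
    for i, idx in enumerate(interleaved):
        word = rated[idx].baseform
        pattern = word[:4] + "*" if rng.random() < 0.6 and len(word) > 4 else word
        cats = {categories[(i // 2) % n_categories]}
        if rng.random() < 0.3:
            cats.add(categories[int(rng.integers(n_categories))])
        patterns[pattern] = patterns.get(pattern, set()) | cats
    return CategoryDictionary(categories=categories, patterns=patterns)


def _correlated(common: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """A condition-specific standard-normal realization correlating
    ``rho`` with its counterpart from the other condition."""
    return np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=common.shape)


def _narrative(rng: np.random.Generator, n_words: int, base_words: list[str],
               weights: np.ndarray, variant_map: dict[str, list[str]],
               p_inflected: float, p_oov: float, mean_sentence_len: float = 11.0) -> str:
    idx = rng.choice(len(base_words), size=n_words, p=weights)
    tokens = []
    for i in idx:
        if rng.random() < p_oov:
            tokens.append("q" + _make_word(rng, int(rng.integers(2, 4))))
            continue
        word = base_words[i]
        variants = variant_map.get(word)
        if variants and rng.random() < p_inflected:
            tokens.append(variants[int(rng.integers(len(variants)))])
        else:
            tokens.append(word)
    sentences, pos = [], 0
    while pos < len(tokens):
        length = int(np.clip(rng.poisson(mean_sentence_len) + 3, 4, 40))
        sentences.append(" ".join(tokens[pos:pos + length]) + ".")
        pos += length
    return " ".join(sentences)


def generate_corpus(config: GeneratorConfig) -> SyntheticStudy:
    """Generate a full synthetic study under ``config`` (see module
    docstring for the latent structure)."""
    rng = np.random.default_rng(config.seed)
    lexicon = make_lexicon(config.lexicon_size, rng)
    dictionary = make_category_dictionary(lexicon, config.n_categories, rng)

    rated = [e for e in lexicon.entries.values() if e.has_ratings]
    base_words = [e.word for e in rated]
    z_image = _zscore(np.array([e.imageability for e in rated]))
    z_valence = _zscore(np.array([e.valence for e in rated]))
    quality_axis = 0.5 * (z_image + z_valence)
    is_adjective = np.array([e.word_class is WordClass.ADJECTIVE for e in rated], dtype=float)
    variant_map: dict[str, list[str]] = {}
    for e in lexicon.entries.values():
        if not e.has_ratings:
            variant_map.setdefault(e.baseform, []).append(e.word)

    n = config.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    verbosity = rng.normal(size=n)
    richness = rng.normal(size=n)
    quantity = {c: _correlated(verbosity, config.rho, rng) for c in Condition}
    quality = {c: _correlated(richness, config.rho, rng) for c in Condition}

    transcripts: list[Transcript] = []
    score_rows = []
    for s, subject in enumerate(subjects):
        for cond in Condition:
            qz, rz = quantity[cond][s], quality[cond][s]
            # longer narratives also carry relatively more adjectives and
            # longer sentences, as observed in real feature matrices
            weights = np.exp(config.richness_tilt * rz * quality_axis
                             + config.adjective_tilt * qz * is_adjective)
            weights = weights / weights.sum()
            mean_len = 11.0 * float(np.exp(config.sentence_length_effect * qz))
            for cue in range(config.cues_per_condition):
                n_words = max(5, int(round(np.exp(
                    np.log(config.words_per_cue) + config.verbosity_effect * qz
                    + rng.normal(0.0, config.word_count_spread)))))
                text = _narrative(rng, n_words, base_words, weights, variant_map,
                                  config.p_inflected, config.p_oov, mean_len)
                transcripts.append(Transcript(subject, cond, f"cue{cue + 1:02d}", text))

            am = cond is Condition.AM
            internal = (config.internal_base + (config.internal_am_shift if am else 0)
                        + config.internal_quantity * qz + config.internal_quality * rz
                        + rng.normal(0.0, config.internal_noise))
            semantic = (config.semantic_base + (0 if am else config.semantic_eft_shift)
                        + config.semantic_quantity * qz
                        + rng.normal(0.0, config.semantic_noise))
            external = (config.external_base + (config.external_am_shift if am else 0)
                        + 0.2 * config.internal_quantity * qz
                        + rng.normal(0.0, config.external_noise))
            score_rows.append({
                "subject_id": subject, "condition": cond.value,
                "internal": max(0, int(round(internal))),
                "semantic": max(0, int(round(semantic))),
                "external": max(0, int(round(external))),
            })
    scores = pd.DataFrame(score_rows)

    sqrt_k = np.clip(
        config.sqrt_k_base
        + config.sqrt_k_quantity * verbosity + config.sqrt_k_quality * richness
        + rng.normal(0.0, config.sqrt_k_noise, size=n),
        config.sqrt_k_floor, None)
    k_true = sqrt_k ** 2

    choice_frames = []
    for subject, k in zip(subjects, k_true):
        frame = trials_to_frame(simulate_adaptive_task(
            k_true=float(k), beta=config.choice_beta, config=StaircaseConfig(), seed=rng))
        frame.insert(0, "subject_id", subject)
        choice_frames.append(frame)
    choices = pd.concat(choice_frames, ignore_index=True)

    truth = pd.DataFrame({
        "subject_id": subjects,
        "verbosity": verbosity,
        "richness": richness,
        "quantity_AM": quantity[Condition.AM], "quantity_EFT": quantity[Condition.EFT],
        "quality_AM": quality[Condition.AM], "quality_EFT": quality[Condition.EFT],
        "k_true": k_true, "sqrt_k_true": sqrt_k,
    })
    return SyntheticStudy(config=config, lexicon=lexicon, dictionary=dictionary,
                          transcripts=transcripts, scores=scores, choices=choices,
                          truth=truth)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study to disk: lexicon TSV, dictionary .dic, transcripts
    JSONL, scores/choices CSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lexicon": outdir / "lexicon.tsv",
        "dictionary": outdir / "categories.dic",
        "transcripts": outdir / "transcripts.jsonl",
        "scores": outdir / "scores.csv",
        "choices": outdir / "choices.csv",
        "truth": outdir / "truth.json",
    }
    save_lexicon(study.lexicon, paths["lexicon"])
    save_category_dictionary(study.dictionary, paths["dictionary"])
    with open(paths["transcripts"], "w", encoding="utf-8") as fh:
        for t in study.transcripts:
            fh.write(json.dumps({"subject_id": t.subject_id, "condition": t.condition.value,
                                 "cue_id": t.cue_id, "text": t.text}) + "\n")
    study.scores.to_csv(paths["scores"], index=False)
    study.choices.to_csv(paths["choices"], index=False)
    truth = {"config": asdict(study.config),
             "subjects": study.truth.to_dict(orient="records")}
    paths["truth"].write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return paths


def load_transcripts(path: str | Path) -> list[Transcript]:
    """Read a transcripts JSONL file back into Transcript records."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(Transcript(obj["subject_id"], Condition(obj["condition"]),
                                  obj["cue_id"], obj["text"]))
    return out
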