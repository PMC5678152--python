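import numpy as np
import pytest

from aitext.lexicon import CategoryDictionary, Lexicon, LexiconEntry, WordClass
from aitext.features import Condition, Transcript
from aitext.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_lexicon() -> Lexicon:
    """Hand-built lexicon: rated base entries plus unrated inflected rows
    (the conversion table) and one rated inflected form."""
    entries = [
        # word, baseform, class, valence, arousal, imageability, freq
        LexiconEntry("hund", "hund", WordClass.NOUN, 1.0, 2.0, 6.5, 120.0),
        LexiconEntry("hunde", "hund", WordClass.NOUN),            # conversion row
        LexiconEntry("freundlich", "freundlich", WordClass.ADJECTIVE, 2.0, 1.5, 3.0, 40.0),
        LexiconEntry("freundlichste", "freundlich", WordClass.ADJECTIVE),
        LexiconEntry("rennen", "rennen", WordClass.VERB, -1.0, 4.0, 4.0, 15.0),
        LexiconEntry("rennt", "rennen", WordClass.VERB),
        LexiconEntry("haus", "haus", WordClass.NOUN, 0.5, 1.2, 7.0, 300.0),
        LexiconEntry("und", "und", WordClass.OTHER, 0.0, 1.0, 1.0, 9000.0),
        LexiconEntry("spiel", "spiel", WordClass.NOUN, 1.5, 3.0, 5.0, 80.0),
        LexiconEntry("spielt", "spiel", WordClass.VERB),
    ]
    return Lexicon(entries)


@pytest.fixture(scope="session")
def tiny_dictionary() -> CategoryDictionary:
    return CategoryDictionary(
        categories=["leisure", "motion", "social"],
        patterns={"spiel*": {"leisure"}, "renn*": {"motion"},
                  "hund": {"social", "leisure"}},
    )


def _t(subject, cond, cue, text):
    return Transcript(subject, Condition(cond), cue, text)


@pytest.fixture(scope="session")
def small_study():
    """Small but complete synthetic study shared across tests."""
    return generate_corpus(GeneratorConfig(n_subjects=12, cues_per_condition=3,
                                           lexicon_size=120, n_categories=8, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
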