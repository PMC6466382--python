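import random

import pytest

from emoscreen import (
    GeneratorSpec,
    MSAILexicon,
    LexiconEntry,
    build_condition_profile,
    condition_targets,
    make_fixture_lexicon,
    make_modifier_tables,
    make_scale_texts,
)


@pytest.fixture(scope="session")
def spec():
    return GeneratorSpec(seed=1)


@pytest.fixture(scope="session")
def lexicons(spec):
    """(11-category lexicon, 8-category source) pair, seeded."""
    return make_fixture_lexicon(spec)


@pytest.fixture(scope="session")
def msai(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def tables():
    return make_modifier_tables()


@pytest.fixture(scope="session")
def profiles(msai, tables):
    """Scale-derived prototype per condition."""
    return [
        build_condition_profile(
            make_scale_texts(t, msai, rng=random.Random(1)), cond, msai, tables
        )
        for cond, t in condition_targets().items()
    ]


@pytest.fixture()
def tiny_lexicon():
    """Hand-written lexicon for exact scoring traces."""
    lex = MSAILexicon()
    for word, cat, x in [
        ("sad", "sadness", 0.6),
        ("happy", "joy", 0.8),
        ("scared", "fear", 0.7),
        ("nice", "joy", 0.5),
        ("mediocre", "disgust", 0.4),
        ("depressed", "grief", 0.9),
        ("tired", "sadness", 0.3),
    ]:
        lex.add(LexiconEntry(word, cat, x))
    return lex
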