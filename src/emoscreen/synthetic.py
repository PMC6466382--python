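"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (i) a pseudo-word affect lexicon — the 8-emotion source
version has bimodal intensities inside disgust/sadness/fear so the
2-means split has a real boundary; (ii) stand-in screening-scale texts
whose scored profile approximates a chosen target distribution; (iii)
user corpora whose texts are word salads with controlled category
statistics: each user's word counts follow a Dirichlet draw centered on
a target sentiment distribution, so the distribution recovered by the
scoring pipeline concentrates on the target as the concentration grows.

Texts carry no linguistic realism — they validate the arithmetic of the
pipeline, not its behaviour on natural language.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lexicon import (
    CATEGORIES_8,
    CATEGORIES_11,
    EmotionLexicon,
    LexiconEntry,
    MSAILexicon,
    build_msai_lexicon,
)
from .scoring import SentimentDistribution, AffectVector, normalize_distribution
from .textproc import ModifierTables, default_tables
from .training import LabeledUser

#: Source categories split downstream; they get two intensity modes.
_BIMODAL = ("disgust", "sadness", "fear")

#: Target sentiment signatures of the five conditions, echoing their
#: clinical descriptions (depressive: grief/sadness; anxiety: fear and
#: apprehensive anticipation; OCD: disgust/loathing with anticipation;
#: bipolar: alternating joy and depressive mass; panic: terror/fear).
CONDITION_SIGNATURES: dict[str, dict[str, float]] = {
    "depressive": {"grief": 0.40, "sadness": 0.40, "anger": 0.10, "fear": 0.05, "disgust": 0.05},
    "anxiety": {"fear": 0.45, "anticipation": 0.30, "sadness": 0.10, "surprise": 0.10, "terror": 0.05},
    "ocd": {"disgust": 0.35, "loathing": 0.25, "anticipation": 0.20, "fear": 0.10, "anger": 0.10},
    "bipolar": {"joy": 0.30, "sadness": 0.25, "grief": 0.15, "anger": 0.15, "surprise": 0.15},
    "panic": {"terror": 0.45, "fear": 0.30, "surprise": 0.15, "anger": 0.05, "sadness": 0.05},
}

#: Background (control) distribution: mostly positive affect with light
#: negative mass.
BACKGROUND: dict[str, float] = {
    **{c: 0.22 for c in ("joy", "trust", "anticipation", "surprise")},
    **{c: 0.12 / 7 for c in ("anger", "loathing", "disgust", "grief", "sadness", "terror", "fear")},
}


def _as_distribution(mass: Mapping[str, float]) -> SentimentDistribution:
    v = np.zeros(len(CATEGORIES_11))
    for cat, x in mass.items():
        v[CATEGORIES_11.index(cat)] = x
    return normalize_distribution(AffectVector(v))


def condition_targets() -> dict[str, SentimentDistribution]:
    return {c: _as_distribution(m) for c, m in CONDITION_SIGNATURES.items()}


def background_target() -> SentimentDistribution:
    return _as_distribution(BACKGROUND)


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic corpora.

    Cohort sizes follow the recovery experiment (5 conditions x 20 users
    plus 100 controls); tweets per user sits in the observed 12–18
    median range; the Dirichlet concentration controls how tightly a
    user's word statistics follow their target distribution.
    """

    n_words_per_category: int = 4
    n_users_per_condition: int = 20
    n_controls: int = 100
    n_unlabeled: int = 200
    tweets_per_user: int = 14
    words_per_tweet: int = 8
    concentration: float = 50.0
    modifier_rate: float = 0.1
    multi_label_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words_per_category < 2:
            raise ValueError("need at least 2 words per category")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for rate in (self.modifier_rate, self.multi_label_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# pseudo-word lexicon

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
#: words the tokenizer treats specially, or common fillers used in items
_RESERVED = {
    "i", "feel", "am", "and", "the", "a", "today", "me", "my",
}


def _pseudo_word(rng: random.Random, taken: set[str], reserved: set[str]) -> str:
    while True:
        w = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(3)
        )
        if w not in taken and w not in reserved:
            taken.add(w)
            return w


def make_fixture_lexicon(
    spec: GeneratorSpec, tables: ModifierTables | None = None
) -> tuple[MSAILexicon, EmotionLexicon]:
    """Generate the 8-category source lexicon and its 11-category refinement.

    Split-bound categories get ``n_words_per_category`` words in each of
    two intensity modes (low 0.15–0.35, high 0.75–0.95, gap >= 0.3), so
    every final category holds ``n_words_per_category`` words; the other
    source categories draw intensities uniformly from 0.2–0.95.
    """
    tables = tables or default_tables()
    rng = random.Random(spec.seed)
    reserved = (
        _RESERVED
        | set(tables.degree_adverbs)
        | tables.negations
        | tables.adversatives
    )
    taken: set[str] = set()
    source = EmotionLexicon()
    n = spec.n_words_per_category
    for cat in CATEGORIES_8:
        if cat in _BIMODAL:
            intensities = [rng.uniform(0.15, 0.35) for _ in range(n)] + [
                rng.uniform(0.75, 0.95) for _ in range(n)
            ]
        else:
            intensities = [rng.uniform(0.2, 0.95) for _ in range(n)]
            while len(set(intensities)) < 2:  # guard degenerate categories
                intensities[-1] = rng.uniform(0.2, 0.95)
        for x in intensities:
            source.add(LexiconEntry(_pseudo_word(rng, taken, reserved), cat, x))
    msai = build_msai_lexicon(source, seed=spec.seed)
    return msai, source


def make_modifier_tables() -> ModifierTables:
    """The package's default qualifier tables."""
    return default_tables()


# ---------------------------------------------------------------------------
# scale texts


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive mass")
    quota = w / w.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


def make_scale_texts(
    target: SentimentDistribution,
    msai: MSAILexicon,
    n_items: int = 40,
    rng: random.Random | None = None,
) -> list[str]:
    """Stand-in screening-scale items whose scored profile tracks ``target``.

    Each item names one sentiment word; categories receive items in
    proportion to their target mass, using each category's
    maximum-intensity word so the item contributions are equal and the
    resulting profile matches the target up to apportionment rounding.
    These are synthetic stand-ins for published scales, not their text.
    """
    rng = rng or random.Random(0)
    counts = _apportion(target.values, n_items)
    items: list[str] = []
    templates = ("i feel {w}.", "i am {w} all day.", "everything makes me {w}.")
    for cat, k in zip(CATEGORIES_11, counts):
        if k == 0:
            continue
        entries = msai.entries_for(cat)
        if not entries:
            raise ValueError(f"lexicon has no words for category {cat!r}")
        word = max(entries, key=lambda e: e.intensity).word
        for _ in range(int(k)):
            items.append(rng.choice(templates).format(w=word))
    rng.shuffle(items)
    return items


def perturb_profile(
    profile,
    rng: np.random.Generator,
    background_mix: float = 0.45,
    concentration: float = 80.0,
):
    """Dirichlet-perturb a condition profile toward the background.

    Emulates the deviation between a scale-derived prototype and how the
    same condition presents in social-media language: the profile is
    mixed ``background_mix`` of the way toward the background
    distribution, then one Dirichlet draw at ``concentration`` adds
    sampling noise.  The result sits where healthy controls hover near
    the positive-diagnosis boundary — the regime profile training is
    meant to correct.
    """
    from .diagnosis import ConditionProfile

    center = (1 - background_mix) * profile.vector + background_mix * background_target().values
    v = rng.dirichlet(concentration * center + 1e-4)
    return ConditionProfile(profile.condition, v / v.sum())


# ---------------------------------------------------------------------------
# user and cohort generation


def generate_user(
    target: SentimentDistribution,
    spec: GeneratorSpec,
    rng: random.Random,
    user_id: str = "u0",
    conditions: set[str] | None = None,
    tables: ModifierTables | None = None,
    msai: MSAILexicon | None = None,
    lexicon_cache: dict | None = None,
) -> LabeledUser:
    """Compose a user's tweets around a target sentiment distribution.

    A per-user category mixture is drawn from Dirichlet(concentration *
    target); word counts are then apportioned deterministically to the
    mixture (weighted inversely by each category's mean intensity so the
    *intensity mass*, which is what scoring measures, matches the
    mixture), and words cycle through each category's vocabulary.
    Qualifiers are injected at ``modifier_rate`` per word: degree adverbs
    (p=.5), sentiment punctuation (p=.25) or negation (p=.25).
    """
    if msai is None:
        raise ValueError("a lexicon is required to compose texts")
    tables = tables or default_tables()
    if lexicon_cache is None:
        lexicon_cache = {}
    if "by_cat" not in lexicon_cache:
        by_cat = {}
        for cat in CATEGORIES_11:
            entries = sorted(msai.entries_for(cat), key=lambda e: e.word)
            by_cat[cat] = entries
        lexicon_cache["by_cat"] = by_cat
        lexicon_cache["mean_int"] = {
            cat: (np.mean([e.intensity for e in es]) if es else 1.0)
            for cat, es in by_cat.items()
        }
    by_cat = lexicon_cache["by_cat"]
    mean_int = lexicon_cache["mean_int"]

    n_words = spec.tweets_per_user * spec.words_per_tweet
    alpha = spec.concentration * target.values + 1e-4
    theta = np.random.default_rng(rng.randrange(2**31)).dirichlet(alpha)
    # intensity mass per category should follow theta, so word *counts*
    # are weighted by 1/mean-intensity
    weights = np.array(
        [theta[i] / mean_int[cat] for i, cat in enumerate(CATEGORIES_11)]
    )
    counts = _apportion(weights, n_words)

    words: list[str] = []
    for cat, k in zip(CATEGORIES_11, counts):
        entries = by_cat[cat]
        if not entries or k == 0:
            continue
        # equal use of the category vocabulary keeps the realized mean
        # intensity at the category mean; remainder slots go to the
        # words nearest the mean so the intensity mass stays on target
        base, rem = divmod(int(k), len(entries))
        words.extend(e.word for e in entries for _ in range(base))
        nearest = sorted(entries, key=lambda e: abs(e.intensity - mean_int[cat]))
        words.extend(e.word for e in nearest[:rem])
    rng.shuffle(words)

    decorated: list[str] = []
    punct_keys = sorted(tables.sentiment_punct)
    degree_keys = sorted(tables.degree_adverbs)
    negation_keys = sorted(tables.negations)
    for w in words:
        if rng.random() < spec.modifier_rate:
            u = rng.random()
            if u < 0.5:
                decorated.append(f"{rng.choice(degree_keys)} {w}")
            elif u < 0.75:
                decorated.append(f"{w}{rng.choice(punct_keys)}")
            else:
                decorated.append(f"{rng.choice(negation_keys)} {w}")
        else:
            decorated.append(w)

    tweets = []
    per = max(1, spec.words_per_tweet)
    for i in range(0, len(decorated), per):
        tweets.append(" ".join(decorated[i : i + per]))
    tweets = tweets[: spec.tweets_per_user] if spec.tweets_per_user else []
    return LabeledUser(user_id, tweets, conditions or set())


def generate_cohort(
    spec: GeneratorSpec,
    msai: MSAILexicon,
    tables: ModifierTables | None = None,
    targets: Mapping[str, SentimentDistribution] | None = None,
) -> tuple[list[LabeledUser], list[LabeledUser]]:
    """Labeled cohort plus unlabeled corpus.

    Condition users are drawn around their condition's signature
    (occasionally around a two-condition mixture when
    ``multi_label_rate`` > 0), controls around the background
    distribution.  The unlabeled corpus mixes background users (half)
    with condition-signature users (half, cycling conditions), so its
    average sentiment is biased toward the condition profiles.
    Deterministic given ``spec.seed``.
    """
    tables = tables or default_tables()
    targets = dict(targets or condition_targets())
    rng = random.Random(spec.seed + 1)
    cache: dict = {}
    labeled: list[LabeledUser] = []
    uid = 0
    conditions = list(targets)
    for cond in conditions:
        for _ in range(spec.n_users_per_condition):
            labels = {cond}
            target = targets[cond]
            if spec.multi_label_rate and rng.random() < spec.multi_label_rate:
                other = rng.choice([c for c in conditions if c != cond])
                labels.add(other)
                target = normalize_distribution(
                    AffectVector((target.values + targets[other].values) / 2)
                )
            labeled.append(
                generate_user(
                    target, spec, rng, f"user{uid:04d}", labels, tables, msai, cache
                )
            )
            uid += 1
    bg = background_target()
    for _ in range(spec.n_controls):
        labeled.append(
            generate_user(bg, spec, rng, f"user{uid:04d}", set(), tables, msai, cache)
        )
        uid += 1

    unlabeled: list[LabeledUser] = []
    for i in range(spec.n_unlabeled):
        if i % 2 == 0:
            target = bg
        else:
            target = targets[conditions[(i // 2) % len(conditions)]]
        unlabeled.append(
            generate_user(target, spec, rng, f"anon{i:04d}", set(), tables, msai, cache)
        )
    return labeled, unlabeled
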