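"""Affect-intensity quantification and 11-dimensional sentiment distributions.

Per sentence, each matched sentiment word contributes

    intensity(w) * prod(alpha_k) * beta * eta + gamma + tau

to its category dimension, where the alpha_k are the attached degree-
adverb weights (empty product = 1), eta is −1 for a negated word and +1
otherwise, beta is 1.5 after an adversative and 1.0 before, and gamma /
tau are the attached emoticon / sentiment-punctuation weights (0 when
absent).  Sentence vectors are summed over the text (and over all of a
user's texts in the observation window), then clamped at 0 and
normalized to a probability vector — the user's sentiment distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .lexicon import CATEGORIES_11, MSAILexicon
from .textproc import (
    ModifierTables,
    ScoredWordContext,
    attach_modifiers,
    split_sentences,
    tokenize,
)

N_DIM = len(CATEGORIES_11)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES_11)}

ADVERSATIVE_WEIGHT = 1.5  # clause weight after an adversative


@dataclass
class AffectVector:
    """Raw (unnormalized) 11-dimensional affect-intensity vector."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(N_DIM))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DIM,):
            raise ValueError(f"expected {N_DIM} components, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite affect component")

    def __add__(self, other: "AffectVector") -> "AffectVector":
        return AffectVector(self.values + other.values)

    def __getitem__(self, category: str) -> float:
        return float(self.values[_CAT_INDEX[category]])


@dataclass
class SentimentDistribution:
    """Normalized 11-dimensional sentiment distribution D_s.

    ``empty`` marks a text window with no (net) sentiment evidence; its
    values are all zero and it must not be fed to similarity scoring.
    """

    values: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DIM,):
            raise ValueError(f"expected {N_DIM} components, got {self.values.shape}")
        if self.empty:
            if np.any(self.values != 0):
                raise ValueError("empty distribution must be all-zero")
        else:
            if np.any(self.values < 0) or abs(self.values.sum() - 1.0) > 1e-9:
                raise ValueError("distribution must be a probability vector")

    def __getitem__(self, category: str) -> float:
        return float(self.values[_CAT_INDEX[category]])

    @classmethod
    def from_mapping(cls, mass: dict[str, float]) -> "SentimentDistribution":
        v = np.zeros(N_DIM)
        for cat, x in mass.items():
            v[_CAT_INDEX[cat]] = x
        return normalize_distribution(AffectVector(v))


def word_contribution(ctx: ScoredWordContext, degree_override: float | None = None) -> float:
    """Quantified contribution of one sentiment word given its qualifiers."""
    alpha = 1.0
    if degree_override is not None:
        alpha = degree_override
    else:
        for a in ctx.degree_weights:
            alpha *= a
    beta = ADVERSATIVE_WEIGHT if ctx.after_adversative else 1.0
    eta = -1.0 if ctx.negated else 1.0
    return ctx.word.intensity * alpha * beta * eta + ctx.emoticon_weight + ctx.punct_weight


def score_sentence(
    contexts: Sequence[ScoredWordContext],
    degree_override: float | None = None,
) -> AffectVector:
    """Vector-valued sentence quantification q(s): per-word contributions
    added to each word's category dimension.

    ``degree_override`` replaces every word's degree factor with a fixed
    weight — used when scoring scale items at the highest severity level.
    """
    v = np.zeros(N_DIM)
    for ctx in contexts:
        v[_CAT_INDEX[ctx.word.category]] += word_contribution(ctx, degree_override)
    return AffectVector(v)


def accumulate(sentence_vectors: Iterable[AffectVector]) -> AffectVector:
    """Element-wise sum of sentence (or text) vectors: V = sum_i q(s_i)."""
    total = np.zeros(N_DIM)
    for v in sentence_vectors:
        total += v.values
    return AffectVector(total)


def normalize_distribution(v: AffectVector) -> SentimentDistribution:
    """Clamp negative components to 0, then normalize to unit mass.

    Negative mass can arise from negation; within-sentence cancellation
    has already happened in :func:`accumulate`, so clamping here keeps
    D_s a probability vector.  Zero (or wholly negative) input yields the
    flagged empty distribution.
    """
    clamped = np.clip(v.values, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        return SentimentDistribution(np.zeros(N_DIM), empty=True)
    return SentimentDistribution(clamped / total)


def score_text(
    text: str,
    lex: MSAILexicon,
    tables: ModifierTables,
    window: int = 3,
    degree_override: float | None = None,
) -> AffectVector:
    """Score one short text: split, tokenize, attach qualifiers, sum."""
    vectors = []
    for sentence in split_sentences(text):
        tokens = tokenize(sentence, tables, lex)
        contexts = attach_modifiers(tokens, lex, tables, window=window)
        vectors.append(score_sentence(contexts, degree_override))
    return accumulate(vectors)


def score_user(
    texts: Iterable[str],
    lex: MSAILexicon,
    tables: ModifierTables,
    window: int = 3,
) -> SentimentDistribution:
    """Accumulate all of a user's texts, then normalize to D_s."""
    total = accumulate(score_text(t, lex, tables, window=window) for t in texts)
    return normalize_distribution(total)
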