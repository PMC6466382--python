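"""Stochastic error-feedback training of condition profiles, and metrics.

Scale-derived prototypes deviate from how the same disorders present in
social-media language, so each profile Vs(c) is corrected against the
ambient ("public") sentiment of an unlabeled corpus.  One training cycle
per condition:

1. draw a batch of unlabeled users and average their sentiment
   distributions into A_sd;
2. rank A_sd's categories within a positive/negative polarity partition;
3. pick, uniformly at random, one of the top-2 positive and one of the
   top-3 negative categories; each chosen category's sentiment ratio
   S_r — a percentage, divided by 100 into a fraction — is the
   increment (learning rate) added to that dimension;
4. add the increments to Vs(c), renormalize to Vs(c)*;
5. accept the candidate iff its diagnostic error rate on the labeled
   cohort is strictly lower (Err* < Err).

The accept gate makes the accepted-update error sequence non-increasing.
The randomly chosen update direction trades per-step optimality for less
oscillation near convergence.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .diagnosis import THRES_MMU, ConditionProfile, probability
from .lexicon import CATEGORIES_11
from .scoring import SentimentDistribution, normalize_distribution, AffectVector

#: Default polarity partition of the 11 categories (Plutchik valence;
#: surprise grouped positive so the top-2 positive pool is non-trivial).
POSITIVE_CATEGORIES: frozenset[str] = frozenset({"joy", "trust", "anticipation", "surprise"})
NEGATIVE_CATEGORIES: frozenset[str] = frozenset(
    {"anger", "loathing", "disgust", "grief", "sadness", "terror", "fear"}
)


@dataclass
class LabeledUser:
    """A user's texts with their (possibly empty) set of condition labels."""

    user_id: str
    texts: list[str]
    conditions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.conditions and not self.texts:
            raise ValueError(f"condition user {self.user_id!r} has no texts")


@dataclass
class TrainingConfig:
    batch_size: int = 1000
    outer_iters: int = 100  # cycles per condition
    top_pos: int = 2
    top_neg: int = 3
    positive_categories: frozenset[str] = POSITIVE_CATEGORIES
    negative_categories: frozenset[str] = NEGATIVE_CATEGORIES
    positive_threshold: float = THRES_MMU
    #: multiplies the sentiment-ratio increment; 1.0 reads S_r/100 as a
    #: percent-to-fraction conversion (increment = the ratio itself),
    #: 0.01 as a further division of the fractional ratio by 100.
    learning_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if set(self.positive_categories) | set(self.negative_categories) != set(CATEGORIES_11):
            raise ValueError("polarity partition must cover all 11 categories")
        if set(self.positive_categories) & set(self.negative_categories):
            raise ValueError("polarity partition must be disjoint")


@dataclass
class TraceStep:
    condition: str
    iteration: int
    chosen_positive: str
    chosen_negative: str
    err_current: float
    err_candidate: float
    accepted: bool


# ---------------------------------------------------------------------------


def average_distribution(users: Sequence[SentimentDistribution]) -> SentimentDistribution:
    """Average sentiment distribution A_sd of a user batch (renormalized)."""
    present = [u for u in users if not u.empty]
    if not present:
        raise ValueError("no non-empty distributions to average")
    mean = np.mean([u.values for u in present], axis=0)
    return normalize_distribution(AffectVector(mean))


def propose_update(
    vs: ConditionProfile,
    asd: SentimentDistribution,
    cfg: TrainingConfig,
    rng: random.Random,
) -> tuple[ConditionProfile, str, str]:
    """One candidate correction Vs(c)* from the batch average A_sd.

    Positive and negative categories are ranked by their sentiment ratio
    in A_sd; one of the top ``top_pos`` positive and one of the top
    ``top_neg`` negative categories is drawn uniformly, and each chosen
    dimension of Vs(c) is incremented by its ratio (percentage / 100,
    times ``cfg.learning_scale``) before renormalization.  Returns
    (candidate, chosen positive, chosen negative).
    """
    if asd.empty:
        raise ValueError("A_sd is empty")

    def top(cats: Iterable[str], k: int) -> list[str]:
        ranked = sorted(
            (c for c in cats if asd[c] > 0), key=lambda c: asd[c], reverse=True
        )
        if not ranked:  # all-zero polarity side: fall back to the full side
            ranked = sorted(cats, key=lambda c: asd[c], reverse=True)
        return ranked[:k]

    pos_pool = top(cfg.positive_categories, cfg.top_pos)
    neg_pool = top(cfg.negative_categories, cfg.top_neg)
    chosen_pos = rng.choice(pos_pool)
    chosen_neg = rng.choice(neg_pool)

    v = vs.vector.copy()
    for cat in (chosen_pos, chosen_neg):
        i = CATEGORIES_11.index(cat)
        v[i] += asd[cat] * cfg.learning_scale
    candidate = ConditionProfile(vs.condition, v / v.sum())
    return candidate, chosen_pos, chosen_neg


def error_rate(
    vs: ConditionProfile,
    cohort: Sequence[tuple[SentimentDistribution, bool]],
    positive_threshold: float = THRES_MMU,
) -> float:
    """Diagnostic error rate of Vs(c) on a labeled cohort.

    ``cohort`` pairs each user's sentiment distribution with the boolean
    "has condition c".  A user is diagnosed positive iff Prob(c) >= the
    positive threshold; the error rate is the misclassified fraction.
    Users without sentiment evidence count as diagnosed negative.
    """
    if not cohort:
        raise ValueError("empty cohort")
    errors = 0
    for ds, has_condition in cohort:
        predicted = (not ds.empty) and probability(vs, ds) >= positive_threshold
        if predicted != has_condition:
            errors += 1
    return errors / len(cohort)


def train(
    profiles: Sequence[ConditionProfile],
    unlabeled_corpus: Sequence[SentimentDistribution],
    labeled_cohort: Sequence[tuple[SentimentDistribution, set[str]]],
    cfg: TrainingConfig,
) -> tuple[list[ConditionProfile], list[TraceStep]]:
    """Run the accept/reject correction loop for every condition.

    ``unlabeled_corpus`` supplies batch distributions (sampled with
    replacement when smaller than the batch size); ``labeled_cohort``
    pairs each user's distribution with their label set.  Returns the
    trained profiles and the full per-iteration trace.  Reproducible
    given ``cfg.seed``.
    """
    if not unlabeled_corpus:
        raise ValueError("empty unlabeled corpus")
    rng = random.Random(cfg.seed)
    trained: list[ConditionProfile] = []
    trace: list[TraceStep] = []
    for vs in profiles:
        current = vs
        cohort = [(ds, vs.condition in labels) for ds, labels in labeled_cohort]
        err = error_rate(current, cohort, cfg.positive_threshold)
        for it in range(cfg.outer_iters):
            batch = [
                unlabeled_corpus[rng.randrange(len(unlabeled_corpus))]
                for _ in range(cfg.batch_size)
            ]
            asd = average_distribution(batch)
            candidate, cpos, cneg = propose_update(current, asd, cfg, rng)
            err_candidate = error_rate(candidate, cohort, cfg.positive_threshold)
            accepted = err_candidate < err
            trace.append(
                TraceStep(vs.condition, it, cpos, cneg, err, err_candidate, accepted)
            )
            if accepted:
                current, err = candidate, err_candidate
        trained.append(current)
    return trained, trace


# ---------------------------------------------------------------------------
# evaluation


def average_diagnostic_precision(
    correct_with: Sequence[int], correct_without: Sequence[int], n_users: int
) -> float:
    """Mean per-condition diagnostic accuracy:

        adp = sum_i (c_i(h) + c_i(n)) / (n_conditions * n_users)

    where c_i(h) / c_i(n) count users correctly classified as having /
    not having condition i.
    """
    if n_users <= 0:
        raise ValueError("n_users must be positive")
    if len(correct_with) != len(correct_without) or not correct_with:
        raise ValueError("per-condition count sequences must match and be non-empty")
    n = len(correct_with)
    for h, c in zip(correct_with, correct_without):
        if h + c > n_users:
            raise ValueError("correct counts exceed cohort size")
    return sum(h + c for h, c in zip(correct_with, correct_without)) / (n * n_users)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean from confusion counts."""
    if tp + fp == 0:
        raise ZeroDivisionError("precision undefined: no positive predictions")
    if tp + fn == 0:
        raise ZeroDivisionError("recall undefined: no positive labels")
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return p, r, f1_from_precision_recall(p, r)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2 P R / (P + R)."""
    if precision + recall == 0:
        raise ZeroDivisionError("F1 undefined: P + R = 0")
    return 2 * precision * recall / (precision + recall)


def split_cohort(
    cohort: Sequence[LabeledUser], train_frac: float, seed: int
) -> tuple[list[LabeledUser], list[LabeledUser]]:
    """Stratified train/test split (condition users vs. controls).

    Within each stratum the train size is round-half-up of
    ``train_frac * stratum size``; the split is a disjoint, exhaustive
    shuffle, deterministic given ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = random.Random(seed)
    train_set: list[LabeledUser] = []
    test_set: list[LabeledUser] = []
    for stratum in (
        [u for u in cohort if u.conditions],
        [u for u in cohort if not u.conditions],
    ):
        if not stratum:
            continue
        if len(stratum) < 2:
            raise ValueError("stratum too small to split")
        shuffled = stratum[:]
        rng.shuffle(shuffled)
        n_train = math.floor(train_frac * len(stratum) + 0.5)  # round half up
        train_set.extend(shuffled[:n_train])
        test_set.extend(shuffled[n_train:])
    return train_set, test_set
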