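"""Condition profiles and similarity-based risk diagnosis.

Each mental-disorder condition is represented by a normalized 11-dim
prototype vector Vs(c), seeded by scoring the items of a screening-scale
text with every degree factor forced to the maximum configured weight
(the severity reference: the prototype is the *severe* presentation).
A user's probability of matching condition c is the cosine similarity
between Vs(c) and the user's sentiment distribution D_s; risk levels:

    SMU (severe)      Prob(c) > 0.8
    MMU (moderate)    0.6 <= Prob(c) <= 0.8
    NMU (none/mild)   Prob(c) < 0.6

A diagnosis is *positive* (higher-risk) at MMU or above.  Conditions are
scored independently: a user may match several.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .lexicon import CATEGORIES_11, MSAILexicon
from .scoring import (
    SentimentDistribution,
    accumulate,
    normalize_distribution,
    score_text,
    score_user,
)
from .textproc import ModifierTables

#: The five conditions studied; the set is extensible.
CONDITIONS: tuple[str, ...] = ("depressive", "anxiety", "ocd", "bipolar", "panic")

THRES_MMU = 0.6
THRES_SMU = 0.8


class RiskLevel(str, enum.Enum):
    NMU = "NMU"
    MMU = "MMU"
    SMU = "SMU"


@dataclass
class ConditionProfile:
    """Normalized prototype sentiment vector Vs(c) of one condition."""

    condition: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (len(CATEGORIES_11),):
            raise ValueError("profile must have 11 components")
        if np.any(self.vector < 0) or abs(self.vector.sum() - 1.0) > 1e-9:
            raise ValueError("profile must lie on the simplex")

    def as_distribution(self) -> SentimentDistribution:
        return SentimentDistribution(self.vector)


@dataclass
class DiagnosisResult:
    user_id: str
    probs: dict[str, float]
    levels: dict[str, RiskLevel]
    thresholds: tuple[float, float] = (THRES_MMU, THRES_SMU)
    insufficient_evidence: bool = False

    def positive(self, condition: str) -> bool:
        return self.levels[condition] in (RiskLevel.MMU, RiskLevel.SMU)


def build_condition_profile(
    scale_text: Sequence[str],
    condition: str,
    lex: MSAILexicon,
    tables: ModifierTables,
) -> ConditionProfile:
    """Score scale items at the highest severity level into Vs(c).

    Every matched sentiment word's degree factor is forced to the
    maximum configured degree-adverb weight, treating the most severe
    presentation as the reference; items are accumulated and normalized.
    """
    override = tables.max_degree_weight
    total = accumulate(
        score_text(item, lex, tables, degree_override=override) for item in scale_text
    )
    ds = normalize_distribution(total)
    if ds.empty:
        raise ValueError(
            f"scale text for {condition!r} matched no sentiment content; profile undefined"
        )
    return ConditionProfile(condition, ds.values)


def probability(vs: ConditionProfile, ds: SentimentDistribution) -> float:
    """Prob(c): cosine similarity of Vs(c) and D_s; in [0, 1] since both
    vectors are non-negative."""
    if ds.empty:
        raise ValueError("insufficient sentiment evidence: empty distribution")
    a, b = vs.vector, ds.values
    denom = float(np.linalg.norm(a) * np.linalg.norm(b))
    if denom == 0:
        return 0.0
    return float(np.clip(a @ b / denom, 0.0, 1.0))


def classify_risk(
    prob: float, thresholds: tuple[float, float] = (THRES_MMU, THRES_SMU)
) -> RiskLevel:
    """Map a probability to a risk level; boundary values fall to MMU."""
    if not 0 <= prob <= 1:
        raise ValueError(f"probability {prob} outside [0, 1]")
    mmu, smu = thresholds
    if prob > smu:
        return RiskLevel.SMU
    if prob >= mmu:
        return RiskLevel.MMU
    return RiskLevel.NMU


def diagnose_distribution(
    user_id: str,
    ds: SentimentDistribution,
    profiles: Iterable[ConditionProfile],
    thresholds: tuple[float, float] = (THRES_MMU, THRES_SMU),
) -> DiagnosisResult:
    """Per-condition Prob(c) and level for an already-scored user."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one condition profile required")
    if ds.empty:
        return DiagnosisResult(
            user_id,
            probs={p.condition: 0.0 for p in profiles},
            levels={p.condition: RiskLevel.NMU for p in profiles},
            thresholds=thresholds,
            insufficient_evidence=True,
        )
    probs = {p.condition: probability(p, ds) for p in profiles}
    levels = {c: classify_risk(pr, thresholds) for c, pr in probs.items()}
    return DiagnosisResult(user_id, probs, levels, thresholds)


def diagnose_user(
    user_id: str,
    texts: Sequence[str],
    profiles: Iterable[ConditionProfile],
    lex: MSAILexicon,
    tables: ModifierTables,
    thresholds: tuple[float, float] = (THRES_MMU, THRES_SMU),
) -> DiagnosisResult:
    """Score a user's texts and diagnose every condition independently.

    A user whose texts match no lexicon word gets an all-NMU result with
    ``insufficient_evidence`` set.
    """
    ds = score_user(texts, lex, tables)
    return diagnose_distribution(user_id, ds, profiles, thresholds)
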