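"""Multipolarity sentiment affect-intensity lexicon (MSAI lexicon).

An 8-emotion affect-intensity lexicon (the hashtag-emotion TSV dialect:
one word per row with an emotion label and a real-valued intensity) is
refined into 11 sentiment categories: the three negative emotions whose
vocabularies mix mild and extreme words — disgust, sadness, fear — are
each split in two by one-dimensional 2-means clustering of their
intensities, the higher-intensity cluster taking the stronger Plutchik
label (loathing, grief, terror).  Intensities are then min–max normalized
to [0, 1] within each of the 11 categories.  The fixed category order
defined here indexes every 11-dimensional vector in the package.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Source lexicon categories, in canonical order.
CATEGORIES_8: tuple[str, ...] = (
    "anger",
    "disgust",
    "sadness",
    "surprise",
    "fear",
    "trust",
    "joy",
    "anticipation",
)

#: Fixed 11-category order; index i of every affect vector refers to
#: CATEGORIES_11[i].  Strong variants directly precede their mild parent.
CATEGORIES_11: tuple[str, ...] = (
    "anger",
    "loathing",
    "disgust",
    "grief",
    "sadness",
    "surprise",
    "terror",
    "fear",
    "trust",
    "joy",
    "anticipation",
)

#: (source category, strong sub-label, mild sub-label) for the split step.
SPLIT_MAP: tuple[tuple[str, str, str], ...] = (
    ("disgust", "loathing", "disgust"),
    ("sadness", "grief", "sadness"),
    ("fear", "terror", "fear"),
)


@dataclass(frozen=True, slots=True)
class LexiconEntry:
    """A single (word, category, intensity) record."""

    word: str
    category: str
    intensity: float

    def __post_init__(self) -> None:
        if not self.word or any(ch.isspace() for ch in self.word):
            raise ValueError(f"invalid lexicon word: {self.word!r}")
        if not math.isfinite(self.intensity):
            raise ValueError(f"non-finite intensity for {self.word!r}")


class _Lexicon:
    """Shared container behaviour: a dict keyed by (word, category)."""

    categories: tuple[str, ...] = ()

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        """Insert an entry; duplicate (word, category) keeps the max intensity."""
        if entry.category not in self.categories:
            raise ValueError(f"unknown category: {entry.category!r}")
        key = (entry.word, entry.category)
        old = self._entries.get(key)
        if old is None or entry.intensity > old.intensity:
            self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def get(self, word: str, category: str) -> LexiconEntry | None:
        return self._entries.get((word, category))

    def entries_for(self, category: str) -> list[LexiconEntry]:
        return [e for e in self._entries.values() if e.category == category]

    def words(self) -> set[str]:
        return {w for (w, _c) in self._entries}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, _Lexicon):
            return NotImplemented
        return self._entries == other._entries


class EmotionLexicon(_Lexicon):
    """The 8-emotion source lexicon."""

    categories = CATEGORIES_8


class MSAILexicon(_Lexicon):
    """The 11-category multipolarity sentiment affect-intensity lexicon.

    ``category_order`` (== :data:`CATEGORIES_11`) fixes the dimension
    index of every sentiment vector built from this lexicon.
    """

    categories = CATEGORIES_11
    category_order = CATEGORIES_11

    def best_match(self, word: str) -> LexiconEntry | None:
        """Highest-intensity entry for *word* across categories, or None."""
        best: LexiconEntry | None = None
        for cat in self.category_order:
            e = self.get(word, cat)
            if e is not None and (best is None or e.intensity > best.intensity):
                best = e
        return best


# ---------------------------------------------------------------------------
# TSV I/O

#: column orders for the 3-column TSV; the hashtag-lexicon dialect is
#: (category, word, intensity).
_DIALECTS: dict[str, tuple[int, int, int]] = {
    "category-word-intensity": (0, 1, 2),
    "word-category-intensity": (1, 0, 2),
}


def load_emotion_lexicon(
    path: str | Path,
    dialect: str = "category-word-intensity",
    *,
    cls: type[_Lexicon] = EmotionLexicon,
    max_bad_fraction: float = 0.10,
) -> _Lexicon:
    """Read a 3-column TSV lexicon.

    Malformed rows are logged and skipped; more than ``max_bad_fraction``
    malformed rows raises, as does an unknown category name.  Duplicate
    (word, category) rows keep the maximum intensity.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    ci, wi, ii = _DIALECTS[dialect]
    lex = cls()
    n_rows = n_bad = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        n_rows += 1
        parts = line.rstrip("\n").split("\t")
        try:
            if len(parts) != 3:
                raise ValueError(f"expected 3 columns, got {len(parts)}")
            entry = LexiconEntry(
                word=parts[wi].strip().lower(),
                category=parts[ci].strip().lower(),
                intensity=float(parts[ii]),
            )
            lex.add(entry)
        except ValueError as exc:
            if parts[ci].strip().lower() not in cls.categories and len(parts) == 3:
                # unknown category is a hard error: wrong file, not a typo
                raise ValueError(f"{path}:{lineno}: unknown category {parts[ci]!r}") from exc
            n_bad += 1
            logger.warning("%s:%d: skipping malformed row (%s)", path, lineno, exc)
    if n_rows and n_bad / n_rows > max_bad_fraction:
        raise ValueError(f"{path}: {n_bad}/{n_rows} malformed rows")
    logger.info("%s: %d entries, %d rows skipped", path, len(lex), n_bad)
    return lex


def save_msai(lex: MSAILexicon, path: str | Path) -> None:
    """Write the 11-category lexicon as TSV (category, word, intensity)."""
    if len(lex) == 0:
        raise ValueError("refusing to save an empty lexicon")
    path = Path(path)
    rows = sorted(lex, key=lambda e: (e.category, e.word))
    with path.open("w", encoding="utf-8") as fh:
        for e in rows:
            fh.write(f"{e.category}\t{e.word}\t{e.intensity!r}\n")


def load_msai(path: str | Path) -> MSAILexicon:
    """Load an 11-category lexicon saved by :func:`save_msai`."""
    return load_emotion_lexicon(path, cls=MSAILexicon)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# one-dimensional k-means


@dataclass
class ClusterState:
    """Converged 1-D k-means state over affect intensities."""

    points: list[float]
    K: int
    centers: list[float]
    assignments: list[int]
    cost: float

    def cluster(self, k: int) -> list[float]:
        return [p for p, a in zip(self.points, self.assignments) if a == k]


def _assign(points: Sequence[float], centers: Sequence[float]) -> list[int]:
    return [min(range(len(centers)), key=lambda k: (p - centers[k]) ** 2) for p in points]


def _cost(points: Sequence[float], centers: Sequence[float], assign: Sequence[int]) -> float:
    return sum((p - centers[a]) ** 2 for p, a in zip(points, assign))


def _best_contiguous_split_centers(pts: Sequence[float]) -> tuple[float, float]:
    """Centers of the minimum-cost 2-way split of the sorted sample."""
    srt = sorted(pts)
    best_cost, best_centers = float("inf"), (srt[0], srt[-1])
    for i in range(1, len(srt)):
        left, right = srt[:i], srt[i:]
        cl = sum(left) / len(left)
        cr = sum(right) / len(right)
        cost = sum((p - cl) ** 2 for p in left) + sum((p - cr) ** 2 for p in right)
        if cost < best_cost:
            best_cost, best_centers = cost, (cl, cr)
    return best_centers


def kmeans_1d(
    points: Sequence[float],
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    n_restarts: int = 10,
) -> ClusterState:
    """Lloyd's algorithm on a 1-D sample, with seeded random restarts.

    Each restart draws K distinct initial centers from the point values,
    the first uniformly and the rest with squared-distance weighting
    (spread-out random centers escape the poor local optima that plain
    uniform seeding falls into); the best of ``n_restarts`` runs (lowest
    within-cluster squared-distance cost) is returned.  For K=2 one
    additional restart is seeded from the best sorted contiguous split —
    in one dimension the squared-loss optimum is always such a split, so
    that restart makes the solver exact.  Deterministic given ``seed``;
    the cost is non-increasing across Lloyd iterations by construction.
    """
    pts = list(points)
    if not pts:
        raise ValueError("empty point set")
    distinct = sorted(set(pts))
    if K > len(distinct):
        raise ValueError(f"K={K} exceeds {len(distinct)} distinct points")
    rng = random.Random(seed)
    inits: list[list[float]] = []
    if K == 2:
        inits.append(list(_best_contiguous_split_centers(pts)))
    for _ in range(n_restarts):
        centers = [rng.choice(distinct)]
        while len(centers) < K:
            weights = [min((p - c) ** 2 for c in centers) for p in distinct]
            centers.append(rng.choices(distinct, weights=weights)[0])
        inits.append(centers)
    best: ClusterState | None = None
    for centers in inits:
        assign = _assign(pts, centers)
        for _ in range(max_iter):
            new_centers = []
            for k in range(K):
                members = [p for p, a in zip(pts, assign) if a == k]
                if members:
                    new_centers.append(sum(members) / len(members))
                else:  # re-seed an empty cluster at the worst-fit point
                    worst = max(pts, key=lambda p: (p - centers[assign[pts.index(p)]]) ** 2)
                    new_centers.append(worst)
            new_assign = _assign(pts, new_centers)
            if new_centers == centers and new_assign == assign:
                break
            centers, assign = new_centers, new_assign
        state = ClusterState(pts, K, centers, assign, _cost(pts, centers, assign))
        if best is None or state.cost < best.cost - 1e-15:
            best = state
    assert best is not None
    return best


def split_emotion(
    lex: EmotionLexicon,
    category: str,
    strong_label: str,
    mild_label: str,
    seed: int = 0,
) -> tuple[list[LexiconEntry], list[LexiconEntry]]:
    """Split one source category in two by 2-means on intensity.

    The cluster with the larger center takes ``strong_label`` (the
    higher-arousal Plutchik variant), the other ``mild_label``.  Returns
    (strong entries, mild entries); together they partition the category.
    """
    entries = lex.entries_for(category)
    if not entries:
        raise ValueError(f"category {category!r} not present")
    intensities = [e.intensity for e in entries]
    if len(set(intensities)) < 2:
        raise ValueError(f"category {category!r} has <2 distinct intensities")
    state = kmeans_1d(intensities, K=2, seed=seed)
    strong_k = max(range(2), key=lambda k: state.centers[k])
    strong, mild = [], []
    for e, a in zip(entries, state.assignments):
        label = strong_label if a == strong_k else mild_label
        (strong if a == strong_k else mild).append(
            LexiconEntry(e.word, label, e.intensity)
        )
    return strong, mild


# ---------------------------------------------------------------------------
# synonym expansion and normalization

SynonymProvider = Callable[[str], Iterable[tuple[str, float]]]


def expand_synonyms(
    lex: MSAILexicon,
    synonym_source: SynonymProvider | Mapping[str, Iterable[tuple[str, float]]] | None,
    threshold: float = 0.7,
) -> MSAILexicon:
    """Add synonyms with sense similarity strictly above ``threshold``.

    Each added synonym inherits the seed word's category and intensity.
    Collisions with existing entries keep the larger intensity; nothing is
    ever removed.  A missing provider returns the input unchanged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if synonym_source is None:
        logger.warning("no synonym source available; lexicon unchanged")
        return lex
    lookup: SynonymProvider
    if isinstance(synonym_source, Mapping):
        lookup = lambda w: synonym_source.get(w, ())  # noqa: E731
    else:
        lookup = synonym_source
    out = MSAILexicon(lex)
    for entry in list(lex):
        for candidate, similarity in lookup(entry.word):
            if similarity > threshold:
                word = candidate.strip().lower()
                if word and not any(ch.isspace() for ch in word):
                    out.add(LexiconEntry(word, entry.category, entry.intensity))
    return out


def normalize_lexicon(lex: MSAILexicon) -> MSAILexicon:
    """Min–max scale intensities to [0, 1] within each category.

    A category whose intensities are all equal maps to 1.0 (the words are
    equally, fully representative of their category).  Idempotent on
    categories already spanning [0, 1].
    """
    out = MSAILexicon()
    for cat in lex.categories:
        entries = lex.entries_for(cat)
        if not entries:
            continue
        lo = min(e.intensity for e in entries)
        hi = max(e.intensity for e in entries)
        for e in entries:
            scaled = 1.0 if hi == lo else (e.intensity - lo) / (hi - lo)
            out.add(LexiconEntry(e.word, cat, scaled))
    return out


def build_msai_lexicon(
    source: EmotionLexicon,
    synonym_source: SynonymProvider | Mapping | None = None,
    threshold: float = 0.7,
    seed: int = 0,
) -> MSAILexicon:
    """Full refinement: split disgust/sadness/fear, expand synonyms, normalize.

    Anger, surprise, trust, joy and anticipation pass through unchanged.
    Synonym expansion runs on raw intensities, before normalization.
    """
    msai = MSAILexicon()
    split_sources = {cat for cat, _s, _m in SPLIT_MAP}
    for cat in CATEGORIES_8:
        if cat in split_sources:
            continue
        for e in source.entries_for(cat):
            msai.add(LexiconEntry(e.word, cat, e.intensity))
    for cat, strong_label, mild_label in SPLIT_MAP:
        strong, mild = split_emotion(source, cat, strong_label, mild_label, seed=seed)
        for e in strong + mild:
            msai.add(e)
    msai = expand_synonyms(msai, synonym_source, threshold)
    return normalize_lexicon(msai)
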