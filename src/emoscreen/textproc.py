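"""Sentence splitting, tweet tokenization and nearest-modifier attachment.

Affect scoring needs, for every sentiment word, the qualifiers that
modify it: degree adverbs (weight 0–2, e.g. "very"=1.5, "little"=0.5),
negations (weight −1), an adversative ("but") that up-weights everything
after it by 1.5, and emoticons / sentiment punctuation (additive weights
in 0–1).  Each qualifier attaches to the *closest* sentiment word — a
proximity rule, not a parse.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import MSAILexicon, LexiconEntry

TokenKind = str  # sentiment_word | degree_adverb | negation | adversative | emoticon | sentiment_punctuation | other


@dataclass(frozen=True, slots=True)
class Token:
    surface: str
    kind: TokenKind
    position: int


@dataclass
class ModifierTables:
    """Qualifier vocabularies and weights.

    Only "very"=1.5 and "little"=0.5 are fixed by the quantification
    rules; the remaining defaults are editable fixture values (see
    :func:`default_tables`), loadable from TSV.
    """

    degree_adverbs: dict[str, float] = field(default_factory=dict)
    negations: set[str] = field(default_factory=set)
    adversatives: set[str] = field(default_factory=set)
    emoticons: dict[str, float] = field(default_factory=dict)
    sentiment_punct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, a in self.degree_adverbs.items():
            if not 0 <= a <= 2:
                raise ValueError(f"degree adverb {w!r} weight {a} outside [0, 2]")
        for table_name in ("emoticons", "sentiment_punct"):
            for s, w in getattr(self, table_name).items():
                if not 0 <= w <= 1:
                    raise ValueError(f"{table_name} {s!r} weight {w} outside [0, 1]")

    @property
    def max_degree_weight(self) -> float:
        return max(self.degree_adverbs.values(), default=2.0)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for w, a in sorted(self.degree_adverbs.items()):
                fh.write(f"degree_adverb\t{w}\t{a!r}\n")
            for w in sorted(self.negations):
                fh.write(f"negation\t{w}\t-1\n")
            for w in sorted(self.adversatives):
                fh.write(f"adversative\t{w}\t1.5\n")
            for s, w in sorted(self.emoticons.items()):
                fh.write(f"emoticon\t{s}\t{w!r}\n")
            for s, w in sorted(self.sentiment_punct.items()):
                fh.write(f"sentiment_punctuation\t{s}\t{w!r}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModifierTables":
        t = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            kind, surface, weight = line.split("\t")
            w = float(weight)
            if kind == "degree_adverb":
                t.degree_adverbs[surface] = w
            elif kind == "negation":
                t.negations.add(surface)
            elif kind == "adversative":
                t.adversatives.add(surface)
            elif kind == "emoticon":
                t.emoticons[surface] = w
            elif kind == "sentiment_punctuation":
                t.sentiment_punct[surface] = w
            else:
                raise ValueError(f"unknown modifier kind {kind!r}")
        return t.__class__(**vars(t))  # re-validate ranges


def default_tables() -> ModifierTables:
    """Built-in qualifier tables (config-overridable)."""
    return ModifierTables(
        degree_adverbs={
            "very": 1.5,
            "little": 0.5,
            "extremely": 1.8,
            "utterly": 2.0,
            "really": 1.4,
            "so": 1.3,
            "too": 1.3,
            "quite": 1.2,
            "rather": 1.1,
            "somewhat": 0.7,
            "slightly": 0.3,
            "barely": 0.2,
        },
        negations={"not", "never", "no", "n't", "cannot", "nothing", "neither"},
        adversatives={"but", "however", "yet", "although", "though", "whereas"},
        emoticons={
            ":)": 0.5, ":-)": 0.5, ":d": 0.7, ":(": 0.5, ":-(": 0.5,
            ":'(": 0.8, ";)": 0.4, ":/": 0.3, "<3": 0.6, ":o": 0.4,
        },
        sentiment_punct={
            "!": 0.3, "!!": 0.5, "!!!": 0.7, "?!": 0.6, "??": 0.4, "...": 0.2,
        },
    )


# ---------------------------------------------------------------------------
# sentence splitting and tokenization

_SENT_RE = re.compile(r"[^.!?…]+[.!?…]*")
_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@\w+")
_PUNCT_RUN_RE = re.compile(r"[!?]+|\.{3,}|…")
_WORD_RE = re.compile(r"[a-z']+")


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation runs, keeping the run with its sentence."""
    text = text.strip()
    if not text:
        return []
    sentences = [m.group(0).strip() for m in _SENT_RE.finditer(text)]
    return [s for s in sentences if s]


def _classify_word(word: str, tables: ModifierTables, lex: MSAILexicon) -> TokenKind:
    # sentiment-word lookup wins over qualifier tables
    if lex.best_match(word) is not None:
        return "sentiment_word"
    if word in tables.degree_adverbs:
        return "degree_adverb"
    if word in tables.negations:
        return "negation"
    if word in tables.adversatives:
        return "adversative"
    return "other"


def tokenize(sentence: str, tables: ModifierTables, lex: MSAILexicon) -> list[Token]:
    """Lowercase, strip URLs/@-mentions/# prefixes, emit labeled tokens.

    Emoticons and runs of sentiment punctuation become single tokens;
    hashtag bodies survive as plain words.
    """
    s = unicodedata.normalize("NFC", sentence).lower()
    s = _URL_RE.sub(" ", s)
    s = _MENTION_RE.sub(" ", s)
    s = s.replace("#", " ")
    tokens: list[Token] = []

    # longest-match emoticons first so ":)" is not shredded into punctuation
    emoticon_keys = sorted(tables.emoticons, key=len, reverse=True)
    i = 0
    pieces: list[tuple[str, TokenKind | None]] = []
    while i < len(s):
        matched = False
        for emo in emoticon_keys:
            if s.startswith(emo, i):
                pieces.append((emo, "emoticon"))
                i += len(emo)
                matched = True
                break
        if matched:
            continue
        m = _PUNCT_RUN_RE.match(s, i)
        if m:
            pieces.append((m.group(0), "sentiment_punctuation"))
            i = m.end()
            continue
        m = _WORD_RE.match(s, i)
        if m:
            pieces.append((m.group(0), None))
            i = m.end()
            continue
        i += 1

    for surface, kind in pieces:
        if kind is None:
            surface = surface.strip("'")
            if not surface:
                continue
            kind = _classify_word(surface, tables, lex)
        elif kind == "sentiment_punctuation":
            if _punct_weight(surface, tables) == 0.0:
                continue  # e.g. a bare "?" carries no affect weight
        tokens.append(Token(surface, kind, len(tokens)))
    return tokens


def _punct_weight(surface: str, tables: ModifierTables) -> float:
    """Weight of a punctuation run: exact match, else longest known prefix."""
    if surface in tables.sentiment_punct:
        return tables.sentiment_punct[surface]
    for n in range(len(surface) - 1, 0, -1):
        if surface[:n] in tables.sentiment_punct:
            return tables.sentiment_punct[surface[:n]]
    return 0.0


# ---------------------------------------------------------------------------
# nearest-modifier attachment


@dataclass
class ScoredWordContext:
    """A matched sentiment word with its attached qualifiers."""

    word: LexiconEntry
    degree_weights: list[float] = field(default_factory=list)
    negated: bool = False
    after_adversative: bool = False
    emoticon_weight: float = 0.0
    punct_weight: float = 0.0


def _nearest_word_index(
    pos: int, word_positions: list[int], window: int | None
) -> int | None:
    """Index into word_positions of the sentiment word closest to pos.

    Ties between an equidistant preceding and following word go to the
    following one (qualifiers usually precede what they modify).
    """
    best_i: int | None = None
    best_key: tuple[int, int] | None = None
    for i, wp in enumerate(word_positions):
        d = abs(wp - pos)
        if window is not None and d > window:
            continue
        key = (d, 0 if wp > pos else 1)  # prefer following on ties
        if best_key is None or key < best_key:
            best_key, best_i = key, i
    return best_i


def attach_modifiers(
    tokens: list[Token],
    lex: MSAILexicon,
    tables: ModifierTables,
    window: int = 3,
) -> list[ScoredWordContext]:
    """Build one qualifier context per sentiment word in a sentence.

    Degree adverbs and negations attach to the nearest sentiment word
    within ``window`` tokens; emoticons and sentiment punctuation to the
    nearest sentiment word anywhere in the sentence; a sentiment word is
    ``after_adversative`` iff any adversative precedes it.  Every
    qualifier token attaches to at most one sentiment word; an odd number
    of attached negations flips the word's sign.
    """
    word_tokens = [t for t in tokens if t.kind == "sentiment_word"]
    contexts = []
    for t in word_tokens:
        entry = lex.best_match(t.surface)
        assert entry is not None
        contexts.append(ScoredWordContext(word=entry))
    if not contexts:
        return []
    word_positions = [t.position for t in word_tokens]
    adversative_positions = [t.position for t in tokens if t.kind == "adversative"]
    neg_counts = [0] * len(contexts)

    for t in tokens:
        if t.kind in ("degree_adverb", "negation"):
            i = _nearest_word_index(t.position, word_positions, window)
            if i is None:
                continue
            if t.kind == "degree_adverb":
                contexts[i].degree_weights.append(tables.degree_adverbs[t.surface])
            else:
                neg_counts[i] += 1
        elif t.kind == "emoticon":
            i = _nearest_word_index(t.position, word_positions, None)
            if i is not None:
                w = tables.emoticons[t.surface]
                contexts[i].emoticon_weight = max(contexts[i].emoticon_weight, w)
        elif t.kind == "sentiment_punctuation":
            i = _nearest_word_index(t.position, word_positions, None)
            if i is not None:
                w = _punct_weight(t.surface, tables)
                contexts[i].punct_weight = max(contexts[i].punct_weight, w)

    for i, ctx in enumerate(contexts):
        ctx.negated = neg_counts[i] % 2 == 1
        ctx.after_adversative = any(p < word_positions[i] for p in adversative_positions)
    return contexts
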