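"""Lexicon construction: TSV parsing, 1-D clustering, category refinement."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from emoscreen import (
    CATEGORIES_8,
    CATEGORIES_11,
    EmotionLexicon,
    LexiconEntry,
    MSAILexicon,
    build_msai_lexicon,
    expand_synonyms,
    kmeans_1d,
    load_emotion_lexicon,
    load_msai,
    normalize_lexicon,
    save_msai,
    split_emotion,
)


# ---------------------------------------------------------------------------
# TSV reader


def _write(tmp_path, rows, name="lex.tsv"):
    p = tmp_path / name
    p.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return p


def test_load_parses_well_formed_rows(tmp_path):
    p = _write(tmp_path, ["anger\tfury\t0.9", "joy\tglee\t0.8", "fear\tdread\t0.7"])
    lex = load_emotion_lexicon(p)
    assert len(lex) == 3
    assert lex.get("fury", "anger").intensity == 0.9


def test_duplicate_word_category_keeps_max_intensity(tmp_path):
    p = _write(tmp_path, ["joy\tglee\t0.3", "joy\tglee\t0.5"])
    lex = load_emotion_lexicon(p)
    assert len(lex) == 1
    assert lex.get("glee", "joy").intensity == 0.5


def test_malformed_rows_skipped_until_threshold(tmp_path, caplog):
    good = [f"joy\tword{i}\t0.{i+1}" for i in range(22)]
    bad = ["joy\tbroken\tnot-a-number", "joy\tonly-two-columns"]
    rows = good[:10] + bad[:1] + good[10:] + bad[1:]
    lex = load_emotion_lexicon(_write(tmp_path, rows))
    assert len(lex) == 22


def test_too_many_malformed_rows_raise(tmp_path):
    rows = ["joy\tok\t0.5"] + ["joy\tbad\tx"] * 3
    with pytest.raises(ValueError, match="malformed"):
        load_emotion_lexicon(_write(tmp_path, rows))


def test_unknown_category_raises(tmp_path):
    with pytest.raises(ValueError, match="unknown category"):
        load_emotion_lexicon(_write(tmp_path, ["serenity\tcalm\t0.5"]))


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_emotion_lexicon(tmp_path / "absent.tsv")


def test_word_category_dialect(tmp_path):
    p = _write(tmp_path, ["glee\tjoy\t0.8"])
    lex = load_emotion_lexicon(p, dialect="word-category-intensity")
    assert lex.get("glee", "joy") is not None


# ---------------------------------------------------------------------------
# 1-D k-means against an exhaustive oracle


def brute_force_cost(points, K):
    """Exhaustive minimum of the within-cluster squared-distance cost
    over every assignment of points to K labels."""
    best = float("inf")
    for labels in itertools.product(range(K), repeat=len(points)):
        if len(set(labels)) < K:
            continue
        cost = 0.0
        for k in range(K):
            members = [p for p, l in zip(points, labels) if l == k]
            c = sum(members) / len(members)
            cost += sum((p - c) ** 2 for p in members)
        if cost < best:
            best = cost
    return best


def test_two_points_two_clusters_zero_cost():
    state = kmeans_1d([0.1, 0.9], K=2, seed=0)
    assert state.cost == pytest.approx(0.0)
    assert sorted(state.centers) == [0.1, 0.9]


def test_two_pair_partition():
    state = kmeans_1d([0.1, 0.2, 0.8, 0.9], K=2, seed=0)
    assert sorted(state.centers) == pytest.approx([0.15, 0.85])
    assert state.cost == pytest.approx(brute_force_cost([0.1, 0.2, 0.8, 0.9], 2))


@pytest.mark.parametrize("trial", range(20))
def test_kmeans_matches_exhaustive_oracle(trial):
    rng = random.Random(1000 + trial)
    n = rng.randint(3, 10)
    pts = [round(rng.random(), 3) for _ in range(n)]
    while len(set(pts)) < 2:
        pts[-1] = round(rng.random(), 3)
    state = kmeans_1d(pts, K=2, seed=trial)
    assert state.cost == pytest.approx(brute_force_cost(pts, 2), abs=1e-9)


def test_kmeans_deterministic_given_seed():
    pts = [0.11, 0.45, 0.52, 0.87, 0.9]
    a = kmeans_1d(pts, K=2, seed=7)
    b = kmeans_1d(pts, K=2, seed=7)
    assert a.centers == b.centers and a.assignments == b.assignments


def test_kmeans_rejects_bad_k_and_empty():
    with pytest.raises(ValueError):
        kmeans_1d([0.5, 0.5], K=2, seed=0)
    with pytest.raises(ValueError):
        kmeans_1d([], K=1, seed=0)


# ---------------------------------------------------------------------------
# emotion splitting


def _fear_lex(intensities):
    lex = EmotionLexicon()
    for i, x in enumerate(intensities):
        lex.add(LexiconEntry(f"w{i}", "fear", x))
    return lex


def test_split_larger_center_takes_strong_label():
    strong, mild = split_emotion(_fear_lex([0.2, 0.25, 0.8]), "fear", "terror", "fear")
    assert {e.intensity for e in strong} == {0.8}
    assert {e.intensity for e in mild} == {0.2, 0.25}
    assert all(e.category == "terror" for e in strong)


def test_split_is_partition_and_deterministic():
    lex = _fear_lex([0.1, 0.3, 0.6, 0.7, 0.95])
    a = split_emotion(lex, "fear", "terror", "fear", seed=3)
    b = split_emotion(lex, "fear", "terror", "fear", seed=3)
    assert {e.word for e in a[0]} == {e.word for e in b[0]}
    assert {e.word for e in a[0]} | {e.word for e in a[1]} == lex.words()
    assert not ({e.word for e in a[0]} & {e.word for e in a[1]})


def test_split_requires_two_distinct_intensities():
    with pytest.raises(ValueError, match="distinct"):
        split_emotion(_fear_lex([0.5, 0.5]), "fear", "terror", "fear")


# ---------------------------------------------------------------------------
# synonym expansion


def _msai(entries):
    lex = MSAILexicon()
    for w, c, x in entries:
        lex.add(LexiconEntry(w, c, x))
    return lex


def test_expand_strict_threshold_and_inheritance():
    lex = _msai([("sad", "sadness", 0.6)])
    out = expand_synonyms(lex, {"sad": [("unhappy", 0.8), ("blue", 0.7)]}, 0.7)
    assert out.get("unhappy", "sadness").intensity == 0.6
    assert out.get("blue", "sadness") is None  # similarity must exceed 0.7


def test_expand_collision_keeps_larger_intensity():
    lex = _msai([("sad", "sadness", 0.6), ("unhappy", "sadness", 0.9)])
    out = expand_synonyms(lex, {"sad": [("unhappy", 0.9)]}, 0.7)
    assert out.get("unhappy", "sadness").intensity == 0.9


def test_expand_no_source_is_identity():
    lex = _msai([("sad", "sadness", 0.6)])
    assert expand_synonyms(lex, None) is lex
    assert len(expand_synonyms(lex, {})) == len(lex)


@given(st.floats(0.0, 1.0))
@settings(max_examples=25, deadline=None)
def test_expand_never_removes_or_lowers(sim):
    lex = _msai([("sad", "sadness", 0.6), ("low", "sadness", 0.2)])
    out = expand_synonyms(lex, {"sad": [("low", sim), ("new", sim)]}, 0.7)
    assert len(out) >= len(lex)
    assert out.get("sad", "sadness").intensity == 0.6
    assert out.get("low", "sadness").intensity >= 0.2


# ---------------------------------------------------------------------------
# normalization and round-trip


def test_minmax_normalization():
    out = normalize_lexicon(_msai([("a", "joy", 1), ("b", "joy", 3), ("c", "joy", 5)]))
    assert [out.get(w, "joy").intensity for w in "abc"] == [0, 0.5, 1]


def test_normalization_idempotent_and_degenerate():
    spanned = _msai([("a", "joy", 0.0), ("b", "joy", 0.5), ("c", "joy", 1.0)])
    again = normalize_lexicon(normalize_lexicon(spanned))
    assert [again.get(w, "joy").intensity for w in "abc"] == [0, 0.5, 1]
    const = normalize_lexicon(_msai([("a", "joy", 2), ("b", "joy", 2)]))
    assert {e.intensity for e in const} == {1.0}


def test_save_load_round_trip(tmp_path, msai):
    p = tmp_path / "msai.tsv"
    save_msai(msai, p)
    assert load_msai(p) == msai


def test_save_empty_lexicon_rejected(tmp_path):
    with pytest.raises(ValueError):
        save_msai(MSAILexicon(), tmp_path / "x.tsv")


# ---------------------------------------------------------------------------
# full refinement


def test_refinement_preserves_word_count(lexicons):
    msai, source = lexicons
    assert len(msai) == len(source)
    assert {e.category for e in msai} == set(CATEGORIES_11)


def test_refinement_normalizes_every_category(lexicons):
    msai, _ = lexicons
    for cat in CATEGORIES_11:
        vals = [e.intensity for e in msai.entries_for(cat)]
        assert vals and min(vals) >= 0 and max(vals) == pytest.approx(1.0)


def test_passthrough_categories_unchanged(lexicons):
    msai, source = lexicons
    for cat in ("anger", "surprise", "trust", "joy", "anticipation"):
        assert {e.word for e in msai.entries_for(cat)} == {
            e.word for e in source.entries_for(cat)
        }
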