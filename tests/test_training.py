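"""Profile-correction loop, evaluation metrics and cohort splitting."""

import random

import numpy as np
import pytest

from emoscreen import (
    CATEGORIES_11,
    ConditionProfile,
    LabeledUser,
    TrainingConfig,
    average_diagnostic_precision,
    average_distribution,
    error_rate,
    f1_from_precision_recall,
    precision_recall_f1,
    propose_update,
    split_cohort,
    train,
)
from emoscreen.scoring import SentimentDistribution


def _dist(mass):
    v = np.zeros(len(CATEGORIES_11))
    for cat, x in mass.items():
        v[CATEGORIES_11.index(cat)] = x
    return SentimentDistribution(v / v.sum())


def _profile(cond, mass):
    d = _dist(mass)
    return ConditionProfile(cond, d.values)


UNIFORM = _dist({c: 1.0 for c in CATEGORIES_11})


# ---------------------------------------------------------------------------
# batch averaging


def test_average_of_identical_inputs_is_identity():
    d = _dist({"sadness": 2, "joy": 1})
    assert average_distribution([d, d, d]).values == pytest.approx(d.values)


def test_average_of_two_point_masses():
    avg = average_distribution([_dist({"anger": 1}), _dist({"loathing": 1})])
    assert avg["anger"] == avg["loathing"] == pytest.approx(0.5)


def test_average_hand_mean():
    ds = [_dist({"joy": 1}), _dist({"joy": 1, "trust": 1}), _dist({"trust": 1})]
    avg = average_distribution(ds)
    assert avg["joy"] == pytest.approx(0.5)
    assert avg["trust"] == pytest.approx(0.5)


def test_average_requires_evidence():
    empty = SentimentDistribution(np.zeros(11), empty=True)
    with pytest.raises(ValueError):
        average_distribution([empty])


# ---------------------------------------------------------------------------
# proposal step


def test_uniform_asd_increments_by_one_eleventh():
    cfg = TrainingConfig(batch_size=1, outer_iters=1, seed=0)
    vs = _profile("d", {"sadness": 1, "joy": 1})
    cand, cpos, cneg = propose_update(vs, UNIFORM, cfg, random.Random(0))
    # chosen dims gain 1/11 (the sentiment ratio) before renormalization
    v = vs.vector.copy()
    for cat in (cpos, cneg):
        v[CATEGORIES_11.index(cat)] += 1 / 11
    assert cand.vector == pytest.approx(v / v.sum())


def test_increment_equals_sentiment_ratio():
    asd = _dist({"joy": 4, "trust": 3, "sadness": 2, "fear": 1})
    cfg = TrainingConfig(batch_size=1, outer_iters=1, top_pos=1, top_neg=1, seed=0)
    vs = _profile("d", {"sadness": 1})
    cand, cpos, cneg = propose_update(vs, asd, cfg, random.Random(0))
    assert cpos == "joy" and cneg == "sadness"
    v = vs.vector.copy()
    v[CATEGORIES_11.index("joy")] += 0.4
    v[CATEGORIES_11.index("sadness")] += 0.2
    assert cand.vector == pytest.approx(v / v.sum())


def test_fractional_learning_scale_reading():
    """With learning_scale=0.01 a ratio of 0.4 increments by 0.004."""
    asd = _dist({"joy": 4, "trust": 3, "sadness": 2, "fear": 1})
    cfg = TrainingConfig(top_pos=1, top_neg=1, learning_scale=0.01, seed=0)
    vs = _profile("d", {"sadness": 1})
    cand, _, _ = propose_update(vs, asd, cfg, random.Random(0))
    v = vs.vector.copy()
    v[CATEGORIES_11.index("joy")] += 0.004
    v[CATEGORIES_11.index("sadness")] += 0.002
    assert cand.vector == pytest.approx(v / v.sum())


def test_proposal_stays_on_simplex():
    cfg = TrainingConfig(seed=0)
    rng = random.Random(1)
    vs = _profile("d", {"grief": 3, "sadness": 2, "joy": 1})
    for _ in range(25):
        cand, _, _ = propose_update(vs, UNIFORM, cfg, rng)
        assert cand.vector.sum() == pytest.approx(1.0)
        assert np.all(cand.vector >= 0)
        vs = cand


def test_proposal_with_sparse_polarity_pools():
    """Fewer nonzero categories than the pool size: sample what exists."""
    asd = _dist({"joy": 1, "sadness": 1})
    cfg = TrainingConfig(seed=0)
    cand, cpos, cneg = propose_update(
        _profile("d", {"sadness": 1}), asd, cfg, random.Random(0)
    )
    assert cpos == "joy" and cneg == "sadness"


# ---------------------------------------------------------------------------
# error rate


def _cohort(vs, pos_dists, neg_dists):
    return [(d, True) for d in pos_dists] + [(d, False) for d in neg_dists]


def test_error_rate_perfect_separation():
    vs = _profile("d", {"sadness": 1})
    cohort = _cohort(vs, [_dist({"sadness": 1})], [_dist({"joy": 1})])
    assert error_rate(vs, cohort) == 0.0


def test_error_rate_all_misclassified():
    vs = _profile("d", {"sadness": 1})
    cohort = _cohort(vs, [_dist({"joy": 1})], [_dist({"sadness": 1})])
    assert error_rate(vs, cohort) == 1.0


def test_error_rate_hand_count():
    vs = _profile("d", {"sadness": 1})
    sad, joy = _dist({"sadness": 1}), _dist({"joy": 1})
    mixed = _dist({"sadness": 1, "joy": 1})  # cos = 1/sqrt(2) ~ 0.707 -> positive
    cohort = _cohort(vs, [sad] * 4 + [joy], [joy] * 4 + [mixed])
    # errors: 1 false negative (joy-positive user) + 1 false positive (mixed)
    assert error_rate(vs, cohort) == pytest.approx(2 / 10)


def test_error_rate_empty_cohort_rejected():
    with pytest.raises(ValueError):
        error_rate(_profile("d", {"sadness": 1}), [])


# ---------------------------------------------------------------------------
# training loop


def _training_setup():
    vs = _profile("d", {"sadness": 1})
    labeled = [
        (_dist({"sadness": 1}), {"d"}),
        (_dist({"sadness": 3, "grief": 1}), {"d"}),
        (_dist({"joy": 1}), set()),
        (_dist({"trust": 1}), set()),
    ]
    corpus = [_dist({"joy": 2, "sadness": 1}), _dist({"trust": 1, "fear": 1})]
    return vs, labeled, corpus


def test_perfect_cohort_never_accepts():
    vs, labeled, corpus = _training_setup()
    cfg = TrainingConfig(batch_size=2, outer_iters=20, seed=0)
    trained, trace = train([vs], corpus, labeled, cfg)
    assert not any(s.accepted for s in trace)
    assert trained[0].vector == pytest.approx(vs.vector)


def test_same_seed_identical_trace():
    vs, labeled, corpus = _training_setup()
    cfg = TrainingConfig(batch_size=2, outer_iters=10, seed=42)
    _, trace_a = train([vs], corpus, labeled, cfg)
    _, trace_b = train([vs], corpus, labeled, cfg)
    assert trace_a == trace_b


def test_accepted_error_sequence_non_increasing():
    rng = np.random.default_rng(0)
    vs = ConditionProfile("d", rng.dirichlet(np.ones(11)))
    labeled = []
    for _ in range(40):
        labeled.append((SentimentDistribution(rng.dirichlet(np.ones(11) * 2)), {"d"}))
    for _ in range(40):
        labeled.append((SentimentDistribution(rng.dirichlet(np.ones(11) * 2)), set()))
    corpus = [SentimentDistribution(rng.dirichlet(np.ones(11) * 2)) for _ in range(30)]
    cfg = TrainingConfig(batch_size=10, outer_iters=40, seed=5)
    _, trace = train([vs], corpus, labeled, cfg)
    errs = [s.err_current for s in trace]
    assert errs == sorted(errs, reverse=True)
    for s in trace:
        if s.accepted:
            assert s.err_candidate < s.err_current


# ---------------------------------------------------------------------------
# metrics


def test_adp_all_correct():
    assert average_diagnostic_precision([10] * 5, [0] * 5, 10) == 1.0


def test_adp_single_condition():
    assert average_diagnostic_precision([5], [3], 10) == pytest.approx(0.8)


def test_adp_five_condition_hand_value():
    cw = [3, 2, 1, 0, 4]
    cn = [5, 6, 7, 8, 4]
    # sum = 8+8+8+8+8 = 40; 5 conditions x 10 users
    assert average_diagnostic_precision(cw, cn, 10) == pytest.approx(40 / 50)


def test_adp_rejects_zero_users():
    with pytest.raises(ValueError):
        average_diagnostic_precision([1], [1], 0)


@pytest.mark.parametrize(
    "p,r,f1",
    [(0.77, 0.92, 0.84), (0.69, 0.79, 0.74), (0.75, 0.82, 0.78)],
)
def test_f1_harmonic_mean_two_decimals(p, r, f1):
    assert round(f1_from_precision_recall(p, r), 2) == f1


def test_prf_from_counts():
    p, r, f1 = precision_recall_f1(tp=8, fp=2, fn=0)
    assert (p, r) == (0.8, 1.0)
    assert f1 == pytest.approx(2 * 0.8 / 1.8)
    assert precision_recall_f1(5, 0, 0) == (1.0, 1.0, 1.0)


def test_prf_undefined_denominators_signal():
    with pytest.raises(ZeroDivisionError):
        precision_recall_f1(0, 0, 3)
    with pytest.raises(ZeroDivisionError):
        precision_recall_f1(0, 3, 0)


# ---------------------------------------------------------------------------
# cohort splitting


def _users(n, labeled):
    return [
        LabeledUser(f"{'c' if labeled else 'n'}{i}", ["text"], {"d"} if labeled else set())
        for i in range(n)
    ]


def test_split_reproduces_study_counts():
    cohort = _users(396, True) + _users(400, False)
    tr, te = split_cohort(cohort, 0.7, seed=0)
    assert sum(bool(u.conditions) for u in tr) == 277
    assert sum(bool(u.conditions) for u in te) == 119
    assert sum(not u.conditions for u in tr) == 280
    assert sum(not u.conditions for u in te) == 120


def test_split_disjoint_exhaustive_deterministic():
    cohort = _users(30, True) + _users(41, False)
    a_tr, a_te = split_cohort(cohort, 0.7, seed=9)
    b_tr, b_te = split_cohort(cohort, 0.7, seed=9)
    assert [u.user_id for u in a_tr] == [u.user_id for u in b_tr]
    ids = {u.user_id for u in a_tr} | {u.user_id for u in a_te}
    assert len(ids) == 71 and not ({u.user_id for u in a_tr} & {u.user_id for u in a_te})


def test_split_rejects_bad_fraction():
    with pytest.raises(ValueError):
        split_cohort(_users(4, True), 1.0, seed=0)
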