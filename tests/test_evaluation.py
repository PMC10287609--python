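import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radconcept.evaluation import (
    BootstrapResult,
    ConfusionCounts,
    MetricSet,
    bootstrap_evaluate,
    confusion,
    metrics,
    per_concept_confusion,
    roc_auc,
    roc_curve_points,
    round_half_up,
)


class TestConfusion:
    def test_hand_countable(self):
        c = confusion([1, 1, 0], [1, 0, 0])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 0)

    def test_perfect(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_random_pairs_match_tally(self, rng):
        y_true = rng.integers(0, 2, size=1000)
        y_pred = rng.integers(0, 2, size=1000)
        c = confusion(y_true, y_pred)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for t, p in zip(y_true, y_pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        assert c.total == 1000

    def test_per_concept_one_vs_rest(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        per = per_concept_confusion(y_true, y_pred)
        for lab, c in per.items():
            assert c.tp == int(np.sum((y_true == lab) & (y_pred == lab)))
            assert c.total == 200

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestMetrics:
    def test_paper_worked_example(self):
        m = metrics(ConfusionCounts(tp=510, fp=0, fn=94, tn=896), rounding=2)
        assert m.sensitivity == 0.84
        assert m.ppv == 1.0
        assert m.f1 == 0.92
        assert m.npv == 0.91
        assert m.accuracy == 0.94

    def test_all_perfect(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_random_counts_match_formulas(self, rng):
        for _ in range(500):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, size=4))
            if tp + fp + fn + tn == 0:
                continue
            m = metrics(ConfusionCounts(tp, fp, fn, tn))
            total = tp + fp + fn + tn
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn), abs=1e-12)
            else:
                assert m.sensitivity is None
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
            else:
                assert m.ppv is None
            if tn + fn:
                assert m.npv == pytest.approx(tn / (tn + fn), abs=1e-12)
            else:
                assert m.npv is None
            assert m.accuracy == pytest.approx((tp + tn) / total, abs=1e-12)
            if m.ppv is not None and m.sensitivity is not None and (m.ppv + m.sensitivity) > 0:
                assert m.f1 == pytest.approx(
                    2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity), abs=1e-12
                )

    def test_accuracy_identity_exact(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = (int(x) + 1 for x in rng.integers(0, 30, size=4))
            c = ConfusionCounts(tp, fp, fn, tn)
            m = metrics(c)
            assert m.accuracy * c.total == pytest.approx(tp + tn, abs=1e-9)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_undefined_is_none_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m.ppv is None and m.f1 is None
        assert m.sensitivity == 0.0

    def test_rounding_half_up(self):
        assert round_half_up(0.905, 2) == 0.91
        assert round_half_up(0.944999, 2) == 0.94
        assert round_half_up(0.845, 2) == 0.85


@settings(max_examples=200, deadline=None)
@given(st.tuples(*(st.integers(0, 100) for _ in range(4))))
def test_f1_harmonic_identity_property(counts):
    tp, fp, fn, tn = counts
    if tp + fp + fn + tn == 0:
        return
    m = metrics(ConfusionCounts(tp, fp, fn, tn))
    if m.f1 is not None:
        assert m.f1 == pytest.approx(
            2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity), abs=1e-12
        )


class TestBootstrap:
    def test_perfect_classifier(self, rng):
        y = rng.integers(0, 2, size=100)
        res = bootstrap_evaluate(y, lambda idx: y[idx], n_trials=20, seed=0)
        assert res.mean["accuracy"] == 1.0
        assert res.sd["accuracy"] == 0.0

    def test_seed_determinism(self, rng):
        y = rng.integers(0, 2, size=80)
        pred = rng.integers(0, 2, size=80)
        a = bootstrap_evaluate(y, lambda idx: pred[idx], n_trials=10, seed=5)
        b = bootstrap_evaluate(y, lambda idx: pred[idx], n_trials=10, seed=5)
        assert [m.as_dict() for m in a.per_trial] == [m.as_dict() for m in b.per_trial]

    def test_mean_consistent_with_point_estimate(self, rng):
        y = rng.integers(0, 2, size=300)
        pred = np.where(rng.random(300) < 0.85, y, 1 - y)  # ~85% accurate
        point = metrics(confusion(y, pred)).accuracy
        res = bootstrap_evaluate(y, lambda idx: pred[idx], n_trials=20, seed=1)
        assert abs(res.mean["accuracy"] - point) <= 2 * res.sd["accuracy"]

    def test_formatting_style(self):
        res = BootstrapResult(
            n_trials=2,
            per_trial=[],
            mean={k: 0.7712 for k in ("sensitivity", "ppv", "npv", "f1", "accuracy")},
            sd={k: 0.0151 for k in ("sensitivity", "ppv", "npv", "f1", "accuracy")},
        )
        out = res.formatted()
        assert out["accuracy"] == "0.77(0.02)"

    def test_sd_approaches_binomial_se(self, rng):
        y = rng.integers(0, 2, size=400)
        pred = np.where(rng.random(400) < 0.8, y, 1 - y)
        point = metrics(confusion(y, pred)).accuracy
        res = bootstrap_evaluate(y, lambda idx: pred[idx], n_trials=200, seed=2)
        se = np.sqrt(point * (1 - point) / 400)
        assert res.sd["accuracy"] == pytest.approx(se, rel=0.35)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            bootstrap_evaluate([], lambda idx: idx, n_trials=5, seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_null_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        scores = rng.random(2000)
        n_pos = int(y.sum())
        n_neg = 2000 - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(roc_auc(y, scores) - 0.5) < 3 * se

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            scores = rng.integers(0, 6, size=n).astype(float)  # ties likely
            wins = ties = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    if scores[i] > scores[j]:
                        wins += 1
                    elif scores[i] == scores[j]:
                        ties += 1
            expected = (wins + 0.5 * ties) / (y.sum() * (n - y.sum()))
            assert roc_auc(y, scores) == pytest.approx(expected, abs=1e-12)

    def test_curve_points_monotone(self, rng):
        y = rng.integers(0, 2, size=100)
        scores = rng.random(100)
        pts = roc_curve_points(y, scores)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        assert pts[0, 0] == 0.0 and pts[-1, 1] == 1.0


def test_metricset_rounded_preserves_none():
    m = MetricSet(sensitivity=0.8443, ppv=None, npv=0.905, f1=None, accuracy=0.9373)
    r = m.rounded(2)
    assert r.ppv is None and r.npv == 0.91


def test_bootstrap_format_regex():
    res = BootstrapResult(
        n_trials=1,
        per_trial=[],
        mean={k: 0.5 for k in ("sensitivity", "ppv", "npv", "f1", "accuracy")},
        sd={k: 0.01 for k in ("sensitivity", "ppv", "npv", "f1", "accuracy")},
    )
    for v in res.formatted().values():
        assert re.fullmatch(r"\d\.\d{2}\(\d\.\d{2}\)", v)
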