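"""Threshold selection, gamma normalization, and random-forest training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slcontology.classify import (
    HyperGrid,
    gamma_normalize,
    labels_from_closures,
    predict_orphans,
    select_threshold,
    train_term_classifier,
)
from slcontology.features import feature_matrix
from slcontology.synthetic import FixtureSpec, make_sequence_fixture

QUICK_GRID = HyperGrid(mtry=(10, 30), ntree=(300,))


def sweep_oracle(scores, labels, min_precision):
    """Exhaustive threshold sweep: evaluate precision/recall at every
    distinct score value and apply the stated tie-breaks directly."""
    best = None
    fallback_best = None
    for t in sorted(set(scores)):
        pred = [s >= t for s in scores]
        tp = sum(p and l for p, l in zip(pred, labels))
        fp = sum(p and not l for p, l in zip(pred, labels))
        fn = sum((not p) and l for p, l in zip(pred, labels))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        if fallback_best is None or (prec, rec, t) > fallback_best:
            fallback_best = (prec, rec, t)
        if prec >= min_precision:
            if best is None or (rec, prec, t) > best:
                best = (rec, prec, t)
    if best is not None:
        return best[2], False
    return fallback_best[2], True


class TestSelectThreshold:
    def test_worked_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.2])
        labels = np.array([1, 1, 1, 0])
        t, fb = select_threshold(scores, labels, 0.75)
        assert t == 0.4 and not fb  # precision 1.0, recall 1.0 at 0.4

    def test_perfect_separation(self):
        t, fb = select_threshold(np.array([0.9, 0.8, 0.1, 0.05]),
                                 np.array([1, 1, 0, 0]), 0.75)
        assert t == 0.8 and not fb

    def test_pathological_order_triggers_fallback(self):
        # every positive scores below every negative: no cut reaches 75%
        # precision (best achievable is the base rate 0.5)
        t, fb = select_threshold(np.array([0.1, 0.2, 0.8, 0.9]),
                                 np.array([1, 1, 0, 0]), 0.75)
        assert fb

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = rng.choice(np.round(rng.uniform(0, 1, 10), 3), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        got = select_threshold(scores, labels, 0.75)
        want = sweep_oracle(scores.tolist(), labels.tolist(), 0.75)
        assert got == pytest.approx(want)


class TestGammaNormalize:
    def test_threshold_maps_to_half_exactly(self):
        for t in (0.1, 0.3, 0.5, 0.9):
            assert gamma_normalize(t, t) == pytest.approx(0.5, abs=1e-15)

    def test_endpoints_fixed(self):
        assert gamma_normalize(0.0, 0.3) == 0.0
        assert gamma_normalize(1.0, 0.3) == 1.0

    def test_invalid_threshold_rejected(self):
        for t in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                gamma_normalize(0.5, t)

    @settings(max_examples=200, derandomize=True)
    @given(
        s1=st.floats(1e-6, 1, exclude_max=True),
        delta=st.floats(1e-6, 1),
        t=st.floats(0.05, 0.9),
    )
    def test_order_preserved(self, s1, delta, t):
        s2 = min(1.0, s1 + delta)
        if s1 < s2:
            assert gamma_normalize(s1, t) < gamma_normalize(s2, t)

    def test_bijection_roundtrip(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 1, 100)
        t = 0.3
        gamma = np.log(0.5) / np.log(t)
        back = gamma_normalize(s, t) ** (1 / gamma)
        assert np.allclose(back, s)


@pytest.fixture(scope="module")
def planted_training_set():
    spec = FixtureSpec(seed=21, class_signal=0.25)
    ids = [f"P{i:03d}" for i in range(120)]
    pos = set(ids[:40])
    prots, _ = make_sequence_fixture(spec, ids, pos)
    X, _ = feature_matrix(prots)
    y = np.array([1 if i in pos else 0 for i in X.index])
    return X, y


class TestTraining:
    def test_planted_signal_recovered(self, planted_training_set):
        X, y = planted_training_set
        spec = train_term_classifier(X, y, "TOY:0001", grid=QUICK_GRID, seed=0)
        assert spec.auroc > 0.9
        assert spec.n_pos == 40 and spec.n_neg == 80

    def test_permuted_labels_give_chance_auroc(self, planted_training_set):
        X, y = planted_training_set
        aurocs = []
        for seed in range(5):
            yp = np.random.default_rng(seed).permutation(y)
            spec = train_term_classifier(X, yp, "T", grid=QUICK_GRID, seed=seed)
            aurocs.append(spec.auroc)
        assert 0.4 <= float(np.mean(aurocs)) <= 0.6

    def test_too_few_positives_is_explicit_error(self, planted_training_set):
        X, y = planted_training_set
        y_sparse = np.zeros_like(y)
        y_sparse[:3] = 1
        with pytest.raises(ValueError, match="positives"):
            train_term_classifier(X, y_sparse, "T", grid=QUICK_GRID, seed=0)

    def test_metrics_consistent_with_confusion_at_threshold(self, planted_training_set):
        X, y = planted_training_set
        spec = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=0)
        pred = spec.oob_scores >= spec.threshold
        tp = int(np.sum(pred & (spec.labels == 1)))
        fp = int(np.sum(pred & (spec.labels == 0)))
        fn = int(np.sum(~pred & (spec.labels == 1)))
        assert spec.precision == pytest.approx(tp / (tp + fp))
        assert spec.recall == pytest.approx(tp / (tp + fn))
        assert spec.f1 == pytest.approx(
            2 * spec.precision * spec.recall / (spec.precision + spec.recall)
        )

    def test_determinism_fixed_seed_identical_spec(self, planted_training_set):
        X, y = planted_training_set
        a = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=7)
        b = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=7)
        assert a.to_json_dict() == b.to_json_dict()
        assert np.array_equal(a.oob_scores, b.oob_scores)

    def test_labels_from_closures(self):
        closures = {"S1": {"T1", "T2"}, "S2": {"T2"}, "S3": set()}
        y = labels_from_closures(closures, "T2", ["S1", "S2", "S3"])
        assert y.tolist() == [1, 1, 0]


class TestPredict:
    def test_empty_orphan_list(self, planted_training_set):
        X, y = planted_training_set
        spec = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=0)
        out = predict_orphans([spec], X.iloc[0:0])
        assert len(out) == 0

    def test_feature_mismatch_is_contract_error(self, planted_training_set):
        X, y = planted_training_set
        spec = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=0)
        with pytest.raises(ValueError, match="feature"):
            predict_orphans([spec], X.iloc[:2, ::-1])

    def test_clone_of_strong_positive_called_positive(self, planted_training_set):
        X, y = planted_training_set
        spec = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=0)
        # orphan identical in features to the highest-scoring positive
        best_pos = int(np.argmax(np.where(y == 1, spec.oob_scores, -1)))
        orphan = X.iloc[[best_pos]].rename(index={X.index[best_pos]: "ORPHAN1"})
        out = predict_orphans([spec], orphan)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["normalized_score"] > 0.5 and bool(row["call"])
        # normalized score crosses 0.5 exactly when raw crosses threshold
        assert (row["raw_score"] >= spec.threshold) == row["call"]

    def test_synthetic_orphans_from_positive_distribution_called(self):
        spec_fix = FixtureSpec(seed=31, class_signal=0.25)
        ids = [f"P{i:03d}" for i in range(120)]
        pos = set(ids[:40])
        prots, _ = make_sequence_fixture(spec_fix, ids, pos)
        X, _ = feature_matrix(prots)
        y = np.array([1 if i in pos else 0 for i in X.index])
        model = train_term_classifier(X, y, "T", grid=QUICK_GRID, seed=1)
        orphan_ids = [f"O{i:02d}" for i in range(20)]
        orphans, _ = make_sequence_fixture(
            spec_fix, orphan_ids, set(orphan_ids), seed=99
        )
        OX, _ = feature_matrix(orphans)
        out = predict_orphans([model], OX)
        assert out["call"].mean() >= 0.8
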