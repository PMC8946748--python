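"""Bin classifier: balancing, training, prediction, review, FPR, sweeps."""

import numpy as np
import pytest

from clicktypes import (
    BinLabel,
    NetworkSpec,
    TrainingConfig,
    build_balanced_set,
    estimate_fpr,
    features_from_summary,
    predict_bins,
    threshold_sweep,
    train_network,
)
from clicktypes.classifier import (
    CLASS_REGISTRY,
    apply_review_mask,
    review_labels,
    train_val_split,
)

SMALL = TrainingConfig(examples_per_class=220, train_per_class=200, test_per_class=20)


def _blobs(rng, n_per_class, k=3, d=12, noise=0.05):
    centers = rng.random((k, d))
    return {
        f"c{i}": np.clip(centers[i] + noise * rng.normal(0, 1, (n_per_class, d)), 0, 1)
        for i in range(k)
    }


class TestBalancing:
    def test_default_counts_majority_and_minority(self):
        """10,000- and 800-example classes both emerge with 5,500 examples,
        split 5,000 train / 500 test per class."""
        rng = np.random.default_rng(0)
        parts = build_balanced_set(
            {"big": rng.random((10_000, 4)), "small": rng.random((800, 4))}
        )
        for cls in ("big", "small"):
            assert int((parts.y_train == cls).sum()) == 5000
            assert int((parts.y_test == cls).sum()) == 500

    def test_minority_class_keeps_originals_and_augments(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 6))
        cfg = TrainingConfig(examples_per_class=100, train_per_class=90, test_per_class=10)
        parts = build_balanced_set({"m": X}, cfg)
        combined = np.concatenate([parts.X_train, parts.X_test])
        assert len(combined) == 100
        # every original example survives balancing exactly
        orig = {tuple(np.round(r, 12)) for r in X}
        got = {tuple(np.round(r, 12)) for r in combined}
        assert orig <= got
        # augmented copies stay in the valid feature range
        assert combined.min() >= 0.0 and combined.max() <= 1.0

    def test_train_val_subdivision_80_20(self):
        rng = np.random.default_rng(2)
        parts = build_balanced_set(_blobs(rng, 300), SMALL)
        Xtr, Xval, ytr, yval = train_val_split(parts)
        for cls in parts.classes:
            assert int((ytr == cls).sum()) == 160  # 80% of 200
            assert int((yval == cls).sum()) == 40

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_balanced_set({"empty": np.zeros((0, 5))}, SMALL)

    def test_registry_has_twenty_classes(self):
        assert len(CLASS_REGISTRY) == 20
        assert len(set(CLASS_REGISTRY)) == 20


class TestTraining:
    def test_separable_classes_high_accuracy(self):
        """Linearly separable blobs: test accuracy above 0.99."""
        rng = np.random.default_rng(3)
        parts = build_balanced_set(_blobs(rng, 300, noise=0.03), SMALL)
        model = train_network(parts, NetworkSpec(hidden_layers=(32, 32), max_epochs=80), seed=0)
        acc = float((model.predict(parts.X_test) == parts.y_test).mean())
        assert acc > 0.99

    def test_permuted_labels_near_chance(self):
        """Label-permuted training collapses to chance accuracy."""
        rng = np.random.default_rng(4)
        parts = build_balanced_set(_blobs(rng, 300, noise=0.03), SMALL)
        parts.y_train = rng.permutation(parts.y_train)
        model = train_network(parts, NetworkSpec(hidden_layers=(16,), max_epochs=30), seed=0)
        acc = float((model.predict(parts.X_test) == parts.y_test).mean())
        assert acc < 0.55  # chance is 1/3


@pytest.fixture(scope="module")
def model_and_summaries(planted_summaries):
    summaries, truth = planted_summaries
    feats = {}
    for s, t in zip(summaries, truth):
        feats.setdefault(t, []).append(features_from_summary(s))
    cfg = TrainingConfig(
        examples_per_class=60, train_per_class=50, test_per_class=10, seed=1
    )
    parts = build_balanced_set({k: np.array(v) for k, v in feats.items()}, cfg)
    model = train_network(parts, NetworkSpec(hidden_layers=(64, 64), max_epochs=60), seed=1)
    return model, summaries, truth


class TestPrediction:

    def test_empty_input_empty_output(self, model_and_summaries):
        model, _, _ = model_and_summaries
        assert predict_bins(model, []) == []

    def test_probabilities_normalized(self, model_and_summaries):
        model, summaries, _ = model_and_summaries
        X = np.array([features_from_summary(s) for s in summaries])
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_held_out_type_majority_label(self, model_and_summaries):
        """UD28 bins are labeled UD28 by majority."""
        model, summaries, truth = model_and_summaries
        ud28 = [s for s, t in zip(summaries, truth) if t == "UD28"]
        labels = predict_bins(model, ud28)
        pred = [l.predicted_class for l in labels]
        assert pred.count("UD28") / len(pred) > 0.5

    def test_feature_length_mismatch_rejected(self, model_and_summaries):
        model, summaries, _ = model_and_summaries
        bad = summaries[0]
        bad_s = type(bad)(
            bin_start=0.0,
            mean_spectrum_db=np.zeros(50),
            ici_hist=np.zeros(10),
            mean_envelope=np.zeros(50),
            n_clicks=1,
        )
        with pytest.raises(ValueError, match="feature length"):
            predict_bins(model, [bad_s])


def _labels(n, cls="A", site="S", depl="d1", wrong_idx=()):
    labels = [
        BinLabel(bin_start=i, predicted_class=cls, probability=1.0, site=site,
                 deployment=depl, mean_rl_db=125.0, n_clicks=10)
        for i in range(n)
    ]
    truth = [cls if i not in wrong_idx else "OTHER" for i in range(n)]
    return labels, truth


class TestReview:
    def test_mask_bookkeeping(self, planted_summaries):
        summaries, truth = planted_summaries
        labels = [
            BinLabel(bin_start=s.bin_start, predicted_class=t, probability=1.0)
            for s, t in zip(summaries, truth)
        ]
        order = review_labels(labels, summaries, "Gg")
        assert len(order) == truth.count("Gg")
        # sorted artifact rows follow peak-frequency order
        peaks = [float(np.argmax(summaries[i].mean_spectrum_db)) for i in order]
        assert peaks == sorted(peaks)
        removed = apply_review_mask(labels, order[:3])
        assert removed == 3
        assert sum(not l.review_flag for l in labels) == 3
        assert apply_review_mask(labels, np.array([], dtype=int)) == 0

    def test_review_artifact_written(self, tmp_path, planted_summaries):
        summaries, truth = planted_summaries
        labels = [
            BinLabel(bin_start=s.bin_start, predicted_class=t, probability=1.0)
            for s, t in zip(summaries, truth)
        ]
        out = tmp_path / "review_Gg.png"
        review_labels(labels, summaries, "Gg", out_path=out)
        assert out.exists() and out.stat().st_size > 0


class TestFPR:
    def test_all_correct_zero_fpr(self):
        labels, truth = _labels(40)
        (est,) = estimate_fpr(labels, truth)
        assert est.fpr == 0.0

    def test_five_wrong_of_fifty(self):
        labels, truth = _labels(50, wrong_idx=set(range(5)))
        (est,) = estimate_fpr(labels, truth, n_per_stratum=50)
        assert est.fpr == pytest.approx(0.10)
        assert est.n_reviewed == 50

    def test_stratified_close_to_exhaustive(self):
        rng = np.random.default_rng(8)
        wrong = set(rng.choice(1000, size=200, replace=False).tolist())
        labels, truth = _labels(1000, wrong_idx=wrong)
        (est,) = estimate_fpr(labels, truth, n_per_stratum=100, seed=3)
        assert est.fpr == pytest.approx(0.2, abs=0.05)

    def test_estimator_unbiased_over_seeds(self):
        """Mean stratified estimate over 100 seeds within 0.02 of truth."""
        rng = np.random.default_rng(9)
        wrong = set(rng.choice(600, size=60, replace=False).tolist())
        labels, truth = _labels(600, wrong_idx=wrong)
        ests = [
            estimate_fpr(labels, truth, n_per_stratum=50, seed=s)[0].fpr
            for s in range(100)
        ]
        assert float(np.mean(ests)) == pytest.approx(0.10, abs=0.02)

    def test_averaging_repeated_deployments(self):
        l1, t1 = _labels(20, depl="d1", wrong_idx={0, 1})  # fpr 0.1
        l2, t2 = _labels(20, depl="d2", wrong_idx={0, 1, 2, 3})  # fpr 0.2
        est = estimate_fpr(l1 + l2, t1 + t2, average_deployments=True)
        assert len(est) == 1
        assert est[0].fpr == pytest.approx(0.15)

    def test_unreviewed_labels_excluded(self):
        labels, truth = _labels(20, wrong_idx={0})
        labels[0].review_flag = False
        (est,) = estimate_fpr(labels, truth)
        assert est.fpr == 0.0


class TestThresholdSweep:
    def _contaminated(self):
        """Noisy low-RL bins mislabeled; clean high-RL bins correct."""
        labels, truth = [], []
        for i in range(40):
            labels.append(BinLabel(bin_start=i, predicted_class="A", probability=1.0,
                                   mean_rl_db=130.0, n_clicks=50))
            truth.append("A")
        for i in range(10):
            labels.append(BinLabel(bin_start=100 + i, predicted_class="A", probability=1.0,
                                   mean_rl_db=121.0, n_clicks=3))
            truth.append("NOISE")
        return labels, truth

    def test_noop_thresholds_full_retention(self):
        labels, truth = self._contaminated()
        table = threshold_sweep(labels, truth, [0.0], [0])
        assert table.retention.iloc[0] == 1.0

    def test_retention_monotone_and_fpr_improves(self):
        labels, truth = self._contaminated()
        table = threshold_sweep(labels, truth, [0.0, 122.0, 126.0], [0, 5, 10])
        base = table[(table.min_rl_db == 0.0) & (table.min_clicks == 0)].iloc[0]
        strict = table[(table.min_rl_db == 126.0) & (table.min_clicks == 10)].iloc[0]
        assert strict.fpr <= base.fpr
        for nc in (0, 5, 10):  # monotone along the RL axis
            r = table[table.min_clicks == nc].sort_values("min_rl_db").retention.to_numpy()
            assert np.all(np.diff(r) <= 0)
        for rl in (0.0, 122.0, 126.0):  # monotone along the clicks axis
            r = table[table.min_rl_db == rl].sort_values("min_clicks").retention.to_numpy()
            assert np.all(np.diff(r) <= 0)
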