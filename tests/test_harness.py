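import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import pulsemap as pm
from pulsemap import LabeledFeatureSet, TrainConfig
from pulsemap.harness import augment, class_weights, confusion_metrics, make_cv_splits
from pulsemap.nn import LinearModel, build_model


class TestCVSplits:
    def test_110_subjects_give_22_disjoint_folds(self):
        subjects = [f"S{i:03d}" for i in range(110)]
        plan = make_cv_splits(subjects, group_size=5, seed=0)
        assert plan.n_folds == 22
        tests = [set(te) for _, te in plan.folds]
        assert all(len(t) == 5 for t in tests)
        union = set().union(*tests)
        assert union == set(subjects)
        for i in range(len(tests)):
            for j in range(i + 1, len(tests)):
                assert not tests[i] & tests[j]

    def test_no_subject_leakage(self):
        plan = make_cv_splits([f"s{i}" for i in range(20)], group_size=5, seed=3)
        for train, test in plan.folds:
            assert not set(train) & set(test)
            assert set(train) | set(test) == {f"s{i}" for i in range(20)}

    def test_ten_subjects_two_folds(self):
        plan = make_cv_splits([f"s{i}" for i in range(10)], group_size=5, seed=1)
        assert plan.n_folds == 2

    def test_non_divisible_warns_with_smaller_last_fold(self):
        with pytest.warns(UserWarning, match="not divisible"):
            plan = make_cv_splits([f"s{i}" for i in range(12)], group_size=5, seed=0)
        sizes = sorted(len(te) for _, te in plan.folds)
        assert sizes == [2, 5, 5]

    def test_group_too_large(self):
        with pytest.raises(ValueError):
            make_cv_splits(["a", "b"], group_size=5)

    def test_duplicated_ids_deduplicated(self):
        plan = make_cv_splits(["a", "b", "a", "c", "b", "d"], group_size=2, seed=0)
        assert plan.n_folds == 2


class TestClassWeights:
    def test_balanced_labels_weigh_one(self):
        labels = list("ADFSN") * 4
        assert all(w == pytest.approx(1.0) for w in class_weights(labels).values())

    def test_inverse_frequency_formula(self):
        labels = ["A"] * 10 + ["D"] * 10 + ["F"] * 5 + ["S"] * 10 + ["N"] * 15
        w = class_weights(labels)
        assert w["F"] == pytest.approx(50 / (5 * 5))  # = 2.0
        assert w["N"] == pytest.approx(50 / (5 * 15))

    def test_order_invariance(self):
        labels = ["A"] * 3 + ["D", "F", "S", "N"] * 2
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(labels))
        assert class_weights(labels) == class_weights(shuffled)

    def test_missing_class_listed_in_error(self):
        with pytest.raises(ValueError, match="F"):
            class_weights(["A", "D", "S", "N"])


class TestAugment:
    def test_rotation_180_is_involution(self, fake_rng_factory):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(8, 8, 5))
        rot = augment(block, fake_rng_factory(2), pixel_drop_p=0.0)
        back = augment(rot, fake_rng_factory(2), pixel_drop_p=0.0)
        np.testing.assert_array_equal(back, block)

    def test_identity_under_zero_rotation_and_drop(self, fake_rng_factory):
        block = np.random.default_rng(1).normal(size=(6, 6, 5))
        out = augment(block, fake_rng_factory(0), pixel_drop_p=0.0)
        np.testing.assert_array_equal(out, block)

    def test_pixel_drop_expectation(self):
        rng = np.random.default_rng(42)
        block = np.ones((224, 224, 5))
        counts = []
        for _ in range(200):
            out = augment(block, rng, pixel_drop_p=1 / 124)
            counts.append((out[..., 0] == 0).sum())
        expected = 224 * 224 / 124  # ~405 binomial mean
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_drop_zeroes_full_depth_vector(self):
        rng = np.random.default_rng(0)
        out = augment(np.ones((20, 20, 5)), rng, pixel_drop_p=0.5)
        dropped = out[..., 0] == 0
        assert dropped.any()
        assert not out[dropped].any()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            augment(np.ones((4, 6, 5)), np.random.default_rng(0))


class TestBuildModel:
    def test_forward_shape_contract(self):
        model = build_model(5, 5, backbone="tiny", input_hw=56, seed=0)
        logits = model.predict_logits(np.zeros((2, 56, 56, 5), dtype=np.float32))
        assert logits.shape == (2, 5)

    def test_depth_ten_accepted(self):
        model = build_model(10, 5, backbone="tiny", input_hw=56, seed=0)
        assert model.predict(np.zeros((1, 56, 56, 10))).shape == (1,)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            build_model(5, 5, backbone="transformer")
        with pytest.raises(ValueError):
            build_model(0, 5)

    def test_tiny_cnn_overfits_memorizable_set(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=(8, 56, 56, 5)).astype(np.float32)
        y = np.array([0, 1, 2, 3, 4, 0, 1, 2])
        model = build_model(5, 5, backbone="tiny", input_hw=56, seed=0)
        cfg = TrainConfig(epochs=200, batch_size=8, dropout=0.0, augment=False)
        model.fit(x, y, None, cfg, np.random.default_rng(1))
        assert (model.predict(x) == y).mean() == 1.0

    def test_training_is_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 28, 28, 2)).astype(np.float32)
        y = rng.integers(0, 5, size=10)
        preds = []
        for _ in range(2):
            m = build_model(2, 5, backbone="tiny", input_hw=28, seed=7)
            m.fit(x, y, None, TrainConfig(epochs=5, batch_size=4, augment=False),
                  np.random.default_rng(11))
            preds.append(m.predict(x))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestConfusionMetrics:
    def test_two_class_worked_example(self):
        m = np.array([[3, 1], [2, 4]])
        report = confusion_metrics([m], classes=("P", "Q"))
        assert report.per_class_precision[0, 0] == pytest.approx(3 / 5)
        assert report.per_class_recall[0, 0] == pytest.approx(3 / 4)
        assert report.per_class_f1[0, 0] == pytest.approx(
            2 * (0.6 * 0.75) / (0.6 + 0.75)
        )
        assert report.accuracy == pytest.approx(7 / 10)

    def test_identity_matrix_perfect_scores(self):
        report = confusion_metrics([np.eye(5, dtype=int) * 4])
        assert report.accuracy == 1.0
        assert (report.per_class_f1 == 1.0).all()

    @pytest.mark.parametrize("case_seed", range(4))
    def test_row_normalization_and_sklearn_agreement(self, case_seed):
        rng = np.random.default_rng(case_seed)
        y_true = rng.integers(0, 5, size=200)
        y_pred = rng.integers(0, 5, size=200)
        mat = np.zeros((5, 5), dtype=int)
        np.add.at(mat, (y_true, y_pred), 1)
        report = confusion_metrics([mat])
        rows = report.row_normalized.sum(axis=1)
        np.testing.assert_allclose(rows[mat.sum(axis=1) > 0], 1.0)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=range(5), zero_division=0
        )
        np.testing.assert_allclose(report.per_class_precision[0], p, atol=1e-12)
        np.testing.assert_allclose(report.per_class_recall[0], r, atol=1e-12)
        np.testing.assert_allclose(report.per_class_f1[0], f, atol=1e-12)

    def test_macro_mean_and_sd_across_folds(self):
        mats = [np.eye(5, dtype=int) * 2, np.full((5, 5), 1, dtype=int)]
        report = confusion_metrics(mats)
        accs = report.fold_accuracies
        assert report.macro["accuracy"][0] == pytest.approx(accs.mean())
        assert report.macro["accuracy"][1] == pytest.approx(accs.std(ddof=1))

    def test_zero_division_convention(self):
        m = np.zeros((5, 5), dtype=int)
        m[0, 0] = 5  # only class 0 present and predicted
        report = confusion_metrics([m])
        assert report.per_class_precision[0, 1] == 0.0
        assert report.n_undefined > 0


def toy_feature_set(n_subjects=6, clips_each=5, hw=8, seed=0):
    """Blocks whose mean encodes the class index (linearly separable)."""
    rng = np.random.default_rng(seed)
    blocks, labels, subjects = [], [], []
    classes = pm.EMOTION_CLASSES
    for s in range(n_subjects):
        for c in range(clips_each):
            label = classes[c % 5]
            mean = classes.index(label) * 2.0
            blocks.append(rng.normal(mean, 0.3, size=(hw, hw, 5)))
            labels.append(label)
            subjects.append(f"s{s}")
    return LabeledFeatureSet(np.stack(blocks).astype(np.float32), labels, subjects)


class TestTrainAndEvaluate:
    def test_oracle_model_scores_perfectly(self):
        data = toy_feature_set()
        plan = make_cv_splits(sorted(set(data.subject_ids)), group_size=3, seed=0)

        class Oracle:
            def fit(self, *a, **k):
                return []

            def predict(self, x):
                return np.clip(np.round(x.mean(axis=(1, 2, 3)) / 2.0), 0, 4).astype(int)

        report = pm.train_and_evaluate(
            data, plan, TrainConfig(epochs=1), seed=0,
            model_factory=lambda *a: Oracle(),
        )
        assert report.accuracy == 1.0
        off_diag = report.summed_matrix - np.diag(np.diag(report.summed_matrix))
        assert not off_diag.any()
        assert (report.per_class_f1 == 1.0).all()

    def test_constant_predictor_metrics(self):
        data = toy_feature_set()
        plan = make_cv_splits(sorted(set(data.subject_ids)), group_size=3, seed=0)
        n_idx = pm.EMOTION_CLASSES.index("N")

        class AlwaysN:
            def fit(self, *a, **k):
                return []

            def predict(self, x):
                return np.full(len(x), n_idx)

        report = pm.train_and_evaluate(
            data, plan, TrainConfig(epochs=1), seed=0,
            model_factory=lambda *a: AlwaysN(),
        )
        recalls = report.per_class_recall.mean(axis=0)
        assert recalls[n_idx] == 1.0
        assert recalls[np.arange(5) != n_idx].max() == 0.0
        prevalence = np.mean([l == "N" for l in data.labels])
        assert report.accuracy == pytest.approx(prevalence)

    def test_accuracy_matches_prediction_recount(self):
        data = toy_feature_set(n_subjects=4, clips_each=5)
        plan = make_cv_splits(sorted(set(data.subject_ids)), group_size=2, seed=0)
        report = pm.train_and_evaluate(
            data, plan,
            TrainConfig(epochs=10, batch_size=8, augment=False),
            seed=0,
            model_factory=lambda depth, k, hw, s: LinearModel(depth, k, hw, seed=s),
        )
        hits = sum((yt == yp).sum() for yt, yp in report.predictions)
        total = sum(len(yt) for yt, _ in report.predictions)
        assert report.accuracy == pytest.approx(hits / total)

    def test_weighted_loss_improves_minority_recall(self):
        # paired-seed comparison on an imbalanced overlapping 2-class toy
        def minority_recall(weighted, seed):
            rng = np.random.default_rng(seed)
            x = np.concatenate([
                rng.normal(0.0, 1.0, size=(90, 4, 4, 1)),
                rng.normal(0.8, 1.0, size=(10, 4, 4, 1)),
            ]).astype(np.float32)
            y = np.r_[np.zeros(90, int), np.ones(10, int)]
            x_test = rng.normal(0.8, 1.0, size=(200, 4, 4, 1)).astype(np.float32)
            cw = np.array([100 / 180, 100 / 20]) if weighted else None
            cfg = TrainConfig(epochs=40, batch_size=32, augment=False,
                              weighted_loss=weighted)
            m = LinearModel(1, 2, input_hw=4, seed=seed)
            m.fit(x, y, cw, cfg, np.random.default_rng(seed + 1))
            return (m.predict(x_test) == 1).mean()

        diffs = [
            minority_recall(True, s) - minority_recall(False, s) for s in range(10)
        ]
        assert np.mean(diffs) > 0.05
        assert sum(d >= 0 for d in diffs) >= 8

    def test_input_normalization_option(self):
        data = toy_feature_set(n_subjects=4, clips_each=5)
        plan = make_cv_splits(sorted(set(data.subject_ids)), group_size=2, seed=0)
        seen = []

        class Probe:
            def fit(self, x, *a, **k):
                seen.append(x)
                return []

            def predict(self, x):
                return np.zeros(len(x), dtype=int)

        pm.train_and_evaluate(
            data, plan, TrainConfig(epochs=1, normalize_inputs=True), seed=0,
            model_factory=lambda *a: Probe(),
        )
        x = seen[0]
        np.testing.assert_allclose(x.mean(axis=(1, 2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(x.std(axis=(1, 2, 3)), 1.0, atol=1e-4)

    def test_plan_subject_mismatch_rejected(self):
        data = toy_feature_set(n_subjects=4)
        plan = make_cv_splits(["x1", "x2"], group_size=1, seed=0)
        with pytest.raises(ValueError):
            pm.train_and_evaluate(data, plan, TrainConfig(epochs=1), seed=0)
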