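import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr
from sklearn.tree import DecisionTreeClassifier

from cytocycle.boost import (
    CVReport,
    LSBoostParams,
    RUSBoostParams,
    cross_validate,
    fit_lsboost,
    fit_rusboost,
    internal_cv_stopping,
    lofo_importance,
    load_model,
    merge_phase_labels,
    save_model,
)


def _toy_regression(n=200, n_feat=5, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, n_feat)), columns=[f"f{i}" for i in range(n_feat)])
    y = 3.0 * X["f0"].to_numpy() + noise * rng.normal(size=n)
    return X, y


def _toy_classification(n=400, minority=8, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    labels = np.array(["common"] * n, dtype=object)
    labels[:minority] = "rare"
    X.loc[labels == "rare", "a"] += sep
    return X, labels


class TestLSBoost:
    def test_realizable_target_fits_tightly(self):
        X, y = _toy_regression()
        model = fit_lsboost(X, y, LSBoostParams(M=500), seed=0)
        assert pearsonr(model.predict(X), y)[0] >= 0.999

    def test_prediction_identity(self):
        X, y = _toy_regression(seed=1)
        model = fit_lsboost(X, y, LSBoostParams(M=50), seed=0)
        assert np.array_equal(model.predict(X), model.train_predictions)

    def test_zero_variance_target_rejected(self):
        X, _ = _toy_regression()
        with pytest.raises(ValueError, match="variance"):
            fit_lsboost(X, np.ones(len(X)), LSBoostParams(M=10))

    def test_training_loss_non_increasing(self):
        X, y = _toy_regression(noise=1.0, seed=2)
        model = fit_lsboost(X, y, LSBoostParams(M=100), seed=0)
        losses = [
            np.mean((p - y) ** 2) for p in model.estimator.staged_predict(X.to_numpy())
        ]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_feature_name_mismatch_rejected(self):
        X, y = _toy_regression()
        model = fit_lsboost(X, y, LSBoostParams(M=10), seed=0)
        wrong = X.rename(columns={"f0": "g0"})
        with pytest.raises(ValueError, match="manifest"):
            model.predict(wrong)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = _toy_regression(noise=0.5, seed=3)
        model = fit_lsboost(X, y, LSBoostParams(M=40), seed=1)
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.allclose(back.predict(X), model.predict(X))


class TestInternalStopping:
    def test_pure_noise_selects_few_stages(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(300, 5)))
        y = rng.normal(size=300)
        m_star = internal_cv_stopping(X, y, LSBoostParams(M_max=100), task="regression", seed=0)
        assert m_star <= 10

    def test_learnable_target_selects_many_stages(self):
        X, y = _toy_regression(n=300, seed=5)
        m_star = internal_cv_stopping(X, y, LSBoostParams(M_max=100), task="regression", seed=0)
        assert m_star >= 50

    def test_deterministic(self):
        X, y = _toy_regression(noise=1.0, seed=6)
        params = LSBoostParams(M_max=60)
        a = internal_cv_stopping(X, y, params, task="regression", seed=7)
        b = internal_cv_stopping(X, y, params, task="regression", seed=7)
        assert a == b


class TestRUSBoost:
    def test_separable_balanced_classes_learned_perfectly(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=list("xy"))
        y = np.where(X["x"] > 0, "pos", "neg")
        model = fit_rusboost(X, y, RUSBoostParams(M=20), seed=0)
        pred = model.predict(X)
        assert (pred[y == "pos"] == "pos").all()
        assert (pred[y == "neg"] == "neg").all()

    def test_single_class_rejected(self):
        X, _ = _toy_regression(n=50)
        with pytest.raises(ValueError, match="2 classes"):
            fit_rusboost(X, np.array(["only"] * 50), RUSBoostParams(M=5))

    def test_predictions_within_training_classes(self):
        X, y = _toy_classification(seed=8)
        model = fit_rusboost(X, y, RUSBoostParams(M=15), seed=0)
        assert set(model.predict(X)) <= set(y)

    def test_undersampling_rescues_minority_recall(self):
        # 2% minority: with per-stage undersampling the minority class is
        # recalled; the plain (no-undersampling) ensemble neglects it
        X, y = _toy_classification(n=500, minority=10, sep=2.0, seed=9)
        rep_rus = cross_validate(X, y, k=5, task="classification", seed=1,
                                 params=RUSBoostParams(M=30))
        rep_ada = cross_validate(X, y, k=5, task="classification", seed=1,
                                 params=RUSBoostParams(M=30, undersample_ratio=None))
        assert rep_rus.mean["rare"] >= rep_ada.mean["rare"]

    def test_no_undersampling_equals_adaboost_oracle(self):
        # brute-force SAMME loop with the same weak learners and seeds
        X, y = _toy_classification(n=40, minority=12, sep=2.5, seed=10)
        params = RUSBoostParams(M=8, undersample_ratio=None)
        model = fit_rusboost(X, y, params, seed=3)

        Xm = X.to_numpy(float)
        classes = sorted(set(y))
        K = len(classes)
        n = len(Xm)
        w = np.full(n, 1.0 / n)
        scores = np.zeros((n, K))
        rng = np.random.default_rng(np.random.SeedSequence((3, 0xB005)))
        for _ in range(params.M):
            tree = DecisionTreeClassifier(
                max_depth=params.max_depth,
                min_samples_leaf=params.min_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xm, y, sample_weight=w / w.sum())
            pred = tree.predict(Xm)
            miss = pred != y
            err = float((w * miss).sum() / w.sum())
            if err >= 1 - 1 / K:
                break
            err = max(err, 1e-10)
            alpha = np.log((1 - err) / err) + np.log(K - 1)
            for ci, c in enumerate(classes):
                scores[pred == c, ci] += alpha
            w = w * np.exp(alpha * miss)
            w = w / w.sum()
            if err <= 1e-10:
                break
        oracle = np.asarray(classes, dtype=object)[scores.argmax(axis=1)]
        assert np.array_equal(model.predict(X), oracle)


class TestCrossValidate:
    def test_partition_each_cell_once(self):
        X, y = _toy_regression(n=120, noise=1.0, seed=11)
        rep = cross_validate(X, y, k=6, task="regression", seed=0, params=LSBoostParams(M=20))
        assert rep.fold_of.notna().all()
        assert sorted(rep.fold_of.unique()) == list(range(6))

    def test_leave_one_out_regression_rejected(self):
        X, y = _toy_regression(n=30, seed=12)
        with pytest.raises(ValueError, match="Pearson"):
            cross_validate(X, y, k=30, task="regression", params=LSBoostParams(M=5))

    def test_perfect_classifier_reports_unit_tpr(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=list("uv"))
        y = np.where(X["u"] > 0, "pos", "neg")
        X["u"] += np.where(y == "pos", 3.0, -3.0)  # widen the margin
        rep = cross_validate(X, y, k=5, task="classification", seed=0,
                             params=RUSBoostParams(M=10))
        assert rep.mean["pos"] == 1.0 and rep.mean["neg"] == 1.0
        assert rep.sd["pos"] == 0.0

    def test_seeded_determinism(self):
        X, y = _toy_regression(n=100, noise=1.0, seed=14)
        a = cross_validate(X, y, k=5, task="regression", seed=2, params=LSBoostParams(M=15))
        b = cross_validate(X, y, k=5, task="regression", seed=2, params=LSBoostParams(M=15))
        assert a.fold_metrics == b.fold_metrics
        assert a.mean == b.mean

    def test_confusion_row_sums_match_class_counts(self):
        X, y = _toy_classification(n=200, minority=20, seed=15)
        rep = cross_validate(X, y, k=5, task="classification", seed=0,
                             params=RUSBoostParams(M=10))
        row_sums = rep.confusion.sum(axis=1)
        for c in rep.confusion.index:
            assert row_sums[c] == (y == c).sum()


class TestLofoImportance:
    def test_zero_variance_feature_unimportant_and_bookkeeping(self):
        X, y = _toy_regression(n=150, noise=0.5, seed=16)
        X["dead"] = 1.0
        X["dup"] = X["f0"]
        cats = {c: ("signal" if c in ("f0", "dup") else "other") for c in X.columns}
        per_feature, per_category = lofo_importance(
            X, y, task="regression", seed=0, k=5,
            params=LSBoostParams(M=20), categories=cats,
        )
        table = per_feature.set_index("feature")["importance"]
        fold_sd = np.std(
            cross_validate(X, y, k=5, task="regression", seed=0,
                           params=LSBoostParams(M=20)).fold_metrics
        )
        assert abs(table["dead"]) <= fold_sd
        # a duplicated informative feature is individually expendable
        assert abs(table["dup"]) <= fold_sd + 0.05
        assert per_category["importance"].sum() == pytest.approx(
            per_feature["importance"].sum()
        )


class TestMergePhaseLabels:
    def test_interphase_merge(self):
        labs = merge_phase_labels(["G1", "S", "G2", "prophase", "telophase"])
        assert list(labs) == ["interphase", "interphase", "interphase", "prophase", "telophase"]

    def test_post_prophase_merge(self):
        labs = merge_phase_labels(
            ["metaphase", "anaphase", "telophase", "prophase", "G1"],
            merge_post_prophase=True,
        )
        assert list(labs) == ["others", "others", "others", "prophase", "interphase"]
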