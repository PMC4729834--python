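"""Boosted ensembles for label-free cell-cycle prediction.

Two learners cover the two prediction tasks:

* **Least-squares boosting** (:func:`fit_lsboost`) regresses continuous DNA
  content (integrated nuclear-stain intensity) on the morphological
  profile. It is stagewise gradient boosting with squared-error loss,
  shallow regression trees and shrinkage; scikit-learn's
  ``GradientBoostingRegressor`` provides the stagewise machinery.
* **Random-undersampling boosting** (:func:`fit_rusboost`) classifies the
  mitotic phase. Mitotic classes are rare (a few percent of cells), so at
  every boosting stage each majority class is randomly undersampled to a
  multiple of the minority class size before the weak classifier is fit;
  stage weights still come from the weighted error on the *full* training
  set, so the ensemble stays an AdaBoost (SAMME) ensemble and reduces to
  plain AdaBoost when undersampling is disabled.

The number of boosting stages is chosen by five-fold internal
cross-validation on the training split only (:func:`internal_cv_stopping`),
which guards against overfitting without ever touching the outer test
fold. Evaluation is 10-fold cross-validation (:func:`cross_validate`) with
per-fold Pearson r (regression) or per-class true-positive rates
(classification), and :func:`lofo_importance` scores features by the drop
in cross-validated performance when a single feature is left out.

Weak-learner depth, shrinkage, stage budget and the undersampling ratio
are conventional defaults and fully configurable; nothing downstream
depends on their exact values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LSBoostParams",
    "RUSBoostParams",
    "LSBoostModel",
    "RUSBoostModel",
    "CVReport",
    "fit_lsboost",
    "fit_rusboost",
    "internal_cv_stopping",
    "predict",
    "cross_validate",
    "lofo_importance",
    "save_model",
    "load_model",
    "merge_phase_labels",
]

INTERPHASE_LABEL = "interphase"
POST_PROPHASE_LABEL = "others"


def merge_phase_labels(
    labels: Sequence[str],
    merge_interphase: bool = True,
    merge_post_prophase: bool = False,
) -> np.ndarray:
    """Map raw phase labels onto classifier classes.

    ``merge_interphase`` folds G1/S/G2 into a single ``interphase`` class
    (DNA content, not the classifier, resolves those). With
    ``merge_post_prophase``, metaphase/anaphase/telophase collapse into an
    ``others`` class — the grouping used when a mitotic block leaves too
    few cells in the late phases to score individually.
    """
    out = []
    for lab in labels:
        if merge_interphase and lab in ("G1", "S", "G2"):
            out.append(INTERPHASE_LABEL)
        elif merge_post_prophase and lab in ("metaphase", "anaphase", "telophase"):
            out.append(POST_PROPHASE_LABEL)
        else:
            out.append(lab)
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# parameters and models


@dataclass(frozen=True)
class LSBoostParams:
    """LS-boosting knobs: stage budget, shrinkage and weak-tree shape.

    ``max_features="sqrt"`` subsamples candidate features per split; with
    a wide, highly correlated profile this is the standard variance/speed
    trade-off and costs no measurable accuracy here.
    """

    M_max: int = 500
    nu: float = 0.1
    max_depth: int = 3
    min_leaf: int = 10
    max_features: Optional[Union[str, int, float]] = "sqrt"
    M: Optional[int] = None  # fixed stage count; None -> internal CV stopping
    stopping_k: int = 5


@dataclass(frozen=True)
class RUSBoostParams:
    """RUS-boosting knobs; ``undersample_ratio=None`` disables undersampling.

    ``M=None`` selects the stage count by five-fold internal
    cross-validation up to ``M_max``.
    """

    M: Optional[int] = 100
    M_max: int = 200
    max_depth: int = 4  # >= ceil(log2(#classes)) + margin: one weak tree
    # must be able to give every phase its own leaf
    min_leaf: int = 5
    max_features: Optional[Union[str, int, float]] = None
    undersample_ratio: Optional[float] = 1.0
    stopping_k: int = 5


def _as_matrix(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)


def _feature_names(X) -> Optional[List[str]]:
    return list(X.columns) if isinstance(X, pd.DataFrame) else None


def _check_features(model, X):
    names = _feature_names(X)
    if model.feature_names is not None and names is not None and names != model.feature_names:
        raise ValueError("feature columns do not match the model's training manifest")
    n = X.shape[1]
    if model.feature_names is not None and n != len(model.feature_names):
        raise ValueError(f"model expects {len(model.feature_names)} features, got {n}")


def _export_tree(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value.reshape(t.node_count, -1).tolist(),
    }


def _predict_tree_dict(d: dict, X: np.ndarray) -> np.ndarray:
    left = np.asarray(d["children_left"])
    right = np.asarray(d["children_right"])
    feat = np.asarray(d["feature"])
    thr = np.asarray(d["threshold"])
    value = np.asarray(d["value"])
    node = np.zeros(len(X), dtype=np.intp)
    while True:
        leaf = left[node] == -1
        if leaf.all():
            break
        go_left = X[np.arange(len(X)), np.where(leaf, 0, feat[node])] <= thr[node]
        nxt = np.where(go_left, left[node], right[node])
        node = np.where(leaf, node, nxt)
    return value[node]


@dataclass
class LSBoostModel:
    """Trained least-squares boosting ensemble for DNA-content regression."""

    estimator: Optional[GradientBoostingRegressor]
    baseline: float
    nu: float
    M: int
    params: LSBoostParams
    seed: int
    feature_names: Optional[List[str]]
    manifest_version: Optional[str]
    train_predictions: np.ndarray
    trees: Optional[List[dict]] = None  # set when deserialized from JSON

    def predict(self, X) -> np.ndarray:
        _check_features(self, X)
        Xm = _as_matrix(X)
        if self.estimator is not None:
            return self.estimator.predict(Xm)
        out = np.full(len(Xm), self.baseline)
        for d in self.trees:
            out += self.nu * _predict_tree_dict(d, Xm)[:, 0]
        return out


@dataclass
class RUSBoostModel:
    """Trained random-undersampling AdaBoost (SAMME) phase classifier."""

    estimators: List[DecisionTreeClassifier]
    alphas: List[float]
    classes: List[str]
    params: RUSBoostParams
    seed: int
    feature_names: Optional[List[str]]
    manifest_version: Optional[str]
    train_predictions: np.ndarray
    undersample_records: List[dict] = field(default_factory=list)
    trees: Optional[List[dict]] = None
    tree_classes: Optional[List[List[int]]] = None  # class indices per stage

    def decision_scores(self, X, n_stages: Optional[int] = None) -> np.ndarray:
        """Aggregated, alpha-weighted vote matrix (cells x classes)."""
        _check_features(self, X)
        Xm = _as_matrix(X)
        scores = np.zeros((len(Xm), len(self.classes)))
        stages = len(self.alphas) if n_stages is None else n_stages
        for m in range(stages):
            if self.estimators:
                pred = self.estimators[m].predict(Xm)
                idx = np.array([self.classes.index(p) for p in pred])
            else:
                leaf_vals = _predict_tree_dict(self.trees[m], Xm)
                local = np.argmax(leaf_vals, axis=1)
                idx = np.asarray(self.tree_classes[m])[local]
            scores[np.arange(len(Xm)), idx] += self.alphas[m]
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        # argmax ties resolve to the first class in the class list
        return np.asarray(self.classes, dtype=object)[scores.argmax(axis=1)]

    def staged_predictions(self, X):
        """Yield class predictions after each boosting stage."""
        _check_features(self, X)
        Xm = _as_matrix(X)
        scores = np.zeros((len(Xm), len(self.classes)))
        cls = np.asarray(self.classes, dtype=object)
        for m in range(len(self.alphas)):
            if self.estimators:
                pred = self.estimators[m].predict(Xm)
                idx = np.array([self.classes.index(p) for p in pred])
            else:
                leaf_vals = _predict_tree_dict(self.trees[m], Xm)
                idx = np.asarray(self.tree_classes[m])[np.argmax(leaf_vals, axis=1)]
            scores[np.arange(len(Xm)), idx] += self.alphas[m]
            yield cls[scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# fitting


def fit_lsboost(
    X,
    y,
    params: LSBoostParams = LSBoostParams(),
    seed: int = 0,
    manifest_version: Optional[str] = None,
) -> LSBoostModel:
    """Fit the LS-boosting regressor; stages via internal CV unless fixed."""
    y = np.asarray(y, dtype=float)
    Xm = _as_matrix(X)
    if len(Xm) < 20:
        raise ValueError("need at least 20 cells to fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if np.std(y) == 0:
        raise ValueError("target has zero variance")
    M = params.M if params.M is not None else internal_cv_stopping(
        X, y, params, k=params.stopping_k, task="regression", seed=seed
    )
    est = GradientBoostingRegressor(
        n_estimators=M,
        learning_rate=params.nu,
        max_depth=params.max_depth,
        min_samples_leaf=params.min_leaf,
        max_features=params.max_features,
        random_state=seed,
    )
    est.fit(Xm, y)
    return LSBoostModel(
        estimator=est,
        baseline=float(y.mean()),
        nu=params.nu,
        M=M,
        params=params,
        seed=seed,
        feature_names=_feature_names(X),
        manifest_version=manifest_version,
        train_predictions=est.predict(Xm),
    )


def fit_rusboost(
    X,
    labels,
    params: RUSBoostParams = RUSBoostParams(),
    seed: int = 0,
    manifest_version: Optional[str] = None,
) -> RUSBoostModel:
    """Fit the RUS-boosting classifier.

    Per stage: undersample every majority class to
    ``undersample_ratio x minority size`` (without replacement,
    weight-agnostic), fit a shallow tree on the undersampled set with the
    current boosting weights, then compute the SAMME stage weight from the
    weighted error on the *full* training set and reweight.
    """
    labels = np.asarray(labels, dtype=object)
    Xm = _as_matrix(X)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if params.M is None:
        m_star = internal_cv_stopping(
            X, labels, params, k=params.stopping_k, task="classification", seed=seed
        )
        params = replace(params, M=m_star)
    K = len(classes)
    n = len(Xm)
    y_idx = np.array([classes.index(l) for l in labels])
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB005)))
    w = np.full(n, 1.0 / n)
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    min_count = min(len(v) for v in class_idx.values())

    estimators, alphas, records = [], [], []
    n_failures = 0
    for m in range(params.M):
        if params.undersample_ratio is None:
            sel = np.arange(n)
        else:
            # uniform random undersampling of each majority class, freshly
            # drawn per stage; the boosting weights still enter through
            # the weak learner's sample_weight and the stage error
            target = max(1, int(round(params.undersample_ratio * min_count)))
            parts = []
            for c in classes:
                idx = class_idx[c]
                if len(idx) > target:
                    idx = rng.choice(idx, size=target, replace=False)
                parts.append(idx)
            sel = np.sort(np.concatenate(parts))
        # tiny undersampled sets (rare classes of a few cells) cannot
        # honour the nominal leaf size; shrink it rather than fail
        leaf = min(params.min_leaf, max(1, len(sel) // (2 * K)))
        tree = DecisionTreeClassifier(
            max_depth=params.max_depth,
            min_samples_leaf=leaf,
            max_features=params.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        sw = w[sel]
        tree.fit(Xm[sel], labels[sel], sample_weight=sw / sw.sum())
        pred = tree.predict(Xm)
        miss = pred != labels
        err = float((w * miss).sum() / w.sum())
        if err >= 1.0 - 1.0 / K:
            # stage failed the SAMME chance bound: discard it and redraw;
            # give up only if failures dominate the stage budget
            n_failures += 1
            if n_failures >= max(10, params.M // 2) and not estimators:
                raise ValueError("weak learners no better than chance")
            continue
        err = max(err, 1e-10)
        alpha = float(np.log((1.0 - err) / err) + np.log(K - 1))
        estimators.append(tree)
        alphas.append(alpha)
        records.append({"stage": m, "n_kept": int(len(sel))})
        w = w * np.exp(alpha * miss)
        w = w / w.sum()
        if err <= 1e-10:
            break

    model = RUSBoostModel(
        estimators=estimators,
        alphas=alphas,
        classes=classes,
        params=params,
        seed=seed,
        feature_names=_feature_names(X),
        manifest_version=manifest_version,
        train_predictions=np.empty(0, dtype=object),
        undersample_records=records,
    )
    model.train_predictions = model.predict(X)
    return model


def internal_cv_stopping(
    X,
    target_or_labels,
    params,
    k: int = 5,
    task: str = "regression",
    seed: int = 0,
) -> int:
    """Pick the boosting stage count by k-fold CV on the training split.

    The selected ``M*`` minimises the mean validation loss over stages
    (squared error for regression, misclassification rate for
    classification); ties break to the smallest stage count. The routine
    only ever sees the split it is given, never the outer test fold.
    """
    Xm = _as_matrix(X)
    y = np.asarray(target_or_labels)
    if task == "regression":
        M_max = params.M_max
        losses = np.zeros(M_max)
        folds = KFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, va in folds.split(Xm):
            est = GradientBoostingRegressor(
                n_estimators=M_max,
                learning_rate=params.nu,
                max_depth=params.max_depth,
                min_samples_leaf=params.min_leaf,
                max_features=params.max_features,
                random_state=seed,
            )
            est.fit(Xm[tr], y[tr].astype(float))
            for m, pred in enumerate(est.staged_predict(Xm[va])):
                losses[m] += float(np.mean((pred - y[va].astype(float)) ** 2))
    elif task == "classification":
        M_max = params.M_max
        losses = np.zeros(M_max)
        folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for tr, va in folds.split(Xm, y):
            sub = fit_rusboost(Xm[tr], y[tr], replace(params, M=M_max), seed=seed)
            fold_loss = np.empty(M_max)
            m = -1
            for m, pred in enumerate(sub.staged_predictions(Xm[va])):
                fold_loss[m] = float(np.mean(pred != y[va]))
            if m < 0:
                continue
            fold_loss[m + 1 :] = fold_loss[m]  # early stop: carry last loss forward
            losses += fold_loss
    else:
        raise ValueError(f"unknown task {task!r}")
    losses /= k
    return int(np.argmin(losses)) + 1


def predict(model, X):
    """Predict with a trained model (continuous values or class labels)."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class CVReport:
    """Cross-validation report: per-fold metrics, their mean and s.d."""

    task: str
    k: int
    metric_name: str
    fold_metrics: Union[List[float], pd.DataFrame]
    mean: Union[float, Dict[str, float]]
    sd: Union[float, Dict[str, float]]
    confusion: Optional[pd.DataFrame]
    predictions: pd.Series
    fold_of: pd.Series

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "k": self.k,
            "metric": self.metric_name,
            "mean": self.mean,
            "sd": self.sd,
        }
        if isinstance(self.fold_metrics, pd.DataFrame):
            payload["fold_metrics"] = json.loads(self.fold_metrics.to_json())
        else:
            payload["fold_metrics"] = self.fold_metrics
        if self.confusion is not None:
            payload["confusion"] = json.loads(self.confusion.to_json())
        return json.dumps(payload, indent=1, sort_keys=True)


def _regression_strata(y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    return pd.qcut(y, q=min(n_bins, len(np.unique(y))), labels=False, duplicates="drop")


def cross_validate(
    X,
    truth,
    k: int = 10,
    task: str = "regression",
    seed: int = 0,
    params=None,
) -> CVReport:
    """Stratified k-fold cross-validation of either prediction task.

    Folds are stratified by label (classification) or by target decile
    (regression); every cell lands in exactly one test fold. Regression
    reports per-fold Pearson r between predicted and true DNA intensity;
    classification reports per-class true-positive rates
    (diag(confusion)/row sums). A class absent from some fold's test set
    yields a missing fold value for that class, excluded from the mean
    with a warning.
    """
    y = np.asarray(truth)
    n = len(y)
    if n < k:
        raise ValueError("need at least k cells")
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    Xm = _as_matrix(X)
    names = _feature_names(X)

    if task == "regression":
        if params is None:
            params = LSBoostParams()
        if n // k < 2:
            raise ValueError("regression folds need >= 2 cells (Pearson r undefined otherwise)")
        strata = _regression_strata(y.astype(float))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(Xm, strata)
    elif task == "classification":
        if params is None:
            params = RUSBoostParams()
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(Xm, y)
    else:
        raise ValueError(f"unknown task {task!r}")

    preds = pd.Series(index=index, dtype=object if task == "classification" else float)
    fold_of = pd.Series(index=index, dtype=int)
    fold_r: List[float] = []
    fold_tpr_rows = []
    classes = sorted(set(y)) if task == "classification" else None
    confusion = (
        pd.DataFrame(0, index=classes, columns=classes) if task == "classification" else None
    )

    for fold, (tr, te) in enumerate(split):
        Xtr = X.iloc[tr] if isinstance(X, pd.DataFrame) else Xm[tr]
        Xte = X.iloc[te] if isinstance(X, pd.DataFrame) else Xm[te]
        if task == "regression":
            model = fit_lsboost(Xtr, y[tr].astype(float), params, seed=seed + fold)
            p = model.predict(Xte)
            fold_r.append(float(stats.pearsonr(p, y[te].astype(float))[0]))
            preds.iloc[te] = p
        else:
            model = fit_rusboost(Xtr, y[tr], params, seed=seed + fold)
            p = model.predict(Xte)
            preds.iloc[te] = p
            row = {}
            for ci, c in enumerate(classes):
                sel = y[te] == c
                if sel.sum() == 0:
                    row[c] = np.nan
                else:
                    row[c] = float(np.mean(p[sel] == c))
                for cj, c2 in enumerate(classes):
                    confusion.loc[c, c2] += int(np.sum(p[sel] == c2))
            fold_tpr_rows.append(row)
        fold_of.iloc[te] = fold

    if task == "regression":
        return CVReport(
            task=task,
            k=k,
            metric_name="pearson_r",
            fold_metrics=fold_r,
            mean=float(np.mean(fold_r)),
            sd=float(np.std(fold_r, ddof=1)),
            confusion=None,
            predictions=preds,
            fold_of=fold_of,
        )
    tpr = pd.DataFrame(fold_tpr_rows)
    if tpr.isna().any().any():
        missing = list(tpr.columns[tpr.isna().any()])
        warnings.warn(
            f"classes {missing} absent from some test folds; "
            "their fold TPRs are excluded from the mean"
        )
    return CVReport(
        task=task,
        k=k,
        metric_name="per_class_tpr",
        fold_metrics=tpr,
        mean={c: float(tpr[c].mean()) for c in tpr.columns},
        sd={c: float(tpr[c].std(ddof=1)) for c in tpr.columns},
        confusion=confusion,
        predictions=preds,
        fold_of=fold_of,
    )


def lofo_importance(
    X: pd.DataFrame,
    truth,
    task: str = "regression",
    seed: int = 0,
    k: int = 10,
    params=None,
    categories: Optional[Dict[str, str]] = None,
    baseline: Optional[CVReport] = None,
):
    """Leave-one-feature-out importance.

    For each feature, cross-validation is re-run on the table without that
    column; the importance is the drop in the mean metric (Pearson r, or
    macro-averaged TPR for classification) relative to the baseline. With
    many correlated features individual importances are expectedly small —
    dropping one column rarely removes information the rest cannot supply.

    Returns ``(per_feature, per_category)`` DataFrames, both sorted by
    descending importance; category roll-ups sum their members.
    """
    if baseline is None:
        baseline = cross_validate(X, truth, k=k, task=task, seed=seed, params=params)

    def _scalar(report: CVReport) -> float:
        if task == "regression":
            return report.mean
        return float(np.mean(list(report.mean.values())))

    base = _scalar(baseline)
    rows = []
    for col in X.columns:
        rep = cross_validate(X.drop(columns=[col]), truth, k=k, task=task, seed=seed, params=params)
        rows.append(
            {
                "feature": col,
                "category": (categories or {}).get(col, "uncategorized"),
                "importance": base - _scalar(rep),
            }
        )
    per_feature = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    per_feature = per_feature.reset_index(drop=True)
    per_category = (
        per_feature.groupby("category", as_index=False)["importance"]
        .sum()
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return per_feature, per_category


# ---------------------------------------------------------------------------
# serialization (versioned JSON; trees stored as node arrays)


def save_model(model, path) -> None:
    path = Path(path)
    if isinstance(model, LSBoostModel):
        trees = model.trees or [_export_tree(t[0]) for t in model.estimator.estimators_]
        payload = {
            "kind": "lsboost",
            "format_version": 1,
            "baseline": model.baseline,
            "nu": model.nu,
            "M": model.M,
            "seed": model.seed,
            "feature_names": model.feature_names,
            "manifest_version": model.manifest_version,
            "train_predictions": model.train_predictions.tolist(),
            "trees": trees,
        }
    elif isinstance(model, RUSBoostModel):
        if model.trees is not None:
            trees, tree_classes = model.trees, model.tree_classes
        else:
            trees = [_export_tree(t) for t in model.estimators]
            tree_classes = [
                [model.classes.index(c) for c in t.classes_] for t in model.estimators
            ]
        payload = {
            "kind": "rusboost",
            "format_version": 1,
            "alphas": model.alphas,
            "classes": model.classes,
            "seed": model.seed,
            "feature_names": model.feature_names,
            "manifest_version": model.manifest_version,
            "train_predictions": list(model.train_predictions),
            "undersample_records": model.undersample_records,
            "trees": trees,
            "tree_classes": tree_classes,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    path.write_text(json.dumps(payload))


def load_model(path):
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "lsboost":
        return LSBoostModel(
            estimator=None,
            baseline=payload["baseline"],
            nu=payload["nu"],
            M=payload["M"],
            params=LSBoostParams(M=payload["M"], nu=payload["nu"]),
            seed=payload["seed"],
            feature_names=payload["feature_names"],
            manifest_version=payload["manifest_version"],
            train_predictions=np.asarray(payload["train_predictions"]),
            trees=payload["trees"],
        )
    if payload["kind"] == "rusboost":
        return RUSBoostModel(
            estimators=[],
            alphas=payload["alphas"],
            classes=payload["classes"],
            params=RUSBoostParams(M=len(payload["alphas"])),
            seed=payload["seed"],
            feature_names=payload["feature_names"],
            manifest_version=payload["manifest_version"],
            train_predictions=np.asarray(payload["train_predictions"], dtype=object),
            undersample_records=payload["undersample_records"],
            trees=payload["trees"],
            tree_classes=payload["tree_classes"],
        )
    raise ValueError(f"unknown model kind {payload['kind']!r}")
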