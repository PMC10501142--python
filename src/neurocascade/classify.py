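"""Hierarchical two-stage classification and the nested CV harness.

Multi-class identification of AD / MCI / HC is decomposed into two binary
problems: stage 1 separates patients (AD together with MCI) from controls; stage 2
separates AD from MCI among the patients stage 1 passes through.  Each
stage runs its own feature selection and hyperparameter search on its own
training rows.  Generalisation is estimated by nested stratified 10-fold
cross-validation: the outer folds hold out test subjects, the inner folds
(training rows only) drive selection and tuning, and a row guard turns any
test-row access during training into a hard error.

The RBF-SVM hyperparameter grid is C, gamma in {2^p : p = -8, -7.5, ..., 8}
(33 values each).  The ANN variants reuse the same cascade structure (or a
direct 3-class network) with the hidden-layer width tuned on 2..20 nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._guard import LeakageError, RowGuard
from .ann import AnnClassifier, select_hidden_nodes
from .roi import FeatureTable
from .selection import mrmr_rank, pca_reduce, sfc_search

__all__ = [
    "SvmHyperParams",
    "StageModel",
    "CascadeModel",
    "ClassificationReport",
    "train_rbf_svm",
    "train_cascade",
    "predict_cascade",
    "nested_cv",
    "LeakageError",
]

PATIENT = "PAT"
CONTROL = "HC"


def _pow2_grid(lo: float = -8.0, hi: float = 8.0, step: float = 0.5) -> np.ndarray:
    return 2.0 ** np.arange(lo, hi + step / 2, step)


@dataclass
class SvmHyperParams:
    """Log-spaced C/gamma grids (33 points each by default) and the kernel."""

    C_grid: np.ndarray = field(default_factory=_pow2_grid)
    gamma_grid: np.ndarray = field(default_factory=_pow2_grid)
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        self.C_grid = np.sort(np.asarray(self.C_grid, dtype=float))
        self.gamma_grid = np.sort(np.asarray(self.gamma_grid, dtype=float))
        if (self.C_grid <= 0).any() or (self.gamma_grid <= 0).any():
            raise ValueError("grids must be positive")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")

    @classmethod
    def reduced(cls, kernel: str = "rbf") -> "SvmHyperParams":
        """Coarse 5×5 grid for small-sample experiments."""
        g = 2.0 ** np.arange(-6.0, 7.0, 3.0)
        return cls(C_grid=g, gamma_grid=g, kernel=kernel)


def _inner_folds(y: np.ndarray, n_inner: int, seed: int) -> list:
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    k = max(2, min(n_inner, int(counts.min())))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def train_rbf_svm(
    X: np.ndarray,
    y: np.ndarray,
    params: SvmHyperParams | None = None,
    n_inner: int = 10,
    seed: int = 0,
):
    """Grid-search an SVM by inner stratified CV accuracy and refit.

    All (C, gamma) pairs are scored; ties resolve to the smaller C, then
    the smaller gamma (strict-improvement scan in ascending grid order).
    Features are z-scored with training statistics inside every split.
    Returns ``(fitted_svc, scaler, C, gamma, inner_accuracy_percent)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    params = params or SvmHyperParams()
    splits = _inner_folds(y, n_inner, seed)

    gammas = params.gamma_grid if params.kernel == "rbf" else np.array([1.0])
    best = (-1.0, None, None)
    for C in params.C_grid:
        for gamma in gammas:
            correct = 0
            for tr, te in splits:
                sc = StandardScaler().fit(X[tr])
                clf = SVC(C=C, gamma=gamma, kernel=params.kernel)
                clf.fit(sc.transform(X[tr]), y[tr])
                correct += int(np.sum(clf.predict(sc.transform(X[te])) == y[te]))
            acc = 100.0 * correct / len(y)
            if acc > best[0]:
                best = (acc, C, gamma)
    acc, C, gamma = best
    scaler = StandardScaler().fit(X)
    model = SVC(C=C, gamma=gamma, kernel=params.kernel)
    model.fit(scaler.transform(X), y)
    return model, scaler, float(C), float(gamma), float(acc)


def _svm_subset_evaluator(
    X: np.ndarray, y: np.ndarray, n_inner: int, seed: int
):
    """SFC evaluator: inner-CV accuracy of a fixed-hyperparameter RBF-SVM.

    The search uses C=1 and gamma=1/n_features ('scale' heuristic on
    z-scored data); the full grid search is run once on the winning subset.
    """
    splits = _inner_folds(y, n_inner, seed)

    def evaluate(columns: tuple[int, ...]) -> float:
        Xs = X[:, list(columns)]
        correct = 0
        for tr, te in splits:
            sc = StandardScaler().fit(Xs[tr])
            clf = SVC(C=1.0, gamma=1.0 / len(columns), kernel="rbf")
            clf.fit(sc.transform(Xs[tr]), y[tr])
            correct += int(np.sum(clf.predict(sc.transform(Xs[te])) == y[te]))
        return 100.0 * correct / len(y)

    return evaluate


def select_stage_features(
    X: np.ndarray,
    y: np.ndarray,
    selector: str = "mrmr-sfc",
    top_m: int = 50,
    n_inner: int = 10,
    seed: int = 0,
    cvcr: float = 0.80,
):
    """Stage-level feature selection on training rows only.

    Returns ``(columns, pca, info)``: explicit column indices for
    'mrmr-sfc'/'none', or a fitted PCA projection for 'pca'.
    """
    p = X.shape[1]
    if selector == "none":
        return list(range(p)), None, {}
    if selector == "mrmr-sfc":
        m = min(top_m, p)
        ranked = mrmr_rank(X, y, top_m=m)
        if m < 2:
            return list(ranked.order), None, {"sfc": None}
        res = sfc_search(ranked, _svm_subset_evaluator(X, y, n_inner, seed))
        return list(res.columns), None, {"sfc": res}
    if selector == "pca":
        _, _, n_comp = pca_reduce(X, cvcr)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=n_comp).fit(X)
        return None, pca, {"n_components": n_comp}
    raise ValueError(f"unknown selector {selector!r}")


@dataclass
class StageModel:
    """One fitted binary stage: projection + scaler + classifier + tuning info."""

    classifier: object
    scaler: StandardScaler
    columns: list[int] | None
    pca: object | None
    chosen: dict

    def _project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.pca is not None:
            return self.pca.transform(X)
        missing = [c for c in self.columns if c >= X.shape[1]]
        if missing:
            raise ValueError(f"input lacks selected feature columns {missing}")
        return X[:, self.columns]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(self._project(X))
        return self.classifier.predict(Z)

    def decision_scores(self, X: np.ndarray, positive: str) -> np.ndarray:
        """Scalar score per row, oriented so larger favours ``positive``."""
        Z = self.scaler.transform(self._project(X))
        clf = self.classifier
        classes = list(clf.classes_)
        if isinstance(clf, SVC):
            s = clf.decision_function(Z)
            return s if classes[1] == positive else -s
        out = clf.decision_function(Z) if hasattr(clf, "decision_function") else None
        if out is None or out.ndim == 1:
            raise TypeError("classifier does not expose 2-column scores")
        i_pos = classes.index(positive)
        i_neg = 1 - i_pos
        return out[:, i_pos] - out[:, i_neg]


@dataclass
class CascadeModel:
    """Stage-1 (patients vs HC) and stage-2 (AD vs MCI) fitted models."""

    stage1: StageModel
    stage2: StageModel
    stage2_fallback_used: bool = False


def _fit_stage(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str,
    selector: str,
    params: SvmHyperParams | None,
    top_m: int,
    n_inner: int,
    seed: int,
    ann_nodes: Sequence[int],
    cvcr: float,
) -> StageModel:
    cols, pca, info = select_stage_features(
        X, y, selector=selector, top_m=top_m, n_inner=n_inner, seed=seed, cvcr=cvcr
    )
    Xs = pca.transform(X) if pca is not None else X[:, cols]
    if classifier == "svm":
        model, scaler, C, gamma, acc = train_rbf_svm(
            Xs, y, params=params, n_inner=n_inner, seed=seed
        )
        chosen = {"C": C, "gamma": gamma, "inner_acc": acc}
    elif classifier == "ann":
        w, acc = select_hidden_nodes(
            StandardScaler().fit(Xs).transform(Xs),
            y,
            node_range=list(ann_nodes),
            n_folds=n_inner,
            seed=seed,
        )
        scaler = StandardScaler().fit(Xs)
        model = AnnClassifier(hidden_nodes=w, seed=seed).fit(scaler.transform(Xs), y)
        chosen = {"hidden_nodes": w, "inner_acc": acc}
    else:
        raise ValueError(f"unknown stage classifier {classifier!r}")
    if info.get("sfc") is not None:
        chosen["sfc_accuracy"] = info["sfc"].cv_accuracy
    return StageModel(classifier=model, scaler=scaler, columns=cols, pca=pca, chosen=chosen)


def train_cascade(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    selector: str = "mrmr-sfc",
    params: SvmHyperParams | None = None,
    top_m: int = 50,
    n_inner: int = 10,
    seed: int = 0,
    stage2_on_correct: bool = True,
    ann_nodes: Sequence[int] = range(2, 21),
    cvcr: float = 0.80,
) -> CascadeModel:
    """Train the two-stage cascade on training rows.

    Stage 2 is trained on the patients stage 1 classifies correctly on its
    own training data (the study's literal procedure); if that filtering
    removes a class entirely, training falls back to all patients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = set(np.unique(y))
    if not {"AD", "MCI", "HC"} <= classes:
        raise ValueError("all three classes (AD, MCI, HC) must be present")

    y1 = np.where(y == "HC", CONTROL, PATIENT)
    stage1 = _fit_stage(
        X, y1, classifier, selector, params, top_m, n_inner, seed, ann_nodes, cvcr
    )

    is_patient = y != "HC"
    if stage2_on_correct:
        s1_train_pred = stage1.predict(X)
        keep = is_patient & (s1_train_pred == PATIENT)
    else:
        keep = is_patient
    fallback = False
    if len(np.unique(y[keep])) < 2:
        keep = is_patient  # a class was lost entirely: fall back, flagged
        fallback = True
    stage2 = _fit_stage(
        X[keep], y[keep], classifier, selector, params, top_m, n_inner, seed + 1,
        ann_nodes, cvcr,
    )
    return CascadeModel(stage1=stage1, stage2=stage2, stage2_fallback_used=fallback)


def predict_cascade(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Two sequential binary decisions -> one 3-class label per row.

    A true patient that stage 1 sends to HC keeps the HC label (it counts
    against its own class in the confusion matrix).
    """
    X = np.asarray(X, dtype=float)
    s1 = model.stage1.predict(X)
    out = np.array(["HC"] * X.shape[0], dtype=object)
    pat = s1 == PATIENT
    if pat.any():
        out[pat] = model.stage2.predict(X[pat])
    return out.astype(str)


@dataclass
class ClassificationReport:
    """Fold-wise predictions plus the aggregate headline numbers
    (overall and per-class accuracy, stage AUCs, feature counts)."""

    confusion: pd.DataFrame
    overall_acc: float
    per_class_acc: dict[str, float]
    auc_stage1: float | None
    auc_stage2: dict[str, float | None]
    stage2_acc: dict[str, float | None]
    per_fold_features: list[dict[str, list]]
    n_features_per_fold: list[int]
    predictions: pd.DataFrame
    method: str
    seed: int

    def recompute_accuracy(self) -> tuple[float, dict[str, float]]:
        """Re-derive the headline numbers from the confusion matrix
        (accounting identity used by the tests)."""
        cm = self.confusion.to_numpy(dtype=float)
        overall = 100.0 * np.trace(cm) / cm.sum()
        per_class = {
            cls: 100.0 * cm[i, i] / cm[i].sum()
            for i, cls in enumerate(self.confusion.index)
        }
        return overall, per_class


def _column_keys(table: FeatureTable | None, cols: list[int] | None):
    if cols is None:
        return ["<pca>"]
    if table is None:
        return list(cols)
    keys = table.column_keys()
    return [keys[c] for c in cols]


def nested_cv(
    table: FeatureTable,
    method: str = "svm-cascade",
    selector: str = "mrmr-sfc",
    params: SvmHyperParams | None = None,
    n_outer: int = 10,
    n_inner: int = 10,
    top_m: int = 50,
    seed: int = 0,
    stage2_on_correct: bool = True,
    ann_nodes: Sequence[int] = range(2, 21),
    cvcr: float = 0.80,
) -> ClassificationReport:
    """Nested stratified cross-validation of one classification method.

    ``method`` is one of 'svm-cascade', 'ann-cascade', 'ann-direct',
    'bayes', 'forest'.  Feature selection and all tuning see training rows
    only (enforced by the row guard); outer-test predictions are pooled
    into the final confusion matrix, per-class rates and stage AUCs.
    """
    X = table.X
    y = table.y.astype(str)
    classes = ["AD", "MCI", "HC"]
    skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)

    rows = []
    fold_features: list[dict[str, list]] = []
    n_feats: list[int] = []
    s1_scores, s1_truth = [], []
    s2_scores_pred, s2_truth_pred = [], []
    s2_scores_all, s2_truth_all = [], []
    s2_correct_pred, s2_correct_all = [], []

    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        guard = RowGuard(X, y, forbidden=test_idx)
        Xtr, ytr = guard.take(train_idx)
        fold_seed = seed * 1009 + fold * 13 + 1  # deterministic, < 2**31
        if method in ("svm-cascade", "ann-cascade"):
            model = train_cascade(
                Xtr,
                ytr,
                classifier="svm" if method == "svm-cascade" else "ann",
                selector=selector,
                params=params,
                top_m=top_m,
                n_inner=n_inner,
                seed=fold_seed,
                stage2_on_correct=stage2_on_correct,
                ann_nodes=ann_nodes,
                cvcr=cvcr,
            )
            Xte, yte = guard.test_rows()
            pred = predict_cascade(model, Xte)

            s1_scores.append(model.stage1.decision_scores(Xte, positive=PATIENT))
            s1_truth.append(yte != "HC")
            s1_pred = model.stage1.predict(Xte)
            true_pat = yte != "HC"
            passed = true_pat & (s1_pred == PATIENT)
            if passed.any():
                s2_scores_pred.append(
                    model.stage2.decision_scores(Xte[passed], positive="MCI")
                )
                s2_truth_pred.append(yte[passed] == "MCI")
                s2_correct_pred.append(model.stage2.predict(Xte[passed]) == yte[passed])
            if true_pat.any():
                s2_scores_all.append(
                    model.stage2.decision_scores(Xte[true_pat], positive="MCI")
                )
                s2_truth_all.append(yte[true_pat] == "MCI")
                s2_correct_all.append(pred[true_pat] == yte[true_pat])

            feats = {
                "stage1": _column_keys(table, model.stage1.columns),
                "stage2": _column_keys(table, model.stage2.columns),
            }
            union = set(map(tuple, feats["stage1"])) | set(map(tuple, feats["stage2"])) \
                if model.stage1.columns is not None else set()
            n_feats.append(len(union) if union else 0)
        else:
            cols, pca, _ = select_stage_features(
                Xtr, ytr, selector=selector, top_m=top_m, n_inner=n_inner,
                seed=fold_seed, cvcr=cvcr,
            )
            Xs = pca.transform(Xtr) if pca is not None else Xtr[:, cols]
            scaler = StandardScaler().fit(Xs)
            Zs = scaler.transform(Xs)
            if method == "ann-direct":
                w, _ = select_hidden_nodes(
                    Zs, ytr, node_range=list(ann_nodes), n_folds=n_inner, seed=fold_seed
                )
                clf = AnnClassifier(hidden_nodes=w, seed=fold_seed).fit(Zs, ytr)
            elif method == "bayes":
                clf = GaussianNB().fit(Zs, ytr)
            elif method == "forest":
                clf = RandomForestClassifier(
                    n_estimators=200, random_state=fold_seed
                ).fit(Zs, ytr)
            else:
                raise ValueError(f"unknown method {method!r}")
            Xte, yte = guard.test_rows()
            Zte = scaler.transform(pca.transform(Xte) if pca is not None else Xte[:, cols])
            pred = clf.predict(Zte)
            feats = {"direct": _column_keys(table, cols)}
            n_feats.append(len(cols) if cols is not None else 0)

        fold_features.append(feats)
        _, yte = guard.test_rows()
        for sid, t, p in zip(table.values.index[sorted(test_idx)], yte, pred):
            rows.append({"subject_id": sid, "fold": fold, "true": t, "pred": p})

    pred_df = pd.DataFrame(rows).set_index("subject_id")
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for _, r in pred_df.iterrows():
        cm.loc[r["true"], r["pred"]] += 1
    overall = 100.0 * np.trace(cm.to_numpy()) / len(pred_df)
    per_class = {
        c: 100.0 * cm.loc[c, c] / cm.loc[c].sum() for c in classes
    }

    def _pooled_auc(scores, truth):
        if not scores:
            return None
        s = np.concatenate(scores)
        t = np.concatenate(truth)
        if len(np.unique(t)) < 2:
            return None
        return float(roc_auc_score(t, s))

    auc1 = _pooled_auc(s1_scores, s1_truth)
    auc2 = {
        "predicted_patients": _pooled_auc(s2_scores_pred, s2_truth_pred),
        "all_patients": _pooled_auc(s2_scores_all, s2_truth_all),
    }
    s2acc = {
        "predicted_patients": (
            100.0 * float(np.mean(np.concatenate(s2_correct_pred)))
            if s2_correct_pred
            else None
        ),
        "all_patients": (
            100.0 * float(np.mean(np.concatenate(s2_correct_all)))
            if s2_correct_all
            else None
        ),
    }

    return ClassificationReport(
        confusion=cm,
        overall_acc=float(overall),
        per_class_acc=per_class,
        auc_stage1=auc1,
        auc_stage2=auc2,
        stage2_acc=s2acc,
        per_fold_features=fold_features,
        n_features_per_fold=n_feats,
        predictions=pred_df,
        method=method,
        seed=seed,
    )
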