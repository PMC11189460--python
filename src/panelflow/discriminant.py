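"""Biomarker panel discovery and sample classification.

The workflow standardizes protein values (z-score per protein, missing
values imputed by the training median), splits samples 70/30 stratified by
class, and on the training 70% runs a linear soft-margin SVM with
cross-validated recursive feature elimination (stratified 5-fold) to pick
the most discriminating protein subset.  The refit panel model is
evaluated on the held-out 30% with ROC and precision–recall curves, and on
the whole cohort by repeated stratified cross-validation (6 splits × 40
repetitions).  Significance of a model specification is assessed by label
permutation of its cross-validated score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import RFE, RFECV
from sklearn.metrics import (
    auc,
    balanced_accuracy_score,
    f1_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_curve,
)
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.svm import LinearSVC

from .qc import FeatureTable

__all__ = [
    "zscore_impute",
    "PanelDiscriminantModel",
    "PanelDiscriminantResults",
    "train_svm_rfe",
    "roc_pr_curves",
    "repeated_cv_metrics",
    "CvMetrics",
    "permutation_test_svm",
    "pca_scores",
]


def _make_svc() -> LinearSVC:
    # soft-margin linear SVM, C = 1, squared hinge — library defaults
    return LinearSVC(C=1.0, loss="squared_hinge", dual=False, max_iter=5000)


def zscore_impute(
    values: pd.DataFrame, fit_rows: pd.Index | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-wise z-scoring with median imputation of missing values.

    Missing cells are replaced by the fit-row median *before* scaling; the
    mean and population SD are then computed on the (imputed) fit rows
    only, so test rows never leak into the scaler.  Constant proteins map
    to all zeros.  Returns (standardized matrix, scaler frame with
    median/mean/sd per protein).
    """
    if fit_rows is None:
        fit_rows = values.index
    fit = values.loc[fit_rows]
    all_missing = fit.isna().all()
    if all_missing.any():
        dropped = list(fit.columns[all_missing])
        import warnings

        warnings.warn(f"dropping proteins entirely missing in fit rows: {dropped}", stacklevel=2)
        values = values.drop(columns=dropped)
        fit = fit.drop(columns=dropped)
    median = fit.median()
    fit_imputed = fit.fillna(median)
    mean = fit_imputed.mean()
    sd = fit_imputed.std(ddof=0)
    sd_safe = sd.replace(0.0, 1.0)
    z = (values.fillna(median) - mean) / sd_safe
    z.loc[:, sd == 0] = 0.0
    scaler = pd.DataFrame({"median": median, "mean": mean, "sd": sd})
    return z, scaler


@dataclass
class CvMetrics:
    """Repeated-CV classification metrics, mean ± SD over repetitions."""

    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    balanced_accuracy: tuple[float, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["precision", "recall", "f1", "balanced_accuracy"],
                "mean": [self.precision[0], self.recall[0], self.f1[0], self.balanced_accuracy[0]],
                "sd": [self.precision[1], self.recall[1], self.f1[1], self.balanced_accuracy[1]],
            }
        )


class PanelDiscriminantModel:
    """Linear-SVM panel discovery model for a two-class cohort.

    Parameters
    ----------
    table : FeatureTable (or plain DataFrame of values) with samples as rows.
    labels : per-sample class labels (e.g. "HC"/"PD"), aligned with rows.
    classes : optional (negative, positive) ordering; default sorted.
    """

    def __init__(self, table: FeatureTable | pd.DataFrame, labels, classes=None,
                 test_fraction: float = 0.30, cv_folds: int = 5):
        self.values = table.values if isinstance(table, FeatureTable) else table
        labels = pd.Series(np.asarray(labels), index=self.values.index)
        found = np.unique(labels)
        if classes is None:
            classes = sorted(found)
        if len(classes) != 2 or set(found) - set(classes):
            raise ValueError(f"need exactly two classes, got {found.tolist()}")
        self.classes_ = list(classes)
        self.labels = labels
        self.test_fraction = test_fraction
        self.cv_folds = cv_folds
        counts = labels.value_counts()
        if (counts < cv_folds).any():
            raise ValueError(
                f"each class needs >= {cv_folds} members for stratified CV, got {counts.to_dict()}"
            )

    def fit(self, seed: int) -> "PanelDiscriminantResults":
        """70/30 stratified split, RFECV feature selection, refit, held-out eval.

        ``seed`` drives the split and the CV shuffling; it is a required
        explicit argument so the partition is always reproducible.
        """
        y = (self.labels == self.classes_[1]).astype(int)
        train_idx, test_idx = train_test_split(
            self.values.index,
            test_size=self.test_fraction,
            stratify=y,
            random_state=seed,
        )
        z, scaler = zscore_impute(self.values, fit_rows=train_idx)
        Xtr, ytr = z.loc[train_idx].to_numpy(), y.loc[train_idx].to_numpy()
        Xte, yte = z.loc[test_idx].to_numpy(), y.loc[test_idx].to_numpy()

        cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=seed)
        rfecv = RFECV(_make_svc(), step=1, cv=cv, scoring="accuracy", min_features_to_select=1)
        rfecv.fit(Xtr, ytr)
        selected = [p for p, keep in zip(z.columns, rfecv.support_) if keep]

        svc = _make_svc()
        svc.fit(Xtr[:, rfecv.support_], ytr)
        test_scores = svc.decision_function(Xte[:, rfecv.support_])
        test_pred = (test_scores > 0).astype(int)

        return PanelDiscriminantResults(
            model=self,
            selected_proteins=selected,
            weights=pd.Series(svc.coef_[0], index=selected),
            intercept=float(svc.intercept_[0]),
            scaler=scaler,
            split_seed=seed,
            train_index=pd.Index(train_idx),
            test_index=pd.Index(test_idx),
            test_scores=pd.Series(test_scores, index=test_idx),
            test_true=pd.Series(yte, index=test_idx),
            test_pred=pd.Series(test_pred, index=test_idx),
            cv_scores=pd.Series(
                rfecv.cv_results_["mean_test_score"],
                index=range(1, len(rfecv.cv_results_["mean_test_score"]) + 1),
            ),
        )


@dataclass
class PanelDiscriminantResults:
    """Fitted SVM panel: selected proteins, weights, held-out evaluation."""

    model: PanelDiscriminantModel
    selected_proteins: list[str]
    weights: pd.Series
    intercept: float
    scaler: pd.DataFrame
    split_seed: int
    train_index: pd.Index
    test_index: pd.Index
    test_scores: pd.Series
    test_true: pd.Series
    test_pred: pd.Series
    cv_scores: pd.Series = field(default_factory=pd.Series)

    @property
    def test_accuracy(self) -> float:
        return float((self.test_pred == self.test_true).mean())

    def decision_function(self, values: pd.DataFrame) -> pd.Series:
        """Signed distance to the separating hyperplane for new samples.

        Missing model proteins in a sample are imputed by the training
        medians; samples missing *all* model proteins are NaN (unpredictable).
        """
        sub = values.reindex(columns=self.selected_proteins)
        all_missing = sub.isna().all(axis=1)
        sc = self.scaler.loc[self.selected_proteins]
        z = (sub.fillna(sc["median"]) - sc["mean"]) / sc["sd"].replace(0.0, 1.0)
        scores = z.to_numpy() @ self.weights.to_numpy() + self.intercept
        out = pd.Series(scores, index=values.index)
        out[all_missing] = np.nan
        return out

    def predict(self, values: pd.DataFrame) -> pd.Series:
        """Class per sample by the sign of the decision value (never unclassified)."""
        scores = self.decision_function(values)
        neg, pos = self.model.classes_
        out = pd.Series(np.where(scores > 0, str(pos), str(neg)), index=values.index, dtype=object)
        out[scores.isna()] = "unpredictable"
        return out

    def roc_pr(self) -> dict:
        """Held-out-set ROC and PR curves for the combined panel."""
        return roc_pr_curves(self.test_scores.to_numpy(), self.test_true.to_numpy())

    def summary(self) -> str:
        roc = self.roc_pr()
        lines = [
            "Linear SVM panel (RFECV-selected)",
            "==================================",
            f"classes:           {self.model.classes_[0]} (neg) vs {self.model.classes_[1]} (pos)",
            f"train/test:        {len(self.train_index)}/{len(self.test_index)}"
            f" (split seed {self.split_seed})",
            f"selected proteins: {', '.join(self.selected_proteins)}",
            f"test accuracy:     {self.test_accuracy:.3f}",
            f"test ROC AUC:      {roc['roc_auc']:.3f}",
            f"test PR AUC:       {roc['pr_auc']:.3f}",
        ]
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": "svm_panel",
            "classes": [str(c) for c in self.model.classes_],
            "selected_proteins": self.selected_proteins,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "scaler": self.scaler.loc[self.selected_proteins].to_dict(orient="index"),
            "split_seed": self.split_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def train_svm_rfe(
    table: FeatureTable | pd.DataFrame, labels, seed: int, classes=None, **kw
) -> PanelDiscriminantResults:
    """Convenience wrapper: build and fit a :class:`PanelDiscriminantModel`."""
    return PanelDiscriminantModel(table, labels, classes=classes, **kw).fit(seed)


def rfe_fixed_k(values: pd.DataFrame, labels01: np.ndarray, k: int) -> list[str]:
    """RFE retaining exactly ``k`` features (|weight| ranking, step 1)."""
    z, _ = zscore_impute(values)
    rfe = RFE(_make_svc(), n_features_to_select=k, step=1)
    rfe.fit(z.to_numpy(), labels01)
    return [p for p, keep in zip(z.columns, rfe.support_) if keep]


def roc_pr_curves(scores, labels) -> dict:
    """ROC and precision–recall curves with trapezoid / step-wise AUCs.

    ``labels`` are 0/1; ties in scores are handled by simultaneous
    threshold inclusion (scikit-learn's sweep).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    pr_auc = float(-np.sum(np.diff(rec) * prec[:-1]))  # step-wise interpolation
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "roc_auc": float(auc(fpr, tpr)),
        "precision": prec,
        "recall": rec,
        "pr_thresholds": pr_thr,
        "pr_auc": pr_auc,
    }


def repeated_cv_metrics(
    table: FeatureTable | pd.DataFrame,
    labels,
    splits: int = 6,
    reps: int = 40,
    seed: int = 0,
    features: list[str] | None = None,
) -> CvMetrics:
    """Repeated stratified CV of the linear SVM: macro metrics, mean ± SD.

    ``splits``-fold stratified CV repeated ``reps`` times with distinct
    shuffles; the scaler/imputer are refit inside every training fold.
    Fold metrics are averaged per repetition, and mean ± SD are taken over
    the repetition means.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    if features is not None:
        values = values[features]
    y = pd.Series(np.asarray(labels), index=values.index)
    classes = sorted(np.unique(y))
    y01 = (y == classes[1]).astype(int).to_numpy()

    rskf = RepeatedStratifiedKFold(n_splits=splits, n_repeats=reps, random_state=seed)
    fold_rows = []
    for fold_id, (tr, te) in enumerate(rskf.split(values, y01)):
        z, _ = zscore_impute(values, fit_rows=values.index[tr])
        svc = _make_svc()
        svc.fit(z.iloc[tr].to_numpy(), y01[tr])
        pred = svc.predict(z.iloc[te].to_numpy())
        fold_rows.append(
            {
                "rep": fold_id // splits,
                "precision": precision_score(y01[te], pred, average="macro", zero_division=0),
                "recall": recall_score(y01[te], pred, average="macro", zero_division=0),
                "f1": f1_score(y01[te], pred, average="macro", zero_division=0),
                "balanced_accuracy": balanced_accuracy_score(y01[te], pred),
            }
        )
    df = pd.DataFrame(fold_rows)
    rep_means = df.groupby("rep").mean()

    def _ms(col: str) -> tuple[float, float]:
        return float(rep_means[col].mean()), float(rep_means[col].std(ddof=0))

    return CvMetrics(
        precision=_ms("precision"),
        recall=_ms("recall"),
        f1=_ms("f1"),
        balanced_accuracy=_ms("balanced_accuracy"),
    )


def permutation_test_svm(
    table: FeatureTable | pd.DataFrame,
    labels,
    B: int = 1000,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[float, float]:
    """Label-permutation p for the SVM's cross-validated accuracy.

    Returns (p, observed mean CV accuracy); p = (#{perm ≥ obs} + 1)/(B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    values = table.values if isinstance(table, FeatureTable) else table
    y = pd.Series(np.asarray(labels), index=values.index)
    classes = sorted(np.unique(y))
    y01 = (y == classes[1]).astype(int).to_numpy()
    z, _ = zscore_impute(values)
    X = z.to_numpy()
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    obs = float(cross_val_score(_make_svc(), X, y01, cv=cv, scoring="accuracy").mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(y01)
        score = float(cross_val_score(_make_svc(), X, perm, cv=cv, scoring="accuracy").mean())
        if score >= obs:
            count += 1
    return (count + 1) / (B + 1), obs


def pca_scores(
    table: FeatureTable | pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized PCA: per-sample scores and explained-variance fractions.

    Values are z-scored (median-imputed) before the decomposition;
    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    values = table.values if isinstance(table, FeatureTable) else table
    z, _ = zscore_impute(values)
    rank = min(z.shape[0] - 1, z.shape[1])
    if n_components > rank:
        import warnings

        warnings.warn(f"n_components truncated from {n_components} to rank {rank}", stacklevel=2)
        n_components = rank
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.to_numpy())
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=values.index, columns=cols), pca.explained_variance_ratio_
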