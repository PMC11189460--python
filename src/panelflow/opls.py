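"""Orthogonal projections to latent structures (OPLS / OPLS-DA).

OPLS splits the predictor variation into a single component correlated
with the response (the *predictive* component) and components that are
systematic but orthogonal to it.  For a two-class response coded 0/1 this
is OPLS-DA.  The implementation follows the classical NIPALS-style
orthogonal-projection scheme:

1. ``w ∝ Xᵀy`` (normalized) gives the predictive weight direction.
2. For each orthogonal component: take the loading ``p = Xᵀt/(tᵀt)`` of
   the current predictive score ``t = Xw``, strip its projection on ``w``
   to get ``w_orth``, form orthogonal scores/loadings, and deflate X.
3. Re-derive the predictive component from the deflated X.

Model quality is summarized by R²Y (explained response variance) and Q²
(7-fold cross-validated predictive ability, 1 − PRESS/SS).  Class
predictions leave a *no-class band*: a predicted response falling inside
a central interval (default [0.35, 0.65] on the 0/1 coding) is reported
as "unclassified", mirroring how SIMCA-style discriminant predictions
leave ambiguous samples without a class.

Significance is assessed by label permutation: the model is refit on
permuted responses B times and ``p = (#{Q²_perm ≥ Q²_obs} + 1)/(B + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OplsDa", "OplsDaResults", "fit_oplsda", "permutation_test_oplsda"]

DEFAULT_NOCLASS_BAND = (0.35, 0.65)


def _center_scale(X: np.ndarray, mean=None, scale=None):
    if mean is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """Fit OPLS on centered/scaled X and centered y.

    Returns dict of predictive weights/loadings/regression coefficient and
    orthogonal weight/loading matrices, plus score vectors.
    """
    Xd = X.copy()
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response is orthogonal to every predictor (degenerate)")
    w /= nw
    W_o, P_o = [], []
    for _ in range(n_ortho):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = (y @ t) / (t @ t)
    t_orth = np.column_stack([X @ wo for wo in W_o]) if W_o else np.empty((X.shape[0], 0))
    return {
        "w": w,
        "p": p,
        "c": float(c),
        "W_ortho": np.array(W_o).T if W_o else np.empty((X.shape[1], 0)),
        "P_ortho": np.array(P_o).T if P_o else np.empty((X.shape[1], 0)),
        "t_pred": t,
        "t_ortho": t_orth,
    }


def _predict_response(core: dict, Xcs: np.ndarray) -> np.ndarray:
    """Predicted centered response for centered/scaled X."""
    Xd = Xcs.copy()
    W_o, P_o = core["W_ortho"], core["P_ortho"]
    for j in range(W_o.shape[1]):
        t_o = Xd @ W_o[:, j]
        Xd = Xd - np.outer(t_o, P_o[:, j])
    return core["c"] * (Xd @ core["w"])


class OplsDa:
    """Two-class OPLS-DA model specification.

    Parameters
    ----------
    X : array-like or DataFrame, samples × features.
    y : array of two class labels (strings or numbers).
    n_ortho : number of orthogonal components, or "auto" to choose the
        count (0..max_ortho) maximizing 7-fold Q².
    """

    def __init__(self, X, y, n_ortho: int | str = "auto", max_ortho: int = 3,
                 noclass_band: tuple[float, float] = DEFAULT_NOCLASS_BAND):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"OPLS-DA needs exactly two classes, got {classes.tolist()}")
        self.classes_ = classes
        self.X = X
        self.y01 = (y == classes[1]).astype(float)
        if np.all(self.y01 == self.y01[0]):
            raise ValueError("constant response")
        self.n_ortho = n_ortho
        self.max_ortho = max_ortho
        self.noclass_band = tuple(noclass_band)
        min_n = 2 + (max_ortho if n_ortho == "auto" else int(n_ortho))
        if X.shape[0] <= min_n:
            raise ValueError(f"need more than {min_n} samples")

    # -- fitting ---------------------------------------------------------
    def fit(self, cv_folds: int = 7, seed: int = 0) -> "OplsDaResults":
        Xcs, mean, scale = _center_scale(self.X)
        yc = self.y01 - self.y01.mean()
        if self.n_ortho == "auto":
            q2s = {
                k: self._cv_q2(k, cv_folds, seed) for k in range(self.max_ortho + 1)
            }
            n_ortho = max(q2s, key=lambda k: q2s[k])
            q2 = q2s[n_ortho]
        else:
            n_ortho = int(self.n_ortho)
            q2 = self._cv_q2(n_ortho, cv_folds, seed)
        core = _opls_core(Xcs, yc, n_ortho)
        yhat = _predict_response(core, Xcs)
        ss = float(yc @ yc)
        r2y = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss
        return OplsDaResults(
            model=self, core=core, x_mean=mean, x_scale=scale,
            y_mean=float(self.y01.mean()), n_ortho=n_ortho,
            r2y=r2y, q2=q2,
        )

    def _cv_q2(self, n_ortho: int, folds: int, seed: int) -> float:
        """7-fold cross-validated Q² = 1 − PRESS/SS for a given n_ortho."""
        n = self.X.shape[0]
        folds = min(folds, n)
        rng = np.random.default_rng(seed)
        idx = rng.permutation(n)
        press = 0.0
        yc_all = self.y01 - self.y01.mean()
        ss = float(yc_all @ yc_all)
        for f in range(folds):
            test = idx[f::folds]
            train = np.setdiff1d(idx, test)
            if np.unique(self.y01[train]).size < 2:
                return -np.inf
            Xtr, mean, scale = _center_scale(self.X[train])
            ytr = self.y01[train] - self.y01[train].mean()
            try:
                core = _opls_core(Xtr, ytr, n_ortho)
            except ValueError:
                return -np.inf
            Xte = (self.X[test] - mean) / scale
            yhat = _predict_response(core, Xte) + self.y01[train].mean()
            press += float(np.sum((self.y01[test] - yhat) ** 2))
        return 1.0 - press / ss


@dataclass
class OplsDaResults:
    """Fitted OPLS-DA model: components, fit quality, prediction."""

    model: OplsDa
    core: dict
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    n_ortho: int
    r2y: float
    q2: float
    permutation_p: float | None = field(default=None)

    @property
    def scores_pred(self) -> np.ndarray:
        return self.core["t_pred"]

    @property
    def scores_ortho(self) -> np.ndarray:
        return self.core["t_ortho"]

    @property
    def loadings_pred(self) -> np.ndarray:
        return self.core["p"]

    def predicted_response(self, X) -> np.ndarray:
        """Predicted class response on the 0/1 coding for new samples."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        Xcs = (X - self.x_mean) / self.x_scale
        return _predict_response(self.core, Xcs) + self.y_mean

    def predict(self, X) -> np.ndarray:
        """Class labels with the no-class band.

        Predicted responses inside ``noclass_band`` are returned as
        ``"unclassified"``; otherwise the nearer class label.
        """
        yhat = self.predicted_response(X)
        lo, hi = self.model.noclass_band
        out = np.empty(yhat.shape, dtype=object)
        out[yhat < lo] = str(self.model.classes_[0])
        out[yhat > hi] = str(self.model.classes_[1])
        out[(yhat >= lo) & (yhat <= hi)] = "unclassified"
        return out

    def summary(self) -> str:
        lines = [
            "OPLS-DA results",
            "================",
            f"classes:            {self.model.classes_[0]} (0) vs {self.model.classes_[1]} (1)",
            f"n samples:          {self.model.X.shape[0]}",
            f"n features:         {self.model.X.shape[1]}",
            f"orthogonal comps:   {self.n_ortho}",
            f"R2Y:                {self.r2y:.4f}",
            f"Q2 (7-fold CV):     {self.q2:.4f}",
            f"no-class band:      {self.model.noclass_band}",
        ]
        if self.permutation_p is not None:
            lines.append(f"permutation p:      {self.permutation_p:.4g}")
        return "\n".join(lines)


def fit_oplsda(X, y, n_ortho: int | str = "auto", seed: int = 0, **kw) -> OplsDaResults:
    """Convenience wrapper: construct and fit an :class:`OplsDa` model."""
    return OplsDa(X, y, n_ortho=n_ortho, **kw).fit(seed=seed)


def permutation_test_oplsda(
    X, y, n_ortho: int | str = "auto", B: int = 1000, seed: int = 0
) -> tuple[float, OplsDaResults]:
    """Label-permutation significance of an OPLS-DA fit.

    Refits the model on B permutations of the class labels and compares
    the cross-validated Q²; ``p = (#{Q²_perm ≥ Q²_obs} + 1)/(B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    res = fit_oplsda(X, y, n_ortho=n_ortho, seed=seed)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    count = 0
    for _ in range(B):
        perm = rng.permutation(y)
        if np.unique(perm).size < 2:
            continue
        try:
            q2p = fit_oplsda(X, perm, n_ortho=n_ortho, seed=seed).q2
        except ValueError:
            q2p = -np.inf
        if q2p >= res.q2:
            count += 1
    p = (count + 1) / (B + 1)
    res.permutation_p = p
    return p, res
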