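"""Partial least squares discriminant analysis (PLS-DA).

PLS-DA regresses a +/-1 class code on gene expression through a small number
of latent variables and classifies by the sign of the prediction relative to
a midpoint threshold.  The loadings of the latent variables are the gene
signature: they show which genes carry the class difference.

The fit is NIPALS PLS1 (univariate y), written as a scikit-learn style
estimator so it composes with sklearn model selection; the independent
cross-check against ``sklearn.cross_decomposition.PLSRegression`` lives in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .panel import ExpressionMatrix


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """Two-class PLS-DA with NIPALS PLS1 components.

    Parameters
    ----------
    n_components:
        Number of latent variables A.  Two reproduces the usual
        scores/loadings scatter plane.
    scale:
        Autoscale columns to unit variance after centering (default on; a
        constant column then raises, naming the gene).

    Attributes (after ``fit``)
    --------------------------
    x_weights_ : (p, A) NIPALS weight vectors W
    x_loadings_ : (p, A) loadings P
    y_loadings_ : (A,) inner-regression coefficients q
    x_scores_ : (n, A) training scores T (mutually orthogonal)
    coef_ : (p,) regression vector in the original (centered/scaled) space
    threshold_ : midpoint of the class-mean predictions, the decision cut
    """

    def __init__(self, n_components: int = 2, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y, feature_names: list[str] | None = None) -> "PLSDAClassifier":
        if feature_names is None and isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        classes = np.unique(y)
        if not np.array_equal(classes, [-1.0, 1.0]):
            raise ValueError("y must contain both classes coded -1 and +1")
        self.feature_names_in_ = feature_names

        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                j = int(np.argmin(sd))
                name = feature_names[j] if feature_names else f"column {j}"
                raise ValueError(f"constant feature with scaling on: {name}")
            self.x_std_ = sd
            Xc = Xc / sd
        else:
            self.x_std_ = np.ones(X.shape[1])
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_

        n, p = Xc.shape
        A = self.n_components
        if A < 1 or A > min(n - 1, p):
            raise ValueError(f"n_components={A} out of range for shape {Xc.shape}")

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        T = np.zeros((n, A))
        Xd = Xc.copy()
        norms = []
        for a in range(A):
            w = Xd.T @ yc
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("deflated X orthogonal to y; reduce n_components")
            w /= nw
            t = Xd @ w
            tt = t @ t
            p_a = Xd.T @ t / tt
            q_a = yc @ t / tt
            Xd = Xd - np.outer(t, p_a)
            norms.append(np.linalg.norm(Xd))
            W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t

        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.deflation_norms_ = np.array(norms)
        # regression vector: B = W (P' W)^-1 q
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)

        yhat = self._predict_continuous(X)
        self.threshold_ = 0.5 * (yhat[y > 0].mean() + yhat[y < 0].mean())
        self.classes_ = np.array([-1.0, 1.0])
        return self

    def _predict_continuous(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xc = (X - self.x_mean_) / self.x_std_
        return Xc @ self.coef_ + self.y_mean_

    def decision_function(self, X) -> np.ndarray:
        return self._predict_continuous(X) - self.threshold_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)

    def transform(self, X) -> np.ndarray:
        """Project onto the latent-variable space (scores for new samples)."""
        X = np.asarray(X, dtype=float)
        Xc = (X - self.x_mean_) / self.x_std_
        # scores via the direct projection weights R = W (P'W)^-1
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xc @ R

    def loadings_table(self) -> pd.DataFrame:
        names = self.feature_names_in_ or [f"x{j}" for j in range(len(self.coef_))]
        cols = {f"LV{a + 1}": self.x_loadings_[:, a]
                for a in range(self.x_loadings_.shape[1])}
        return pd.DataFrame(cols, index=names)


def fit_plsda(X, y, n_components: int = 2, scale: bool = True,
              feature_names: list[str] | None = None) -> PLSDAClassifier:
    """Thin functional wrapper over :class:`PLSDAClassifier`."""
    return PLSDAClassifier(n_components=n_components, scale=scale).fit(
        X, y, feature_names=feature_names)


def select_outcome_cohort(m: ExpressionMatrix) -> ExpressionMatrix:
    """Balance recurrence events against the longest-followed non-events.

    Keeps every BCR-positive sample (n_e of them) plus exactly the n_e
    BCR-negative samples with the longest follow-up — short-follow-up
    negatives may simply not have recurred *yet* and would contaminate the
    indolent class.  Ties at the follow-up cutoff break by sample-id order.
    """
    md = m.metadata
    if "bcr_event" not in md.columns:
        raise ValueError("no BCR annotations on this matrix")
    annotated = md["bcr_event"].notna()
    events = md.index[annotated & (md["bcr_event"] == True)]  # noqa: E712
    negatives = md.index[annotated & (md["bcr_event"] == False)]  # noqa: E712
    if len(events) == 0:
        raise ValueError("no BCR events")
    if len(negatives) < len(events):
        raise ValueError("fewer BCR-negative samples than events")
    neg = md.loc[negatives, ["bcr_time_years"]].copy()
    neg["_sid"] = neg.index
    neg = neg.sort_values(["bcr_time_years", "_sid"], ascending=[False, True],
                          kind="stable")
    keep = list(events) + list(neg.index[: len(events)])
    return m.select_samples(keep)


def outcome_design(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, gene_names) with y=+1 for BCR events (aggressive), -1 indolent."""
    md = m.metadata
    y = np.where(md["bcr_event"].astype(bool).to_numpy(), 1.0, -1.0)
    return m.values.to_numpy(), y, list(m.gene_symbols)


@dataclass
class CVReport:
    """Cross-validation summary for a PLS-DA model."""

    train_accuracy_mean: float
    train_accuracy_sd: float
    test_accuracy_mean: float
    test_accuracy_sd: float
    per_repeat_train: np.ndarray
    per_repeat_test: np.ndarray
    loocv_predictions: np.ndarray | None = None
    roc_points: np.ndarray | None = None   # (fpr, tpr) rows
    auc: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "train_accuracy_mean": self.train_accuracy_mean,
            "train_accuracy_sd": self.train_accuracy_sd,
            "test_accuracy_mean": self.test_accuracy_mean,
            "test_accuracy_sd": self.test_accuracy_sd,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def _stratified_split(y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        if n_test >= len(idx):
            n_test = len(idx) - 1
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.concatenate(test_idx)
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def cv_accuracy(X, y, n_components: int = 2, scheme: str = "repeated_split",
                repeats: int = 100, test_fraction: float = 0.3,
                n_folds: int = 5, seed: int = 0, scale: bool = True) -> CVReport:
    """Training and held-out accuracy under resampled validation.

    ``repeated_split`` (default) draws ``repeats`` stratified 70/30 splits
    and reports the accuracy on the training portion (mean +/- s.d., the
    "training accuracy" of the scores plots) alongside the held-out
    accuracy.  ``kfold`` runs stratified K-fold instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise ValueError("both classes need >= 2 members")
    rng = np.random.default_rng(seed)
    train_acc, test_acc = [], []

    if scheme == "repeated_split":
        splits = (_stratified_split(y, test_fraction, rng) for _ in range(repeats))
    elif scheme == "kfold":
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        splits = ((tr, te) for tr, te in skf.split(X, y))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    for train, test in splits:
        for _ in range(10):
            if len(np.unique(y[train])) == 2:
                break
            train, test = _stratified_split(y, test_fraction, rng)
        else:
            raise ValueError("could not form a split containing both classes")
        model = PLSDAClassifier(n_components=min(n_components, len(train) - 1),
                                scale=scale).fit(X[train], y[train])
        train_acc.append(float((model.predict(X[train]) == y[train]).mean()))
        test_acc.append(float((model.predict(X[test]) == y[test]).mean()))

    train_acc, test_acc = np.array(train_acc), np.array(test_acc)
    return CVReport(
        train_accuracy_mean=float(train_acc.mean()),
        train_accuracy_sd=float(train_acc.std(ddof=1)) if len(train_acc) > 1 else 0.0,
        test_accuracy_mean=float(test_acc.mean()),
        test_accuracy_sd=float(test_acc.std(ddof=1)) if len(test_acc) > 1 else 0.0,
        per_repeat_train=train_acc, per_repeat_test=test_acc,
    )


def rank_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formula (ties counted half)."""
    from scipy.stats import rankdata
    pos = np.asarray(scores_pos, float)
    neg = np.asarray(scores_neg, float)
    allv = np.concatenate([pos, neg])
    ranks = rankdata(allv)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def loocv_roc(X, y, n_components: int = 2, scale: bool = True) -> CVReport:
    """Leave-one-out cross-validated predictions, ROC curve and rank AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if min((y == 1).sum(), (y == -1).sum()) < 3:
        raise ValueError("need >= 3 samples per class for LOOCV ROC")
    n = len(y)
    yhat = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = PLSDAClassifier(n_components=n_components, scale=scale).fit(
            X[keep], y[keep])
        yhat[i] = model._predict_continuous(X[i][None, :])[0]
    auc = rank_auc(yhat[y == 1], yhat[y == -1])
    # threshold sweep over the observed prediction values
    thresholds = np.concatenate([[np.inf], np.sort(yhat)[::-1]])
    fpr = [( (yhat[y == -1] >= t).mean()) for t in thresholds]
    tpr = [( (yhat[y == 1] >= t).mean()) for t in thresholds]
    roc = np.column_stack([fpr, tpr])
    acc = float((np.where(yhat >= 0, 1.0, -1.0) == y).mean())
    return CVReport(train_accuracy_mean=np.nan, train_accuracy_sd=np.nan,
                    test_accuracy_mean=acc, test_accuracy_sd=0.0,
                    per_repeat_train=np.array([]), per_repeat_test=np.array([acc]),
                    loocv_predictions=yhat, roc_points=roc, auc=auc)
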