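"""Consensus K-means clustering of metastasis samples.

Clustering is repeated on random subsamples; the consensus matrix records
how often each sample pair co-clusters when co-sampled.  The number of
clusters K is chosen by minimising the PAC score (proportion of ambiguous
co-clustering: consensus entries that are neither near 0 nor near 1), and a
chi-square / permutation test measures the association between the final
clusters and the patients the metastases came from.

K-means itself is a small Lloyd's-algorithm implementation with k-means++
seeding, best-of-restarts selection, and farthest-point reseeding of empty
clusters; the cross-check against ``sklearn.cluster.KMeans`` lives in the
test suite.  Keeping it in-package makes the 500-resample consensus loops
on these small cohorts fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    k = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            mask = new_labels == j
            if not mask.any():
                # reseed an empty cluster from the farthest point
                far = d2.min(axis=1).argmax()
                centers[j] = X[far]
                new_labels[far] = j
                mask = new_labels == j
            centers[j] = X[mask].mean(axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(labels)), labels].sum())
    return labels, centers, wcss


def kmeans(X, k: int, restarts: int = 5,
           seed: int | np.random.Generator | None = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts K-means (k-means++ + Lloyd); returns
    ``(labels, centers, wcss)``."""
    X = np.asarray(X, dtype=float)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        labels, centers, wcss = _lloyd(X, _kmeans_pp_init(X, k, rng))
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    return best


def consensus_matrix(X, k: int, n_resamples: int = 500,
                     subsample_fraction: float = 0.8,
                     restarts: int = 3,
                     seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Pairwise co-clustering frequency over subsampled K-means runs.

    ``M[i, j]`` = (#runs where i and j co-clustered) / (#runs where both were
    sampled); pairs never co-sampled are NaN and excluded from PAC.  The
    diagonal is 1.
    """
    X = np.asarray(X, dtype=float)
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    m = max(k, int(round(subsample_fraction * n)))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels, _, _ = kmeans(X[idx], k, restarts=restarts, seed=rng)
        ind = np.zeros((m, k))
        ind[np.arange(m), labels] = 1.0
        co = ind @ ind.T
        sampled[np.ix_(idx, idx)] += 1.0
        together[np.ix_(idx, idx)] += co
    with np.errstate(invalid="ignore"):
        M = together / sampled
    np.fill_diagonal(M, 1.0)
    return M


def pac_score(M: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous co-clustering among defined off-diagonal pairs."""
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no defined off-diagonal consensus entries")
    return float(((vals > lower) & (vals < upper)).mean())


@dataclass
class KSelection:
    k: int
    pac_by_k: dict[int, float]
    low_confidence: bool


def select_k(consensus_by_k: dict[int, np.ndarray],
             lower: float = 0.1, upper: float = 0.9,
             confidence_pac: float = 0.3) -> KSelection:
    """Choose K minimising PAC; ties break toward smaller K.

    If even the best PAC is above ``confidence_pac`` the structure is weak
    (pure-noise data behaves this way) and the selection is flagged.
    """
    if len(consensus_by_k) < 1:
        raise ValueError("no candidate K")
    pac = {k: pac_score(M, lower, upper) for k, M in sorted(consensus_by_k.items())}
    best_k = min(pac, key=lambda k: (pac[k], k))
    return KSelection(k=best_k, pac_by_k=pac, low_confidence=pac[best_k] > confidence_pac)


def _consensus_partition(M: np.ndarray, k: int) -> np.ndarray:
    """Cut average-linkage clustering of the consensus dissimilarity at k."""
    D = 1.0 - np.nan_to_num(M, nan=0.5)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    return fcluster(linkage(squareform(D, checks=False), method="average"),
                    k, criterion="maxclust") - 1


def align_labels(labels: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Relabel clusters to best match a reference partition (Hungarian)."""
    k = max(labels.max(), reference.max()) + 1
    cost = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            cost[a, b] = -np.sum((labels == a) & (reference == b))
    _, col = linear_sum_assignment(cost)
    mapping = {a: col[a] for a in range(k)}
    return np.array([mapping[v] for v in labels])


class ConsensusKMeans(BaseEstimator, ClusterMixin):
    """Consensus K-means with PAC-based selection of the cluster number.

    Attributes (after ``fit``)
    --------------------------
    consensus_ : dict K -> consensus matrix
    pac_ : dict K -> PAC score
    k_ : selected number of clusters
    low_confidence_ : True when even the best PAC is weak
    labels_ : final assignments (full-data K-means at k_, aligned to the
        consensus blocks by Hungarian matching)
    """

    def __init__(self, k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
                 n_resamples: int = 500, subsample_fraction: float = 0.8,
                 restarts: int = 3, final_restarts: int = 20,
                 random_state: int | None = 0):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.restarts = restarts
        self.final_restarts = final_restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "ConsensusKMeans":
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(self.random_state)
        self.consensus_ = {}
        for k in self.k_range:
            if k > X.shape[0]:
                continue
            self.consensus_[k] = consensus_matrix(
                X, k, n_resamples=self.n_resamples,
                subsample_fraction=self.subsample_fraction,
                restarts=self.restarts, seed=rng)
        sel = select_k(self.consensus_)
        self.k_ = sel.k
        self.pac_ = sel.pac_by_k
        self.low_confidence_ = sel.low_confidence
        labels, centers, _ = kmeans(X, self.k_, restarts=self.final_restarts, seed=rng)
        reference = _consensus_partition(self.consensus_[self.k_], self.k_)
        self.labels_ = align_labels(labels, reference)
        self.cluster_centers_ = centers
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_patient_association(
    assignments, patient_ids, n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> dict:
    """Association between cluster labels and patients of origin.

    Pearson chi-square on the cluster x patient contingency table, with a
    permutation p-value alongside the asymptotic one because expected counts
    in these small cohorts are far below the asymptotic regime.
    """
    labels = np.asarray(assignments)
    patients = np.asarray(patient_ids)
    if len(labels) != len(patients):
        raise ValueError("assignments and patient_ids must align")
    if len(np.unique(labels)) < 2 or len(np.unique(patients)) < 2:
        raise ValueError("need >= 2 clusters and >= 2 patients")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(patients, name="patient"))
    chi2, p_asym, dof, _ = stats.chi2_contingency(table, correction=False)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(patients)
        t = pd.crosstab(labels, perm)
        c, _, _, _ = stats.chi2_contingency(t, correction=False)
        if c >= chi2 - 1e-12:
            count += 1
    p_perm = (count + 1) / (n_permutations + 1)
    return {"chi2": float(chi2), "df": int(dof), "p_asymptotic": float(p_asym),
            "p_permutation": float(p_perm), "table": table}
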