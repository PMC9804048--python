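"""Recurring connectivity states via k-means with city-block (L1) distance.

Windows from all subjects and both phases are pooled and clustered with
k-means under the L1 metric: assignment by minimal city-block distance,
centroid update by the element-wise median (the exact minimizer of the
within-cluster L1 cost).  Many random restarts are run and the solution
with the lowest total cost kept; states are renumbered by descending
total occurrence so that "state 1" is always the most frequent pattern
of a given fit.  The number of states is chosen by the elbow criterion
on a cluster-validity index (mean within-cluster distance over mean
between-centroid distance), operationalized as the point of maximum
discrete curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, ClusterMixin

from ._utils import pair_index
from .windows import WindowSpec, WindowedFCSeries


class ConnectivityKMeans(ClusterMixin, BaseEstimator):
    """L1 (city-block) k-means over windowed connectivity vectors.

    Parameters
    ----------
    n_clusters : int
        Number of states k.
    n_restarts : int, default 500
        Random initializations; the best (lowest total L1 cost) run is kept.
    max_iter : int, default 200
        Lloyd iterations per restart.
    tol : float, default 1e-6
        Absolute convergence tolerance on the total cost.
    random_state : int, default 0

    Attributes
    ----------
    cluster_centers_ : (k, n_features) element-wise medians.
    labels_ : 0-based assignment of the fitted windows.
    inertia_ : total within-cluster L1 cost.
    """

    def __init__(self, n_clusters: int = 5, n_restarts: int = 500,
                 max_iter: int = 200, tol: float = 1e-6, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        # k-means++-style seeding under the L1 metric
        n = X.shape[0]
        centers = [X[rng.integers(n)]]
        for _ in range(self.n_clusters - 1):
            d = cdist(X, np.asarray(centers), metric="cityblock").min(axis=1)
            total = d.sum()
            if total <= 0:
                centers.append(X[rng.integers(n)])
                continue
            centers.append(X[rng.choice(n, p=d / total)])
        return np.asarray(centers, dtype=float)

    def _lloyd(self, X: np.ndarray, centers: np.ndarray):
        prev_cost = np.inf
        labels = np.zeros(X.shape[0], dtype=np.int64)
        self._last_cost_history = []
        for _ in range(self.max_iter):
            D = cdist(X, centers, metric="cityblock")
            labels = D.argmin(axis=1)  # argmin takes the lowest index on ties
            cost = D[np.arange(X.shape[0]), labels].sum()
            self._last_cost_history.append(cost)
            for c in range(self.n_clusters):
                members = labels == c
                if members.any():
                    centers[c] = np.median(X[members], axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    far = int(D.min(axis=1).argmax())
                    centers[c] = X[far]
            if abs(prev_cost - cost) <= self.tol * max(1.0, abs(cost)):
                prev_cost = cost
                break
            prev_cost = cost
        D = cdist(X, centers, metric="cityblock")
        labels = D.argmin(axis=1)
        cost = D[np.arange(X.shape[0]), labels].sum()
        return labels, centers, cost

    def fit(self, X, y=None, extra_inits=()):
        """Fit with ``n_restarts`` random initializations (plus any
        caller-provided candidate center sets), keeping the lowest-cost run."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (windows x pairs)")
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"k={self.n_clusters} exceeds the {X.shape[0]} available windows"
            )
        rng = np.random.default_rng(self.random_state)
        best = None
        inits = [self._init_centers(X, rng) for _ in range(self.n_restarts)]
        inits += [np.asarray(c, dtype=float) for c in extra_inits]
        for centers in inits:
            if centers.shape != (self.n_clusters, X.shape[1]):
                raise ValueError("candidate centers have the wrong shape")
            labels, centers, cost = self._lloyd(X, centers.copy())
            if best is None or cost < best[2]:
                best = (labels, centers, cost)
        self.labels_, self.cluster_centers_, self.inertia_ = best
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return cdist(X, self.cluster_centers_, metric="cityblock").argmin(axis=1)


@dataclass
class StateModel:
    """Fitted state clustering: centroids in pair space plus assignments.

    States are 1-based and ordered by descending total occurrence.
    """

    k: int
    centroids: np.ndarray  # (k, n_pairs)
    assignments: dict  # session key -> (n_windows,) 1-based states
    total_cost: float
    occurrence_counts: np.ndarray
    occurrence_percent: np.ndarray

    def __post_init__(self):
        if not math.isclose(float(self.occurrence_percent.sum()), 100.0, abs_tol=1e-6):
            raise ValueError("state occurrence percentages must sum to 100")


def cluster_states(series: dict | list, k: int, n_restarts: int = 500,
                   seed: int = 0, max_iter: int = 200) -> StateModel:
    """Pool all sessions' windows and cluster them into k states.

    ``series`` maps session keys to :class:`WindowedFCSeries` (a list is
    treated as enumerated sessions).  Windows of every subject and phase
    are pooled, as the states are defined over the entire cohort.
    """
    if not isinstance(series, dict):
        series = dict(enumerate(series))
    keys = list(series.keys())
    mats = [series[key].values for key in keys]
    X = np.concatenate(mats, axis=0)
    km = ConnectivityKMeans(
        n_clusters=k, n_restarts=n_restarts, max_iter=max_iter, random_state=seed
    ).fit(X)
    # renumber by descending occurrence
    counts = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    labels = relabel[km.labels_] + 1
    centroids = km.cluster_centers_[order]
    counts = counts[order]
    assignments = {}
    offset = 0
    for key, m in zip(keys, mats):
        assignments[key] = labels[offset : offset + m.shape[0]]
        offset += m.shape[0]
    return StateModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        total_cost=float(km.inertia_),
        occurrence_counts=counts,
        occurrence_percent=100.0 * counts / counts.sum(),
    )


def validity_index(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Mean within-cluster L1 distance / mean between-centroid L1 distance."""
    within = cdist(X, centers, metric="cityblock")[
        np.arange(X.shape[0]), labels
    ].mean()
    between = pdist(centers, metric="cityblock").mean()
    return float(within / between)


def elbow_from_curve(k_values, index_values) -> int:
    """Elbow = interior k maximizing the discrete curvature of the curve.

    Raises if fewer than 3 k values are given or the curve has no positive
    curvature (e.g. it is exactly linear in k).
    """
    ks = np.asarray(list(k_values))
    I = np.asarray(list(index_values), dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow selection needs at least 3 candidate k values")
    curv = I[:-2] - 2 * I[1:-1] + I[2:]
    scale = max(1e-12, float(np.max(np.abs(I))))
    if np.max(curv) <= 1e-9 * scale:
        raise ValueError("validity curve has no elbow (no positive curvature)")
    return int(ks[1:-1][int(np.argmax(curv))])


def elbow_select_k(series: dict | list, k_range, n_restarts: int = 500,
                   seed: int = 0, max_iter: int = 200):
    """Fit every k in ``k_range`` and pick the elbow of the validity index.

    Returns (selected_k, {k: validity index}).
    """
    if not isinstance(series, dict):
        series = dict(enumerate(series))
    X = np.concatenate([s.values for s in series.values()], axis=0)
    ks = sorted(k_range)
    curve = {}
    prev_centers = None
    for k in ks:
        extra = ()
        if prev_centers is not None and prev_centers.shape[0] == k - 1:
            # hierarchical warm start: previous solution plus the point
            # farthest from it, so the validity curve degrades gracefully
            d = cdist(X, prev_centers, metric="cityblock").min(axis=1)
            extra = (np.vstack([prev_centers, X[int(d.argmax())]]),)
        km = ConnectivityKMeans(
            n_clusters=k, n_restarts=n_restarts, max_iter=max_iter,
            random_state=seed,
        ).fit(X, extra_inits=extra)
        prev_centers = km.cluster_centers_
        curve[k] = validity_index(X, km.labels_, km.cluster_centers_)
    return elbow_from_curve(ks, [curve[k] for k in ks]), curve


def top_connections(centroid: np.ndarray, n_components: int,
                    fraction: float = 0.05) -> list[tuple[int, int, str, float]]:
    """Strongest connections of a centroid: the ceil(fraction * n_pairs)
    pairs with largest absolute value, tagged by sign.

    Returns (component_i, component_j, sign, value) with 1-based components.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    centroid = np.asarray(centroid, dtype=float)
    i, j = pair_index(n_components)
    n_keep = math.ceil(fraction * len(centroid))
    order = np.argsort(-np.abs(centroid), kind="stable")[:n_keep]
    out = []
    for idx in order:
        v = float(centroid[idx])
        sign = "positive" if v > 0 else ("negative" if v < 0 else "zero")
        out.append((int(i[idx]) + 1, int(j[idx]) + 1, sign, v))
    return out


def window_majority_labels(path: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Label each window by the majority hidden state over its nominal extent.

    Used to compare recovered window states with the generator's hidden
    path; ties go to the lower state index.
    """
    path = np.asarray(path)
    nw = (len(path) - spec.width_tr) // spec.step_tr + 1
    out = np.empty(nw, dtype=np.int64)
    for w in range(nw):
        s = w * spec.step_tr
        seg = path[s : s + spec.width_tr]
        out[w] = np.bincount(seg).argmax()
    return out


def state_series_from_model(model: StateModel) -> dict:
    """Per-session 1-based window-state sequences (alias for assignments)."""
    return model.assignments


def majority_map_states(model_labels: np.ndarray, true_labels: np.ndarray,
                        k: int) -> np.ndarray:
    """Map each recovered state to its majority true state (for diagnostics)."""
    mapping = np.zeros(k, dtype=np.int64)
    for s in range(1, k + 1):
        mask = model_labels == s
        mapping[s - 1] = (
            np.bincount(true_labels[mask]).argmax() if mask.any() else 0
        )
    return mapping
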