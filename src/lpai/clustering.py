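"""Protein trajectory clustering: LOESS curves + k-means + elbow rule.

Each protein's pooled observations are z-scored, LOESS-smoothed against
age (degree-1 local regression with tricube weights) and evaluated on a
common age grid; k-means groups the fitted curves into trajectory
archetypes (e.g. flat, rising, declining, non-monotone), with the
number of clusters picked at the elbow of the within-cluster
sum-of-squares curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import LongitudinalDataset

__all__ = [
    "ClusterResult",
    "TrajectoryClusterer",
    "fit_loess_curves",
    "cluster_trajectories",
    "choose_k_elbow",
]


@dataclass
class ClusterResult:
    grid: np.ndarray
    curves: pd.DataFrame  # protein x grid
    labels: pd.Series  # protein -> 1..k
    k: int
    wss: dict  # candidate k -> within-cluster sum of squares
    mean_curves: pd.DataFrame  # cluster -> grid curve


def fit_loess_curves(dataset: LongitudinalDataset, span: float = 0.75,
                     grid_size: int = 51, min_points: int = 10) -> tuple:
    """Z-scored LOESS trajectory per protein on a common age grid.

    Returns ``(grid, curves)`` with curves indexed by protein. A
    constant protein has an undefined z-score; its curve is defined as
    all zeros with a warning (keeps the matrix dense).
    """
    lo, hi = dataset.age_domain
    grid = np.linspace(lo, hi, grid_size)
    rows = {}
    for pid in dataset.proteins:
        sub = dataset.observations[dataset.observations["protein_id"] == pid]
        ages = sub["age"].to_numpy(float)
        values = sub["value"].to_numpy(float)
        if ages.size < min_points:
            raise ValueError(
                f"protein {pid!r} has {ages.size} points < {min_points}"
            )
        if int(np.ceil(span * ages.size)) < 2:
            raise ValueError(f"span {span} leaves <2 points per neighborhood")
        sd = values.std(ddof=0)
        if sd == 0:
            warnings.warn(f"protein {pid!r} is constant; z-scored curve set "
                          "to zero", RuntimeWarning)
            rows[pid] = np.zeros(grid_size)
            continue
        z = (values - values.mean()) / sd
        fitted = lowess(z, ages, frac=span, it=0, xvals=grid)
        rows[pid] = fitted
    curves = pd.DataFrame(rows, index=grid).T
    return grid, curves


def _kmeans_wss(curves: np.ndarray, k: int, random_state, restarts: int):
    km = KMeans(n_clusters=k, n_init=restarts, random_state=random_state)
    labels = km.fit_predict(curves)
    return km, labels, float(km.inertia_)


def cluster_trajectories(curves: pd.DataFrame, k: int, random_state=None,
                         restarts: int = 20,
                         grid: np.ndarray | None = None) -> ClusterResult:
    """K-means over fitted curves; labels renumbered by cluster size.

    The best of ``restarts`` seeded initializations (by within-cluster
    sum of squares) is kept; labels are renumbered 1..k by descending
    cluster size so that equal inputs yield identical labelings.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(curves):
        raise ValueError(f"k={k} exceeds the {len(curves)} proteins")
    X = curves.to_numpy(float)
    _, raw_labels, wss = _kmeans_wss(X, k, random_state, restarts)
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # size desc, old label asc
    relabel = np.empty(k, int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw_labels], index=curves.index, name="cluster")
    mean_curves = curves.groupby(labels).mean()
    mean_curves.index.name = "cluster"
    if grid is None:
        grid = curves.columns.to_numpy(float)
    return ClusterResult(grid=np.asarray(grid, float), curves=curves,
                         labels=labels, k=k, wss={k: wss},
                         mean_curves=mean_curves)


def elbow_from_wss(wss_sequence, k_values) -> int:
    """The k at maximal curvature of the WSS-vs-k polyline.

    Curvature is measured as the second difference of log WSS. On the
    log scale a constant proportional decay (splitting noise) is a
    straight line, so the maximizer is where the decay rate itself
    collapses — the point beyond which extra clusters buy little. A raw
    second difference would instead lock onto the earliest large drop
    whenever cluster separations are heterogeneous. Ties resolve to the
    smaller k; endpoints (without both neighbors) are not eligible.
    """
    seq = np.asarray(wss_sequence, float)
    ks = list(k_values)
    if seq.size != len(ks) or seq.size < 3:
        raise ValueError("need WSS for at least 3 candidate k values")
    if np.any(np.diff(seq) > 1e-9 * max(seq[0], 1.0)):
        raise ValueError("within-cluster SS not non-increasing in k; "
                         "increase restarts")
    eps = 1e-12 * max(seq[0], 1.0)
    logseq = np.log(np.maximum(seq, eps))
    curv = logseq[:-2] - 2.0 * logseq[1:-1] + logseq[2:]
    best = int(np.argmax(curv))  # first occurrence = smaller k on ties
    return ks[best + 1]


def choose_k_elbow(curves: pd.DataFrame, k_candidates, random_state=None,
                   restarts: int = 20) -> tuple[int, dict]:
    """Elbow rule over fitted curves; returns ``(k, wss_by_k)``."""
    ks = sorted(set(int(k) for k in k_candidates))
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate values of k")
    X = curves.to_numpy(float)
    wss = {}
    for k in ks:
        _, _, w = _kmeans_wss(X, k, random_state, restarts)
        wss[k] = w
    return elbow_from_wss([wss[k] for k in ks], ks), wss


class TrajectoryClusterer(BaseEstimator):
    """LOESS + k-means trajectory clustering as a single estimator.

    ``k="auto"`` chooses the cluster count by the elbow rule over
    ``k_candidates``.
    """

    def __init__(self, span=0.75, grid_size=51, k="auto",
                 k_candidates=tuple(range(1, 9)), restarts=20,
                 random_state=None):
        self.span = span
        self.grid_size = grid_size
        self.k = k
        self.k_candidates = k_candidates
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, dataset: LongitudinalDataset):
        grid, curves = fit_loess_curves(dataset, span=self.span,
                                        grid_size=self.grid_size)
        if self.k == "auto":
            k, wss = choose_k_elbow(curves, self.k_candidates,
                                    random_state=self.random_state,
                                    restarts=self.restarts)
        else:
            k, wss = int(self.k), {}
        result = cluster_trajectories(curves, k,
                                      random_state=self.random_state,
                                      restarts=self.restarts, grid=grid)
        result.wss.update(wss)
        self.grid_ = grid
        self.curves_ = curves
        self.labels_ = result.labels
        self.k_ = k
        self.wss_ = result.wss
        self.mean_curves_ = result.mean_curves
        self.result_ = result
        return self

    def fit_predict(self, dataset: LongitudinalDataset) -> pd.Series:
        return self.fit(dataset).labels_
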