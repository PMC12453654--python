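"""From-scratch k-means with restarts, the within-cluster SSE objective and
an elbow-point selector for choosing the number of majority clusters.

The SSE objective is the standard within-cluster sum of squared Euclidean
distances,

    SSE = sum_i || x_i - c_{a(i)} ||^2,

with x_i a feature row, c_k a cluster centre and a(i) the assignment of
point i.  Lloyd iterations monotonically decrease this objective; the elbow
scan runs restarted k-means for k = 1..cluster_n, keeps the best SSE per k,
and the selector picks the k of maximum perpendicular distance to the chord
of the (min-max normalized) curve — a deterministic stand-in for the visual
"rate of decrease slows down" criterion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("mciic")


@dataclass
class ClusterModel:
    centers: np.ndarray          # k×d
    assignments: np.ndarray      # n ints in [0, k)
    sse: float
    n_iter: int
    converged: bool
    empty_cluster_repairs: int = 0


@dataclass
class ElbowCurve:
    """SSE over k = 1..cluster_n plus the selected elbow k (the Nc of the
    relabeling step)."""

    k_values: list[int]
    sse_values: list[float]
    chosen_k: int = 0

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["k", "sse"])
            for k, s in zip(self.k_values, self.sse_values):
                w.writerow([k, s])

    def save_plot(self, path: str | Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.k_values, self.sse_values, "o-")
        if self.chosen_k:
            ax.axvline(self.chosen_k, color="r", ls="--",
                       label=f"elbow k={self.chosen_k}")
            ax.legend()
        ax.set_xlabel("k (number of clusters)")
        ax.set_ylabel("SSE")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def sse(points: np.ndarray, centers: np.ndarray, assignments: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances."""
    points = np.asarray(points, dtype=np.float64)
    centers = np.asarray(centers, dtype=np.float64)
    assignments = np.asarray(assignments, dtype=np.intp)
    if points.shape[1] != centers.shape[1]:
        raise ValueError("points and centers have mismatched dimensionality")
    if assignments.shape[0] != points.shape[0]:
        raise ValueError("one assignment per point required")
    if assignments.min(initial=0) < 0 or (points.shape[0] and assignments.max() >= len(centers)):
        raise ValueError("assignment index out of range")
    diff = points - centers[assignments]
    return float(np.einsum("ij,ij->", diff, diff))


def _squared_distances(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """n×k matrix of squared Euclidean distances."""
    # ||x||^2 - 2 x.c + ||c||^2, clipped: cancellation can go slightly negative
    d2 = (
        np.sum(points ** 2, axis=1)[:, None]
        - 2.0 * points @ centers.T
        + np.sum(centers ** 2, axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _plusplus_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted greedy seeding: each new centre is drawn with
    probability proportional to its squared distance to the nearest chosen
    centre."""
    n = points.shape[0]
    centers = np.empty((k, points.shape[1]), dtype=np.float64)
    centers[0] = points[rng.integers(n)]
    closest = _squared_distances(points, centers[:1]).ravel()
    for j in range(1, k):
        total = closest.sum()
        if total <= 0:
            centers[j] = points[rng.integers(n)]
        else:
            centers[j] = points[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, _squared_distances(points, centers[j:j + 1]).ravel())
    return centers


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int, tol: float) -> ClusterModel:
    """Lloyd iterations from the given centres until the maximum centre
    displacement drops below tol.  An emptied cluster is reseeded at the
    point currently farthest from its assigned centre."""
    k = centers.shape[0]
    centers = centers.copy()
    repairs = 0
    assignments = np.zeros(points.shape[0], dtype=np.intp)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = _squared_distances(points, centers)
        assignments = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        point_d2 = d2[np.arange(points.shape[0]), assignments]
        for j in range(k):
            mask = assignments == j
            if mask.any():
                new_centers[j] = points[mask].mean(axis=0)
            else:
                far = int(np.argmax(point_d2))
                new_centers[j] = points[far]
                point_d2[far] = 0.0
                repairs += 1
        shift = np.sqrt(np.max(np.sum((new_centers - centers) ** 2, axis=1)))
        centers = new_centers
        if shift < tol:
            converged = True
            break
    assignments = np.argmin(_squared_distances(points, centers), axis=1)
    return ClusterModel(
        centers=centers,
        assignments=assignments,
        sse=sse(points, centers, assignments),
        n_iter=it,
        converged=converged,
        empty_cluster_repairs=repairs,
    )


def kmeans(points: np.ndarray, k: int, seed: int, max_iter: int = 300,
           tol: float = 1e-4, n_restarts: int = 10,
           init_centers: np.ndarray | None = None) -> ClusterModel:
    """Restarted Lloyd's algorithm; the lowest-SSE run wins.

    Deterministic given ``seed``.  ``init_centers``, when given, is added as
    one extra candidate start (used by the elbow scan for nested seeding).
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be an n×d matrix")
    n = points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")

    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    starts: list[np.ndarray] = [_plusplus_init(points, k, rng) for _ in range(n_restarts)]
    if init_centers is not None:
        if init_centers.shape != (k, points.shape[1]):
            raise ValueError("init_centers must be k×d")
        starts.append(np.asarray(init_centers, dtype=np.float64))
    for start in starts:
        model = _lloyd(points, start, max_iter, tol)
        if best is None or model.sse < best.sse:
            best = model
    assert best is not None
    if best.empty_cluster_repairs:
        logger.info("kmeans k=%d: %d empty-cluster repairs", k, best.empty_cluster_repairs)
    return best


def select_elbow_k(curve: ElbowCurve) -> int:
    """Elbow = point of maximum perpendicular distance to the first-last chord
    after min-max normalizing both axes to [0,1].

    Ties break to the smallest k; a length-1 or flat curve returns k=1.  The
    result is invariant to affine rescaling of either axis.
    """
    ks = np.asarray(curve.k_values, dtype=np.float64)
    ss = np.asarray(curve.sse_values, dtype=np.float64)
    if len(ks) == 0:
        raise ValueError("empty elbow curve")
    if len(ks) == 1 or np.ptp(ss) == 0 or np.ptp(ks) == 0:
        return int(curve.k_values[0])
    x = (ks - ks.min()) / np.ptp(ks)
    y = (ss - ss.min()) / np.ptp(ss)
    # distance from (x,y) to the chord joining (x0,y0)-(x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
    # floating error breaks exact ties (e.g. a perfectly linear decline);
    # treat near-maximal distances as tied and take the smallest k
    tied = np.flatnonzero(dist >= dist.max() - 1e-9)
    return int(curve.k_values[int(tied[0])])


def elbow_scan(points: np.ndarray, cluster_n: int, seed: int,
               n_restarts: int = 10) -> ElbowCurve:
    """Best-of-restarts k-means for k = 1..cluster_n, then elbow selection.

    For each k the best (k-1)-solution's centres augmented with the point
    farthest from its centre are added as a candidate start, which makes the
    SSE curve non-increasing in k by construction.
    """
    points = np.asarray(points, dtype=np.float64)
    if cluster_n < 1:
        raise ValueError("cluster_n must be >= 1")
    if points.shape[0] < cluster_n:
        raise ValueError("need at least cluster_n points")
    ks: list[int] = []
    sses: list[float] = []
    prev: ClusterModel | None = None
    for k in range(1, cluster_n + 1):
        init = None
        if prev is not None:
            d2 = _squared_distances(points, prev.centers)
            per_point = d2[np.arange(points.shape[0]), prev.assignments]
            split = points[int(np.argmax(per_point))]
            init = np.vstack([prev.centers, split])
        model = kmeans(points, k, seed=seed + k, n_restarts=n_restarts,
                       init_centers=init)
        ks.append(k)
        sses.append(model.sse)
        prev = model
    curve = ElbowCurve(k_values=ks, sse_values=sses)
    curve.chosen_k = select_elbow_k(curve)
    return curve
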