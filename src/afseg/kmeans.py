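"""K-means pixel clustering and Z-stack label harmonization.

The clustering engine is the textbook Lloyd procedure: pick K centroids,
assign every point (image pixel) to its closest centroid, recompute each
cluster's centroid, and repeat until no reassignment occurs — minimizing the
sum of squared point-to-centroid distances.  On top of the bare recipe this
implementation adds the machinery pixel clustering needs in practice:
careful ("plus-plus") seeding with the literal random-points option kept,
multiple restarts scored by objective, deterministic seeding, and repair of
empty clusters by reseeding at the farthest point.

Ties: a point equidistant to several centroids goes to the lowest centroid
index.  The objective is checked to be non-increasing at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .gabor import FeatureStack
from .volumes import LabelVolume


@dataclass
class KMeansConfig:
    K: int = 4
    init: str = "plus-plus"  # or "random-points"
    n_restarts: int = 5
    max_iter: int = 300
    tol: float = 1e-6  # relative objective-change convergence threshold
    seed: int = 0
    subsample: int | None = None  # fit on this many points, predict all

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.init not in ("plus-plus", "random-points"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class KMeansResult:
    centroids: np.ndarray  # (K, F)
    assignments: np.ndarray  # (N,) int in [0, K)
    objective: float  # sum of squared distances to assigned centroids
    n_iter: int
    restart_objectives: list[float]
    objective_history: list[float] = field(default_factory=list)


def inertia(points: np.ndarray, centroids: np.ndarray, assignments: np.ndarray) -> float:
    """Sum of squared distances of each point to its assigned centroid."""
    points = np.asarray(points, dtype=np.float64)
    assignments = np.asarray(assignments)
    if points.shape[0] != assignments.shape[0]:
        raise ValueError("points and assignments disagree in length")
    if assignments.size and (assignments.min() < 0 or assignments.max() >= len(centroids)):
        raise ValueError("assignment index out of range")
    diff = points - centroids[assignments]
    return float(np.einsum("ij,ij->", diff, diff))


def _init_centroids(
    points: np.ndarray, K: int, init: str, rng: np.random.Generator
) -> np.ndarray:
    n = points.shape[0]
    if init == "random-points":
        idx = rng.choice(n, size=K, replace=False)
        return points[idx].copy()
    # plus-plus: D^2 sampling
    centroids = np.empty((K, points.shape[1]), dtype=np.float64)
    centroids[0] = points[rng.integers(n)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a centroid
            centroids[k] = points[rng.integers(n)]
            continue
        probs = d2 / total
        centroids[k] = points[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((points - centroids[k]) ** 2, axis=1))
    return centroids


def _lloyd(
    points: np.ndarray, K: int, config: KMeansConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centroids = _init_centroids(points, K, config.init, rng)
    prev_assign: np.ndarray | None = None
    prev_obj = np.inf
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        d2 = cdist(points, centroids, "sqeuclidean")
        assign = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        obj = float(d2[np.arange(len(points)), assign].sum())
        if obj > prev_obj * (1 + 1e-9) + 1e-12:
            raise RuntimeError(
                f"objective increased during Lloyd iteration: {prev_obj} -> {obj}"
            )
        history.append(obj)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        if np.isfinite(prev_obj) and prev_obj > 0 and (prev_obj - obj) / prev_obj < config.tol:
            break
        prev_assign = assign
        prev_obj = obj
        # update step, with empty-cluster repair
        for k in range(K):
            members = assign == k
            if members.any():
                centroids[k] = points[members].mean(axis=0)
        empties = [k for k in range(K) if not (assign == k).any()]
        if empties:
            dist_to_own = np.sqrt(((points - centroids[assign]) ** 2).sum(axis=1))
            order = np.argsort(dist_to_own)[::-1]
            for j, k in enumerate(empties):
                far = order[j]  # farthest not-yet-used point
                centroids[k] = points[far]
    d2 = cdist(points, centroids, "sqeuclidean")
    assign = np.argmin(d2, axis=1)
    obj = float(d2[np.arange(len(points)), assign].sum())
    return centroids, assign, obj, n_iter, history


def kmeans(points: np.ndarray, config: KMeansConfig) -> KMeansResult:
    """Cluster points into ``config.K`` groups; best of ``n_restarts`` runs.

    Deterministic for a given ``(points, config)``: restart seeds are derived
    from ``config.seed`` via a seed sequence.
    """
    config.validate()
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError(f"points must be (N, F), got shape {points.shape}")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite values")
    n = points.shape[0]
    if n < config.K:
        raise ValueError(f"need at least K={config.K} points, got {n}")

    fit_points = points
    predict_all = False
    ss = np.random.SeedSequence(config.seed)
    if config.subsample is not None and n > config.subsample:
        sub_rng = np.random.default_rng(ss.spawn(1)[0])
        idx = sub_rng.choice(n, size=config.subsample, replace=False)
        fit_points = points[idx]
        predict_all = True

    best: tuple | None = None
    restart_objs: list[float] = []
    for child in ss.spawn(config.n_restarts):
        rng = np.random.default_rng(child)
        centroids, assign, obj, n_iter, history = _lloyd(
            fit_points, config.K, config, rng
        )
        restart_objs.append(obj)
        if best is None or obj < best[2]:
            best = (centroids, assign, obj, n_iter, history)
    assert best is not None
    centroids, assign, obj, n_iter, history = best
    if predict_all:
        d2 = cdist(points, centroids, "sqeuclidean")
        assign = np.argmin(d2, axis=1)
        obj = float(d2[np.arange(n), assign].sum())
    return KMeansResult(
        centroids=centroids,
        assignments=assign,
        objective=obj,
        n_iter=n_iter,
        restart_objectives=restart_objs,
        objective_history=history,
    )


def segment_slice(
    features: FeatureStack, config: KMeansConfig
) -> tuple[np.ndarray, KMeansResult]:
    """Cluster a slice's pixels; returns the (H, W) label map and the fit."""
    h, w, _ = features.planes.shape
    result = kmeans(features.as_points(), config)
    return result.assignments.reshape(h, w), result


def harmonize_volume(
    per_slice_results: list[tuple[np.ndarray, KMeansResult]],
    appearance_indices: list[int] | None = None,
    class_names: dict[int, str] | None = None,
) -> LabelVolume:
    """Relabel per-slice clusters so each class keeps one index through depth.

    Slice 0's cluster indices are the reference.  Each subsequent slice's
    clusters are matched one-to-one to the previous (already harmonized)
    slice's clusters by minimizing total centroid distance over the
    appearance features only (spatial coordinate planes excluded via
    ``appearance_indices``), then relabeled accordingly.
    """
    if not per_slice_results:
        raise ValueError("no slices to harmonize")
    Ks = {r.centroids.shape[0] for _, r in per_slice_results}
    if len(Ks) > 1:
        raise ValueError(f"differing cluster counts across slices: {sorted(Ks)}")
    shapes = {lm.shape for lm, _ in per_slice_results}
    if len(shapes) > 1:
        raise ValueError(f"differing slice shapes: {sorted(shapes)}")

    first_map, first_res = per_slice_results[0]
    if appearance_indices is None:
        appearance_indices = list(range(first_res.centroids.shape[1]))
    out = [first_map.copy()]
    ref_centroids = first_res.centroids[:, appearance_indices]
    for label_map, res in per_slice_results[1:]:
        cur = res.centroids[:, appearance_indices]
        cost = cdist(ref_centroids, cur)  # rows: reference index, cols: current
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(len(rows), dtype=np.int64)
        for r, c in zip(rows, cols):
            perm[c] = r  # current cluster c becomes reference index r
        out.append(perm[label_map])
        new_ref = np.empty_like(ref_centroids)
        for r, c in zip(rows, cols):
            new_ref[r] = cur[c]
        ref_centroids = new_ref
    names = class_names or {k: f"cluster_{k}" for k in range(next(iter(Ks)))}
    return LabelVolume(data=np.stack(out), class_names=names)
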