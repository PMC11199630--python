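"""dCrawler: threshold-distance unsupervised clustering.

The only input is a threshold distance Th(d); no cluster count, density
kernel, or spread assumption is needed.  Three phases repeat until the
assignment is stable:

* **crawl** — points are visited in order; a point within Th(d) of an
  existing centroid joins that cluster (the centroid updates immediately),
  otherwise it seeds a new cluster.  The first point is always the first
  cluster.
* **adjust** — points are re-allocated to their nearest centroid and
  centroids recomputed, iterated to a fixed point, removing the primacy
  bias of the crawl.
* **merge** — while any two centroids are within the merge threshold they
  are fused (closest pair first); points left farther than Th(d) from
  their new centroid are unassigned and re-enter the next crawl.

To guarantee termination, the merge threshold decays by a factor 0.99 per
loop after 20 loops.  At convergence every point is within Th(d) of its
centroid.  Centroids are magnitude-weighted means of member colour
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colour_space import ColourVector

__all__ = ["ClusterSet", "crawl", "adjust", "merge", "dcrawler"]

UNASSIGNED = -1


def _as_arrays(points):
    """(values matrix, weights vector) from ColourVectors or raw arrays."""
    vals = np.stack(
        [p.values if isinstance(p, ColourVector) else np.asarray(p, float)
         for p in points]
    )
    w = np.array(
        [p.magnitude if isinstance(p, ColourVector) else 1.0 for p in points]
    )
    return vals, w


@dataclass
class ClusterSet:
    """Assignment of points to clusters plus per-cluster centroids."""

    assignments: np.ndarray           # (n,) int, UNASSIGNED allowed pre-convergence
    centroids: np.ndarray             # (k, d)
    th_d: float
    n_loops: int = 0
    final_merge_threshold: float = None

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.final_merge_threshold is None:
            self.final_merge_threshold = self.th_d

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def compact(self, values: np.ndarray, weights: np.ndarray) -> "ClusterSet":
        """Drop empty clusters and renumber ids contiguously."""
        used = np.unique(self.assignments[self.assignments != UNASSIGNED])
        remap = {old: new for new, old in enumerate(used)}
        assignments = np.array(
            [remap.get(a, UNASSIGNED) for a in self.assignments]
        )
        centroids = _centroids_of(values, weights, assignments, len(used))
        return ClusterSet(
            assignments, centroids, self.th_d, self.n_loops,
            self.final_merge_threshold,
        )


def _centroids_of(values, weights, assignments, k):
    cents = np.zeros((k, values.shape[1]))
    for c in range(k):
        sel = assignments == c
        w = weights[sel]
        total = w.sum()
        if total > 0:
            cents[c] = (w[:, None] * values[sel]).sum(axis=0) / total
        elif sel.any():
            cents[c] = values[sel].mean(axis=0)
    return cents


def crawl(values, weights, assignments, centroids, th_d):
    """Accrete every unassigned point in input order.

    A point joins the nearest centroid within th_d (ties by lowest cluster
    id via argmin) and that centroid is updated immediately; otherwise the
    point seeds a new cluster.  Returns (assignments, centroids) with
    running per-cluster weight totals maintained internally.
    """
    assignments = assignments.copy()
    cents = [c.copy() for c in centroids]
    totals = []
    for c in range(len(cents)):
        sel = assignments == c
        totals.append(weights[sel].sum())
    for i in np.flatnonzero(assignments == UNASSIGNED):
        if cents:
            d = np.linalg.norm(np.stack(cents) - values[i], axis=1)
            j = int(np.argmin(d))
            if d[j] <= th_d:
                w = weights[i]
                new_total = totals[j] + w
                if new_total > 0:
                    cents[j] = (cents[j] * totals[j] + values[i] * w) / new_total
                totals[j] = new_total
                assignments[i] = j
                continue
        assignments[i] = len(cents)
        cents.append(values[i].copy())
        totals.append(weights[i])
    return assignments, np.stack(cents) if cents else np.empty((0, values.shape[1]))


def adjust(values, weights, assignments, centroids, max_iter: int = 100):
    """Nearest-centroid reassignment iterated to a fixed point.

    Ties go to the lowest cluster id (argmin convention).  Empty clusters
    keep their last centroid so ids stay stable within the loop.

    Centroids are recomputed from the incoming assignment before the first
    reassignment: the previous merge phase may have evicted points without
    updating the survivors' centroids.
    """
    assignments = assignments.copy()
    fresh = _centroids_of(values, weights, assignments, len(centroids))
    occupied = np.isin(np.arange(len(centroids)), assignments)
    cents = np.where(occupied[:, None], fresh, centroids)
    for _ in range(max_iter):
        d = np.linalg.norm(values[:, None, :] - cents[None, :, :], axis=2)
        new = np.argmin(d, axis=1)
        if np.array_equal(new, assignments):
            return assignments, cents
        assignments = new
        fresh = _centroids_of(values, weights, assignments, len(cents))
        occupied = np.isin(np.arange(len(cents)), assignments)
        cents = np.where(occupied[:, None], fresh, cents)
    import warnings

    warnings.warn("adjust phase hit the iteration cap without converging",
                  stacklevel=2)
    return assignments, cents


def merge(values, weights, assignments, centroids, merge_threshold, th_d):
    """Fuse centroid pairs closer than the merge threshold, closest first.

    After each fusion the merged centroid is the weighted centroid of the
    combined membership.  Once no pair remains within the threshold,
    points farther than th_d from their centroid are unassigned.
    """
    assignments = assignments.copy()
    cents = centroids.copy()
    k = len(cents)
    alive = np.ones(k, dtype=bool)
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        sub = cents[idx]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        flat = np.argmin(d)
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > merge_threshold:
            break
        a, b = sorted((idx[i], idx[j]))
        assignments[assignments == b] = a
        alive[b] = False
        sel = assignments == a
        w = weights[sel]
        total = w.sum()
        if total > 0:
            cents[a] = (w[:, None] * values[sel]).sum(axis=0) / total
        elif sel.any():
            cents[a] = values[sel].mean(axis=0)
    # evict points outside th_d of their (possibly moved) centroid
    for c in np.flatnonzero(alive):
        sel = assignments == c
        if not sel.any():
            alive[c] = False
            continue
        far = np.linalg.norm(values[sel] - cents[c], axis=1) > th_d
        if far.any():
            ids = np.flatnonzero(sel)[far]
            assignments[ids] = UNASSIGNED
    # renumber alive clusters contiguously
    remap = {old: new for new, old in enumerate(np.flatnonzero(alive))}
    assignments = np.array(
        [remap.get(a, UNASSIGNED) for a in assignments]
    )
    cents = cents[np.flatnonzero(alive)]
    return assignments, cents


def dcrawler(
    points,
    th_d: float,
    order: str = "input",
    decay_after: int = 20,
    decay: float = 0.99,
    max_loops: int = 1000,
) -> ClusterSet:
    """Run dCrawler to a stable solution.

    Parameters
    ----------
    points : sequence of ColourVector (or raw arrays)
        Points to cluster; magnitudes weight the centroid updates.
    th_d : float
        The threshold distance Th(d).
    order : {"input", "magnitude"}
        Crawl order; "magnitude" visits brighter (more reliable) points
        first.
    decay_after, decay : int, float
        After ``decay_after`` outer loops the merge threshold is multiplied
        by ``decay`` each loop, which guarantees eventual stability.

    Returns a :class:`ClusterSet`; at convergence every point lies within
    th_d of its centroid and centroids are pairwise separated by more than
    the final merge threshold.
    """
    if th_d <= 0:
        raise ValueError("th_d must be > 0")
    pts = list(points)
    if not pts:
        raise ValueError("no points to cluster")
    values, weights = _as_arrays(pts)
    n = len(values)
    perm = np.arange(n)
    if order == "magnitude":
        perm = np.argsort(-weights, kind="stable")
    elif order != "input":
        raise ValueError("order must be 'input' or 'magnitude'")
    v, w = values[perm], weights[perm]

    assignments = np.full(n, UNASSIGNED)
    centroids = np.empty((0, values.shape[1]))
    merge_threshold = th_d
    prev = None
    for loop in range(1, max_loops + 1):
        assignments, centroids = crawl(v, w, assignments, centroids, th_d)
        assignments, centroids = adjust(v, w, assignments, centroids)
        assignments, centroids = merge(
            v, w, assignments, centroids, merge_threshold, th_d
        )
        if (
            prev is not None
            and np.array_equal(assignments, prev)
            and (assignments != UNASSIGNED).all()
        ):
            break
        prev = assignments.copy()
        if loop >= decay_after:
            merge_threshold *= decay
    else:
        raise RuntimeError("dCrawler exceeded the loop cap without stabilizing")

    # undo the crawl-order permutation
    out = np.empty(n, dtype=int)
    out[perm] = assignments
    cs = ClusterSet(out, centroids, th_d, n_loops=loop,
                    final_merge_threshold=merge_threshold)
    return cs.compact(values, weights)
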