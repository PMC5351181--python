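"""CURE agglomerative clustering with representative points and shrinkage.

Each cluster is summarised by up to ``num_rep`` well-scattered representative
points, chosen farthest-first from the member points and shrunk toward the
centroid by the factor ``alpha``.  Inter-cluster distance is the minimum
Euclidean distance between representative points, which lets the procedure
find non-spherical clusters while staying robust to outliers.  Two noise
rules apply: during merging, a small cluster that has not participated in a
merge for ``stall_rounds`` rounds is removed; after merging, clusters holding
less than a ``small_cluster_fraction`` share of the points are removed.

The minority classes this is applied to are small, so representatives are
recomputed exactly from the member points at every merge rather than updated
incrementally.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Cluster",
    "CureParams",
    "euclidean_distance",
    "cluster_distance",
    "merge_clusters",
    "select_representatives",
    "cure_cluster",
    "CureClusterer",
    "write_cluster_debug",
]


@dataclass
class Cluster:
    """A CURE cluster: member indices, centroid and shrunk representatives."""

    members: list
    centroid: np.ndarray
    representatives: list
    merge_age: int = 0
    cid: int = -1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CureParams:
    """CURE tuning knobs.

    ``n_clusters`` is the stopping cluster count; ``num_rep`` the maximum
    representatives per cluster; ``alpha`` the shrinkage toward the centroid
    (0 = none, 1 = collapse onto the centroid); ``stall_rounds`` the merge
    stagnation budget before a small cluster is declared noise;
    ``small_cluster_fraction`` the small-cluster threshold, defaulting to
    ``1/(10 * n_clusters)`` of the points being clustered.
    """

    n_clusters: int = 5
    num_rep: int = 15
    alpha: float = 0.5
    stall_rounds: int = 10
    small_cluster_fraction: float = None

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.num_rep < 1:
            raise ValueError("num_rep must be >= 1")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0,1]")
        if self.small_cluster_fraction is None:
            self.small_cluster_fraction = 1.0 / (10.0 * self.n_clusters)


def euclidean_distance(a, b) -> float:
    """Plain Euclidean distance between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch in euclidean_distance")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def cluster_distance(u: Cluster, v: Cluster) -> float:
    """Minimum distance over all pairs of representative points."""
    if not u.representatives or not v.representatives:
        raise ValueError("cluster has an empty representative set")
    pu = np.asarray(u.representatives)
    pv = np.asarray(v.representatives)
    diff = pu[:, None, :] - pv[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def select_representatives(points: np.ndarray, centroid: np.ndarray,
                           num_rep: int) -> list:
    """Farthest-first scatter selection (unshrunk).

    The first representative is the point farthest from the centroid; each
    subsequent one maximises the minimum distance to the already-chosen set.
    Ties break toward the lowest row index.  When there are at most
    ``num_rep`` points, all of them are selected (in farthest-first order).
    """
    n = points.shape[0]
    k = min(num_rep, n)
    chosen = []
    d = np.sqrt(((points - centroid) ** 2).sum(axis=1))
    first = int(np.argmax(d))  # argmax takes the lowest index on ties
    chosen.append(first)
    mind = np.sqrt(((points - points[first]) ** 2).sum(axis=1))
    while len(chosen) < k:
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.sqrt(((points - points[nxt]) ** 2).sum(axis=1)))
    return chosen


def _shrink(points, centroid, alpha):
    return [p + alpha * (centroid - p) for p in points]


def merge_clusters(u: Cluster, v: Cluster, params: CureParams,
                   all_points: np.ndarray = None, cid: int = -1) -> Cluster:
    """Merge two disjoint clusters.

    The centroid is the size-weighted mean of the two centroids; the
    representatives are recomputed farthest-first from the merged member
    points and shrunk by ``alpha`` toward the new centroid.  ``all_points``
    is the coordinate array the member indices refer to; when omitted, the
    union of the parents' (unshrunk) representative points is used.
    """
    if set(u.members) & set(v.members):
        raise ValueError("clusters share member indices")
    nu, nv = u.size, v.size
    centroid = (nu * u.centroid + nv * v.centroid) / (nu + nv)
    members = list(u.members) + list(v.members)
    if all_points is None:
        raise ValueError("all_points is required to recompute representatives")
    pts = all_points[np.asarray(members, dtype=int)]
    sel = select_representatives(pts, centroid, params.num_rep)
    reps = _shrink([pts[i].astype(float) for i in sel], centroid, params.alpha)
    return Cluster(members, centroid, reps, merge_age=0, cid=cid)


def cure_cluster(points: np.ndarray, params: CureParams):
    """Agglomerate ``points`` down to ``params.n_clusters`` CURE clusters.

    Returns ``(clusters, noise_indices, merge_log)`` where ``merge_log``
    records, per merge round, the member-index sets of the two clusters
    merged (useful for comparing merge order against reference linkage
    implementations).  ``noise_indices`` collects members of clusters removed
    by either noise rule.  Distance ties break toward the lowest
    ``(cluster id, cluster id)`` pair; ids are assigned in input order and
    then in merge-creation order.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < params.n_clusters:
        raise ValueError("fewer points than requested clusters")
    clusters = {}
    for i in range(n):
        clusters[i] = Cluster([i], points[i].astype(float),
                              [points[i].astype(float)], merge_age=0, cid=i)
    next_id = n
    heap = []
    ids = sorted(clusters)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            heapq.heappush(heap, (cluster_distance(clusters[ids[a]], clusters[ids[b]]),
                                  ids[a], ids[b]))
    noise = []
    merge_log = []
    small = params.small_cluster_fraction * n
    # the stall rule activates only once agglomeration is underway (cluster
    # count down to a third of the points), echoing CURE's two-phase outlier
    # handling; stagnation is counted from activation, so a point that is
    # merely awaiting its turn early on is not mistaken for an outlier
    activation = max(n / 3.0, params.n_clusters)
    state = {"active": False}

    def remove_stalled():
        if not state["active"]:
            if len(clusters) > activation:
                return
            state["active"] = True
            for cl in clusters.values():
                cl.merge_age = 0
            return
        stalled = [cid for cid, cl in clusters.items()
                   if cl.merge_age > params.stall_rounds and cl.size < small]
        for cid in stalled:
            noise.extend(clusters[cid].members)
            del clusters[cid]

    while len(clusters) > params.n_clusters:
        # pop the nearest still-alive pair (stale heap entries reference dead ids)
        while heap:
            d, ia, ib = heapq.heappop(heap)
            if ia in clusters and ib in clusters:
                break
        else:
            break
        u, v = clusters.pop(ia), clusters.pop(ib)
        merged = merge_clusters(u, v, params, all_points=points, cid=next_id)
        merge_log.append((frozenset(u.members), frozenset(v.members)))
        for cl in clusters.values():
            cl.merge_age += 1
        clusters[next_id] = merged
        for cid, cl in clusters.items():
            if cid != next_id:
                heapq.heappush(
                    heap,
                    (cluster_distance(merged, cl), min(cid, next_id), max(cid, next_id)),
                )
        next_id += 1
        remove_stalled()

    # final small-cluster sweep
    for cid in list(clusters):
        if clusters[cid].size < small:
            noise.extend(clusters[cid].members)
            del clusters[cid]

    if not clusters:
        warnings.warn("every cluster was removed as noise", stacklevel=2)
        return [], sorted(noise), merge_log
    if len(clusters) < params.n_clusters:
        warnings.warn("noise removal left fewer clusters than requested",
                      stacklevel=2)
    ordered = [clusters[cid] for cid in sorted(clusters)]
    return ordered, sorted(noise), merge_log


class CureClusterer:
    """Estimator-style wrapper around :func:`cure_cluster`.

    After :meth:`fit`, ``labels_`` assigns each point its cluster index
    (``-1`` for noise), ``clusters_`` holds :class:`Cluster` objects and
    ``noise_indices_`` the removed points.
    """

    def __init__(self, n_clusters=5, num_rep=15, alpha=0.5,
                 stall_rounds=10, small_cluster_fraction=None):
        self.n_clusters = n_clusters
        self.num_rep = num_rep
        self.alpha = alpha
        self.stall_rounds = stall_rounds
        self.small_cluster_fraction = small_cluster_fraction

    def get_params(self, deep=True):
        return {
            "n_clusters": self.n_clusters,
            "num_rep": self.num_rep,
            "alpha": self.alpha,
            "stall_rounds": self.stall_rounds,
            "small_cluster_fraction": self.small_cluster_fraction,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _params(self) -> CureParams:
        return CureParams(self.n_clusters, self.num_rep, self.alpha,
                          self.stall_rounds, self.small_cluster_fraction)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        clusters, noise, log = cure_cluster(X, self._params())
        self.clusters_ = clusters
        self.noise_indices_ = np.asarray(noise, dtype=int)
        self.merge_log_ = log
        labels = np.full(X.shape[0], -1, dtype=int)
        for k, cl in enumerate(clusters):
            labels[np.asarray(cl.members, dtype=int)] = k
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def write_cluster_debug(path, points, clusterer: CureClusterer,
                        delimiter=",") -> None:
    """Dump points with cluster id / representative / noise flags as text."""
    points = np.asarray(points, dtype=float)
    rows = []
    for k, cl in enumerate(clusterer.clusters_):
        for r in cl.representatives:
            rows.append((r, k, 1, 0))
    for i, p in enumerate(points):
        k = int(clusterer.labels_[i])
        rows.append((p, k, 0, 1 if k == -1 else 0))
    with open(path, "w") as fh:
        fh.write(delimiter.join(["coords", "cluster", "is_representative", "is_noise"]) + "\n")
        for p, k, is_rep, is_noise in rows:
            coord = ";".join(f"{v:.6g}" for v in np.atleast_1d(p))
            fh.write(delimiter.join([coord, str(k), str(is_rep), str(is_noise)]) + "\n")
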