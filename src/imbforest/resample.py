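"""Minority-class oversamplers with per-point provenance.

Seven samplers share one contract: original rows are preserved verbatim and
in order, synthetic minority rows are appended one at a time until the
imbalance ratio (minority/majority) strictly exceeds ``target_ir``, and every
synthetic row is reproducible bitwise from its provenance record as
``origin + rand * (anchor - origin)``.

* ``RandomOversampler`` – duplicate uniformly drawn minority rows.
* ``Smote`` – interpolate toward one of the k nearest minority neighbours.
* ``BorderlineSmote1`` – interpolate only from "danger" minority points,
  those whose all-class neighbourhood is between half and fully majority.
* ``SafeLevelSmote`` – bias the interpolation gap toward the safer end of
  the segment using minority counts in each endpoint's neighbourhood.
* ``CentroidSmote`` – interpolate from minority points toward the minority
  mean (C-SMOTE).
* ``KMeansSmote`` – k-means on the minority class, then within-cluster
  interpolation proportional to cluster size.
* ``CureSmote`` – CURE-cluster the minority class (noise removed), then
  interpolate between retained minority points and their cluster's shrunk
  representative points, in min-max normalized space.

The estimators follow the ``fit_resample(X, y)`` convention; the fitted
``result_`` attribute carries the full :class:`OversampleResult`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .cure import CureParams, cure_cluster
from .datasets import (LabeledDataset, apply_minmax, imbalance_ratio,
                       minmax_params)

__all__ = [
    "ProvenanceRecord",
    "OversampleResult",
    "BaseOversampler",
    "RandomOversampler",
    "Smote",
    "BorderlineSmote1",
    "SafeLevelSmote",
    "CentroidSmote",
    "KMeansSmote",
    "CureSmote",
    "SAMPLERS",
    "random_oversample",
    "smote",
    "borderline_smote1",
    "safe_level_smote",
    "c_smote",
    "kmeans_smote",
    "cure_smote",
    "replay_synthetic",
    "write_provenance",
]


@dataclass
class ProvenanceRecord:
    """How one synthetic row was generated."""

    method: str
    origin_index: int          # row index into the output dataset
    origin: np.ndarray         # coordinates of the interpolation origin
    anchor: np.ndarray         # coordinates of the interpolation target
    rand: float                # draw in [0, 1)
    extra: dict = field(default_factory=dict)


@dataclass
class OversampleResult:
    """Augmented dataset plus per-synthetic-row provenance."""

    dataset: LabeledDataset
    synthetic_index: np.ndarray
    provenance: list
    achieved_ir: float
    warnings: list = field(default_factory=list)


def replay_synthetic(record: ProvenanceRecord) -> np.ndarray:
    """Recompute a synthetic row from its provenance record."""
    return record.origin + record.rand * (record.anchor - record.origin)


def write_provenance(path, result: OversampleResult, delimiter=",") -> None:
    """One line per synthetic row: method, origin index, anchor, rand."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(
            ["row", "method", "origin_index", "anchor", "rand"]) + "\n")
        for row, rec in zip(result.synthetic_index.tolist(), result.provenance):
            anchor = ";".join(f"{v!r}" for v in rec.anchor)
            fh.write(delimiter.join(
                [str(row), rec.method, str(rec.origin_index), anchor,
                 repr(rec.rand)]) + "\n")


def _knn_indices(X, i, k, candidates=None):
    """Indices of the k nearest rows to X[i] (self excluded); distance ties
    break toward the lower index via a stable sort."""
    cand = np.arange(X.shape[0]) if candidates is None else np.asarray(candidates)
    cand = cand[cand != i]
    d = np.sqrt(((X[cand] - X[i]) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")
    return cand[order[:k]]


class BaseOversampler(BaseEstimator):
    """Shared generation loop: append synthetic minority rows until the
    imbalance ratio strictly exceeds ``target_ir``, checked after each row."""

    method_name = "base"

    def __init__(self, target_ir=0.7, positive_label=None, random_state=None):
        self.target_ir = target_ir
        self.positive_label = positive_label
        self.random_state = random_state

    # subclasses yield (row_vector, ProvenanceRecord) indefinitely (or stop
    # early with a warning when they cannot generate any more points)
    def _generate(self, X, y, minority, majority, rng):
        raise NotImplementedError

    def _prepare(self, X, y):
        """Hook for samplers that transform the feature space (CURE-SMOTE
        normalizes); default is the identity."""
        return X

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) != 2:
            raise ValueError("oversamplers require exactly two classes")
        if self.positive_label is not None:
            minority = self.positive_label
        else:
            minority = labels[np.argmin(counts)]
        majority = [l for l in labels if l != minority][0]
        n_min = int((y == minority).sum())
        n_maj = int((y == majority).sum())
        if n_min == 0:
            raise ValueError("no minority samples to oversample")
        rng = np.random.RandomState(self.random_state)
        X_work = self._prepare(X, y)

        caught = []
        rows, provs = [], []
        n_syn = 0
        if n_min / n_maj <= self.target_ir:
            # upper bound on useful points plus slack for skip-prone methods
            need = int(np.ceil(self.target_ir * n_maj)) - n_min + 1
            cap = 10 * need + 1000
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                gen = self._generate(X_work, y, minority, majority, rng)
                for row, prov in gen:
                    prov.origin_index = int(prov.origin_index)
                    prov.method = self.method_name
                    rows.append(np.asarray(row, dtype=float))
                    provs.append(prov)
                    n_syn += 1
                    if (n_min + n_syn) / n_maj > self.target_ir:
                        break
                    if n_syn >= cap:
                        warnings.warn("synthetic-point cap reached before the "
                                      "target imbalance ratio", stacklevel=2)
                        break
            caught = [str(w.message) for w in wlist]

        X_out = np.vstack([X_work] + rows) if rows else X_work.copy()
        y_out = np.concatenate([y, np.full(len(rows), minority, dtype=y.dtype)])
        self.minority_label_ = minority
        self.majority_label_ = majority
        ds = LabeledDataset(X_out, y_out, positive_label=minority)
        self.result_ = OversampleResult(
            dataset=ds,
            synthetic_index=np.arange(len(y), len(y_out)),
            provenance=provs,
            achieved_ir=imbalance_ratio(y_out),
            warnings=caught,
        )
        for msg in caught:
            warnings.warn(msg, stacklevel=2)
        return X_out, y_out

    def sample(self, ds: LabeledDataset) -> OversampleResult:
        """Convenience wrapper taking and returning :class:`LabeledDataset`."""
        if self.positive_label is None and ds.positive_label is not None:
            self.positive_label = ds.positive_label
        self.fit_resample(ds.features, ds.labels)
        self.result_.dataset.feature_names = list(ds.feature_names)
        return self.result_


class RandomOversampler(BaseOversampler):
    """Duplicate uniformly drawn minority rows (with replacement)."""

    method_name = "random"

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        while True:
            i = int(min_idx[rng.randint(len(min_idx))])
            yield X[i].copy(), ProvenanceRecord(
                self.method_name, i, X[i].copy(), X[i].copy(), 0.0)


class _SmoteMixin:
    """k-nearest-minority bookkeeping shared by the SMOTE family."""

    def _minority_knn(self, X, min_idx, k):
        if len(min_idx) <= k:
            warnings.warn(
                f"minority size {len(min_idx)} <= k_neighbors {k}; "
                f"reducing k to {len(min_idx) - 1}", stacklevel=2)
            k = max(len(min_idx) - 1, 0)
        return {int(i): _knn_indices(X, int(i), k, candidates=min_idx)
                for i in min_idx}, k


class Smote(BaseOversampler, _SmoteMixin):
    """Classic SMOTE: interpolate between a minority point and one of its k
    nearest minority neighbours, balanced round-robin over origins."""

    method_name = "smote"

    def __init__(self, k_neighbors=5, target_ir=0.7, positive_label=None,
                 random_state=None):
        super().__init__(target_ir, positive_label, random_state)
        self.k_neighbors = k_neighbors

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        knn, k = self._minority_knn(X, min_idx, self.k_neighbors)
        while True:
            for i in rng.permutation(min_idx):
                i = int(i)
                nbrs = knn[i]
                if len(nbrs) == 0:
                    j = i  # single minority point: duplicate
                else:
                    j = int(nbrs[rng.randint(len(nbrs))])
                r = float(rng.uniform())
                row = X[i] + r * (X[j] - X[i])
                yield row, ProvenanceRecord(
                    self.method_name, i, X[i].copy(), X[j].copy(), r)


class BorderlineSmote1(BaseOversampler, _SmoteMixin):
    """Borderline-SMOTE1: interpolation origins restricted to danger points.

    A minority point's m nearest neighbours in the whole set classify it:
    all-majority -> noisy (excluded), less than half majority -> safe
    (excluded), at least half but not all majority -> danger (retained).
    """

    method_name = "borderline1"

    def __init__(self, k_neighbors=5, m_neighbors=20, target_ir=0.7,
                 positive_label=None, random_state=None):
        super().__init__(target_ir, positive_label, random_state)
        self.k_neighbors = k_neighbors
        self.m_neighbors = m_neighbors

    @staticmethod
    def classify_minority(X, y, minority, m):
        """Return dict index -> 'noisy'|'safe'|'danger' for minority points."""
        out = {}
        m_eff = min(m, X.shape[0] - 1)
        for i in np.flatnonzero(y == minority):
            nbrs = _knn_indices(X, int(i), m_eff)
            k_prime = int((y[nbrs] != minority).sum())
            if k_prime == m_eff:
                out[int(i)] = "noisy"
            elif k_prime < m_eff / 2:
                out[int(i)] = "safe"
            else:
                out[int(i)] = "danger"
        return out

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        cls = self.classify_minority(X, y, minority, self.m_neighbors)
        danger = np.array([i for i in min_idx if cls[int(i)] == "danger"])
        if len(danger) == 0:
            warnings.warn("no danger points found; falling back to plain "
                          "SMOTE over all minority points", stacklevel=2)
            danger = min_idx
        knn, k = self._minority_knn(X, min_idx, self.k_neighbors)
        while True:
            for i in rng.permutation(danger):
                i = int(i)
                nbrs = knn[i]
                j = i if len(nbrs) == 0 else int(nbrs[rng.randint(len(nbrs))])
                r = float(rng.uniform())
                row = X[i] + r * (X[j] - X[i])
                yield row, ProvenanceRecord(
                    self.method_name, i, X[i].copy(), X[j].copy(), r,
                    {"class": "danger"})


class SafeLevelSmote(BaseOversampler, _SmoteMixin):
    """Safe-level SMOTE: the interpolation gap is biased toward whichever
    endpoint sits in the more minority-dense neighbourhood.

    The safe level sl(x) is the minority count among the m nearest
    neighbours of x in the whole set.  With origin p and minority
    neighbour q the gap follows the five-case scheme:

    1. sl(p)=0 and sl(q)=0  -> skip the pair (nothing generated);
    2. sl(q)=0, sl(p)>0     -> gap = 0 (duplicate p);
    3. sl(p)=sl(q)          -> gap ~ U(0, 1);
    4. sl(p)>sl(q)          -> gap ~ U(0, sl(q)/sl(p));
    5. sl(p)<sl(q)          -> gap ~ U(1 - sl(p)/sl(q), 1).
    """

    method_name = "safelevel"

    def __init__(self, k_neighbors=5, m_neighbors=20, target_ir=0.7,
                 positive_label=None, random_state=None):
        super().__init__(target_ir, positive_label, random_state)
        self.k_neighbors = k_neighbors
        self.m_neighbors = m_neighbors

    @staticmethod
    def gap(sl_p, sl_q, rng):
        """Draw the interpolation gap for one (origin, neighbour) pair;
        returns None when the pair must be skipped."""
        if sl_p == 0 and sl_q == 0:
            return None
        if sl_q == 0:
            return 0.0
        ratio = sl_p / sl_q
        if ratio == 1.0:
            return float(rng.uniform(0.0, 1.0))
        if ratio > 1.0:
            return float(rng.uniform(0.0, 1.0 / ratio))
        return float(rng.uniform(1.0 - ratio, 1.0))

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        m_eff = min(self.m_neighbors, X.shape[0] - 1)
        sl = {int(i): int((y[_knn_indices(X, int(i), m_eff)] == minority).sum())
              for i in min_idx}
        knn, k = self._minority_knn(X, min_idx, self.k_neighbors)
        while True:
            emitted = False
            for i in rng.permutation(min_idx):
                i = int(i)
                nbrs = knn[i]
                j = i if len(nbrs) == 0 else int(nbrs[rng.randint(len(nbrs))])
                g = self.gap(sl[i], sl[j], rng)
                if g is None:
                    continue
                emitted = True
                row = X[i] + g * (X[j] - X[i])
                yield row, ProvenanceRecord(
                    self.method_name, i, X[i].copy(), X[j].copy(), g,
                    {"sl_p": sl[i], "sl_q": sl[j]})
            if not emitted:
                warnings.warn("safe-level SMOTE skipped every pair; no "
                              "synthetic points generated", stacklevel=2)
                return


class CentroidSmote(BaseOversampler):
    """C-SMOTE: interpolate from minority points toward the minority mean."""

    method_name = "csmote"

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        centre = X[min_idx].mean(axis=0)
        while True:
            i = int(min_idx[rng.randint(len(min_idx))])
            r = float(rng.uniform())
            row = X[i] + r * (centre - X[i])
            yield row, ProvenanceRecord(
                self.method_name, i, X[i].copy(), centre.copy(), r)


def _kmeans(X, k, rng, max_iter=100, tol=1e-6):
    """Seeded Lloyd k-means: initial centres drawn from the data points,
    100-iteration cap, relative centre-shift tolerance 1e-6; an emptied
    cluster is reseeded to a random data point.  Assignment ties break to
    the lower cluster index."""
    n = X.shape[0]
    centres = X[rng.choice(n, size=k, replace=False)].astype(float)
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d, axis=1)
        new = centres.copy()
        for c in range(k):
            mask = labels == c
            if mask.any():
                new[c] = X[mask].mean(axis=0)
            else:
                new[c] = X[rng.randint(n)]
        shift = np.sqrt(((new - centres) ** 2).sum())
        scale = max(np.sqrt((centres ** 2).sum()), 1e-12)
        centres = new
        if shift / scale < tol:
            break
    d = ((X[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d, axis=1)
    return labels, centres


class KMeansSmote(BaseOversampler, _SmoteMixin):
    """k-means clustering of the minority class followed by within-cluster
    SMOTE interpolation, sampled proportionally to cluster size; singleton
    clusters duplicate their point."""

    method_name = "kmeans"

    def __init__(self, n_clusters=5, k_neighbors=5, target_ir=0.7,
                 positive_label=None, random_state=None):
        super().__init__(target_ir, positive_label, random_state)
        self.n_clusters = n_clusters
        self.k_neighbors = k_neighbors

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        k_clusters = self.n_clusters
        if len(min_idx) < k_clusters:
            warnings.warn(
                f"minority size {len(min_idx)} < n_clusters {k_clusters}; "
                "reducing the cluster count", stacklevel=2)
            k_clusters = len(min_idx)
        labels, _ = _kmeans(X[min_idx], k_clusters, rng)
        members = [min_idx[labels == c] for c in range(k_clusters)]
        sizes = np.array([len(mm) for mm in members], dtype=float)
        probs = sizes / sizes.sum()
        knn_cache = {}
        while True:
            c = int(rng.choice(k_clusters, p=probs))
            mm = members[c]
            i = int(mm[rng.randint(len(mm))])
            if len(mm) == 1:
                yield X[i].copy(), ProvenanceRecord(
                    self.method_name, i, X[i].copy(), X[i].copy(), 0.0,
                    {"cluster": c})
                continue
            if i not in knn_cache:
                kk = min(self.k_neighbors, len(mm) - 1)
                knn_cache[i] = _knn_indices(X, i, kk, candidates=mm)
            nbrs = knn_cache[i]
            j = int(nbrs[rng.randint(len(nbrs))])
            r = float(rng.uniform())
            row = X[i] + r * (X[j] - X[i])
            yield row, ProvenanceRecord(
                self.method_name, i, X[i].copy(), X[j].copy(), r,
                {"cluster": c})


class CureSmote(BaseOversampler):
    """CURE-SMOTE: normalize, CURE-cluster the minority class to drop noise
    and outliers, then interpolate between retained minority points and their
    cluster's shrunk representative points.

    The whole dataset is min-max normalized first and the result is returned
    in normalized space (downstream classification happens there); the
    fitted ``norm_lo_``/``norm_range_`` attributes let callers map held-out
    data into the same space.
    """

    method_name = "cure"

    def __init__(self, n_clusters=5, num_rep=15, alpha=0.5, stall_rounds=10,
                 small_cluster_fraction=None, target_ir=0.7,
                 positive_label=None, random_state=None):
        super().__init__(target_ir, positive_label, random_state)
        self.n_clusters = n_clusters
        self.num_rep = num_rep
        self.alpha = alpha
        self.stall_rounds = stall_rounds
        self.small_cluster_fraction = small_cluster_fraction

    def _prepare(self, X, y):
        self.norm_lo_, self.norm_range_ = minmax_params(X)
        return apply_minmax(X, self.norm_lo_, self.norm_range_)

    def transform(self, X):
        """Map new rows into the normalized space of the resampled data."""
        return apply_minmax(np.asarray(X, dtype=float),
                            self.norm_lo_, self.norm_range_)

    def _generate(self, X, y, minority, majority, rng):
        min_idx = np.flatnonzero(y == minority)
        params = CureParams(
            n_clusters=min(self.n_clusters, len(min_idx)),
            num_rep=self.num_rep, alpha=self.alpha,
            stall_rounds=self.stall_rounds,
            small_cluster_fraction=self.small_cluster_fraction)
        clusters, noise, _ = cure_cluster(X[min_idx], params)
        self.clusters_ = clusters
        self.noise_indices_ = min_idx[np.asarray(noise, dtype=int)] \
            if len(noise) else np.array([], dtype=int)
        retained = []
        owner = {}
        for k, cl in enumerate(clusters):
            for local in cl.members:
                gi = int(min_idx[local])
                retained.append(gi)
                owner[gi] = k
        if not retained:
            raise ValueError("minority class entirely removed as noise")
        retained = np.array(sorted(retained))
        while True:
            i = int(retained[rng.randint(len(retained))])
            cl = clusters[owner[i]]
            rep = cl.representatives[rng.randint(len(cl.representatives))]
            r = float(rng.uniform())
            row = X[i] + r * (rep - X[i])
            yield row, ProvenanceRecord(
                self.method_name, i, X[i].copy(), np.asarray(rep, float).copy(),
                r, {"cluster": owner[i]})


SAMPLERS = {
    "random": RandomOversampler,
    "smote": Smote,
    "borderline1": BorderlineSmote1,
    "safelevel": SafeLevelSmote,
    "csmote": CentroidSmote,
    "kmeans": KMeansSmote,
    "cure": CureSmote,
}


def _run(cls, ds, seed, **kw):
    return cls(random_state=seed, **kw).sample(ds)


def random_oversample(ds, target_ir=0.7, seed=0):
    return _run(RandomOversampler, ds, seed, target_ir=target_ir)


def smote(ds, k_neighbors=5, target_ir=0.7, seed=0):
    return _run(Smote, ds, seed, k_neighbors=k_neighbors, target_ir=target_ir)


def borderline_smote1(ds, k_neighbors=5, m_neighbors=20, target_ir=0.7, seed=0):
    return _run(BorderlineSmote1, ds, seed, k_neighbors=k_neighbors,
                m_neighbors=m_neighbors, target_ir=target_ir)


def safe_level_smote(ds, k_neighbors=5, m_neighbors=20, target_ir=0.7, seed=0):
    return _run(SafeLevelSmote, ds, seed, k_neighbors=k_neighbors,
                m_neighbors=m_neighbors, target_ir=target_ir)


def c_smote(ds, target_ir=0.7, seed=0):
    return _run(CentroidSmote, ds, seed, target_ir=target_ir)


def kmeans_smote(ds, n_clusters=5, k_neighbors=5, target_ir=0.7, seed=0):
    return _run(KMeansSmote, ds, seed, n_clusters=n_clusters,
                k_neighbors=k_neighbors, target_ir=target_ir)


def cure_smote(ds, n_clusters=5, num_rep=15, alpha=0.5, stall_rounds=10,
               target_ir=0.7, seed=0):
    return _run(CureSmote, ds, seed, n_clusters=n_clusters, num_rep=num_rep,
                alpha=alpha, stall_rounds=stall_rounds, target_ir=target_ir)
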