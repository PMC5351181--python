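"""CART random forest with bootstrap sampling, per-node random feature
subsets and out-of-bag (OOB) accounting.

Trees are grown by Gini minimisation over thresholds placed at midpoints
between consecutive distinct sorted feature values; at every node a fresh
uniform subset of ``kappa`` features (without replacement within the node)
is drawn from all features.  A branch stops at purity, ``max_depth``,
``min_leaf`` or when no valid split exists.  Prediction is majority voting
with ties going to the lexicographically smallest class label.

Two OOB error estimates are exposed: the per-tree average (each tree's
misclassification rate on the samples absent from its bootstrap, averaged
over trees) — the quantity minimised by the hybrid optimizers — and the
conventional aggregate-vote estimate.

The hot loops (tree growth, traversal) are numba-jitted; the module also
provides pure-Python ``gini``/``gini_split``/``best_split`` reference
functions whose split rule the jitted code replicates exactly (asserted in
the test suite).
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "gini",
    "gini_split",
    "best_split",
    "RandomForest",
    "train_forest",
    "predict",
    "oob_error",
    "margin",
    "bootstrap_distinct_fraction",
    "dump_forest",
]


# ---------------------------------------------------------------------------
# Pure-Python reference operations
# ---------------------------------------------------------------------------

def gini(labels) -> float:
    """Gini impurity 1 - sum(p_i^2) of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini of an empty multiset is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p ** 2))


def gini_split(labels, partition) -> float:
    """Size-weighted child impurity sum over a partition of ``labels``."""
    labels = np.asarray(labels)
    blocks = [np.asarray(b) for b in partition]
    total = sum(b.size for b in blocks)
    if total != labels.size or sorted(
            np.concatenate(blocks).tolist()) != sorted(labels.tolist()):
        raise ValueError("blocks do not partition the labels")
    return float(sum(b.size / total * gini(b) for b in blocks if b.size))


def best_split(X, y, candidate_features, min_leaf=1):
    """Best (feature, threshold) by Gini over candidate features.

    Thresholds are midpoints between consecutive distinct sorted values.
    Ties break toward the lowest feature index, then the lowest threshold
    (guaranteed by scanning features and thresholds in ascending order with
    a strict improvement test).  Returns ``(feature, threshold, score)`` or
    ``None`` when no split is valid (constant features, or every split
    violates ``min_leaf``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    candidate_features = sorted(int(f) for f in candidate_features)
    if len(candidate_features) == 0:
        raise ValueError("no candidate features")
    n = X.shape[0]
    classes, y_codes = np.unique(y, return_inverse=True)
    c = len(classes)
    # scores are compared as exact integer fractions so that ties (frequent
    # on small nodes) break deterministically by feature then threshold:
    # n * weighted_gini = (nl^2*nr - sl*nr + nr^2*nl - sr*nl) / (nl*nr)
    best = None          # (feature, threshold, num, den)
    for f in candidate_features:
        vals = X[:, f]
        order = np.argsort(vals, kind="mergesort")
        left = np.zeros(c, dtype=np.int64)
        total = np.bincount(y_codes, minlength=c).astype(np.int64)
        nl = 0
        for p in range(n - 1):
            o = order[p]
            left[y_codes[o]] += 1
            nl += 1
            v, vnext = vals[o], vals[order[p + 1]]
            if vnext <= v:
                continue
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sl = int(np.sum(left ** 2))
            sr = int(np.sum((total - left) ** 2))
            num = nl * nl * nr - sl * nr + nr * nr * nl - sr * nl
            den = nl * nr
            thr = 0.5 * (v + vnext)
            if best is None or num * best[3] < best[2] * den:
                best = (f, float(thr), num, den)
    if best is None:
        return None
    return best[0], best[1], best[2] / (best[3] * n)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _node_best_split(X, y_codes, idx, start, end, feats, n_classes, min_leaf):
    # exact integer score comparison, mirroring the pure-Python best_split
    n = end - start
    best_feat = -1
    best_thr = 0.0
    best_num = np.int64(0)
    best_den = np.int64(0)     # den == 0 marks "no split yet"
    total = np.zeros(n_classes, dtype=np.int64)
    for i in range(start, end):
        total[y_codes[idx[i]]] += 1
    vals = np.empty(n)
    labs = np.empty(n, dtype=np.int64)
    for fi in range(feats.shape[0]):
        f = feats[fi]
        for i in range(n):
            vals[i] = X[idx[start + i], f]
            labs[i] = y_codes[idx[start + i]]
        order = np.argsort(vals)  # stability irrelevant: equal values yield no threshold
        left = np.zeros(n_classes, dtype=np.int64)
        nl = 0
        for p in range(n - 1):
            o = order[p]
            left[labs[o]] += 1
            nl += 1
            v = vals[o]
            vnext = vals[order[p + 1]]
            if vnext <= v:
                continue
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            sl = np.int64(0)
            sr = np.int64(0)
            for cc in range(n_classes):
                pl = left[cc]
                pr = total[cc] - left[cc]
                sl += pl * pl
                sr += pr * pr
            num = np.int64(nl) * nl * nr - sl * nr + np.int64(nr) * nr * nl - sr * nl
            den = np.int64(nl) * nr
            if best_den == 0 or num * best_den < best_num * den:
                best_num = num
                best_den = den
                best_feat = f
                best_thr = 0.5 * (v + vnext)
    if best_den == 0:
        return best_feat, best_thr, 1e300
    return best_feat, best_thr, best_num / (best_den * n)


@njit(cache=True)
def _sample_features(m, kappa, scratch):
    # partial Fisher-Yates over scratch (a length-m int array), then sort
    for i in range(m):
        scratch[i] = i
    for i in range(kappa):
        j = i + np.random.randint(0, m - i)
        t = scratch[i]
        scratch[i] = scratch[j]
        scratch[j] = t
    sel = np.sort(scratch[:kappa].copy())
    return sel


@njit(cache=True)
def _grow_tree(X, y_codes, boot, kappa, max_depth, min_leaf, n_classes,
               feat_arr, thr_arr, left_arr, right_arr, label_arr, counts_arr,
               scratch):
    n = boot.shape[0]
    m = X.shape[1]
    idx = boot.copy()
    # stack of (node, start, end, depth)
    stack = np.empty((2 * n + 2, 4), dtype=np.int64)
    top = 0
    n_nodes = 1
    stack[top, 0] = 0
    stack[top, 1] = 0
    stack[top, 2] = n
    stack[top, 3] = 0
    top += 1
    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]
        size = end - start
        counts = np.zeros(n_classes, dtype=np.int64)
        for i in range(start, end):
            counts[y_codes[idx[i]]] += 1
        for cc in range(n_classes):
            counts_arr[node, cc] = counts[cc]
        # majority label, ties to lowest class index
        best_c = 0
        for cc in range(1, n_classes):
            if counts[cc] > counts[best_c]:
                best_c = cc
        pure = counts[best_c] == size
        if pure or depth >= max_depth or size < 2 * min_leaf or size < 2:
            feat_arr[node] = -1
            label_arr[node] = best_c
            continue
        feats = _sample_features(m, kappa, scratch)
        f, thr, score = _node_best_split(X, y_codes, idx, start, end, feats,
                                         n_classes, min_leaf)
        if f < 0:
            feat_arr[node] = -1
            label_arr[node] = best_c
            continue
        # partition idx[start:end] in place: <= thr to the left
        lo = start
        hi = end - 1
        while lo <= hi:
            if X[idx[lo], f] <= thr:
                lo += 1
            else:
                t = idx[lo]
                idx[lo] = idx[hi]
                idx[hi] = t
                hi -= 1
        mid = lo
        feat_arr[node] = f
        thr_arr[node] = thr
        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        left_arr[node] = left_id
        right_arr[node] = right_id
        stack[top, 0] = left_id
        stack[top, 1] = start
        stack[top, 2] = mid
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = right_id
        stack[top, 1] = mid
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1
    return n_nodes


@njit(cache=True)
def _train_forest_impl(X, y_codes, n_trees, kappa, max_depth, min_leaf,
                       n_classes, seed):
    n, m = X.shape
    max_nodes = 2 * n + 2
    np.random.seed(seed)
    # only feat_arr needs a fill value (-2 marks unallocated nodes for the
    # text dump); every other entry is written before it is read
    feat_arr = np.full((n_trees, max_nodes), -2, dtype=np.int64)
    thr_arr = np.empty((n_trees, max_nodes))
    left_arr = np.empty((n_trees, max_nodes), dtype=np.int64)
    right_arr = np.empty((n_trees, max_nodes), dtype=np.int64)
    label_arr = np.empty((n_trees, max_nodes), dtype=np.int64)
    counts_arr = np.empty((n_trees, max_nodes, n_classes), dtype=np.int64)
    boots = np.empty((n_trees, n), dtype=np.int64)
    scratch = np.empty(m, dtype=np.int64)
    for t in range(n_trees):
        for i in range(n):
            boots[t, i] = np.random.randint(0, n)
        _grow_tree(X, y_codes, boots[t], kappa, max_depth, min_leaf,
                   n_classes, feat_arr[t], thr_arr[t], left_arr[t],
                   right_arr[t], label_arr[t], counts_arr[t], scratch)
    return feat_arr, thr_arr, left_arr, right_arr, label_arr, counts_arr, boots


@njit(cache=True)
def _tree_apply(feat, thr, left, right, label, x):
    node = 0
    while feat[node] >= 0:
        if x[feat[node]] <= thr[node]:
            node = left[node]
        else:
            node = right[node]
    return label[node]


@njit(cache=True)
def _forest_votes(feat_arr, thr_arr, left_arr, right_arr, label_arr, X,
                  n_classes):
    n_trees = feat_arr.shape[0]
    n = X.shape[0]
    votes = np.zeros((n, n_classes), dtype=np.int64)
    for t in range(n_trees):
        for i in range(n):
            c = _tree_apply(feat_arr[t], thr_arr[t], left_arr[t],
                            right_arr[t], label_arr[t], X[i])
            votes[i, c] += 1
    return votes


@njit(cache=True)
def _oob_stats(feat_arr, thr_arr, left_arr, right_arr, label_arr, boots,
               X, y_codes, n_classes):
    n_trees, n = boots.shape
    in_bag = np.zeros(n, dtype=np.bool_)
    per_tree_err = np.zeros(n_trees)
    empty_oob = 0
    oob_votes = np.zeros((n, n_classes), dtype=np.int64)
    for t in range(n_trees):
        for i in range(n):
            in_bag[i] = False
        for i in range(n):
            in_bag[boots[t, i]] = True
        n_oob = 0
        n_err = 0
        for i in range(n):
            if not in_bag[i]:
                c = _tree_apply(feat_arr[t], thr_arr[t], left_arr[t],
                                right_arr[t], label_arr[t], X[i])
                oob_votes[i, c] += 1
                n_oob += 1
                if c != y_codes[i]:
                    n_err += 1
        if n_oob > 0:
            per_tree_err[t] = n_err / n_oob
        else:
            per_tree_err[t] = 0.0
            empty_oob += 1
    return per_tree_err, oob_votes, empty_oob


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class RandomForest(BaseEstimator, ClassifierMixin):
    """CART random forest classifier.

    Parameters
    ----------
    n_trees : int in [1, 500]
        Ensemble size (``nTree``).
    kappa : int or None
        Features drawn per node; ``None`` means ``floor(sqrt(M))``.
    max_depth : int, default 20
    min_leaf : int, default 1
    random_state : int or None

    Fitted attributes (with trailing underscore) include ``classes_``,
    ``oob_error_`` (per-tree average), ``oob_error_aggregate_``
    (aggregate-vote estimate) and ``bootstrap_indices_``.
    """

    def __init__(self, n_trees=100, kappa=None, max_depth=20, min_leaf=1,
                 random_state=None):
        self.n_trees = n_trees
        self.kappa = kappa
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one label per row")
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        kappa = self.kappa
        if kappa is None:
            kappa = max(1, int(np.floor(np.sqrt(m))))
        if not (1 <= kappa <= m):
            raise ValueError(f"kappa={kappa} outside [1, {m}]")
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        y_codes = y_codes.astype(np.int64)
        seed = self.random_state if self.random_state is not None else 0
        seed = int(seed) % (2 ** 31 - 1)
        (feat, thr, left, right, label, counts, boots) = _train_forest_impl(
            X, y_codes, int(self.n_trees), int(kappa), int(self.max_depth),
            int(self.min_leaf), len(self.classes_), seed)
        self._nodes = (feat, thr, left, right, label, counts)
        self.kappa_ = kappa
        self.n_features_in_ = m
        self.bootstrap_indices_ = boots
        self._y_codes = y_codes
        self._X_train = X
        per_tree, oob_votes, empty = _oob_stats(
            feat, thr, left, right, label, boots, X, y_codes,
            len(self.classes_))
        if empty:
            warnings.warn(f"{empty} tree(s) had an empty OOB set and "
                          "contribute error 0", stacklevel=2)
        self.oob_per_tree_error_ = per_tree
        self.oob_error_ = float(per_tree.mean())
        seen = oob_votes.sum(axis=1) > 0
        if seen.any():
            agg_pred = np.argmax(oob_votes, axis=1)
            self.oob_error_aggregate_ = float(
                np.mean(agg_pred[seen] != y_codes[seen]))
        else:
            self.oob_error_aggregate_ = 0.0
        self.oob_mask_ = self._oob_masks(boots, n)
        return self

    @staticmethod
    def _oob_masks(boots, n):
        masks = np.ones((boots.shape[0], n), dtype=bool)
        for t in range(boots.shape[0]):
            masks[t, boots[t]] = False
        return masks

    def _votes(self, X):
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from training data")
        feat, thr, left, right, label, _ = self._nodes
        return _forest_votes(feat, thr, left, right, label, X,
                             len(self.classes_))

    def predict(self, X):
        votes = self._votes(X)
        return self.classes_[np.argmax(votes, axis=1)]

    def predict_proba(self, X):
        """Per-class vote fractions (rows sum to 1)."""
        votes = self._votes(X)
        return votes / votes.sum(axis=1, keepdims=True)

    def vote_margin(self, X, y):
        """Mean over samples of (true-class vote fraction) minus the largest
        other-class vote fraction; in [-1, 1]."""
        y = np.asarray(y)
        frac = self.predict_proba(X)
        code = np.searchsorted(self.classes_, y)
        margins = np.empty(len(y))
        for i in range(len(y)):
            true_f = frac[i, code[i]]
            other = np.delete(frac[i], code[i])
            margins[i] = true_f - (other.max() if other.size else 0.0)
        return float(margins.mean())


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train_forest(train, n_trees=100, kappa=None, max_depth=20, min_leaf=1,
                 seed=0) -> RandomForest:
    """Train a forest from a :class:`~imbforest.datasets.LabeledDataset`."""
    rf = RandomForest(n_trees=n_trees, kappa=kappa, max_depth=max_depth,
                      min_leaf=min_leaf, random_state=seed)
    return rf.fit(train.features, train.labels)


def predict(forest: RandomForest, X):
    """Labels and per-class vote fractions for ``X``."""
    return forest.predict(X), forest.predict_proba(X)


def oob_error(forest: RandomForest) -> float:
    """Per-tree-average OOB error of a fitted forest."""
    return forest.oob_error_


def margin(forest: RandomForest, X, y) -> float:
    return forest.vote_margin(X, y)


def bootstrap_distinct_fraction(n, replicates, seed=0) -> float:
    """Mean fraction of distinct samples in a size-n bootstrap (about
    1 - (1 - 1/n)^n, i.e. ~0.632 for large n)."""
    rng = np.random.RandomState(seed)
    fracs = [len(np.unique(rng.randint(0, n, size=n))) / n
             for _ in range(replicates)]
    return float(np.mean(fracs))


def dump_forest(forest: RandomForest, path) -> None:
    """Line-oriented text dump (tree, node, feature, threshold, counts)."""
    feat, thr, left, right, label, counts = forest._nodes
    with open(path, "w") as fh:
        fh.write("tree\tnode\tfeature\tthreshold\tleft\tright\tleaf_label\tcounts\n")
        for t in range(feat.shape[0]):
            for node in range(feat.shape[1]):
                if feat[t, node] == -2:
                    continue
                leaf = forest.classes_[label[t, node]] if feat[t, node] < 0 else ""
                fh.write(
                    f"{t}\t{node}\t{feat[t, node]}\t{thr[t, node]:.9g}\t"
                    f"{left[t, node]}\t{right[t, node]}\t{leaf}\t"
                    f"{','.join(map(str, counts[t, node]))}\n")
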