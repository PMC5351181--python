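"""Labeled tabular datasets: I/O, normalization, stratified partitioning and
synthetic generators for imbalanced-classification experiments.

The central container is :class:`LabeledDataset`, a thin immutable-ish wrapper
around a numeric feature matrix and a label vector.  Labels are opaque symbols;
the minority class is determined by count unless ``positive_label`` is given.
All generators are pure functions of their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "read_delimited_dataset",
    "write_delimited_dataset",
    "min_max_normalize",
    "minmax_params",
    "apply_minmax",
    "imbalance_ratio",
    "stratified_split",
    "stratified_kfold",
    "make_circle_data",
    "make_informative_gaussian",
]


@dataclass
class LabeledDataset:
    """A numeric feature matrix with class labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Finite real-valued feature matrix.
    labels : ndarray of shape (n_samples,)
        Class labels; treated as opaque symbols.
    feature_names : list of str, optional
        Column names; defaults to ``f0 .. f{M-1}``.
    positive_label : object, optional
        Designated minority (positive) class.  When absent the minority
        class is the least frequent label.
    metadata : dict
        Free-form provenance (e.g. informative feature indices of a
        synthetic generator, label column name of a parsed file).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list = None
    positive_label: object = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        n, m = self.features.shape
        if n < 1 or m < 1:
            raise ValueError("dataset must have at least one row and one column")
        if len(self.labels) != n:
            raise ValueError("labels length does not match feature row count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(m)]
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match column count")
        if self.positive_label is not None and self.positive_label not in self.labels:
            raise ValueError("positive_label does not occur in labels")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def m(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def minority_label(self):
        """Least frequent label, or ``positive_label`` when set."""
        if self.positive_label is not None:
            return self.positive_label
        counts = self.class_counts()
        # ties: smallest label string representation for determinism
        return min(sorted(counts, key=str), key=lambda k: counts[k])

    def majority_label(self):
        counts = self.class_counts()
        minority = self.minority_label()
        rest = {k: v for k, v in counts.items() if k != minority}
        return max(sorted(rest, key=str), key=lambda k: rest[k])

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.features[indices],
            self.labels[indices],
            list(self.feature_names),
            self.positive_label,
            dict(self.metadata),
        )

    def copy(self) -> "LabeledDataset":
        return LabeledDataset(
            self.features.copy(),
            self.labels.copy(),
            list(self.feature_names),
            self.positive_label,
            dict(self.metadata),
        )


@dataclass
class SplitSpec:
    """Stratified partitioning parameters (3:1 split and 4-fold CV defaults)."""

    train_fraction: float = 0.75
    folds: int = 4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0,1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_delimited_dataset(path, label_column, positive_label=None,
                           delimiter=",", header=True) -> LabeledDataset:
    """Read a delimiter-separated text table into a :class:`LabeledDataset`.

    ``label_column`` may be a column name (requires a header row) or a
    0-based integer index.  All non-label columns must parse as numbers.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    except FileNotFoundError:
        raise FileNotFoundError(f"dataset file not found: {path}")
    if isinstance(label_column, int):
        if not (-df.shape[1] <= label_column < df.shape[1]):
            raise ValueError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} absent from file")
        label_name = label_column
    labels = df[label_name].to_numpy()
    feats = df.drop(columns=[label_name])
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise ValueError(f"non-numeric feature cell(s) in column(s): {bad}")
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class dataset: label column has one distinct value")
    return LabeledDataset(
        numeric.to_numpy(dtype=float),
        labels,
        [str(c) for c in feats.columns],
        positive_label,
        {"label_column": str(label_name)},
    )


def write_delimited_dataset(ds: LabeledDataset, path, delimiter=",") -> None:
    """Write a dataset as delimited text with a header; inverse of the reader."""
    label_name = ds.metadata.get("label_column", "class")
    df = pd.DataFrame(ds.features, columns=ds.feature_names)
    df[label_name] = ds.labels
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def minmax_params(features: np.ndarray):
    """Per-column (min, range) with zero range for constant columns."""
    lo = features.min(axis=0)
    rng = features.max(axis=0) - lo
    return lo, rng


def apply_minmax(features: np.ndarray, lo, rng) -> np.ndarray:
    """Map columns by (x - lo) / rng; columns with zero range map to 0."""
    safe = np.where(rng > 0, rng, 1.0)
    out = (features - lo) / safe
    out[:, rng == 0] = 0.0
    return out


def min_max_normalize(ds: LabeledDataset) -> LabeledDataset:
    """Map every feature column to [0, 1]; constant columns become all-zero.

    Constant columns are sent to 0 rather than NaN so that downstream
    distances stay finite.
    """
    lo, rng = minmax_params(ds.features)
    out = ds.copy()
    out.features = apply_minmax(ds.features, lo, rng)
    return out


# ---------------------------------------------------------------------------
# Imbalance accounting
# ---------------------------------------------------------------------------

def imbalance_ratio(ds) -> float:
    """Minority-to-majority class size ratio, in (0, 1].

    Accepts a :class:`LabeledDataset` or a raw label vector.  With more
    than two classes the ratio of the smallest to the largest class is
    returned (an extension; the samplers themselves are binary).
    """
    labels = ds.labels if isinstance(ds, LabeledDataset) else np.asarray(ds)
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2:
        raise ValueError("imbalance ratio undefined for a single-class dataset")
    return counts.min() / counts.max()


# ---------------------------------------------------------------------------
# Stratified partitioning
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(ds: LabeledDataset, spec: SplitSpec):
    """Stratified train/test split at ``spec.train_fraction`` (3:1 default).

    Per-class train counts are ``floor(fraction * n_c + 0.5)`` followed by an
    adjustment pass so the total train size equals ``floor(fraction*N + 0.5)``;
    adjustments take from (or give to) the classes whose allocation deviates
    most from the exact fractional count, largest class first on ties.
    """
    rng = np.random.RandomState(spec.seed)
    f = spec.train_fraction
    values, counts = np.unique(ds.labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    alloc = {}
    for v, c in zip(values.tolist(), counts.tolist()):
        t = _round_half_up(f * c)
        alloc[v] = min(max(t, 1), c - 1)  # keep >=1 sample on each side
    target = _round_half_up(f * ds.n)
    order = sorted(alloc, key=str)
    cnt = dict(zip(values.tolist(), counts.tolist()))
    while sum(alloc.values()) > target:
        over = max(order, key=lambda v: (alloc[v] - f * cnt[v], alloc[v]))
        if alloc[over] <= 1:
            break
        alloc[over] -= 1
    while sum(alloc.values()) < target:
        under = min(order, key=lambda v: (alloc[v] - f * cnt[v], -alloc[v]))
        if alloc[under] >= cnt[under] - 1:
            break
        alloc[under] += 1
    train_idx, test_idx = [], []
    for v in order:
        idx = np.flatnonzero(ds.labels == v)
        perm = rng.permutation(len(idx))
        k = alloc[v]
        train_idx.extend(idx[perm[:k]].tolist())
        test_idx.extend(idx[perm[k:]].tolist())
    train_idx = np.sort(np.array(train_idx, dtype=int))
    test_idx = np.sort(np.array(test_idx, dtype=int))
    return ds.subset(train_idx), ds.subset(test_idx)


def stratified_kfold(ds: LabeledDataset, folds: int, seed: int):
    """Stratified k-fold index pairs ``(train_indices, validation_indices)``.

    Each class's indices are shuffled and dealt round-robin into folds, so
    per-class fold sizes differ by at most one sample.
    """
    values, counts = np.unique(ds.labels, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class size {counts.min()}"
        )
    rng = np.random.RandomState(seed)
    fold_members = [[] for _ in range(folds)]
    for v in sorted(values.tolist(), key=str):
        idx = np.flatnonzero(ds.labels == v)
        idx = idx[rng.permutation(len(idx))]
        for i, j in enumerate(idx):
            fold_members[i % folds].append(int(j))
    pairs = []
    all_idx = set(range(ds.n))
    for members in fold_members:
        val = np.sort(np.array(members, dtype=int))
        train = np.sort(np.array(list(all_idx - set(members)), dtype=int))
        pairs.append((train, val))
    return pairs


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------

def make_circle_data(n_major=113, n_minor=23, noise_minor=0, seed=0,
                     n_clumps=2, clump_sigma=0.1,
                     major_label=0, minor_label=1) -> LabeledDataset:
    """Two-dimensional imbalanced toy data: an annular majority region with
    small interior minority clump(s) plus optional scattered minority noise.

    Majority points are uniform on the annulus with radii 0.5-1.0; minority
    points are truncated Gaussians (3 sigma) around interior centres so that
    every clump point lies within a bounded clump radius; ``noise_minor``
    extra minority points are scattered uniformly over the majority annulus.
    Defaults mirror a 136-sample configuration with imbalance ratio near 0.2.
    """
    if n_major < 1:
        raise ValueError("n_major must be >= 1")
    rng = np.random.RandomState(seed)

    def annulus(k):
        # uniform over the annulus area between r=0.5 and r=1.0
        r = np.sqrt(rng.uniform(0.25, 1.0, size=k))
        theta = rng.uniform(0, 2 * np.pi, size=k)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    X_major = annulus(n_major)
    centres = [np.array([-0.2, 0.0]), np.array([0.2, 0.0])][: max(1, n_clumps)]
    clump_points = []
    for i in range(n_minor):
        c = centres[i % len(centres)]
        p = rng.normal(0.0, clump_sigma, size=2)
        while np.linalg.norm(p) > 3 * clump_sigma:  # truncate at 3 sigma
            p = rng.normal(0.0, clump_sigma, size=2)
        clump_points.append(c + p)
    X_minor = (
        np.array(clump_points).reshape(n_minor, 2)
        if n_minor
        else np.empty((0, 2))
    )
    X_noise = annulus(noise_minor) if noise_minor else np.empty((0, 2))
    X = np.vstack([X_major, X_minor, X_noise])
    y = np.array(
        [major_label] * n_major + [minor_label] * (n_minor + noise_minor)
    )
    return LabeledDataset(
        X, y, ["x", "y"], positive_label=minor_label,
        metadata={
            "generator": "circle",
            "clump_centres": [c.tolist() for c in centres],
            "clump_radius": 3 * clump_sigma,
            "noise_indices": list(range(n_major + n_minor, n_major + n_minor + noise_minor)),
        },
    )


def make_informative_gaussian(n_per_class=(150, 150), m_informative=3,
                              m_noise=7, effect_size=2.0, seed=0) -> LabeledDataset:
    """Two Gaussian classes whose means differ by ``effect_size`` on the first
    ``m_informative`` coordinates only; the remaining coordinates are
    standard-normal noise for both classes.

    The informative index set is recorded under ``metadata['informative']``.
    """
    if m_informative < 1:
        raise ValueError("m_informative must be >= 1")
    n0, n1 = n_per_class
    m = m_informative + m_noise
    rng = np.random.RandomState(seed)
    X0 = rng.normal(0.0, 1.0, size=(n0, m))
    X1 = rng.normal(0.0, 1.0, size=(n1, m))
    X1[:, :m_informative] += effect_size
    X = np.vstack([X0, X1])
    y = np.array([0] * n0 + [1] * n1)
    positive = 1 if n1 <= n0 else 0
    return LabeledDataset(
        X, y, [f"f{j}" for j in range(m)], positive_label=positive,
        metadata={"generator": "informative_gaussian",
                  "informative": list(range(m_informative))},
    )
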