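"""Seeded experiment drivers: the oversampler benchmark and the hybrid
feature/parameter optimization comparison.

Both drivers are pure functions of (configuration, seed): per-repeat seeds
are derived from the master seed and logged with every record, so the
reported means can be re-derived from the per-repeat log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .datasets import LabeledDataset, SplitSpec, stratified_kfold, stratified_split
from .forest import RandomForest
from .optimize import OPTIMIZERS
from .resample import SAMPLERS, CureSmote

__all__ = [
    "ExperimentConfig",
    "baseline_kappas",
    "run_oversample_benchmark",
    "run_hybrid_optimization",
    "REFERENCE_CLASS_COUNTS",
]


# Printed class counts of the benchmark tables' datasets (minority, majority);
# used for imbalance-ratio accounting without redistributing the UCI files.
REFERENCE_CLASS_COUNTS = {
    "blood-transfusion": (178, 570),
    "habermans-survival": (81, 225),
    "breast-cancer-wisconsin": (243, 459),
    "spect-train": (26, 54),
    "connectionist-bench": (97, 111),
    "wine": (59, 71),
    "ionosphere": (126, 225),
}


@dataclass
class ExperimentConfig:
    """Settings for one driver invocation."""

    dataset: LabeledDataset
    samplers: list = field(default_factory=lambda: list(SAMPLERS))
    optimizers: list = field(default_factory=lambda: list(OPTIMIZERS))
    repeats: int = 100
    train_fraction: float = 0.75
    folds: int = 4
    n_trees: int = 100
    max_depth: int = 20
    sampler_params: dict = field(default_factory=dict)
    optimizer_params: dict = field(default_factory=dict)
    target_ir: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for name in self.samplers:
            if name != "none" and name not in SAMPLERS:
                raise ValueError(f"unknown sampler {name!r}")
        for name in self.optimizers:
            if name not in OPTIMIZERS:
                raise ValueError(f"unknown optimizer {name!r}")


def _repeat_seed(master: int, r: int) -> int:
    return int((master * 100003 + 7919 * r + 1) % (2 ** 31 - 1))


def _evaluate_fold(train: LabeledDataset, test: LabeledDataset, sampler_name,
                   cfg: ExperimentConfig, seed):
    positive = train.positive_label or train.minority_label()
    X_test = test.features
    if sampler_name == "none":
        aug = train
    else:
        sampler = SAMPLERS[sampler_name](
            random_state=seed, target_ir=cfg.target_ir,
            **cfg.sampler_params.get(sampler_name, {}))
        result = sampler.sample(train)
        aug = result.dataset
        if isinstance(sampler, CureSmote):
            # classification happens in the sampler's normalized space
            X_test = sampler.transform(X_test)
    rf = RandomForest(n_trees=cfg.n_trees, max_depth=cfg.max_depth,
                      random_state=seed)
    rf.fit(aug.features, aug.labels)
    pred = rf.predict(X_test)
    pos_col = int(np.flatnonzero(rf.classes_ == positive)[0])
    scores = rf.predict_proba(X_test)[:, pos_col]
    cm = metrics.confusion(test.labels, pred, positive)
    return {
        "f_value": metrics.f_value(cm),
        "g_mean": metrics.g_mean(cm),
        "auc": metrics.auc(test.labels, scores, positive),
        "oob_error": rf.oob_error_,
    }


def run_oversample_benchmark(cfg: ExperimentConfig):
    """Repeat a stratified 3:1 split, oversample the training side, train a
    forest (100 trees, depth 20 by default) and score F-value, G-mean and
    AUC on the held-out side plus OOB error on the (augmented) training
    side; report per-sampler means over the repeats.

    Returns ``(report, log)``: a per-sampler mean table and the per-repeat
    record list (seeds included).  Sampler failures are recorded and
    excluded from the means.
    """
    log = []
    for r in range(cfg.repeats):
        seed = _repeat_seed(cfg.seed, r)
        train, test = stratified_split(
            cfg.dataset, SplitSpec(cfg.train_fraction, cfg.folds, seed))
        for name in cfg.samplers:
            rec = {"repeat": r, "seed": seed, "method": name}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec.update(_evaluate_fold(train, test, name, cfg, seed))
                rec["error"] = ""
            except Exception as exc:  # recorded, excluded from means
                rec["error"] = str(exc)
            log.append(rec)
    log_df = pd.DataFrame(log)
    ok = log_df[log_df["error"] == ""]
    report = (ok.groupby("method", sort=False)
              [["f_value", "g_mean", "auc", "oob_error"]].mean()
              .reindex(cfg.samplers))
    report["n_ok"] = ok.groupby("method", sort=False).size().reindex(
        cfg.samplers).fillna(0).astype(int)
    return report, log_df


def baseline_kappas(m: int) -> list:
    """The four fixed per-node feature counts compared against the
    optimizers: 1, floor(sqrt(M)), floor(log2(M)+1) and M."""
    return [1, max(1, int(np.floor(np.sqrt(m)))),
            max(1, int(np.floor(np.log2(m) + 1))), m]


def _cv_accuracy(ds: LabeledDataset, n_trees, kappa, feature_idx, cfg, seed):
    accs = []
    for train_idx, val_idx in stratified_kfold(ds, cfg.folds, seed):
        tr, va = ds.subset(train_idx), ds.subset(val_idx)
        rf = RandomForest(n_trees=n_trees, kappa=kappa,
                          max_depth=cfg.max_depth, random_state=seed)
        rf.fit(np.ascontiguousarray(tr.features[:, feature_idx]), tr.labels)
        pred = rf.predict(np.ascontiguousarray(va.features[:, feature_idx]))
        accs.append(float(np.mean(pred == va.labels)))
    return float(np.mean(accs))


def run_hybrid_optimization(cfg: ExperimentConfig):
    """Compare fixed-kappa forests (all features, 100 trees) against the
    GA/PSO/AFSA-tuned forests on one dataset.

    Per method the report carries the OOB error (per-tree average; the
    optimizers' objective), the vote margin on the training data, the
    stratified k-fold cross-validated accuracy, and the chosen nTree,
    kappa and selected-feature count.
    """
    ds = cfg.dataset
    m = ds.m
    if m < 2:
        raise ValueError("hybrid optimization needs at least 2 features")
    seed = _repeat_seed(cfg.seed, 0)
    all_features = np.arange(m)
    rows = []
    for kappa in baseline_kappas(m):
        rf = RandomForest(n_trees=cfg.n_trees, kappa=kappa,
                          max_depth=cfg.max_depth, random_state=seed)
        rf.fit(ds.features, ds.labels)
        rows.append({
            "method": f"kappa={kappa}",
            "oob_error": rf.oob_error_,
            "margin": rf.vote_margin(ds.features, ds.labels),
            "cv_accuracy": _cv_accuracy(ds, cfg.n_trees, kappa, all_features,
                                        cfg, seed),
            "n_tree": cfg.n_trees,
            "kappa": kappa,
            "n_features": m,
        })
    for name in cfg.optimizers:
        opt = OPTIMIZERS[name](random_state=seed, max_depth=cfg.max_depth,
                               **cfg.optimizer_params.get(name, {}))
        opt.fit(ds.features, ds.labels)
        rows.append({
            "method": name,
            "oob_error": opt.best_oob_error_,
            "margin": opt.forest_.vote_margin(
                np.ascontiguousarray(ds.features[:, opt.selected_features_]),
                ds.labels),
            "cv_accuracy": _cv_accuracy(ds, opt.best_ntree_, opt.best_kappa_,
                                        opt.selected_features_, cfg, seed),
            "n_tree": opt.best_ntree_,
            "kappa": opt.best_kappa_,
            "n_features": int(len(opt.selected_features_)),
        })
    return pd.DataFrame(rows).set_index("method")
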