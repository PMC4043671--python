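"""Randomized-split evaluation protocol and summary metrics.

The evaluation mirrors a repeated random-subsampling design: on each of
``n_iterations`` iterations, ``n_train_per_class`` images per treatment are
drawn without replacement for training and the classifiers are scored on
every remaining image.  Sensitivity, specificity, positive predictive
value and accuracy are averaged over iterations (accuracy additionally
reported with its between-iteration standard deviation).  The stressed
(N-I) treatment is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .classifiers import (STRESSED, WELL_WATERED, fuse, gpc_predict,
                          svm_predict, train_gpc_ep, train_linear_svm)
from .features import FEATURE_NAMES, FEATURE_SUBSETS

__all__ = [
    "LABEL_STRESSED",
    "LABEL_WATERED",
    "CVConfig",
    "MetricsSummary",
    "labels_to_y",
    "compute_metrics",
    "run_cv",
    "ablate",
    "probability_moisture_correlation",
    "split_probabilities",
]

LABEL_STRESSED = "N-I"
LABEL_WATERED = "I"


def labels_to_y(labels) -> np.ndarray:
    """Map treatment strings {"I", "N-I"} to {-1, +1}."""
    arr = np.asarray(labels)
    if not np.all(np.isin(arr, (LABEL_STRESSED, LABEL_WATERED))):
        raise ValueError("labels must be 'I' or 'N-I'")
    return np.where(arr == LABEL_STRESSED, STRESSED, WELL_WATERED)


@dataclass(frozen=True)
class CVConfig:
    """Configuration of the repeated random-split evaluation."""

    n_iterations: int = 200
    n_train_per_class: int = 18
    feature_subset: str = "proposed"
    classifier: str = "fused"  # {"svm", "gpc", "fused"}
    seed: int = 0
    svm_C: float = 1.0
    kernel_variance: float = 1.0
    fuse_hi: float = 0.8
    fuse_lo: float = 0.2
    standardize: bool = True

    def feature_names(self) -> tuple[str, ...]:
        try:
            return FEATURE_SUBSETS[self.feature_subset]
        except KeyError:
            names = tuple(self.feature_subset.split(","))
            unknown = [n for n in names if n not in FEATURE_NAMES]
            if unknown:
                raise ValueError(f"unknown features {unknown}") from None
            return names


@dataclass
class MetricsSummary:
    """Percent metrics averaged over iterations (NaN-aware means)."""

    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float
    accuracy_sd: float
    per_iteration: pd.DataFrame = field(repr=False, default=None)


def compute_metrics(predictions, truth) -> dict[str, float]:
    """Sensitivity/specificity/PPV/accuracy in percent; the stressed class
    (+1) is positive.  Ratios with zero denominator are NaN (missing), not
    zero."""
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predictions and truth must be equal-length and "
                         "non-empty")
    tp = np.sum((pred == STRESSED) & (y == STRESSED))
    tn = np.sum((pred == WELL_WATERED) & (y == WELL_WATERED))
    fp = np.sum((pred == STRESSED) & (y == WELL_WATERED))
    fn = np.sum((pred == WELL_WATERED) & (y == STRESSED))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "accuracy": ratio(tp + tn, len(y)),
    }


def _train_and_predict(X_tr, y_tr, X_te, config: CVConfig):
    """Returns (labels on the test set, P_s or None) for the configured
    classifier."""
    p_s = None
    if config.classifier in ("svm", "fused"):
        svm = train_linear_svm(X_tr, y_tr, C=config.svm_C,
                               standardize=config.standardize)
        svm_labels = svm_predict(svm, X_te)
    if config.classifier in ("gpc", "fused"):
        gpc = train_gpc_ep(X_tr, y_tr, kernel_variance=config.kernel_variance,
                           standardize=config.standardize)
        p_s = gpc_predict(gpc, X_te)
    if config.classifier == "svm":
        return svm_labels, None
    if config.classifier == "gpc":
        return np.where(p_s >= 0.5, STRESSED, WELL_WATERED), p_s
    if config.classifier == "fused":
        return fuse(svm_labels, p_s, hi=config.fuse_hi, lo=config.fuse_lo), p_s
    raise ValueError(f"unknown classifier {config.classifier!r}")


def _split_indices(y: np.ndarray, n_train_per_class: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    for cls in (WELL_WATERED, STRESSED):
        members = np.flatnonzero(y == cls)
        if len(members) <= n_train_per_class:
            raise ValueError(
                f"class {cls} has {len(members)} samples; cannot hold out "
                f"after drawing {n_train_per_class} for training")
        train_idx.append(rng.choice(members, n_train_per_class, replace=False))
    train = np.concatenate(train_idx)
    test = np.setdiff1d(np.arange(len(y)), train)
    return train, test


def run_cv(dataset: pd.DataFrame, config: CVConfig) -> MetricsSummary:
    """Repeated random-split evaluation of one classifier configuration.

    ``dataset`` must carry the feature columns plus a ``label`` column
    ("I"/"N-I").  Fully reproducible from ``config.seed``.
    """
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    names = list(config.feature_names())
    X = dataset[names].to_numpy(dtype=float)
    y = labels_to_y(dataset["label"].to_numpy())
    rng = np.random.default_rng(config.seed)

    rows = []
    for it in range(config.n_iterations):
        tr, te = _split_indices(y, config.n_train_per_class, rng)
        pred, _ = _train_and_predict(X[tr], y[tr], X[te], config)
        m = compute_metrics(pred, y[te])
        m["iteration"] = it
        rows.append(m)
    per_iter = pd.DataFrame(rows)
    return MetricsSummary(
        sensitivity=float(np.nanmean(per_iter["sensitivity"])),
        specificity=float(np.nanmean(per_iter["specificity"])),
        ppv=float(np.nanmean(per_iter["ppv"])),
        accuracy=float(np.nanmean(per_iter["accuracy"])),
        accuracy_sd=float(np.nanstd(per_iter["accuracy"])),
        per_iteration=per_iter,
    )


def ablate(dataset: pd.DataFrame, config: CVConfig,
           subsets: dict[str, tuple[str, ...]] | None = None,
           classifiers: tuple[str, ...] = ("svm", "gpc", "fused"),
           ) -> pd.DataFrame:
    """Sweep feature subsets x classifiers; one summary row per combination.

    Every combination is evaluated with the same seed, hence on identical
    train/test splits.
    """
    if subsets is None:
        subsets = {k: FEATURE_SUBSETS[k] for k in
                   ("colour", "thermal", "full", "proposed")}
    rows = []
    for subset_name, names in subsets.items():
        for clf in classifiers:
            cfg = replace(config, feature_subset=",".join(names),
                          classifier=clf)
            summary = run_cv(dataset, cfg)
            rows.append({
                "feature_subset": subset_name,
                "classifier": clf,
                "sensitivity": summary.sensitivity,
                "specificity": summary.specificity,
                "ppv": summary.ppv,
                "accuracy": summary.accuracy,
                "accuracy_sd": summary.accuracy_sd,
            })
    return pd.DataFrame(rows)


def probability_moisture_correlation(p_s, soil_moisture) -> float:
    """Pearson correlation between stress probability and soil moisture."""
    p = np.asarray(p_s, dtype=float)
    sm = np.asarray(soil_moisture, dtype=float)
    if p.shape != sm.shape or p.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(p) == 0 or np.std(sm) == 0:
        raise ValueError("zero variance in p_s or soil moisture")
    return float(pearsonr(p, sm).statistic)


def split_probabilities(dataset: pd.DataFrame, config: CVConfig
                        ) -> pd.DataFrame:
    """One train/test split; returns the held-out frame with a ``p_s``
    column (GPC stress probabilities) for correlation analysis."""
    names = list(config.feature_names())
    X = dataset[names].to_numpy(dtype=float)
    y = labels_to_y(dataset["label"].to_numpy())
    rng = np.random.default_rng(config.seed)
    tr, te = _split_indices(y, config.n_train_per_class, rng)
    gpc = train_gpc_ep(X[tr], y[tr], kernel_variance=config.kernel_variance,
                       standardize=config.standardize)
    out = dataset.iloc[te].copy()
    out["p_s"] = gpc_predict(gpc, X[te])
    return out
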