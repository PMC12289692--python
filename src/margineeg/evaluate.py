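"""Subject-independent evaluation: LOSO folds, metrics, ANOVA, ablation.

Class separation is reported as the Fisher criterion

    J = ||mu_+ - mu_-||^2 / (tr(Sigma_+) + tr(Sigma_-))

computed on attention-pooled feature vectors (population covariances).  The
formula choice matters: absolute J values are only comparable within one
feature space, so ablation conclusions are drawn from orderings, not
magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LOSOFold", "SplitSpec", "MetricsReport",
    "loso_folds", "classification_metrics", "class_separation",
    "one_way_anova", "stratified_split", "attention_heatmap",
]


@dataclass(frozen=True)
class LOSOFold:
    test_subject: int
    train_subjects: tuple[int, ...]

    def __post_init__(self):
        if self.test_subject in self.train_subjects:
            raise ValueError("test subject must not appear in the training set")


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15

    def __post_init__(self):
        if abs(self.train + self.validation + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    sensitivity: float
    class_separation: float = np.nan
    per_subject: pd.DataFrame | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "f1": self.f1,
             "sensitivity": self.sensitivity,
             "class_separation": self.class_separation, "seed": self.seed}
        if self.per_subject is not None:
            d["per_subject"] = self.per_subject.to_dict(orient="records")
        return d


def loso_folds(subject_ids) -> list[LOSOFold]:
    """One fold per subject, in sorted order; each subject tests exactly once."""
    ids = sorted(set(int(s) for s in subject_ids))
    if len(ids) < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    return [LOSOFold(test_subject=s,
                     train_subjects=tuple(t for t in ids if t != s))
            for s in ids]


def classification_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(accuracy, F1, sensitivity) for labels in {-1,+1}; +1 is the positive class.

    Zero denominators (no positive predictions / no positives) yield 0 with a
    warning rather than an error.
    """
    y_true = np.asarray(y_true).reshape(-1)
    y_pred = np.asarray(y_pred).reshape(-1)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if not (np.all(np.isin(y_true, (-1, 1))) and np.all(np.isin(y_pred, (-1, 1)))):
        raise ValueError("labels must be -1 or +1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    accuracy = float((y_true == y_pred).mean())

    def safe(num, den, name):
        if den == 0:
            warnings.warn(f"zero denominator in {name}; reporting 0")
            return 0.0
        return num / den

    sensitivity = safe(tp, tp + fn, "sensitivity")
    precision = safe(tp, tp + fp, "precision")
    f1 = safe(2 * precision * sensitivity, precision + sensitivity, "F1")
    return accuracy, f1, sensitivity


def class_separation(features: np.ndarray, labels) -> float:
    """Fisher criterion of a binary-labelled feature set (see module docstring)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).reshape(-1)
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    mu_diff = pos.mean(axis=0) - neg.mean(axis=0)
    scatter = float(pos.var(axis=0).sum() + neg.var(axis=0).sum())
    if scatter == 0:
        return np.inf if mu_diff @ mu_diff > 0 else 0.0
    return float(mu_diff @ mu_diff) / scatter


def one_way_anova(groups: list) -> tuple[float, float]:
    """Standard one-way ANOVA over per-subject accuracy lists.

    All-constant input has zero between- and within-group variance; the F
    statistic is undefined and (nan, nan) is returned with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float).reshape(-1) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        warnings.warn("all values identical: ANOVA F undefined, returning NaN")
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def stratified_split(labels: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Indices (rest, held_out) with the held-out fraction stratified by label."""
    labels = np.asarray(labels)
    held = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        k = int(round(fraction * len(idx)))
        held.append(idx[:k])
    held = np.sort(np.concatenate(held))
    rest = np.setdiff1d(np.arange(len(labels)), held)
    return rest, held


def attention_heatmap(weights: np.ndarray, out_path) -> None:
    """Write a PNG heatmap of attention weights (trials x key positions).

    Rows must sum to 1 (they are distributions over key positions).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if not np.allclose(W.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("attention weight rows must sum to 1")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(W, aspect="auto", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("key position")
    ax.set_ylabel("trial")
    ax.set_title("Attention weights")
    fig.colorbar(im, ax=ax, label="weight")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
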