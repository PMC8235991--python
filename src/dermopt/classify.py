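"""SVM decision stage and evaluation metrics.

A thin wrapper around scikit-learn's SVC with z-score standardization
fitted on the training split, plus confusion-count based metrics (PPV,
NPV, specificity, accuracy, sensitivity) and the repeated stratified
85/15 holdout protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "ConfusionCounts",
    "SVMModel",
    "train_svm",
    "predict",
    "confusion",
    "evaluate",
    "holdout_protocol",
]

POSITIVE = "cancerous"
NEGATIVE = "healthy"


@dataclass
class LabeledDataset:
    """Feature matrix with per-row class labels ('cancerous'/'healthy')."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature/label row mismatch")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")

    @property
    def y(self) -> np.ndarray:
        """Labels as +1 (cancerous) / -1 (healthy)."""
        return np.where(self.labels == POSITIVE, 1, -1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class SVMModel:
    scaler: StandardScaler
    svc: SVC
    classes: tuple[str, str] = (NEGATIVE, POSITIVE)


def train_svm(
    data: LabeledDataset, kernel: str = "rbf", c: float = 1.0, gamma: str | float = "scale"
) -> SVMModel:
    """Fit a kernel SVM on z-scored features."""
    y = data.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    scaler = StandardScaler().fit(data.features)
    svc = SVC(kernel=kernel, C=c, gamma=gamma)
    svc.fit(scaler.transform(data.features), y)
    return SVMModel(scaler=scaler, svc=svc)


def predict(model: SVMModel, features: np.ndarray) -> np.ndarray:
    """Labels ('cancerous'/'healthy') for a feature matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.scaler.n_features_in_:
        raise ValueError("feature dimension mismatch")
    signs = model.svc.predict(model.scaler.transform(features))
    return np.where(signs > 0, POSITIVE, NEGATIVE)


def confusion(pred: Sequence, truth: Sequence) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty inputs")
    pos_p, pos_t = pred == POSITIVE, truth == POSITIVE
    return ConfusionCounts(
        tp=int(np.sum(pos_p & pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )


def _ratio(num: int, den: int, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def evaluate(pred: Sequence, truth: Sequence) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and the five metrics; zero denominators give 0 + flag."""
    c = confusion(pred, truth)
    flags: list[str] = []
    metrics = {
        "ppv": _ratio(c.tp, c.tp + c.fp, "ppv", flags),
        "npv": _ratio(c.tn, c.tn + c.fn, "npv", flags),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity", flags),
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy", flags),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity", flags),
        "undefined": flags,
    }
    if flags:
        warnings.warn(f"zero-denominator metrics reported as 0: {flags}")
    return c, metrics


METRIC_NAMES = ("ppv", "npv", "specificity", "accuracy", "sensitivity")


def holdout_protocol(
    data: LabeledDataset,
    seeds: Sequence[int] = tuple(range(10)),
    test_size: float = 0.15,
    selection_cfg: "object | None" = None,
    kernel: str = "rbf",
    c: float = 1.0,
) -> dict:
    """Repeated stratified holdout: selection and training on the 85% split,
    metrics on the held-out 15%; returns per-seed rows and a mean/std summary.

    ``selection_cfg`` is a :class:`dermopt.selection.SelectionConfig`; when
    given, wrapper feature selection runs on the training split only and the
    final SVM uses the selected columns.
    """
    from . import selection as _selection  # local import to avoid a cycle

    rows = []
    for seed in seeds:
        idx_train, idx_test = train_test_split(
            np.arange(data.features.shape[0]),
            test_size=test_size,
            random_state=int(seed),
            stratify=data.labels,
        )
        train = LabeledDataset(data.features[idx_train], data.labels[idx_train])
        test_x = data.features[idx_test]
        test_y = data.labels[idx_test]

        if selection_cfg is not None:
            mask = _selection.select_features(train, selection_cfg, seed=int(seed))
            cols = np.nonzero(mask.bits)[0]
        else:
            cols = np.arange(data.features.shape[1])

        model = train_svm(
            LabeledDataset(train.features[:, cols], train.labels), kernel=kernel, c=c
        )
        pred = predict(model, test_x[:, cols])
        _, metrics = evaluate(pred, test_y)
        row = {name: metrics[name] for name in METRIC_NAMES}
        row["seed"] = int(seed)
        row["n_selected"] = int(len(cols))
        rows.append(row)

    summary = {
        name: {
            "mean": float(np.mean([r[name] for r in rows])),
            "std": float(np.std([r[name] for r in rows])),
        }
        for name in METRIC_NAMES
    }
    return {"per_seed": rows, "summary": summary}
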