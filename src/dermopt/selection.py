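"""Wrapper feature selection driven by the modified thermal-exchange optimizer.

A continuous position in [0, 1]^d is decoded to a bit mask (component > 0.5);
each candidate subset is scored by stratified cross-validated SVM
classification on the training data, pooling the fold confusions into the
Matthews-correlation cost.  The optimizer minimizes the negated score, so
better subsets have lower cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import ConfusionCounts, LabeledDataset, confusion, predict, train_svm
from .mteo import OptimizerConfig, optimize

__all__ = [
    "SelectionMask",
    "SelectionConfig",
    "cost_function",
    "decode",
    "evaluate_subset",
    "select_features",
]


@dataclass(frozen=True)
class SelectionMask:
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits).astype(np.int8)
        if bits.ndim != 1 or bits.sum() < 1:
            raise ValueError("selection mask must be 1-D with at least one bit set")
        object.__setattr__(self, "bits", bits)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())


@dataclass
class SelectionConfig:
    """Search budget and inner-evaluation settings for :func:`select_features`."""

    iterations: int = 750
    restarts: int = 20
    pop_size: int = 10
    cv_folds: int = 5
    cv_repeats: int = 1  # >1 averages the score over reshuffled fold splits
    size_penalty: float = 0.0  # lambda * n_selected / d added to the cost
    kernel: str = "rbf"
    c: float = 1.0
    use_obl: bool = True
    use_chaos: bool = True


def cost_function(c: ConfusionCounts) -> float:
    """Matthews-correlation subset score in [-1, 1]; zero denominator gives 0."""
    den = (
        (c.tn + c.fp) * (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)


def decode(position: np.ndarray) -> SelectionMask:
    """Threshold a [0, 1] position at 0.5; all-zero masks are repaired by
    switching on the largest component's bit."""
    position = np.asarray(position, dtype=float)
    bits = (position > 0.5).astype(np.int8)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1
    return SelectionMask(bits)


def evaluate_subset(
    mask: SelectionMask,
    data: LabeledDataset,
    cv_folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    c: float = 1.0,
    repeats: int = 1,
) -> float:
    """Negated pooled-confusion MCC of an SVM under stratified k-fold CV.

    With ``repeats`` > 1 the score is averaged over reshuffled fold
    splits, which smooths the granularity of the pooled counts.  Folds
    are reduced automatically if a class is too small to stratify.
    """
    cols = np.nonzero(mask.bits)[0]
    x = data.features[:, cols]
    y = data.labels
    _, counts = np.unique(y, return_counts=True)
    folds = int(min(cv_folds, counts.min()))
    if folds < 2:
        raise ValueError("need at least 2 samples per class for cross-validation")

    scores = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * rep)
        preds = np.empty(y.shape, dtype=y.dtype)
        for train_idx, test_idx in skf.split(x, y):
            model = train_svm(
                LabeledDataset(x[train_idx], y[train_idx]), kernel=kernel, c=c
            )
            preds[test_idx] = predict(model, x[test_idx])
        scores.append(-cost_function(confusion(preds, y)))
    return float(np.mean(scores))


def select_features(
    data: LabeledDataset, cfg: SelectionConfig | None = None, seed: int = 0
) -> SelectionMask:
    """Best subset over independent optimizer restarts (never empty).

    Subset scores are memoized per restart: the optimizer explores a
    continuous space but only 2^d distinct masks exist, so repeated
    evaluations are free.
    """
    if cfg is None:
        cfg = SelectionConfig()
    d = data.features.shape[1]
    restart_seeds = np.random.SeedSequence(seed).generate_state(cfg.restarts)

    best_mask: SelectionMask | None = None
    best_score = np.inf
    scores = []
    for r in range(cfg.restarts):
        cache: dict[tuple, float] = {}

        def objective(position: np.ndarray) -> float:
            m = decode(position)
            key = tuple(m.bits.tolist())
            if key not in cache:
                score = evaluate_subset(
                    m, data, cv_folds=cfg.cv_folds, seed=seed,
                    kernel=cfg.kernel, c=cfg.c, repeats=cfg.cv_repeats,
                )
                if cfg.size_penalty:
                    score += cfg.size_penalty * m.n_selected / d
                cache[key] = score
            return cache[key]

        ocfg = OptimizerConfig(
            pop_size=cfg.pop_size,
            max_iter=cfg.iterations,
            bounds=(np.zeros(d), np.ones(d)),
            seed=int(restart_seeds[r]),
            use_obl=cfg.use_obl,
            use_chaos=cfg.use_chaos,
            tm_size=min(4, cfg.pop_size // 2),
        )
        result = optimize(objective, ocfg)
        scores.append(result.best_cost)
        if result.best_cost < best_score:
            best_score = result.best_cost
            best_mask = decode(result.best_position)
    assert best_mask is not None
    select_features.last_scores = scores  # per-restart scores, for reporting
    return best_mask
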