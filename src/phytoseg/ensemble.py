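"""Majority and BWO-weighted replication voting over nine base masks.

Each of the nine thresholders contributes one binary mask. The weighted vote
conceptually replicates each mask as many times as its integer weight
(0-100) and takes a per-pixel majority over the replicated set; this is
implemented as the equivalent comparison ``sum_i w_i m_i > (sum_i w_i) / 2``
(strict, ties -> healthy). The weights are learned by BWO in integer mode
with CSI fitness on the training region; the initial population is seeded
with the one-hot and the equal-weight vectors, so the trained ensemble's
training CSI cannot fall below any single base mask's or the plain majority
vote's.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .bwo import BWOConfig, BelugaWhaleOptimizer
from .io import BinaryMask

__all__ = ["majority_vote", "weighted_vote", "BWOVoteEnsemble", "fit_ensemble_weights"]


def _stack_masks(masks: Sequence[BinaryMask]) -> np.ndarray:
    if len(masks) == 0:
        raise ValueError("at least one mask is required")
    arrays = [m.array if isinstance(m, BinaryMask) else np.asarray(m) for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all masks must share one shape")
    return np.stack(arrays).astype(np.int64)


def majority_vote(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Per-pixel relative majority; ties go to healthy (0)."""
    votes = _stack_masks(masks)
    return BinaryMask((2 * votes.sum(axis=0) > len(masks)).astype(np.uint8))


def weighted_vote(masks: Sequence[BinaryMask], weights: Sequence[int]) -> BinaryMask:
    """Integer-replication vote: each mask counts ``w_i`` times.

    Identical to literally replicating mask i w_i times and taking a
    majority: the replicated set holds sum(w) votes of which
    ``sum_i w_i m_i`` are positive, so a pixel is positive iff
    ``2 * sum_i w_i m_i > sum_i w_i``.
    """
    votes = _stack_masks(masks)
    w = np.asarray(weights)
    if w.shape != (len(masks),):
        raise ValueError("one weight per mask is required")
    if not np.issubdtype(w.dtype, np.integer):
        if not np.all(w == np.round(w)):
            raise ValueError("weights must be integers")
        w = w.astype(np.int64)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = int(w.sum())
    if total == 0:
        raise ValueError("all-zero weight vector")
    score = np.tensordot(w, votes, axes=(0, 0))
    return BinaryMask((2 * score > total).astype(np.uint8))


class BWOVoteEnsemble(BaseEstimator):
    """Learn integer vote weights in [0, 100]^9 by BWO with CSI fitness.

    Fitted attributes: ``weights_`` (ints), ``training_csi_``, ``history_``.
    """

    def __init__(
        self,
        pop_size: int = 50,
        iters: int = 50,
        weight_max: int = 100,
        warm_start: bool = True,
        random_state: int | None = None,
    ):
        self.pop_size = pop_size
        self.iters = iters
        self.weight_max = weight_max
        self.warm_start = warm_start
        self.random_state = random_state

    def fit(self, masks_region: Sequence[BinaryMask], truth_region: BinaryMask):
        votes = _stack_masks(masks_region)
        truth = np.asarray(
            truth_region.array if isinstance(truth_region, BinaryMask) else truth_region
        )
        if truth.min() == truth.max():
            raise ValueError("training region must contain both classes")
        m = len(masks_region)
        cfg = BWOConfig(
            dims=m,
            pop_size=self.pop_size,
            iters=self.iters,
            lower=0.0,
            upper=float(self.weight_max),
            seed=self.random_state,
            mode="integer",
        )

        truth_b = truth.astype(bool)
        n_truth = truth_b.sum()

        def fitness(w: np.ndarray) -> float:
            wi = w.astype(np.int64)
            total = wi.sum()
            if total == 0:
                return 0.0
            score = np.tensordot(wi, votes, axes=(0, 0))
            pred = 2 * score > total
            tp = np.sum(pred & truth_b)
            denom = tp + (n_truth - tp) + np.sum(pred & ~truth_b)  # TP+FN+FP
            return float(tp / denom) if denom else 0.0

        init = None
        if self.warm_start:
            onehot = np.eye(m) * self.weight_max
            init = np.vstack([onehot, np.ones((1, m))])

        result = BelugaWhaleOptimizer(cfg).optimize(fitness, init_positions=init)
        self.weights_ = result.best_position.astype(np.int64)
        self.history_ = result.history
        self.training_csi_ = fitness(self.weights_.astype(np.float64))
        return self

    def predict(self, masks: Sequence[BinaryMask]) -> BinaryMask:
        """Weighted vote with the trained weights over full-scene masks."""
        return weighted_vote(masks, self.weights_)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights_.tolist(),
            "training_csi": self.training_csi_,
            "history": self.history_.tolist(),
            "random_state": self.random_state,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "BWOVoteEnsemble":
        d = json.loads(Path(path).read_text())
        model = cls(random_state=d.get("random_state"))
        model.weights_ = np.asarray(d["weights"], dtype=np.int64)
        model.training_csi_ = d["training_csi"]
        model.history_ = np.asarray(d["history"], dtype=np.float64)
        return model


def fit_ensemble_weights(
    masks_region: Sequence[BinaryMask],
    truth_region: BinaryMask,
    pop_size: int = 50,
    iters: int = 50,
    seed: int | None = None,
) -> BWOVoteEnsemble:
    """Functional wrapper: train integer vote weights on a region."""
    model = BWOVoteEnsemble(pop_size=pop_size, iters=iters, random_state=seed)
    return model.fit(masks_region, truth_region)
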