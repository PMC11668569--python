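"""Learned weighted fusion of vegetation-index planes.

The fused index is a pixelwise weighted sum of n selected normalized index
planes, ``VI_new = sum_i w_i * VI_i``, re-normalized to [0, 1] so the
threshold segmenters receive a standard grayscale plane. The weights are
real values in a bounded box (default [-10, 10]) found by BWO maximizing the
Critical Success Index of the thresholded fused plane against ground truth
on a small labeled training region.

The initial BWO population is seeded with the one-hot weight vectors (each
single index by itself), which makes the learned index at least as good on
the training region as the best constituent index under the same
thresholder.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .bwo import BWOConfig, BelugaWhaleOptimizer
from .indices import IndexStack, normalize_plane
from .io import BinaryMask, GrayImage, Region
from .thresholding import DegenerateImageError, ThresholdParams, segment

__all__ = ["fuse", "csi_fitness", "FusedIndexSegmenter", "fit_fused_index"]


def fuse(stack: IndexStack, names: Sequence[str], weights: Sequence[float]) -> GrayImage:
    """Weighted sum of the named planes, min-max re-normalized to [0, 1]."""
    names = list(names)
    weights = np.asarray(weights, dtype=np.float64)
    if len(names) != weights.size:
        raise ValueError("one weight per feature name is required")
    if np.all(weights == 0):
        raise ValueError("all-zero weight vector is degenerate")
    missing = [n for n in names if n not in stack.names]
    if missing:
        raise KeyError(f"features not in stack: {missing}")
    idx = [stack.names.index(n) for n in names]
    combined = np.tensordot(weights, stack.planes[idx], axes=(0, 0))
    return normalize_plane(combined)


def csi_fitness(
    weights: Sequence[float],
    stack_region: IndexStack,
    truth_region: BinaryMask,
    params: ThresholdParams,
) -> float:
    """CSI of the thresholded fused plane on the training region.

    Any failure (all-zero weights, degenerate fused plane) maps to fitness 0
    so the optimizer simply avoids that region of weight space.
    """
    try:
        plane = fuse(stack_region, stack_region.names, weights)
        mask = segment(plane, params)
    except (ValueError, DegenerateImageError) as exc:
        warnings.warn(f"fitness 0 for weights {np.round(weights, 3)}: {exc}")
        return 0.0
    return metrics.csi(metrics.confusion(mask, truth_region))


class FusedIndexSegmenter(BaseEstimator):
    """Learn BWO weights for a fused vegetation index tied to one thresholder.

    Parameters
    ----------
    features : index names to fuse (order fixes the weight order); None uses
        every feature in the stack passed to :meth:`fit`.
    method : thresholder id or :class:`ThresholdParams` used both during
        fitness evaluation and at prediction time.
    pop_size, iters, bound : BWO population, iterations and symmetric box
        half-width (weights live in [-bound, bound]).
    warm_start_onehot : seed the initial population with the one-hot weight
        vectors (guarantees training-region dominance over single indices).
    random_state : seed for the whole fit.

    Fitted attributes: ``weights_``, ``feature_names_``, ``training_csi_``,
    ``history_`` (best CSI per BWO iteration).
    """

    def __init__(
        self,
        features: Sequence[str] | None = None,
        method: str | ThresholdParams = "otsu",
        pop_size: int = 50,
        iters: int = 50,
        bound: float = 10.0,
        warm_start_onehot: bool = True,
        random_state: int | None = None,
    ):
        self.features = features
        self.method = method
        self.pop_size = pop_size
        self.iters = iters
        self.bound = bound
        self.warm_start_onehot = warm_start_onehot
        self.random_state = random_state

    def _params(self) -> ThresholdParams:
        if isinstance(self.method, ThresholdParams):
            return self.method
        return ThresholdParams(method=self.method)

    def fit(self, stack: IndexStack, truth: BinaryMask, region: Region | None = None):
        names = tuple(self.features) if self.features is not None else stack.names
        sub = stack.subset(names)
        if region is not None:
            sub = sub.crop(region)
            truth_region = BinaryMask(truth.array[region.slices])
        else:
            truth_region = truth
        labels = truth_region.array
        if labels.min() == labels.max():
            raise ValueError("training region must contain both classes")

        params = self._params()
        n = len(names)
        cfg = BWOConfig(
            dims=n,
            pop_size=self.pop_size,
            iters=self.iters,
            lower=-self.bound,
            upper=self.bound,
            seed=self.random_state,
        )
        init = np.eye(n) if self.warm_start_onehot else None

        def fitness(w: np.ndarray) -> float:
            return csi_fitness(w, sub, truth_region, params)

        result = BelugaWhaleOptimizer(cfg).optimize(fitness, init_positions=init)
        self.feature_names_ = names
        self.weights_ = result.best_position
        self.history_ = result.history
        # re-evaluate so the reported CSI is exactly the returned weights'
        self.training_csi_ = fitness(self.weights_)
        return self

    def transform(self, stack: IndexStack) -> GrayImage:
        """The fused, normalized index plane for a full scene."""
        return fuse(stack, self.feature_names_, self.weights_)

    def predict(self, stack: IndexStack) -> BinaryMask:
        """Segment the fused plane with the trained thresholder."""
        return segment(self.transform(stack), self._params())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names_),
            "weights": self.weights_.tolist(),
            "threshold_params": asdict(self._params()),
            "training_csi": self.training_csi_,
            "history": self.history_.tolist(),
            "random_state": self.random_state,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "FusedIndexSegmenter":
        d = json.loads(Path(path).read_text())
        tp = ThresholdParams(**d["threshold_params"])
        model = cls(features=d["feature_names"], method=tp,
                    random_state=d.get("random_state"))
        model.feature_names_ = tuple(d["feature_names"])
        model.weights_ = np.asarray(d["weights"], dtype=np.float64)
        model.training_csi_ = d["training_csi"]
        model.history_ = np.asarray(d["history"], dtype=np.float64)
        return model


def fit_fused_index(
    stack: IndexStack,
    truth: BinaryMask,
    region: Region | None,
    method: str | ThresholdParams = "otsu",
    pop_size: int = 50,
    iters: int = 50,
    bound: float = 10.0,
    seed: int | None = None,
) -> FusedIndexSegmenter:
    """Functional wrapper: fit a fused-index model for one thresholder."""
    model = FusedIndexSegmenter(
        method=method, pop_size=pop_size, iters=iters, bound=bound,
        random_state=seed,
    )
    return model.fit(stack, truth, region)
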