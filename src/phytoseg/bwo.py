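"""Beluga Whale Optimization (BWO) over a bounded box, maximizing a fitness.

A population of n "whales" (candidate positions in [Lb, Ub]^d) is evolved for
T iterations through three phases:

* **exploration** — paired swimming: each dimension moves relative to a
  random partner whale in a random pivot dimension, modulated by sine/cosine
  terms (even/odd dimension index);
* **exploitation** — a Levy-flight step toward the incumbent best position,
  with jump intensity decaying over iterations;
* **whale fall** — each whale is independently repositioned with probability
  Wf(t) = 0.1 - 0.05 t/T by a randomized step whose length shrinks
  exponentially with iteration.

The phase per whale is decided by the balance factor Bf = B0 * (1 - t/(2T)),
B0 ~ U(-5, 5): Bf > 0.5 explores, otherwise exploits. Position updates are
clamped to the box and accepted greedily (a whale keeps its old position when
the new fitness is worse), so the best-so-far history is non-decreasing.

``mode="integer"`` keeps positions continuous but rounds them half-up at
fitness evaluation — used for the integer ensemble vote weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "BWOConfig",
    "BWOResult",
    "BelugaWhaleOptimizer",
    "optimize",
    "balance_factor",
    "whale_fall_probability",
    "levy_sigma",
]

BETA = 1.5  # Levy exponent


@dataclass(frozen=True)
class BWOConfig:
    """Optimizer settings. Defaults follow the method's standard operating
    point: 50 whales, 50 iterations, box [-10, 10]."""

    dims: int
    pop_size: int = 50
    iters: int = 50
    lower: float | Sequence[float] = -10.0
    upper: float | Sequence[float] = 10.0
    seed: int | None = None
    mode: Literal["continuous", "integer"] = "continuous"

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        lb, ub = self.bounds()
        if not np.all(lb < ub):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lower, dtype=np.float64), (self.dims,))
        ub = np.broadcast_to(np.asarray(self.upper, dtype=np.float64), (self.dims,))
        return lb.copy(), ub.copy()


@dataclass
class BWOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness after each iteration, non-decreasing
    n_evaluations: int


def balance_factor(t: int, T: int, rng: np.random.Generator) -> float:
    """Bf = B0 * (1 - t / (2T)) with fresh B0 ~ U(-5, 5); Bf > 0.5 explores."""
    if not 0 <= t < T:
        raise ValueError("iteration index must satisfy 0 <= t < T")
    b0 = rng.uniform(-5.0, 5.0)
    return b0 * (1.0 - t / (2.0 * T))


def whale_fall_probability(t: float, T: float) -> float:
    """Wf = 0.1 - 0.05 t/T, linearly decaying from 0.1 to 0.05."""
    return 0.1 - 0.05 * t / T


def levy_sigma(beta: float = BETA) -> float:
    """Mantegna scale sigma of the Levy step for exponent beta."""
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def _levy_step(rng: np.random.Generator, beta: float = BETA) -> float:
    """LF = 0.05 * mu * sigma / |V|^(1/beta), mu and V standard normal."""
    mu = rng.standard_normal()
    v = rng.standard_normal()
    return 0.05 * mu * levy_sigma(beta) / max(abs(v), 1e-300) ** (1.0 / beta)


class BelugaWhaleOptimizer:
    """Run BWO for a given fitness (higher is better)."""

    def __init__(self, config: BWOConfig):
        self.config = config

    # -- single-whale phase updates (exposed for unit testing) -------------

    @staticmethod
    def explore_step(
        X: np.ndarray, i: int, t: int, T: int, lb: np.ndarray, ub: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Cooperative-swimming update around a random partner whale."""
        n, d = X.shape
        p = int(rng.integers(0, d))
        r = int(rng.integers(0, n))
        new = X[i].copy()
        for j in range(d):
            r1 = rng.uniform(0.0, 1.0)
            r2 = rng.uniform(0.0, 1.0)
            delta = (X[r, p] - X[i, p]) * (1.0 + r1)
            trig = math.sin(2.0 * math.pi * r2) if j % 2 == 0 else math.cos(2.0 * math.pi * r2)
            new[j] = X[i, p] + delta * trig
        return np.clip(new, lb, ub)

    @staticmethod
    def exploit_step(
        X: np.ndarray, i: int, best: np.ndarray, t: int, T: int,
        lb: np.ndarray, ub: np.ndarray, rng: np.random.Generator,
    ) -> np.ndarray:
        """Levy-flight move toward the incumbent best position."""
        n, _ = X.shape
        r = int(rng.integers(0, n))
        r3 = rng.uniform(0.0, 1.0)
        r4 = rng.uniform(0.0, 1.0)
        c1 = 2.0 * r4 * (1.0 - t / T)
        lf = _levy_step(rng)
        new = r3 * best - r4 * X[i] + c1 * lf * (X[r] - X[i])
        return np.clip(new, lb, ub)

    @staticmethod
    def whale_fall_step(
        X: np.ndarray, i: int, t: int, T: int, lb: np.ndarray, ub: np.ndarray,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Randomized repositioning with exponentially shrinking step."""
        n, _ = X.shape
        r = int(rng.integers(0, n))
        r5, r6, r7 = rng.uniform(0.0, 1.0, size=3)
        wf = whale_fall_probability(t, T)
        c2 = 2.0 * wf * n
        x_step = math.exp(-c2 * t / T) * (ub - lb)
        new = r5 * X[i] - r6 * X[r] + r7 * x_step
        return np.clip(new, lb, ub)

    # -- main loop ---------------------------------------------------------

    def optimize(
        self,
        fitness: Callable[[np.ndarray], float],
        init_positions: np.ndarray | None = None,
    ) -> BWOResult:
        """Maximize ``fitness`` over the box.

        ``init_positions`` (m x d, m <= pop_size) overwrites the first m rows
        of the uniform-random initial population — used to warm-start the
        search with known feasible candidates.
        """
        cfg = self.config
        lb, ub = cfg.bounds()
        rng = np.random.default_rng(cfg.seed)
        n, d, T = cfg.pop_size, cfg.dims, cfg.iters

        warned = False

        def evaluate(x: np.ndarray) -> float:
            nonlocal warned
            z = np.floor(x + 0.5) if cfg.mode == "integer" else x
            f = float(fitness(z))
            if not math.isfinite(f):
                if not warned:
                    warnings.warn("fitness returned a non-finite value; treated as -inf")
                    warned = True
                return -math.inf
            return f

        X = rng.uniform(lb, ub, size=(n, d))
        if init_positions is not None:
            init = np.atleast_2d(np.asarray(init_positions, dtype=np.float64))
            m = min(len(init), n)
            X[:m] = np.clip(init[:m], lb, ub)
        F = np.array([evaluate(x) for x in X])
        n_eval = n

        best_i = int(np.argmax(F))
        best_x = X[best_i].copy()
        best_f = float(F[best_i])
        history = np.empty(T)

        for t in range(T):
            for i in range(n):
                bf = balance_factor(t, T, rng)
                if bf > 0.5:
                    cand = self.explore_step(X, i, t, T, lb, ub, rng)
                else:
                    cand = self.exploit_step(X, i, best_x, t, T, lb, ub, rng)
                f = evaluate(cand)
                n_eval += 1
                if f >= F[i]:  # greedy acceptance
                    X[i], F[i] = cand, f
                if f > best_f:
                    best_f, best_x = f, cand.copy()
            wf = whale_fall_probability(t, T)
            for i in range(n):
                if rng.uniform(0.0, 1.0) < wf:
                    cand = self.whale_fall_step(X, i, t, T, lb, ub, rng)
                    f = evaluate(cand)
                    n_eval += 1
                    if f >= F[i]:
                        X[i], F[i] = cand, f
                    if f > best_f:
                        best_f, best_x = f, cand.copy()
            history[t] = best_f

        if cfg.mode == "integer":
            best_x = np.floor(best_x + 0.5)
        return BWOResult(best_x, best_f, history, n_eval)


def optimize(
    fitness: Callable[[np.ndarray], float],
    config: BWOConfig,
    init_positions: np.ndarray | None = None,
) -> BWOResult:
    """Functional entry point for :class:`BelugaWhaleOptimizer`."""
    return BelugaWhaleOptimizer(config).optimize(fitness, init_positions)
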