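"""Architecture search over pooling-layer count and connected-layer budget.

The search space is a 2D plane: an integer pooling-layer count in
[2, 5] and a continuous connected-layer budget bounded by
``max_connected_layer``.  Candidates are scored by a profit value (the
negated regularized least-squares objective J, or any user-supplied
evaluator); each iteration moves the non-best candidates a fraction
``explore_fraction`` of the way toward the current best, with the step
direction perturbed by a bounded random angular deviation (at most
+-pi/6 by default) so the plane keeps being explored.  The best
configuration ever evaluated is returned; the whole procedure is
deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Tuple

import numpy as np

from .network import FDCNetConfig

__all__ = [
    "LayerSearchConfig",
    "max_connected_layer",
    "objective_J",
    "objective_J_grads",
    "profit",
    "layer_search",
]


@dataclass
class LayerSearchConfig:
    """Parameters of the candidate search."""

    alpha: float = 1.0
    var_high: float = 1.0
    var_low: float = 0.0
    pool_range: Tuple[int, int] = (2, 5)
    n_candidates: int = 20
    n_iterations: int = 8
    lam: float = 0.1
    explore_fraction: float = 0.5
    deviation: float = np.pi / 6
    seed: int = 0

    def __post_init__(self):
        if self.var_high <= self.var_low:
            raise ValueError("var_high must exceed var_low")
        lo, hi = self.pool_range
        if not (2 <= lo <= hi <= 5):
            raise ValueError("pool_range must lie within [2, 5]")
        if not (0.0 <= self.explore_fraction <= 1.0):
            raise ValueError("explore_fraction must lie in [0, 1]")


def max_connected_layer(alpha: float, n_current: float, n_total: float,
                        var_high: float, var_low: float) -> float:
    """Connected-layer amplitude alpha * (n_current/n_total) * (range)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return alpha * (n_current / n_total) * (var_high - var_low)


def objective_J(X, Theta, Y, R, lam: float) -> float:
    """Regularized bilinear least squares over observed entries.

    J = 1/2 sum_{(i,j): r_ij=1} (theta_j^T x_i - y_ij)^2
        + lam/2 (sum ||x||^2 + sum ||theta||^2)
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    X = np.asarray(X, dtype=np.float64)
    Theta = np.asarray(Theta, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    R = np.asarray(R, dtype=bool)
    E = (X @ Theta.T - Y) * R
    return float(0.5 * np.sum(E * E)
                 + 0.5 * lam * (np.sum(X * X) + np.sum(Theta * Theta)))


def objective_J_grads(X, Theta, Y, R, lam: float):
    """Analytic gradients (dJ/dX, dJ/dTheta) of :func:`objective_J`."""
    X = np.asarray(X, dtype=np.float64)
    Theta = np.asarray(Theta, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    R = np.asarray(R, bool)
    E = (X @ Theta.T - Y) * R
    return E @ Theta + lam * X, E.T @ X + lam * Theta


def profit(config, eval_fn: Callable[..., float]) -> float:
    """Suitability of a candidate: the negated objective value."""
    return -float(eval_fn(config))


def _clip_candidate(c, cfg: LayerSearchConfig, cap: float):
    lo, hi = cfg.pool_range
    pool = int(np.clip(np.rint(c[0]), lo, hi))
    budget = float(np.clip(c[1], cfg.var_low, min(cfg.var_high, cap)))
    return np.array([pool, budget])


def layer_search(search: LayerSearchConfig,
                 train_eval: Callable[[int, float], float],
                 base_config: Optional[FDCNetConfig] = None) -> FDCNetConfig:
    """Search the (pool count, connected budget) plane for the best profit.

    ``train_eval(pool_layers, budget)`` must return an objective value
    to minimize (profit is its negation).  Returns a copy of
    ``base_config`` with the winning pool-layer count and budget.
    """
    if search.n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(search.seed)
    lo, hi = search.pool_range
    cap = search.var_high

    cands = np.stack([
        np.array([rng.integers(lo, hi + 1),
                  rng.uniform(search.var_low, search.var_high)])
        for _ in range(search.n_candidates)
    ])
    scores = np.array([profit((int(c[0]), float(c[1])),
                              lambda pc: train_eval(int(pc[0]), float(pc[1])))
                       for c in cands])
    best_c, best_s = cands[int(np.argmax(scores))].copy(), scores.max()

    for it in range(search.n_iterations):
        cap = max_connected_layer(search.alpha, it + 1, search.n_iterations,
                                  search.var_high, search.var_low)
        leader = int(np.argmax(scores))
        for j in range(len(cands)):
            if j == leader:
                continue
            step = search.explore_fraction * (cands[leader] - cands[j])
            phi = rng.uniform(-search.deviation, search.deviation)
            rot = np.array([[np.cos(phi), -np.sin(phi)],
                            [np.sin(phi), np.cos(phi)]])
            cand = _clip_candidate(cands[j] + rot @ step, search, cap)
            s = profit((int(cand[0]), float(cand[1])),
                       lambda pc: train_eval(int(pc[0]), float(pc[1])))
            if s >= scores[j]:
                cands[j], scores[j] = cand, s
            if s > best_s:
                best_s, best_c = s, cand.copy()

    base = base_config or FDCNetConfig()
    return replace(base, pool_layers=int(best_c[0]),
                   connected_budget=float(best_c[1]))
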