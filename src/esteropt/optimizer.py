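"""Surrogate maximization over the coded factor box.

The trained network is cheap to evaluate, so the search is deliberately
blunt: a coarse full-factorial lattice scan to locate the promising
region, followed by multi-start Nelder–Mead refinement from seeded
interior starts (the lattice incumbent is always one of the starts).  The
default search box is the factorial region, coded [−1, +1] per factor;
``bounds="axial"`` widens it to the full star region ±1.75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import Bounds, minimize

from .doe import DEFAULT_ALPHA, FactorSpec, ReactionCondition, decode
from .mlp_quickprop import MLPModel

__all__ = ["OptimumReport", "find_optimum", "maximize_objective", "profile"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimumReport:
    """Proposed optimum: where, what the surrogate predicts, and how found."""

    condition: ReactionCondition
    coded: tuple[float, ...]
    predicted_conversion: float
    bounds: tuple[tuple[float, float], ...]  #: coded intervals searched
    restarts: int
    objective_trace: tuple[float, ...]  #: best objective after each restart


def maximize_objective(
    fn: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    restarts: int = 64,
    seed: int = 0,
    lattice_points: int = 5,
) -> tuple[np.ndarray, float, list[float], float]:
    """Maximize a vectorized objective over a box.

    ``fn`` maps an (m, k) array of points to (m,) values.  Returns
    (argmax, value, per-restart best trace, lattice-scan best value).
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate bounds: every interval needs lo < hi")
    k = lo.size

    axes = [np.linspace(lo[i], hi[i], lattice_points) for i in range(k)]
    grid = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)
    vals = np.asarray(fn(grid), dtype=float)
    i_best = int(np.argmax(vals))
    best_x, best_val = grid[i_best].copy(), float(vals[i_best])
    lattice_val = best_val

    rng = np.random.default_rng(seed)
    starts = [best_x] + list(rng.uniform(lo, hi, size=(restarts, k)))
    trace: list[float] = []
    for x0 in starts:
        res = minimize(
            lambda x: -float(fn(x[None, :])[0]),
            x0,
            method="Nelder-Mead",
            bounds=Bounds(lo, hi),
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if -res.fun > best_val:
            best_val = float(-res.fun)
            best_x = np.clip(res.x, lo, hi)
        trace.append(best_val)
    if best_val <= lattice_val:
        logger.warning("no restart improved on the lattice scan; returning lattice best")
    return best_x, best_val, trace, lattice_val


def _resolve_bounds(bounds, k: int) -> tuple[tuple[float, float], ...]:
    if bounds == "unit" or bounds is None:
        return tuple((-1.0, 1.0) for _ in range(k))
    if bounds == "axial":
        return tuple((-DEFAULT_ALPHA, DEFAULT_ALPHA) for _ in range(k))
    bounds = tuple((float(a), float(b)) for a, b in bounds)
    if len(bounds) != k:
        raise ValueError(f"need {k} bound pairs, got {len(bounds)}")
    return bounds


def find_optimum(
    model,
    factors: Sequence[FactorSpec],
    bounds="unit",
    restarts: int = 64,
    seed: int = 0,
) -> OptimumReport:
    """Propose the reaction condition maximizing predicted conversion.

    ``model`` is a single fitted network or a sequence of them (a
    committee, whose mean prediction is maximized).  ``bounds`` is "unit"
    (coded ±1, the factorial box — default), "axial" (±1.75), or explicit
    coded (lo, hi) pairs per factor.
    """
    factors = list(factors)
    models = list(model) if isinstance(model, (list, tuple)) else [model]
    box = _resolve_bounds(bounds, len(factors))
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])

    def objective(coded: np.ndarray) -> np.ndarray:
        natural = centers + coded * steps
        return np.mean([m.predict(natural) for m in models], axis=0)

    x, val, trace, _ = maximize_objective(objective, box, restarts=restarts, seed=seed)
    natural = tuple(decode(f, c) for f, c in zip(factors, x))
    return OptimumReport(
        condition=ReactionCondition.from_array(natural),
        coded=tuple(float(c) for c in x),
        predicted_conversion=val,
        bounds=box,
        restarts=restarts,
        objective_trace=tuple(trace),
    )


def profile(
    model: MLPModel,
    factors: Sequence[FactorSpec],
    factor_index: int,
    others_fixed: ReactionCondition,
    grid: int,
    coded_range: tuple[float, float] = (-1.0, 1.0),
) -> list[tuple[float, float]]:
    """1-D slice of predicted conversion along one factor.

    The chosen factor sweeps ``grid`` evenly spaced coded values across
    ``coded_range`` while the other factors stay at ``others_fixed``.
    Returns (natural value, predicted conversion%) pairs.
    """
    if grid < 2:
        raise ValueError("grid must be >= 2")
    factors = list(factors)
    base = others_fixed.as_array()
    coded = np.linspace(coded_range[0], coded_range[1], grid)
    X = np.tile(base, (grid, 1))
    X[:, factor_index] = [decode(factors[factor_index], c) for c in coded]
    preds = model.predict(X)
    return [(float(x), float(p)) for x, p in zip(X[:, factor_index], preds)]
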