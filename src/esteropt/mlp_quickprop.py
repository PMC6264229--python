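"""Multilayer perceptron trained with Fahlman's Quick Propagation.

The network mirrors the surrogate used in the esterquat optimization
study: five inputs (the reaction factors), one sigmoid hidden layer, one
sigmoid output predicting conversion %.  Inputs are min–max scaled to
[−1, 1]; the target is min–max scaled into [0.1, 0.9] of the sigmoid's
range so the training targets stay away from saturation.  Because the
output unit is a sigmoid, predictions in natural units are always bounded
by the inverse image of (0, 1) under the target scaling.

Quickprop is a batch second-order heuristic: per weight it treats the
error surface as a parabola through the last two gradients and jumps to
the parabola's vertex, Δw(t) = S(t) / (S(t−1) − S(t)) · Δw(t−1), with the
step magnitude capped at ``mu`` times the previous step and a plain
gradient step −ε·S(t) as the fallback whenever the quadratic step is
undefined, non-finite, or points uphill.  Training stops early when the
test-set RMSE has not improved for ``patience`` consecutive epochs; the
weights returned are those of the best test-RMSE epoch.

Hidden-layer width is chosen by a repeated-restart topology search:
train ``repeats`` freshly initialized networks for every candidate width
and keep the width with the lowest mean test RMSE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .dataset import ExperimentRecord
from .doe import ReactionCondition
from . import metrics as _metrics

__all__ = [
    "MLPModel",
    "QuickpropState",
    "TopologyResult",
    "TrainConfig",
    "TrainHistory",
    "fit_committee",
    "fit_mlp",
    "forward",
    "init_model",
    "model_from_json",
    "model_to_json",
    "quickprop_epoch",
    "topology_search",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass
class MLPModel:
    """Weights plus the input/target scaling that makes them meaningful.

    ``hidden_weights`` is (n_inputs+1, n_hidden) with the bias in the last
    row; ``output_weights`` is (n_hidden+1,) with the bias last.
    """

    n_hidden: int
    hidden_weights: np.ndarray
    output_weights: np.ndarray
    input_min: np.ndarray  #: per-factor minimum, natural units
    input_max: np.ndarray  #: per-factor maximum, natural units
    target_min: float  #: conversion % mapped to out_lo
    target_max: float  #: conversion % mapped to out_hi
    out_lo: float = 0.1  #: sigmoid activation the minimum target maps to
    out_hi: float = 0.9

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[0] - 1

    @property
    def n_params(self) -> int:
        return self.hidden_weights.size + self.output_weights.size

    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        span = self.input_max - self.input_min
        return 2.0 * (X - self.input_min) / span - 1.0

    def _activation_to_target(self, o: np.ndarray) -> np.ndarray:
        return self.target_min + (o - self.out_lo) / (self.out_hi - self.out_lo) * (
            self.target_max - self.target_min
        )

    def _target_to_activation(self, y: np.ndarray) -> np.ndarray:
        return self.out_lo + (y - self.target_min) / (self.target_max - self.target_min) * (
            self.out_hi - self.out_lo
        )

    def predict(self, X) -> np.ndarray:
        """Predicted conversion % for natural-unit inputs, shape (m, n_inputs)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.any(X < self.input_min) or np.any(X > self.input_max):
            logger.info("predicting outside the fitted input range (extrapolation)")
        Xs = self.scale_inputs(X)
        o, _ = _forward_scaled(self.hidden_weights, self.output_weights, Xs)
        return self._activation_to_target(o)


def forward(model: MLPModel, condition: ReactionCondition) -> float:
    """Predicted conversion % for a single reaction condition."""
    return float(model.predict(condition.as_array()[None, :])[0])


@dataclass
class TrainConfig:
    """Quickprop settings.

    epsilon — gradient step size used on fallback (and first) steps;
    mu — maximum growth factor bounding each quickprop jump;
    patience — epochs without test-RMSE improvement before stopping;
    decay — Fahlman's weight-decay term added to every slope, which keeps
    quickprop's geometrically growing steps from inflating the weights
    (essential when the trained surface itself is the object of interest,
    as in surrogate optimization; off by default).
    """

    epsilon: float = 0.1
    mu: float = 1.75
    max_epochs: int = 5000
    patience: int = 50
    seed: int = 0
    decay: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.mu <= 1 or self.max_epochs < 0 or self.patience < 0:
            raise ValueError(f"invalid training configuration: {self}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")


@dataclass
class QuickpropState:
    """Previous gradient and previous weight update, flattened."""

    prev_grad: Optional[np.ndarray] = None
    prev_step: Optional[np.ndarray] = None


@dataclass
class TrainHistory:
    train_loss: np.ndarray  #: MSE on scaled targets, per epoch
    test_rmse: np.ndarray  #: natural-unit test RMSE per epoch (empty without a test set)
    best_epoch: int  #: epoch whose weights were kept (0 = initial weights)
    n_epochs: int


@dataclass(frozen=True)
class TopologyResult:
    n_hidden: int
    repeat: int
    train_metrics: _metrics.FitMetrics
    test_metrics: _metrics.FitMetrics
    final_epoch: int


# ---------------------------------------------------------------------------
# forward / backward on scaled data


def _forward_scaled(w1: np.ndarray, w2: np.ndarray, Xs: np.ndarray):
    ones = np.ones((Xs.shape[0], 1))
    Xb = np.hstack([Xs, ones])
    h = expit(Xb @ w1)
    hb = np.hstack([h, ones])
    o = expit(hb @ w2)
    return o, (Xb, h, hb)


def _loss_and_grad(w1, w2, Xs, t):
    """MSE on scaled targets and its analytic gradient."""
    o, (Xb, h, hb) = _forward_scaled(w1, w2, Xs)
    r = o - t
    loss = float(np.mean(r**2))
    d_out = (2.0 / t.size) * r * o * (1.0 - o)
    g2 = hb.T @ d_out
    d_hid = np.outer(d_out, w2[:-1]) * h * (1.0 - h)
    g1 = Xb.T @ d_hid
    return loss, g1, g2


def _pack(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    return np.concatenate([g1.ravel(), g2.ravel()])


def _unpack(flat: np.ndarray, model: MLPModel):
    n1 = model.hidden_weights.size
    return flat[:n1].reshape(model.hidden_weights.shape), flat[n1:]


def _quickprop_step(grad: np.ndarray, state: QuickpropState, config: TrainConfig) -> np.ndarray:
    gd_step = -config.epsilon * grad
    if state.prev_step is None:
        return gd_step
    prev_g, prev_s = state.prev_grad, state.prev_step
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        quotient = grad / (prev_g - grad)
        quad = quotient * prev_s
    cap = config.mu * np.abs(prev_s)
    quad = np.clip(quad, -cap, cap)
    # Fahlman's heuristic: while successive slopes keep the same sign the
    # minimum has not been crossed, so the gradient term joins the
    # quadratic step; this also revives weights whose step has decayed to
    # nothing while the slope persists.
    step = quad + np.where(grad * prev_g > 0.0, gd_step, 0.0)
    # fallback: dead previous step, undefined quadratic, or uphill direction
    bad = (prev_s == 0.0) | ~np.isfinite(step) | (step * grad > 0.0)
    return np.where(bad, gd_step, step)


def quickprop_epoch(
    model: MLPModel,
    Xs: np.ndarray,
    t: np.ndarray,
    state: QuickpropState,
    config: TrainConfig,
) -> float:
    """One batch quickprop update, in place.  Returns the pre-update loss."""
    loss, g1, g2 = _loss_and_grad(model.hidden_weights, model.output_weights, Xs, t)
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite training loss {loss}")
    grad = _pack(g1, g2)
    if config.decay:
        grad = grad + config.decay * _pack(model.hidden_weights, model.output_weights)
    step = _quickprop_step(grad, state, config)
    d1, d2 = _unpack(step, model)
    model.hidden_weights = model.hidden_weights + d1
    model.output_weights = model.output_weights + d2
    state.prev_grad = grad
    state.prev_step = step
    return loss


# ---------------------------------------------------------------------------
# training


def _records_to_arrays(records: Sequence[ExperimentRecord]):
    X = np.array([r.condition.as_array() for r in records], dtype=float)
    y = np.array([r.conversion_actual for r in records], dtype=float)
    return X, y


def init_model(
    records: Sequence[ExperimentRecord],
    n_hidden: int,
    rng: np.random.Generator,
    out_lo: float = 0.1,
    out_hi: float = 0.9,
) -> MLPModel:
    """Fit scalers on ``records`` and draw initial weights uniform on ±0.3."""
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    X, y = _records_to_arrays(records)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target range: all conversions identical")
    n_in = X.shape[1]
    return MLPModel(
        n_hidden=n_hidden,
        hidden_weights=rng.uniform(-0.3, 0.3, size=(n_in + 1, n_hidden)),
        output_weights=rng.uniform(-0.3, 0.3, size=n_hidden + 1),
        input_min=X.min(axis=0),
        input_max=X.max(axis=0),
        target_min=float(y.min()),
        target_max=float(y.max()),
        out_lo=out_lo,
        out_hi=out_hi,
    )


def train(
    model: MLPModel,
    train_records: Sequence[ExperimentRecord],
    test_records: Sequence[ExperimentRecord],
    config: TrainConfig,
) -> tuple[MLPModel, TrainHistory]:
    """Quickprop training with early stopping on the test set.

    The caller fits the model's scalers on the union of the records it
    passes (see :func:`init_model`).  With an empty ``test_records`` no
    early stopping is applied and the final weights are returned.
    """
    if len(train_records) < 2:
        raise ValueError("need at least 2 training records")
    X_tr, y_tr = _records_to_arrays(train_records)
    if np.ptp(y_tr) == 0:
        raise ValueError("degenerate target range: all conversions identical")
    Xs = model.scale_inputs(X_tr)
    t = model._target_to_activation(y_tr)

    monitor = len(test_records) > 0
    if monitor:
        X_te, y_te = _records_to_arrays(test_records)

    state = QuickpropState()
    losses: list[float] = []
    test_rmse: list[float] = []
    best = (np.inf, model.hidden_weights.copy(), model.output_weights.copy(), 0)
    stale = 0
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        losses.append(quickprop_epoch(model, Xs, t, state, config))
        if monitor:
            pred = model.predict(X_te)
            r = _metrics.rmse(pred, y_te)
            test_rmse.append(r)
            if r < best[0]:
                best = (r, model.hidden_weights.copy(), model.output_weights.copy(), epoch)
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    if monitor and np.isfinite(best[0]):
        model.hidden_weights, model.output_weights = best[1], best[2]
        best_epoch = best[3]
    else:
        best_epoch = epoch
    history = TrainHistory(
        train_loss=np.array(losses),
        test_rmse=np.array(test_rmse),
        best_epoch=best_epoch,
        n_epochs=len(losses),
    )
    return model, history


def fit_mlp(
    train_records: Sequence[ExperimentRecord],
    test_records: Sequence[ExperimentRecord],
    n_hidden: int,
    config: TrainConfig,
    out_lo: float = 0.1,
    out_hi: float = 0.9,
) -> tuple[MLPModel, TrainHistory]:
    """Initialize (scalers on the union of records) and train in one call."""
    rng = np.random.default_rng(config.seed)
    model = init_model(
        list(train_records) + list(test_records), n_hidden, rng, out_lo=out_lo, out_hi=out_hi
    )
    return train(model, train_records, test_records, config)


def fit_committee(
    records: Sequence[ExperimentRecord],
    n_hidden: int,
    n_members: int,
    config: TrainConfig,
    test_records: Sequence[ExperimentRecord] = (),
    out_lo: float = 0.25,
    out_hi: float = 0.75,
) -> list[MLPModel]:
    """Train a committee of independently initialized networks.

    A committee's mean prediction is a steadier response surface than any
    single network's — individual fits wiggle between design points and
    the wiggles average out — which is what matters when the surface will
    be *maximized* rather than merely evaluated at the design.  The wider
    default output headroom ([0.25, 0.75] of the sigmoid range) leaves
    room for the surface to rise above the best observed response, which
    a near-saturated target scaling suppresses.

    Each member trains from a seed derived from ``config.seed``; with
    ``test_records`` given, members early-stop on it, otherwise they train
    to ``max_epochs``.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    models = []
    all_records = list(records) + list(test_records)
    for k in range(n_members):
        seed = _derived_seed(config.seed, n_hidden, k)
        rng = np.random.default_rng(seed)
        model = init_model(all_records, n_hidden, rng, out_lo=out_lo, out_hi=out_hi)
        member_cfg = TrainConfig(
            epsilon=config.epsilon, mu=config.mu, max_epochs=config.max_epochs,
            patience=config.patience, seed=seed, decay=config.decay,
        )
        model, _ = train(model, records, list(test_records), member_cfg)
        models.append(model)
    return models


def _derived_seed(base: int, n_hidden: int, repeat: int) -> int:
    ss = np.random.SeedSequence([int(base), int(n_hidden), int(repeat)])
    return int(ss.generate_state(1)[0] % (2**31))


def topology_search(
    train_records: Sequence[ExperimentRecord],
    test_records: Sequence[ExperimentRecord],
    h_range: Sequence[int],
    repeats: int,
    config: TrainConfig,
) -> tuple[list[TopologyResult], int]:
    """Grid over hidden-layer widths with repeated random restarts.

    Every (width, repeat) cell trains from a distinct seed derived from
    ``config.seed``.  The selected width minimizes mean test RMSE; ties go
    to the smaller network.
    """
    h_range = list(h_range)
    if not h_range:
        raise ValueError("h_range must be non-empty")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X_tr, y_tr = _records_to_arrays(train_records)
    X_te, y_te = _records_to_arrays(test_records)

    results: list[TopologyResult] = []
    mean_rmse: dict[int, float] = {}
    for h in h_range:
        cell = []
        for rep in range(repeats):
            cfg = TrainConfig(
                epsilon=config.epsilon,
                mu=config.mu,
                max_epochs=config.max_epochs,
                patience=config.patience,
                seed=_derived_seed(config.seed, h, rep),
            )
            model, history = fit_mlp(train_records, test_records, h, cfg)
            tr = _metrics.evaluate(model.predict(X_tr), y_tr)
            te = _metrics.evaluate(model.predict(X_te), y_te)
            results.append(TopologyResult(h, rep, tr, te, history.n_epochs))
            cell.append(te.rmse)
        mean_rmse[h] = float(np.mean(cell))
    best_h = min(sorted(mean_rmse), key=lambda h: mean_rmse[h])
    return results, best_h


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: MLPModel, path) -> None:
    payload = {
        "n_hidden": model.n_hidden,
        "hidden_weights": model.hidden_weights.tolist(),
        "output_weights": model.output_weights.tolist(),
        "input_min": model.input_min.tolist(),
        "input_max": model.input_max.tolist(),
        "target_min": model.target_min,
        "target_max": model.target_max,
        "out_lo": model.out_lo,
        "out_hi": model.out_hi,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def model_from_json(path) -> MLPModel:
    with open(path) as fh:
        payload = json.load(fh)
    return MLPModel(
        n_hidden=int(payload["n_hidden"]),
        hidden_weights=np.asarray(payload["hidden_weights"], dtype=float),
        output_weights=np.asarray(payload["output_weights"], dtype=float),
        input_min=np.asarray(payload["input_min"], dtype=float),
        input_max=np.asarray(payload["input_max"], dtype=float),
        target_min=float(payload["target_min"]),
        target_max=float(payload["target_max"]),
        out_lo=float(payload["out_lo"]),
        out_hi=float(payload["out_hi"]),
    )
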