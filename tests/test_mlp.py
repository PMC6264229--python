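"""Quickprop MLP: forward arithmetic, gradients, update rule, training."""

import math

import numpy as np
import pytest

from esteropt import doe, metrics
from esteropt import mlp_quickprop as mq
from esteropt.dataset import ExperimentRecord
from esteropt.doe import ReactionCondition
from esteropt.mlp_quickprop import (
    MLPModel,
    QuickpropState,
    TrainConfig,
    _loss_and_grad,
    _pack,
    _quickprop_step,
)


def make_model(n_inputs, n_hidden, rng=None, lo=0.1, hi=0.9):
    rng = rng or np.random.default_rng(0)
    return MLPModel(
        n_hidden=n_hidden,
        hidden_weights=rng.uniform(-0.3, 0.3, (n_inputs + 1, n_hidden)),
        output_weights=rng.uniform(-0.3, 0.3, n_hidden + 1),
        input_min=np.full(n_inputs, -1.0),
        input_max=np.full(n_inputs, 1.0),
        target_min=0.0,
        target_max=100.0,
        out_lo=lo,
        out_hi=hi,
    )


def linear_records(amplitude=5.0):
    """Noiseless response linear in the first factor's coded value."""
    design = doe.generate_ccd(doe.esterification_factors())
    return [
        ExperimentRecord(
            i + 1, ReactionCondition.from_array(p.natural), 50 + amplitude * p.coded[0], "train"
        )
        for i, p in enumerate(design)
    ]


class TestForward:
    def test_zero_weights_predict_midrange(self):
        m = make_model(5, 4, lo=0.0, hi=1.0)
        m.hidden_weights[:] = 0.0
        m.output_weights[:] = 0.0
        # sigmoid(0) = 0.5 everywhere -> midpoint of the 0..100 target range
        assert m.predict(np.zeros((3, 5))) == pytest.approx([50.0, 50.0, 50.0], abs=1e-12)

    def test_hand_computed_sigmoid_chain(self):
        m = make_model(1, 1, lo=0.0, hi=1.0)
        m.hidden_weights = np.array([[0.7], [0.1]])
        m.output_weights = np.array([1.3, -0.2])
        x = 0.4  # scaling is identity for min/max = -1/1
        h = 1.0 / (1.0 + math.exp(-(0.7 * x + 0.1)))
        o = 1.0 / (1.0 + math.exp(-(1.3 * h - 0.2)))
        assert m.predict([[x]])[0] == pytest.approx(100.0 * o, abs=1e-12)

    def test_parameter_count_5_11_1(self):
        m = make_model(5, 11)
        assert m.n_params == 78  # (5+1)*11 + (11+1)

    def test_predictions_bounded_by_inverse_sigmoid_image(self):
        m = make_model(5, 6)
        m.hidden_weights *= 100  # saturate hard
        m.output_weights *= 100
        X = np.random.default_rng(1).uniform(-1, 1, (200, 5))
        preds = m.predict(X)
        # closed interval: float sigmoid saturates to exactly 0/1
        lo_bound = m.target_min - m.out_lo / 0.8 * 100.0
        hi_bound = m.target_min + (1 - m.out_lo) / 0.8 * 100.0
        assert np.all(preds >= lo_bound) and np.all(preds <= hi_bound)


class TestGradients:
    def test_analytic_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        w1 = rng.normal(0, 0.5, (4, 3))
        w2 = rng.normal(0, 0.5, 4)
        Xs = rng.uniform(-1, 1, (6, 3))
        t = rng.uniform(0.2, 0.8, 6)
        _, g1, g2 = _loss_and_grad(w1, w2, Xs, t)
        grad = _pack(g1, g2)
        eps = 1e-6
        flat = _pack(w1, w2)
        fd = np.empty_like(flat)
        for i in range(flat.size):
            for sgn, store in ((1, "plus"), (-1, "minus")):
                pert = flat.copy()
                pert[i] += sgn * eps
                pw1 = pert[: w1.size].reshape(w1.shape)
                pw2 = pert[w1.size :]
                loss = _loss_and_grad(pw1, pw2, Xs, t)[0]
                if sgn == 1:
                    up = loss
                else:
                    down = loss
            fd[i] = (up - down) / (2 * eps)
        assert np.allclose(grad, fd, rtol=1e-6, atol=1e-9)


class TestQuickpropStep:
    def test_first_step_is_plain_gradient_descent(self):
        g = np.array([0.5, -2.0, 0.0])
        cfg = TrainConfig(epsilon=0.1)
        step = _quickprop_step(g, QuickpropState(), cfg)
        assert np.allclose(step, -0.1 * g, atol=1e-15)

    def test_step_magnitude_capped_by_mu(self):
        cfg = TrainConfig(epsilon=0.1, mu=1.75)
        # nearly equal successive gradients -> huge quadratic quotient
        state = QuickpropState(prev_grad=np.array([1.0]), prev_step=np.array([-0.1]))
        step = _quickprop_step(np.array([0.999]), state, cfg)
        # capped quadratic plus the same-sign gradient term
        assert step[0] == pytest.approx(1.75 * -0.1 + -0.1 * 0.999)

    def test_uphill_step_falls_back_to_gradient(self):
        cfg = TrainConfig(epsilon=0.1)
        # sign flip with shrinking magnitude: quadratic step would be uphill
        state = QuickpropState(prev_grad=np.array([-1.0]), prev_step=np.array([0.1]))
        g = np.array([2.0])
        step = _quickprop_step(g, state, cfg)
        assert step[0] * g[0] <= 0  # never ascent-directed

    def test_converges_faster_than_gradient_descent_on_quadratic(self):
        """1-D parabola: quickprop's secant jump lands near the vertex."""

        def epochs_to_converge(quickprop: bool) -> int:
            w = np.array([10.0])
            state = QuickpropState()
            cfg = TrainConfig(epsilon=0.1)
            for epoch in range(1, 1000):
                g = 2 * (w - 3.0)
                if quickprop:
                    step = _quickprop_step(g, state, cfg)
                    state.prev_grad, state.prev_step = g, step
                else:
                    step = -cfg.epsilon * g
                w = w + step
                if abs(w[0] - 3.0) < 1e-8:
                    return epoch
            return 1000

        assert epochs_to_converge(True) < epochs_to_converge(False)


class TestTraining:
    def test_zero_epochs_leaves_model_unchanged(self):
        recs = linear_records()
        rng = np.random.default_rng(0)
        model = mq.init_model(recs, 3, rng)
        w1 = model.hidden_weights.copy()
        model, history = mq.train(model, recs, [], TrainConfig(max_epochs=0))
        assert np.array_equal(model.hidden_weights, w1)
        assert history.n_epochs == 0

    def test_learns_linear_trend(self):
        """Noiseless linear-in-x1 response: ≥9/10 seeds below 1% RMSE."""
        recs = linear_records()
        X = np.array([r.condition.as_array() for r in recs])
        y = np.array([r.conversion_actual for r in recs])
        hits = 0
        for seed in range(10):
            model, _ = mq.fit_mlp(recs, [], 3, TrainConfig(seed=seed, max_epochs=2000))
            hits += metrics.rmse(model.predict(X), y) < 1.0
        assert hits >= 9

    def test_reproducible_loss_history(self, reference_split):
        train, test = reference_split
        cfg = TrainConfig(seed=11, max_epochs=200)
        _, h1 = mq.fit_mlp(train, test, 5, cfg)
        _, h2 = mq.fit_mlp(train, test, 5, cfg)
        assert np.array_equal(h1.train_loss, h2.train_loss)
        assert np.array_equal(h1.test_rmse, h2.test_rmse)

    def test_patience_zero_stops_at_first_non_improvement(self, reference_split):
        train, test = reference_split
        _, h = mq.fit_mlp(train, test, 5, TrainConfig(seed=1, patience=0, max_epochs=5000))
        r = h.test_rmse
        assert h.n_epochs < 5000
        running_best = np.minimum.accumulate(r)
        first_stall = int(np.argmax(r[1:] >= running_best[:-1])) + 1
        assert h.n_epochs == first_stall + 1

    def test_early_stop_returns_best_test_epoch_weights(self, reference_split):
        train, test = reference_split
        model, h = mq.fit_mlp(train, test, 8, TrainConfig(seed=5))
        X = np.array([r.condition.as_array() for r in test])
        y = [r.conversion_actual for r in test]
        assert metrics.rmse(model.predict(X), y) == pytest.approx(h.test_rmse.min(), abs=1e-9)
        assert h.best_epoch == int(np.argmin(h.test_rmse)) + 1

    def test_degenerate_targets_rejected(self):
        recs = [
            ExperimentRecord(i, ReactionCondition(5, 16, 60 + i, 2, 400), 50.0, "train")
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            mq.fit_mlp(recs, [], 3, TrainConfig())

    def test_too_few_records_rejected(self):
        recs = linear_records()[:1]
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mq.train(mq.init_model(linear_records(), 3, rng), recs, [], TrainConfig())


class TestTopologySearch:
    def test_single_cell(self, reference_split):
        train, test = reference_split
        results, best = mq.topology_search(train, test, [3], 1, TrainConfig(max_epochs=300))
        assert len(results) == 1
        assert best == 3
        assert results[0].n_hidden == 3

    def test_grid_shape_and_selection(self, reference_split):
        train, test = reference_split
        results, best = mq.topology_search(
            train, test, [2, 4], 3, TrainConfig(seed=9, max_epochs=300)
        )
        assert len(results) == 6
        by_h = {}
        for r in results:
            by_h.setdefault(r.n_hidden, []).append(r.test_metrics.rmse)
        means = {h: np.mean(v) for h, v in by_h.items()}
        assert best == min(means, key=means.get)

    def test_distinct_seeds_give_distinct_repeats(self, reference_split):
        train, test = reference_split
        results, _ = mq.topology_search(train, test, [3], 3, TrainConfig(seed=0, max_epochs=200))
        rmses = [r.test_metrics.rmse for r in results]
        assert len(set(rmses)) > 1


def test_model_json_round_trip(tmp_path, reference_split):
    train, test = reference_split
    model, _ = mq.fit_mlp(train, test, 4, TrainConfig(seed=2, max_epochs=100))
    path = tmp_path / "model.json"
    mq.model_to_json(model, path)
    back = mq.model_from_json(path)
    X = np.array([r.condition.as_array() for r in test])
    assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
    assert back.n_hidden == model.n_hidden
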