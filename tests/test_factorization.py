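import numpy as np
import pytest

from cdsml import (
    BinaryResponseMatrix,
    Hyperparameters,
    Scenario,
    ScoreMatrix,
    fit_one,
    fit_predict,
    rank_unknown,
    threshold_scores,
)
from cdsml.factorization import gradients, loss, newton_step


def _binary(labels, mask=None):
    labels = np.asarray(labels, dtype=float)
    m, n = labels.shape
    return BinaryResponseMatrix(labels, [f"c{i}" for i in range(m)],
                                [f"d{j}" for j in range(n)], mask)


def _random_weights(rng, n):
    R = rng.standard_normal((n, n))
    return 0.5 * (R + R.T)


class TestLoss:
    def test_exact_factorization_zero_loss(self, rng):
        X = rng.standard_normal((3, 2))
        Y = rng.standard_normal((4, 2))
        B = X @ Y.T
        hp = Hyperparameters(alpha=0.0, beta=0.0, seed=0)
        value = loss(B, np.ones_like(B), X, Y, None, None, hp,
                     Scenario(False, False, False))
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_gives_zero_mse(self):
        hp = Hyperparameters(alpha=0.0, beta=0.0, seed=0)
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        X = np.ones((2, 1))
        Y = np.ones((2, 1))
        value = loss(B, np.zeros_like(B), X, Y, None, None, hp,
                     Scenario(False, False, True))
        assert value == 0.0

    def test_hand_case_regularizer_only(self):
        # B = I2 = X Y^T with X = Y = I2, alpha=1: MSE 0, reg 1/2*(2+2) = 2
        hp = Hyperparameters(alpha=1.0, beta=0.0, seed=0)
        B = np.eye(2)
        value = loss(B, np.ones_like(B), np.eye(2), np.eye(2), None, None, hp,
                     Scenario(False, False, False))
        assert value == pytest.approx(2.0)

    def test_scenario_nesting_at_beta_zero(self, rng):
        hp = Hyperparameters(alpha=0.7, beta=0.0, seed=0)
        B = (rng.random((4, 3)) > 0.5).astype(float)
        mask = np.ones_like(B)
        X, Y = rng.standard_normal((4, 2)), rng.standard_normal((3, 2))
        SC, SD = _random_weights(rng, 4), _random_weights(rng, 3)
        values = {
            name: loss(B, mask, X, Y, SC, SD, hp,
                       Scenario.from_name(name, True))
            for name in ("both", "sc", "sd", "none")
        }
        assert len({round(v, 12) for v in values.values()}) == 1


class TestGradients:
    @pytest.mark.parametrize("scenario_name", ["both", "sc", "sd", "none"])
    def test_matches_central_differences(self, scenario_name, rng):
        m, n, K = 6, 5, 3
        hp = Hyperparameters(alpha=1.3, beta=0.8, k_prime=0.5, seed=0)
        scen = Scenario.from_name(scenario_name, True)
        B = (rng.random((m, n)) > 0.5).astype(float)
        mask = (rng.random((m, n)) > 0.3).astype(float)
        X, Y = rng.standard_normal((m, K)), rng.standard_normal((n, K))
        SC = _random_weights(rng, m) if scen.use_sc else None
        SD = _random_weights(rng, n) if scen.use_sd else None
        gX, gY, hX, hY = gradients(B, mask, X, Y, SC, SD, hp, scen)
        eps = 1e-6

        def numeric(A, which):
            G = np.zeros_like(A)
            for i in range(A.shape[0]):
                for k in range(A.shape[1]):
                    up, dn = A.copy(), A.copy()
                    up[i, k] += eps
                    dn[i, k] -= eps
                    if which == "X":
                        G[i, k] = (loss(B, mask, up, Y, SC, SD, hp, scen)
                                   - loss(B, mask, dn, Y, SC, SD, hp, scen)) / (2 * eps)
                    else:
                        G[i, k] = (loss(B, mask, X, up, SC, SD, hp, scen)
                                   - loss(B, mask, X, dn, SC, SD, hp, scen)) / (2 * eps)
            return G

        scale_x = max(1.0, np.abs(gX).max())
        scale_y = max(1.0, np.abs(gY).max())
        assert np.abs(gX - numeric(X, "X")).max() / scale_x < 1e-5
        assert np.abs(gY - numeric(Y, "Y")).max() / scale_y < 1e-5


class TestNewtonStep:
    def test_zero_gradient_is_stationary(self):
        factor = np.ones((3, 2))
        out, new_loss = newton_step(factor, np.zeros_like(factor),
                                    np.ones_like(factor), lambda F: 5.0, 5.0)
        np.testing.assert_array_equal(out, factor)

    def test_exact_on_scalar_quadratic(self):
        # loss 1/2 (b - x*y)^2 with y fixed: Newton lands at x = b/y
        b, y, x0 = 3.0, 2.0, 10.0
        def f(x):
            return 0.5 * (b - float(x) * y) ** 2
        g = np.array([[-(b - x0 * y) * y]])
        h = np.array([[y * y]])
        out, _ = newton_step(np.array([[x0]]), g, h,
                             lambda F: f(F[0, 0]), f(x0))
        assert out[0, 0] == pytest.approx(b / y)

    def test_non_finite_gradient_raises(self):
        with pytest.raises(FloatingPointError):
            newton_step(np.ones((1, 1)), np.array([[np.inf]]),
                        np.ones((1, 1)), lambda F: 0.0, 0.0)


class TestFitOne:
    def test_rank_one_exact_recovery(self):
        B = _binary(np.ones((4, 4)))
        hp = Hyperparameters(alpha=0.0, beta=0.0, k_prime=0.25,
                             tol=1e-6, seed=1)
        result = fit_one(B, None, None, hp, Scenario(False, False, False))
        assert result.final_loss < 1e-4

    def test_loss_trace_non_increasing(self, small_bundle):
        B = small_bundle.binary_response
        hp = Hyperparameters(seed=7)
        result = fit_one(B, None, None, hp, Scenario(False, False, True))
        trace = np.array(result.loss_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_seed_determinism(self, small_bundle):
        B = small_bundle.binary_response
        hp = Hyperparameters(seed=11)
        r1 = fit_one(B, None, None, hp, Scenario(False, False, True))
        r2 = fit_one(B, None, None, hp, Scenario(False, False, True))
        np.testing.assert_array_equal(r1.X, r2.X)
        np.testing.assert_array_equal(r1.Y, r2.Y)

    def test_empty_missing_set_identical_to_plain_path(self, rng):
        # with nothing missing, the missing-aware loss path must match the
        # imputed-matrix path bit for bit
        B = _binary((rng.random((6, 5)) > 0.4).astype(float))
        SC, SD = _random_weights(rng, 6), _random_weights(rng, 5)
        hp = Hyperparameters(alpha=1.0, beta=0.2, k_prime=0.4, seed=3)
        aware = fit_one(B, SC, SD, hp, Scenario(True, True, True))
        plain = fit_one(B, SC, SD, hp, Scenario(True, True, False))
        np.testing.assert_array_equal(aware.X, plain.X)
        np.testing.assert_array_equal(aware.Y, plain.Y)
        assert aware.loss_trace == plain.loss_trace


class TestFitPredict:
    def test_reconstructs_representable_matrix(self):
        labels = np.zeros((6, 6))
        labels[:3, :3] = 1.0
        labels[3:, 3:] = 1.0
        B = _binary(labels)
        hp = Hyperparameters(alpha=0.0, beta=0.0, k_prime=0.34,
                             tol=1e-6, seed=0)
        scores = fit_predict(B, None, None, hp, Scenario(False, False, False))
        assert np.abs(scores.scores - labels).max() < 1e-3

    def test_shape_and_ids(self, small_bundle):
        B = small_bundle.binary_response
        scores = fit_predict(B, None, None, Hyperparameters(seed=0),
                             Scenario(False, False, True))
        assert scores.scores.shape == B.shape
        assert scores.row_ids == B.row_ids and scores.col_ids == B.col_ids


class TestThresholdScores:
    def test_perfect_separation_reaches_corner(self):
        scores = ScoreMatrix(np.array([[0.9, 0.8], [0.1, 0.2]]),
                             ["c1", "c2"], ["d1", "d2"])
        known = _binary([[1, 1], [0, 0]])
        labels, thr = threshold_scores(scores, known)
        np.testing.assert_array_equal(labels.labels, known.labels)
        assert 0.2 < thr <= 0.8

    def test_matches_exhaustive_threshold_scan(self):
        values = np.linspace(0.1, 1.0, 10).reshape(2, 5)
        truth = (values >= 0.6).astype(float)
        scores = ScoreMatrix(values, ["c1", "c2"], [f"d{j}" for j in range(5)])
        known = _binary(truth)
        _, thr = threshold_scores(scores, known)

        flat_s, flat_y = values.ravel(), truth.ravel()
        best = None
        for cand in np.unique(flat_s)[::-1]:
            pred = flat_s >= cand
            tp = np.sum(pred & (flat_y == 1))
            prec = tp / pred.sum()
            rec = tp / flat_y.sum()
            d2 = (1 - prec) ** 2 + (1 - rec) ** 2
            if best is None or d2 < best[0]:
                best = (d2, cand)
        assert thr == pytest.approx(best[1])

    def test_tied_scores_warn(self):
        scores = ScoreMatrix(np.full((2, 2), 0.5), ["a", "b"], ["x", "y"])
        known = _binary([[1, 0], [1, 0]])
        with pytest.warns(UserWarning, match="identical"):
            labels, thr = threshold_scores(scores, known)
        assert np.all(labels.labels == 1.0)

    def test_single_class_raises(self):
        scores = ScoreMatrix(np.array([[0.1, 0.9]]), ["a"], ["x", "y"])
        with pytest.raises(ValueError, match="single class"):
            threshold_scores(scores, _binary([[1, 1]]))


class TestRankUnknown:
    def test_orders_masked_entries_by_score(self, rng):
        values = rng.random((6, 6))
        mask = rng.random((6, 6)) < 0.3
        mask[0, 0] = True
        B = _binary((values > 0.5).astype(float) * 0 + 0.0, mask)
        scores = ScoreMatrix(values, B.row_ids, B.col_ids)
        ranking = rank_unknown(scores, B, top_n=mask.sum())
        expected = sorted(
            [(B.row_ids[i], B.col_ids[j], values[i, j])
             for i, j in zip(*np.nonzero(mask))],
            key=lambda t: (-t[2], t[0], t[1]))
        assert [(c, d) for c, d, _ in ranking] == [(c, d) for c, d, _ in expected]

    def test_truncation_and_empty(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 1] = True
        B = _binary(np.zeros((2, 2)), mask)
        scores = ScoreMatrix(np.arange(4.0).reshape(2, 2), B.row_ids, B.col_ids)
        assert rank_unknown(scores, B, top_n=5) == [("c1", "d1", 3.0)]
        B_full = _binary(np.zeros((2, 2)))
        with pytest.warns(UserWarning, match="no missing"):
            assert rank_unknown(scores, B_full, top_n=5) == []
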