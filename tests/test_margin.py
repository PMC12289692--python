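"""Margin-optimized attention: hinge surrogate, QP agreement, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from margineeg import (AttentionInputs, HingeInstance, MarginAttentionParams,
                       fit_hinge, hinge_gradient, hinge_objective,
                       margin_attention_forward, margin_scores,
                       softmax_attention, total_loss)


def dual_qp_value(phi, y, C):
    """Independent oracle: the SVM dual (box-constrained QP, one equality),
    solved by SLSQP; strong duality gives the primal optimum value."""
    n = len(y)
    Q = (phi @ phi.T) * np.outer(y, y)

    def neg(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def jac(a):
        return -(np.ones(n) - Q @ a)

    cons = [{"type": "eq", "fun": lambda a: a @ y,
             "jac": lambda a: y.astype(float)}]
    best = np.inf
    for frac in (0.0, 0.5, 0.9):
        sol = optimize.minimize(neg, np.full(n, C * frac), jac=jac,
                                bounds=[(0, C)] * n, constraints=cons,
                                method="SLSQP",
                                options={"maxiter": 2000, "ftol": 1e-14})
        best = min(best, sol.fun)
    return -best


def random_instance(rng, n=6, d=2):
    phi = 2.0 * rng.normal(size=(n, d))
    y = rng.choice([-1, 1], size=n)
    if len(set(y)) < 2:
        y[0] = -y[0]
    return HingeInstance(phi, y)


class TestSoftmaxAttention:
    def test_single_key_weight_one(self):
        inp = AttentionInputs(Q=[[1.0, 2.0]], K=[[0.5, 0.1]], V=[[3.0, 4.0, 5.0]])
        w, ctx = softmax_attention(inp)
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(ctx, [[3.0, 4.0, 5.0]])

    def test_equal_logits_uniform(self):
        inp = AttentionInputs(Q=[[0.0]], K=[[1.0], [1.0], [1.0]],
                              V=[[1.0], [2.0], [3.0]])
        w, ctx = softmax_attention(inp)
        np.testing.assert_allclose(w, [[1 / 3] * 3])
        np.testing.assert_allclose(ctx, [[2.0]])

    def test_two_key_hand_computed(self):
        """d_k=1, logits (1, 0) -> weights (e/(e+1), 1/(e+1))."""
        inp = AttentionInputs(Q=[[1.0]], K=[[1.0], [0.0]], V=[[1.0], [0.0]])
        w, _ = softmax_attention(inp)
        e = np.e
        np.testing.assert_allclose(w, [[e / (e + 1), 1 / (e + 1)]], rtol=1e-12)

    @given(st.integers(1, 6), st.integers(1, 5), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rows_are_distributions(self, n_q, n, seed):
        rng = np.random.default_rng(seed)
        inp = AttentionInputs(Q=rng.normal(size=(n_q, 3)),
                              K=rng.normal(size=(n, 3)),
                              V=rng.normal(size=(n, 2)))
        w, _ = softmax_attention(inp)
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestHingeObjective:
    def test_zero_params_loss_is_Cn(self):
        inst = HingeInstance(np.ones((4, 3)), [1, -1, 1, -1])
        res = hinge_objective(MarginAttentionParams(A=np.zeros(3), C=1.0), inst)
        assert res.loss == pytest.approx(4.0)
        np.testing.assert_allclose(res.hinge_terms, 1.0)

    def test_satisfied_margins_leave_only_regularizer(self):
        inst = HingeInstance([[2.0], [-2.0]], [1, -1])
        res = hinge_objective(MarginAttentionParams(A=[1.0], b=0.0, C=1.0), inst)
        assert res.loss == pytest.approx(0.5)
        np.testing.assert_allclose(res.margins, 2.0)
        np.testing.assert_allclose(res.hinge_terms, 0.0)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            HingeInstance([[1.0]], [0])

    def test_dimension_mismatch_rejected(self):
        inst = HingeInstance([[1.0, 2.0]], [1])
        with pytest.raises(ValueError):
            hinge_objective(MarginAttentionParams(A=[1.0]), inst)

    def test_minimum_matches_dual_qp_on_random_instances(self):
        """>=20 random small instances: primal optimum vs dual QP to 1e-4."""
        rng = np.random.default_rng(42)
        for _ in range(22):
            inst = random_instance(rng)
            C = float(rng.uniform(0.3, 3.0))
            _, res = fit_hinge(inst, C=C)
            oracle = dual_qp_value(inst.phi, inst.y, C)
            assert res.loss == pytest.approx(oracle, abs=1e-4)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            inst = random_instance(rng, n=8, d=3)
            A = rng.normal(size=3)
            b = float(rng.normal())
            C = 1.3
            p = MarginAttentionParams(A=A, b=b, C=C)
            gA, gb = hinge_gradient(p, inst)
            eps = 1e-6
            g_num = np.zeros(4)
            for i in range(4):
                def at(delta, i=i):
                    v = np.concatenate([A, [b]])
                    v[i] += delta
                    return hinge_objective(
                        MarginAttentionParams(A=v[:3], b=v[3], C=C), inst).loss
                g_num[i] = (at(eps) - at(-eps)) / (2 * eps)
            g_ana = np.concatenate([gA, [gb]])
            scale = np.abs(g_num).max() + 1e-12
            assert np.abs(g_ana - g_num).max() / scale < 1e-5


class TestConvexityAndMonotonicity:
    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_chord_inequality(self, seed):
        """f(t x1 + (1-t) x2) <= t f(x1) + (1-t) f(x2) in (A, b)."""
        rng = np.random.default_rng(seed)
        inst = random_instance(rng, n=7, d=3)
        C = float(rng.uniform(0.2, 4.0))

        def f(v):
            return hinge_objective(
                MarginAttentionParams(A=v[:3], b=v[3], C=C), inst).loss

        v1, v2 = rng.normal(size=4), rng.normal(size=4)
        t = float(rng.uniform())
        assert f(t * v1 + (1 - t) * v2) <= t * f(v1) + (1 - t) * f(v2) + 1e-9

    def test_total_slack_non_increasing_in_C(self):
        rng = np.random.default_rng(8)
        inst = random_instance(rng, n=10, d=2)
        slacks = []
        for C in (0.05, 0.2, 1.0, 5.0, 25.0):
            _, res = fit_hinge(inst, C=C)
            slacks.append(res.hinge_terms.sum())
        assert all(a >= b - 1e-6 for a, b in zip(slacks, slacks[1:]))


class TestParameterRecovery:
    def test_separating_direction_recovered(self):
        """Planted separable direction recovered within 10 degrees, 10 seeds."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            w_true = rng.normal(size=2)
            w_true /= np.linalg.norm(w_true)
            n = 100
            margin_pos = rng.uniform(0.5, 2.0, size=n)
            y = np.where(np.arange(n) % 2 == 0, 1, -1)
            # bounded orthogonal spread: the max-margin boundary stays
            # perpendicular to the planted direction
            ortho = np.array([-w_true[1], w_true[0]])
            phi = (y * margin_pos)[:, None] * w_true + \
                rng.uniform(-3.0, 3.0, size=(n, 1)) * ortho
            params, _ = fit_hinge(HingeInstance(phi, y), C=100.0)
            cosang = params.A @ w_true / np.linalg.norm(params.A)
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            assert angle < 10.0
            # sign(score) matches the label on the training set
            assert np.all(np.sign(margin_scores(params, phi)) == y)


class TestForwardAndTotalLoss:
    def test_zero_params_give_uniform_weights_and_mean_context(self, rng):
        K = rng.normal(size=(5, 3))
        V = rng.normal(size=(5, 2))
        inp = AttentionInputs(Q=K, K=K, V=V)
        params = MarginAttentionParams(A=np.zeros(3), b=0.0)
        w, ctx, aux = margin_attention_forward(inp, params)
        np.testing.assert_allclose(w, 0.2)
        np.testing.assert_allclose(ctx, V.mean(axis=0))
        assert aux == 0.0  # inference mode

    def test_training_mode_aux_is_hinge_on_pooled_feature(self, rng):
        K = rng.normal(size=(4, 2))
        inp = AttentionInputs(Q=K, K=K, V=K)
        params = MarginAttentionParams(A=[1.0, -1.0], b=0.5, C=2.0)
        w, _, aux = margin_attention_forward(inp, params, label=1)
        pooled = w @ K
        expected = 0.5 * 2.0 + 2.0 * max(0.0, 1 - (pooled @ [1.0, -1.0] + 0.5))
        assert aux == pytest.approx(expected)

    def test_clip_normalization_stays_on_simplex(self, rng):
        K = rng.normal(size=(6, 3))
        inp = AttentionInputs(Q=K, K=K, V=K)
        params = MarginAttentionParams(A=rng.normal(size=3), b=-10.0)
        w, _, _ = margin_attention_forward(inp, params, normalization="clip")
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0)

    def test_total_loss_arithmetic(self):
        assert total_loss(1.0, 2.0, 0.5) == pytest.approx(2.0)
        assert total_loss(0.7, 123.0, 0.0) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -0.1)

    def test_total_gradient_is_lambda_times_hinge_gradient(self):
        """d(ce + lambda*L_SVM)/dA via central differences = lambda * analytic."""
        rng = np.random.default_rng(5)
        inst = random_instance(rng, n=6, d=2)
        A, b, C, lam = rng.normal(size=2), 0.3, 1.5, 0.7
        gA, _ = hinge_gradient(MarginAttentionParams(A=A, b=b, C=C), inst)
        eps = 1e-6
        for i in range(2):
            def at(delta, i=i):
                Ai = A.copy()
                Ai[i] += delta
                aux = hinge_objective(
                    MarginAttentionParams(A=Ai, b=b, C=C), inst).loss
                return total_loss(2.0, aux, lam)
            num = (at(eps) - at(-eps)) / (2 * eps)
            assert num == pytest.approx(lam * gA[i], rel=1e-5, abs=1e-8)
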