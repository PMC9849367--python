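"""Multi-kernel SVM: kernels, simplex search space, dual solver, prediction."""

import numpy as np
import pytest
from sklearn.svm import SVC

from jssenet.mksvm import (
    KernelSet,
    MKSVMModel,
    combine_kernels,
    decision_value,
    dual_objective,
    linear_kernel,
    predict,
    simplex_grid,
    train,
)


class TestKernels:
    def test_orthonormal_rows_give_identity(self):
        X = np.eye(3)[:2]
        np.testing.assert_allclose(linear_kernel(X), np.eye(2))

    def test_hand_inner_products(self):
        K = linear_kernel(np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(K, [[1.0], [3.0]])

    def test_gram_symmetric_psd(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        K = linear_kernel(X)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_kernel(np.ones((2, 3)), np.ones((2, 4)))


class TestCombine:
    def test_unit_weight_reduces_to_single_kernel(self):
        rng = np.random.default_rng(1)
        grams = KernelSet(grams=tuple(linear_kernel(rng.normal(size=(5, 3))) for _ in range(3)))
        np.testing.assert_array_equal(
            combine_kernels(grams, [1.0, 0.0, 0.0]), grams.grams[0]
        )

    def test_uniform_weights_of_identical_grams(self):
        g = linear_kernel(np.random.default_rng(2).normal(size=(4, 2)))
        out = combine_kernels([g, g, g], [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(out, g)

    def test_combination_stays_psd(self):
        rng = np.random.default_rng(3)
        grams = [linear_kernel(rng.normal(size=(6, 2))) for _ in range(2)]
        out = combine_kernels(grams, [0.3, 0.7])
        assert np.linalg.eigvalsh(out).min() >= -1e-8

    def test_negative_weights_rejected(self):
        g = np.eye(3)
        with pytest.raises(ValueError):
            combine_kernels([g, g], [1.5, -0.5])


class TestSimplexGrid:
    def test_counts(self):
        assert len(simplex_grid(3, 0.1)) == 66
        assert len(simplex_grid(3, 0.5)) == 6
        assert len(simplex_grid(2, 0.1)) == 11
        assert simplex_grid(1, 0.5) == [(1.0,)]

    def test_all_points_on_simplex(self):
        for beta in simplex_grid(3, 0.2):
            assert min(beta) >= 0
            assert sum(beta) == pytest.approx(1.0)


class TestTrain:
    def test_two_point_closed_form(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = train(linear_kernel(X), y, C=1e3)
        np.testing.assert_allclose(model.alpha, [0.5, 0.5], atol=1e-8)
        assert model.b == pytest.approx(0.0, abs=1e-8)
        # midpoint of the margin scores zero; the support vectors score +/-1
        assert decision_value(model, [np.zeros(2)]) == pytest.approx(0.0, abs=1e-8)
        assert decision_value(model, [linear_kernel(X, X[1:])[:, 0]]) == pytest.approx(1.0, abs=1e-6)

    def test_duplicating_points_leaves_predictions_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        y = np.where(X[:, 0] + 0.2 * rng.normal(size=10) > 0, 1.0, -1.0)
        if np.unique(y).size < 2:
            y[0] *= -1
        Xd = np.vstack([X, X])
        yd = np.concatenate([y, y])
        m1 = train(linear_kernel(X), y, C=1.0)
        m2 = train(linear_kernel(Xd), yd, C=1.0)
        tests = rng.normal(size=(20, 3))
        for t in tests:
            d1 = decision_value(m1, [linear_kernel(X, t[None])[:, 0]])
            d2 = decision_value(m2, [linear_kernel(Xd, t[None])[:, 0]])
            assert np.sign(d1) == np.sign(d2)

    def test_prediction_invariant_to_sample_ordering(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        y = np.where(X[:, 1] > 0, 1.0, -1.0)
        if np.unique(y).size < 2:
            y[0] *= -1
        perm = rng.permutation(12)
        m1 = train(linear_kernel(X), y, C=2.0)
        m2 = train(linear_kernel(X[perm]), y[perm], C=2.0)
        t = rng.normal(size=(1, 4))
        d1 = decision_value(m1, [linear_kernel(X, t)[:, 0]])
        d2 = decision_value(m2, [linear_kernel(X[perm], t)[:, 0]])
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            train(np.eye(4), np.ones(4), C=1.0)

    def test_matches_single_kernel_reference_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(16, 5))
        y = np.where(X @ rng.normal(size=5) > 0, 1.0, -1.0)
        if np.unique(y).size < 2:
            y[0] *= -1
        K = linear_kernel(X)
        model = train(K, y, C=1.0)
        sk = SVC(C=1.0, kernel="precomputed", tol=1e-9).fit(K, y)
        for k in range(16):
            ours = 1 if decision_value(model, [K[:, k]]) >= 0 else -1
            assert ours == sk.predict(K[k : k + 1])[0]

    def test_model_invariants_and_serialization(self, tmp_path):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        y = np.where(rng.random(10) > 0.5, 1.0, -1.0)
        if np.unique(y).size < 2:
            y[0] *= -1
        model = train(linear_kernel(X), y, C=0.5, beta=np.array([0.6, 0.4]))
        model.check_invariants()
        model.to_json(tmp_path / "m.json")
        back = MKSVMModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.alpha, model.alpha)
        assert back.b == pytest.approx(model.b)
        np.testing.assert_allclose(back.beta, [0.6, 0.4])


class TestDecision:
    def test_modality_columns_combined_by_beta(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        if np.unique(y).size < 2:
            y[0] *= -1
        K = linear_kernel(X)
        model = train(K, y, C=1.0, beta=np.array([0.5, 0.5]))
        col = K[:, 0]
        combined = decision_value(model, [col, col])
        single = float((model.alpha * model.y) @ col + model.b)
        assert combined == pytest.approx(single, abs=1e-12)

    def test_misaligned_columns_error(self):
        model = train(np.eye(4), np.array([1.0, -1.0, 1.0, -1.0]), C=1.0)
        with pytest.raises(ValueError):
            decision_value(model, [np.ones(3)])

    def test_tie_breaks_toward_positive(self):
        model = train(np.eye(2), np.array([1.0, -1.0]), C=1e-9)
        # a vanishing-C model gives a ~zero decision value
        assert predict(model, [np.zeros(2)]) == 1
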