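import itertools
import warnings

import numpy as np
import pytest

from kregkit.descriptors import (
    PermutationGroups,
    REDescriptor,
    SortedREDescriptor,
    UnsupportedDerivativeError,
)
from kregkit.kernels import KernelSpec, NotDifferentiableError, kernel_value
from kregkit.krr import (
    KernelRidgeRegressor,
    SingularSystemError,
    load_model,
    save_model,
)
from kregkit.synthetic import generate_morse_dataset, generate_xh3_dataset, xh3_reference_geometry

from conftest import random_geometry


def vec_model(**kw):
    return KernelRidgeRegressor(descriptor=None, **kw)


class TestTraining:
    def test_single_point_interpolates_exactly(self):
        m = vec_model(lam=0.0).fit([[1.0, 2.0]], [3.5])
        np.testing.assert_array_equal(m.alpha_, [3.5])  # k(x1,x1)=1
        assert m.predict([[1.0, 2.0]])[0] == 3.5

    def test_two_point_closed_form(self):
        x = np.array([[0.0], [1.0]])
        y = np.array([1.0, -2.0])
        lam = 0.01
        m = vec_model(sigma=0.8, lam=lam).fit(x, y)
        k12 = kernel_value(KernelSpec(sigma=0.8), x[0], x[1])
        det = (1 + lam) ** 2 - k12**2
        expected = np.array(
            [((1 + lam) * y[0] - k12 * y[1]) / det, ((1 + lam) * y[1] - k12 * y[0]) / det]
        )
        np.testing.assert_allclose(m.alpha_, expected, atol=1e-12)

    def test_heavy_ridge_shrinks_alpha(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        m = vec_model(lam=1e12).fit(x, y)
        assert np.max(np.abs(m.alpha_)) <= np.max(np.abs(y)) / 1e12 * (1 + 1e-9)
        assert np.max(np.abs(m.predict(x))) < 1e-10

    def test_interpolation_on_training_set(self, morse_train, morse_ref):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=0.05, lam=1e-16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(morse_train.geometries, morse_train.values)
        pred = m.predict(morse_train.geometries)
        scale = np.max(np.abs(morse_train.values))
        assert np.max(np.abs(pred - morse_train.values)) / scale <= 1e-8

    def test_monotone_regularization(self, morse_train, morse_ref):
        rmses = []
        for lam in np.logspace(-10, -2, 10):
            m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=0.05, lam=lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m.fit(morse_train.geometries, morse_train.values)
            pred = m.predict(morse_train.geometries)
            rmses.append(float(np.sqrt(np.mean((pred - morse_train.values) ** 2))))
        assert all(b >= a for a, b in zip(rmses, rmses[1:]))

    def test_solver_equivalence(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        alphas = {}
        for solver in ("cholesky", "bunch_kaufman", "lu"):
            m = vec_model(sigma=2.0, lam=1e-6, solver=solver).fit(x, y)
            assert m.solver_used_ == solver
            alphas[solver] = m.alpha_
        ref = alphas["cholesky"]
        scale = np.max(np.abs(ref))
        for other in ("bunch_kaufman", "lu"):
            assert np.max(np.abs(alphas[other] - ref)) / scale <= 1e-8

    def test_duplicate_points_lam_zero_raise(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(SingularSystemError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vec_model(lam=0.0).fit(x, [1.0, 2.0])

    def test_cholesky_failure_falls_back_with_warning(self):
        # a dense 1-D grid with a very wide kernel: K is numerically indefinite,
        # Cholesky fails, Bunch-Kaufman succeeds
        x = np.linspace(0, 1, 30)[:, None]
        y = np.sin(3 * x[:, 0])
        with pytest.warns(RuntimeWarning, match="fell back"):
            m = vec_model(sigma=10.0, lam=0.0).fit(x, y)
        assert m.solver_used_ != "cholesky"


class TestPrediction:
    def test_zero_alpha_predicts_zero(self):
        m = vec_model().fit([[0.0], [1.0]], [0.0, 0.0])
        np.testing.assert_allclose(m.predict([[0.3], [0.9]]), 0.0, atol=1e-15)

    def test_morse_generalization(self, morse_train, morse_test, morse_ref, morse_spec):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=0.5, lam=2.0**-35)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(morse_train.geometries, morse_train.values)
        pred = m.predict(morse_test.geometries)
        rmse = np.sqrt(np.mean((pred - morse_test.values) ** 2))
        assert rmse < 0.01 * morse_spec.well_depth

    def test_element_mismatch_rejected(self, morse_train, morse_ref, water):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref))
        m.fit(morse_train.geometries, morse_train.values)
        with pytest.raises(ValueError, match="element"):
            m.predict([water])


class TestGradientPrediction:
    def test_matches_finite_differences(self, morse_spec, morse_ref):
        # modest alpha keeps finite-difference cancellation noise below tolerance
        train = generate_morse_dataset(10, morse_spec, seed=20)
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=1.0, lam=1e-6)
        m.fit(train.geometries, train.values)
        g0 = generate_morse_dataset(1, morse_spec, seed=21).geometries[0]
        grad = m.predict_gradients([g0])[0]
        h = 1e-5
        fd = np.zeros((2, 3))
        for a in range(2):
            for t in range(3):
                cp = g0.coordinates.copy(); cp[a, t] += h
                cm = g0.coordinates.copy(); cm[a, t] -= h
                fd[a, t] = (m.predict([g0.with_coordinates(cp)])[0]
                            - m.predict([g0.with_coordinates(cm)])[0]) / (2 * h)
        scale = max(np.max(np.abs(fd)), 1e-10)
        assert np.max(np.abs(grad - fd)) / scale <= 1e-6

    def test_constant_targets_give_near_zero_gradients(self, morse_spec, morse_ref):
        # the interpolant of constant data is near-constant; its gradient is
        # limited by the wiggle of the kernel interpolant between nodes, which
        # is small but not machine-zero for finite sigma
        train = generate_morse_dataset(20, morse_spec, seed=22)
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=0.5, lam=1e-14)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(train.geometries, np.full(20, 2.5))
        grads = m.predict_gradients(train.geometries[:5])
        assert max(np.max(np.abs(g)) for g in grads) <= 1e-4
        # and a model whose coefficients are exactly zero has exactly zero gradient
        m.alpha_ = np.zeros_like(m.alpha_)
        g0 = m.predict_gradients(train.geometries[:1])[0]
        np.testing.assert_array_equal(g0, 0.0)

    def test_antisymmetric_diatomic_force(self, morse_spec, morse_ref):
        train = generate_morse_dataset(15, morse_spec, seed=23)
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=1.0, lam=1e-8)
        m.fit(train.geometries, train.values)
        g = m.predict_gradients([train.geometries[0]])[0]
        np.testing.assert_allclose(g[0], -g[1], atol=1e-10)  # Newton's third law on a pair

    def test_refused_for_sorted_descriptor(self, xh3_train, xh3_ref):
        m = KernelRidgeRegressor(descriptor=SortedREDescriptor(xh3_ref), sigma=1.0, lam=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(xh3_train.geometries, xh3_train.values)
        with pytest.raises(UnsupportedDerivativeError):
            m.predict_gradients(xh3_train.geometries[:1])

    def test_refused_for_non_differentiable_kernel(self, morse_train, morse_ref):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), kernel="laplacian")
        m.fit(morse_train.geometries, morse_train.values)
        with pytest.raises(NotDifferentiableError):
            m.predict_gradients(morse_train.geometries[:1])

    def test_refused_for_user_supplied_vectors(self):
        m = vec_model().fit([[0.0], [1.0]], [0.0, 1.0])
        with pytest.raises(ValueError, match="Jacobian"):
            m.predict_gradients([])


class TestPermutedKREG:
    def test_query_permutation_invariance(self, xh3_train, xh3_ref):
        groups = PermutationGroups([(1, 2, 3)])
        m = KernelRidgeRegressor(
            descriptor=REDescriptor(xh3_ref), sigma=1.0, lam=1e-8, permutation_groups=groups
        )
        m.fit(xh3_train.geometries, xh3_train.values)
        q = generate_xh3_dataset(1, seed=24).geometries[0]
        preds = [m.predict([q.permuted([0, *p])])[0] for p in itertools.permutations([1, 2, 3])]
        assert np.ptp(preds) <= 1e-10

    def test_gradient_matches_finite_differences(self, xh3_ref):
        groups = PermutationGroups([(1, 2, 3)])
        train = generate_xh3_dataset(10, seed=25)
        m = KernelRidgeRegressor(
            descriptor=REDescriptor(xh3_ref), sigma=1.5, lam=1e-8, permutation_groups=groups
        )
        m.fit(train.geometries, train.values)
        q = generate_xh3_dataset(1, seed=26).geometries[0]
        grad = m.predict_gradients([q])[0]
        h = 1e-5
        fd = np.zeros((4, 3))
        for a in range(4):
            for t in range(3):
                cp = q.coordinates.copy(); cp[a, t] += h
                cm = q.coordinates.copy(); cm[a, t] -= h
                fd[a, t] = (m.predict([q.with_coordinates(cp)])[0]
                            - m.predict([q.with_coordinates(cm)])[0]) / (2 * h)
        scale = max(np.max(np.abs(fd)), 1e-10)
        assert np.max(np.abs(grad - fd)) / scale <= 1e-6


class TestSerialization:
    def test_roundtrip_predictions_bit_identical(self, tmp_path, morse_train, morse_ref, morse_spec):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref), sigma=0.4, lam=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m.fit(morse_train.geometries, morse_train.values)
        path = tmp_path / "model.krr"
        save_model(m, path)
        m2 = load_model(path)
        probes = generate_morse_dataset(10, morse_spec, seed=27).geometries
        np.testing.assert_array_equal(m.predict(probes), m2.predict(probes))

    def test_metadata_preserved(self, tmp_path, morse_train, morse_ref):
        m = KernelRidgeRegressor(
            descriptor=REDescriptor(morse_ref), kernel="matern", matern_n=3, sigma=0.7, lam=1e-9
        )
        m.fit(morse_train.geometries, morse_train.values)
        path = tmp_path / "model.krr"
        save_model(m, path)
        m2 = load_model(path)
        assert (m2.kernel, m2.sigma, m2.matern_n, m2.lam) == ("matern", 0.7, 3, 1e-9)

    def test_truncated_file_clean_error(self, tmp_path, morse_train, morse_ref):
        m = KernelRidgeRegressor(descriptor=REDescriptor(morse_ref))
        m.fit(morse_train.geometries, morse_train.values)
        path = tmp_path / "model.krr"
        save_model(m, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        import numpy as np

        meta = np.frombuffer(json.dumps({"format": "other-1"}).encode(), dtype=np.uint8)
        with open(tmp_path / "bad.krr", "wb") as fh:
            np.savez(fh, meta=meta, alpha=np.zeros(1))
        with pytest.raises(ValueError, match="incompatible"):
            load_model(tmp_path / "bad.krr")
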