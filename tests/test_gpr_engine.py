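"""Kernels, covariance assembly, concentrated likelihood and prediction,
checked against naive dense-linear-algebra oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alfgp.gpr import (
    AtomicGPR,
    GPRResults,
    concentrated_log_likelihood,
    concentrated_mean,
)
from alfgp.kernels import (
    IllConditionedError,
    KernelSpec,
    build_covariance,
    kernel_matrix,
    kernel_value,
)

MASK5 = np.array([False, False, False, True, True])


def naive_kernel(x1, x2, spec):
    """Term-by-term loop oracle for the product kernel."""
    total = 0.0
    for d in range(spec.n_dim):
        if spec.cyclic_mask[d]:
            total += 2.0 * np.sin((x1[d] - x2[d]) / 2.0) ** 2 / spec.lengthscales[d] ** 2
        else:
            total += (x1[d] - x2[d]) ** 2 / (2.0 * spec.lengthscales[d] ** 2)
    return np.exp(-total)


class TestKernel:
    def test_zero_distance_gives_one(self, rng):
        spec = KernelSpec(rng.uniform(0.3, 2, 5), MASK5)
        x = rng.normal(size=5)
        assert kernel_value(x, x, spec) == pytest.approx(1.0, abs=1e-15)

    def test_full_turn_in_azimuth_gives_one(self, rng):
        spec = KernelSpec(rng.uniform(0.3, 2, 5), MASK5)
        x = rng.normal(size=5)
        shifted = x.copy()
        shifted[3] += 2 * np.pi
        assert kernel_value(x, shifted, spec) == pytest.approx(1.0, abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        spec = KernelSpec(np.ones(5), MASK5)
        x1, x2 = rng.normal(size=5), rng.normal(size=5)
        assert kernel_value(x1, x2, spec) == pytest.approx(
            naive_kernel(x1, x2, spec), rel=1e-14
        )

    def test_dimension_mismatch_raises(self):
        spec = KernelSpec(np.ones(3), np.zeros(3, bool))
        with pytest.raises(ValueError, match="dimension"):
            kernel_value(np.zeros(4), np.zeros(3), spec)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        spec = KernelSpec(r.uniform(0.2, 3, 6), r.uniform(size=6) < 0.5)
        x1, x2 = r.normal(scale=3, size=6), r.normal(scale=3, size=6)
        k12 = kernel_value(x1, x2, spec)
        assert 0.0 < k12 <= 1.0
        assert k12 == pytest.approx(kernel_value(x2, x1, spec), rel=1e-14)

    def test_prior_samples_periodic_in_cyclic_dimension(self, rng):
        # a GP sample with the product kernel, evaluated on a φ grid, must
        # repeat after 2π
        phi = np.linspace(-np.pi, np.pi, 25, endpoint=False)
        X = np.column_stack([np.zeros(50), np.concatenate([phi, phi + 2 * np.pi])])
        spec = KernelSpec([1.0, 0.8], [False, True], 1e-10)
        K = kernel_matrix(X, X, spec) + 1e-10 * np.eye(50)
        sample = np.linalg.cholesky(K) @ rng.normal(size=50)
        np.testing.assert_allclose(sample[:25], sample[25:], atol=1e-4)


class TestCovariance:
    def test_single_point(self):
        spec = KernelSpec([1.0], [False], nugget=1e-6)
        np.testing.assert_allclose(
            build_covariance(np.zeros((1, 1)), spec), [[1.0 + 1e-6]]
        )

    def test_duplicate_point_still_factorizable_at_jitter(self):
        # duplicated rows give off-diagonal 1; the 1e-8 jitter keeps the
        # matrix positive definite
        X = np.array([[0.5, 0.5], [0.5, 0.5], [1.5, 0.2]])
        spec = KernelSpec(np.ones(2), np.zeros(2, bool), nugget=1e-8)
        R = build_covariance(X, spec)
        assert R[0, 1] == pytest.approx(1.0)
        np.linalg.cholesky(R)  # must succeed

    def test_matches_brute_force_assembly(self, rng):
        X = rng.normal(size=(4, 5))
        spec = KernelSpec(rng.uniform(0.5, 2, 5), MASK5, nugget=1e-7)
        R = build_covariance(X, spec)
        expected = np.array(
            [[naive_kernel(X[i], X[j], spec) for j in range(4)] for i in range(4)]
        ) + 1e-7 * np.eye(4)
        np.testing.assert_allclose(R, expected, rtol=1e-13)
        np.testing.assert_allclose(np.diag(R), 1.0 + spec.nugget)

    def test_positive_definite_on_random_sets(self, rng):
        X = rng.normal(size=(200, 4))
        spec = KernelSpec([0.8, 1.0, 1.2, 0.6], [False, False, True, True], 1e-8)
        eigmin = np.linalg.eigvalsh(build_covariance(X, spec))[0]
        assert eigmin > 0


class TestConcentratedLikelihood:
    def test_independent_points_give_arithmetic_mean(self, rng):
        # points separated by thousands of lengthscales: R → I
        X = (np.arange(6, dtype=float) * 1e4)[:, None]
        y = rng.normal(size=6)
        spec = KernelSpec([1.0], [False], 1e-8)
        assert concentrated_mean(X, y, spec) == pytest.approx(y.mean(), rel=1e-6)

    def test_constant_targets_give_that_constant(self, rng):
        X = rng.normal(size=(8, 2))
        spec = KernelSpec([1.0, 1.0], [False, False], 1e-8)
        assert concentrated_mean(X, np.full(8, 3.7), spec) == pytest.approx(3.7)

    def test_agrees_with_grid_maximization_oracle(self, rng):
        # concentrating μ and the process variance must agree with a dense
        # brute-force grid maximization of the full marginal likelihood
        X = rng.uniform(0, 2, size=(6, 2))
        y = rng.normal(1.5, 0.8, size=6)
        spec = KernelSpec([0.9, 1.4], [False, False], 1e-8)
        R = build_covariance(X, spec)
        Rinv = np.linalg.inv(R)
        sign, logdet = np.linalg.slogdet(R)

        def full_loglike(mu, s2):
            resid = y - mu
            return float(
                -0.5 * 6 * np.log(2 * np.pi * s2)
                - 0.5 * logdet
                - 0.5 * resid @ Rinv @ resid / s2
            )

        mus = np.linspace(y.min() - 1, y.max() + 1, 4001)
        s2s = np.geomspace(1e-3, 1e2, 4001)
        best_mu = mus[np.argmax([full_loglike(m, 1.0) for m in mus])]
        grid_best = max(full_loglike(best_mu, s) for s in s2s)
        assert concentrated_mean(X, y, spec) == pytest.approx(best_mu, abs=2e-3)
        assert concentrated_log_likelihood(X, y, spec) == pytest.approx(
            grid_best, abs=1e-4
        )

    def test_invariant_to_training_point_order(self, rng):
        X = rng.normal(size=(7, 3))
        y = rng.normal(size=7)
        spec = KernelSpec([1.0, 0.7, 1.3], [False] * 3, 1e-8)
        perm = rng.permutation(7)
        assert concentrated_log_likelihood(X, y, spec) == pytest.approx(
            concentrated_log_likelihood(X[perm], y[perm], spec), rel=1e-10
        )


class TestPrediction:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.uniform(0, 3, size=(5, 3))
        y = rng.normal(size=5)
        model = AtomicGPR(X, y, cyclic_mask=[False, False, True], nugget=1e-8)
        return model.fit(lengthscales=[1.0, 0.8, 1.2])

    def test_interpolates_training_points(self, fitted):
        pred = fitted.predict(fitted.model.X)
        np.testing.assert_allclose(pred, fitted.model.y, atol=1e-6)

    def test_weights_satisfy_linear_system(self, fitted):
        assert fitted.residual_norm() < 1e-8 * np.linalg.norm(fitted.model.y)

    def test_matches_dense_oracle(self, fitted, rng):
        # prediction and variance from explicit dense inverses
        X, y, spec = fitted.model.X, fitted.model.y, fitted.spec
        R = build_covariance(X, spec)
        Rinv = np.linalg.inv(R)
        ones = np.ones(5)
        mu = ones @ Rinv @ y / (ones @ Rinv @ ones)
        for _ in range(5):
            xs = rng.uniform(-1, 4, size=3)
            r = np.array([naive_kernel(xs, xi, spec) for xi in X])
            expected_pred = mu + r @ Rinv @ (y - mu * ones)
            expected_var = (
                1.0 - r @ Rinv @ r + (1.0 - ones @ Rinv @ r) ** 2 / (ones @ Rinv @ ones)
            )
            assert fitted.predict(xs) == pytest.approx(expected_pred, abs=1e-10)
            assert fitted.predict_variance(xs) == pytest.approx(
                expected_var, abs=1e-10
            )

    def test_far_field_reverts_to_concentrated_mean(self, fitted):
        far = fitted.model.X[0].copy()
        far[:2] += 1e3  # push the noncyclic features 10³ lengthscales away
        assert fitted.predict(far) == pytest.approx(fitted.mu_hat, abs=1e-10)
        assert fitted.predict_variance(far) == pytest.approx(
            fitted.far_field_variance, abs=1e-10
        )

    def test_variance_at_training_point_is_jitter_level(self, fitted):
        var = fitted.predict_variance(fitted.model.X)
        assert np.all(var <= 2 * fitted.spec.nugget)

    def test_prediction_invariant_to_training_order(self, rng):
        X = rng.uniform(0, 2, size=(6, 2))
        y = rng.normal(size=6)
        perm = rng.permutation(6)
        ls = [0.9, 1.1]
        a = AtomicGPR(X, y, nugget=1e-8).fit(lengthscales=ls)
        b = AtomicGPR(X[perm], y[perm], nugget=1e-8).fit(lengthscales=ls)
        xs = rng.normal(size=2)
        assert a.predict(xs) == pytest.approx(b.predict(xs), rel=1e-9)

    def test_dimension_mismatch_raises(self, fitted):
        with pytest.raises(ValueError, match="dimension"):
            fitted.predict(np.zeros(4))


class TestSerialization:
    def test_round_trip_predictions_bit_close(self, rng, tmp_path):
        X = rng.uniform(0, 3, size=(8, 4))
        y = rng.normal(size=8)
        res = AtomicGPR(
            X, y, cyclic_mask=[False, True, False, True], nugget=1e-8,
            property_tag="q00", atom_tag="O1",
        ).fit(lengthscales=[0.7, 1.0, 1.4, 0.9])
        path = tmp_path / "model.json"
        res.save(path)
        again = GPRResults.load(path)
        pts = rng.uniform(-1, 4, size=(100, 4))
        np.testing.assert_allclose(again.predict(pts), res.predict(pts), atol=1e-12)
        assert again.model.property_tag == "q00"
        assert again.mu_hat == pytest.approx(res.mu_hat, abs=1e-15)

    def test_unknown_schema_major_rejected(self, tmp_path, rng):
        X = rng.uniform(size=(3, 2))
        res = AtomicGPR(X, rng.normal(size=3)).fit(lengthscales=1.0)
        path = tmp_path / "model.json"
        res.save(path)
        import json

        data = json.loads(path.read_text())
        data["schema_version"] = "2.0"
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="schema"):
            GPRResults.load(path)
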