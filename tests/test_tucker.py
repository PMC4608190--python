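"""Tucker3 engine: unfolding, reconstruction, HOSVD, ALS, core, fit."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetcube.interpret import match_components
from hetcube.simulate import PlantedCubeSpec, generate_planted_cube
from hetcube.tucker import (
    Tucker3,
    compute_core,
    fit_als,
    fit_percentage,
    hosvd_init,
    reconstruct,
    refold,
    unfold,
)
from .conftest import random_cube, triple_loop_reconstruct


class TestUnfold:
    def test_person_mode_index_convention(self):
        # X[i,j,t] = i + 2(j-1) + 4(t-1), 1-based -> row 1 is (1, 3, 5, 7)
        X = np.zeros((2, 2, 2))
        for i in range(2):
            for j in range(2):
                for t in range(2):
                    X[i, j, t] = (i + 1) + 2 * j + 4 * t
        np.testing.assert_array_equal(unfold(X, "person")[0], [1, 3, 5, 7])

    @pytest.mark.parametrize("mode", [0, 1, 2, "person", "symptom", "time"])
    def test_refold_inverts_unfold(self, mode):
        for seed in range(10):
            X = random_cube(seed, (4, 3, 5))
            np.testing.assert_array_equal(refold(unfold(X, mode), mode, X.shape), X)

    def test_zero_cube_and_bad_mode(self):
        assert not unfold(np.zeros((2, 2, 2)), 1).any()
        with pytest.raises(ValueError, match="mode"):
            unfold(np.zeros((2, 2, 2)), "rows")


class TestReconstruct:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((3, 2))
        C = rng.standard_normal((2, 2))
        G = rng.standard_normal((2, 2, 2))
        np.testing.assert_allclose(
            reconstruct(A, B, C, G), triple_loop_reconstruct(A, B, C, G), atol=1e-12
        )

    def test_rank_one_constant_cube(self):
        n, m, T = 4, 3, 2
        A = np.full((n, 1), 1 / np.sqrt(n))
        B = np.full((m, 1), 1 / np.sqrt(m))
        C = np.full((T, 1), 1 / np.sqrt(T))
        G = np.array([[[np.sqrt(n * m * T) * 5.0]]])
        np.testing.assert_allclose(reconstruct(A, B, C, G), 5.0)

    def test_zero_core(self):
        rng = np.random.default_rng(0)
        out = reconstruct(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                          rng.normal(size=(3, 2)), np.zeros((2, 2, 2)))
        assert not out.any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="core"):
            reconstruct(np.eye(3), np.eye(3), np.eye(3), np.zeros((2, 2, 2)))


class TestHosvd:
    def test_columns_orthonormal(self):
        X = random_cube(1, (6, 5, 4))
        for M, k in zip(hosvd_init(X, 3, 2, 2), (3, 2, 2)):
            np.testing.assert_allclose(M.T @ M, np.eye(k), atol=1e-10)

    def test_full_size_spans_everything(self):
        X = random_cube(2, (4, 3, 3))
        A, B, C = hosvd_init(X, 4, 3, 3)
        G = compute_core(X, A, B, C)
        np.testing.assert_allclose(reconstruct(A, B, C, G), X, atol=1e-9)

    def test_recovers_planted_subspace(self):
        cube, truth = generate_planted_cube(
            PlantedCubeSpec(n=20, m=8, T=6, P=2, Q=2, R=2, noise_sd=0.0, seed=5)
        )
        A, B, C = hosvd_init(cube.values, 2, 2, 2)
        for M, key in ((A, "A"), (B, "B"), (C, "C")):
            # principal angles between estimated and planted column spaces
            s = np.linalg.svd(M.T @ truth[key], compute_uv=False)
            np.testing.assert_allclose(s, 1.0, atol=1e-8)

    def test_component_bounds(self):
        with pytest.raises(ValueError, match="component"):
            hosvd_init(random_cube(3, (4, 3, 3)), 5, 1, 1)


class TestComputeCore:
    def test_parseval_identity(self):
        X = random_cube(4, (6, 5, 4))
        A, B, C = hosvd_init(X, 3, 2, 2)
        G = compute_core(X, A, B, C)
        xhat = reconstruct(A, B, C, G)
        assert np.sum(G**2) == pytest.approx(np.sum(xhat**2), rel=1e-10)

    def test_recovers_planted_core(self):
        rng = np.random.default_rng(6)
        A, _ = np.linalg.qr(rng.standard_normal((6, 2)))
        B, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        C, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        G = rng.standard_normal((2, 2, 2))
        X = reconstruct(A, B, C, G)
        np.testing.assert_allclose(compute_core(X, A, B, C), G, atol=1e-10)

    def test_zero_cube_zero_core(self):
        A, B, C = hosvd_init(random_cube(7, (4, 3, 3)), 2, 2, 2)
        assert not compute_core(np.zeros((4, 3, 3)), A, B, C).any()

    def test_non_orthonormal_rejected(self):
        X = random_cube(8, (4, 3, 3))
        with pytest.raises(ValueError, match="orthonormal"):
            compute_core(X, 2 * np.eye(4, 2), np.eye(3, 2), np.eye(3, 2))


class TestFitAls:
    def test_saturated_model_reaches_full_fit(self):
        X = random_cube(9, (5, 4, 3))
        res = fit_als(X, 5, 4, 3, n_starts=1)
        assert res.fit_percent == pytest.approx(100.0, abs=1e-6)

    def test_noise_free_planted(self):
        cube, _ = generate_planted_cube(PlantedCubeSpec(noise_sd=0.0, seed=11))
        res = fit_als(cube.values, 3, 2, 2, seed=11)
        assert res.fit_percent >= 99.999

    def test_deterministic_per_seed(self):
        X = random_cube(10, (8, 6, 5))
        a = fit_als(X, 2, 2, 2, seed=3)
        b = fit_als(X, 2, 2, 2, seed=3)
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.core, b.core)
        assert a.fit_percent == b.fit_percent

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_trace_monotone_and_beats_hosvd(self, seed):
        X = random_cube(seed, (7, 5, 4))
        res = fit_als(X, 3, 2, 2, seed=seed, n_starts=3)
        assert np.all(np.diff(res.fit_trace) >= -1e-10)
        hosvd_only = fit_als(X, 3, 2, 2, n_starts=1, max_iter=1)
        assert res.fit_percent >= hosvd_only.fit_trace[0] - 1e-9

    def test_sign_convention(self):
        X = random_cube(12, (7, 5, 4))
        res = fit_als(X, 3, 2, 2, seed=0)
        for M in (res.A, res.B, res.C):
            for c in range(M.shape[1]):
                assert M[np.argmax(np.abs(M[:, c])), c] > 0

    def test_rotation_indeterminacy(self):
        X = random_cube(13, (7, 5, 4))
        res = fit_als(X, 3, 2, 2, seed=0)
        rng = np.random.default_rng(1)
        Rm, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        A2 = res.A @ Rm
        G2 = np.einsum("pqr,ps->sqr", res.core, Rm)
        np.testing.assert_allclose(
            reconstruct(A2, res.B, res.C, G2), res.reconstruct(), atol=1e-10
        )

    def test_component_ordering_by_explained_ss(self):
        X = random_cube(14, (8, 6, 5))
        res = fit_als(X, 3, 2, 2, seed=0)
        ss = np.sum(res.core.reshape(3, -1) ** 2, axis=1)
        assert np.all(np.diff(ss) <= 1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_als(random_cube(0, (3, 3, 3)), 4, 1, 1)
        bad = random_cube(0, (3, 3, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(Exception):
            Tucker3(bad, (1, 1, 1))


class TestFitPercentage:
    def test_perfect_and_zero_fit(self):
        X = random_cube(15, (5, 4, 3))
        full = fit_als(X, 5, 4, 3, n_starts=1)
        assert fit_percentage(X, full).fit_percent == pytest.approx(100.0, abs=1e-6)

    def test_degenerate_cube_rejected(self):
        X = random_cube(16, (4, 3, 3))
        model = fit_als(X, 1, 1, 1, n_starts=1)
        with pytest.raises(ValueError, match="zero"):
            fit_percentage(np.zeros_like(X), model)

    def test_noisy_fit_near_construction_expectation(self):
        cube, truth = generate_planted_cube(PlantedCubeSpec(target_fit=80.0, seed=17))
        res = fit_als(cube.values, 3, 2, 2, seed=17)
        assert res.fit_percent == pytest.approx(truth["expected_fit"], abs=2.0)
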