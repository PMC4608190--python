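"""Synthetic-data generators: determinism and construction guarantees."""
import numpy as np
import pytest
from scipy.cluster.vq import kmeans2

from hetcube.cube import QIDS_RAW_ITEMS, build_cube, merge_top_category, recode_items
from hetcube.preprocess import preprocess
from hetcube.selection import grid_search, select_model
from hetcube.simulate import (
    PlantedCubeSpec,
    QidsLikeSpec,
    generate_growth_data,
    generate_lca_data,
    generate_planted_cube,
    generate_qids_like,
    noise_sd_for_expected_fit,
)
from hetcube.tucker import fit_als


class TestPlantedCube:
    def test_deterministic_per_seed(self):
        a, _ = generate_planted_cube(PlantedCubeSpec(seed=9))
        b, _ = generate_planted_cube(PlantedCubeSpec(seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_free_fit_is_exact(self):
        cube, _ = generate_planted_cube(PlantedCubeSpec(noise_sd=0.0, seed=1))
        res = fit_als(cube.values, 3, 2, 2, seed=1)
        assert res.fit_percent == pytest.approx(100.0, abs=1e-6)

    def test_expected_fit_matches_construction(self):
        # n*m*T = 8856 >= 5000: the law-of-large-numbers regime
        cube, truth = generate_planted_cube(PlantedCubeSpec(target_fit=80.0, seed=2))
        assert truth["expected_fit"] == pytest.approx(80.0, abs=1e-9)
        res = fit_als(cube.values, 3, 2, 2, seed=2)
        assert res.fit_percent == pytest.approx(80.0, abs=2.0)

    def test_noise_sd_helper_is_consistent(self):
        sd = noise_sd_for_expected_fit(100.0, 1000, 50.0)
        assert 100.0 / (100.0 + 1000 * sd**2) == pytest.approx(0.5)

    def test_ground_truth_reconstructs_signal(self):
        _, truth = generate_planted_cube(PlantedCubeSpec(n=15, m=8, T=6, seed=3))
        from hetcube.tucker import reconstruct

        np.testing.assert_allclose(
            reconstruct(truth["A"], truth["B"], truth["C"], truth["G"]),
            truth["signal"], atol=1e-9,
        )

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PlantedCubeSpec(n=2, P=3)
        with pytest.raises(ValueError):
            PlantedCubeSpec(noise_sd=-1.0)


class TestQidsLike:
    def test_deterministic_and_complete(self):
        rec1, _ = generate_qids_like(QidsLikeSpec(seed=4))
        rec2, truth = generate_qids_like(QidsLikeSpec(seed=4))
        assert rec1.equals(rec2)
        cube = build_cube(rec1)
        assert cube.shape == (82, 12, 9)
        assert set(rec1.score) <= {0, 1, 2}
        assert len(truth["archetypes"]) == 82

    def test_downward_severity_trend(self):
        rec, _ = generate_qids_like(QidsLikeSpec(seed=5))
        cube = build_cube(rec)
        means = cube.values.mean(axis=(0, 1))
        assert means[-1] < means[0]

    def test_raw_scale_exercises_recoding(self):
        rec, _ = generate_qids_like(QidsLikeSpec(seed=6, raw_scale=True))
        assert set(rec["item"]) == set(QIDS_RAW_ITEMS)
        assert rec.score.max() <= 3
        cube = build_cube(recode_items(merge_top_category(rec)))
        assert cube.shape == (82, 12, 9)

    def test_planted_structure_dominates_noise_structure(self):
        # with the planted interactions removed, the fit gained by the
        # (3,2,2) model over (1,1,1) collapses to residual-noise overfitting
        def gain(spec):
            pre = preprocess(build_cube(generate_qids_like(spec)[0]))
            grid = grid_search(pre, 3, 2, 2, seed=spec.seed)
            fits = grid.fits()
            return fits[(3, 2, 2)] - fits[(1, 1, 1)]

        structured = gain(QidsLikeSpec(seed=7))
        flat = gain(QidsLikeSpec(seed=7, interaction_scale=0.0))
        assert structured > 2.5 * flat

    def test_default_spec_selects_planted_sizes(self):
        rec, _ = generate_qids_like(QidsLikeSpec(seed=8))
        pre = preprocess(build_cube(rec))
        grid = grid_search(pre, 4, 4, 4, seed=8)
        assert select_model(grid, 1.0).selected == (3, 2, 2)

    def test_invalid_specs(self):
        with pytest.raises(ValueError, match="simplex"):
            QidsLikeSpec(archetype_weights=(0.5, 0.6))
        with pytest.raises(ValueError, match="cutpoints"):
            QidsLikeSpec(cutpoints=(1.0, 0.5))
        with pytest.raises(ValueError, match="m=12"):
            QidsLikeSpec(m=10, raw_scale=True)


class TestLcaGenerator:
    def test_degenerate_cases(self):
        probs = np.zeros((1, 4, 3))
        probs[:, :, 2] = 1.0
        X, z = generate_lca_data([1.0], probs, 25, seed=0)
        assert (X == 2).all() and (z == 0).all()

    def test_marginal_frequencies_converge(self):
        probs = np.array(
            [
                [[0.7, 0.2, 0.1]] * 4,
                [[0.1, 0.3, 0.6]] * 4,
            ]
        )
        w = np.array([0.6, 0.4])
        X, _ = generate_lca_data(w, probs, 10000, seed=1)
        implied = np.einsum("k,kjc->jc", w, probs)
        for j in range(4):
            freq = np.bincount(X[:, j], minlength=3) / len(X)
            np.testing.assert_allclose(freq, implied[j], atol=0.02)

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            generate_lca_data([0.5, 0.6], np.full((2, 2, 3), 1 / 3), 10)
        bad = np.full((1, 2, 3), 0.5)
        with pytest.raises(ValueError):
            generate_lca_data([1.0], bad, 10)


class TestGrowthGenerator:
    def test_noiseless_rows_are_exact_polynomials(self):
        Y, z = generate_growth_data(
            [(1.0, (10.0, -1.0, 0.1))], 5, 6, kind="lcgm", sigma2=0.0, seed=0
        )
        t = np.arange(1, 7.0)
        expected = np.tile(10.0 - t + 0.1 * t * t, (5, 1))
        np.testing.assert_allclose(Y, expected, atol=1e-12)

    def test_well_separated_classes_cluster(self):
        Y, z = generate_growth_data(
            [(0.5, (30.0, -2.0, 0.0)), (0.5, (10.0, 0.5, 0.0))],
            200, 9, kind="lcgm", sigma2=1.0, seed=1,
        )
        _, labels = kmeans2(Y, 2, seed=0, minit="++")
        agreement = max(np.mean(labels == z), np.mean(labels != z))
        assert agreement >= 0.95

    def test_deterministic(self):
        a, _ = generate_growth_data([(1.0, (5, 0, 0))], 10, 5, sigma2=1.0, seed=2)
        b, _ = generate_growth_data([(1.0, (5, 0, 0))], 10, 5, sigma2=1.0, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_invalid_variances(self):
        with pytest.raises(ValueError):
            generate_growth_data([(1.0, (5, 0, 0))], 10, 5, sigma2=-1.0)
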