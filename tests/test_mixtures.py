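"""Latent class analysis, growth mixtures and information criteria."""
import numpy as np
import pytest

from hetcube.interpret import match_components
from hetcube.mixtures import (
    GrowthMixture,
    LatentClassModel,
    class_profile_table,
    comparison_table,
    fit_growth_mixture,
    fit_lca,
    information_criteria,
)
from hetcube.simulate import generate_growth_data, generate_lca_data

WELL_SEPARATED = np.array(
    [
        [[0.85, 0.10, 0.05]] * 6,
        [[0.05, 0.10, 0.85]] * 6,
    ]
)


class TestInformationCriteria:
    def test_formulas(self):
        ic = information_criteria(-10.0, 2, 100)
        assert ic.aic == pytest.approx(24.0)
        assert ic.bic == pytest.approx(20.0 + 2 * np.log(100))

    def test_bic_exceeds_aic_for_n_at_least_8(self):
        ic = information_criteria(-5.0, 3, 8)
        assert ic.bic >= ic.aic

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 0, 100)
        with pytest.raises(ValueError):
            information_criteria(np.nan, 2, 100)


class TestLatentClass:
    def test_one_class_is_empirical_frequencies(self):
        X, _ = generate_lca_data([1.0], WELL_SEPARATED[:1], 200, seed=0)
        res = fit_lca(X, 1)
        assert res.weights == pytest.approx([1.0])
        n, m = X.shape
        for j in range(m):
            freq = np.bincount(X[:, j], minlength=3) / n
            np.testing.assert_allclose(res.item_probs[0, j], freq, atol=1e-8)

    def test_one_class_loglik_multinomial_oracle(self):
        X, _ = generate_lca_data([1.0], WELL_SEPARATED[:1], 200, seed=1)
        res = fit_lca(X, 1)
        n, m = X.shape
        oracle = 0.0
        for j in range(m):
            counts = np.bincount(X[:, j], minlength=3)
            freq = counts / n
            oracle += sum(c * np.log(f) for c, f in zip(counts, freq) if c > 0)
        assert res.loglik == pytest.approx(oracle, abs=1e-6)

    def test_em_loglik_monotone(self):
        X, _ = generate_lca_data([0.5, 0.5], WELL_SEPARATED, 300, seed=2)
        res = fit_lca(X, 2, seed=2)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7)

    def test_two_class_recovery(self):
        X, _ = generate_lca_data([0.5, 0.5], WELL_SEPARATED, 1000, seed=3)
        res = fit_lca(X, 2, seed=3)
        m = match_components(
            res.item_probs.reshape(2, -1).T, WELL_SEPARATED.reshape(2, -1).T
        )
        err = np.abs(res.item_probs[list(m.permutation)] - WELL_SEPARATED).max()
        assert err <= 0.05

    def test_classes_ordered_by_weight(self):
        X, _ = generate_lca_data([0.7, 0.3], WELL_SEPARATED, 600, seed=4)
        res = fit_lca(X, 2, seed=4)
        assert res.weights[0] >= res.weights[1]

    def test_n_params_convention(self):
        X, _ = generate_lca_data([0.5, 0.5], WELL_SEPARATED, 50, seed=5)
        assert LatentClassModel(X, 2).n_params == (2 - 1) + 2 * 6 * 2

    def test_invalid_inputs(self):
        X, _ = generate_lca_data([1.0], WELL_SEPARATED[:1], 10, seed=6)
        with pytest.raises(ValueError, match="exceeds"):
            fit_lca(X, 11)
        with pytest.raises(ValueError):
            fit_lca(X + 5, 2)

    def test_profile_table_is_nonzero_probability(self):
        X, _ = generate_lca_data([0.5, 0.5], WELL_SEPARATED, 400, seed=7)
        res = fit_lca(X, 2, seed=7)
        table = class_profile_table(res)
        np.testing.assert_allclose(
            table.to_numpy(), 1.0 - res.item_probs[:, :, 0].T, atol=1e-12
        )
        constant = np.zeros((20, 3), dtype=int)
        res1 = fit_lca(constant, 1)
        assert class_profile_table(res1).to_numpy() == pytest.approx(0.0, abs=1e-9)


TWO_CLASS_CURVES = [(0.6, (20.0, -2.0, 0.05)), (0.4, (22.0, -0.5, 0.0))]


class TestGrowthMixture:
    def test_one_class_is_pooled_quadratic_ols(self):
        Y, _ = generate_growth_data(
            [(1.0, (15.0, -1.0, 0.02))], 80, 9, kind="lcgm", sigma2=2.0, seed=0
        )
        res = fit_growth_mixture(Y, 1, kind="lcgm", seed=0)
        t = np.arange(1, 10.0)
        X = np.column_stack([np.ones(9), t, t * t])
        beta, *_ = np.linalg.lstsq(X, Y.mean(axis=0), rcond=None)
        np.testing.assert_allclose(res.coef[0], beta, atol=1e-8)
        resid = Y - X @ beta
        assert res.sigma2 == pytest.approx(np.mean(resid**2), rel=1e-6)

    def test_em_loglik_monotone(self):
        Y, _ = generate_growth_data(TWO_CLASS_CURVES, 150, 9, sigma2=4.0, tau2=2.0, seed=1)
        for kind in ("lcgm", "gmm_ri"):
            res = fit_growth_mixture(Y, 2, kind=kind, seed=1)
            assert np.all(np.diff(res.loglik_trace) >= -1e-6)

    def test_class_proportion_recovery(self):
        Y, z = generate_growth_data(
            TWO_CLASS_CURVES, 500, 9, kind="lcgm", sigma2=4.0, tau2=0.0, seed=2
        )
        res = fit_growth_mixture(Y, 2, kind="lcgm", seed=2)
        truth = np.bincount(z) / len(z)
        assert res.weights[0] == pytest.approx(max(truth), abs=0.05)

    def test_random_intercept_nests_lcgm(self):
        for seed in range(5):
            Y, _ = generate_growth_data(
                TWO_CLASS_CURVES, 120, 9, sigma2=4.0, tau2=3.0, seed=seed
            )
            lcgm = fit_growth_mixture(Y, 2, kind="lcgm", seed=seed)
            gmm = fit_growth_mixture(Y, 2, kind="gmm_ri", seed=seed)
            assert gmm.loglik >= lcgm.loglik - 1e-6

    def test_lcgm_fixes_tau_to_zero(self):
        Y, _ = generate_growth_data(TWO_CLASS_CURVES, 100, 9, sigma2=4.0, seed=3)
        res = fit_growth_mixture(Y, 2, kind="lcgm", seed=3)
        assert res.tau2 == 0.0
        assert res.n_params + 1 == GrowthMixture(Y, 2, kind="gmm_ri").n_params

    def test_invalid_inputs(self):
        Y, _ = generate_growth_data(TWO_CLASS_CURVES, 20, 9, sigma2=1.0, seed=4)
        with pytest.raises(ValueError, match="T >= 3"):
            fit_growth_mixture(Y[:, :2], 1)
        with pytest.raises(ValueError, match="kind"):
            fit_growth_mixture(Y, 2, kind="banana")
        with pytest.raises(ValueError, match="K"):
            fit_growth_mixture(Y, 21)

    def test_small_class_warning(self):
        Y, _ = generate_growth_data(
            [(0.96, (20.0, -2.0, 0.05)), (0.04, (40.0, 0.0, 0.0))],
            120, 9, kind="lcgm", sigma2=1.0, seed=5,
        )
        with pytest.warns(UserWarning, match="smallest class"):
            fit_growth_mixture(Y, 2, kind="lcgm", seed=5)


def test_bic_rejects_spurious_second_class_on_homogeneous_data():
    picks = 0
    for seed in range(10):
        Y, _ = generate_growth_data(
            [(1.0, (18.0, -1.2, 0.03))], 500, 9, kind="lcgm", sigma2=4.0, seed=seed
        )
        k1 = fit_growth_mixture(Y, 1, kind="lcgm", seed=seed)
        k2 = fit_growth_mixture(Y, 2, kind="lcgm", seed=seed, n_starts=4)
        picks += k1.bic < k2.bic
    assert picks >= 9


def test_comparison_table_shape():
    Y, _ = generate_growth_data(TWO_CLASS_CURVES, 80, 9, sigma2=4.0, tau2=2.0, seed=6)
    models = {
        "LCGM 2-class": fit_growth_mixture(Y, 2, kind="lcgm", seed=6),
        "GMM 2-class": fit_growth_mixture(Y, 2, kind="gmm_ri", seed=6),
    }
    table = comparison_table(models)
    assert list(table.columns) == ["model", "k", "loglik", "AIC", "BIC"]
    assert len(table) == 2
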