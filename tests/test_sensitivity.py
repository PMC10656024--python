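import numpy as np
import pytest
from scipy.stats import ks_1samp, uniform
from sklearn.cross_decomposition import PLSRegression

from placigg.parameters import ParameterRange
from placigg.sensitivity import fit_oplsr, lhs_design, sensitivity_experiment


@pytest.fixture(scope="module")
def toy_ranges():
    return ParameterRange({f"p{j}": (0.0, 1.0) for j in range(6)})


class TestLhsDesign:
    def test_shape_and_bounds(self, ranges):
        d = lhs_design(ranges, 1000, seed=5)
        assert d.X.shape == (1000, 11)
        lo, hi = ranges.as_arrays()
        assert np.all(d.X >= lo) and np.all(d.X <= hi)

    def test_stratification_covers_every_bin_once(self, toy_ranges):
        n = 100
        d = lhs_design(toy_ranges, n, seed=0)
        for j in range(d.X.shape[1]):
            bins = np.floor(d.X[:, j] * n).astype(int)
            assert sorted(bins) == list(range(n))

    def test_marginals_close_to_uniform(self, toy_ranges):
        d = lhs_design(toy_ranges, 1000, seed=1)
        for j in range(d.X.shape[1]):
            stat = ks_1samp(d.X[:, j], uniform.cdf).statistic
            assert stat < 0.05

    def test_degenerate_range_gives_constant_column(self):
        r = ParameterRange({"a": (2.0, 2.0), "b": (0.0, 1.0)})
        d = lhs_design(r, 50, seed=0)
        assert np.all(d.X[:, 0] == 2.0)

    def test_seed_determinism(self, toy_ranges):
        a = lhs_design(toy_ranges, 64, seed=7).X
        b = lhs_design(toy_ranges, 64, seed=7).X
        np.testing.assert_array_equal(a, b)

    def test_fewer_samples_than_parameters_rejected(self, toy_ranges):
        with pytest.raises(ValueError):
            lhs_design(toy_ranges, 3, seed=0)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(12)
    X = rng.uniform(size=(400, 8))
    y = 3.0 * X[:, 2] + 1e-4 * rng.standard_normal(400)
    return X, y


class TestOplsr:
    def test_single_driver_dominates_vip(self, linear_data):
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=0, seed=0)
        assert m.q2 > 0.99
        big = np.abs(m.vip) > 1.0
        assert big.sum() == 1 and big[2]
        assert m.vip[2] > 0  # positively signed along its LV1 loading

    def test_vip_normalization(self, linear_data):
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=0, seed=0)
        assert (m.vip**2).sum() == pytest.approx(X.shape[1], abs=1e-9)

    def test_predictions_match_plain_two_component_pls(self, linear_data):
        """Orthogonalization is a rotation of the latent plane; the fitted
        subspace and hence the predictions are those of ordinary PLS1."""
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=0, seed=0)
        sk = PLSRegression(n_components=2, scale=True).fit(X, y)
        np.testing.assert_allclose(
            m.predict(X), sk.predict(X).ravel(), rtol=1e-6, atol=1e-8
        )

    def test_rotation_preserves_fitted_values(self, linear_data):
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=0, seed=0)
        # scores @ y-loadings reconstructs the same in-sample fit as the
        # regression vector.
        z_fit = m.scores @ m.y_loadings
        Z = (X - m.x_mean) / m.x_std
        np.testing.assert_allclose(z_fit, Z @ m.coef, rtol=1e-8, atol=1e-10)

    def test_lv1_carries_the_explained_variance(self, linear_data):
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=0, seed=0)
        assert m.y_loadings[1] == pytest.approx(0.0, abs=1e-12)
        assert m.y_variance_lv1 > 0.99

    def test_permuted_outcome_has_no_predictive_power(self, linear_data):
        X, y = linear_data
        rng = np.random.default_rng(3)
        m = fit_oplsr(X, rng.permutation(y), n_permutations=0, seed=0)
        assert m.q2 < 0.2

    def test_q2_matches_printed_formula(self, linear_data):
        """Q^2 = 1 - PRESS/TSS over held-out folds, recomputed by hand."""
        X, y = linear_data
        m = fit_oplsr(X, y, cv_folds=5, n_permutations=0, seed=4)
        from placigg.sensitivity import _cv_press, _kfold_indices

        rng = np.random.default_rng(4)
        folds = _kfold_indices(X.shape[0], 5, rng)
        press = _cv_press(X, y, folds)
        assert m.q2 == pytest.approx(1.0 - press / ((y - y.mean()) ** 2).sum())

    def test_permutation_p_small_for_real_signal(self, linear_data):
        X, y = linear_data
        m = fit_oplsr(X, y, n_permutations=50, seed=0)
        assert m.permutation_p == 0.0

    def test_seed_reproducibility(self, linear_data):
        X, y = linear_data
        a = fit_oplsr(X, y, n_permutations=25, seed=8)
        b = fit_oplsr(X, y, n_permutations=25, seed=8)
        assert a.q2 == b.q2
        assert a.permutation_p == b.permutation_p

    def test_constant_outcome_rejected(self, linear_data):
        X, _ = linear_data
        with pytest.raises(ValueError):
            fit_oplsr(X, np.ones(X.shape[0]), n_permutations=0, seed=0)


class TestExperiment:
    def test_shared_design_reuses_outcomes(self, ranges, small_design_outcomes):
        design, total, _ = small_design_outcomes
        out = sensitivity_experiment(
            outcome="total_igg", ranges=ranges, design=design,
            outcomes_vector=total, n_permutations=50,
        )
        assert out["n_effective"] == 150
        assert out["model"].q2 > 0.9

    def test_transfer_capacity_parameters_dominate(self, ranges, small_design_outcomes):
        design, total, _ = small_design_outcomes
        out = sensitivity_experiment(
            outcome="total_igg", ranges=ranges, design=design,
            outcomes_vector=total, n_permutations=0,
        )
        top3 = set(out["model"].top_vip(3))
        assert "k_trans" in top3 and "FcRnSTBtotal_end" in top3

    def test_constant_outcome_errors(self, ranges, small_design_outcomes):
        design, _, _ = small_design_outcomes
        with pytest.raises(ValueError):
            sensitivity_experiment(
                outcome="total_igg", ranges=ranges, design=design,
                outcomes_vector=np.ones(150), n_permutations=0,
            )

    def test_excess_failed_rows_abort(self, ranges, small_design_outcomes):
        design, total, _ = small_design_outcomes
        bad = total.copy()
        bad[:20] = np.nan
        with pytest.raises(RuntimeError):
            sensitivity_experiment(
                outcome="total_igg", ranges=ranges, design=design,
                outcomes_vector=bad, n_permutations=0,
            )

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_experiment(outcome="nope")
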