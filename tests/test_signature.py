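"""Level calling: skewness, ranked set sampling, EM fits, MAP assignment."""

import numpy as np
import pytest

import gatescribe as g
from gatescribe import errors
from gatescribe.signature import RSSConfig, _em_once


class TestSkewness:
    def test_symmetric_is_zero(self):
        assert g.compute_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_bernoulli_like_sample(self):
        # g1 of [0,0,0,10] equals (1-2p)/sqrt(p(1-p)) at p=0.25
        assert g.compute_skewness([0, 0, 0, 10]) == pytest.approx(1.1547, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=200)
        assert g.compute_skewness(-x) == pytest.approx(-g.compute_skewness(x))

    def test_zero_variance_convention(self):
        assert g.compute_skewness([2.0, 2.0, 2.0, 2.0]) == 0.0


class TestRSS:
    def test_constant_input(self):
        left, right, ok = g.ranked_set_sample([3.0] * 10, RSSConfig(n_cycles=5, seed=0))
        assert ok and np.all(left == 3.0) and np.all(right == 3.0)

    def test_output_sizes(self):
        left, right, _ = g.ranked_set_sample(
            np.arange(100.0), RSSConfig(n_cycles=5, seed=1)
        )
        assert len(left) == 5 and len(right) == 5

    def test_uniform_rightmost_mean_is_two_thirds(self):
        # E[max of two U(0,1)] = 2/3, E[min] = 1/3
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 1, 50_000)
        left, right, _ = g.ranked_set_sample(values, RSSConfig(n_cycles=100_000, seed=2))
        assert right.mean() == pytest.approx(2 / 3, abs=0.01)
        assert left.mean() == pytest.approx(1 / 3, abs=0.01)

    def test_small_input_fallback(self):
        with pytest.warns(UserWarning):
            left, right, ok = g.ranked_set_sample([1.0, 2.0], RSSConfig(n_cycles=5))
        assert not ok and list(left) == [1.0, 2.0]

    def test_tail_selection_follows_skew_sign(self):
        rng = np.random.default_rng(4)
        right_skewed = np.exp(rng.normal(0, 1, 20_000))
        cfg = RSSConfig(n_cycles=50_000, seed=5)
        sample = g.select_tail_sample(right_skewed, cfg)
        assert sample.mean() > right_skewed.mean()
        left_skewed = -right_skewed
        sample = g.select_tail_sample(left_skewed, cfg)
        assert sample.mean() < left_skewed.mean()

    def test_symmetric_sample_selects_leftmost(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 10)
        assert g.compute_skewness(x) == pytest.approx(0.0)
        cfg = RSSConfig(n_cycles=5000, seed=6)
        sample = g.select_tail_sample(x, cfg)
        left, _, _ = g.ranked_set_sample(x, cfg)
        np.testing.assert_array_equal(sample, left)


class TestGMMFit:
    def test_recovers_means_variable_variance(self, two_component_values):
        fit = g.fit_marker_gmm(two_component_values, G=2, variance_mode="V")
        assert fit.means == pytest.approx([0.0, 5.0], abs=0.1)
        assert fit.weights == pytest.approx([0.5, 0.5], abs=0.05)

    def test_equal_variance_shared_sd(self, two_component_values):
        fit = g.fit_marker_gmm(two_component_values, G=2, variance_mode="E")
        assert fit.sds[0] == fit.sds[1]
        assert fit.sds[0] == pytest.approx(0.25, abs=0.05)

    def test_agrees_with_sklearn(self, two_component_values):
        """Independent cross-check of the EM against sklearn's mixtures."""
        from sklearn.mixture import GaussianMixture

        x = two_component_values.reshape(-1, 1)
        for mode, cov in (("V", "diag"), ("E", "tied")):
            ours = g.fit_marker_gmm(two_component_values, G=2, variance_mode=mode)
            ref = GaussianMixture(2, covariance_type=cov, random_state=0, n_init=3).fit(x)
            np.testing.assert_allclose(
                ours.means, np.sort(ref.means_.ravel()), atol=0.05
            )

    def test_three_components(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(c, 0.3, 700) for c in (0.0, 3.0, 6.0)])
        fit = g.fit_marker_gmm(x, G=3, variance_mode="V")
        assert fit.means == pytest.approx([0.0, 3.0, 6.0], abs=0.1)

    def test_degenerate_input(self):
        with pytest.raises(errors.DegenerateDataError):
            g.fit_marker_gmm([1.0] * 100, G=2)

    def test_too_few_values(self):
        with pytest.raises(errors.ParameterError):
            g.fit_marker_gmm([0.0, 1.0, 2.0], G=2)

    def test_em_monotone_likelihood(self):
        rng = np.random.default_rng(14)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(4, 0.5, 300)])
        fit = _em_once(x, 2, "V")
        assert fit.converged
        assert np.isfinite(fit.log_likelihood)

    def test_parameter_recovery_rmse(self):
        """20 seeded two-component simulations at 6 sd separation: RMSE of
        recovered means stays below 0.1 sd."""
        sd = 0.4
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, sd, 800), rng.normal(6 * sd, sd, 800)])
            fit = g.fit_marker_gmm(x, G=2, variance_mode="V")
            errs.extend([(fit.means[0] - 0.0) ** 2, (fit.means[1] - 6 * sd) ** 2])
        rmse = np.sqrt(np.mean(errs))
        assert rmse <= 0.1 * sd


class TestAssignment:
    def test_equal_mixture_boundary_at_midpoint(self):
        fit = g.GMMFit(
            means=[0.0, 5.0], sds=[1.0, 1.0], weights=[0.5, 0.5], G=2, variance_mode="E"
        )
        assert list(g.assign_expression_levels([2.4, 2.6], fit)) == ["-", "+"]

    def test_weighted_mixture_shifts_boundary(self):
        # posterior equality at 2.5 + ln(9)/5 ~ 2.94, so 2.5 is still negative
        fit = g.GMMFit(
            means=[0.0, 5.0], sds=[1.0, 1.0], weights=[0.9, 0.1], G=2, variance_mode="E"
        )
        boundary = 2.5 + np.log(9) / 5
        values = [2.5, boundary - 0.01, boundary + 0.01]
        assert list(g.assign_expression_levels(values, fit)) == ["-", "-", "+"]

    def test_three_component_middle_symbol(self):
        fit = g.GMMFit(
            means=[0.0, 3.0, 6.0], sds=[1.0] * 3, weights=[1 / 3] * 3, G=3,
            variance_mode="E",
        )
        assert list(g.assign_expression_levels([4.4], fit)) == ["m"]

    def test_assignment_deterministic(self):
        fit = g.GMMFit(
            means=[0.0, 5.0], sds=[1.0, 1.0], weights=[0.5, 0.5], G=2, variance_mode="E"
        )
        x = np.random.default_rng(2).normal(2.5, 2, 500)
        a = g.assign_expression_levels(x, fit)
        b = g.assign_expression_levels(x, fit)
        np.testing.assert_array_equal(a, b)


class TestSignatureMatrix:
    def test_two_marker_recovery(self):
        rng = np.random.default_rng(21)
        n = 2000
        comp = rng.integers(0, 2, size=(n, 2))
        values = rng.normal(comp * 3.0, 0.3)
        m = g.ExpressionMatrix(values=values, marker_names=["A", "B"])
        sig, fits = g.build_signature_matrix(m, {"A": 2, "B": 2})
        expected = np.where(comp == 1, "+", "-")
        agreement = (sig.levels == expected).mean()
        assert agreement >= 0.99
        assert set(fits) == {"A", "B"}

    def test_g3_marker_emits_all_three_symbols(self):
        rng = np.random.default_rng(22)
        x = np.concatenate([rng.normal(c, 0.3, 500) for c in (0.0, 2.0, 4.0)])
        m = g.ExpressionMatrix(values=x.reshape(-1, 1), marker_names=["A"])
        sig, _ = g.build_signature_matrix(m, {"A": 3})
        assert set(sig.column("A")) == {"-", "m", "+"}

    def test_rss_vs_plain_on_balanced_mixture(self):
        rng = np.random.default_rng(23)
        x = np.concatenate([rng.normal(0, 0.3, 2500), rng.normal(2, 0.3, 2500)])
        m = g.ExpressionMatrix(values=x.reshape(-1, 1), marker_names=["A"])
        plain, _ = g.build_signature_matrix(m, {"A": 2}, use_rss=False, seed=1)
        rss, _ = g.build_signature_matrix(m, {"A": 2}, use_rss=True, seed=1)
        assert (plain.levels == rss.levels).mean() >= 0.98

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(24)
        x = rng.normal(0, 1, 1000) + (rng.random(1000) > 0.5) * 4
        m = g.ExpressionMatrix(values=x.reshape(-1, 1), marker_names=["A"])
        a, _ = g.build_signature_matrix(m, {"A": 2}, use_rss=True, seed=7)
        b, _ = g.build_signature_matrix(m, {"A": 2}, use_rss=True, seed=7)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_unknown_marker_rejected(self):
        m = g.ExpressionMatrix(values=np.zeros((5, 1)) + np.arange(5)[:, None], marker_names=["A"])
        with pytest.raises(errors.ParameterError, match="B"):
            g.build_signature_matrix(m, {"B": 2})

    def test_skipped_markers_absent(self):
        rng = np.random.default_rng(25)
        values = np.column_stack([rng.normal(0, 1, 200) + (rng.random(200) > 0.5) * 5,
                                  rng.normal(0, 1, 200)])
        m = g.ExpressionMatrix(values=values, marker_names=["A", "B"])
        sig, _ = g.build_signature_matrix(m, {"A": 2})
        assert sig.marker_names == ["A"]
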