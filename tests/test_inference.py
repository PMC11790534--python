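"""DIC, model ranking, posterior-overlap tests, cross-modality correlation."""

import math

import numpy as np
import pytest
from scipy import stats

from wienerfit.generate import GroundTruth, exp1_design, generate_experiment1
from wienerfit.inference import (
    ModelScore,
    compare_models,
    cross_modality_correlation,
    dic,
    dic_from_deviance,
    posterior_overlap_test,
)
from wienerfit.sampler import fit_model


class TestDIC:
    def test_degenerate_posterior_has_zero_penalty(self):
        value, p_d = dic_from_deviance(np.full(500, 123.4), 123.4)
        assert p_d == pytest.approx(0.0, abs=1e-12)
        assert value == pytest.approx(123.4, abs=1e-12)

    def test_matches_conjugate_normal_closed_form(self):
        # y_i ~ N(theta, sigma^2) with known sigma, theta ~ N(mu0, tau^2):
        # the posterior is Normal(m, V) in closed form, so the posterior
        # mean deviance and the plug-in deviance are available analytically
        rng = np.random.default_rng(6)
        y = rng.normal(1.0, 2.0, size=40)
        sigma, mu0, tau = 2.0, 0.0, 3.0
        n = y.size
        lam = 1 / tau**2 + n / sigma**2
        m = (mu0 / tau**2 + y.sum() / sigma**2) / lam
        V = 1 / lam

        def deviance(theta):
            return n * math.log(2 * math.pi * sigma**2) + ((y - theta) ** 2).sum() / sigma**2

        mean_dev = deviance(m) + n * V / sigma**2
        expected_dic = mean_dev + (mean_dev - deviance(m))
        # any trace with the exact posterior-mean deviance is equivalent
        trace = np.array([mean_dev - 0.5, mean_dev + 0.5])
        value, p_d = dic_from_deviance(trace, deviance(m))
        assert value == pytest.approx(expected_dic, abs=1e-6)
        assert p_d == pytest.approx(n * V / sigma**2, abs=1e-6)

    def test_nonfinite_deviances_named(self):
        trace = np.array([1.0, np.inf, 2.0])
        with pytest.raises(ValueError, match=r"\[1\]"):
            dic_from_deviance(trace, 1.0)

    def test_unused_split_parameter_costs_a_positive_penalty(self):
        # generating truth has no modality effect at all; the drift split of
        # M2 is pure flexibility and should cost DIC on average
        truth = GroundTruth(t_point=0.5, t_swipe=0.5, rho_subject=1.0)
        deltas = []
        for rep in range(6):
            df = generate_experiment1(
                exp1_design(n_subjects=4, trials_per_block=24, seed=500 + rep), truth
            )
            d1 = fit_model("M1", df, draws=400, burn_in=120, chains=2, seed=rep).dic
            d2 = fit_model("M2", df, draws=400, burn_in=120, chains=2, seed=rep).dic
            deltas.append(d2 - d1)
        assert np.mean(deltas) > 0

    def test_dic_recomputed_from_fit_trace(self, exp1_small):
        fit = fit_model("M1", exp1_small, draws=300, burn_in=100, chains=2, seed=1)
        assert dic(fit) == pytest.approx(fit.dic)


class TestCompareModels:
    # the four published deviance information criteria of the modality
    # model family, used as pure ranking-logic inputs
    PRINTED = [
        ModelScore("M1", 38863.42, "None", 0),
        ModelScore("M2", 38746.18, "Drift rate depends on the response modality", 1),
        ModelScore("M3", 34590.90, "Non-decision time depends on the response modality", 1),
        ModelScore("M4", 34500.64, "Drift rate and non-decision time depend on the response modality", 2),
    ]

    def test_published_dic_values_rank_m4_first(self):
        table = compare_models(self.PRINTED)
        assert list(table["model"]) == ["M4", "M3", "M2", "M1"]
        assert table["delta_dic"].iloc[0] == 0.0
        assert (table["delta_dic"].diff().dropna() > 0).all()

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="two fits"):
            compare_models(self.PRINTED[:1])

    def test_fits_on_different_data_rejected(self):
        a = ModelScore("A", 10.0, "", 0, data_hash=1)
        b = ModelScore("B", 11.0, "", 0, data_hash=2)
        with pytest.raises(ValueError, match="differing"):
            compare_models([a, b])

    def test_dic_tie_broken_by_fewer_dependencies(self):
        a = ModelScore("simple", 100.0, "", 0)
        b = ModelScore("complex", 100.0, "", 2)
        assert list(compare_models([b, a])["model"]) == ["simple", "complex"]

    def test_ranking_invariant_to_input_order(self):
        fwd = compare_models(self.PRINTED)
        rev = compare_models(self.PRINTED[::-1])
        assert list(fwd["model"]) == list(rev["model"])


class TestPosteriorOverlap:
    def test_identical_samples_give_exactly_half(self):
        x = np.random.default_rng(0).normal(size=2000)
        res = posterior_overlap_test(x, x)
        assert res.probability == 0.5 and not res.significant

    def test_disjoint_samples_give_one(self):
        res = posterior_overlap_test(np.arange(10, 20), np.arange(0, 10))
        assert res.probability == 1.0 and res.significant

    def test_matches_normal_difference_closed_form(self):
        rng = np.random.default_rng(3)
        n = 5000
        a = rng.normal(0.3, 0.1, n)
        b = rng.normal(0.0, 0.1, n)
        exact = stats.norm.cdf(0.3 / math.sqrt(0.02))
        mc_se = math.sqrt(exact * (1 - exact) / n)
        res = posterior_overlap_test(a, b)
        assert abs(res.probability - exact) < 3 * mc_se

    def test_directional_probabilities_sum_to_one(self, rng):
        a = rng.normal(0, 1, 3000).round(1)  # rounding forces ties
        b = rng.normal(0.2, 1, 3000).round(1)
        p_ab = posterior_overlap_test(a, b).probability
        p_ba = posterior_overlap_test(b, a).probability
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_common_location_shift(self, rng):
        a = rng.normal(0.5, 0.2, 4000)
        b = rng.normal(0.3, 0.2, 4000)
        p0 = posterior_overlap_test(a, b).probability
        p1 = posterior_overlap_test(a + 10.0, b + 10.0).probability
        assert p0 == p1

    def test_unequal_lengths_need_explicit_resampling(self, rng):
        a, b = rng.normal(size=1000), rng.normal(size=1500)
        with pytest.raises(ValueError, match="paired"):
            posterior_overlap_test(a, b, paired=True)
        res = posterior_overlap_test(a, b, paired=False, seed=1)
        assert 0.0 <= res.probability <= 1.0

    def test_symmetric_significance_rule(self):
        assert posterior_overlap_test(np.arange(10, 20), np.arange(10)).significant
        assert posterior_overlap_test(np.arange(10), np.arange(10, 20)).significant
        draws = np.random.default_rng(5).normal(size=(2, 2000))
        assert not posterior_overlap_test(draws[0], draws[1]).significant


class TestCrossModalityCorrelation:
    def test_identical_subject_values_give_unit_correlation(self):
        x = np.linspace(0.2, 1.5, 27)
        res = cross_modality_correlation(x, x, "v")
        assert res.r == pytest.approx(1.0)

    def test_df_is_subjects_minus_two(self, rng):
        x, y = rng.normal(size=27), rng.normal(size=27)
        assert cross_modality_correlation(x, y, "t").df == 25

    def test_subject_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_modality_correlation(rng.normal(size=10), rng.normal(size=12), "v")

    def test_sampling_distribution_covers_generating_correlation(self):
        # bivariate-normal subject effects with rho = 0.6, n = 27: the
        # Fisher-z 95% sampling interval around rho should contain the
        # estimate in ~95% of replicates
        rho, n = 0.6, 27
        rng = np.random.default_rng(8)
        zc = np.arctanh(rho)
        half = 1.96 / math.sqrt(n - 3)
        inside = 0
        for _ in range(100):
            cov = [[1, rho], [rho, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            r = cross_modality_correlation(xy[:, 0], xy[:, 1], "v").r
            inside += abs(np.arctanh(r) - zc) <= half
        assert inside >= 90

    def test_two_separate_fits_correlate_subject_means(self, exp1_small):
        point = exp1_small[exp1_small["modality"] == "point"]
        swipe = exp1_small[exp1_small["modality"] == "swipe"]
        fp = fit_model("M1", point, draws=300, burn_in=100, chains=2, seed=61)
        fs = fit_model("M1", swipe, draws=300, burn_in=100, chains=2, seed=62)
        res = cross_modality_correlation(fp, fs, "t")
        assert res.df == fp.samples.subjects.__len__() - 2
        assert -1.0 <= res.r <= 1.0
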