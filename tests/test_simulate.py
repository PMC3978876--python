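"""Template-sampling simulator against exact binomial oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from qfikit.simulate import (
    ArtifactModel,
    SamplingModel,
    analytic_cv,
    artifact_site_call_probability,
    dilution_series,
    enumerate_fn_rate,
    expected_calls,
    false_negative_rate,
    simulate_false_positives,
    simulate_mutant_fraction,
)


def exact_fraction_moments(n, p):
    """Mean, SD and central 3rd/4th moments of Binomial(n, p)/n, enumerated."""
    ks = np.arange(n + 1)
    pmf = stats.binom.pmf(ks, n, p)
    x = ks / n
    mu = float(np.sum(pmf * x))
    c = x - mu
    var = float(np.sum(pmf * c**2))
    mu3 = float(np.sum(pmf * c**3))
    mu4 = float(np.sum(pmf * c**4))
    return mu, math.sqrt(var), mu3, mu4


def cv_standard_error(n, p, reps):
    """Delta-method SE of the sample CV of Binomial(n,p)/n at ``reps`` draws."""
    mu, sd, mu3, mu4 = exact_fraction_moments(n, p)
    var_mean = sd**2 / reps
    var_sd = (mu4 - sd**4) / (4 * sd**2 * reps)
    cov = mu3 / (2 * sd * reps)
    var_cv = (var_sd / mu**2 + sd**2 / mu**4 * var_mean
              - 2 * sd / mu**3 * cov)
    return math.sqrt(max(var_cv, 0.0))


class TestAnalyticCv:
    @pytest.mark.parametrize(
        "n,p,expected",
        [(379, 0.30, 7.84), (10, 0.5, 31.6)],
    )
    def test_closed_form(self, n, p, expected):
        assert analytic_cv(n, p) == pytest.approx(expected, abs=0.05)

    def test_limits(self):
        assert analytic_cv(1e12, 0.3) == pytest.approx(0.0, abs=1e-3)
        assert analytic_cv(100, 0.0) == 0.0
        assert analytic_cv(100, 1.0) == 0.0

    def test_decreasing_in_n(self):
        cvs = [analytic_cv(n, 0.3) for n in (10, 50, 200, 1000)]
        assert cvs == sorted(cvs, reverse=True)


class TestSimulateMutantFraction:
    def test_zero_mutant_fraction(self):
        out = simulate_mutant_fraction(
            SamplingModel(100, 0.0, replicates=500, seed=1)
        )
        assert out.mean_observed_fraction == 0.0
        assert out.cv_percent == 0.0

    def test_cv_matches_analytic_fixed_n(self):
        n, p, reps = 379, 0.30, 10000
        out = simulate_mutant_fraction(
            SamplingModel(n, p, replicates=reps, poisson_delivery=False, seed=0)
        )
        se = 100 * cv_standard_error(n, p, reps)
        assert out.cv_percent == pytest.approx(analytic_cv(n, p), abs=3 * se)

    def test_read_depth_converges_to_template_fraction(self):
        n, p = 95, 0.30
        deep = simulate_mutant_fraction(
            SamplingModel(n, p, read_depth=200000, replicates=4000,
                          poisson_delivery=False, seed=2)
        )
        inf = simulate_mutant_fraction(
            SamplingModel(n, p, read_depth=None, replicates=4000,
                          poisson_delivery=False, seed=2)
        )
        assert deep.cv_percent == pytest.approx(inf.cv_percent, rel=0.05)

    def test_poisson_delivery_inflates_variance(self):
        # law of total variance: random template counts add variance
        fixed = simulate_mutant_fraction(
            SamplingModel(30, 0.3, replicates=20000, poisson_delivery=False,
                          seed=3)
        )
        poisson = simulate_mutant_fraction(
            SamplingModel(30, 0.3, replicates=20000, poisson_delivery=True,
                          seed=3)
        )
        assert poisson.cv_percent > fixed.cv_percent

    def test_dropouts_recorded(self):
        out = simulate_mutant_fraction(
            SamplingModel(0.5, 0.3, replicates=2000, poisson_delivery=True,
                          seed=4)
        )
        assert out.n_dropout > 0
        assert np.isnan(out.per_replicate_values).sum() == out.n_dropout

    def test_bit_identical_under_seed(self):
        model = SamplingModel(50, 0.3, read_depth=500, replicates=1000, seed=7)
        a = simulate_mutant_fraction(model).per_replicate_values
        b = simulate_mutant_fraction(model).per_replicate_values
        np.testing.assert_array_equal(a, b)
        c = simulate_mutant_fraction(
            SamplingModel(50, 0.3, read_depth=500, replicates=1000, seed=8)
        ).per_replicate_values
        assert not np.array_equal(a, c, equal_nan=True)


class TestFalseNegativeRate:
    def test_threshold_zero(self):
        assert false_negative_rate(SamplingModel(24, 0.3, seed=0), 0.0) == 0.0

    def test_exact_enumeration_small_n(self):
        # 24 templates at 30% mutant: observing <6% requires <=1 mutant copy
        model = SamplingModel(24, 0.3, poisson_delivery=False, seed=0)
        expected = stats.binom.cdf(1, 24, 0.3)
        assert false_negative_rate(model, 0.06) == pytest.approx(
            expected, rel=1e-12
        )
        assert enumerate_fn_rate(24, 0.3, 0.06) == pytest.approx(
            expected, rel=1e-12
        )

    def test_concentration_at_high_n(self):
        model = SamplingModel(3030, 0.3, poisson_delivery=False,
                              replicates=2000, seed=1)
        assert false_negative_rate(model, 0.06) == pytest.approx(0.0, abs=1e-3)

    def test_simulated_path_matches_enumeration(self):
        n, p, t, reps = 24, 0.3, 0.10, 20000
        exact = enumerate_fn_rate(n, p, t)
        out = simulate_mutant_fraction(
            SamplingModel(n, p, replicates=reps, poisson_delivery=False, seed=5)
        )
        simulated = float((out.per_replicate_values < t).mean())
        se = math.sqrt(exact * (1 - exact) / reps)
        assert simulated == pytest.approx(exact, abs=3 * se)

    def test_low_template_brafs_often_read_below_six_percent(self):
        # a 30% mutation in 24 templates has real mass below a 6% cutoff
        assert enumerate_fn_rate(24, 0.3, 0.06) > 1e-3


class TestFalsePositives:
    def test_lesion_rate_zero_is_snp_baseline(self):
        a = ArtifactModel(lesion_rate_per_base=0.0, region_bp=13000)
        assert expected_calls(500, a) == pytest.approx(13.0, rel=1e-12)
        out = simulate_false_positives(500, a, replicates=2000, seed=0)
        se = math.sqrt(13.0 / 2000)  # binomial count, nearly Poisson
        assert out.expected_variant_calls == pytest.approx(13.0, abs=3 * se)

    def test_zero_region_zero_calls(self):
        a = ArtifactModel(region_bp=0)
        out = simulate_false_positives(100, a, replicates=10, seed=0)
        assert out.expected_variant_calls == 0.0

    def test_expected_calls_monotone_in_copies(self):
        a = ArtifactModel(lesion_rate_per_base=1e-4)
        values = [expected_calls(n, a) for n in (24, 36, 100, 200, 500, 3030)]
        assert all(x >= y for x, y in zip(values, values[1:]))

    def test_simulated_monotone_with_shared_germline_noise(self):
        a = ArtifactModel(lesion_rate_per_base=1e-4)
        means = [
            simulate_false_positives(n, a, replicates=1000, seed=11)
            .expected_variant_calls
            for n in (30, 500)
        ]
        assert means[0] > means[1]

    def test_site_probability_zero_without_templates_or_lesions(self):
        a = ArtifactModel(lesion_rate_per_base=1e-3)
        assert artifact_site_call_probability(0, a) == 0.0
        assert artifact_site_call_probability(
            100, ArtifactModel(lesion_rate_per_base=0.0)
        ) == 0.0

    def test_infinite_depth_threshold_indicator(self):
        # at infinite depth, a site is called iff the lesion fraction
        # reaches the threshold: for n=20, t=0.05 that is >=1 lesion
        a = ArtifactModel(lesion_rate_per_base=1e-3, af_call_threshold=0.05,
                          read_depth=None)
        expected = 1 - (1 - 1e-3) ** 20
        assert artifact_site_call_probability(20, a) == pytest.approx(
            expected, rel=1e-9
        )

    def test_bit_identical_under_seed(self):
        a = ArtifactModel()
        x = simulate_false_positives(36, a, 500, seed=9).per_replicate_values
        y = simulate_false_positives(36, a, 500, seed=9).per_replicate_values
        np.testing.assert_array_equal(x, y)


class TestDilutionSeries:
    def test_two_fold_series_reaches_24(self):
        levels = dilution_series(3030, 2.0, 8)
        assert levels == [3030, 1515, 758, 379, 189, 95, 47, 24]

    def test_single_level(self):
        assert dilution_series(500, 2.0, 1) == [500]

    def test_ten_fold(self):
        assert dilution_series(1000, 10.0, 3) == [1000, 100, 10]

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            dilution_series(100, 1.0, 3)
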