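import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dietrisk import (
    DistributionSpec,
    FitError,
    ValidationError,
    anderson_darling_statistic,
    chi_square_statistic,
    lognormal_from_moments,
    select_best_fit,
    zero_inflated_lognormal,
)
from dietrisk.distribution_fitting import FitResult, fit_family


def ad_oracle(samples, cdf):
    """Literal transcription of the A^2 formula, independent of the package."""
    x = sorted(samples)
    n = len(x)
    f = [cdf(v) for v in x]
    total = 0.0
    for i in range(1, n + 1):
        total += (2 * i - 1) * (math.log(f[i - 1]) + math.log(1 - f[n - i]))
    return -n - total / n


class TestLognormalFromMoments:
    def test_closed_form_example(self):
        spec = lognormal_from_moments(1.14, 1.12)
        assert spec.params[0] == pytest.approx(-0.2068, abs=1e-4)
        assert spec.params[1] == pytest.approx(0.8219, abs=1e-4)

    def test_degenerate_limit(self):
        spec = lognormal_from_moments(2.5, 0.0)
        assert spec.params == (math.log(2.5), 0.0)
        assert spec.mean() == 2.5
        assert spec.sd() == 0.0

    def test_round_trip(self):
        spec = lognormal_from_moments(3.3, 0.7)
        again = lognormal_from_moments(spec.mean(), spec.sd())
        assert again.params[0] == pytest.approx(spec.params[0], abs=1e-12)
        assert again.params[1] == pytest.approx(spec.params[1], abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            lognormal_from_moments(0.0, 1.0)
        with pytest.raises(ValidationError):
            lognormal_from_moments(-1.0, 1.0)

    @given(
        mean=st.floats(1e-3, 1e3),
        sd=st.one_of(st.just(0.0), st.floats(1e-6, 1e3)),
    )
    @settings(max_examples=100, deadline=None)
    def test_moment_matching_property(self, mean, sd):
        spec = lognormal_from_moments(mean, sd)
        assert spec.mean() == pytest.approx(mean, rel=1e-9)
        assert spec.sd() == pytest.approx(sd, rel=1e-7, abs=1e-12)

    def test_moments_against_simulation(self, rng):
        spec = lognormal_from_moments(1.14, 1.12)
        draws = spec.sample(rng, 10**6)
        assert draws.mean() == pytest.approx(1.14, rel=0.01)
        assert draws.std() == pytest.approx(1.12, rel=0.02)


class TestZeroInflatedLognormal:
    def test_overall_moments(self):
        spec = zero_inflated_lognormal(0.2564, 0.2363, 0.1)
        assert spec.zero_mass == 0.1
        assert spec.mean() == pytest.approx(0.2564, rel=1e-9)
        assert spec.sd() == pytest.approx(0.2363, rel=1e-9)

    def test_infeasible_targets_rejected(self):
        # the zero atom alone would need more variance than requested
        with pytest.raises(FitError):
            zero_inflated_lognormal(1.0, 0.01, 0.5)

    def test_sample_zero_share(self, rng):
        spec = zero_inflated_lognormal(1.0, 2.0, 0.3)
        draws = spec.sample(rng, 10**5)
        assert np.mean(draws == 0.0) == pytest.approx(0.3, abs=5e-3)


class TestAndersonDarling:
    def test_single_sample_at_median(self):
        spec = DistributionSpec("normal", (0.0, 1.0))
        a2 = anderson_darling_statistic([0.0], spec)
        assert a2 == pytest.approx(-1 - 2 * math.log(0.5), abs=1e-12)
        assert a2 == pytest.approx(0.3863, abs=5e-5)

    def test_monotone_transform_invariance(self, rng):
        mu, sigma = 0.3, 0.8
        log_spec = DistributionSpec("lognormal", (mu, sigma))
        norm_spec = DistributionSpec("normal", (mu, sigma))
        x = sps.lognorm(s=sigma, scale=math.exp(mu)).rvs(size=40, random_state=rng)
        assert anderson_darling_statistic(x, log_spec) == pytest.approx(
            anderson_darling_statistic(np.log(x), norm_spec), rel=1e-12
        )

    def test_equiprobable_quantiles_small_statistic(self):
        spec = DistributionSpec("normal", (0.0, 1.0))
        x = sps.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        a2 = anderson_darling_statistic(x, spec)
        assert a2 == pytest.approx(ad_oracle(x, sps.norm.cdf), rel=1e-12)
        assert a2 < 0.05

    def test_matches_oracle_on_random_data(self, rng):
        spec = DistributionSpec("normal", (0.2, 1.5))
        x = rng.normal(0.0, 1.0, 25)
        assert anderson_darling_statistic(x, spec) == pytest.approx(
            ad_oracle(x, sps.norm(0.2, 1.5).cdf), rel=1e-12
        )

    def test_decreases_toward_fitted_quantiles(self):
        spec = DistributionSpec("normal", (0.0, 1.0))
        good = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        worse = good + 0.5
        assert anderson_darling_statistic(good, spec) < anderson_darling_statistic(worse, spec)

    def test_degenerate_cdf_rejected(self):
        spec = DistributionSpec("weibull", (1.5, 1.0))
        with pytest.raises(FitError):
            anderson_darling_statistic([-1.0, 0.5], spec)  # CDF(-1) == 0

    def test_discrete_spec_rejected(self):
        with pytest.raises(ValidationError):
            anderson_darling_statistic([1.0, 2.0], DistributionSpec("poisson", (2.0,)))


class TestChiSquare:
    def test_observed_equals_expected(self):
        spec = DistributionSpec("normal", (0.0, 1.0))
        # 100 samples placed to match expected counts in 4 equiprobable bins
        edges = sps.norm.ppf([0.0, 0.25, 0.5, 0.75, 1.0])
        x = np.concatenate([
            np.full(25, -1.0), np.full(25, -0.3), np.full(25, 0.3), np.full(25, 1.0)
        ])
        assert chi_square_statistic(x, spec, bins=edges) == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_arithmetic(self):
        spec = DistributionSpec("normal", (0.0, 1.0))
        x = np.concatenate([np.full(60, -1.0), np.full(40, 1.0)])
        assert chi_square_statistic(x, spec, bins=[-5.0, 0.0, 5.0]) == pytest.approx(4.0)

    def test_poisson_fit_matches_bin_count_oracle(self, rng):
        lam = 55.0
        x = rng.poisson(lam, 97)
        fitted = DistributionSpec("poisson", (float(x.mean()),))
        edges = np.array([-0.5, 45.5, 50.5, 55.5, 60.5, 200.5])
        stat = chi_square_statistic(x, fitted, bins=edges)
        # independent tabulation with the same bins
        dist = sps.poisson(x.mean())
        cum = np.concatenate(([0.0], dist.cdf(edges[1:-1]), [1.0]))
        expected = 97 * np.diff(cum)
        observed = np.array([
            np.sum((x > edges[i]) & (x <= edges[i + 1])) for i in range(len(edges) - 1)
        ])
        assert stat == pytest.approx(float(np.sum((observed - expected) ** 2 / expected)), rel=1e-9)

    def test_default_binning_keeps_expected_counts(self, rng):
        spec = DistributionSpec("normal", (0.0, 1.0))
        x = rng.normal(0.0, 1.0, 200)
        stat = chi_square_statistic(x, spec)
        assert stat >= 0.0 and math.isfinite(stat)

    def test_empty_expected_rejected(self):
        spec = DistributionSpec("normal", (0.0, 1e-12))
        with pytest.raises((FitError, ValidationError)):
            chi_square_statistic([1.0, 2.0, 3.0], spec, bins=[10.0, 11.0, 12.0])


class TestSelectBestFit:
    def test_single_candidate(self, rng):
        x = rng.lognormal(0.0, 1.0, 200)
        result = select_best_fit(x, ["gamma"])
        assert result.spec.family == "gamma"

    def test_lognormal_beats_normal_on_lognormal_data(self, rng):
        x = rng.lognormal(0.0, 1.0, 500)
        result = select_best_fit(x, ["normal", "lognormal"])
        assert result.spec.family == "lognormal"
        # the statistic comparison is the oracle
        assert result.statistic < fit_family(x, "normal").statistic

    def test_tie_breaks_to_first_candidate(self, rng):
        x = rng.lognormal(0.0, 1.0, 100)
        first = select_best_fit(x, ["lognormal", "lognormal"])
        assert first.spec.family == "lognormal"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            select_best_fit([1.0, 2.0], ["normal"])

    def test_all_degenerate_rejected(self):
        with pytest.raises(FitError):
            select_best_fit([0.0, 0.0, 0.0, 0.0, 0.0], ["lognormal"])

    def test_parameter_recovery_within_002(self, rng):
        mu, sigma = 0.4, 0.9
        x = rng.lognormal(mu, sigma, 10_000)
        result = select_best_fit(x, ["lognormal"])
        assert result.spec.params[0] == pytest.approx(mu, abs=0.02)
        assert result.spec.params[1] == pytest.approx(sigma, abs=0.02)

    def test_zero_mass_equals_observed_zero_fraction(self, rng):
        pos = rng.lognormal(0.0, 0.5, 80)
        x = np.concatenate([pos, np.zeros(20)])
        result = select_best_fit(x, ["lognormal"])
        assert result.spec.zero_mass == 0.2

    def test_fit_result_validates_statistic(self):
        with pytest.raises(ValidationError):
            FitResult(DistributionSpec("normal", (0.0, 1.0)), float("nan"), "anderson_darling")
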