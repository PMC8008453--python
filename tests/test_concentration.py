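"""Concentration model: parameterizations, fitting, GOF statistics, truncation."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special, stats

import mehgsim as m
from mehgsim.concentration import ad_statistic_cdf, ks_statistic_cdf
from mehgsim.errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
    NumericDomainError,
    PathologicalTruncationError,
)


def make_dataset(values) -> m.ConcentrationDataset:
    return m.ConcentrationDataset(m.FishGroup.TUNA_SWORDFISH, np.asarray(values, float))


# ---------------------------------------------------------------------------
# moments <-> log-scale parameterization
# ---------------------------------------------------------------------------


class TestMomentsConversion:
    def test_highest_group_row(self):
        """(0.54, 0.53) maps to log_mu ~ -0.954, log_sigma ~ 0.821 (closed form)."""
        p = m.moments_to_logparams(0.54, 0.53)
        assert p.log_mu == pytest.approx(-0.9535010, abs=1e-6)
        assert p.log_sigma == pytest.approx(0.8213585, abs=1e-6)

    def test_round_trip_low_group(self):
        """Converting (0.07, 0.07) and recomputing moments returns (0.07, 0.07)."""
        p = m.moments_to_logparams(0.07, 0.07)
        s2 = p.log_sigma**2
        mean_back = math.exp(p.log_mu + s2 / 2)
        sd_back = math.sqrt((math.exp(s2) - 1) * math.exp(2 * p.log_mu + s2))
        assert mean_back == pytest.approx(0.07, rel=1e-9)
        assert sd_back == pytest.approx(0.07, rel=1e-9)

    def test_degenerate_variance_limit(self):
        """As sd -> 0+, log_sigma -> 0 and log_mu -> ln(mean)."""
        p = m.moments_to_logparams(2.5, 1e-9)
        assert p.log_sigma == pytest.approx(0.0, abs=1e-8)
        assert p.log_mu == pytest.approx(math.log(2.5), abs=1e-9)

    @pytest.mark.parametrize("mean,sd", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_invalid_inputs_rejected(self, mean, sd):
        with pytest.raises(InvalidParameterError):
            m.moments_to_logparams(mean, sd)

    @given(
        mean=st.floats(1e-3, 1e3),
        cv=st.floats(1e-3, 5.0),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_dual_parameterization_consistency(self, mean, cv):
        """Arithmetic moments recomputed from log-scale agree to 1e-9 relative."""
        p = m.moments_to_logparams(mean, cv * mean)
        s2 = p.log_sigma**2
        assert math.exp(p.log_mu + s2 / 2) == pytest.approx(p.arithmetic_mean, rel=1e-9)
        var = (math.exp(s2) - 1) * math.exp(2 * p.log_mu + s2)
        assert math.sqrt(var) == pytest.approx(p.arithmetic_sd, rel=1e-9)

    def test_inconsistent_dual_parameterization_rejected(self):
        with pytest.raises(InvalidParameterError):
            m.LogNormalParams(
                arithmetic_mean=1.0, arithmetic_sd=1.0, log_mu=0.0, log_sigma=0.5
            )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitLognormal:
    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateDataError):
            m.fit_lognormal(make_dataset([0.4, 0.4, 0.4]))

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientDataError):
            m.fit_lognormal(make_dataset([0.4]))

    def test_two_point_mle_by_hand(self):
        """Logs {0, 2} have mean 1 and population SD 1."""
        p = m.fit_lognormal(make_dataset([1.0, math.e**2]), method="mle")
        assert p.log_mu == pytest.approx(1.0, rel=1e-12)
        assert p.log_sigma == pytest.approx(1.0, rel=1e-12)

    def test_moments_method_matches_sample_moments(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(-1.0, 0.8, size=500)
        p = m.fit_lognormal(make_dataset(values), method="moments")
        expected = m.moments_to_logparams(values.mean(), values.std(ddof=1))
        assert p.log_mu == pytest.approx(expected.log_mu, rel=1e-12)
        assert p.log_sigma == pytest.approx(expected.log_sigma, rel=1e-12)

    def test_mle_parameter_recovery_large_sample(self, tuna_params):
        """MLE on 10,000 draws recovers log_mu within 0.03 and log_sigma within 0.02.

        Bounds are ~3.5 standard errors (sigma/sqrt(n) and sigma/sqrt(2n)).
        """
        rng = np.random.default_rng(2718)
        values = rng.lognormal(tuna_params.log_mu, tuna_params.log_sigma, size=10_000)
        p = m.fit_lognormal(make_dataset(values), method="mle")
        assert abs(p.log_mu - tuna_params.log_mu) < 0.03
        assert abs(p.log_sigma - tuna_params.log_sigma) < 0.02

    def test_mle_replicate_recovery_small_samples(self, tuna_params):
        """1000 fits of n=70 datasets: log_mu unbiased; log_sigma biased only by
        the normal-theory finite-sample factor c4(n) * sqrt((n-1)/n).

        The MLE of a normal SD is biased low by that known factor at small n, so
        recovery is assessed net of the analytic expectation.
        """
        n, reps = 70, 1000
        rng = np.random.default_rng(99)
        mus = np.empty(reps)
        sigmas = np.empty(reps)
        for i in range(reps):
            values = rng.lognormal(tuna_params.log_mu, tuna_params.log_sigma, size=n)
            p = m.fit_lognormal(make_dataset(values), method="mle")
            mus[i] = p.log_mu
            sigmas[i] = p.log_sigma
        se_mu = mus.std(ddof=1) / math.sqrt(reps)
        assert abs(mus.mean() - tuna_params.log_mu) < 3 * se_mu
        c4 = math.sqrt(2 / (n - 1)) * math.exp(
            special.gammaln(n / 2) - special.gammaln((n - 1) / 2)
        )
        expected_sigma = tuna_params.log_sigma * c4 * math.sqrt((n - 1) / n)
        se_sigma = sigmas.std(ddof=1) / math.sqrt(reps)
        assert abs(sigmas.mean() - expected_sigma) < 3 * se_sigma


# ---------------------------------------------------------------------------
# goodness-of-fit statistics
# ---------------------------------------------------------------------------


class TestGOFStatistics:
    def test_ks_at_midpoint_quantiles(self, tuna_params):
        """A sample placed at F^-1((i-0.5)/n) has KS distance exactly 0.5/n."""
        n = 8
        q = (np.arange(1, n + 1) - 0.5) / n
        values = tuna_params.frozen().ppf(q)
        d = m.ks_statistic(make_dataset(values), tuna_params)
        assert d == pytest.approx(0.5 / n, rel=1e-9)

    def test_ks_single_point_at_median(self, tuna_params):
        d = m.ks_statistic(make_dataset([tuna_params.median]), tuna_params)
        assert d == pytest.approx(0.5, rel=1e-9)

    def test_ks_matches_scipy(self, tuna_params):
        rng = np.random.default_rng(31)
        values = rng.lognormal(tuna_params.log_mu, tuna_params.log_sigma, size=200)
        ours = m.ks_statistic(make_dataset(values), tuna_params)
        reference = stats.kstest(values, tuna_params.cdf).statistic
        assert ours == pytest.approx(reference, rel=1e-9)

    def test_ad_brute_force_oracle(self, tuna_params):
        """A^2 for n=4 PIT-uniform points matches an index-by-index summation."""
        n = 4
        q = (np.arange(1, n + 1) - 0.5) / n
        values = tuna_params.frozen().ppf(q)
        ours = m.ad_statistic(make_dataset(values), tuna_params)
        f = np.sort(tuna_params.cdf(np.sort(values)))
        total = 0.0
        for i in range(1, n + 1):  # brute-force, no vectorization
            total += (2 * i - 1) * (
                math.log(f[i - 1]) + math.log(1 - f[n - i])
            )
        expected = -n - total / n
        assert ours == pytest.approx(expected, rel=1e-12)

    def test_ad_matches_scipy_normal_case(self):
        """Cross-check A^2 against scipy.stats.anderson on the normal family."""
        rng = np.random.default_rng(17)
        z = rng.normal(size=150)
        result = stats.anderson(z, dist="norm")
        cdf = stats.norm(loc=z.mean(), scale=z.std(ddof=1)).cdf
        assert ad_statistic_cdf(z, cdf) == pytest.approx(result.statistic, rel=1e-9)

    def test_ad_scale_invariance(self, tuna_params):
        rng = np.random.default_rng(41)
        values = rng.lognormal(tuna_params.log_mu, tuna_params.log_sigma, size=50)
        a1 = m.ad_statistic(make_dataset(values), tuna_params)
        scaled = m.LogNormalParams.from_log_params(
            tuna_params.log_mu + math.log(10.0), tuna_params.log_sigma
        )
        a2 = m.ad_statistic(make_dataset(values * 10.0), scaled)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_ad_domain_error_at_cdf_limits(self, tuna_params):
        with pytest.raises(NumericDomainError):
            m.ad_statistic(make_dataset([1e-200]), tuna_params)

    def test_lognormal_beats_moment_matched_normal(self, tuna_params):
        """On a 200-draw log-normal sample both statistics prefer the log-normal
        over a normal with the same arithmetic moments (the model-selection rule)."""
        rng = np.random.default_rng(8)
        values = rng.lognormal(tuna_params.log_mu, tuna_params.log_sigma, size=200)
        normal_cdf = stats.norm(
            loc=tuna_params.arithmetic_mean, scale=tuna_params.arithmetic_sd
        ).cdf
        assert m.ks_statistic(make_dataset(values), tuna_params) < ks_statistic_cdf(
            values, normal_cdf
        )
        assert m.ad_statistic(make_dataset(values), tuna_params) < ad_statistic_cdf(
            values, normal_cdf
        )


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tuna_dataset():
    return make_dataset([0.2, 0.5, 1.1, 1.9])


class TestTruncation:
    def test_limits_per_scenario(self, tuna_dataset):
        assert m.truncation_limit(tuna_dataset, m.TruncationScenario.NONE) == math.inf
        assert m.truncation_limit(
            tuna_dataset, m.TruncationScenario.TWICE_MAX
        ) == pytest.approx(3.8)
        assert m.truncation_limit(
            tuna_dataset, m.TruncationScenario.AT_MAX
        ) == pytest.approx(1.9)

    def test_untruncated_sample_mean(self, tuna_params):
        rng = np.random.default_rng(12)
        draws = m.sample_concentrations(tuna_params, math.inf, 100_000, rng)
        se = tuna_params.arithmetic_sd / math.sqrt(100_000)
        assert abs(draws.mean() - 0.54) < 3 * se

    def test_truncated_draws_respect_limit(self, tuna_params):
        rng = np.random.default_rng(13)
        draws = m.sample_concentrations(tuna_params, 1.9, 50_000, rng)
        assert draws.max() <= 1.9
        assert draws.min() > 0

    def test_truncated_sample_mean_matches_closed_form(self, tuna_params):
        rng = np.random.default_rng(14)
        draws = m.sample_concentrations(tuna_params, 3.8, 100_000, rng)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - m.truncated_mean(tuna_params, 3.8)) < 3 * se

    def test_sampler_reproducible(self, tuna_params):
        a = m.sample_concentrations(tuna_params, 3.8, 1000, np.random.default_rng(7))
        b = m.sample_concentrations(tuna_params, 3.8, 1000, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_pathological_limit_rejected(self, tuna_params):
        assert tuna_params.cdf(1e-6) < 1e-6
        with pytest.raises(PathologicalTruncationError):
            m.sample_concentrations(tuna_params, 1e-6, 10, np.random.default_rng(1))

    def test_truncated_mean_limits(self, tuna_params):
        assert m.truncated_mean(tuna_params, math.inf) == pytest.approx(0.54, rel=1e-9)
        assert m.truncated_mean(tuna_params, tuna_params.median) < 0.54

    def test_truncated_mean_quadrature_oracle(self, tuna_params):
        """Closed form agrees with direct integration of x f(x)/F(L) to 1e-6."""
        frozen = tuna_params.frozen()
        for limit in (0.5, 1.9, 3.8):
            integral, _ = integrate.quad(
                lambda x: x * frozen.pdf(x), 0.0, limit, limit=200
            )
            expected = integral / frozen.cdf(limit)
            assert m.truncated_mean(tuna_params, limit) == pytest.approx(
                expected, rel=1e-6
            )

    def test_truncated_mean_monotone_in_limit(self, tuna_params):
        limits = [0.1, 0.5, 1.0, 1.9, 3.8, 10.0, math.inf]
        means = [m.truncated_mean(tuna_params, L) for L in limits]
        assert all(a < b for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# dataset container and CSV I/O
# ---------------------------------------------------------------------------


class TestDatasetIO:
    @pytest.mark.parametrize("bad", [[0.1, 0.0], [0.1, -0.2], [0.1, math.nan]])
    def test_nonpositive_values_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            make_dataset(bad)

    def test_csv_round_trip(self, conc_datasets, tmp_path):
        path = tmp_path / "conc.csv"
        from mehgsim.concentration import write_concentration_csv

        write_concentration_csv(conc_datasets, path)
        loaded = m.load_concentration_csv(path)
        assert set(loaded) == set(conc_datasets)
        for group, dataset in conc_datasets.items():
            np.testing.assert_allclose(loaded[group].values, dataset.values)

    def test_unknown_group_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "group,species,concentration_mg_per_kg\nshark,shark,0.5\n", encoding="utf-8"
        )
        with pytest.raises(InvalidParameterError):
            m.load_concentration_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("group,value\ntuna_swordfish,0.5\n", encoding="utf-8")
        with pytest.raises(InvalidParameterError):
            m.load_concentration_csv(path)

    def test_fit_report_contents(self, conc_datasets):
        report = m.fit_report(conc_datasets)
        assert set(report) == {g.value for g in m.GROUP_ORDER}
        tuna = report[m.FishGroup.TUNA_SWORDFISH.value]
        assert tuna["n"] == 70
        assert tuna["max_observed"] <= 1.9
        assert tuna["log_sigma"] > 0
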