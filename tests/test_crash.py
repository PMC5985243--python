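"""Crash incidence, severity sampling, and risk derivations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from avcea.crash import (
    DEFAULT_RISK_CURVE,
    CrashOutcome,
    CrashProfile,
    ExceedanceRiskCurve,
    crash_profile,
    default_delta_v_distribution,
    outcomes_from_uniforms,
    per_mile_to_annual,
    relative_risk,
    sample_crash_outcome,
    severity_from_delta_v,
)
from avcea.strategy import Strategy


class TestCrashProfile:
    def test_hpv_profile_matches_published_values(self, params):
        profile = crash_profile(Strategy.HPV, params)
        assert profile.annual_crash_prob == 0.0646
        raw = np.array([0.6091, 0.3766, 0.0090, 0.0054])
        np.testing.assert_allclose(profile.severity_split, raw / raw.sum())

    def test_av_profile_and_sharing_across_av_strategies(self, params):
        av = crash_profile(Strategy.AV, params)
        assert av.annual_crash_prob == 0.08385
        for s in (Strategy.AV_5YR, Strategy.AV_TAXI):
            other = crash_profile(s, params)
            assert other.annual_crash_prob == av.annual_crash_prob
            np.testing.assert_array_equal(
                other.severity_split, av.severity_split
            )
        hpt = crash_profile(Strategy.HPT, params)
        assert hpt.annual_crash_prob == 0.0646

    def test_unknown_strategy_rejected(self, params):
        with pytest.raises(ValueError):
            crash_profile("BICYCLE", params)

    def test_unreported_crash_scenario_multiplier(self, params):
        p = params.with_values({"unreported_crash_multiplier": 1.89})
        assert crash_profile(Strategy.HPV, p).annual_crash_prob == (
            pytest.approx(0.0646 * 1.89)
        )
        # AV record contains every incident; multiplier must not touch it
        assert crash_profile(Strategy.AV, p).annual_crash_prob == 0.08385

    def test_bad_split_rejected(self):
        with pytest.raises(ValueError):
            CrashProfile(0.1, np.array([0.4, 0.3, 0.1, 0.05]))  # sums to .85


class TestAnnualization:
    def test_zero_rate(self):
        assert per_mile_to_annual(0.0, 14_133) == 0.0

    def test_observed_av_record(self):
        rate = 14 / 2_102_047
        assert per_mile_to_annual(rate, 14_133) == pytest.approx(0.0898, abs=5e-5)
        assert per_mile_to_annual(rate, 14_133, form="product") == pytest.approx(
            0.0941, abs=5e-5
        )

    def test_small_rate_limit(self):
        assert per_mile_to_annual(1e-9, 1) == pytest.approx(1e-9, rel=1e-6)

    def test_rate_above_one_rejected(self):
        with pytest.raises(ValueError):
            per_mile_to_annual(1.5, 100)


class TestRelativeRisk:
    def test_published_crash_and_fatality_ratios(self, params):
        rr = relative_risk(
            params.value("prob_crash_av"), params.value("prob_crash_hpv")
        )
        assert round(rr, 2) == 1.30
        rr_fatal = relative_risk(
            params.value("prob_crash_av") * params.value("split_fatal_av"),
            params.value("prob_crash_hpv") * params.value("split_fatal_hpv"),
        )
        assert round(rr_fatal, 2) == 0.02

    def test_identity(self):
        assert relative_risk(0.37, 0.37) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(0.1, 0.0)

    @given(
        a=st.floats(1e-6, 1.0),
        b=st.floats(1e-6, 1.0),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, a, b, k):
        assert relative_risk(k * a, k * b) == pytest.approx(
            relative_risk(a, b), rel=1e-9
        )


class TestOutcomeSampling:
    def test_zero_probability_never_crashes(self, rng):
        profile = CrashProfile(0.0, np.array([0.25, 0.25, 0.25, 0.25]))
        assert all(
            sample_crash_outcome(profile, rng) is CrashOutcome.NONE
            for _ in range(50)
        )

    def test_certain_pdo(self, rng):
        profile = CrashProfile(1.0, np.array([1.0, 0.0, 0.0, 0.0]))
        assert all(
            sample_crash_outcome(profile, rng) is CrashOutcome.PDO
            for _ in range(50)
        )

    def test_empirical_distribution(self, params, rng):
        """10^6 outcome draws: fatal frequency within 3 SE of the product
        of crash probability and conditional fatality share, and the full
        five-way distribution passes a chi-square test at alpha=0.001."""
        profile = crash_profile(Strategy.HPV, params)
        n = 1_000_000
        out = outcomes_from_uniforms(profile, rng.random(n), rng.random(n))
        p_fatal = profile.annual_crash_prob * profile.severity_split[3]
        freq = (out == 3).mean()
        se = np.sqrt(p_fatal * (1 - p_fatal) / n)
        assert abs(freq - p_fatal) < 3 * se
        assert p_fatal == pytest.approx(0.0646 * 0.0054, rel=2e-4)

        observed = np.array([(out == v).sum() for v in (-1, 0, 1, 2, 3)])
        p = profile.annual_crash_prob
        expected = n * np.concatenate([[1 - p], p * profile.severity_split])
        _, pvalue = stats.chisquare(observed, expected)
        assert pvalue > 0.001


class TestSeverityFromDeltaV:
    def test_no_energy_crash_is_damage_only(self):
        split = severity_from_delta_v((np.array([0.0]), np.array([1.0])))
        np.testing.assert_allclose(split, [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_two_point_mixture_is_average_of_pointwise_splits(self):
        v1, v2 = 5.0, 25.0
        s1 = severity_from_delta_v((np.array([v1]), np.array([1.0])))
        s2 = severity_from_delta_v((np.array([v2]), np.array([1.0])))
        mix = severity_from_delta_v(
            (np.array([v1, v2]), np.array([0.5, 0.5]))
        )
        np.testing.assert_allclose(mix, (s1 + s2) / 2, atol=1e-12)

    def test_default_curve_reproduces_av_split(self, params):
        """Expectation of the calibrated risk curve over the default
        delta-V distribution (mean 3.91 mph) lands within 10% of each
        published AV severity-split component."""
        target = np.array([
            params.value("split_pdo_av"),
            params.value("split_minor_av"),
            params.value("split_severe_av"),
            params.value("split_fatal_av"),
        ])
        target = target / target.sum()
        split = severity_from_delta_v(default_delta_v_distribution())
        np.testing.assert_allclose(split, target, rtol=0.10)

    def test_dominating_curve_gives_stochastically_worse_split(self):
        mild = ExceedanceRiskCurve(120.0, 40.0, 16.0)
        harsh = ExceedanceRiskCurve(60.0, 20.0, 8.0)  # dominates pointwise
        dist = default_delta_v_distribution()
        s_mild = severity_from_delta_v(dist, mild)
        s_harsh = severity_from_delta_v(dist, harsh)
        # exceedance of each severity level is higher under the harsh curve
        for level in (1, 2, 3):
            assert s_harsh[level:].sum() >= s_mild[level:].sum()

    def test_invalid_curve_rejected(self):
        def bad_curve(v):
            v = np.asarray(v, dtype=float)
            one = np.full_like(v, 0.6)
            return one, one, one, one  # sums to 2.4

        with pytest.raises(ValueError):
            severity_from_delta_v(
                (np.array([10.0]), np.array([1.0])), bad_curve
            )
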