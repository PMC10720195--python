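"""Hazard and survival-curve behavior for the three retention categories."""

import math

import numpy as np
import pytest

from wgdretain import (
    EvaluationDomainError,
    RetentionClassParams,
    SeriesConfig,
    SeriesConvergenceError,
    get_profile,
    hazard,
    survival,
)


class TestHazard:
    def test_constant_hazard_when_b_zero(self, profile):
        # b = 0 makes the exponential term identically 1, so h = d + f
        non = profile["non"]
        for t in (0.0, 0.05, 0.3, 1.7):
            assert hazard(non, t) == pytest.approx(25.0, abs=0)

    def test_dosage_hazard_starts_at_zero(self, profile):
        # printed dos parameters satisfy d + f = 0 exactly
        assert hazard(profile["dos"], 0.0) == 0.0

    def test_alt_func_hazard_decays_to_d(self, profile):
        alt = profile["alt_func"]
        assert hazard(alt, 5.0) == pytest.approx(alt.d, rel=1e-6)

    def test_negative_time_rejected(self, profile):
        with pytest.raises(EvaluationDomainError):
            hazard(profile["non"], -0.1)

    def test_exp_overflow_is_a_domain_error(self):
        # strongly negative b at large t overflows exp; must not return inf
        p = RetentionClassParams("dos", b=-17.0, c=1.0, d=0.0, f=1e-6, t_check=1.0)
        with pytest.raises(EvaluationDomainError):
            hazard(p, 1e6)


class TestParamValidation:
    def test_c_must_be_positive(self):
        with pytest.raises(ValueError, match="c must be"):
            RetentionClassParams("non", b=0.0, c=0.0, d=1.0, f=1.0)

    def test_initial_hazard_nonnegative(self):
        with pytest.raises(ValueError, match="d \\+ f"):
            RetentionClassParams("non", b=0.0, c=1.0, d=-2.0, f=1.0)

    def test_hazard_negativity_on_domain_rejected(self):
        # d < 0 with a decaying excess rate goes negative at larger t
        with pytest.raises(ValueError, match="hazard is negative"):
            RetentionClassParams("dos", b=5.0, c=1.0, d=-0.5, f=1.0, t_check=2.0)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown category"):
            RetentionClassParams("neo", b=0.0, c=1.0, d=1.0, f=1.0)

    def test_series_config_tolerance_ordering(self):
        with pytest.raises(ValueError):
            SeriesConfig(rel_tol=1e-6, fail_tol=1e-8)
        with pytest.raises(ValueError):
            SeriesConfig(n_max=0)


class TestSurvival:
    def test_survival_at_zero_is_exactly_one(self, profile, series):
        for params in profile.values():
            assert survival(params, 0.0, series) == 1.0

    def test_constant_hazard_closed_form(self, profile, series):
        # with b = 0 the series collapses to its n = 0 term and
        # S(t) = exp(-(d+f) t) exactly
        non = profile["non"]
        for t in np.linspace(0.01, 2.0, 25):
            assert survival(non, float(t), series) == pytest.approx(
                math.exp(-25.0 * t), rel=1e-15
            )

    def test_non_category_printed_value(self, profile, series):
        assert survival(profile["non"], 0.1, series) == pytest.approx(
            0.0820850, abs=5e-8
        )

    def test_dosage_survival_asymptote_at_zero(self, profile, series):
        # dosage-balance retention is transient: essentially no pair
        # survives to t = 2 under the printed parameters
        assert survival(profile["dos"], 2.0, series) <= 1e-6

    @pytest.mark.parametrize("category", ["alt_func", "dos", "non"])
    def test_series_matches_quadrature_oracle(
        self, profile, series, quad_survival, category
    ):
        params = profile[category]
        for t in np.linspace(0.025, 0.5, 20):
            s_series = survival(params, float(t), series)
            s_quad = quad_survival(params, float(t))
            assert abs(s_series - s_quad) <= 1e-8, (category, t)

    @pytest.mark.parametrize("category", ["alt_func", "dos", "non"])
    def test_survival_non_increasing(self, profile, series, category):
        params = profile[category]
        ts = np.linspace(0.0, 0.5, 500)
        values = [survival(params, float(t), series) for t in ts]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("category", ["alt_func", "dos", "non"])
    def test_log_survival_slope_matches_hazard(self, profile, series, category):
        # -d/dt log S(t) is the hazard; central differences at step 1e-6
        params = profile[category]
        h = 1e-6
        for t in (0.05, 0.1, 0.3):
            lo = math.log(survival(params, t - h, series))
            hi = math.log(survival(params, t + h, series))
            slope = -(hi - lo) / (2 * h)
            expect = hazard(params, t)
            if expect == 0.0:
                assert abs(slope) < 1e-4
            else:
                assert slope == pytest.approx(expect, rel=1e-4)

    def test_negative_time_rejected(self, profile, series):
        with pytest.raises(EvaluationDomainError):
            survival(profile["non"], -1.0, series)


class TestSeriesTermination:
    """Term-sign structure and the truncation contract of the series."""

    def test_single_sign_terms_converge_over_full_domain(self, profile, series):
        # b < 0: all terms positive, no cancellation; clean termination on (0, 2]
        for t in np.linspace(0.05, 2.0, 40):
            s = survival(profile["dos"], float(t), series)
            assert 0.0 <= s <= 1.0

    def test_alternating_terms_converge_where_truncation_allows(
        self, profile, series
    ):
        # b > 0: alternating series; n_max = 100 suffices while |b| t^c stays
        # moderate
        for t in np.linspace(0.05, 1.4, 28):
            s = survival(profile["alt_func"], float(t), series)
            assert 0.0 <= s <= 1.0

    def test_non_convergence_raises_explicitly(self, profile, series):
        # at t = 2 the alternating series still has O(1e11) terms at the
        # truncation cap; a silent result would be garbage, so it must raise
        with pytest.raises(SeriesConvergenceError, match="did not converge"):
            survival(profile["alt_func"], 2.0, series)

    def test_larger_cap_restores_termination(self, profile):
        # purely a truncation matter: raising n_max lets the same series
        # terminate (accuracy there is a separate, cancellation-bound question)
        s = survival(profile["alt_func"], 1.6, SeriesConfig(n_max=400))
        assert 0.0 <= s <= 1.0


class TestProfiles:
    def test_builtin_profile_has_all_categories(self, profile):
        assert set(profile) == {"alt_func", "dos", "non"}
        assert profile["alt_func"].b == 10.0
        assert profile["dos"].c == 0.2573
        assert profile["non"].d == 20.0

    def test_unknown_profile_name(self):
        with pytest.raises(KeyError, match="unknown profile"):
            get_profile("nope")
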