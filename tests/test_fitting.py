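"""Estimation of (k, L_max), model comparison, and deviating-age screening."""

import math

import numpy as np
import pytest
from scipy import integrate

import growthlaw as gl
from growthlaw.errors import DegenerateDesignError, DomainError, InsufficientDataError

from conftest import line_normal_equations, quad_normal_equations


def _pairs(L, dL):
    return gl.IncrementSet(L=np.asarray(L, float), dL=np.asarray(dL, float))


class TestFitLinear:
    def test_exact_collinear_points(self):
        fit = gl.fit_linear(_pairs([0, 10, 20], [10, 8, 6]))
        assert fit.slope == pytest.approx(-0.2, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-12)
        assert fit.k == pytest.approx(0.2) and fit.L_max == pytest.approx(50.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_against_hand_computed_normal_equations(self):
        # slope = Sxy/Sxx = -45/200, intercept from the means
        fit = gl.fit_linear(_pairs([0, 10, 20], [10, 8.5, 5.5]))
        assert fit.slope == pytest.approx(-0.225, abs=1e-12)
        assert fit.intercept == pytest.approx(10.25, abs=1e-12)
        assert fit.k == pytest.approx(0.225)
        assert fit.L_max == pytest.approx(10.25 / 0.225)
        assert fit.r2 == pytest.approx(1 - 0.375 / 10.5)

    def test_positive_slope_leaves_law_parameters_undefined(self):
        fit = gl.fit_linear(_pairs([0, 10, 20], [1, 2, 3]))
        assert fit.k is None and fit.L_max is None
        assert fit.slope > 0

    def test_degenerate_and_insufficient_designs(self):
        with pytest.raises(DegenerateDesignError):
            gl.fit_linear(_pairs([5, 5, 5], [1, 2, 3]))
        with pytest.raises(InsufficientDataError):
            gl.fit_linear(_pairs([0, 10], [1, 2]))

    def test_matches_normal_equations_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(4, 20)
            L = rng.uniform(0, 400, n)
            dL = rng.uniform(-5, 60, n)
            fit = gl.fit_linear(_pairs(L, dL))
            slope, intercept, ss_res, _ = line_normal_equations(L, dL)
            assert fit.slope == pytest.approx(slope, rel=1e-8, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-10)
            assert fit.ss_res == pytest.approx(ss_res, rel=1e-8, abs=1e-8)


class TestFitQuadratic:
    def test_recovers_exact_parabola(self):
        # increment-by-length parabola of a small laboratory fish
        c2, c1, c0 = -0.0027, 0.078, 0.25
        L = np.array([0.0, 10.0, 20.0, 30.0])
        fit = gl.fit_quadratic(_pairs(L, c2 * L**2 + c1 * L + c0))
        assert fit.c2 == pytest.approx(c2, abs=1e-9)
        assert fit.c1 == pytest.approx(c1, abs=1e-9)
        assert fit.c0 == pytest.approx(c0, abs=1e-9)
        assert not fit.inverted

    def test_collinear_points_give_zero_curvature(self):
        L = np.array([0.0, 10.0, 20.0, 30.0])
        fit = gl.fit_quadratic(_pairs(L, 10.0 - 0.2 * L))
        assert fit.c2 == pytest.approx(0.0, abs=1e-12)
        assert fit.c1 == pytest.approx(-0.2) and fit.c0 == pytest.approx(10.0)

    def test_inverted_orientation_flag(self):
        L = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        fit = gl.fit_quadratic(_pairs(L, 0.01 * L**2 - 0.5 * L + 12.0))
        assert fit.inverted

    def test_matches_vandermonde_oracle_on_noisy_parabolas(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(5, 25)
            L = rng.uniform(0, 300, n)
            dL = -0.001 * L**2 + 0.05 * L + 2 + rng.normal(0, 1, n)
            fit = gl.fit_quadratic(_pairs(L, dL))
            beta, ss_res = quad_normal_equations(L, dL)
            assert np.allclose([fit.c0, fit.c1, fit.c2], beta, rtol=1e-7, atol=1e-10)
            assert fit.ss_res == pytest.approx(ss_res, rel=1e-7, abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            gl.fit_quadratic(_pairs([1, 1, 2, 2], [3, 4, 5, 6]))


def _f_sf_by_integration(x, d1, d2):
    """Upper tail of F(d1, d2) by direct integration of the density."""

    def dens(t):
        b = math.gamma(d1 / 2) * math.gamma(d2 / 2) / math.gamma((d1 + d2) / 2)
        return (
            (d1 / d2) ** (d1 / 2)
            * t ** (d1 / 2 - 1)
            * (1 + d1 * t / d2) ** (-(d1 + d2) / 2)
            / b
        )

    val, _ = integrate.quad(dens, x, np.inf)
    return val


class TestCompareModels:
    def test_exact_line_is_a_tie_broken_toward_simplicity(self, exact_line_pairs):
        lin = gl.fit_linear(exact_line_pairs)
        quad = gl.fit_quadratic(exact_line_pairs)
        cmp = gl.compare_models(lin, quad)
        assert cmp.f_stat == 0.0
        assert cmp.verdict == "linear-preferred"
        assert cmp.exact_tie

    def test_exact_parabola_over_inexact_line(self):
        L = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        pairs = _pairs(L, -0.01 * L**2 + 0.1 * L + 5)
        cmp = gl.compare_models(gl.fit_linear(pairs), gl.fit_quadratic(pairs))
        assert cmp.p_value == 0.0
        assert cmp.verdict == "quadratic-preferred"

    def test_p_value_matches_independent_f_integration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = rng.integers(6, 15)
            L = rng.uniform(0, 300, n)
            dL = 100 - 0.25 * L + rng.normal(0, 3, n)
            pairs = _pairs(L, dL)
            cmp = gl.compare_models(gl.fit_linear(pairs), gl.fit_quadratic(pairs))
            expected = _f_sf_by_integration(cmp.f_stat, cmp.df_num, cmp.df_den)
            assert cmp.p_value == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_agrees_with_statsmodels_nested_f_test(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        L = rng.uniform(0, 300, 12)
        dL = 90 - 0.2 * L + rng.normal(0, 2, 12)
        pairs = _pairs(L, dL)
        cmp = gl.compare_models(gl.fit_linear(pairs), gl.fit_quadratic(pairs))
        reduced = sm.OLS(dL, sm.add_constant(L)).fit()
        full = sm.OLS(dL, np.column_stack([np.ones_like(L), L, L**2])).fit()
        f, p, _ = full.compare_f_test(reduced)
        assert cmp.f_stat == pytest.approx(float(f), rel=1e-9)
        assert cmp.p_value == pytest.approx(float(p), rel=1e-9)

    def test_small_n_rejected(self):
        L = np.array([0.0, 10.0, 20.0, 30.0])
        pairs = _pairs(L, 10 - 0.2 * L)
        with pytest.raises(InsufficientDataError):
            gl.compare_models(gl.fit_linear(pairs), gl.fit_quadratic(pairs))

    def test_aicc_criterion_prefers_line_for_linear_truth(self):
        rng = np.random.default_rng(3)
        L = np.linspace(0, 300, 12)
        pairs = _pairs(L, 90 - 0.2 * L + rng.normal(0, 1, 12))
        cmp = gl.compare_models(
            gl.fit_linear(pairs), gl.fit_quadratic(pairs), criterion="aicc"
        )
        assert cmp.criterion == "aicc"
        assert cmp.aicc_linear < cmp.aicc_quadratic
        assert cmp.verdict == "linear-preferred"


class TestDetectDeviatingAges:
    def test_exact_line_excludes_nothing(self, herring_params):
        table = gl.generate_table(gl.SyntheticSpec(params=herring_params, n_cohorts=1))
        det = gl.detect_deviating_ages(gl.extract_cohorts(table)[0])
        assert det.excluded_ages.size == 0
        assert det.threshold_met and det.fit.r2 == pytest.approx(1.0)

    def test_suppressed_young_ages_are_excluded(self, herring_params):
        spec = gl.SyntheticSpec(
            params=herring_params, n_cohorts=1, k_overrides={1: 0.15, 2: 0.15}
        )
        det = gl.detect_deviating_ages(gl.extract_cohorts(gl.generate_table(spec))[0])
        assert list(det.excluded_ages) == [1, 2]
        assert det.fit.r2 == pytest.approx(1.0)
        assert det.fit.k == pytest.approx(0.3, abs=1e-9)
        assert det.fit.L_max == pytest.approx(354.0, rel=1e-9)

    def test_exclusion_matches_exhaustive_prefix_search(self, herring_params):
        """Oracle: evaluate every drop-youngest prefix and take the first hit."""
        spec = gl.SyntheticSpec(
            params=herring_params, n_cohorts=1, k_overrides={1: 0.1, 2: 0.2}
        )
        series = gl.extract_cohorts(gl.generate_table(spec))[0]
        pairs = gl.increments(series)
        expected_drop = None
        for d in range(len(pairs) - 3 + 1):
            sub = pairs.subset(np.arange(len(pairs)) >= d)
            if gl.fit_linear(sub).r2 >= 0.98:
                expected_drop = d
                break
        det = gl.detect_deviating_ages(series)
        assert det.excluded_ages.size == expected_drop

    def test_three_pair_boundary_returns_full_set_flagged(self):
        # 3 scattered pairs below threshold: nothing can be dropped
        series = gl.CohortSeries(
            2000, np.array([1, 2, 3, 4]), np.array([10.0, 30.0, 35.0, 60.0])
        )
        det = gl.detect_deviating_ages(series)
        assert not det.threshold_met
        assert det.excluded_ages.size == 0
        assert np.array_equal(det.core_ages, series.ages)

    def test_idempotent_on_own_output(self, herring_params):
        spec = gl.SyntheticSpec(
            params=herring_params, n_cohorts=1, k_overrides={1: 0.15, 2: 0.15}
        )
        series = gl.extract_cohorts(gl.generate_table(spec))[0]
        det = gl.detect_deviating_ages(series)
        core = gl.CohortSeries(
            series.birth_year,
            series.ages[np.isin(series.ages, det.core_ages)],
            series.lengths[np.isin(series.ages, det.core_ages)],
        )
        det2 = gl.detect_deviating_ages(core)
        assert det2.excluded_ages.size == 0
        assert np.array_equal(det2.core_ages, det.core_ages)


class TestPerAgeK:
    @pytest.mark.parametrize(
        "dL, L, L_max, expected",
        [
            (20.0, 100.0, 354.0, 20.0 / 254.0),
            (0.0, 100.0, 354.0, 0.0),
            (5.4, 300.0, 354.0, 0.1),  # inverse of the pointwise prediction
        ],
    )
    def test_k_for_age(self, dL, L, L_max, expected):
        assert gl.k_for_age(dL, L, L_max) == pytest.approx(expected, abs=1e-12)

    def test_k_for_age_clamps_negative_and_rejects_domain(self):
        assert gl.k_for_age(-2.0, 100.0, 354.0) == 0.0
        with pytest.raises(DomainError):
            gl.k_for_age(5.0, 354.0, 354.0)

    def test_constant_k_recovered_everywhere(self, herring_params, noiseless_table):
        yk = gl.k_by_yearclass(gl.extract_cohorts(noiseless_table))
        assert all(e.k == pytest.approx(0.3, abs=1e-9) for e in yk.estimates)

    def test_suppressed_young_k_recovered_off_line(self, herring_params):
        spec = gl.SyntheticSpec(
            params=herring_params, n_cohorts=3, k_overrides={1: 0.15, 2: 0.15}
        )
        cohorts = [
            c
            for c in gl.extract_cohorts(gl.generate_table(spec))
            if c.ages.size == 9
        ]
        yk = gl.k_by_yearclass(cohorts)
        for e in yk.estimates:
            if e.age in (1, 2):
                assert e.source == "off-line"
                assert e.k == pytest.approx(0.15, abs=1e-6)
            else:
                assert e.source == "on-line"
                assert e.k == pytest.approx(0.30, abs=1e-6)

    def test_single_cohort_shared_L_max_is_its_own(self, herring_params):
        table = gl.generate_table(gl.SyntheticSpec(params=herring_params, n_cohorts=1))
        series = gl.extract_cohorts(table)[0]
        yk = gl.k_by_yearclass([series])
        det = gl.detect_deviating_ages(series)
        assert yk.shared_L_max == pytest.approx(det.fit.L_max)


class TestScaleEquivariance:
    def test_fit_statistics_invariant_under_unit_change(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = rng.integers(6, 15)
            L = rng.uniform(10, 400, n)
            dL = 100 - 0.25 * L + rng.normal(0, 3, n)
            c = rng.uniform(0.1, 10)
            base_l = gl.fit_linear(_pairs(L, dL))
            base_q = gl.fit_quadratic(_pairs(L, dL))
            base_c = gl.compare_models(base_l, base_q)
            sc_l = gl.fit_linear(_pairs(c * L, c * dL))
            sc_q = gl.fit_quadratic(_pairs(c * L, c * dL))
            sc_c = gl.compare_models(sc_l, sc_q)
            assert sc_l.k == pytest.approx(base_l.k, rel=1e-9)
            assert sc_l.L_max == pytest.approx(c * base_l.L_max, rel=1e-9)
            assert sc_l.r2 == pytest.approx(base_l.r2, rel=1e-9)
            assert sc_c.f_stat == pytest.approx(base_c.f_stat, rel=1e-6)
            assert sc_c.p_value == pytest.approx(base_c.p_value, rel=1e-6)


def test_ci_conservative_under_survey_length_noise(herring_params):
    """Length noise makes adjacent dL errors negatively correlated, so the
    nominal delta-method CIs over-cover; they must never under-cover."""
    base = gl.noiseless_lengths(gl.SyntheticSpec(params=herring_params, n_cohorts=1))
    sd = 0.05 * np.diff(base).mean()
    rng = np.random.default_rng(2718)
    cov = 0
    reps = 200
    for _ in range(reps):
        spec = gl.SyntheticSpec(
            params=herring_params,
            n_cohorts=1,
            noise_sd=sd,
            seed=int(rng.integers(2**31)),
        )
        fit = gl.fit_linear(gl.increments(gl.extract_cohorts(gl.generate_table(spec))[0]))
        lo, hi = fit.k_ci()
        cov += lo <= 0.3 <= hi
    assert cov / reps >= 0.95
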