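"""Main-effects fitting, dummy-based error, significance, validation, recommendation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spequant as sq
from spequant._errors import ConfigurationError, FitError, IncompleteDataError
from spequant.screening import ScreeningFit


def _response_set(design, y_by_run):
    return sq.ResponseSet({rid: {"y": float(v)} for rid, v in y_by_run.items()})


def _fit_random_instance(design, rng, sd=1.0):
    y = {rid: rng.normal(0.0, sd) for rid in design.run_ids}
    return sq.fit_screening_model(design, _response_set(design, y), "y"), y


@pytest.fixture(scope="module")
def design():
    return sq.build_pb_design(9, 2, 3, seed=7)


class TestFit:
    def test_constant_response(self, design):
        rs = _response_set(design, {rid: 123.4 for rid in design.run_ids})
        fit = sq.fit_screening_model(design, rs, "y")
        assert fit.intercept == pytest.approx(123.4)
        assert np.allclose(fit.coefficients, 0.0, atol=1e-9)
        assert fit.predicted_center == fit.intercept

    def test_matches_normal_equations_oracle(self, design):
        rng = np.random.default_rng(0)
        X = design.factorial_block.astype(float)
        A = np.column_stack([np.ones(len(X)), X])
        for _ in range(10):
            fit, y = _fit_random_instance(design, rng, sd=3.0)
            yv = np.array([y[r] for r in design.factorial_run_ids])
            beta = np.linalg.solve(A.T @ A, A.T @ yv)
            assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
            assert np.allclose(fit.coefficients, beta[1:], rtol=1e-10, atol=1e-12)

    def test_intercept_is_mean_of_factorial_responses(self, design):
        rng = np.random.default_rng(1)
        fit, y = _fit_random_instance(design, rng)
        mean = np.mean([y[r] for r in design.factorial_run_ids])
        assert fit.intercept == pytest.approx(mean, rel=1e-12)

    def test_planted_signs_recovered(self, design):
        rng = np.random.default_rng(5)
        b = {"x4": 8000.0, "x2": -6000.0, "x5": 4000.0}
        bvec = np.array([b.get(n, 0.0) for n in design.factor_names])
        mu = 50_000.0 + design.coded_matrix @ bvec
        y = {rid: m + rng.normal(0, 2500.0) for rid, m in zip(design.run_ids, mu)}
        fit = sq.fit_screening_model(design, _response_set(design, y), "y")
        assert fit.coefficient("x4") > 0
        assert fit.coefficient("x2") < 0
        assert fit.coefficient("x5") > 0

    def test_missing_run_named(self, design):
        y = {rid: 1.0 for rid in design.run_ids}
        del y[9]
        with pytest.raises(IncompleteDataError, match="run 9"):
            sq.fit_screening_model(design, _response_set(design, y), "y")

    def test_rank_deficient_plan_rejected(self, design):
        corrupted = sq.ScreeningDesign(
            factors=design.factors,
            coded_matrix=np.where(
                np.arange(design.coded_matrix.shape[1]) == 1,
                design.coded_matrix[:, [0]],
                design.coded_matrix,
            ),
            run_ids=design.run_ids,
            center_run_ids=design.center_run_ids,
        )
        rs = _response_set(design, {rid: 1.0 for rid in design.run_ids})
        with pytest.raises(FitError):
            sq.fit_screening_model(corrupted, rs, "y")


def _fit_with_dummies(d1, d2):
    names = tuple(f"x{i}" for i in range(1, 12))
    coefs = np.zeros(11)
    coefs[9], coefs[10] = d1, d2
    return ScreeningFit(
        response_name="y", intercept=0.0, coefficients=coefs,
        factor_names=names, dummy_index=(9, 10), n_runs=12, df_resid=0,
    )


class TestDummyError:
    def test_closed_form(self):
        fit = _fit_with_dummies(3.0, -4.0)
        se, band = sq.estimate_error_from_dummies(fit)
        assert se == pytest.approx(3.536, abs=1e-3)
        assert band == pytest.approx(4.0)

    def test_noise_free_data_gives_zero(self, design, noise_free_config):
        rs = sq.simulate_screening_responses(design, noise_free_config)
        fit = sq.fit_screening_model(design, rs, "cyclophosphamide_area")
        se, band = sq.estimate_error_from_dummies(fit)
        scale = abs(fit.intercept)
        assert se <= 1e-10 * scale
        assert band <= 1e-10 * scale

    def test_no_dummies_rejected(self):
        fit = ScreeningFit(
            response_name="y", intercept=0.0, coefficients=np.zeros(3),
            factor_names=("a", "b", "c"), dummy_index=(), n_runs=12, df_resid=8,
        )
        with pytest.raises(ConfigurationError):
            sq.estimate_error_from_dummies(fit)

    def test_sampling_distribution(self, design):
        # each dummy coefficient ~ N(0, sigma^2/N); the RMS of two of them
        # averages to about sqrt(pi)/2 * sigma/sqrt(N)
        sigma = 120.0
        rng = np.random.default_rng(99)
        ses = []
        for _ in range(1000):
            fit, _ = _fit_random_instance(design, rng, sd=sigma)
            se, _ = sq.estimate_error_from_dummies(fit)
            ses.append(se)
        assert np.mean(ses) == pytest.approx(sigma / np.sqrt(12), rel=0.15)


class TestSignificance:
    def test_coefficient_below_band_insignificant(self):
        fit = _fit_with_dummies(3.0, -4.0)
        fit.coefficients[0] = 3.5  # |b_1| < band of 4
        fit.coefficients[1] = -7.0
        flags = sq.flag_significant(fit, rule="dummy_band")
        assert flags["x1"] is False
        assert flags["x2"] is True

    def test_all_zero_none_significant(self):
        fit = _fit_with_dummies(0.0, 0.0)
        flags = sq.flag_significant(fit, rule="dummy_band")
        assert not any(flags.values())  # boundary is a strict inequality

    def test_unknown_rule_rejected(self):
        fit = _fit_with_dummies(1.0, 1.0)
        with pytest.raises(ValueError):
            sq.flag_significant(fit, rule="bonferroni")

    def test_power_for_large_effect(self, design):
        # effect 10x the noise sd must be detected essentially always
        sigma = 500.0
        bvec = np.array(
            [10 * sigma if n == "x4" else 0.0 for n in design.factor_names]
        )
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            mu = design.coded_matrix @ bvec
            y = {rid: m + rng.normal(0, sigma) for rid, m in zip(design.run_ids, mu)}
            fit = sq.fit_screening_model(design, _response_set(design, y), "y")
            if sq.flag_significant(fit)["x4"]:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_coverage_of_t_based_bounds(self, design):
        # planted coefficients fall inside b_hat +/- t(0.975, df=2) * effect_se
        # in ~95% of replicates (the dummy-based se follows the same error law)
        from scipy import stats

        sigma = 300.0
        bvec = np.array(
            [1000.0 if n in ("x2", "x4") else 0.0 for n in design.factor_names]
        )
        rng = np.random.default_rng(11)
        crit = stats.t.ppf(0.975, df=2)
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            mu = design.coded_matrix @ bvec
            y = {rid: m + rng.normal(0, sigma) for rid, m in zip(design.run_ids, mu)}
            fit = sq.fit_screening_model(design, _response_set(design, y), "y")
            se, _ = sq.estimate_error_from_dummies(fit)
            if abs(fit.coefficient("x4") - 1000.0) <= crit * se:
                covered += 1
        assert covered / n_sim >= 0.93

    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_flags_invariant_under_scaling(self, k):
        fit = _fit_with_dummies(3.0, -4.0)
        fit.coefficients[:5] = [3.5, -7.0, 4.5, 0.0, -2.0]
        base = sq.flag_significant(fit, rule="dummy_band")
        scaled = _fit_with_dummies(3.0 * k, -4.0 * k)
        scaled.coefficients = fit.coefficients * k
        assert sq.flag_significant(scaled, rule="dummy_band") == base

    def test_internal_standard_mostly_clean(self, design):
        # a response with no planted effects should usually show no
        # significant factor under the t rule (robustness expectation)
        from spequant.screening import flag_significant

        rng = np.random.default_rng(2024)
        clean = 0
        n_sim = 100
        for _ in range(n_sim):
            y = {rid: 60_000.0 + rng.normal(0, 2000.0) for rid in design.run_ids}
            fit = sq.fit_screening_model(design, _response_set(design, y), "y")
            flags = flag_significant(fit, rule="t_test", alpha=0.05)
            real = [n for i, n in enumerate(fit.factor_names) if i not in fit.dummy_index]
            if not any(flags[n] for n in real):
                clean += 1
        assert clean / n_sim >= 0.5


class TestCenterValidation:
    def test_overlapping_intervals_validated(self):
        v = sq.ValidationVerdict.from_intervals(65_490, 10_678, 59_339, 10_678)
        assert v.verdict == "validated"

    def test_disjoint_intervals_not_validated(self):
        v = sq.ValidationVerdict.from_intervals(716, 9, 804, 9)
        assert v.verdict == "not_validated"

    def test_identical_means_always_validated(self):
        v = sq.ValidationVerdict.from_intervals(100.0, 5.0, 100.0, 5.0)
        assert v.validated

    def test_computed_from_replicates(self, design, noise_free_config):
        cfg = noise_free_config
        cfg.screening["cyclophosphamide_area"].noise_sd = 1500.0
        rs = sq.simulate_screening_responses(design, cfg, seed=3)
        fit = sq.fit_screening_model(design, rs, "cyclophosphamide_area")
        center = rs.vector(design.center_run_ids, "cyclophosphamide_area")
        verdict = sq.validate_at_center(fit, center, alpha=0.05)
        assert verdict.experimental_halfwidth > 0
        assert verdict.predicted == fit.intercept
        assert verdict.precision_rsd > 0

    def test_requires_two_replicates(self, design):
        fit = _fit_with_dummies(1.0, 1.0)
        with pytest.raises(IncompleteDataError):
            sq.validate_at_center(fit, [100.0])


class TestRecommendation:
    @staticmethod
    def _study_like_fits(design, noise_free_config):
        rs = sq.simulate_screening_responses(design, noise_free_config)
        fits = {}
        for name in ("cyclophosphamide_area", "duration_s"):
            fit = sq.fit_screening_model(design, rs, name)
            sq.flag_significant(fit)
            fits[name] = fit
        return fits

    def test_levels_follow_signs(self, study_plan, noise_free_config):
        fits = self._study_like_fits(study_plan, noise_free_config)
        rec = sq.recommend_conditions(
            fits,
            {"cyclophosphamide_area": "maximize", "duration_s": "minimize"},
            priority=["cyclophosphamide_area", "duration_s"],
        )
        # the three dominant sensitivity factors reproduce the chosen levels
        assert rec.levels["x4"] == 1
        assert rec.levels["x2"] == -1
        assert rec.levels["x5"] == 1

    def test_minimize_duration_prefers_fast_loading(self, study_plan, noise_free_config):
        rs = sq.simulate_screening_responses(study_plan, noise_free_config)
        fit = sq.fit_screening_model(study_plan, rs, "duration_s")
        sq.flag_significant(fit)
        rec = sq.recommend_conditions({"duration_s": fit}, {"duration_s": "minimize"})
        assert rec.levels["x5"] == 1  # negative coefficient, minimize -> high level

    def test_all_insignificant_leaves_factors_free(self):
        fit = _fit_with_dummies(5.0, -5.0)  # band swallows everything
        fit.coefficients[:9] = 1.0
        sq.flag_significant(fit)
        rec = sq.recommend_conditions({"y": fit}, {"y": "maximize"})
        assert all(level == 0 for level in rec.levels.values())
        assert all(t.get("note") == "free" for t in rec.trace)

    def test_empty_objectives_rejected(self):
        with pytest.raises(ValueError):
            sq.recommend_conditions({}, {})

    def test_decision_trace_records_source(self, study_plan, noise_free_config):
        fits = self._study_like_fits(study_plan, noise_free_config)
        rec = sq.recommend_conditions(
            fits,
            {"cyclophosphamide_area": "maximize", "duration_s": "minimize"},
        )
        by_factor = {t["factor"]: t for t in rec.trace}
        assert by_factor["x4"]["decided_by"] == "cyclophosphamide_area"
        assert by_factor["x4"]["coefficient"] > 0
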