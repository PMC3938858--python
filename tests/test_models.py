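"""Correlation screening and log-link GLMs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from soilhealth import (
    MulticollinearityError,
    correlation_matrix,
    critical_r,
    fit_sir_glm,
    pearson_r,
    select_model,
)


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 40)
            x, y = rng.standard_normal((2, n))
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            expect = np.sum((x - x.mean()) * (y - y.mean())) / (
                np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
            )
            assert pearson_r(x, y) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCriticalR:
    def test_closed_form_small_n(self):
        # t_{0.025,1} = 12.706 -> r = 12.706/sqrt(12.706^2 + 1)
        assert critical_r(3) == pytest.approx(0.997, abs=5e-4)

    def test_monotone_decreasing_to_zero(self):
        grid = [10, 30, 100, 300, 1000, 10_000]
        vals = [critical_r(n) for n in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.02

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2)

    def test_false_positive_rate_of_threshold(self):
        # independent pairs at n=279 should exceed the threshold ~5% of the time
        rng = np.random.default_rng(1)
        rc = critical_r(279)
        hits = sum(
            abs(pearson_r(*rng.standard_normal((2, 279)))) > rc for _ in range(400)
        )
        assert 0.02 <= hits / 400 <= 0.09


class TestCorrelationMatrix:
    def test_lower_triangle_and_symmetry_under_reordering(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        m1 = correlation_matrix(df, ["a", "b", "c"])
        assert len(m1) == 3
        m2 = correlation_matrix(df, ["c", "a", "b"])
        lut = {frozenset((r.var_a, r.var_b)): r.r for r in m2.itertuples()}
        for r in m1.itertuples():
            assert lut[frozenset((r.var_a, r.var_b))] == pytest.approx(r.r)

    def test_listwise_deletion_reports_common_n(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        df.loc[:4, "a"] = np.nan
        m = correlation_matrix(df, ["a", "b"])
        assert (m["n"] == 35).all()

    def test_too_few_complete_cases_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_matrix(df, ["a", "b"])


def _glm_data(n=60, c=2.0, rng=None):
    rng = rng or np.random.default_rng(0)
    e = rng.uniform(5, 50, n)
    return pd.DataFrame({"zone_id": np.arange(n), "O": c * e, "E": e})


class TestGLM:
    def test_intercept_only_closed_form(self):
        d = _glm_data(c=2.5)
        fit = fit_sir_glm(d, soil_covariate=None, air=None, decile_col=None)
        assert fit.table["estimate"].iloc[0] == pytest.approx(np.log(2.5), abs=1e-6)

    def test_two_soil_metals_refused(self):
        d = _glm_data()
        with pytest.raises(MulticollinearityError):
            fit_sir_glm(d, soil_covariate=["gm_Ni", "gm_Pb"], air=None, decile_col=None)

    def test_both_air_pollutants_refused(self):
        d = _glm_data()
        with pytest.raises(MulticollinearityError):
            fit_sir_glm(d, soil_covariate=None, air=["no2", "pm10"], decile_col=None)

    def test_offset_model_with_unit_expected_reduces_to_poisson_loglinear(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.standard_normal(n)
        o = rng.poisson(np.exp(0.5 + 0.3 * x))
        d = pd.DataFrame({"O": o, "E": 1.0, "soil_index": x})
        ours = fit_sir_glm(d, air=None, decile_col=None)
        X = sm.add_constant(x)
        ref = sm.GLM(o, X, family=sm.families.Poisson()).fit()
        assert np.allclose(ours.table["estimate"], ref.params, atol=1e-8)
        assert ours.aic == pytest.approx(ref.aic)

    def test_gaussian_log_family_available(self):
        d = _glm_data(c=1.5)
        fit = fit_sir_glm(d, soil_covariate=None, air=None, decile_col=None, family="gaussian_log")
        assert fit.table["estimate"].iloc[0] == pytest.approx(np.log(1.5), abs=1e-6)

    def test_table_shape_with_deciles(self, default_study):
        from soilhealth import compute_sir, derive_standard_rates

        s = default_study
        rates = derive_standard_rates(s.population, s.cases_by_stratum)
        sir = compute_sir(s.population, rates, s.cases)
        d = sir.merge(s.covariates, on="zone_id")
        fit = fit_sir_glm(d)
        terms = list(fit.table["term"])
        assert terms[0] == "Intercept"
        assert terms[1] == "Soil metal index"
        assert terms[2:11] == [f"Decile {k}" for k in range(2, 11)]
        assert terms[11] == "Air NO2"
        assert np.isfinite(fit.aic)


class TestSelectModel:
    def test_single_candidate_and_ties(self):
        d = _glm_data()
        a = fit_sir_glm(d, soil_covariate=None, air=None, decile_col=None)
        assert select_model([a]) is a
        b = fit_sir_glm(d.assign(noise=0.0), soil_covariate=None, air=None, decile_col=None)
        b.aic = a.aic  # forced tie: smaller model must win
        b.table = pd.concat([b.table, b.table]).reset_index(drop=True)
        assert select_model([b, a]) is a

    def test_noise_covariate_raises_aic_in_expectation(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(25):
            d = _glm_data(n=80, rng=rng)
            d["O"] = rng.poisson(1.8 * d["E"])
            if (d["O"] == 0).all():
                continue
            d["noise"] = rng.standard_normal(len(d))
            base = fit_sir_glm(d, soil_covariate=None, air=None, decile_col=None)
            noisy = fit_sir_glm(
                d, soil_covariate=None, air=None, decile_col=None, extra_covariates=["noise"]
            )
            diffs.append(noisy.aic - base.aic)
            assert select_model([base, noisy]).aic == min(base.aic, noisy.aic)
        assert np.mean(diffs) > 0

    def test_true_covariate_beats_null_on_strong_signal(self):
        rng = np.random.default_rng(6)
        n = 150
        x = rng.standard_normal(n)
        e = np.full(n, 20.0)
        d = pd.DataFrame({"O": rng.poisson(e * np.exp(0.4 * x)), "E": e, "soil_index": x})
        null = fit_sir_glm(d, soil_covariate=None, air=None, decile_col=None)
        true = fit_sir_glm(d, air=None, decile_col=None)
        assert select_model([null, true]) is true

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([])
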