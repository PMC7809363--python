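"""Analysis-table assembly, contingency statistics, and the GEE solver
(cross-checked against statsmodels and closed-form oracles)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from asthma_qa.config import SimulationConfig
from asthma_qa.gee import EstimationError, gee_logistic
from asthma_qa.models import (
    ExacerbationGEE,
    Term,
    age_band,
    build_analysis_table,
    build_design,
    column_percentages,
    contingency,
    fit_gee,
    fit_subgroup_models,
)
from asthma_qa.synthetic import simulate_analysis_rows


def correlated_binary(n, T, beta, rho, seed):
    """Copula draw with known marginal logistic model; returns a frame."""
    rng = np.random.default_rng(seed)
    x1 = rng.integers(0, 2, (n, 1)).repeat(T, axis=1)
    x2 = rng.normal(size=(n, T))
    lin = beta[0] + beta[1] * x1 + beta[2] * x2
    p = expit(lin)
    z = rng.standard_normal((n, T))
    for t in range(1, T):
        z[:, t] = rho * z[:, t - 1] + np.sqrt(1 - rho**2) * z[:, t]
    y = (norm.cdf(z) < p).astype(float)
    return pd.DataFrame(
        {
            "y": y.ravel(),
            "x1": x1.ravel().astype(float),
            "x2": x2.ravel(),
            "pid": np.repeat(np.arange(n), T),
            "t": np.tile(np.arange(T), n),
        }
    )


class TestGEESolver:
    def test_independence_single_observation_equals_logistic_mle(self):
        df = correlated_binary(1000, 1, (-1.0, 0.8, 0.5), 0.0, seed=1)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        res = gee_logistic(X, df["y"], df["pid"], corstr="independence")
        mle = sm.Logit(df["y"], X).fit(disp=0)
        np.testing.assert_allclose(res.params, mle.params, atol=1e-6)

    @pytest.mark.parametrize("corstr", ["ar1", "exchangeable"])
    def test_matches_statsmodels_gee(self, corstr):
        df = correlated_binary(1500, 3, (-1.0, 0.5, 0.3), 0.45, seed=2)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        res = gee_logistic(
            X, df["y"], df["pid"], df["t"], corstr=corstr
        )
        cs = (
            sm.cov_struct.Autoregressive(grid=True)
            if corstr == "ar1"
            else sm.cov_struct.Exchangeable()
        )
        smres = sm.GEE(
            df["y"].to_numpy(), X, groups=df["pid"].to_numpy(),
            time=df["t"].to_numpy(),
            family=sm.families.Binomial(), cov_struct=cs,
        ).fit()
        np.testing.assert_allclose(res.params, smres.params, atol=5e-3)
        np.testing.assert_allclose(res.bse, smres.bse, rtol=0.02)
        # QICu agrees with the statsmodels definition at unit scale
        np.testing.assert_allclose(res.qicu, smres.qic(scale=1.0)[1], rtol=1e-4)

    def test_working_structures_give_similar_coefficients(self):
        df = correlated_binary(3000, 3, (-1.2, 0.4, 0.3), 0.5, seed=3)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        fits = {
            c: gee_logistic(X, df["y"], df["pid"], df["t"], corstr=c)
            for c in ("ar1", "exchangeable", "independence")
        }
        se = fits["ar1"].bse
        for a in ("exchangeable", "independence"):
            assert np.all(np.abs(fits[a].params - fits["ar1"].params) < se)

    def test_sandwich_is_symmetric_psd(self):
        df = correlated_binary(800, 3, (-1.0, 0.3, 0.2), 0.3, seed=4)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        res = gee_logistic(X, df["y"], df["pid"], df["t"], corstr="ar1")
        V = res.cov_robust
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-12

    def test_rank_deficiency_and_few_clusters_rejected(self):
        X = np.ones((10, 2))
        y = np.zeros(10)
        with pytest.raises(EstimationError):
            gee_logistic(X, y, np.arange(10))
        X2 = np.column_stack([np.ones(4), [0, 1, 0, 1]])
        with pytest.raises(EstimationError):
            gee_logistic(X2, np.array([0, 1, 0, 1]), np.zeros(4))


@pytest.fixture(scope="module")
def rows():
    return simulate_analysis_rows(SimulationConfig(n_patients=3000, seed=5))


class TestModelInterface:

    def test_or_ci_consistency(self, rows):
        fit = fit_gee(rows)
        s = fit.summary
        assert (s["ci_low"] <= s["OR"]).all() and (s["OR"] <= s["ci_high"]).all()
        np.testing.assert_allclose(s["OR"], np.exp(s["coef"]))

    def test_reference_switch_flips_sign_keeps_probabilities(self, rows):
        t1 = [Term("grade", ref="Tertiary"), Term("comorbidity", ref="no")]
        t2 = [Term("grade", ref="Tertiary"), Term("comorbidity", ref="yes")]
        m1 = ExacerbationGEE(terms=t1).fit(rows)
        m2 = ExacerbationGEE(terms=t2).fit(rows)
        np.testing.assert_allclose(
            m1.coef_["comorbidity[yes]"], -m2.coef_["comorbidity[no]"], atol=1e-8
        )
        np.testing.assert_allclose(
            m1.predict_proba(rows), m2.predict_proba(rows), atol=1e-8
        )

    def test_estimator_params_round_trip(self):
        est = ExacerbationGEE(corstr="exchangeable", max_iter=50)
        params = est.get_params()
        est2 = ExacerbationGEE().set_params(**params)
        assert est2.corstr == "exchangeable" and est2.max_iter == 50

    def test_subgroup_fit_bookkeeping(self, rows):
        fits = fit_subgroup_models(rows)
        assert set(fits.by_severity) == set(rows["severity"].unique())
        for sev, fit in fits.by_severity.items():
            assert fit.result.n_obs == (rows["severity"] == sev).sum()
            assert "severity[II]" not in fit.summary.index
            assert "total_rank" in fit.summary.index
        total = sum(f.qicu for f in fits.by_severity.values())
        assert fits.total_qicu == pytest.approx(total)

    def test_single_outcome_stratum_skipped(self, rows):
        r = rows.copy()
        r.loc[r["severity"] == "IV", "exacerbated"] = 1
        with pytest.warns(UserWarning, match="severity IV"):
            fits = fit_subgroup_models(r)
        assert fits.skipped == ["IV"]

    def test_heterogeneous_grade_effects_favor_subgroup_model(self):
        cfg = SimulationConfig(
            n_patients=12000,
            seed=17,
            grade_log_odds={
                # strong heterogeneity across severity groups
                "Unsatisfactory": (0.8, -0.6, 0.9, -0.5),
                "Satisfactory": (-0.5, 0.8, -0.6, 0.9),
            },
        )
        rows = simulate_analysis_rows(cfg)
        fits = fit_subgroup_models(rows)
        assert fits.total_qicu < fits.whole.qicu


class TestContingency:
    def test_column_percentages_of_published_style_counts(self):
        counts = pd.DataFrame(
            {0: [1833, 23061, 22612, 41779], 1: [1446, 4901, 6886, 11430]},
            index=["0", "1", "2", "3"],
        )
        pct = column_percentages(counts)
        np.testing.assert_allclose(pct[0], [2.1, 25.8, 25.3, 46.8])
        np.testing.assert_allclose(pct[1], [5.9, 19.9, 27.9, 46.3])

    def test_two_by_two_matches_closed_form(self):
        a, b, c, d = 30, 70, 45, 55
        df = pd.DataFrame(
            {
                "v": ["x"] * (a + b) + ["y"] * (c + d),
                "exacerbated": [1] * a + [0] * b + [1] * c + [0] * d,
            }
        )
        res = contingency(df, "v")
        n = a + b + c + d
        expected = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        assert res.chi2 == pytest.approx(expected)
        assert res.dof == 1

    def test_independent_table_gives_zero_statistic(self):
        df = pd.DataFrame(
            {
                "v": ["x", "x", "y", "y"] * 25,
                "exacerbated": [0, 1, 0, 1] * 25,
            }
        )
        assert contingency(df, "v").chi2 == pytest.approx(0.0)

    def test_low_expected_cell_warns_but_returns(self):
        df = pd.DataFrame(
            {"v": ["x"] * 99 + ["y"], "exacerbated": [0] * 99 + [1]}
        )
        with pytest.warns(UserWarning, match="expected cell"):
            res = contingency(df, "v")
        assert res.chi2 >= 0


class TestAnalysisTable:
    def _stages(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2"],
                "period": [1, 2, 1],
                "stream": "primary",
                "institution_id": "C1",
                "age": [40, 41, 70],
                "sex": ["F", "F", "M"],
            }
        )
        severity = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2"],
                "period": [1, 2, 1],
                "severity": ["I", "II", "III"],
                "total_rank": [10.0, 120.0, 700.0],
            }
        )
        covs = pd.DataFrame(
            {
                "patient_id": ["p1", "p1", "p2"],
                "period": [1, 2, 1],
                "mpr_level": [3, 2, 1],
                "comorbidity": [True, False, True],
                "exacerbated": [False, True, True],
            }
        )
        grades = pd.DataFrame(
            {"institution_id": ["C1", "C1"], "period": [1, 2],
             "grade": ["Satisfactory", "Unsatisfactory"]}
        )
        return cohort, severity, covs, grades

    def test_join_and_recoding(self):
        rows = build_analysis_table(*self._stages())
        assert len(rows) == 3
        assert set(rows["comorbidity"]) == {"yes", "no"}
        assert rows.loc[rows["patient_id"] == "p2", "age_band"].iloc[0] == "65+"
        assert rows["exacerbated"].tolist() == [0, 1, 1]

    def test_duplicate_observation_rejected(self):
        cohort, severity, covs, grades = self._stages()
        dup = pd.concat([cohort, cohort.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            build_analysis_table(dup, severity, covs, grades)

    def test_disjoint_stages_warn_and_return_empty(self):
        cohort, severity, covs, grades = self._stages()
        severity = severity.assign(period=severity["period"] + 10)
        covs = covs.assign(period=covs["period"] + 10)
        with pytest.warns(UserWarning, match="disjoint"):
            rows = build_analysis_table(cohort, severity, covs, grades)
        assert len(rows) == 0

    def test_partially_missing_keys_listed(self):
        cohort, severity, covs, grades = self._stages()
        severity = severity.iloc[:2]
        with pytest.raises(ValueError, match="severity"):
            build_analysis_table(cohort, severity, covs, grades)

    def test_age_bands_cover_the_analysis_range(self):
        bands = age_band([15, 34, 35, 44, 45, 54, 55, 64, 65, 90])
        assert list(bands) == [
            "15-34", "15-34", "35-44", "35-44", "45-54", "45-54",
            "55-64", "55-64", "65+", "65+",
        ]

    def test_design_matrix_reference_levels(self):
        df = pd.DataFrame(
            {"grade": ["Tertiary", "Satisfactory", "Unsatisfactory"],
             "total_rank": [1.0, 2.0, 3.0]}
        )
        X, names = build_design(
            df, [Term("grade", ref="Tertiary"), Term("total_rank", "numeric")]
        )
        assert names == ["Intercept", "grade[Satisfactory]",
                         "grade[Unsatisfactory]", "total_rank"]
        np.testing.assert_array_equal(X[0], [1, 0, 0, 1.0])
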