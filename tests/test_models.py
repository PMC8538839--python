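"""Association models: IQR scaling, coverage, mixed-model behaviour."""

import numpy as np
import pandas as pd
import pytest

from airmeth.models import (
    bivariate_tests,
    fit_mixed_model,
    fit_visit_model,
    sensitivity_suite,
)


def synth_frame(
    n=300,
    slope=0.0,
    seed=0,
    n_visits=1,
    intercept_sd=0.0,
    resid_sd=1.0,
    exposure_sd=3.0,
):
    """Observation-level frame with a known per-unit exposure slope."""
    rng = np.random.default_rng(seed)
    e = rng.normal(15.0, exposure_sd, n)
    b0 = rng.normal(0, intercept_sd, n)
    rows = []
    for v in range(n_visits):
        visit = "age9" if (n_visits == 2 and v == 0) else "age15"
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": [f"P{i:04d}" for i in range(n)],
                    "visit": visit,
                    "exposure": e,
                    "score": slope * e + b0 + rng.normal(0, resid_sd, n),
                    "child_sex": rng.choice(["male", "female"], n),
                    "age_at_measure": rng.normal(12, 1, n),
                    "income_to_needs": rng.lognormal(0.4, 0.8, n),
                    "marital_status": rng.choice(["married", "not_married"], n),
                    "race_ethnicity": rng.choice(["nh_white", "nh_black", "hispanic"], n),
                    "immune": rng.beta(9, 1, n),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestVisitModel:
    def test_iqr_scaling_identity(self):
        data = synth_frame(n=400, slope=0.01, seed=1)
        per_unit = fit_visit_model(data, iqr=1.0)
        per_iqr = fit_visit_model(data, iqr=3.20)
        assert per_iqr.effect == pytest.approx(per_unit.effect * 3.20, rel=1e-12)
        assert per_iqr.iqr_used == 3.20

    def test_subsample_iqr_default(self):
        data = synth_frame(n=400, slope=0.01, seed=1)
        res = fit_visit_model(data)
        q1, q3 = np.percentile(data["exposure"], [25, 75])
        assert res.iqr_used == pytest.approx(q3 - q1)

    def test_known_slope_recovered(self):
        data = synth_frame(n=5000, slope=0.05, seed=3, resid_sd=0.3)
        res = fit_visit_model(data, iqr=1.0)
        assert res.effect == pytest.approx(0.05, abs=0.01)
        assert res.ci_low <= res.effect <= res.ci_high

    def test_null_ci_coverage(self):
        """95% CIs cover zero 95% +/- 2% of the time under the null."""
        cover = 0
        n_rep = 500
        for s in range(n_rep):
            data = synth_frame(n=120, slope=0.0, seed=1000 + s)
            res = fit_visit_model(data, iqr=1.0)
            cover += res.ci_low <= 0 <= res.ci_high
        assert cover / n_rep == pytest.approx(0.95, abs=0.02)

    def test_zero_exposure_variance_errors(self):
        data = synth_frame(n=50, seed=2)
        data["exposure"] = 10.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_visit_model(data)

    def test_rank_deficiency_names_aliased_terms(self):
        data = synth_frame(n=100, seed=4)
        data["copy_of_exposure"] = data["exposure"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_visit_model(data, extra_adjust=("copy_of_exposure",))

    def test_complete_case_only(self):
        data = synth_frame(n=100, seed=5)
        data.loc[:9, "income_to_needs"] = np.nan
        res = fit_visit_model(data)
        assert res.n_obs == 90


class TestMixedModel:
    def test_singleton_groups_match_ols(self):
        data = synth_frame(n=250, slope=0.02, seed=6)
        ols = fit_visit_model(data, iqr=3.2)
        mixed = fit_mixed_model(data, iqr=3.2)
        assert mixed.effect == pytest.approx(ols.effect, abs=1e-6)

    def test_variance_components_recovered(self):
        """Planted intercept sd 0.5, residual sd 0.5 -> variance ratio ~ 1."""
        import statsmodels.formula.api as smf

        ratios = []
        for s in range(4):
            data = synth_frame(n=750, slope=0.0, seed=7 + s, n_visits=2,
                               intercept_sd=0.5, resid_sd=0.5)
            fit = smf.mixedlm(
                "score ~ exposure", data, groups=data["participant_id"]
            ).fit(reml=True)
            ratios.append(float(fit.cov_re.iloc[0, 0]) / float(fit.scale))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_pooled_slope_recovery_with_repeated_measures(self):
        ests = []
        for s in range(6):
            data = synth_frame(n=750, slope=-0.046, seed=100 + s, n_visits=2,
                               intercept_sd=0.5, resid_sd=0.5)
            ests.append(fit_mixed_model(data, iqr=3.20).effect)
        target = -0.046 * 3.20
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < 3 * se + 1e-3

    def test_result_counts(self):
        data = synth_frame(n=100, seed=8, n_visits=2)
        res = fit_mixed_model(data)
        assert res.n_indiv == 100 and res.n_obs == 200


class TestBivariate:
    def test_null_continuous_large_p(self):
        rng = np.random.default_rng(0)
        e = pd.Series(rng.normal(size=800))
        cov = pd.DataFrame({"x": rng.normal(size=800)})
        out = bivariate_tests(e, cov)
        assert out.loc[0, "p_value"] > 0.01

    def test_planted_shift_detected(self):
        """1-sd mean shift at n=400/arm is detected at p < 0.001 essentially always."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            e = pd.Series(np.concatenate([rng.normal(0, 1, 400), rng.normal(10, 1, 400)]))
            x = pd.Series(np.where(e > e.median(), rng.normal(1, 1, 800), rng.normal(0, 1, 800)))
            out = bivariate_tests(e, pd.DataFrame({"x": x}))
            hits += out.loc[0, "p_value"] < 0.001
        assert hits >= 19

    def test_constant_categorical_fisher_p_one(self):
        rng = np.random.default_rng(2)
        e = pd.Series(rng.normal(size=100))
        out = bivariate_tests(e, pd.DataFrame({"g": ["a"] * 100}))
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_fisher_2x2_balanced(self):
        rng = np.random.default_rng(3)
        e = pd.Series(rng.normal(size=400))
        g = pd.Series(rng.choice(["a", "b"], 400))
        out = bivariate_tests(e, pd.DataFrame({"g": g}))
        assert out.loc[0, "test"] == "fisher"
        assert 0 < out.loc[0, "p_value"] <= 1

    def test_monte_carlo_fisher_rxc(self):
        rng = np.random.default_rng(4)
        e = pd.Series(rng.normal(size=600))
        g = pd.Series(rng.choice(["a", "b", "c", "d"], 600))
        out = bivariate_tests(e, pd.DataFrame({"g": g}), seed=5)
        assert 0.001 < out.loc[0, "p_value"] <= 1

    def test_degenerate_stratum(self):
        e = pd.Series([1.0, 1.0, 1.0])
        out = bivariate_tests(e, pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.isnan(out.loc[0, "p_value"])
        assert out.loc[0, "reason"] == "degenerate stratum"

    def test_ties_go_to_lower_stratum(self):
        e = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        cov = pd.DataFrame({"x": np.arange(6.0)})
        out = bivariate_tests(e, cov)  # median 2.5; low stratum has 3 members
        assert out.loc[0, "test"] == "welch_t"


class TestSensitivitySuite:
    def make_sens_frame(self, n=400, seed=0, cpg_slope=0.0):
        # separate stream from synth_frame's so extra columns are independent
        rng = np.random.default_rng(seed + 777_000)
        base = synth_frame(n=n, seed=seed, n_visits=2)
        base = base.rename(columns={"exposure": "pm10_birth", "score": "score_pm10"})
        base["pm25_birth"] = rng.normal(27.9, 7.0, len(base))
        base["score_pm25"] = rng.normal(size=len(base))
        base["score_no2"] = rng.normal(size=len(base))
        base["pm10_age1"] = rng.normal(14.6, 3.0, len(base))
        base["cg20340716"] = 92.8 + (cpg_slope / 3.20) * base["pm10_birth"] + rng.normal(0, 1.0, len(base))
        return base

    def test_all_analyses_produce_models(self):
        frame = self.make_sens_frame()
        rep = sensitivity_suite(frame, cpg_columns=("cg20340716",),
                                analyses=("copollutant", "age1", "no2", "cpg"))
        tags = {r.variant for r in rep.results}
        assert any("copollutant" in t for t in tags)
        assert any("age1" in t for t in tags)
        assert any("no2_specificity" in t for t in tags)
        assert "single_cpg_percent" in tags

    def test_missing_postnatal_exposure_skipped(self):
        frame = self.make_sens_frame().drop(columns=["pm10_age1"])
        rep = sensitivity_suite(frame, analyses=("age1",))
        assert any("age1:pm10" in s for s in rep.skipped)
        assert not [r for r in rep.results if "age1" in r.variant and r.exposure == "pm10"]

    def test_single_cpg_percent_effect_recovered(self):
        """Planted +0.135 percent-per-IQR effect at cg20340716 is recovered."""
        ests = [
            next(
                r.effect
                for r in sensitivity_suite(
                    self.make_sens_frame(n=800, seed=50 + s, cpg_slope=0.135),
                    analyses=("cpg",),
                    cpg_columns=("cg20340716",),
                    iqr={"pm10": 3.20},
                ).results
            )
            for s in range(10)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.135) < 3 * se + 1e-3

    def test_uncorrelated_copollutant_leaves_estimate(self):
        frame = self.make_sens_frame(n=800, seed=9)
        plain = fit_visit_model(
            frame[frame.visit == "age15"], outcome="score_pm10",
            exposure_col="pm10_birth", stratum="age15", iqr=3.2,
        )
        rep = sensitivity_suite(frame, analyses=("copollutant",))
        adj = next(
            r for r in rep.results
            if r.exposure == "pm10" and r.stratum == "age15" and "copollutant" in r.variant
        )
        assert adj.effect == pytest.approx(plain.effect, abs=0.05)
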