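"""Synthetic-cohort generator: determinism, calibration, plant fidelity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from airmeth.config import CohortConfig, QCFaultCounts, default_config
from airmeth.qc import filter_samples
from airmeth.scores import cumulative_score, load_weights
from airmeth.synthetic import exposure_loading, generate_cohort, inject_qc_faults, site_longitudinal_r


def tiny_config(seed=0, **overrides):
    base = dict(
        n_both=80,
        n_age9_only=3,
        n_age15_only=5,
        n_background_cpgs=40,
        n_reference_cpgs=40,
        include_monitors=False,
    )
    base.update(overrides)
    return dataclasses.replace(default_config(seed=seed), **base)


class TestDeterminism:
    def test_same_seed_identical_cohort(self):
        a = generate_cohort(tiny_config(seed=5))
        b = generate_cohort(tiny_config(seed=5))
        assert a.exposures.equals(b.exposures)
        assert a.covariates.equals(b.covariates)
        for v in a.beta_bundles:
            assert a.beta_bundles[v].beta.equals(b.beta_bundles[v].beta)
            assert a.beta_bundles[v].detp.equals(b.beta_bundles[v].detp)
            assert a.beta_bundles[v].samples.equals(b.beta_bundles[v].samples)

    def test_different_seed_differs(self):
        a = generate_cohort(tiny_config(seed=5))
        b = generate_cohort(tiny_config(seed=6))
        assert not a.exposures["value"].equals(b.exposures["value"])


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(
        tiny_config(seed=11, n_both=0, n_age9_only=0, n_age15_only=10_000)
    )


class TestCalibration:
    def test_marginal_moments_within_three_mc_se(self, big_cohort):
        wide = big_cohort.exposure_wide()
        cal = big_cohort.config.exposure_calibration
        n = len(wide)
        for pol in ("pm25", "pm10"):
            x = wide[f"{pol}_birth"]
            se_mean = cal[pol].sd / np.sqrt(n)
            assert abs(x.mean() - cal[pol].mean) < 3 * se_mean
            se_sd = cal[pol].sd / np.sqrt(2 * (n - 1))
            assert abs(x.std() - cal[pol].sd) < 3 * se_sd

    def test_values_inside_configured_range(self, big_cohort):
        wide = big_cohort.exposure_wide()
        cal = big_cohort.config.exposure_calibration
        for pol in ("pm25", "pm10"):
            for anchor in ("birth", "age1", "age3"):
                x = wide[f"{pol}_{anchor}"]
                assert x.min() >= cal[pol].lower and x.max() <= cal[pol].upper

    def test_cross_time_correlation(self, big_cohort):
        wide = big_cohort.exposure_wide()
        r = np.corrcoef(wide["pm25_birth"], wide["pm25_age1"])[0, 1]
        se = (1 - 0.54**2) / np.sqrt(len(wide))
        assert abs(r - 0.54) < 3 * se

    def test_plant_fidelity_large_n(self, big_cohort):
        """Score-on-exposure slope recovers the planted SD/IQR value."""
        cfg = big_cohort.config
        bundle = big_cohort.beta_bundles["age15"]
        sc = cumulative_score(bundle.beta, load_weights("pm10"), "zscored")
        wide = big_cohort.exposure_wide().set_index("participant_id")
        pid = sc["sample_id"].str.rsplit("_", n=1).str[0]
        e = wide.loc[pid, "pm10_birth"].to_numpy()
        slope = np.polyfit(e, sc["score_standardized"].to_numpy(), 1)[0]
        per_iqr = slope * cfg.exposure_calibration["pm10"].reference_iqr
        # sampling sd of the per-IQR slope at n = 10,000 is ~0.011
        assert per_iqr == pytest.approx(cfg.planted_effects["pm10"], abs=3 * 0.011)

    def test_null_plant_centered_on_zero(self):
        """With all planted effects zero, score-exposure slopes average to zero."""
        slopes = []
        for s in range(12):
            cfg = tiny_config(
                seed=200 + s,
                n_both=0,
                n_age9_only=0,
                n_age15_only=400,
                planted_effects={"pm25": 0.0, "pm10": 0.0, "no2": 0.0},
            )
            co = generate_cohort(cfg)
            bundle = co.beta_bundles["age15"]
            sc = cumulative_score(bundle.beta, load_weights("pm10"), "zscored")
            wide = co.exposure_wide().set_index("participant_id")
            pid = sc["sample_id"].str.rsplit("_", n=1).str[0]
            e = wide.loc[pid, "pm10_birth"].to_numpy()
            slopes.append(np.polyfit(e, sc["score_standardized"].to_numpy(), 1)[0] * 3.20)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < 3 * se + 1e-12


class TestStructure:
    def test_betas_in_unit_interval(self, small_cohort):
        for b in small_cohort.beta_bundles.values():
            arr = b.beta.to_numpy()
            assert arr.min() >= 0 and arr.max() <= 1

    def test_every_participant_has_a_visit(self, small_cohort):
        seen = set()
        for b in small_cohort.beta_bundles.values():
            seen.update(b.samples["participant_id"])
        assert seen == set(small_cohort.covariates["participant_id"])

    def test_visit_counts_exact(self, small_cohort):
        cfg = small_cohort.config
        assert small_cohort.beta_bundles["age9"].n_samples == cfg.n_both + cfg.n_age9_only
        assert small_cohort.beta_bundles["age15"].n_samples == cfg.n_both + cfg.n_age15_only

    def test_infeasible_correlation_matrix_raises(self):
        cfg_kwargs = dict(
            exposure_corr_within={
                "pm25": {("birth", "age1"): 0.95, ("birth", "age3"): 0.95, ("age1", "age3"): -0.9},
                "pm10": {("birth", "age1"): 0.7, ("birth", "age3"): 0.7, ("age1", "age3"): 0.7},
            }
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_cohort(tiny_config(seed=1, **cfg_kwargs))

    def test_planted_effect_too_large_raises(self):
        with pytest.raises(ValueError, match="too large|infeasible"):
            exposure_loading(5.0, np.array([0.001, -0.001]), 1.05)

    def test_site_longitudinal_r_roundtrip(self):
        w = np.array([0.001, -0.001, 0.001, 0.001, -0.002, 0.001])
        rho = exposure_loading(-0.024, w, 3.20 / 3.06)
        lam = site_longitudinal_r(0.22, w, rho)
        # closed-form score correlation with this lambda equals the target
        C = w @ rho
        B = w @ w
        Q = (w * rho) @ (w * rho)
        r = (C**2 + lam * (B - Q)) / (B + C**2 - Q)
        assert r == pytest.approx(0.22, abs=1e-12)


class TestFaultInjection:
    def test_count_exact_faults_recovered_by_filter(self):
        co = generate_cohort(tiny_config(seed=9))
        out = inject_qc_faults(co, QCFaultCounts(5, 3, 2))
        logs = []
        for b in out.beta_bundles.values():
            _, log = filter_samples(b)
            logs.append(log)
        counts = pd.concat(logs)["rule"].value_counts()
        assert counts.get("detection", 0) == 5
        assert counts.get("sex_discordant", 0) == 3
        assert counts.get("abnormal_intensity", 0) == 2

    def test_truth_labels_cover_faults(self):
        co = generate_cohort(tiny_config(seed=9))
        out = inject_qc_faults(co, QCFaultCounts(4, 2, 1))
        faults = out.truth["qc_faults"]
        assert len(faults["detection"]) == 4
        assert len(faults["sex_discordant"]) == 2
        assert len(faults["abnormal_intensity"]) == 1
        all_ids = [sid for ids in faults.values() for sid in ids]
        assert len(all_ids) == len(set(all_ids))  # disjoint samples

    def test_zero_counts_leave_cohort_unchanged(self):
        co = generate_cohort(tiny_config(seed=9))
        out = inject_qc_faults(co, QCFaultCounts(0, 0, 0))
        for v in co.beta_bundles:
            assert co.beta_bundles[v].detp.equals(out.beta_bundles[v].detp)
            assert co.beta_bundles[v].samples.equals(out.beta_bundles[v].samples)

    def test_excessive_counts_raise(self):
        co = generate_cohort(tiny_config(seed=9))
        with pytest.raises(ValueError, match="exceeds"):
            inject_qc_faults(co, QCFaultCounts(10_000, 0, 0))

    def test_config_validation_rejects_excess_faults(self):
        with pytest.raises(ValueError):
            CohortConfig(n_both=2, n_age9_only=0, n_age15_only=0,
                         qc_fault_counts=QCFaultCounts(100, 0, 0))
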