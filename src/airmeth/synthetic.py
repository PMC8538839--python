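"""Seeded synthetic cohort generator.

Emulates the data structure of a two-visit saliva-methylation birth cohort
with monitor-based air-pollution exposure:

* per-participant prenatal/age-1/age-3 PM2.5 and PM10 window-average
  exposures, drawn through a Gaussian copula with moment-matched
  truncated-normal marginals (realized mean/sd/range hit the configured
  calibration targets);
* a dedicated air-quality monitor co-located with each residence whose
  daily series averages exactly to the drawn window exposure, so the
  inverse-distance-weighting stage round-trips the planted values
  (residences sit on a >120 km grid, keeping each participant inside a
  single monitor's 60 km radius);
* a 450k-style beta matrix per visit containing the score CpGs (six
  published PM10 sites, synthetic PM2.5/NO2 placeholder panels),
  deconvolution reference CpGs driven by a two-cell immune/epithelial
  mixture, and bimodal background CpGs;
* planted exposure->methylation effects at the score CpGs, scaled so the
  true slope of the standardized cumulative score per reference IQR of
  exposure equals the configured value;
* detection p-values, sex-check features, per-participant covariates, and
  count-exact injectable QC faults.

Everything is driven by one integer seed; identical config + seed yields a
byte-identical cohort.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ANCHORS, POLLUTANTS, CohortConfig, QCFaultCounts, score_visit_r_targets
from .qc import BetaBundle
from .scores import load_weights

__all__ = ["SyntheticCohort", "generate_cohort", "inject_qc_faults", "write_cohort"]

VISIT_LABELS = ("age9", "age15")

# Fraction of probes driven above the detection threshold in a planted
# detection-failure sample; must exceed the 10% sample-QC rule.
_FAULT_FAIL_FRACTION = 0.12

_RACE_LEVELS = ("nh_white", "nh_black", "hispanic", "other", "multiracial")
_RACE_PROBS = (0.166, 0.563, 0.198, 0.0285, 0.0441)
_MARITAL_LEVELS = ("married", "not_married")
_P_MALE = 0.501
_P_MARRIED = 0.237
_INCOME_MEAN, _INCOME_SD = 2.27, 2.49


@dataclass
class SyntheticCohort:
    """One generated cohort plus the ground truth planted into it."""

    config: CohortConfig
    residences: pd.DataFrame  # participant_id, lat, lon, birth/age1/age3 dates
    monitors: pd.DataFrame | None  # long: monitor_id, lat, lon, date, pollutant, value
    exposures: pd.DataFrame  # long: participant_id, pollutant, anchor, value
    covariates: pd.DataFrame  # one row per participant
    beta_bundles: dict[str, BetaBundle]
    reference: pd.DataFrame  # CpG x (immune, epithelial); synthetic panel
    truth: dict

    def copy(self) -> "SyntheticCohort":
        return SyntheticCohort(
            config=self.config,
            residences=self.residences.copy(),
            monitors=None if self.monitors is None else self.monitors.copy(),
            exposures=self.exposures.copy(),
            covariates=self.covariates.copy(),
            beta_bundles={
                v: BetaBundle(b.beta.copy(), b.detp.copy(), b.samples.copy(), b.visit)
                for v, b in self.beta_bundles.items()
            },
            reference=self.reference.copy(),
            truth=copy.deepcopy(self.truth),
        )

    def exposure_wide(self) -> pd.DataFrame:
        """Exposures pivoted to one row per participant, <pollutant>_<anchor> columns."""
        wide = self.exposures.pivot_table(
            index="participant_id", columns=["pollutant", "anchor"], values="value"
        )
        wide.columns = [f"{p}_{a}" for p, a in wide.columns]
        return wide.reset_index()


# ---------------------------------------------------------------------------
# planted-effect calibration


def exposure_loading(delta: float, weights: np.ndarray, iqr_over_sd: float) -> np.ndarray:
    """Per-site correlation with standardized exposure implying score slope ``delta``.

    With site z-values z_j = rho_j * E~ + sqrt(1 - rho_j^2) * eta_j and the
    cumulative score S = sum_j w_j z_j, the standardized-score slope per
    reference IQR is

        delta = k * (sum w_j rho_j) / sd(S),   k = IQR_ref / sd(E).

    Taking rho_j = r * sign(w_j) (every site contributes in the direction of
    its weight) gives a closed-form solution for r.
    """
    w = np.asarray(weights, float)
    A = np.abs(w).sum()
    B = float(w @ w)
    D = delta / iqr_over_sd
    denom = A**2 - D**2 * (A**2 - B)
    if denom <= 0 or abs(D) >= 1:
        raise ValueError(f"planted effect {delta} too large for this weight panel")
    r = np.sign(D) * np.sqrt(D**2 * B / denom)
    if abs(r) >= 1:
        raise ValueError(f"planted effect {delta} infeasible (|rho|={abs(r):.3f} >= 1)")
    return r * np.sign(w)


def site_longitudinal_r(target_score_r: float, weights: np.ndarray, rho: np.ndarray) -> float:
    """Site-level visit-to-visit residual correlation giving a target score correlation.

    corr(S_v1, S_v2) = (C^2 + lam * (B - Q)) / (B + C^2 - Q) with
    C = sum w_j rho_j, B = sum w_j^2, Q = sum w_j^2 rho_j^2; solve for lam.
    """
    w = np.asarray(weights, float)
    rho = np.asarray(rho, float)
    C = float(w @ rho)
    B = float(w @ w)
    Q = float((w * rho) @ (w * rho))
    lam = (target_score_r * (B + C**2 - Q) - C**2) / (B - Q)
    if not -1.0 <= lam <= 1.0:
        raise ValueError(
            f"target score correlation {target_score_r} infeasible given the "
            f"planted exposure loading (implied site r {lam:.3f})"
        )
    return lam


def _resolved_longitudinal_r(config: CohortConfig, panels: dict) -> dict[str, float]:
    if config.score_site_longitudinal_r is not None:
        return dict(config.score_site_longitudinal_r)
    targets = score_visit_r_targets()
    return {
        pol: site_longitudinal_r(targets[pol], panels[pol]["weights"], panels[pol]["rho"])
        for pol in panels
    }


# ---------------------------------------------------------------------------
# generation stages


def _draw_exposures(config: CohortConfig, rng: np.random.Generator, pids: list[str]):
    """Gaussian copula draw of the six pollutant x anchor exposures."""
    n = len(pids)
    corr = config.latent_correlation()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n, corr.shape[0])) @ chol.T
    from scipy.stats import norm

    u = norm.cdf(z)
    cols = {}
    for k, (pol, anchor) in enumerate(config.exposure_variables()):
        dist = config.exposure_calibration[pol].frozen()
        cols[(pol, anchor)] = dist.ppf(u[:, k])
    records = []
    for (pol, anchor), vals in cols.items():
        records.append(
            pd.DataFrame(
                {"participant_id": pids, "pollutant": pol, "anchor": anchor, "value": vals}
            )
        )
    return pd.concat(records, ignore_index=True)


def _grid_coordinates(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Residence coordinates on a grid with >120 km pairwise separation."""
    ncols = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), ncols)
    lat = -60.0 + 1.2 * rows
    lon = -180.0 + 2.5 * cols
    if lat.max() > 64.0:
        raise ValueError(f"cohort of {n} exceeds the residence grid capacity")
    return lat, lon


def _make_residences(config: CohortConfig, rng: np.random.Generator, pids: list[str]):
    n = len(pids)
    lat, lon = _grid_coordinates(n)
    birth_offset = rng.integers(0, 731, size=n)  # births across two years
    birth = pd.Timestamp("1998-06-01") + pd.to_timedelta(birth_offset, unit="D")
    return pd.DataFrame(
        {
            "participant_id": pids,
            "lat": lat,
            "lon": lon,
            "birth": birth,
            "age1": birth + pd.Timedelta(days=365),
            "age3": birth + pd.Timedelta(days=3 * 365),
        }
    )


def _make_monitors(
    config: CohortConfig,
    rng: np.random.Generator,
    residences: pd.DataFrame,
    exposures: pd.DataFrame,
    window_days: int = 91,
) -> pd.DataFrame:
    """One co-located monitor per residence; each anchor window mean is exact."""
    wide = exposures.pivot_table(
        index="participant_id", columns=["pollutant", "anchor"], values="value"
    )
    frames = []
    day_range = np.arange(-window_days, 0)  # window ends the day before the anchor
    for _, row in residences.iterrows():
        pid = row["participant_id"]
        for anchor in ANCHORS:
            dates = row[anchor] + pd.to_timedelta(day_range, unit="D")
            for pol in POLLUTANTS:
                target = wide.loc[pid, (pol, anchor)]
                noise = rng.normal(0.0, 0.10 * target, size=window_days)
                noise -= noise.mean()
                vals = target + noise
                frames.append(
                    pd.DataFrame(
                        {
                            "monitor_id": f"M_{pid}",
                            "lat": row["lat"],
                            "lon": row["lon"],
                            "date": dates,
                            "pollutant": pol,
                            "value": vals,
                        }
                    )
                )
    monitors = pd.concat(frames, ignore_index=True)
    if (monitors["value"] < 0).any():  # pragma: no cover - ~10 sigma event
        monitors["value"] = monitors["value"].clip(lower=0.0)
    return monitors


def _make_covariates(config: CohortConfig, rng: np.random.Generator, pids: list[str]):
    n = len(pids)
    sex = np.where(rng.random(n) < _P_MALE, "male", "female")
    race = rng.choice(_RACE_LEVELS, size=n, p=np.array(_RACE_PROBS) / sum(_RACE_PROBS))
    sigma2 = np.log1p((_INCOME_SD / _INCOME_MEAN) ** 2)
    income = rng.lognormal(np.log(_INCOME_MEAN) - sigma2 / 2, np.sqrt(sigma2), size=n)
    marital = np.where(rng.random(n) < _P_MARRIED, "married", "not_married")
    return pd.DataFrame(
        {
            "participant_id": pids,
            "child_sex": sex,
            "race_ethnicity": race,
            "income_to_needs": income,
            "marital_status": marital,
        }
    )


def _make_reference(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic two-cell reference panel (not the published saliva panel)."""
    m = config.n_reference_cpgs
    ids = [f"ref{i:05d}" for i in range(m)]
    immune = np.empty(m)
    epithelial = np.empty(m)
    half = m // 2
    immune[:half] = rng.uniform(0.60, 0.95, half)
    epithelial[:half] = rng.uniform(0.05, 0.40, half)
    immune[half:] = rng.uniform(0.05, 0.40, m - half)
    epithelial[half:] = rng.uniform(0.60, 0.95, m - half)
    return pd.DataFrame({"immune": immune, "epithelial": epithelial}, index=pd.Index(ids, name="cpg_id"))


def _score_panels(config: CohortConfig) -> dict:
    """Weight tables + implied per-site exposure loadings, per pollutant score."""
    panels = {}
    for pol in ("pm25", "pm10", "no2"):
        table = load_weights(pol)
        w = table["weight"].to_numpy()
        delta = config.planted_effects.get(pol, 0.0)
        # The NO2 panel is a specificity control; a nonzero planted NO2
        # effect is expressed against prenatal PM10 exposure.
        driver = pol if pol in POLLUTANTS else "pm10"
        cal = config.exposure_calibration[driver]
        k = cal.reference_iqr / cal.sd
        rho = exposure_loading(delta, w, k) if delta != 0 else np.zeros(len(w))
        panels[pol] = {"cpgs": table["cpg_id"].tolist(), "weights": w, "rho": rho, "driver": driver}
    return panels


def _sample_ids(pids, visit: str) -> list[str]:
    return [f"{p}_{visit}" for p in pids]


def _make_betas(
    config: CohortConfig,
    rng: np.random.Generator,
    pids_by_visit: dict[str, list[str]],
    exposures: pd.DataFrame,
    reference: pd.DataFrame,
    panels: dict,
    lam: dict[str, float],
    cellprops: dict[str, pd.Series],
):
    """Beta + detection-p matrices for both visits, with planted effects."""
    all_pids = sorted(set().union(*pids_by_visit.values()))
    pid_pos = {p: i for i, p in enumerate(all_pids)}
    wide = exposures.pivot_table(index="participant_id", columns=["pollutant", "anchor"], values="value")

    # standardized prenatal exposure per pollutant, over all participants
    e_std = {}
    for pol in POLLUTANTS:
        e = wide.loc[all_pids, (pol, "birth")].to_numpy()
        e_std[pol] = (e - e.mean()) / e.std(ddof=0)

    bg_ids = [f"bg{i:05d}" for i in range(config.n_background_cpgs)]
    score_ids = [c for pol in panels for c in panels[pol]["cpgs"]]
    cpg_index = pd.Index(score_ids + list(reference.index) + bg_ids, name="cpg_id")

    # per-site baselines/scales for score CpGs (affine scale is irrelevant to
    # the standardized score; kept mid-range so betas stay inside [0, 1])
    baselines = {}
    for pol in panels:
        k = len(panels[pol]["cpgs"])
        baselines[pol] = (rng.uniform(0.30, 0.70, k), np.full(k, 0.05))

    # background site modes: bimodal on the logit scale
    low = rng.random(config.n_background_cpgs) < 0.5
    bg_logit = np.where(
        low,
        rng.normal(logit(0.10), 0.5, config.n_background_cpgs),
        rng.normal(logit(0.90), 0.5, config.n_background_cpgs),
    )

    # shared (cross-visit) site residual per participant, for score CpGs
    shared = {
        pol: rng.standard_normal((len(all_pids), len(panels[pol]["cpgs"]))) for pol in panels
    }

    bundles = {}
    for visit, pids in pids_by_visit.items():
        sids = _sample_ids(pids, visit)
        rows = [pid_pos[p] for p in pids]
        blocks = []
        for pol in panels:
            rho = panels[pol]["rho"]
            lam_p = lam[pol]
            b0, s0 = baselines[pol]
            e = e_std[panels[pol]["driver"]][rows]
            unique = rng.standard_normal((len(pids), len(rho)))
            resid = np.sqrt(max(lam_p, 0.0)) * shared[pol][rows] + np.sqrt(1 - max(lam_p, 0.0)) * unique
            z = rho[None, :] * e[:, None] + np.sqrt(1 - rho**2)[None, :] * resid
            blocks.append(b0[None, :] + s0[None, :] * z)
        score_block = np.concatenate(blocks, axis=1)  # samples x score sites

        p_imm = cellprops[visit].loc[sids].to_numpy()
        ref_block = (
            p_imm[:, None] * reference["immune"].to_numpy()[None, :]
            + (1 - p_imm)[:, None] * reference["epithelial"].to_numpy()[None, :]
            + rng.normal(0.0, config.reference_noise_sd, (len(pids), len(reference)))
        )

        bg_block = expit(
            bg_logit[None, :] + rng.normal(0.0, config.background_noise_sd, (len(pids), len(bg_ids)))
        )

        beta = np.clip(np.concatenate([score_block, ref_block, bg_block], axis=1), 1e-4, 1 - 1e-4)
        detp = rng.uniform(0.0, 0.005, beta.shape)
        beta_df = pd.DataFrame(beta.T, index=cpg_index, columns=sids)
        detp_df = pd.DataFrame(detp.T, index=cpg_index, columns=sids)
        bundles[visit] = (beta_df, detp_df)
    return bundles, cpg_index


def _make_sample_metadata(
    config: CohortConfig,
    rng: np.random.Generator,
    pids_by_visit: dict[str, list[str]],
    covariates: pd.DataFrame,
):
    sex_by_pid = covariates.set_index("participant_id")["child_sex"]
    meta = {}
    for spec in config.visits:
        pids = pids_by_visit[spec.label]
        sids = _sample_ids(pids, spec.label)
        age = rng.normal(spec.age_mean, spec.age_sd, len(pids))
        recorded = sex_by_pid.loc[pids].to_numpy()
        meta[spec.label] = pd.DataFrame(
            {
                "sample_id": sids,
                "participant_id": pids,
                "visit": spec.label,
                "age_at_measure": age,
                "recorded_sex": recorded,
                "predicted_sex": recorded.copy(),
                "sexchrom_intensity": rng.normal(0.0, 0.5, len(pids)),
            }
        )
    return meta


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one synthetic cohort from ``config`` (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i:05d}" for i in range(n)]
    both = pids[: config.n_both]
    only9 = pids[config.n_both : config.n_both + config.n_age9_only]
    only15 = pids[config.n_both + config.n_age9_only :]
    pids_by_visit = {"age9": both + only9, "age15": both + only15}

    exposures = _draw_exposures(config, rng, pids)
    residences = _make_residences(config, rng, pids)
    covariates = _make_covariates(config, rng, pids)
    reference = _make_reference(config, rng)
    panels = _score_panels(config)
    lam = _resolved_longitudinal_r(config, panels)

    # true cell proportions per observation
    m, s = config.immune_mean, config.immune_sd
    nu = m * (1 - m) / s**2 - 1
    if nu <= 0:
        raise ValueError("immune mean/sd imply an invalid Beta distribution")
    cellprops = {}
    for visit, vpids in pids_by_visit.items():
        p = rng.beta(m * nu, (1 - m) * nu, len(vpids))
        cellprops[visit] = pd.Series(p, index=_sample_ids(vpids, visit), name="immune")

    bundles_raw, cpg_index = _make_betas(
        config, rng, pids_by_visit, exposures, reference, panels, lam, cellprops
    )
    meta = _make_sample_metadata(config, rng, pids_by_visit, covariates)
    beta_bundles = {
        visit: BetaBundle(beta, detp, meta[visit], visit)
        for visit, (beta, detp) in bundles_raw.items()
    }

    monitors = (
        _make_monitors(config, rng, residences, exposures) if config.include_monitors else None
    )

    truth = {
        "seed": config.seed,
        "planted_effects": dict(config.planted_effects),
        "site_loadings": {
            pol: {c: float(r) for c, r in zip(panels[pol]["cpgs"], panels[pol]["rho"])}
            for pol in panels
        },
        "site_longitudinal_r": {k: float(v) for k, v in lam.items()},
        "score_sites": {pol: panels[pol]["cpgs"] for pol in panels},
        "cell_proportions_immune": {
            visit: {sid: float(v) for sid, v in series.items()}
            for visit, series in cellprops.items()
        },
        "qc_faults": {"detection": [], "sex_discordant": [], "abnormal_intensity": []},
    }

    cohort = SyntheticCohort(
        config=config,
        residences=residences,
        monitors=monitors,
        exposures=exposures,
        covariates=covariates,
        beta_bundles=beta_bundles,
        reference=reference,
        truth=truth,
    )
    if config.qc_fault_counts.total() > 0:
        cohort = inject_qc_faults(cohort, config.qc_fault_counts)
    return cohort


# ---------------------------------------------------------------------------
# QC fault injection


def inject_qc_faults(cohort: SyntheticCohort, counts: QCFaultCounts) -> SyntheticCohort:
    """Plant count-exact QC faults into disjoint samples; returns a new cohort.

    * detection: a 12% fraction of that sample's probes get detection
      p-values in U(0.02, 1) (over the >10% sample-drop rule);
    * sex_discordant: the predicted-sex feature is flipped;
    * abnormal_intensity: the sex-chromosome intensity is pushed outside
      the normal band.

    Samples are chosen without replacement across both visits; truth labels
    record exactly which samples carry which fault.
    """
    if isinstance(counts, tuple):
        counts = QCFaultCounts(*counts)
    out = cohort.copy()
    all_samples = [
        (visit, sid) for visit in sorted(out.beta_bundles) for sid in out.beta_bundles[visit].beta.columns
    ]
    total = counts.total()
    if total > len(all_samples):
        raise ValueError(
            f"fault counts total {total} exceeds {len(all_samples)} observations"
        )
    rng = np.random.default_rng([int(out.config.seed) % (2**31), 104729])
    chosen = rng.choice(len(all_samples), size=total, replace=False)
    groups = {
        "detection": chosen[: counts.detection],
        "sex_discordant": chosen[counts.detection : counts.detection + counts.sex_discordant],
        "abnormal_intensity": chosen[counts.detection + counts.sex_discordant :],
    }
    flip = {"male": "female", "female": "male"}
    for kind, idxs in groups.items():
        for i in idxs:
            visit, sid = all_samples[int(i)]
            bundle = out.beta_bundles[visit]
            if kind == "detection":
                n_probes = bundle.n_probes
                n_fail = int(np.ceil(_FAULT_FAIL_FRACTION * n_probes))
                fail_rows = rng.choice(n_probes, size=n_fail, replace=False)
                col = bundle.detp[sid].to_numpy()
                col[fail_rows] = rng.uniform(0.02, 1.0, n_fail)
                bundle.detp[sid] = col
            elif kind == "sex_discordant":
                mask = bundle.samples["sample_id"] == sid
                bundle.samples.loc[mask, "predicted_sex"] = bundle.samples.loc[
                    mask, "recorded_sex"
                ].map(flip)
            else:
                mask = bundle.samples["sample_id"] == sid
                bundle.samples.loc[mask, "sexchrom_intensity"] = 3.0 + rng.random()
            out.truth["qc_faults"][kind].append(sid)
    return out


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort as plain-text tables; returns {name: path}."""
    from pathlib import Path

    from .config import save_config

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(name, df, **kw):
        p = outdir / name
        df.to_csv(p, index=kw.pop("index", False), **kw)
        paths[name] = str(p)

    res = cohort.residences.copy()
    for c in ("birth", "age1", "age3"):
        res[c] = res[c].dt.strftime("%Y-%m-%d")
    _csv("residences.csv", res)
    if cohort.monitors is not None:
        mon = cohort.monitors.copy()
        mon["date"] = mon["date"].dt.strftime("%Y-%m-%d")
        _csv("monitors.csv", mon)
    _csv("exposures_true.csv", cohort.exposures)
    _csv("covariates.csv", cohort.covariates)
    _csv("reference_synthetic.csv", cohort.reference, index=True)
    for visit, bundle in cohort.beta_bundles.items():
        tag = visit.removeprefix("age")
        _csv(f"betas_visit{tag}.tsv", bundle.beta, index=True, sep="\t")
        _csv(f"detp_visit{tag}.tsv", bundle.detp, index=True, sep="\t")
        _csv(f"samples_visit{tag}.csv", bundle.samples)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    paths["truth.json"] = str(outdir / "truth.json")
    save_config(cohort.config, outdir / "config.yaml")
    paths["config.yaml"] = str(outdir / "config.yaml")
    return paths
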