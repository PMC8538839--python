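"""End-to-end pipeline: simulate -> exposure -> qc -> score -> associate -> report.

One YAML config drives all stages; each stage also remains callable on its
own through the per-stage CLI.  The run directory receives every
intermediate table as CSV/TSV, a markdown report with the headline result
tables and QC flow counts, and a manifest (config hash, seed, file
checksums) for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CohortConfig, default_config
from .exposure import assign_exposures
from .models import ModelResult, bivariate_tests, fit_mixed_model, fit_visit_model, sensitivity_suite
from .qc import BetaBundle, estimate_cell_proportions, filter_probes, filter_samples, read_blocklist
from .scores import cumulative_score, load_weights
from .synthetic import SyntheticCohort, generate_cohort, write_cohort

__all__ = ["run_pipeline", "analysis_frame", "PipelineResult", "STAGES"]

STAGES = ("simulate", "exposure", "qc", "score", "associate", "report")

PM10_CANDIDATE_CPGS = (
    "cg00905156",
    "cg06849931",
    "cg15082635",
    "cg18640183",
    "cg20340716",
    "cg24127244",
)


@dataclasses.dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    results: pd.DataFrame | None
    report_path: Path | None


def _merge_bundles(bundles: dict[str, BetaBundle]) -> tuple[pd.DataFrame, pd.Series]:
    """Pooled beta matrix across visits + sample -> visit mapping."""
    beta = pd.concat([bundles[v].beta for v in sorted(bundles)], axis=1)
    visits = pd.concat(
        [
            pd.Series(v, index=bundles[v].beta.columns)
            for v in sorted(bundles)
        ]
    )
    return beta, visits


def analysis_frame(
    bundles: dict[str, BetaBundle],
    exposures_wide: pd.DataFrame,
    covariates: pd.DataFrame,
    cellprops: pd.DataFrame,
    *,
    variant: str = "zscored",
    standardize_pop: str = "pooled",
    pollutants=("pm25", "pm10", "no2"),
    cpg_percent: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One row per observation: scores, exposures, covariates, cell props.

    ``exposures_wide`` has participant_id plus ``<pollutant>_<anchor>``
    columns; ``cellprops`` has sample_id/immune columns.  Score columns are
    named ``score_<pollutant>``; ``cpg_percent`` CpGs are added as
    percent-methylation columns.
    """
    beta, visits = _merge_bundles(bundles)
    frame = pd.concat([bundles[v].samples for v in sorted(bundles)], ignore_index=True)
    for pol in pollutants:
        sc = cumulative_score(
            beta, load_weights(pol), variant, visits=visits,
            standardize_pop=standardize_pop, pollutant=pol,
        )
        frame = frame.merge(
            sc[["sample_id", "score_standardized"]].rename(
                columns={"score_standardized": f"score_{pol}"}
            ),
            on="sample_id",
        )
    for cpg in cpg_percent:
        if cpg in beta.index:
            frame[cpg] = (100.0 * beta.loc[cpg]).reindex(frame["sample_id"]).to_numpy()
    frame = frame.merge(cellprops[["sample_id", "immune"]], on="sample_id", how="left")
    frame = frame.merge(exposures_wide, on="participant_id", how="left")
    frame = frame.merge(covariates, on="participant_id", how="left")
    return frame


def _results_table(rows: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir=None) -> PipelineResult:
    """Execute the enabled stage prefix of the pipeline DAG.

    ``config`` keys: seed, out_dir, stages (prefix of STAGES), cohort
    (CohortConfig overrides), exposure (radius_km/window_days/min_coverage/
    anchors/use_idw), qc (enabled/blocklist), score (variants,
    standardize_pop), associate (iqr_mode subsample|reference, sensitivity
    list, bivariate flag).
    """
    cfg = dict(config)
    out_dir = Path(out_dir or cfg.get("out_dir", "airmeth_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = tuple(cfg.get("stages", STAGES))
    if stages != STAGES[: len(stages)]:
        raise ValueError(f"stages must be a prefix of {STAGES}, got {stages}")
    seed = int(cfg.get("seed", 0))
    log_path = out_dir / "pipeline_log.jsonl"
    log_fh = open(log_path, "w")
    flow: list[dict] = []

    def log(stage, level="info", **kw):
        log_fh.write(json.dumps({"stage": stage, "level": level, **kw}) + "\n")

    written: list[Path] = []
    results_df = None
    report_path = None
    try:
        # ---- simulate -----------------------------------------------------
        cohort_overrides = dict(cfg.get("cohort", {}))
        cohort_cfg = (
            CohortConfig.from_dict({**default_config(seed=seed).to_dict(), **cohort_overrides, "seed": seed})
            if cohort_overrides
            else default_config(seed=seed)
        )
        cohort = generate_cohort(cohort_cfg)
        paths = write_cohort(cohort, out_dir / "cohort")
        written += [Path(p) for p in paths.values()]
        n_obs0 = cohort_cfg.n_observations
        log("simulate", n_participants=cohort_cfg.n_participants, n_obs=n_obs0)
        flow.append({"stage": "simulate", "n_obs_out": n_obs0, "n_dropped": 0})
        if stages[-1] == "simulate":
            raise _Done()

        # ---- exposure -----------------------------------------------------
        exp_cfg = dict(cfg.get("exposure", {}))
        use_idw = bool(exp_cfg.pop("use_idw", True)) and cohort.monitors is not None
        if use_idw:
            anchors = tuple(exp_cfg.pop("anchors", ("birth", "age1", "age3")))
            est = assign_exposures(cohort.monitors, cohort.residences, anchors=anchors, **exp_cfg)
            exposures = est[["participant_id", "pollutant", "anchor", "value"]].dropna()
            n_missing = int(est["value"].isna().sum())
            log("exposure", method="idw", n_estimates=len(est), n_missing=n_missing)
            est_path = out_dir / "exposures.csv"
            est.to_csv(est_path, index=False)
        else:
            exposures = cohort.exposures
            log("exposure", method="generator", note="monitor data unavailable; using drawn exposures")
            est_path = out_dir / "exposures.csv"
            exposures.to_csv(est_path, index=False)
        written.append(est_path)
        exposures_wide = exposures.pivot_table(
            index="participant_id", columns=["pollutant", "anchor"], values="value"
        )
        exposures_wide.columns = [f"{p}_{a}" for p, a in exposures_wide.columns]
        exposures_wide = exposures_wide.reset_index()
        if stages[-1] == "exposure":
            raise _Done()

        # ---- qc -----------------------------------------------------------
        qc_cfg = dict(cfg.get("qc", {}))
        qc_enabled = bool(qc_cfg.get("enabled", True))
        bundles = dict(cohort.beta_bundles)
        qc_log: dict = {"enabled": qc_enabled}
        if qc_enabled:
            sample_logs = []
            kept = {}
            for visit, bundle in bundles.items():
                kb, slog = filter_samples(bundle)
                kept[visit] = kb
                slog["visit"] = visit
                sample_logs.append(slog)
            sample_log = pd.concat(sample_logs, ignore_index=True)
            # probe filter on the pooled post-sample-QC detection matrix so
            # both visits share one probe set
            pooled = BetaBundle(
                pd.concat([kept[v].beta for v in sorted(kept)], axis=1),
                pd.concat([kept[v].detp for v in sorted(kept)], axis=1),
                pd.concat([kept[v].samples for v in sorted(kept)], ignore_index=True),
                "pooled",
            )
            blocklist = qc_cfg.get("blocklist")
            block = read_blocklist(blocklist) if blocklist else []
            pooled_kept, probe_log = filter_probes(pooled, block)
            bundles = {
                v: kept[v].subset_probes(pooled_kept.beta.index) for v in sorted(kept)
            }
            n_after = sum(b.n_samples for b in bundles.values())
            qc_log.update(
                samples_dropped=sample_log["rule"].value_counts().to_dict(),
                probes_dropped=probe_log["rule"].value_counts().to_dict(),
                n_obs_after=n_after,
            )
            sample_log.to_csv(out_dir / "qc_sample_drops.csv", index=False)
            probe_log.to_csv(out_dir / "qc_probe_drops.csv", index=False)
            written += [out_dir / "qc_sample_drops.csv", out_dir / "qc_probe_drops.csv"]
            flow.append(
                {"stage": "qc", "n_obs_out": n_after, "n_dropped": n_obs0 - n_after}
            )
            pooled_after = BetaBundle(
                pd.concat([bundles[v].beta for v in sorted(bundles)], axis=1),
                pd.concat([bundles[v].detp for v in sorted(bundles)], axis=1),
                pd.concat([bundles[v].samples for v in sorted(bundles)], ignore_index=True),
                "pooled",
            )
            cellprops = estimate_cell_proportions(pooled_after, cohort.reference)
        else:
            flow.append({"stage": "qc", "n_obs_out": n_obs0, "n_dropped": 0, "skipped": True})
            truth_imm = {
                sid: v
                for visit in cohort.truth["cell_proportions_immune"]
                for sid, v in cohort.truth["cell_proportions_immune"][visit].items()
            }
            cellprops = pd.DataFrame(
                {"sample_id": list(truth_imm), "immune": list(truth_imm.values())}
            )
            cellprops["epithelial"] = 1 - cellprops["immune"]
        log("qc", **{k: v for k, v in qc_log.items()})
        cellprops.to_csv(out_dir / "cellprops.csv", index=False)
        written.append(out_dir / "cellprops.csv")
        with open(out_dir / "qc_log.json", "w") as fh:
            json.dump(qc_log, fh, indent=1)
        written.append(out_dir / "qc_log.json")
        if stages[-1] == "qc":
            raise _Done()

        # ---- score --------------------------------------------------------
        score_cfg = dict(cfg.get("score", {}))
        variants = tuple(score_cfg.get("variants", ("zscored", "raw", "centered")))
        standardize_pop = score_cfg.get("standardize_pop", "pooled")
        beta, visits = _merge_bundles(bundles)
        score_rows = []
        for pol in ("pm25", "pm10", "no2"):
            for var in variants:
                score_rows.append(
                    cumulative_score(
                        beta, load_weights(pol), var, visits=visits,
                        standardize_pop=standardize_pop, pollutant=pol,
                    )
                )
        scores_df = pd.concat(score_rows, ignore_index=True)
        scores_df.to_csv(out_dir / "scores.csv", index=False)
        written.append(out_dir / "scores.csv")
        log("score", n_rows=len(scores_df), variants=list(variants))
        flow.append({"stage": "score", "n_obs_out": int(visits.size), "n_dropped": 0})
        if stages[-1] == "score":
            raise _Done()

        # ---- associate ----------------------------------------------------
        assoc_cfg = dict(cfg.get("associate", {}))
        iqr_mode = assoc_cfg.get("iqr_mode", "subsample")
        iqr_map = (
            {p: cohort_cfg.exposure_calibration[p].reference_iqr for p in ("pm25", "pm10")}
            if iqr_mode == "reference"
            else {}
        )
        iqr_map.setdefault("no2", None)
        all_rows: list[ModelResult] = []
        frames = {}
        for var in variants:
            frame = analysis_frame(
                bundles, exposures_wide, cohort.covariates, cellprops,
                variant=var, standardize_pop=standardize_pop,
                cpg_percent=PM10_CANDIDATE_CPGS,
            )
            frames[var] = frame
            for pol in ("pm25", "pm10"):
                kw = dict(
                    outcome=f"score_{pol}",
                    exposure_col=f"{pol}_birth",
                    exposure_name=pol,
                    variant=var,
                    iqr=iqr_map.get(pol),
                )
                for visit in sorted(frame["visit"].unique()):
                    all_rows.append(
                        fit_visit_model(frame[frame["visit"] == visit], stratum=visit, **kw)
                    )
                all_rows.append(fit_mixed_model(frame, **kw))
        results_df = _results_table(all_rows)
        results_df.to_csv(out_dir / "results.csv", index=False)
        written.append(out_dir / "results.csv")

        primary = frames[variants[0]]
        if assoc_cfg.get("bivariate", True):
            biv_rows = []
            for pol in ("pm25", "pm10"):
                sub = primary.dropna(subset=[f"{pol}_birth"])
                biv = bivariate_tests(
                    sub[f"{pol}_birth"],
                    sub[["child_sex", "race_ethnicity", "marital_status", "income_to_needs", f"score_{pol}"]],
                    seed=seed,
                )
                biv["exposure"] = pol
                biv_rows.append(biv)
            pd.concat(biv_rows, ignore_index=True).to_csv(out_dir / "bivariate.csv", index=False)
            written.append(out_dir / "bivariate.csv")

        sens_list = tuple(assoc_cfg.get("sensitivity", ("copollutant", "age1", "age3", "no2", "cpg")))
        sens = sensitivity_suite(
            primary, analyses=sens_list, iqr={k: v for k, v in iqr_map.items() if v},
            cpg_columns=PM10_CANDIDATE_CPGS,
        )
        sens_df = _results_table(sens.results)
        sens_df.to_csv(out_dir / "sensitivity.csv", index=False)
        written.append(out_dir / "sensitivity.csv")
        table3 = sens_df[sens_df["variant"] == "single_cpg_percent"]
        table3.to_csv(out_dir / "table3.csv", index=False)
        written.append(out_dir / "table3.csv")
        for item in sens.skipped:
            log("associate", level="warning", skipped=item)
        log("associate", n_models=len(results_df) + len(sens_df))
        if stages[-1] == "associate":
            raise _Done()

        # ---- report -------------------------------------------------------
        report_path = out_dir / "report.md"
        _write_report(report_path, cohort_cfg, flow, results_df, table3, qc_enabled)
        written.append(report_path)
        log("report", path=str(report_path))
    except _Done:
        pass
    finally:
        log_fh.close()

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "stages": list(stages),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in written if p.exists()},
        "flow": flow,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return PipelineResult(out_dir, manifest, results_df, report_path)


class _Done(Exception):
    """Internal: stop after the last enabled stage."""


def _write_report(path, cohort_cfg, flow, results_df, table3, qc_enabled):
    lines = ["# airmeth pipeline report", ""]
    lines.append(f"Cohort: {cohort_cfg.n_participants} participants, "
                 f"{cohort_cfg.n_observations} observations, seed {cohort_cfg.seed}.")
    if not qc_enabled:
        lines.append("")
        lines.append("**QC skipped**: scores were computed on unfiltered betas.")
    lines += ["", "## Sample flow", "", "| stage | n_obs out | dropped |", "|---|---|---|"]
    for f in flow:
        tag = " (skipped)" if f.get("skipped") else ""
        lines.append(f"| {f['stage']}{tag} | {f['n_obs_out']} | {f['n_dropped']} |")
    if results_df is not None and len(results_df):
        lines += ["", "## Score-exposure associations (per IQR of exposure)", ""]
        lines.append("| exposure | stratum | variant | effect | 95% CI | p | n_indiv | n_obs |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for _, r in results_df.iterrows():
            lines.append(
                f"| {r['exposure']} | {r['stratum']} | {r['variant']} | {r['effect']:.4f} | "
                f"({r['ci_low']:.4f}, {r['ci_high']:.4f}) | {r['p_value']:.3g} | "
                f"{r['n_indiv']} | {r['n_obs']} |"
            )
    if table3 is not None and len(table3):
        lines += ["", "## Single-CpG models (percent methylation per IQR of PM10)", ""]
        lines.append("| CpG | effect | 95% CI | p | n_obs |")
        lines.append("|---|---|---|---|---|")
        for _, r in table3.iterrows():
            lines.append(
                f"| {r['outcome']} | {r['effect']:.3f} | ({r['ci_low']:.3f}, {r['ci_high']:.3f}) "
                f"| {r['p_value']:.3g} | {r['n_obs']} |"
            )
    Path(path).write_text("\n".join(lines) + "\n")
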