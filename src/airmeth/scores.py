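"""Cumulative DNA-methylation scores (methylation risk scores).

A cumulative score aggregates methylation at a small panel of
exposure-associated CpGs into one number per sample: each site's beta value
is optionally transformed (z-scored or mean-centered over the
standardization population), weighted by an externally estimated effect
size (here, cord-blood meta-analysis coefficients), and summed; the sums
are then z-score-standardized within the analytic sample so effects read in
SD units.  The construction is the methylation analogue of a polygenic
score.

Three variants are supported:

* ``zscored``  - per-site z-score before weighting (primary definition);
* ``raw``      - untransformed betas;
* ``centered`` - per-site mean-centering.

After the final standardization, ``raw`` and ``centered`` are provably
identical: centering shifts every sample's weighted sum by the same
constant, which standardization removes.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "VARIANTS",
    "load_weights",
    "cumulative_score",
    "score_visit_correlation",
]

VARIANTS = ("zscored", "raw", "centered")

_PACKAGED = {
    "pm10": "weights_pm10.csv",
    "pm25": "weights_pm25_synthetic.csv",
    "no2": "weights_no2_synthetic.csv",
}


def load_weights(source: str) -> pd.DataFrame:
    """Load a CpG weight table.

    ``source`` is either a pollutant key (``pm10``/``pm25``/``no2``) for the
    packaged tables, or a path to a CSV with columns cpg_id, weight[, gene].
    The PM10 table carries the six published cord-blood effect estimates;
    the PM2.5 and NO2 tables are synthetic placeholders (the corresponding
    published site lists are not reproduced here) and are shipped so every
    pipeline stage can run end to end.
    """
    if source in _PACKAGED:
        ref = resources.files("airmeth.data") / _PACKAGED[source]
        with resources.as_file(ref) as path:
            table = pd.read_csv(path)
    else:
        table = pd.read_csv(source)
    required = {"cpg_id", "weight"}
    if not required.issubset(table.columns):
        raise ValueError(f"weight table must have columns {sorted(required)}")
    if table["cpg_id"].duplicated().any():
        dups = table.loc[table["cpg_id"].duplicated(), "cpg_id"].tolist()
        raise ValueError(f"duplicate cpg_ids in weight table: {dups}")
    w = table["weight"].to_numpy(float)
    if not np.all(np.isfinite(w)) or np.any(w == 0):
        raise ValueError("weights must be finite and nonzero")
    if "gene" not in table.columns:
        table["gene"] = ""
    return table[["cpg_id", "weight", "gene"]]


def _site_stats(block: pd.DataFrame, visits: pd.Series | None, pop: str):
    """Per-site mean/sd over the standardization population.

    Returns (mean, sd) DataFrames aligned to block (sites x samples).
    """
    if pop == "pooled" or visits is None:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        return (
            pd.DataFrame(np.tile(mu.to_numpy()[:, None], (1, block.shape[1])), index=block.index, columns=block.columns),
            pd.DataFrame(np.tile(sd.to_numpy()[:, None], (1, block.shape[1])), index=block.index, columns=block.columns),
        )
    mu = pd.DataFrame(index=block.index, columns=block.columns, dtype=float)
    sd = pd.DataFrame(index=block.index, columns=block.columns, dtype=float)
    for visit, cols in visits.groupby(visits).groups.items():
        sub = block[cols]
        mu.loc[:, cols] = np.tile(sub.mean(axis=1).to_numpy()[:, None], (1, len(cols)))
        sd.loc[:, cols] = np.tile(sub.std(axis=1, ddof=0).to_numpy()[:, None], (1, len(cols)))
    return mu, sd


def cumulative_score(
    beta: pd.DataFrame,
    weights: pd.DataFrame,
    variant: str = "zscored",
    *,
    visits: pd.Series | None = None,
    standardize_pop: str = "pooled",
    pollutant: str | None = None,
) -> pd.DataFrame:
    """Compute per-sample cumulative methylation scores.

    Parameters
    ----------
    beta
        CpG x sample matrix of beta values in [0, 1].
    weights
        Weight table (``load_weights`` output or equivalent).
    variant
        One of ``zscored``, ``raw``, ``centered``.
    visits
        Optional sample -> visit label mapping (index = sample ids); carried
        to the output and used when ``standardize_pop='visit'``.
    standardize_pop
        ``'pooled'`` (default): site statistics and the final score
        standardization use all samples pooled across visits.
        ``'visit'``: both are computed within visit.

    Returns
    -------
    DataFrame with one row per sample: sample_id, visit, pollutant, variant,
    score_raw_sum, score_standardized, n_sites_used.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if standardize_pop not in ("pooled", "visit"):
        raise ValueError("standardize_pop must be 'pooled' or 'visit'")
    if standardize_pop == "visit" and visits is None:
        raise ValueError("standardize_pop='visit' requires a visits mapping")
    if visits is not None:
        visits = visits.reindex(beta.columns)

    present = weights["cpg_id"].isin(beta.index)
    if not present.any():
        raise ValueError("no weight-table CpGs are present in the beta matrix")
    missing = weights.loc[~present, "cpg_id"].tolist()
    if missing:
        warnings.warn(
            f"{len(missing)} weight-table CpGs absent from beta matrix and dropped: {missing}",
            stacklevel=2,
        )
    used = weights.loc[present]
    block = beta.loc[used["cpg_id"]]

    if variant == "zscored":
        mu, sd = _site_stats(block, visits, standardize_pop)
        # betas are O(1), so an sd at float-epsilon scale is a constant site
        degenerate = (sd.min(axis=1) <= 1e-12) | (sd.isna().any(axis=1))
        if degenerate.any():
            dropped = block.index[degenerate].tolist()
            warnings.warn(
                f"{len(dropped)} zero-variance sites dropped under 'zscored': {dropped}",
                stacklevel=2,
            )
            keep = ~degenerate
            block, mu, sd = block.loc[keep], mu.loc[keep.to_numpy()], sd.loc[keep.to_numpy()]
            used = used[used["cpg_id"].isin(block.index)]
            if block.empty:
                raise ValueError("all sites degenerate (zero variance) under 'zscored'")
        transformed = (block - mu) / sd
    elif variant == "centered":
        mu, _ = _site_stats(block, visits, standardize_pop)
        transformed = block - mu
    else:
        transformed = block

    w = used.set_index("cpg_id")["weight"].reindex(transformed.index)
    raw_sum = transformed.mul(w, axis=0).sum(axis=0)

    out = pd.DataFrame(
        {
            "sample_id": beta.columns,
            "visit": visits.to_numpy() if visits is not None else "",
            "pollutant": pollutant or "",
            "variant": variant,
            "score_raw_sum": raw_sum.to_numpy(),
            "n_sites_used": len(transformed.index),
        }
    )

    def _standardize(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=0)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError("cumulative score has zero variance; cannot standardize")
        return (x - x.mean()) / sd

    if standardize_pop == "visit":
        out["score_standardized"] = (
            out.groupby("visit", group_keys=False)["score_raw_sum"].apply(_standardize)
        )
    else:
        out["score_standardized"] = _standardize(out["score_raw_sum"])
    return out


def score_visit_correlation(scores_v1: pd.Series, scores_v2: pd.Series) -> float:
    """Pearson correlation of scores across visits, over paired participants.

    Inputs are participant-indexed score series (one per visit); only
    participants present in both are used, and at least 3 pairs are required.
    """
    paired = pd.concat({"v1": scores_v1, "v2": scores_v2}, axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(f"need >= 3 paired participants, got {len(paired)}")
    return float(np.corrcoef(paired["v1"], paired["v2"])[0, 1])
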