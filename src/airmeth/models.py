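"""Exposure-methylation association models with IQR-scaled reporting.

The modelling surface mirrors a repeated-measures epigenetic study:

* bivariate median-split tests (Welch t for continuous covariates,
  Fisher's exact for categorical ones, Monte-Carlo Freeman-Halton for
  tables larger than 2x2);
* per-visit multivariable OLS of the standardized cumulative score on
  exposure plus the adjustment set (child sex, age at measure, maternal
  income-to-needs ratio, marital status, race/ethnicity, immune cell
  proportion);
* random-intercept linear mixed models (REML) pooling both visits;
* a sensitivity suite: co-pollutant adjustment, postnatal-exposure
  adjustment, an NO2-score specificity check, and single-CpG models in
  percent-methylation units.

Effects are reported per interquartile range of exposure: the per-unit
coefficient times either the analytic subsample's IQR (default) or a fixed
reference IQR supplied by the caller.  With exactly two cell types the
estimated proportions sum to one, so only the immune proportion enters the
adjustment set (adding epithelial would be rank-deficient).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "ADJUSTMENT_COLUMNS",
    "bivariate_tests",
    "fit_visit_model",
    "fit_mixed_model",
    "sensitivity_suite",
]

ADJUSTMENT_COLUMNS = (
    "child_sex",
    "age_at_measure",
    "income_to_needs",
    "marital_status",
    "race_ethnicity",
    "immune",
)


@dataclass(frozen=True)
class ModelResult:
    """One fitted model row: IQR-scaled effect with its uncertainty."""

    exposure: str
    stratum: str  # "age9" | "age15" | "all"
    variant: str
    effect: float  # SD of score (or percent methylation) per IQR of exposure
    ci_low: float
    ci_high: float
    p_value: float
    n_indiv: int
    n_obs: int
    iqr_used: float
    model: str = "ols"  # "ols" | "mixed"
    outcome: str = "score"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.effect <= self.ci_high):
            raise ValueError("CI must bracket the effect estimate")
        if self.n_obs < self.n_indiv:
            raise ValueError("n_obs must be >= n_indiv")


def _prepare(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Complete-case subset with reference levels fixed for categoricals.

    Reference levels: largest category for race/ethnicity, 'married' for
    marital status, first alphabetical for sex.
    """
    out = data[columns].dropna().copy()
    if "race_ethnicity" in out:
        order = out["race_ethnicity"].value_counts().index.tolist()
        out["race_ethnicity"] = pd.Categorical(out["race_ethnicity"], categories=order)
    if "marital_status" in out:
        levels = ["married"] + [x for x in out["marital_status"].unique() if x != "married"]
        out["marital_status"] = pd.Categorical(out["marital_status"], categories=levels)
    if "child_sex" in out:
        out["child_sex"] = pd.Categorical(
            out["child_sex"], categories=sorted(out["child_sex"].unique())
        )
    return out


def _formula(outcome: str, exposure: str, adjust: tuple[str, ...], extra: tuple[str, ...]):
    terms = [exposure]
    for c in list(adjust) + list(extra):
        if c in ("child_sex", "marital_status", "race_ethnicity"):
            terms.append(f"C({c})")
        else:
            terms.append(c)
    return f"{outcome} ~ " + " + ".join(terms)


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, _, pivots = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        aliased = sorted(names[i] for i in pivots[rank:])
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")


def _resolve_iqr(values: np.ndarray, iqr: float | None) -> float:
    if iqr is not None:
        return float(iqr)
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def fit_visit_model(
    data: pd.DataFrame,
    *,
    outcome: str = "score",
    exposure_col: str = "exposure",
    exposure_name: str = "",
    stratum: str = "",
    variant: str = "zscored",
    adjust: tuple[str, ...] = ADJUSTMENT_COLUMNS,
    extra_adjust: tuple[str, ...] = (),
    iqr: float | None = None,
) -> ModelResult:
    """Per-visit OLS of ``outcome`` on exposure + adjustment set.

    ``data`` holds one row per observation with a ``participant_id`` column.
    The coefficient is rescaled to the exposure IQR (analytic-subsample IQR
    unless ``iqr`` fixes a reference value); CI and p come from the t
    distribution with residual degrees of freedom.
    """
    cols = ["participant_id", outcome, exposure_col, *adjust, *extra_adjust]
    sub = _prepare(data, cols)
    if len(sub) == 0:
        raise ValueError("no complete-case observations")
    evals = sub[exposure_col].to_numpy(float)
    if np.ptp(evals) == 0:
        raise ValueError("exposure has zero variance in the analytic subsample")
    model = smf.ols(_formula(outcome, exposure_col, adjust, extra_adjust), data=sub)
    _check_rank(model.exog, list(model.exog_names))
    fit = model.fit()
    iqr_used = _resolve_iqr(evals, iqr)
    coef = fit.params[exposure_col]
    se = fit.bse[exposure_col]
    tcrit = scipy.stats.t.ppf(0.975, fit.df_resid)
    return ModelResult(
        exposure=exposure_name or exposure_col,
        stratum=stratum,
        variant=variant,
        effect=float(coef * iqr_used),
        ci_low=float((coef - tcrit * se) * iqr_used),
        ci_high=float((coef + tcrit * se) * iqr_used),
        p_value=float(fit.pvalues[exposure_col]),
        n_indiv=int(sub["participant_id"].nunique()),
        n_obs=int(len(sub)),
        iqr_used=iqr_used,
        model="ols",
        outcome=outcome,
    )


def fit_mixed_model(
    data: pd.DataFrame,
    *,
    outcome: str = "score",
    exposure_col: str = "exposure",
    exposure_name: str = "",
    variant: str = "zscored",
    adjust: tuple[str, ...] = ADJUSTMENT_COLUMNS,
    extra_adjust: tuple[str, ...] = (),
    iqr: float | None = None,
    reml: bool = True,
) -> ModelResult:
    """Random-intercept linear mixed model pooling all visits (REML).

    Participants with a single observation are included.  The fixed-effect
    exposure coefficient is IQR-scaled and its 95% CI is Wald (normal).
    """
    cols = ["participant_id", outcome, exposure_col, *adjust, *extra_adjust]
    sub = _prepare(data, cols)
    if len(sub) == 0:
        raise ValueError("no complete-case observations")
    evals = sub[exposure_col].to_numpy(float)
    if np.ptp(evals) == 0:
        raise ValueError("exposure has zero variance in the analytic subsample")
    model = smf.mixedlm(
        _formula(outcome, exposure_col, adjust, extra_adjust),
        data=sub,
        groups=sub["participant_id"],
    )
    _check_rank(model.exog, list(model.exog_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings are expected
        fit = model.fit(reml=reml)
    if not fit.converged:
        raise RuntimeError(
            "mixed model failed to converge; inspect the optimizer trace via "
            "MixedLM(...).fit(full_output=True)"
        )
    iqr_used = _resolve_iqr(evals, iqr)
    coef = fit.params[exposure_col]
    se = fit.bse[exposure_col]
    z = scipy.stats.norm.ppf(0.975)
    return ModelResult(
        exposure=exposure_name or exposure_col,
        stratum="all",
        variant=variant,
        effect=float(coef * iqr_used),
        ci_low=float((coef - z * se) * iqr_used),
        ci_high=float((coef + z * se) * iqr_used),
        p_value=float(fit.pvalues[exposure_col]),
        n_indiv=int(sub["participant_id"].nunique()),
        n_obs=int(len(sub)),
        iqr_used=iqr_used,
        model="mixed",
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# bivariate median-split tests


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric mass of an r x c table given margins."""
    from scipy.special import gammaln

    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1) - gammaln(table + 1).sum()
    )


def _fisher_p(table: np.ndarray, rng: np.random.Generator, n_mc: int = 2000) -> float:
    """Fisher's exact p; exact for 2x2, Monte-Carlo Freeman-Halton otherwise."""
    table = np.asarray(table, dtype=int)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(scipy.stats.fisher_exact(table)[1])
    obs = _log_table_prob(table)
    sampler = scipy.stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = sampler.rvs(n_mc, random_state=rng)
    lp = np.array([_log_table_prob(t) for t in sims])
    return float((1 + (lp <= obs + 1e-9).sum()) / (n_mc + 1))


def bivariate_tests(
    exposure: pd.Series,
    covariates: pd.DataFrame,
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Median-split the exposure and test covariate balance across strata.

    Ties at the median go to the lower stratum.  Continuous covariates get
    Welch t-tests, categoricals Fisher's exact (Monte-Carlo for r x c).
    Degenerate strata yield NaN with a reason.
    """
    exposure = exposure.dropna()
    covariates = covariates.loc[exposure.index]
    low = exposure <= exposure.median()
    rng = np.random.default_rng(seed)
    rows = []
    for col in covariates.columns:
        x = covariates[col]
        if low.sum() < 2 or (~low).sum() < 2:
            rows.append({"covariate": col, "test": "", "p_value": np.nan, "reason": "degenerate stratum"})
            continue
        if pd.api.types.is_numeric_dtype(x):
            a, b = x[low].dropna(), x[~low].dropna()
            if a.std() == 0 and b.std() == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
                rows.append({"covariate": col, "test": "welch_t", "p_value": p, "reason": "constant covariate"})
                continue
            p = float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append({"covariate": col, "test": "welch_t", "p_value": p, "reason": ""})
        else:
            table = pd.crosstab(low, x).to_numpy()
            p = _fisher_p(table, rng)
            rows.append({"covariate": col, "test": "fisher", "p_value": p, "reason": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity suite


@dataclass
class SensitivityReport:
    results: list[ModelResult] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def _has(frame: pd.DataFrame, col: str) -> bool:
    return col in frame.columns and frame[col].notna().any()


def sensitivity_suite(
    frame: pd.DataFrame,
    *,
    analyses=("copollutant", "age1", "age3", "no2", "cpg"),
    pollutants=("pm25", "pm10"),
    iqr: dict[str, float] | None = None,
    cpg_columns: tuple[str, ...] = (),
    variant: str = "zscored",
) -> SensitivityReport:
    """Re-fit the main models under the sensitivity specifications.

    ``frame`` holds one row per observation with columns
    ``score_<pollutant>`` (standardized scores, incl. ``score_no2`` for the
    specificity check), ``<pollutant>_birth``/``_age1``/``_age3`` exposures,
    the adjustment covariates, ``visit``, and optionally per-CpG
    percent-methylation columns (for ``cpg``).  Models that need a missing
    column are skipped with a log entry.
    """
    iqr = iqr or {}
    rep = SensitivityReport()

    def _visit_and_mixed(outcome, pol, extra, tag):
        kw = dict(
            outcome=outcome,
            exposure_col=f"{pol}_birth",
            exposure_name=pol,
            variant=f"{variant}:{tag}",
            extra_adjust=extra,
            iqr=iqr.get(pol),
        )
        for visit in sorted(frame["visit"].unique()):
            rep.results.append(
                fit_visit_model(frame[frame["visit"] == visit], stratum=visit, **kw)
            )
        rep.results.append(fit_mixed_model(frame, **kw))

    for pol in pollutants:
        other = [p for p in pollutants if p != pol]
        if "copollutant" in analyses:
            extra = tuple(f"{p}_birth" for p in other)
            if all(_has(frame, c) for c in extra):
                _visit_and_mixed(f"score_{pol}", pol, extra, "copollutant")
            else:
                rep.skipped.append(f"copollutant:{pol} (missing co-exposure)")
        for anchor in ("age1", "age3"):
            if anchor in analyses:
                col = f"{pol}_{anchor}"
                if _has(frame, col):
                    _visit_and_mixed(f"score_{pol}", pol, (col,), anchor)
                else:
                    rep.skipped.append(f"{anchor}:{pol} (missing postnatal exposure)")
        if "no2" in analyses:
            if _has(frame, "score_no2"):
                _visit_and_mixed("score_no2", pol, (), "no2_specificity")
            else:
                rep.skipped.append(f"no2:{pol} (missing NO2 score)")

    if "cpg" in analyses:
        age15 = frame[frame["visit"] == "age15"]
        for cpg in cpg_columns:
            if not _has(frame, cpg):
                rep.skipped.append(f"cpg:{cpg} (missing methylation column)")
                continue
            rep.results.append(
                fit_visit_model(
                    age15,
                    outcome=cpg,
                    exposure_col="pm10_birth",
                    exposure_name="pm10",
                    stratum="age15",
                    variant="single_cpg_percent",
                    iqr=iqr.get("pm10"),
                )
            )
    return rep
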