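"""Sample/probe quality control and saliva cell-composition estimation.

The filters mirror standard 450k-array practice for saliva cohorts:

* drop samples whose detection p-values indicate a failed hybridization
  (strictly more than 10% of sites with detection p > 0.01), whose
  methylation-predicted sex disagrees with the recorded sex, or whose sex
  chromosome intensity falls outside the normal band;
* drop probes with detection p > 0.01 in at least 5% of the remaining
  samples, plus any probe on a user-supplied cross-reactive blocklist.

Cell composition is summarized by a two-cell (immune/epithelial) model:
each sample's beta profile at reference CpGs is modelled as a convex
combination of the two reference columns, and the mixing proportion is the
sum-to-one, nonnegativity-constrained least-squares solution (closed form
for two cell types).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "BetaBundle",
    "filter_samples",
    "filter_probes",
    "estimate_cell_proportions",
]

DETECTION_P_THRESHOLD = 0.01
SAMPLE_FAIL_FRACTION = 0.10  # strict >
PROBE_FAIL_FRACTION = 0.05  # inclusive >=
NORMAL_INTENSITY_BAND = (-2.0, 2.0)


@dataclass
class BetaBundle:
    """One visit's methylation data: betas, detection p-values, metadata.

    ``samples`` must contain sample_id, participant_id, recorded_sex,
    predicted_sex and sexchrom_intensity columns; rows align with the
    columns of ``beta``/``detp``.
    """

    beta: pd.DataFrame  # CpG x sample, values in [0, 1]
    detp: pd.DataFrame  # same shape, detection p-values
    samples: pd.DataFrame  # one row per sample
    visit: str

    def __post_init__(self) -> None:
        if self.beta.shape != self.detp.shape or not self.beta.columns.equals(self.detp.columns):
            raise ValueError("beta and detp must have identical shape and columns")
        if not self.beta.index.equals(self.detp.index):
            raise ValueError("beta and detp must share the CpG index")
        ids = self.samples["sample_id"].tolist()
        if ids != list(self.beta.columns):
            raise ValueError("sample metadata rows must align with beta columns")
        b = self.beta.to_numpy()
        if b.size and (np.nanmin(b) < 0 or np.nanmax(b) > 1):
            raise ValueError("beta values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    def subset_samples(self, sample_ids) -> "BetaBundle":
        sample_ids = list(sample_ids)
        return replace(
            self,
            beta=self.beta[sample_ids],
            detp=self.detp[sample_ids],
            samples=self.samples.set_index("sample_id").loc[sample_ids].reset_index(),
        )

    def subset_probes(self, cpg_ids) -> "BetaBundle":
        cpg_ids = list(cpg_ids)
        return replace(self, beta=self.beta.loc[cpg_ids], detp=self.detp.loc[cpg_ids])


def filter_samples(
    bundle: BetaBundle,
    *,
    detp_threshold: float = DETECTION_P_THRESHOLD,
    max_fail_fraction: float = SAMPLE_FAIL_FRACTION,
    intensity_band: tuple[float, float] = NORMAL_INTENSITY_BAND,
) -> tuple[BetaBundle, pd.DataFrame]:
    """Drop QC-failing samples; return the kept bundle and a drop log.

    Rules are evaluated in order (detection, sex_discordant,
    abnormal_intensity) with first-match attribution, so a sample failing
    several rules is logged once under the first.
    """
    meta = bundle.samples
    fail_frac = (bundle.detp > detp_threshold).mean(axis=0)

    rule = pd.Series("", index=meta["sample_id"], dtype=object)
    detection = fail_frac > max_fail_fraction  # strict inequality
    rule[detection[detection].index] = "detection"

    sex_mismatch = (meta["predicted_sex"] != meta["recorded_sex"]).to_numpy()
    lo, hi = intensity_band
    abnormal = ~meta["sexchrom_intensity"].between(lo, hi).to_numpy()
    for sid, mism, abn in zip(meta["sample_id"], sex_mismatch, abnormal):
        if rule[sid]:
            continue
        if mism:
            rule[sid] = "sex_discordant"
        elif abn:
            rule[sid] = "abnormal_intensity"

    dropped = rule[rule != ""]
    log = pd.DataFrame({"sample_id": dropped.index, "rule": dropped.to_numpy()})
    kept_ids = [s for s in meta["sample_id"] if not rule[s]]
    return bundle.subset_samples(kept_ids), log


def filter_probes(
    bundle: BetaBundle,
    blocklist=(),
    *,
    detp_threshold: float = DETECTION_P_THRESHOLD,
    max_fail_fraction: float = PROBE_FAIL_FRACTION,
) -> tuple[BetaBundle, pd.DataFrame]:
    """Drop probes by detection rate and blocklist; return bundle + log.

    The detection rule is inclusive: a probe failing in >= 5% of samples is
    removed.  Blocklist ids absent from the matrix raise a warning only.
    """
    blocklist = set(blocklist)
    unknown = blocklist - set(bundle.beta.index)
    if unknown:
        warnings.warn(
            f"{len(unknown)} blocklist ids not present in the beta matrix", stacklevel=2
        )
    fail_frac = (bundle.detp > detp_threshold).mean(axis=1)
    by_detection = fail_frac >= max_fail_fraction
    rule = pd.Series("", index=bundle.beta.index, dtype=object)
    rule[by_detection[by_detection].index] = "detection"
    in_block = bundle.beta.index.isin(blocklist) & (rule == "").to_numpy()
    rule[bundle.beta.index[in_block]] = "cross_reactive"

    dropped = rule[rule != ""]
    log = pd.DataFrame({"cpg_id": dropped.index, "rule": dropped.to_numpy()})
    kept = [c for c in bundle.beta.index if not rule[c]]
    return bundle.subset_probes(kept), log


def read_blocklist(path) -> list[str]:
    """Read a one-CpG-per-line blocklist file (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def estimate_cell_proportions(bundle: BetaBundle, reference: pd.DataFrame) -> pd.DataFrame:
    """Estimate immune/epithelial proportions per sample.

    ``reference`` is a CpG x 2 matrix with columns ``immune`` and
    ``epithelial``.  For each sample, solve

        min_p || beta - (p * immune + (1 - p) * epithelial) ||^2
        s.t. 0 <= p <= 1,

    whose solution is the unconstrained scalar least-squares estimate
    projected onto [0, 1] (the constrained projection is exact for a 1-D
    simplex).  Requires >= 2 reference CpGs present in the bundle.
    """
    if not {"immune", "epithelial"}.issubset(reference.columns):
        raise ValueError("reference must have 'immune' and 'epithelial' columns")
    shared = reference.index.intersection(bundle.beta.index)
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 reference CpGs present in the bundle, found {len(shared)}"
        )
    ref = reference.loc[shared]
    d = (ref["immune"] - ref["epithelial"]).to_numpy()
    denom = float(d @ d)
    cond = np.linalg.cond(ref.to_numpy())
    if denom < 1e-12 * len(shared):
        raise ValueError(
            "reference columns are collinear (condition number "
            f"{cond:.3g}); cannot deconvolve"
        )
    resid = bundle.beta.loc[shared].to_numpy() - ref["epithelial"].to_numpy()[:, None]
    p = np.clip((d @ resid) / denom, 0.0, 1.0)
    return pd.DataFrame(
        {"sample_id": bundle.beta.columns, "immune": p, "epithelial": 1.0 - p}
    )
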