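import dataclasses

import numpy as np
import pandas as pd
import pytest

from airmeth.config import default_config
from airmeth.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small paired cohort without monitor series (fast to generate)."""
    cfg = dataclasses.replace(
        default_config(seed=42),
        n_both=150,
        n_age9_only=5,
        n_age15_only=10,
        n_background_cpgs=60,
        n_reference_cpgs=60,
        include_monitors=False,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def paired_cohort():
    """Paper-scale paired cohort (747 participants at both visits)."""
    cfg = dataclasses.replace(default_config(seed=7), include_monitors=False)
    return generate_cohort(cfg)


def pooled_beta(cohort):
    """Pooled CpG x sample beta matrix and the sample -> visit mapping."""
    bundles = cohort.beta_bundles
    beta = pd.concat([bundles[v].beta for v in sorted(bundles)], axis=1)
    visits = pd.concat(
        [pd.Series(v, index=bundles[v].beta.columns) for v in sorted(bundles)]
    )
    return beta, visits


def participant_scores(score_df):
    """Split a cumulative_score frame into per-visit participant-indexed series."""
    df = score_df.copy()
    df["pid"] = df["sample_id"].str.rsplit("_", n=1).str[0]
    return {
        visit: sub.set_index("pid")["score_standardized"]
        for visit, sub in df.groupby("visit")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
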