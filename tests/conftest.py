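import numpy as np
import pandas as pd
import pytest

from impactability.config import SynthConfig
from impactability.cohort import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Confounded cohort, heterogeneous benefit, moderate size (shared, read-only)."""
    cfg = SynthConfig(n_patients=2000, n_binary_covariates=40,
                      n_continuous_covariates=5, enrollment_rate=0.08, seed=101)
    return generate_cohort(cfg, n_mc_truth=50_000)


@pytest.fixture(scope="session")
def null_cohort():
    """No treatment effect, no confounding: outcome trajectories coincide."""
    cfg = SynthConfig(n_patients=2000, n_binary_covariates=20,
                      confounder_log_odds=(0, 0, 0, 0, 0),
                      effect_level=0.0, benefit_intercept=0.0,
                      benefit_coefficients=(), benefit_event_scale=0.0,
                      enrollment_rate=0.25, seed=202)
    return generate_cohort(cfg, n_mc_truth=20_000)


def trivial_match(episodes: pd.DataFrame, ratio: int = 1):
    """1:ratio matching by episode order (one episode per comparison patient)."""
    from impactability.matching import MatchResult
    cases = episodes[episodes["role"] == "case"]
    comps = episodes[episodes["role"] == "comparison"].drop_duplicates("patient_id")
    k = min(len(cases) * ratio, len(comps))
    case_ids = np.repeat(cases["episode_id"].to_numpy(), ratio)[:k]
    pairs = pd.DataFrame({
        "case_id": case_ids,
        "comparison_id": comps["episode_id"].to_numpy()[:k],
        "distance": 0.0, "round": 1,
    })
    m = pairs.groupby("case_id")["comparison_id"].transform("size")
    pairs["weight"] = 1.0 / m
    return MatchResult(pairs=pairs)
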