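"""Impute, binarize and screen the raw covariates of the simulated cohort.

Reads results/run/episodes.csv, applies HCC-decile mean imputation,
case-median binarization and the 5%-95% prevalence / 0.8 correlation
screen, and writes the covariate catalog with per-variable retention
reasons.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

RESULTS = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    from impactability.pipeline import prepare_covariates
    cfg = importlib.import_module("01_simulate_cohort").run_config()
    episodes = pd.read_csv(RESULTS / "episodes.csv")
    X, catalog = prepare_covariates(episodes, cfg)
    X.to_csv(RESULTS / "covariates_screened.csv", index=False)
    catalog.to_frame().to_csv(RESULTS / "covariate_catalog.csv", index=False)
    excluded = catalog.excluded
    print(f"screened {len(catalog.entries)} candidate covariates: "
          f"{len(catalog.retained)} retained, {len(excluded)} excluded")
    for reason in ("prevalence", "correlation"):
        n = sum(1 for r in excluded.values() if r == reason)
        print(f"  excluded for {reason}: {n}")


if __name__ == "__main__":
    main()
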