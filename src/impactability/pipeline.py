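"""End-to-end orchestration: synth -> prep -> hdPS -> match -> benefit -> effects.

``run_pipeline`` executes every stage on a synthetic cohort (or one
loaded from episodes/months CSVs), writing all intermediate artifacts,
an attrition-style log of episode counts in and out of each stage, and a
final report table (outcome x overall / high-benefit / no-low-benefit
rows with bootstrap CIs).  Every output is regenerable from the resolved
config + seed, which are persisted beside the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import benefit as bn
from . import covariates as cp
from . import effects as fx
from . import hdps
from .cohort import SynthCohort, generate_cohort
from .config import RunConfig
from .matching import ExactSchedule, balance_report, run_rounds

logger = logging.getLogger(__name__)


def default_exact_schedule(confounder_columns: list[str]) -> ExactSchedule:
    """Nested 5-round schedule: risk category + confounder indicators,
    coarsened by dropping one variable per round down to risk alone."""
    full = ["risk_high"] + confounder_columns[:4]
    rounds = [full[: max(1, len(full) - r)] for r in range(5)]
    return ExactSchedule(rounds=rounds)


def prepare_covariates(episodes: pd.DataFrame, config: RunConfig
                       ) -> tuple[pd.DataFrame, cp.CovariateCatalog]:
    """Impute + binarize continuous covariates, screen the indicator block."""
    import re
    cases = (episodes["role"] == "case").to_numpy()
    binary = [c for c in episodes.columns if re.fullmatch(r"x\d+", c)]
    cont = [c for c in episodes.columns if re.fullmatch(r"c\d+", c)]
    mat = episodes[binary].copy()
    for c in cont:
        imputed = cp.impute_continuous(episodes[c], episodes["hcc_score"])
        try:
            ind, _ = cp.binarize_continuous(imputed, cases)
        except ValueError:
            continue
        mat[f"{c}_high"] = ind
    catalog = cp.screen_variables(mat, cases,
                                  prevalence_low=config.prevalence_low,
                                  prevalence_high=config.prevalence_high,
                                  correlation_cap=config.correlation_cap)
    return mat[catalog.retained], catalog


def baseline_event_flag(episodes: pd.DataFrame, months: pd.DataFrame) -> np.ndarray:
    """Any unplanned event during the baseline year, per episode."""
    base = months[months["month"] < 0]
    flag = base.groupby("episode_id")["any_event"].max()
    return episodes["episode_id"].map(flag).fillna(0).to_numpy(dtype=int)


def run_pipeline(config: RunConfig, outdir: str | Path,
                 cohort: SynthCohort | None = None) -> dict:
    """Execute every stage, write artifacts under ``outdir``, return a report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    attrition: list[dict] = []
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed, "ci_reliable": config.ci_reliable}
    if not config.ci_reliable:
        report["warning"] = "CI unreliable: too few bootstrap replications"

    def stage(name):
        t0 = time.time()
        def done(**counts):
            timings[name] = round(time.time() - t0, 3)
            attrition.append({"stage": name, **counts})
            logger.info("stage %s done in %.2fs: %s", name, timings[name], counts)
        return done

    # ------------------------------------------------------------ simulate
    done = stage("simulate")
    if cohort is None:
        cohort = generate_cohort(config.synth)
    episodes, months = cohort.episodes, cohort.months
    cohort.write(outdir)
    done(episodes=len(episodes),
         cases=int((episodes["role"] == "case").sum()),
         comparison_episodes=int((episodes["role"] == "comparison").sum()))

    # ------------------------------------------------------------ prep
    done = stage("prep")
    X, catalog = prepare_covariates(episodes, config)
    catalog.to_frame().to_csv(outdir / "covariate_catalog.csv", index=False)
    done(candidates=len(catalog.entries), retained=len(catalog.retained))

    # ------------------------------------------------------------ hdps
    done = stage("hdps")
    treated = episodes["treated"].to_numpy()
    outcome_flag = baseline_event_flag(episodes, months)
    ranking = hdps.prioritize_covariates(X, treated, outcome_flag,
                                         alpha=config.significance_alpha)
    ranking.table.to_csv(outdir / "bias_ranking.csv", index=False)
    selected, bic_path, lam = hdps.select_lasso_bic(X[ranking.ranked], treated)
    ps_model = hdps.fit_propensity(X[selected], treated,
                                   selection_lambda=lam, bic_path=bic_path)
    ps_model.to_json(outdir / "propensity_model.json")
    done(prioritized=len(ranking.ranked), selected=len(selected))

    # ------------------------------------------------------------ match
    done = stage("match")
    ep = episodes.copy()
    ep["risk_high"] = (ep["risk_probability"] > config.risk_threshold).astype(int)
    conf_cols = [f"x{j}" for j in config.synth.confounder_indices]
    schedule = (ExactSchedule([list(r) for r in config.exact_schedule])
                if config.exact_schedule else default_exact_schedule(conf_cols))
    match = run_rounds(ep, ps_model.scores, schedule, k_max=config.k_max,
                       max_candidates=config.match_candidate_cap)
    match.pairs.to_csv(outdir / "matches.csv", index=False)
    ep_bal = pd.concat([episodes[["episode_id", "role"]].reset_index(drop=True),
                        X.reset_index(drop=True)], axis=1)
    bal = balance_report(ep_bal, catalog.retained, match,
                         propensity_scores=ps_model.scores,
                         threshold=config.smd_flag_threshold)
    bal.table.to_csv(outdir / "balance.csv", index=False)
    done(matched_cases=int(match.pairs["case_id"].nunique()),
         matched_comparisons=len(match.pairs),
         unmatched_cases=len(match.unmatched_cases),
         flagged_covariates=len(bal.flagged))

    # ------------------------------------------------------------ benefit
    done = stage("benefit")
    ps = pd.Series(ps_model.scores, index=episodes["episode_id"].to_numpy())
    matched_ids = np.concatenate([match.pairs["case_id"].unique(),
                                  match.pairs["comparison_id"].to_numpy()])
    train = episodes.set_index("episode_id").loc[matched_ids].reset_index()
    pay12 = bn.twelve_month_payment(train, months)
    w = np.ones(len(train))
    comp_w = (match.pairs["weight"].to_numpy()
              * (ps.loc[match.pairs["comparison_id"]]
                 / (1 - ps.loc[match.pairs["comparison_id"]])).to_numpy())
    w[len(match.pairs["case_id"].unique()):] = comp_w
    benefit_covs = selected if selected else ranking.ranked[:10]
    Xid = X.copy()
    Xid.index = episodes["episode_id"].to_numpy()
    # join prepared indicators onto the training frame
    for c in benefit_covs:
        if c not in train.columns:
            train[c] = Xid.loc[train["episode_id"], c].to_numpy()
    bmodel = bn.fit_benefit_model(train, pay12, benefit_covs, weights=w)
    bmodel.to_json(outdir / "benefit_model.json")
    score_frame = episodes.copy()
    for c in benefit_covs:
        if c not in score_frame.columns:
            score_frame[c] = Xid.loc[score_frame["episode_id"], c].to_numpy()
    case_rows = score_frame[score_frame["role"] == "case"]
    scores = bmodel.score(case_rows)
    cats = bn.categorize_benefit(scores)
    risk = bn.categorize_risk(case_rows["risk_probability"].to_numpy())
    benefit_table = pd.DataFrame({
        "episode_id": case_rows["episode_id"].to_numpy(),
        "benefit_score": scores, "benefit_quintile": cats.quintile,
        "benefit_label": cats.label, "historic_flag": cats.historic_flag,
        "risk_category": risk,
    })
    benefit_table.to_csv(outdir / "benefit_scores.csv", index=False)
    done(scored_cases=len(benefit_table),
         high_benefit=int((cats.label == "high_benefit").sum()))

    # ------------------------------------------------------------ effects
    done = stage("effects")
    blab = benefit_table.set_index("episode_id")["benefit_label"]
    rcat = benefit_table.set_index("episode_id")["risk_category"]
    adj = bal.flagged
    ep_adj = episodes.copy()
    for c in adj:
        if c not in ep_adj.columns:
            ep_adj[c] = X[c].to_numpy()
    panel = fx.assemble_panel(ep_adj, months, match, ps_model.scores,
                              benefit_labels=blab, risk_categories=rcat,
                              adjustment_covariates=adj)
    panel.to_csv(outdir / "panel.csv", index=False)
    rng = np.random.default_rng(config.seed)
    B = config.bootstrap_replications
    estimates: list[fx.EffectEstimate] = []
    for family, label in (("binomial", "unplanned_events"),
                          ("zip", "event_days"), ("zigamma", "payments")):
        estimates.append(fx.overall_effect(panel, family, adj, B=B, rng=rng,
                                           outcome_name=label))
        estimates.extend(fx.stratified_effects(panel, family, adj, B=B, rng=rng,
                                               outcome_name=label))
    table = pd.DataFrame([e.as_dict() for e in estimates])
    table.to_csv(outdir / "effect_estimates.csv", index=False)
    done(estimates=len(estimates))

    report["attrition"] = attrition
    report["timings_s"] = timings
    report["balance_flagged"] = bal.flagged
    report["selected_variables"] = selected
    report["effects"] = [e.as_dict() for e in estimates]
    if cohort.truth is not None:
        report["truth"] = vars(cohort.truth)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
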