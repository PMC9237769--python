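"""Segmented longitudinal outcome models and per-100-patient effects.

The analysis panel holds one row per matched episode per observed month
(months -12..-1 and 1..12; month 0 does not exist).  Three weighted
segmented (interrupted time-series) models are fit on it, one per
outcome: logit/binomial for the any-event indicator, log/zero-inflated
Poisson for event-days, log/zero-inflated gamma for payments.  Each has
terms for group, pre-period trend, change in level at the anchor, and
post-period trend, all interacted with group, plus residual-confounder
adjustment covariates; analysis weights are ATT inverse-propensity
weights times the inverse number of matches.

Fits are transformed by g-computation into the evaluation quantity:
the predicted reduction per 100 enrolled patients over 1 year, with
percentile bootstrap CIs resampling whole matched sets, Harrell optimism
correction for scores evaluated on their training cohort, and
stratification by benefit category and risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import FitError, GLMFit, fit_logistic_safe, fit_zigamma, fit_zip
from .matching import MatchResult

logger = logging.getLogger(__name__)

FAMILIES = ("binomial", "zip", "zigamma")
OUTCOME_COLUMNS = {"binomial": "any_event", "zip": "event_days", "zigamma": "payment"}

_BASE_TERMS = ["const", "group", "t", "group_t", "post", "group_post",
               "tpost", "group_tpost"]
_COUNTERFACTUAL_ZEROED = ("group_post", "group_tpost")


@dataclass
class SegmentedModel:
    family: str
    terms: list[str]
    beta: np.ndarray
    loglik: float
    pi: float = 0.0           # zero-inflation mass (0 for binomial)
    alpha: float | None = None  # gamma shape
    converged: bool = True
    n_iter: int = 0

    def linear_predictor(self, D: np.ndarray) -> np.ndarray:
        return D @ self.beta

    def mean(self, D: np.ndarray) -> np.ndarray:
        """Marginal outcome mean per month (mixture mean for ZI families)."""
        eta = np.clip(self.linear_predictor(D), -30, 30)
        if self.family == "binomial":
            return expit(eta)
        return (1.0 - self.pi) * np.exp(eta)


@dataclass
class EffectEstimate:
    outcome: str
    reduction_per_100: float
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    stratum: str = "overall"
    n_cases: int = 0
    n_comparisons: int = 0
    bias_corrected: bool = False
    unstable: bool = False

    def as_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in vars(self).items()}


# ----------------------------------------------------------------- panel


def assemble_panel(episodes: pd.DataFrame, months: pd.DataFrame,
                   match_result: MatchResult, propensity_scores: np.ndarray,
                   benefit_labels: pd.Series | None = None,
                   risk_categories: pd.Series | None = None,
                   adjustment_covariates: list[str] | None = None) -> pd.DataFrame:
    """Patient-month panel for matched cases and their comparisons.

    Intent-to-treat: every observed month of a matched episode enters;
    censored months are simply absent.  Weights: cases carry 1 (the ATT
    target); comparisons carry ps/(1-ps), normalized to mean 1 over
    comparison episodes, times 1/m for a set of m matches.  Comparisons
    inherit the benefit label and risk category of their case.
    """
    adjustment_covariates = adjustment_covariates or []
    ep = episodes.set_index("episode_id")
    ps = pd.Series(np.asarray(propensity_scores, dtype=float),
                   index=episodes["episode_id"].to_numpy())

    pairs = match_result.pairs
    case_ids = pairs["case_id"].unique()
    dropped = set(ep.index[ep["role"] == "case"]) - set(case_ids)
    if dropped:
        logger.info("excluding %d unmatched cases from the panel", len(dropped))

    comp = pairs[["comparison_id", "case_id", "weight"]].copy()
    ipw_raw = (ps.loc[comp["comparison_id"]] /
               (1.0 - ps.loc[comp["comparison_id"]])).to_numpy()
    ipw = ipw_raw / ipw_raw.mean() if len(ipw_raw) else ipw_raw
    comp["w"] = comp["weight"].to_numpy() * ipw

    frames = []
    for which, ids, w, anchor in (
            ("case", case_ids, np.ones(len(case_ids)), case_ids),
            ("comparison", comp["comparison_id"].to_numpy(), comp["w"].to_numpy(),
             comp["case_id"].to_numpy())):
        f = pd.DataFrame({"episode_id": ids, "group": which, "w": w,
                          "case_anchor": anchor})
        frames.append(f)
    units = pd.concat(frames, ignore_index=True)

    panel = months.merge(units, on="episode_id", how="inner")
    panel["post"] = (panel["month"] >= 1).astype(int)
    if benefit_labels is not None:
        panel["benefit_label"] = panel["case_anchor"].map(benefit_labels)
    if risk_categories is not None:
        panel["risk_category"] = panel["case_anchor"].map(risk_categories)
    for v in adjustment_covariates:
        panel[v] = panel["episode_id"].map(ep[v])
    return panel


def segmented_design(panel: pd.DataFrame, adjustment_covariates: list[str] | None = None,
                     benefit_interaction: bool = False,
                     counterfactual: bool = False) -> tuple[np.ndarray, list[str]]:
    """Design matrix of the segmented model.

    Terms: intercept; group (case=1); pre-slope t; group x t; post level;
    group x post; post-slope (t-1)+; group x post-slope; adjustment
    covariates.  With ``benefit_interaction``, a high-benefit indicator
    enters as a main effect and crossed with every group/period term.
    With ``counterfactual``, the group x post and group x post-slope
    columns (and their benefit crosses) are zeroed: enrolled patients
    keep their own pre-period trajectory but lose the enrollment-anchored
    level change and trend change.
    """
    adjustment_covariates = adjustment_covariates or []
    g = (panel["group"] == "case").to_numpy(dtype=float)
    t = panel["month"].to_numpy(dtype=float)
    post = (t >= 1).astype(float)
    tpost = np.maximum(t - 1.0, 0.0) * post
    gp = g * post
    gtp = g * tpost
    if counterfactual:
        gp = np.zeros_like(gp)
        gtp = np.zeros_like(gtp)
    cols = {"const": np.ones(len(t)), "group": g, "t": t, "group_t": g * t,
            "post": post, "group_post": gp, "tpost": tpost, "group_tpost": gtp}
    if benefit_interaction:
        hb = (panel["benefit_label"] == "high_benefit").to_numpy(dtype=float)
        for name in list(cols):
            if name == "const":
                cols["hb"] = hb
            else:
                cols[f"hb_{name}"] = hb * cols[name]
        if counterfactual:
            cols["hb_group_post"] = np.zeros(len(t))
            cols["hb_group_tpost"] = np.zeros(len(t))
    for v in adjustment_covariates:
        cols[v] = panel[v].to_numpy(dtype=float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _fit_family(D: np.ndarray, y: np.ndarray, w: np.ndarray, family: str) -> GLMFit:
    if family == "binomial":
        return fit_logistic_safe(D, y, w)
    if family == "zip":
        return fit_zip(D, y, w)
    return fit_zigamma(D, y, w)


def fit_segmented_glm(panel: pd.DataFrame, family: str,
                      adjustment_covariates: list[str] | None = None,
                      benefit_interaction: bool = False) -> SegmentedModel:
    """Weighted ML fit of the segmented model for one outcome family."""
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y = panel[OUTCOME_COLUMNS[family]].to_numpy(dtype=float)
    w = panel["w"].to_numpy(dtype=float)
    if set(panel["group"]) != {"case", "comparison"} or panel["post"].nunique() < 2:
        raise ValueError("panel must contain both groups and both periods")
    if np.all(y == 0):
        raise FitError("degenerate fit: outcome is identically zero")
    D, names = segmented_design(panel, adjustment_covariates, benefit_interaction)
    fit = _fit_family(D, y, w, family)
    extra = fit.extra or {}
    return SegmentedModel(family, names, fit.beta, fit.loglik,
                          pi=extra.get("pi", 0.0), alpha=extra.get("alpha"),
                          converged=fit.converged, n_iter=fit.n_iter)


def predict_per_100(model: SegmentedModel, panel: pd.DataFrame,
                    stratum_mask: np.ndarray | None = None) -> float:
    """Per-100-patient 1-year reduction by g-computation over enrolled cases.

    For each matched case episode and each month 1..12, the outcome mean
    is predicted as enrolled (factual) and under the counterfactual
    comparison trajectory (enrollment-anchored interaction terms zeroed);
    the monthly differences are summed over the year, averaged over
    cases, and scaled to 100 patients.  Positive = fewer events / fewer
    event-days / dollars saved.
    """
    cases = panel[panel["group"] == "case"]
    if stratum_mask is not None:
        cases = cases[np.asarray(stratum_mask)[panel["group"].to_numpy() == "case"]]
    # one row per case episode, replicated over months 1..12
    base = cases.drop_duplicates("episode_id")
    if not len(base):
        raise ValueError("no case episodes to predict for")
    rep = base.loc[base.index.repeat(12)].copy()
    rep["month"] = np.tile(np.arange(1, 13), len(base))
    adj = [c for c in model.terms if c in panel.columns
           and c not in _BASE_TERMS and not c.startswith("hb")]
    hb = any(c.startswith("hb") for c in model.terms)
    Df, _ = segmented_design(rep, adj, benefit_interaction=hb, counterfactual=False)
    Dc, _ = segmented_design(rep, adj, benefit_interaction=hb, counterfactual=True)
    diff = model.mean(Dc) - model.mean(Df)
    per_case = diff.reshape(len(base), 12).sum(axis=1)
    return float(100.0 * per_case.mean())


# --------------------------------------------------------------- bootstrap


def _set_row_indices(panel: pd.DataFrame) -> list[np.ndarray]:
    """Row positions of each matched set (case + its comparisons)."""
    codes, _ = pd.factorize(panel["case_anchor"], sort=False)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(codes.max() + 1))
    return np.split(order, bounds[1:])


def _resample_panel(panel: pd.DataFrame, rng: np.random.Generator,
                    set_rows: list[np.ndarray] | None = None) -> pd.DataFrame:
    """Resample matched sets (case + its comparisons) with replacement."""
    if set_rows is None:
        set_rows = _set_row_indices(panel)
    n_sets = len(set_rows)
    draw = rng.integers(0, n_sets, size=n_sets)
    rows = np.concatenate([set_rows[a] for a in draw])
    out = panel.iloc[rows].reset_index(drop=True)
    # resampled copies of the same set are distinct clusters
    out["case_anchor"] = np.repeat(np.arange(n_sets), [len(set_rows[a]) for a in draw])
    return out


def bootstrap_ci(panel: pd.DataFrame, family: str,
                 adjustment_covariates: list[str] | None = None,
                 B: int = 400, rng: np.random.Generator | int | None = None,
                 benefit_interaction: bool = False,
                 stratum_label: str | None = None) -> tuple[float, float, np.ndarray]:
    """Percentile 95% CI of the per-100 reduction over B matched-set resamples.

    Returns (lower, upper, replicate_values).  Raises if more than 10% of
    replicates fail to fit.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(rng)
    # precompute everything once; replicates only index rows and refit
    D, names = segmented_design(panel, adjustment_covariates, benefit_interaction)
    y = panel[OUTCOME_COLUMNS[family]].to_numpy(dtype=float)
    w = panel["w"].to_numpy(dtype=float)
    set_rows = _set_row_indices(panel)
    # one case per matched set: its 12-month factual/counterfactual designs
    cases = panel[panel["group"] == "case"].drop_duplicates("episode_id")
    base = cases.loc[cases.index.repeat(12)].copy()
    base["month"] = np.tile(np.arange(1, 13), len(cases))
    Df, _ = segmented_design(base, adjustment_covariates, benefit_interaction,
                             counterfactual=False)
    Dc, _ = segmented_design(base, adjustment_covariates, benefit_interaction,
                             counterfactual=True)
    anchor_order = pd.unique(panel["case_anchor"])
    case_of_set = pd.Series(np.arange(len(cases)),
                            index=cases["episode_id"].to_numpy())
    set_case = case_of_set.reindex(anchor_order).to_numpy()  # NaN-free by design
    if stratum_label is not None:
        in_stratum = (cases["benefit_label"] == stratum_label).to_numpy()
    else:
        in_stratum = np.ones(len(cases), dtype=bool)

    def mixture_mean(eta, pi):
        eta = np.clip(eta, -30, 30)
        return expit(eta) if family == "binomial" else (1 - pi) * np.exp(eta)

    reps, failures = [], []
    n_sets = len(set_rows)
    for b in range(B):
        draw = rng.integers(0, n_sets, size=n_sets)
        rows = np.concatenate([set_rows[a] for a in draw])
        try:
            fit = _fit_family(D[rows], y[rows], w[rows], family)
            pi = (fit.extra or {}).get("pi", 0.0)
            diff = (mixture_mean(Dc @ fit.beta, pi)
                    - mixture_mean(Df @ fit.beta, pi)).reshape(len(cases), 12)
            per_case = diff.sum(axis=1)
            drawn_cases = set_case[draw].astype(int)
            keep = in_stratum[drawn_cases]
            if not keep.any():
                raise FitError("no cases of the stratum in this resample")
            reps.append(float(100.0 * per_case[drawn_cases[keep]].mean()))
        except (FitError, np.linalg.LinAlgError, ValueError) as e:
            failures.append((b, repr(e)))
    if len(failures) > 0.1 * B:
        raise FitError(f"{len(failures)}/{B} bootstrap replicates failed: "
                       f"{failures[:5]}")
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi), reps


def bias_correct(apparent: float, fit_benefit_fn, evaluate_fn, cohort,
                 B: int = 200, rng: np.random.Generator | int | None = None
                 ) -> tuple[float, float]:
    """Harrell bootstrap optimism correction for in-sample benefit models.

    ``fit_benefit_fn(resampled_cohort) -> model`` refits the benefit
    model; ``evaluate_fn(model, cohort) -> float`` computes the stratum
    effect of interest.  Optimism is the mean over resamples of
    [resample-fit model evaluated on the resample] minus [same model
    evaluated on the original cohort]; corrected = apparent - optimism.
    Returns (corrected, optimism).
    """
    rng = np.random.default_rng(rng)
    n = len(cohort)
    opts = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        model = fit_benefit_fn(boot)
        opts.append(evaluate_fn(model, boot) - evaluate_fn(model, cohort))
    optimism = float(np.mean(opts))
    return apparent - optimism, optimism


# --------------------------------------------------------------- strata


def stratified_effects(panel: pd.DataFrame, family: str,
                       adjustment_covariates: list[str] | None = None,
                       by_risk: bool = False, B: int = 0,
                       rng: np.random.Generator | int | None = None,
                       outcome_name: str | None = None) -> list[EffectEstimate]:
    """Per-stratum per-100 effects: benefit label as interaction, risk split.

    Risk strata (if ``by_risk``) are fit separately; within each fit the
    high-benefit indicator interacts with every group/period term, and
    per-100 predictions are computed within each benefit stratum.  With
    B > 0, percentile bootstrap CIs are attached.  Strata with fewer than
    10 cases are flagged unstable; empty strata are skipped with a log
    entry.
    """
    rng = np.random.default_rng(rng)
    outcome_name = outcome_name or OUTCOME_COLUMNS[family]
    risk_levels = [None]
    if by_risk and "risk_category" in panel.columns:
        risk_levels = [lv for lv in ("high", "moderate")
                       if (panel["risk_category"] == lv).any()]
    out: list[EffectEstimate] = []
    for rl in risk_levels:
        sub = panel if rl is None else panel[panel["risk_category"] == rl]
        if not len(sub):
            continue
        # a single benefit level makes the interaction columns collinear
        interact = sub["benefit_label"].nunique() > 1
        try:
            model = fit_segmented_glm(sub, family, adjustment_covariates,
                                      benefit_interaction=interact)
        except (FitError, ValueError) as e:
            logger.warning("stratum risk=%s skipped: %s", rl, e)
            continue
        for lbl in ("high_benefit", "no_low_benefit"):
            mask = (sub["benefit_label"] == lbl).to_numpy()
            cases = sub[(sub["group"] == "case") & mask]
            n_cases = cases["episode_id"].nunique()
            if n_cases == 0:
                logger.info("empty stratum risk=%s benefit=%s skipped", rl, lbl)
                continue
            est = predict_per_100(model, sub, stratum_mask=mask)
            name = lbl if rl is None else f"{lbl}|{rl}_risk"
            ee = EffectEstimate(outcome=outcome_name, reduction_per_100=est,
                                stratum=name, n_cases=int(n_cases),
                                n_comparisons=int(
                                    sub[(sub["group"] == "comparison") & mask]
                                    ["episode_id"].nunique()))
            if n_cases < 10:
                warnings.warn(f"stratum {name} has {n_cases} cases; estimate unstable")
                ee.unstable = True
            if B >= 2:
                try:
                    lo, hi, _ = bootstrap_ci(sub, family, adjustment_covariates,
                                             B=B, rng=rng,
                                             benefit_interaction=interact,
                                             stratum_label=lbl)
                    ee.ci_lower, ee.ci_upper = lo, hi
                except FitError as e:
                    logger.warning("bootstrap failed for stratum %s: %s", name, e)
            out.append(ee)
    return out


def overall_effect(panel: pd.DataFrame, family: str,
                   adjustment_covariates: list[str] | None = None,
                   B: int = 0, rng: np.random.Generator | int | None = None,
                   outcome_name: str | None = None) -> EffectEstimate:
    """Overall per-100 effect for one outcome, optionally with a bootstrap CI."""
    model = fit_segmented_glm(panel, family, adjustment_covariates)
    est = predict_per_100(model, panel)
    ee = EffectEstimate(outcome=outcome_name or OUTCOME_COLUMNS[family],
                        reduction_per_100=est,
                        n_cases=int(panel.loc[panel["group"] == "case",
                                              "episode_id"].nunique()),
                        n_comparisons=int(panel.loc[panel["group"] == "comparison",
                                                    "episode_id"].nunique()))
    if B >= 2:
        lo, hi, _ = bootstrap_ci(panel, family, adjustment_covariates, B=B, rng=rng)
        ee.ci_lower, ee.ci_upper = lo, hi
    return ee
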