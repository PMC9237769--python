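"""Synthetic patient-episode cohort generator with known ground truth.

Emulates the data structure of a case-management program evaluation in a
Medicare-ACO-like population: each *case* is a patient anchored at an
enrollment month; each potential *comparison* patient carries one or more
candidate episodes anchored at constructed match dates.  Every episode has
a 1-year monthly baseline (months -12..-1) and up to a 1-year follow-up
(months 1..12, geometric censoring); month 0 does not exist.  Outcomes per
patient-month are: an any-unplanned-event indicator, a count of event-days
in 0..31, and a non-negative monthly payment with excess zeros.

Enrollment is confounded: a logistic treatment model on a designated
subset of the binary covariates, with the intercept calibrated so the
marginal enrollment probability matches ``enrollment_rate``.  Treatment
benefit is heterogeneous: ``b(x)`` dollars/month of expected payment
reduction (and a proportional shift on the event logit), so the
generating truth for any config is available analytically, patient by
patient, and :func:`true_effect_per_100` aggregates it over the treated
population by Monte Carlo over covariate draws only (per-draw expectations
are exact).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import SynthConfig

MONTHS = np.array([m for m in range(-12, 13) if m != 0])
EVENT_DAYS_RATE = 2.0  # extra event-days beyond the first, per event-month


@dataclass
class TrueEffects:
    """Generator-implied per-100-patient 1-year effects (the oracle)."""

    true_per100_payment_reduction: float
    true_per100_event_reduction: float
    mean_benefit_12m: float
    mc_se_payment: float
    mc_se_events: float
    n_mc: int


@dataclass
class SynthCohort:
    episodes: pd.DataFrame
    months: pd.DataFrame
    truth: TrueEffects
    config: SynthConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.episodes.to_csv(outdir / "episodes.csv", index=False)
        self.months.to_csv(outdir / "months.csv", index=False)
        self.config.to_yaml(outdir / "synth_config.yaml")


def binary_columns(config: SynthConfig) -> list[str]:
    return [f"x{j}" for j in range(config.n_binary_covariates)]


def continuous_columns(config: SynthConfig) -> list[str]:
    return [f"c{j}" for j in range(config.n_continuous_covariates)]


def _covariate_draw(config: SynthConfig, n: int, rng: np.random.Generator):
    """Draw the patient-level covariate block (shared by population and truth)."""
    prevalences = _prevalences(config)
    X = (rng.random((n, config.n_binary_covariates)) < prevalences).astype(np.int8)
    hcc = rng.gamma(shape=2.0, scale=1.25, size=n)
    return X, hcc, prevalences


def _treatment_intercept(eta_cov: np.ndarray, rate: float) -> float:
    """Calibrate the logistic intercept so mean enrollment equals `rate`."""
    lo, hi = -30.0, 30.0
    f = lambda b0: expit(b0 + eta_cov).mean() - rate
    return brentq(f, lo, hi, xtol=1e-10)


def _benefit_dollars(config: SynthConfig, X: np.ndarray) -> np.ndarray:
    """b(x): expected monthly payment reduction under enrollment, in dollars."""
    k = len(config.benefit_coefficients)
    b = np.full(X.shape[0], float(config.benefit_intercept))
    if k:
        b = b + X[:, :k] @ np.asarray(config.benefit_coefficients, dtype=float)
    return b


def _prevalences(config: SynthConfig) -> np.ndarray:
    """Per-covariate Bernoulli prevalences, fixed by the config seed."""
    prev_rng = np.random.default_rng(config.seed + 777)
    return prev_rng.uniform(0.05, 0.90, size=config.n_binary_covariates)


def _payment_gamma_mean(config: SynthConfig, X: np.ndarray) -> np.ndarray:
    """Untreated gamma-component mean of monthly payments (log-linear in confounders)."""
    oce = np.asarray(config.outcome_confounder_effects, dtype=float)
    idx = np.asarray(config.confounder_indices, dtype=int)
    if not len(idx):
        return np.full(X.shape[0], float(config.baseline_payment_mean))
    eta = 0.5 * (X[:, idx] @ oce)
    center = 0.5 * float(_prevalences(config)[idx] @ oce)  # analytic E[eta]
    return config.baseline_payment_mean * np.exp(eta - center)


def _event_logit_base(config: SynthConfig, X: np.ndarray) -> np.ndarray:
    oce = np.asarray(config.outcome_confounder_effects, dtype=float)
    idx = np.asarray(config.confounder_indices, dtype=int)
    if not len(idx):
        return np.full(X.shape[0], float(logit(config.baseline_event_prob)))
    eta = X[:, idx] @ oce
    center = float(_prevalences(config)[idx] @ oce)
    return logit(config.baseline_event_prob) + eta - center


def _event_shift(config: SynthConfig, b: np.ndarray) -> np.ndarray:
    """Treated post-enrollment shift on the event logit (negative = fewer events)."""
    return config.effect_level - config.benefit_event_scale * b


def _monthly_payment_reduction(config: SynthConfig, mu: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Realized expected monthly dollar reduction: b(x) unless the floor binds."""
    pi = config.zip_zero_prob
    mu_treated = np.maximum(config.payment_floor, mu - b / (1.0 - pi))
    return (1.0 - pi) * (mu - mu_treated)


def generate_population(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the patient-episode table (no outcomes).

    Returns one row per episode: cases have a single enrollment episode;
    comparison patients carry 1..``max_candidate_episodes`` candidate
    episodes with distinct anchor months.  Columns: identifiers, role,
    binary covariates ``x*``, continuous covariates ``c*`` (with
    missingness), ``hcc_score``, ``risk_probability``, and the
    generator-truth columns ``true_benefit_monthly`` / ``true_benefit_12m``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    X, hcc, _ = _covariate_draw(config, n, rng)

    idx = np.asarray(config.confounder_indices, dtype=int)
    lo = np.asarray(config.confounder_log_odds, dtype=float)
    eta_cov = X[:, idx] @ lo if len(idx) else np.zeros(n)
    b0 = _treatment_intercept(eta_cov, config.enrollment_rate)
    p_treat = expit(b0 + eta_cov)
    treated = rng.random(n) < p_treat

    hcc_z = (hcc - hcc.mean()) / max(hcc.std(), 1e-12)
    risk = expit(-2.4 + 0.5 * (X[:, idx].sum(axis=1) if len(idx) else 0.0)
                 + 0.25 * hcc_z + 0.5 * rng.standard_normal(n))
    risk = np.clip(risk, 1e-4, 0.999)

    q = config.n_continuous_covariates
    C = rng.standard_normal((n, q)) + 0.2 * hcc_z[:, None] if q else np.empty((n, 0))
    if q and config.missing_rate > 0:
        C = C.copy()
        C[rng.random((n, q)) < config.missing_rate] = np.nan

    b = _benefit_dollars(config, X)
    mu = _payment_gamma_mean(config, X)
    red_m = _monthly_payment_reduction(config, mu, b)

    rows = []
    case_ids = np.flatnonzero(treated)
    comp_ids = np.flatnonzero(~treated)
    for pid in case_ids:
        rows.append((pid, "case", int(rng.integers(0, 12))))
    for pid in comp_ids:
        k = int(rng.integers(1, config.max_candidate_episodes + 1))
        anchors = rng.choice(12, size=k, replace=False)
        for a in np.sort(anchors):
            rows.append((pid, "comparison", int(a)))
    ep = pd.DataFrame(rows, columns=["patient_id", "role", "anchor_month"])
    ep.insert(0, "episode_id", np.arange(len(ep)))
    ep["treated"] = (ep["role"] == "case").astype(int)

    pid = ep["patient_id"].to_numpy()
    extras = pd.DataFrame(X[pid], columns=binary_columns(config), index=ep.index)
    if q:
        extras = pd.concat([extras, pd.DataFrame(
            C[pid], columns=continuous_columns(config), index=ep.index)], axis=1)
    extras["hcc_score"] = hcc[pid]
    extras["risk_probability"] = risk[pid]
    extras["true_propensity"] = p_treat[pid]
    extras["true_benefit_monthly"] = red_m[pid]
    extras["true_benefit_12m"] = 12.0 * red_m[pid]
    return pd.concat([ep, extras], axis=1)


def generate_outcomes(population: pd.DataFrame, config: SynthConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the patient-month outcome panel for every episode.

    Baseline months -12..-1 are always present (a complete baseline year
    is an eligibility requirement); follow-up months 1..12 are subject to
    geometric censoring with ``censor_hazard_per_month`` (death is
    absorbing censoring).  ``event_days > 0`` iff ``any_event == 1`` by
    construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n_ep = len(population)
    Xcols = binary_columns(config)
    X = population[Xcols].to_numpy(dtype=np.int8)
    treated = population["treated"].to_numpy(dtype=bool)

    b = _benefit_dollars(config, X)
    eta0 = _event_logit_base(config, X)
    shift = _event_shift(config, b)
    mu0 = _payment_gamma_mean(config, X)
    pi = config.zip_zero_prob
    mu1 = np.maximum(config.payment_floor, mu0 - b / (1.0 - pi))

    # follow-up length: month k (k>=1) observed iff the geometric censor
    # time exceeds k; hazard h per month => P(F >= k) = (1-h)^k
    h = config.censor_hazard_per_month
    u = rng.random(n_ep)
    with np.errstate(divide="ignore"):
        fup = np.full(n_ep, 12) if h == 0 else np.minimum(
            12, np.floor(np.log(np.maximum(u, 1e-300)) / np.log(1.0 - h)).astype(int))
    fup = np.clip(fup, 0, 12)

    n_months = 12 + fup
    ep_idx = np.repeat(np.arange(n_ep), n_months)
    # month indices: -12..-1 then 1..fup
    t = np.concatenate([np.concatenate([np.arange(-12, 0), np.arange(1, f + 1)])
                        for f in fup]) if n_ep else np.empty(0, dtype=int)

    post = (t >= 1).astype(float)
    eta = (eta0[ep_idx] + config.baseline_trend_per_month * t
           + treated[ep_idx] * post * shift[ep_idx])
    p_event = expit(eta)
    any_event = (rng.random(len(t)) < p_event).astype(np.int8)

    extra = rng.poisson(EVENT_DAYS_RATE, size=len(t))
    event_days = np.minimum(31, any_event * (1 + extra)).astype(np.int16)

    mu = np.where(treated[ep_idx] & (post > 0), mu1[ep_idx], mu0[ep_idx])
    nonzero = rng.random(len(t)) >= pi
    payment = np.where(
        nonzero, rng.gamma(config.gamma_shape, mu / config.gamma_shape), 0.0)

    months = pd.DataFrame({
        "episode_id": population["episode_id"].to_numpy()[ep_idx],
        "month": t,
        "any_event": any_event,
        "event_days": event_days,
        "payment": payment,
    })
    return months


def generate_cohort(config: SynthConfig, compute_truth: bool = True,
                    n_mc_truth: int = 200_000) -> SynthCohort:
    """Full cohort: episodes + month panel + generator truth, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    episodes = generate_population(config, rng)
    months = generate_outcomes(episodes, config, rng)
    truth = true_effect_per_100(config, n_mc=n_mc_truth) if compute_truth else None
    return SynthCohort(episodes=episodes, months=months, truth=truth, config=config)


def true_effect_per_100(config: SynthConfig, n_mc: int = 200_000,
                        rng: np.random.Generator | None = None) -> TrueEffects:
    """Generator-implied per-100-patient 1-year reductions among the treated.

    Expectations conditional on covariates are exact (no outcome noise is
    simulated); Monte Carlo enters only through covariate draws, weighted
    by the treatment probability so the estimand is the effect among the
    enrolled.  The estimand assumes 12 observed follow-up months
    (enrollment for one full year), matching the per-100 prediction target.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 424242]))
    X, _, _ = _covariate_draw(config, n_mc, rng)
    idx = np.asarray(config.confounder_indices, dtype=int)
    lo = np.asarray(config.confounder_log_odds, dtype=float)
    eta_cov = X[:, idx] @ lo if len(idx) else np.zeros(n_mc)
    b0 = _treatment_intercept(eta_cov, config.enrollment_rate)
    w = expit(b0 + eta_cov)  # P(enrolled | x)

    b = _benefit_dollars(config, X)
    mu = _payment_gamma_mean(config, X)
    pay_red_12 = 12.0 * _monthly_payment_reduction(config, mu, b)

    eta0 = _event_logit_base(config, X)
    shift = _event_shift(config, b)
    tt = np.arange(1, 13)
    # per-patient expected event-months avoided over follow-up
    ev0 = expit(eta0[:, None] + config.baseline_trend_per_month * tt[None, :])
    ev1 = expit(eta0[:, None] + config.baseline_trend_per_month * tt[None, :] + shift[:, None])
    ev_red = (ev0 - ev1).sum(axis=1)

    sw = w.sum()
    mean_pay = float(np.sum(w * pay_red_12) / sw)
    mean_ev = float(np.sum(w * ev_red) / sw)
    # weighted-mean Monte Carlo standard errors
    se_pay = float(np.sqrt(np.sum((w * (pay_red_12 - mean_pay)) ** 2)) / sw)
    se_ev = float(np.sqrt(np.sum((w * (ev_red - mean_ev)) ** 2)) / sw)
    return TrueEffects(
        true_per100_payment_reduction=100.0 * mean_pay,
        true_per100_event_reduction=100.0 * mean_ev,
        mean_benefit_12m=mean_pay,
        mc_se_payment=100.0 * se_pay,
        mc_se_events=100.0 * se_ev,
        n_mc=n_mc,
    )
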