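"""Benefit ("impactability") scoring and benefit/risk categorization.

The benefit score is the estimated reduction in 12-month payments if a
patient is enrolled in case management — a treatment-effect prediction,
not an outcome prediction.  It is realized here as an inverse-propensity-
weighted linear model of the 12-month payment total on baseline
covariates, treatment, and treatment x covariate interactions; the score
of a patient is the fitted no-treatment-minus-treatment contrast
(positive = expected savings).  The estimator is deliberately simple and
pluggable: anything exposing ``score(episodes) -> dollars`` can replace
:class:`BenefitModel` downstream.

Categorization follows the program's operating rules: positive scores are
split into quintiles 1..5 and negative scores into -5..-1; quintiles 2-5
are "high benefit" and -5..1 "no/low benefit"; the historic program's
operational screen flags scores above $1200.  Risk is "high" iff the
6-month admission/death risk probability exceeds 13% (strictly).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIGH_RISK_THRESHOLD = 0.13
HIGH_BENEFIT_MIN_QUINTILE = 2
HISTORIC_DOLLAR_THRESHOLD = 1200.0


@dataclass
class BenefitModel:
    """IPW linear payment model with full treatment interactions."""

    covariates: list[str]
    coef_main: np.ndarray        # intercept + covariates
    coef_treat: float            # treatment main effect
    coef_interact: np.ndarray    # treatment x covariate
    horizon_months: int = 12

    def score(self, episodes: pd.DataFrame) -> np.ndarray:
        """Benefit in dollars over the 12-month horizon (positive = savings)."""
        missing = [v for v in self.covariates if v not in episodes.columns]
        if missing:
            raise KeyError(f"episodes lack benefit-model covariates: {missing}")
        X = episodes[self.covariates].to_numpy(dtype=float)
        return -(self.coef_treat + X @ self.coef_interact)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "covariates": self.covariates,
            "coef_main": list(map(float, self.coef_main)),
            "coef_treat": float(self.coef_treat),
            "coef_interact": list(map(float, self.coef_interact)),
            "horizon_months": self.horizon_months,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BenefitModel":
        d = json.loads(Path(path).read_text())
        return cls(covariates=d["covariates"],
                   coef_main=np.asarray(d["coef_main"]),
                   coef_treat=d["coef_treat"],
                   coef_interact=np.asarray(d["coef_interact"]),
                   horizon_months=d["horizon_months"])


@dataclass
class BenefitCategories:
    quintile: np.ndarray          # in {-5..-1, 1..5}
    label: np.ndarray             # "high_benefit" | "no_low_benefit"
    historic_flag: np.ndarray     # score > $1200
    positive_boundaries: np.ndarray = field(default_factory=lambda: np.array([]))
    negative_boundaries: np.ndarray = field(default_factory=lambda: np.array([]))


def twelve_month_payment(episodes: pd.DataFrame, months: pd.DataFrame) -> pd.Series:
    """Follow-up payment total per episode, rescaled to a 12-month horizon.

    Episodes censored before month 12 have their observed follow-up total
    scaled by 12/(observed months); episodes with no follow-up months are
    dropped (NaN).
    """
    post = months[months["month"] >= 1]
    g = post.groupby("episode_id")["payment"].agg(["sum", "size"])
    total = g["sum"] * (12.0 / g["size"])
    return episodes["episode_id"].map(total)


def fit_benefit_model(training_episodes: pd.DataFrame, payment_12m: pd.Series,
                      covariates: list[str], weights: np.ndarray | None = None
                      ) -> BenefitModel:
    """Fit the IPW-weighted interaction model of 12-month payments.

    ``training_episodes`` must contain both enrolled and comparison
    episodes (column ``treated``); ``weights`` are analysis weights
    (IPW x 1/m), default 1.  Rows with missing payment are dropped.
    """
    t = training_episodes["treated"].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("training cohort must contain both treatment arms")
    y = np.asarray(payment_12m, dtype=float)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(y)
    if (~ok).any():
        logger.info("dropping %d episodes without follow-up payments", int((~ok).sum()))
    X = training_episodes.loc[ok, covariates].to_numpy(dtype=float)
    t, y, w = t[ok], y[ok], w[ok]
    n, p = X.shape
    D = np.column_stack([np.ones(n), X, t, t[:, None] * X])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(D * sw[:, None], y * sw, rcond=None)
    return BenefitModel(covariates=list(covariates),
                        coef_main=beta[:p + 1],
                        coef_treat=float(beta[p + 1]),
                        coef_interact=beta[p + 2:])


def categorize_benefit(scores: np.ndarray,
                       positive_boundaries: np.ndarray | None = None,
                       negative_boundaries: np.ndarray | None = None
                       ) -> BenefitCategories:
    """Quintile categories within each sign of the benefit score.

    Positive scores are split at their own empirical quintile boundaries
    into 1..5, negative scores into -5..-1 (a score of exactly 0 counts
    as non-positive).  Boundaries may be supplied to score new patients
    against frozen cut-points; otherwise they are computed on the scoring
    population and returned.  Fewer than 10 scores of a sign triggers a
    warning (quantiles still computed from what is available).
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("benefit scores must be finite")
    pos, neg = s > 0, s <= 0
    qs = [0.2, 0.4, 0.6, 0.8]
    if positive_boundaries is None:
        if 0 < pos.sum() < 10:
            warnings.warn("fewer than 10 positive scores; quintile boundaries unstable")
        positive_boundaries = np.quantile(s[pos], qs) if pos.any() else np.array([])
        if not pos.any():
            logger.info("no positive scores; positive quintiles empty")
    if negative_boundaries is None:
        if 0 < neg.sum() < 10:
            warnings.warn("fewer than 10 non-positive scores; quintile boundaries unstable")
        negative_boundaries = np.quantile(s[neg], qs) if neg.any() else np.array([])
        if not neg.any():
            logger.info("no non-positive scores; negative quintiles empty")

    # scores exactly on a boundary go to the upper category, so the top
    # quintile stays populated even for heavily tied (discrete) scores
    q = np.zeros(len(s), dtype=int)
    if pos.any() and len(positive_boundaries):
        q[pos] = 1 + np.searchsorted(positive_boundaries, s[pos], side="right")
    elif pos.any():
        q[pos] = 1
    if neg.any() and len(negative_boundaries):
        q[neg] = -5 + np.searchsorted(negative_boundaries, s[neg], side="right")
        q[neg] = np.clip(q[neg], -5, -1)
    elif neg.any():
        q[neg] = -1
    label = np.where(q >= HIGH_BENEFIT_MIN_QUINTILE, "high_benefit", "no_low_benefit")
    return BenefitCategories(quintile=q, label=label,
                             historic_flag=s > HISTORIC_DOLLAR_THRESHOLD,
                             positive_boundaries=np.asarray(positive_boundaries),
                             negative_boundaries=np.asarray(negative_boundaries))


def categorize_risk(risk_probability: np.ndarray | float) -> np.ndarray | str:
    """'high' iff the 6-month risk probability strictly exceeds 13%."""
    r = np.asarray(risk_probability, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risk probabilities must lie in [0, 1]")
    out = np.where(r > HIGH_RISK_THRESHOLD, "high", "moderate")
    return str(out) if out.ndim == 0 else out
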