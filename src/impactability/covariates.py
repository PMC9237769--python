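"""Covariate preparation: imputation, binarization, and screening.

Raw continuous covariates get simple mean imputation within deciles of
the HCC comorbidity score, then are split into high/low indicators at the
case median.  Categorical covariates get an explicit ``missing`` level.
Candidate indicators are then screened on case prevalence (5%-95%) and a
pairwise correlation cap (|r| <= 0.8), with exclusion reasons recorded in
a :class:`CovariateCatalog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CatalogEntry:
    name: str
    kind: str  # binary | continuous | categorical
    prevalence_cases: float | None = None
    case_median: float | None = None
    retained: bool = True
    reason: str = ""


@dataclass
class CovariateCatalog:
    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [e.name for e in self.entries.values() if e.retained]

    @property
    def excluded(self) -> dict[str, str]:
        return {e.name: e.reason for e in self.entries.values() if not e.retained}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries.values()])


def impute_continuous(values: pd.Series | np.ndarray,
                      hcc_scores: pd.Series | np.ndarray) -> np.ndarray:
    """Mean-impute missing values within deciles of the HCC score.

    Deciles are computed on the full cohort.  A decile with no observed
    values falls back to the overall observed mean (with a warning).
    Observed values pass through unchanged.
    """
    v = np.asarray(values, dtype=float).copy()
    hcc = np.asarray(hcc_scores, dtype=float)
    if np.isnan(hcc).any():
        raise ValueError("hcc_scores must be complete")
    missing = np.isnan(v)
    if not missing.any():
        return v
    observed = ~missing
    if not observed.any():
        raise ValueError("no observed values to impute from")
    overall = v[observed].mean()
    deciles = pd.qcut(pd.Series(hcc), 10, labels=False, duplicates="drop").to_numpy()
    for d in np.unique(deciles[missing]):
        in_d = deciles == d
        obs_d = in_d & observed
        if obs_d.any():
            fill = v[obs_d].mean()
        else:
            fill = overall
            logger.warning("HCC decile %s has no observed values; using overall mean %.4g",
                           d, overall)
        v[in_d & missing] = fill
    return v


def binarize_continuous(values: pd.Series | np.ndarray,
                        case_flags: pd.Series | np.ndarray) -> tuple[np.ndarray, float]:
    """High/low indicator at the case median (strictly greater => high).

    Returns ``(indicator, threshold)``.  Values exactly at the median map
    to 0 (the deterministic tie rule).  Raises if no case has an observed
    value.
    """
    v = np.asarray(values, dtype=float)
    cases = np.asarray(case_flags, dtype=bool)
    case_obs = v[cases & ~np.isnan(v)]
    if case_obs.size == 0:
        raise ValueError("no observed case values; variable cannot be binarized")
    med = float(np.median(case_obs))
    ind = np.where(np.isnan(v), 0, (v > med).astype(int))
    return ind, med


def encode_categorical_missing(values: pd.Series,
                               missing_label: str = "missing") -> pd.Series:
    """Map missing categorical values to an explicit 'missing' level."""
    s = values.astype("object").copy()
    s[s.isna()] = missing_label
    return s.astype("category")


def screen_variables(indicator_matrix: pd.DataFrame,
                     case_flags: pd.Series | np.ndarray,
                     prevalence_low: float = 0.05,
                     prevalence_high: float = 0.95,
                     correlation_cap: float = 0.8) -> CovariateCatalog:
    """Screen binarized covariates on case prevalence and pairwise correlation.

    A variable is excluded (reason ``"prevalence"``) unless its prevalence
    among cases lies in [prevalence_low, prevalence_high].  Among the
    survivors, pairs with |Pearson r| > correlation_cap are pruned
    greedily in catalog (column) order, dropping the later-ordered member
    (reason ``"correlation"``).
    """
    cases = np.asarray(case_flags, dtype=bool)
    if cases.sum() == 0:
        raise ValueError("case set is empty; cannot screen on case prevalence")
    catalog = CovariateCatalog()
    X = indicator_matrix.to_numpy(dtype=float)
    prev = X[cases].mean(axis=0)
    names = list(indicator_matrix.columns)
    for j, name in enumerate(names):
        e = CatalogEntry(name=name, kind="binary", prevalence_cases=float(prev[j]))
        if not (prevalence_low <= prev[j] <= prevalence_high):
            e.retained, e.reason = False, "prevalence"
        catalog.entries[name] = e

    kept = [n for n in names if catalog.entries[n].retained]
    if len(kept) >= 2:
        sub = indicator_matrix[kept].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        alive = np.ones(len(kept), dtype=bool)
        for i in range(len(kept)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(kept)):
                if alive[j] and abs(corr[i, j]) > correlation_cap:
                    alive[j] = False
                    e = catalog.entries[kept[j]]
                    e.retained, e.reason = False, "correlation"
    return catalog
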