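"""High-dimensional propensity score construction.

Covariates that survived screening are (1) ranked by the magnitude of
the confounding bias they could induce — the Bross bias multiplier
computed from their prevalence among cases (pc1) and comparisons (pc0)
and their relative risk for the outcome (rr_cd) — with a two-sided
significance screen on the covariate-outcome association; (2) entered
into an L1-penalized logistic treatment model whose penalty is chosen by
the Schwarz Bayesian criterion of the *unpenalized refit* of each active
set along the path (relaxed-lasso style, which gives BIC a well-defined
likelihood); and (3) the final propensity score is the plain
maximum-likelihood logistic fit on the selected set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._glm import fit_logistic_safe


@dataclass
class BiasRanking:
    """Per-covariate confounding-bias ranking table.

    Columns of ``table``: pc1, pc0, rr_cd, bias_multiplier,
    rank_statistic (=|log BM|), p_value, significant.  ``ranked`` lists
    the significant variables by descending rank statistic (ties broken
    by name).
    """

    table: pd.DataFrame
    ranked: list[str] = field(default_factory=list)


@dataclass
class PropensityModel:
    selected_variables: list[str]
    coefficients: np.ndarray  # intercept first
    scores: np.ndarray
    selection_lambda: float | None = None
    bic_path: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit
        Z = np.column_stack([np.ones(len(X))] +
                            [X[v].to_numpy(dtype=float) for v in self.selected_variables])
        return np.clip(expit(Z @ self.coefficients), 1e-6, 1 - 1e-6)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected_variables": self.selected_variables,
            "coefficients": list(map(float, self.coefficients)),
            "selection_lambda": self.selection_lambda,
            "bic_path": [[float(a), float(b)] for a, b in self.bic_path],
        }, indent=2))


def bross_bias_multiplier(pc1: float | np.ndarray, pc0: float | np.ndarray,
                          rr_cd: float | np.ndarray) -> float | np.ndarray:
    """Multiplicative confounding bias a binary covariate could induce.

    BM = [pc1 (rr_cd - 1) + 1] / [pc0 (rr_cd - 1) + 1], where pc1 and pc0
    are the covariate's prevalence among treated and comparison patients
    and rr_cd its relative risk for the outcome.  Callers must supply
    continuity-corrected inputs so pc in (0,1) and rr_cd > 0; the
    denominator is then strictly positive.
    """
    pc1 = np.asarray(pc1, dtype=float)
    pc0 = np.asarray(pc0, dtype=float)
    rr = np.asarray(rr_cd, dtype=float)
    if np.any((pc1 <= 0) | (pc1 >= 1)) or np.any((pc0 <= 0) | (pc0 >= 1)):
        raise ValueError("prevalences must lie strictly in (0,1); apply continuity correction")
    if np.any(rr <= 0):
        raise ValueError("rr_cd must be positive")
    out = (pc1 * (rr - 1.0) + 1.0) / (pc0 * (rr - 1.0) + 1.0)
    return float(out) if out.ndim == 0 else out


def prioritize_covariates(X: pd.DataFrame, treatment: np.ndarray,
                          outcome_flag: np.ndarray, alpha: float = 0.05) -> BiasRanking:
    """Rank covariates by |log Bross bias multiplier|, screening on significance.

    ``outcome_flag`` is the binary any-unplanned-event indicator over the
    episode year.  rr_cd and its significance test (two-sided chi-square)
    use the covariate-outcome 2x2 table among comparison patients, with a
    0.5 continuity correction on all cells for the risk estimate.
    """
    t = np.asarray(treatment, dtype=bool)
    y = np.asarray(outcome_flag, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("degenerate outcome: cannot estimate covariate-outcome associations")
    M = X.to_numpy(dtype=float)
    n1, n0 = t.sum(), (~t).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both treated and comparison patients are required")

    # prevalence with continuity correction
    pc1 = (M[t].sum(axis=0) + 0.5) / (n1 + 1.0)
    pc0 = (M[~t].sum(axis=0) + 0.5) / (n0 + 1.0)

    Mc, yc = M[~t], y[~t]
    a = (Mc * yc[:, None]).sum(axis=0)          # covariate=1, outcome=1
    b = Mc.sum(axis=0) - a                      # covariate=1, outcome=0
    c = yc.sum() - a                            # covariate=0, outcome=1
    d = (~yc).sum() - b                         # covariate=0, outcome=0
    risk1 = (a + 0.5) / (a + b + 1.0)
    risk0 = (c + 0.5) / (c + d + 1.0)
    rr_cd = risk1 / risk0

    # two-sided chi-square test of the (uncorrected) 2x2 association
    pvals = np.empty(M.shape[1])
    for j in range(M.shape[1]):
        tab = np.array([[a[j], b[j]], [c[j], d[j]]], dtype=float)
        if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
            pvals[j] = 1.0
        else:
            pvals[j] = stats.chi2_contingency(tab, correction=False)[1]

    bm = bross_bias_multiplier(pc1, pc0, rr_cd)
    table = pd.DataFrame({
        "variable": list(X.columns),
        "pc1": pc1, "pc0": pc0, "rr_cd": rr_cd,
        "bias_multiplier": bm,
        "rank_statistic": np.abs(np.log(bm)),
        "p_value": pvals,
        "significant": pvals < alpha,
    })
    sig = table[table["significant"]].sort_values(
        ["rank_statistic", "variable"], ascending=[False, True])
    return BiasRanking(table=table, ranked=list(sig["variable"]))


def select_lasso_bic(X_ranked: pd.DataFrame, treatment: np.ndarray,
                     n_lambdas: int = 40
                     ) -> tuple[list[str], list[tuple[float, float]], float]:
    """Select treatment-model covariates by an L1 path tuned with BIC.

    The lasso path is fit on standardized covariates over a geometric
    penalty grid from the smallest penalty that zeroes every coefficient
    down by three decades.  Each distinct active set along the path is
    refit by unpenalized logistic regression and scored by
    BIC = -2 loglik + k log n (k = active size + intercept); the active
    set with minimal BIC wins (ties: the smaller set, then the earlier
    path point).  Returns ``(selected_names, bic_path, best_lambda)``.
    """
    names = list(X_ranked.columns)
    t = np.asarray(treatment, dtype=float)
    n = len(t)
    if not names:
        return [], [], float("inf")
    Z = StandardScaler().fit_transform(X_ranked.to_numpy(dtype=float))
    Z = np.nan_to_num(Z, nan=0.0)  # constant columns standardize to NaN

    tb = t.mean()
    lam_max = np.max(np.abs(Z.T @ (t - tb))) / n
    if lam_max <= 0:
        return [], [], float("inf")
    lambdas = np.geomspace(lam_max * 1.05, lam_max * 1e-3, n_lambdas)

    ones = np.ones((n, 1))
    null_fit = fit_logistic_safe(ones, t)
    bic_empty = -2.0 * null_fit.loglik + 1.0 * np.log(n)

    seen: dict[frozenset, tuple[float, float]] = {}
    bic_path: list[tuple[float, float]] = []
    best_bic, best_active, best_lam = bic_empty, frozenset(), float("inf")
    for lam in lambdas:
        C = 1.0 / (n * lam)
        clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                 max_iter=2000, tol=1e-8)
        clf.fit(Z, t)
        active = frozenset(np.flatnonzero(np.abs(clf.coef_[0]) > 1e-10))
        if active in seen:
            bic = seen[active][0]
        else:
            cols = sorted(active)
            Xa = np.column_stack([ones] + [X_ranked.iloc[:, j].to_numpy(dtype=float)
                                           for j in cols])
            fit = fit_logistic_safe(Xa, t)
            bic = -2.0 * fit.loglik + (len(cols) + 1) * np.log(n)
            if not np.isfinite(bic):
                bic = np.inf
            seen[active] = (bic, lam)
        bic_path.append((float(lam), float(bic)))
        better = (bic < best_bic - 1e-9
                  or (abs(bic - best_bic) <= 1e-9 and len(active) < len(best_active)))
        if better:
            best_bic, best_active, best_lam = bic, active, lam
    if not np.isfinite(best_bic):
        warnings.warn("no finite-BIC model on the lasso path; using intercept-only")
        return [], bic_path, float(best_lam)
    return [names[j] for j in sorted(best_active)], bic_path, float(best_lam)


def fit_propensity(X_selected: pd.DataFrame, treatment: np.ndarray,
                   selection_lambda: float | None = None,
                   bic_path: list[tuple[float, float]] | None = None) -> PropensityModel:
    """Maximum-likelihood logistic propensity model on the selected set.

    With an empty selection the model is intercept-only and every score
    equals the treated fraction.  Scores are clipped to [1e-6, 1-1e-6].
    """
    t = np.asarray(treatment, dtype=float)
    names = list(X_selected.columns)
    Z = np.column_stack([np.ones(len(t))] +
                        [X_selected[v].to_numpy(dtype=float) for v in names])
    fit = fit_logistic_safe(Z, t)
    from scipy.special import expit
    scores = np.clip(expit(Z @ fit.beta), 1e-6, 1 - 1e-6)
    return PropensityModel(selected_variables=names, coefficients=fit.beta,
                           scores=scores, selection_lambda=selection_lambda,
                           bic_path=bic_path or [])
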