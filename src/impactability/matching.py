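"""Exact + globally optimal variable-ratio propensity matching.

Cases are matched to up to ``k_max`` comparison episodes over several
rounds of exact matching on a nested (monotonically coarsening) schedule
of exact-match variables; within each round's exact strata, assignments
are chosen by a min-cost-flow formulation that is *globally* optimal:
subject to every case receiving between 1 and ``k_max`` comparisons (as
supply allows) and no comparison episode — and no comparison patient —
being used twice, it maximizes the number of matches and, among such
assignments, minimizes the total |propensity-score distance|.  A
tie-only bonus mode (`extra_bonus` as a small float) restricts extra
matches beyond the first to (near-)zero-distance pairs instead.

Balance diagnostics report absolute standardized mean differences before
and after matching, flagging covariates whose post-match SMD exceeds the
threshold for residual-confounder adjustment in the outcome models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

_SCALE = 10**9  # distance resolution for integer flow costs


@dataclass
class ExactSchedule:
    """Ordered rounds of exact-match variable sets, nested and shrinking."""

    rounds: list[list[str]]

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValueError("schedule needs at least one round")
        for r in range(1, len(self.rounds)):
            if not set(self.rounds[r]) <= set(self.rounds[r - 1]):
                raise ValueError(f"round {r + 1} variables must be a subset of round {r}")

    def validate_columns(self, columns) -> None:
        missing = set(self.rounds[0]) - set(columns)
        if missing:
            raise ValueError(f"exact-match variables not in table: {sorted(missing)}")


@dataclass
class MatchResult:
    """case -> 1..k comparison episodes, with distances and 1/m weights."""

    pairs: pd.DataFrame  # case_id, comparison_id, distance, round, weight
    unmatched_cases: list = field(default_factory=list)

    @property
    def n_matches(self) -> pd.Series:
        return self.pairs.groupby("case_id").size()

    def matched_case_ids(self) -> np.ndarray:
        return self.pairs["case_id"].unique()


@dataclass
class BalanceReport:
    table: pd.DataFrame  # variable, smd_before, smd_after
    flagged: list[str]
    threshold: float


def build_strata(episodes: pd.DataFrame, schedule: ExactSchedule,
                 round_index: int) -> pd.Series:
    """Stratum key (tuple of exact-variable values) per episode for a round.

    ``round_index`` is 1-based.  Episodes with a missing exact variable
    are excluded from the round (key ``None``), with a log entry.  An
    empty variable set puts everyone in a single stratum.
    """
    if not (1 <= round_index <= len(schedule.rounds)):
        raise ValueError(f"round_index must be in 1..{len(schedule.rounds)}")
    cols = schedule.rounds[round_index - 1]
    if not cols:
        return pd.Series([()] * len(episodes), index=episodes.index)
    sub = episodes[cols]
    ok = sub.notna().all(axis=1)
    if (~ok).any():
        logger.info("round %d: %d episodes excluded for missing exact variables",
                    round_index, int((~ok).sum()))
    vals: list = [None] * len(episodes)
    arr = sub.to_numpy()
    for i in np.flatnonzero(ok.to_numpy()):
        vals[i] = tuple(arr[i])
    return pd.Series(vals, index=episodes.index, dtype=object)


def _edge_costs(case_scores: np.ndarray, comp_scores: np.ndarray) -> np.ndarray:
    d = np.abs(case_scores[:, None] - comp_scores[None, :])
    return np.round(d * _SCALE).astype(np.int64)


def _fill_assignment(case_scores, comp_scores, slots, comp_patient,
                     max_candidates: int | None = None
                     ) -> list[tuple[int, int]] | None:
    """Fast path for the fill objective when supply is plentiful.

    When every case can be filled to its slot count — after reducing the
    comparison pool to one episode per patient, valid because episodes of
    one patient share a propensity score — the lexicographic objective
    (max matches, then min distance) reduces to a rectangular assignment
    problem with each case row duplicated ``slots`` times, solved exactly
    by ``linear_sum_assignment``.  Returns None when the reduction does
    not apply (scarce supply, or within-patient score differences).
    """
    n_c, n_m = len(case_scores), len(comp_scores)
    pool = np.arange(n_m)
    if comp_patient is not None:
        grp = pd.Series(comp_scores).groupby(np.asarray(comp_patient))
        if not bool(((grp.max() - grp.min()) == 0).all()):
            return None
        # keep the lowest-index episode per patient (the tie rule)
        pool = np.sort(pd.Series(np.arange(n_m))
                       .groupby(np.asarray(comp_patient)).min().to_numpy())
    if int(slots.sum()) > len(pool):
        return None
    rows = np.repeat(np.arange(n_c), slots)
    if len(rows) * len(pool) > 4_000_000:
        # large instance: |score| distances on a line admit a monotone
        # (non-crossing) optimal assignment; O(n m) DP replaces cubic LSA
        order_r = np.argsort(case_scores[rows], kind="stable")
        order_c = np.lexsort((pool, comp_scores[pool]))
        cj = _sorted_assignment_1d(
            np.round(case_scores[rows][order_r] * _SCALE),
            np.round(comp_scores[pool][order_c] * _SCALE))
        return [(int(rows[order_r[i]]), int(pool[order_c[j]]))
                for i, j in enumerate(cj)]
    d = np.abs(case_scores[:, None] - comp_scores[None, pool])
    # integer-rounded distance with comparison-index tie-break, exact in float64
    c = np.round(d * _SCALE) * len(pool) + np.arange(len(pool))[None, :]
    ri, cj = linear_sum_assignment(c[rows])
    return [(int(rows[i]), int(pool[j])) for i, j in zip(ri, cj)]


def _sorted_assignment_1d(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Min-cost assignment of every sorted row value to a distinct sorted
    column value under |r_i - c_j| cost; returns the column index per row.

    Uses the Monge property of absolute-difference costs: some optimal
    assignment is order-preserving, so dp[i][j] = min(dp[i][j-1],
    dp[i-1][j-1] + |r_i - c_j|) with a prefix-min per row.
    """
    n, m = len(r), len(c)
    take = np.zeros((n, m), dtype=bool)
    prev = np.full(m, np.inf)
    for i in range(n):
        cost_i = np.abs(r[i] - c)
        cand = np.full(m, np.inf)
        if i == 0:
            cand[:] = cost_i
        else:
            cand[i:] = prev[i - 1:m - 1] + cost_i[i:]
        dp = np.minimum.accumulate(cand)
        take[i] = cand == dp
        prev = dp
    out = np.empty(n, dtype=np.int64)
    j = m - 1
    for i in range(n - 1, -1, -1):
        while not take[i, j]:
            j -= 1
        out[i] = j
        j -= 1
    return out


def optimal_match(case_scores: np.ndarray, comp_scores: np.ndarray,
                  k_max: int = 4, extra_bonus: str | float = "fill",
                  case_slots: np.ndarray | None = None,
                  case_mandatory: np.ndarray | None = None,
                  comp_patient: np.ndarray | None = None,
                  max_candidates: int | None = None) -> list[tuple[int, int]]:
    """Globally optimal variable-ratio assignment within one stratum.

    Returns (case_index, comparison_index) pairs.  Every case with
    ``case_mandatory`` (default: all) receives at least one comparison if
    any is available; no comparison index — and, if ``comp_patient`` is
    given, no patient — is used twice.  With ``extra_bonus="fill"`` the
    objective is lexicographic (maximize matches, then minimize total
    distance); with a float bonus b, an extra match beyond the first is
    taken only if its marginal distance is below b.  Distance ties are
    broken toward the lower comparison index.  Raises nothing for an
    empty comparison pool: returns [].
    """
    n_c, n_m = len(case_scores), len(comp_scores)
    if n_c == 0 or n_m == 0:
        return []
    slots = np.full(n_c, k_max, dtype=int) if case_slots is None \
        else np.asarray(case_slots, dtype=int)
    mand = np.ones(n_c, dtype=bool) if case_mandatory is None \
        else np.asarray(case_mandatory, dtype=bool)

    if extra_bonus == "fill":
        fast = _fill_assignment(np.asarray(case_scores, float),
                                np.asarray(comp_scores, float),
                                slots, comp_patient, max_candidates)
        if fast is not None:
            return fast
    cost = _edge_costs(np.asarray(case_scores, float), np.asarray(comp_scores, float))
    # tie-break: prefer lower comparison index at equal rounded distance
    M = n_m
    cost_tb = cost.astype(object) * M + np.arange(n_m, dtype=object)[None, :]

    max_edge = int(cost.max()) * M + M
    if extra_bonus == "fill":
        # dominates any augmenting-path cost => lexicographic max-cardinality
        bonus = (n_c * k_max + n_m + 2) * (max_edge + 1)
    else:
        bonus = int(round(float(extra_bonus) * _SCALE)) * M

    n_units_mand = int(mand.sum())
    pool = n_m if comp_patient is None else len(set(comp_patient))
    extra_cap = np.maximum(slots - mand.astype(int), 0)
    n_extra = int(min(extra_cap.sum(), max(pool - n_units_mand, 0)))

    cand: list[np.ndarray]
    if max_candidates is not None and n_m > max_candidates:
        order = np.argsort(cost_tb, axis=1)
        cand = [order[i, :max_candidates] for i in range(n_c)]
    else:
        cand = [np.arange(n_m) for _ in range(n_c)]

    def solve(candidates) -> list[tuple[int, int]]:
        G = nx.DiGraph()
        G.add_node("T", demand=n_units_mand + n_extra)
        G.add_node("X", demand=-n_extra)
        if n_extra:
            G.add_edge("X", "T", capacity=n_extra, weight=0)
        for i in range(n_c):
            G.add_node(("c", i), demand=-(1 if mand[i] else 0))
            if n_extra and extra_cap[i]:
                G.add_edge("X", ("c", i), capacity=int(extra_cap[i]), weight=-bonus)
        patients = {} if comp_patient is None else {}
        for j in range(n_m):
            if comp_patient is None:
                G.add_edge(("m", j), "T", capacity=1, weight=0)
            else:
                p = comp_patient[j]
                G.add_edge(("m", j), ("p", p), capacity=1, weight=0)
                if p not in patients:
                    patients[p] = True
                    G.add_edge(("p", p), "T", capacity=1, weight=0)
        for i in range(n_c):
            for j in candidates[i]:
                G.add_edge(("c", i), ("m", int(j)), capacity=1,
                           weight=int(cost_tb[i, j]))
        flow_cost, flow = nx.network_simplex(G)
        out = []
        for i in range(n_c):
            fd = flow.get(("c", i), {})
            for node, f in fd.items():
                if f > 0 and isinstance(node, tuple) and node[0] == "m":
                    out.append((i, node[1]))
        return out

    try:
        return solve(cand)
    except nx.NetworkXUnfeasible:
        if max_candidates is not None and n_m > max_candidates:
            try:
                return solve([np.arange(n_m) for _ in range(n_c)])
            except nx.NetworkXUnfeasible:
                pass
        # more mandatory cases than available comparisons: match as many as possible
        return _match_with_slack(case_scores, comp_scores, slots, mand,
                                 comp_patient, bonus, cost_tb,
                                 n_extra, max_edge)


def _match_with_slack(case_scores, comp_scores, slots, mand, comp_patient,
                      bonus, cost_tb, n_extra, max_edge) -> list[tuple[int, int]]:
    """Fallback when not every mandatory case can be matched.

    Every unit becomes optional: mandatory units carry a reward that
    dominates everything else, so the flow matches as many cases as
    possible (then honors the extra-match bonus, then distance).
    Triggers only when comparisons are scarcer than mandatory cases.
    """
    n_c, n_m = len(case_scores), len(comp_scores)
    big = (n_c * max(int(slots.max()), 1) + n_m + 2) * (abs(int(bonus)) + max_edge + 1)
    total = int(mand.sum()) + n_extra
    G = nx.DiGraph()
    G.add_node("S", demand=-total)
    G.add_node("T", demand=total)
    G.add_edge("S", "T", capacity=total, weight=0)  # slack for unmatchable units
    for i in range(n_c):
        if mand[i]:
            G.add_edge("S", ("c", i), capacity=1, weight=-big)
        extra_i = int(slots[i]) - int(mand[i])
        if n_extra and extra_i > 0:
            # separate lane for optional units
            G.add_edge("S", ("cx", i), capacity=extra_i, weight=-int(bonus))
            G.add_edge(("cx", i), ("c", i), capacity=extra_i, weight=0)
    patients: dict = {}
    for j in range(n_m):
        if comp_patient is None:
            G.add_edge(("m", j), "T", capacity=1, weight=0)
        else:
            p = comp_patient[j]
            G.add_edge(("m", j), ("p", p), capacity=1, weight=0)
            if p not in patients:
                patients[p] = True
                G.add_edge(("p", p), "T", capacity=1, weight=0)
    for i in range(n_c):
        for j in range(n_m):
            G.add_edge(("c", i), ("m", j), capacity=1, weight=int(cost_tb[i, j]))
    _, flow = nx.network_simplex(G)
    out = []
    for i in range(n_c):
        for node, f in flow.get(("c", i), {}).items():
            if f > 0 and isinstance(node, tuple) and node[0] == "m":
                out.append((i, node[1]))
    return out


def run_rounds(episodes: pd.DataFrame, scores: np.ndarray, schedule: ExactSchedule,
               k_max: int = 4, extra_bonus: str | float = "fill",
               max_candidates: int | None = None) -> MatchResult:
    """Run the full multi-round exact + optimal propensity matching.

    Round r matches cases still lacking ``k_max`` comparisons within the
    round's exact strata; comparison episodes consumed earlier are gone,
    and at most one episode per comparison patient is ever used.  The
    merged result records the round each pair was formed in and gives
    each of a case's m comparisons weight 1/m.  Unmatched cases are
    reported, not fatal.
    """
    schedule.validate_columns(episodes.columns)
    ep = episodes.reset_index(drop=True)
    scores = np.asarray(scores, dtype=float)
    is_case = (ep["role"] == "case").to_numpy()
    eid = ep["episode_id"].to_numpy()
    pid = ep["patient_id"].to_numpy()

    n_have = dict.fromkeys(eid[is_case], 0)
    used_comp_patients: set = set()
    used_comp_episodes: set = set()
    records = []

    for r in range(1, len(schedule.rounds) + 1):
        keys = build_strata(ep, schedule, r)
        open_cases = np.array([is_case[i] and n_have[eid[i]] < k_max
                               for i in range(len(ep))])
        avail_comps = np.array([(not is_case[i]) and eid[i] not in used_comp_episodes
                                and pid[i] not in used_comp_patients
                                for i in range(len(ep))])
        mask = (open_cases | avail_comps) & keys.notna().to_numpy()
        strata: dict[tuple, list[int]] = {}
        for i in np.flatnonzero(mask):
            strata.setdefault(keys.iat[i], []).append(i)
        for key, idxs in strata.items():
            idxs = np.asarray(idxs)
            ci = idxs[open_cases[idxs]]
            mi = idxs[avail_comps[idxs]]
            # a patient consumed in an earlier stratum of this round is gone
            mi = np.array([i for i in mi if pid[i] not in used_comp_patients],
                          dtype=int)
            if len(ci) == 0 or len(mi) == 0:
                continue  # cases (if any) pass to the next round
            slots = np.array([k_max - n_have[eid[i]] for i in ci])
            mandatory = np.array([n_have[eid[i]] == 0 for i in ci])
            pairs = optimal_match(scores[ci], scores[mi], k_max=k_max,
                                  extra_bonus=extra_bonus, case_slots=slots,
                                  case_mandatory=mandatory,
                                  comp_patient=pid[mi],
                                  max_candidates=max_candidates)
            for i_loc, j_loc in pairs:
                i, j = ci[i_loc], mi[j_loc]
                records.append((eid[i], eid[j], abs(scores[i] - scores[j]), r))
                n_have[eid[i]] += 1
                used_comp_episodes.add(eid[j])
                used_comp_patients.add(pid[j])

    pairs_df = pd.DataFrame(records,
                            columns=["case_id", "comparison_id", "distance", "round"])
    if len(pairs_df):
        m = pairs_df.groupby("case_id")["comparison_id"].transform("size")
        pairs_df["weight"] = 1.0 / m
    else:
        pairs_df["weight"] = pd.Series(dtype=float)
    unmatched = [c for c, k in n_have.items() if k == 0]
    if unmatched:
        logger.warning("%d cases remain unmatched after all rounds", len(unmatched))
    return MatchResult(pairs=pairs_df, unmatched_cases=unmatched)


def standardized_mean_difference(x_case: np.ndarray, x_comp: np.ndarray,
                                 weights: np.ndarray | None = None) -> float:
    """|mean difference| / sqrt(mean of the two variances), comparison side weighted.

    Returns 0 when both variances are zero and the means agree, +inf when
    both are zero but the means differ.
    """
    x1 = np.asarray(x_case, dtype=float)
    x0 = np.asarray(x_comp, dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("need at least 2 observations per group")
    w = np.ones(len(x0)) if weights is None else np.asarray(weights, dtype=float)
    m1, v1 = x1.mean(), x1.var()
    m0 = np.average(x0, weights=w)
    v0 = np.average((x0 - m0) ** 2, weights=w)
    num = abs(m1 - m0)
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if num == 0 else float("inf")
    return float(num / denom)


def balance_report(episodes: pd.DataFrame, covariate_names: list[str],
                   match_result: MatchResult,
                   propensity_scores: np.ndarray | None = None,
                   threshold: float = 0.25) -> BalanceReport:
    """Before/after SMDs for every covariate; flag post-match SMD > threshold.

    Before: all case vs all comparison episodes, unweighted.  After:
    matched cases vs matched comparisons, the latter weighted by
    (1/m) x ATT inverse-propensity weight ps/(1-ps).
    """
    ep = episodes.set_index("episode_id")
    is_case = ep["role"] == "case"
    ps = None
    if propensity_scores is not None:
        ps = pd.Series(np.asarray(propensity_scores, dtype=float),
                       index=episodes["episode_id"].to_numpy())

    matched_cases = match_result.pairs["case_id"].unique()
    comp_ids = match_result.pairs["comparison_id"].to_numpy()
    w_m = match_result.pairs["weight"].to_numpy().copy()
    if ps is not None:
        s = ps.loc[comp_ids].to_numpy()
        w_m = w_m * s / (1.0 - s)

    rows, flagged = [], []
    for v in covariate_names:
        before = standardized_mean_difference(
            ep.loc[is_case, v].to_numpy(), ep.loc[~is_case, v].to_numpy())
        after = standardized_mean_difference(
            ep.loc[matched_cases, v].to_numpy(), ep.loc[comp_ids, v].to_numpy(), w_m)
        rows.append((v, before, after))
        if after > threshold:
            flagged.append(v)
    return BalanceReport(
        table=pd.DataFrame(rows, columns=["variable", "smd_before", "smd_after"]),
        flagged=flagged, threshold=threshold)
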