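"""Optimal variable-ratio matching: oracle equivalence, rounds, balance."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

import impactability.matching as mt
from impactability.matching import (BalanceReport, ExactSchedule,
                                    balance_report, build_strata, optimal_match,
                                    run_rounds, standardized_mean_difference)


def total_distance(pairs, cs, ms):
    return sum(abs(cs[i] - ms[j]) for i, j in pairs)


def brute_force_fill(cs, ms, k_max):
    """Exhaustive oracle for the fill objective: maximize match count
    (1..k_max per case, comparisons unique), then minimize total distance.
    Enumerates multiplicity vectors and solves each by expanded assignment."""
    n_c, n_m = len(cs), len(ms)
    M = min(n_m, n_c * k_max)
    best = None
    for mult in product(range(1, k_max + 1), repeat=n_c):
        if sum(mult) != M:
            continue
        rows = np.repeat(np.arange(n_c), mult)
        D = np.abs(cs[rows][:, None] - ms[None, :])
        ri, cj = linear_sum_assignment(D)
        d = D[ri, cj].sum()
        if best is None or d < best - 1e-12:
            best = d
    return best


class TestOptimalMatch:
    def test_single_case_takes_nearest_neighbor(self):
        pairs = optimal_match(np.array([0.5]), np.array([0.1, 0.45, 0.9]), k_max=1)
        assert pairs == [(0, 1)]

    def test_global_optimum_beats_greedy(self):
        cs, ms = np.array([0.2, 0.8]), np.array([0.25, 0.75])
        pairs = optimal_match(cs, ms, k_max=1)
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert total_distance(pairs, cs, ms) == pytest.approx(0.10)
        # the alternative pairing is strictly worse
        assert total_distance([(0, 1), (1, 0)], cs, ms) == pytest.approx(1.10)

    def test_one_to_one_total_distance_matches_assignment_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_c = int(rng.integers(1, 9))
            n_m = int(rng.integers(n_c, 21))
            cs, ms = rng.random(n_c), rng.random(n_m)
            pairs = optimal_match(cs, ms, k_max=1)
            D = np.abs(cs[:, None] - ms[None, :])
            ri, cj = linear_sum_assignment(D)
            assert total_distance(pairs, cs, ms) == pytest.approx(
                D[ri, cj].sum(), abs=1e-9)

    def test_variable_ratio_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n_c = int(rng.integers(1, 5))
            n_m = int(rng.integers(1, 9))
            k = int(rng.integers(1, 4))
            cs, ms = rng.random(n_c), rng.random(n_m)
            if n_m < n_c:
                continue  # mandatory feasibility handled elsewhere
            pairs = optimal_match(cs, ms, k_max=k)
            assert len(pairs) == min(n_m, n_c * k)
            assert total_distance(pairs, cs, ms) == pytest.approx(
                brute_force_fill(cs, ms, k), abs=1e-9)

    def test_flow_path_agrees_with_fast_path(self, monkeypatch):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_c = int(rng.integers(1, 6))
            n_m = int(rng.integers(n_c, 13))
            k = int(rng.integers(1, 4))
            cs, ms = rng.random(n_c), rng.random(n_m)
            fast = optimal_match(cs, ms, k_max=k)
            monkeypatch.setattr(mt, "_fill_assignment", lambda *a, **kw: None)
            flow = optimal_match(cs, ms, k_max=k)
            monkeypatch.undo()
            assert len(fast) == len(flow)
            assert total_distance(fast, cs, ms) == pytest.approx(
                total_distance(flow, cs, ms), abs=1e-9)

    def test_tie_only_bonus_yields_one_to_one(self):
        # with a tiny extra-match bonus, extras are never worth a positive
        # distance, so matching collapses to the optimal 1:1 assignment
        cs, ms = np.array([0.3, 0.6]), np.array([0.31, 0.59, 0.45, 0.7])
        pairs = optimal_match(cs, ms, k_max=4, extra_bonus=1e-9)
        assert len(pairs) == 2
        assert sorted(pairs) == [(0, 0), (1, 1)]

    def test_comparison_episodes_never_reused(self):
        rng = np.random.default_rng(5)
        cs, ms = rng.random(6), rng.random(15)
        pairs = optimal_match(cs, ms, k_max=3)
        used = [j for _, j in pairs]
        assert len(used) == len(set(used))

    def test_patient_constraint_limits_one_episode_per_patient(self):
        cs = np.array([0.5])
        ms = np.array([0.49, 0.51, 0.2])
        pats = np.array([7, 7, 8])  # two episodes of patient 7 both close
        pairs = optimal_match(cs, ms, k_max=4, comp_patient=pats)
        used_pats = {pats[j] for _, j in pairs}
        assert len(pairs) == len(used_pats) == 2

    def test_scarce_comparisons_matches_as_many_cases_as_possible(self):
        cs = np.array([0.1, 0.5, 0.9])
        ms = np.array([0.48, 0.52])
        pairs = optimal_match(cs, ms, k_max=2)
        assert len(pairs) == 2
        assert len({i for i, _ in pairs}) == 2  # two distinct cases served

    def test_more_cases_than_comparison_patients(self):
        # 3 mandatory cases but only 2 distinct patients available
        cs = np.array([0.2, 0.5, 0.8])
        ms = np.array([0.21, 0.49, 0.79, 0.51])
        pats = np.array([1, 2, 1, 2])
        pairs = optimal_match(cs, ms, k_max=2, comp_patient=pats)
        assert len(pairs) == 2
        assert len({pats[j] for _, j in pairs}) == 2
        assert len({i for i, _ in pairs}) == 2

    def test_empty_comparison_pool_returns_empty(self):
        assert optimal_match(np.array([0.4]), np.array([]), k_max=2) == []


class TestSchedule:
    def test_schedule_must_be_nested(self):
        with pytest.raises(ValueError, match="subset"):
            ExactSchedule([["a", "b"], ["c"]])

    def test_empty_round_set_gives_single_stratum(self):
        ep = pd.DataFrame({"episode_id": [0, 1], "role": ["case", "comparison"]})
        keys = build_strata(ep, ExactSchedule([[]]), 1)
        assert keys.nunique() == 1

    def test_two_binary_exact_variables_give_at_most_four_strata(self):
        rng = np.random.default_rng(0)
        ep = pd.DataFrame({"a": rng.integers(0, 2, 50), "b": rng.integers(0, 2, 50)})
        keys = build_strata(ep, ExactSchedule([["a", "b"]]), 1)
        assert keys.nunique() <= 4

    def test_round_two_strata_are_unions_of_round_one_strata(self):
        rng = np.random.default_rng(1)
        ep = pd.DataFrame({"a": rng.integers(0, 2, 80), "b": rng.integers(0, 3, 80)})
        sched = ExactSchedule([["a", "b"], ["a"]])
        k1 = build_strata(ep, sched, 1)
        k2 = build_strata(ep, sched, 2)
        # every round-1 stratum maps into exactly one round-2 stratum
        mapping = pd.DataFrame({"k1": k1, "k2": k2}).groupby("k1")["k2"].nunique()
        assert (mapping == 1).all()


def _episodes_for_rounds():
    """3 cases, 6 comparison episodes (one per patient), one exact variable."""
    rows = []
    scores = {}
    eid = 0
    for i, (s, g) in enumerate([(0.30, 1), (0.50, 1), (0.70, 0)]):
        rows.append((eid, 100 + i, "case", g))
        scores[eid] = s
        eid += 1
    for i, (s, g) in enumerate([(0.31, 1), (0.52, 1), (0.33, 1), (0.45, 1),
                                (0.71, 0), (0.10, 0), (0.90, 0)]):
        rows.append((eid, 200 + i, "comparison", g))
        scores[eid] = s
        eid += 1
    ep = pd.DataFrame(rows, columns=["episode_id", "patient_id", "role", "g"])
    s = np.array([scores[e] for e in ep["episode_id"]])
    return ep, s


class TestRunRounds:
    def test_round_one_fills_everything_when_supply_allows(self):
        ep, s = _episodes_for_rounds()
        res = run_rounds(ep, s, ExactSchedule([["g"], []]), k_max=2)
        assert (res.pairs["round"] == 1).all()
        assert res.pairs.groupby("case_id").size().max() <= 2
        assert not res.unmatched_cases

    def test_case_without_exact_partner_matches_in_final_round(self):
        # case with g=2 never shares a round-1 stratum; matched when g drops
        ep, s = _episodes_for_rounds()
        ep.loc[ep["episode_id"] == 0, "g"] = 2
        res = run_rounds(ep, s, ExactSchedule([["g"], []]), k_max=1)
        r = res.pairs.set_index("case_id")["round"]
        assert r.loc[0] == 2
        assert (r.drop(0) == 1).all()

    def test_one_episode_per_comparison_patient(self):
        ep, s = _episodes_for_rounds()
        dup = ep.iloc[[3]].copy()  # second episode of patient 200, score close
        dup["episode_id"] = 99
        ep2 = pd.concat([ep, dup], ignore_index=True)
        s2 = np.append(s, 0.29)
        res = run_rounds(ep2, s2, ExactSchedule([["g"], []]), k_max=4)
        pats = ep2.set_index("episode_id")["patient_id"]
        matched_pats = pats.loc[res.pairs["comparison_id"]]
        assert matched_pats.is_unique

    def test_weights_per_case_sum_to_one(self):
        ep, s = _episodes_for_rounds()
        res = run_rounds(ep, s, ExactSchedule([["g"], []]), k_max=2)
        sums = res.pairs.groupby("case_id")["weight"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestSMD:
    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2, 3, 4])
        assert standardized_mean_difference(x, x) == 0.0

    def test_known_arithmetic_value(self):
        # |1-0| / sqrt((0.5+0.5)/2) = sqrt(2)
        rng = np.random.default_rng(0)
        x1 = rng.normal(1, np.sqrt(0.5), 200_000)
        x0 = rng.normal(0, np.sqrt(0.5), 200_000)
        assert standardized_mean_difference(x1, x0) == pytest.approx(np.sqrt(2),
                                                                     rel=5e-3)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(1)
        x1, x0 = rng.normal(size=50), rng.normal(0.3, 1, 80)
        w = rng.random(80) + 0.1
        a = standardized_mean_difference(x1, x0, w)
        b = standardized_mean_difference(x1, x0, 2.0 * w)
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_variances(self):
        ones, zeros = np.ones(5), np.zeros(5)
        assert standardized_mean_difference(ones, ones) == 0.0
        assert standardized_mean_difference(ones, zeros) == np.inf


class TestBalanceReport:
    def _confounded(self, seed=0, n=3000):
        from impactability.config import SynthConfig
        from impactability.cohort import generate_population
        from impactability.hdps import fit_propensity
        cfg = SynthConfig(n_patients=n, n_binary_covariates=10,
                          enrollment_rate=0.10, max_candidate_episodes=1,
                          seed=seed)
        ep = generate_population(cfg)
        conf = [f"x{j}" for j in cfg.confounder_indices]
        pm = fit_propensity(ep[conf], ep["treated"].to_numpy())
        res = run_rounds(ep, pm.scores, ExactSchedule([[]]), k_max=4)
        cols = [f"x{j}" for j in range(10)]
        return ep, res, pm.scores, cols

    def test_matching_reduces_confounder_imbalance(self):
        ep, res, scores, cols = self._confounded()
        bal = balance_report(ep, cols, res, scores)
        t = bal.table.set_index("variable")
        conf = [f"x{j}" for j in range(5)]
        assert t.loc[conf, "smd_after"].mean() < t.loc[conf, "smd_before"].mean()

    def test_zero_threshold_flags_every_imbalanced_covariate(self):
        ep, res, scores, cols = self._confounded(seed=1)
        bal = balance_report(ep, cols, res, scores, threshold=0.0)
        nonzero = bal.table.loc[bal.table["smd_after"] > 0, "variable"]
        assert set(nonzero) == set(bal.flagged)
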