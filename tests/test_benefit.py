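"""Benefit-score estimation and benefit/risk categorization rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from impactability.benefit import (BenefitModel, categorize_benefit,
                                   categorize_risk, fit_benefit_model,
                                   twelve_month_payment)


def _training_frame(n, treat_effect_fn, seed=0, p=3, noise_sd=3000.0):
    """Episodes + 12-month payments with a known treatment-effect function."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.5).astype(float)
    t = (rng.random(n) < 0.5).astype(int)
    base = 20_000 + X @ np.full(p, 500.0)
    y = base + t * treat_effect_fn(X) + rng.normal(0, noise_sd, n)
    ep = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    ep["treated"] = t
    ep["episode_id"] = np.arange(n)
    return ep, pd.Series(y)


class TestFitBenefitModel:
    def test_recovers_homogeneous_effect(self):
        ep, y = _training_frame(5000, lambda X: -1000.0)
        m = fit_benefit_model(ep, y, [f"x{j}" for j in range(3)])
        scores = m.score(ep)
        assert scores.mean() == pytest.approx(1000.0, abs=150.0)

    def test_null_effect_scores_near_zero(self):
        ep, y = _training_frame(5000, lambda X: 0.0, seed=1)
        m = fit_benefit_model(ep, y, [f"x{j}" for j in range(3)])
        assert abs(m.score(ep).mean()) < 150.0

    def test_planted_modifier_raises_scores_in_modifier_group(self):
        ep, y = _training_frame(6000, lambda X: -1000.0 - 1000.0 * X[:, 0], seed=2)
        m = fit_benefit_model(ep, y, [f"x{j}" for j in range(3)])
        s = m.score(ep)
        assert s[ep["x0"] == 1].mean() > s[ep["x0"] == 0].mean() + 500

    def test_single_arm_training_raises(self):
        ep, y = _training_frame(100, lambda X: 0.0, seed=3)
        ep["treated"] = 1
        with pytest.raises(ValueError, match="arm"):
            fit_benefit_model(ep, y, ["x0"])


class TestScore:
    def _model(self):
        return BenefitModel(covariates=["a", "b"],
                            coef_main=np.array([100.0, 1.0, 2.0]),
                            coef_treat=-400.0,
                            coef_interact=np.array([-50.0, 30.0]))

    def test_all_zero_covariates_give_baseline_contrast(self):
        m = self._model()
        ep = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert m.score(ep)[0] == pytest.approx(400.0)

    def test_score_is_linear_in_each_covariate(self):
        m = self._model()
        ep = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [5.0, 5.0, 5.0]})
        s = m.score(ep)
        assert s[1] - s[0] == pytest.approx(s[2] - s[1])
        assert s[1] - s[0] == pytest.approx(50.0)

    def test_identical_patients_identical_scores(self):
        m = self._model()
        ep = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        s = m.score(ep)
        assert s[0] == s[1]

    def test_missing_covariate_named_in_error(self):
        m = self._model()
        with pytest.raises(KeyError, match="b"):
            m.score(pd.DataFrame({"a": [1.0]}))

    def test_model_roundtrips_through_json(self, tmp_path):
        m = self._model()
        m.to_json(tmp_path / "m.json")
        m2 = BenefitModel.from_json(tmp_path / "m.json")
        ep = pd.DataFrame({"a": [1.5], "b": [-2.0]})
        assert m2.score(ep)[0] == pytest.approx(m.score(ep)[0])


class TestCategorizeBenefit:
    def test_negative_score_is_no_low_benefit(self):
        rng = np.random.default_rng(0)
        s = np.concatenate([rng.uniform(-5000, -1, 50), rng.uniform(1, 5000, 50)])
        cats = categorize_benefit(s)
        assert (cats.label[s < 0] == "no_low_benefit").all()
        assert (cats.quintile[s < 0] < 0).all()

    def test_top_positive_quintile_is_high_benefit(self):
        rng = np.random.default_rng(1)
        s = np.concatenate([rng.uniform(-100, -1, 50), rng.uniform(1, 100, 50)])
        cats = categorize_benefit(s)
        top = s >= np.quantile(s[s > 0], 0.85)
        assert (cats.quintile[top] == 5).all()
        assert (cats.label[top] == "high_benefit").all()

    def test_quintile_one_is_no_low_benefit_but_two_is_high(self):
        rng = np.random.default_rng(2)
        s = np.concatenate([rng.uniform(-100, -1, 100), rng.uniform(1, 100, 100)])
        cats = categorize_benefit(s)
        assert (cats.label[cats.quintile == 1] == "no_low_benefit").all()
        assert (cats.label[cats.quintile == 2] == "high_benefit").all()

    def test_historic_dollar_threshold(self):
        cats = categorize_benefit(np.array([1250.0, 1150.0] + [-10.0] * 10
                                           + [10.0] * 10))
        assert cats.historic_flag[0]
        assert not cats.historic_flag[1]

    def test_quintile_counts_balanced_within_sign(self):
        rng = np.random.default_rng(3)
        s = np.concatenate([-rng.random(500) * 100, rng.random(500) * 100])
        cats = categorize_benefit(s)
        pos_counts = pd.Series(cats.quintile[cats.quintile > 0]).value_counts()
        neg_counts = pd.Series(cats.quintile[cats.quintile < 0]).value_counts()
        assert pos_counts.max() - pos_counts.min() <= 1
        assert neg_counts.max() - neg_counts.min() <= 1

    def test_frozen_boundaries_reused_for_new_patients(self):
        rng = np.random.default_rng(4)
        s = np.concatenate([-rng.random(100) * 50, rng.random(100) * 50])
        cats = categorize_benefit(s)
        new = np.array([s[s > 0].max() + 1.0])
        cats2 = categorize_benefit(new, cats.positive_boundaries,
                                   cats.negative_boundaries)
        assert cats2.quintile[0] == 5

    def test_one_signed_scores_warns_small_sample(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            categorize_benefit(np.array([5.0, -1.0, -2.0] + [-3.0] * 20))

    def test_estimated_categories_track_true_benefit(self, small_cohort):
        """Spearman: noisy scores around the generator's true per-patient
        benefit must still order the categories correctly."""
        ep = small_cohort.episodes
        truth = ep["true_benefit_12m"].to_numpy()
        rng = np.random.default_rng(5)
        noisy = truth - truth.mean() + rng.normal(0, truth.std() * 0.5, len(truth))
        cats = categorize_benefit(noisy)
        rho = spearmanr(cats.quintile, truth).statistic
        assert rho > 0.5
        means = pd.Series(truth).groupby(cats.quintile).mean()
        assert means.loc[5] > means.loc[means.index.min()]


class TestCategorizeRisk:
    @pytest.mark.parametrize("p,expected", [(0.14, "high"), (0.13, "moderate"),
                                            (0.0, "moderate"), (1.0, "high"),
                                            (0.1301, "high")])
    def test_threshold_rule(self, p, expected):
        assert categorize_risk(p) == expected

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            categorize_risk(1.2)
        with pytest.raises(ValueError):
            categorize_risk(-0.1)

    def test_vectorized(self):
        out = categorize_risk(np.array([0.05, 0.5]))
        assert list(out) == ["moderate", "high"]


class TestTwelveMonthPayment:
    def test_censored_episode_rescaled_to_horizon(self):
        ep = pd.DataFrame({"episode_id": [1, 2]})
        months = pd.DataFrame({
            "episode_id": [1] * 12 + [2] * 6,
            "month": list(range(1, 13)) + list(range(1, 7)),
            "payment": [100.0] * 12 + [100.0] * 6,
        })
        out = twelve_month_payment(ep, months)
        assert out.iloc[0] == pytest.approx(1200.0)
        assert out.iloc[1] == pytest.approx(1200.0)  # 600 x 12/6

    def test_no_follow_up_gives_nan(self):
        ep = pd.DataFrame({"episode_id": [1, 2]})
        months = pd.DataFrame({"episode_id": [1], "month": [3], "payment": [50.0]})
        out = twelve_month_payment(ep, months)
        assert np.isnan(out.iloc[1])
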