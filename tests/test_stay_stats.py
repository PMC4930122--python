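"""Tests of stay-probability tables and group-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from twostep import (
    ParameterSet,
    TaskConfig,
    group_ttest,
    manova_roy,
    mb_interaction,
    mixed_anova_2x2,
    reward_main_effect,
    simulate_session,
    stay_table,
)
from twostep.stay_stats import StayTable

from _helpers import make_session


def table_from_cells(rew_common, rew_rare, unrew_common, unrew_rare, n=50):
    probs = np.array([[unrew_common, unrew_rare], [rew_common, rew_rare]])
    return StayTable(probs=probs, counts=np.full((2, 2), n))


class TestStayTable:
    def test_hand_enumerated_six_trial_session(self):
        # pairs (prev reward, prev transition) -> stay?
        # t0->t1: (rew, common) stay; t1->t2: (unrew, rare) switch;
        # t2->t3: (rew, common) stay; t3->t4: (unrew, common) switch;
        # t4->t5: (rew, rare) stay.
        s = make_session(
            a1=[0, 0, 1, 1, 0, 0],
            is_common=[1, 0, 1, 1, 0, 1],
            s2=[0, 1, 1, 1, 1, 0],
            a2=[0, 1, 0, 1, 0, 1],
            r=[1, 0, 1, 0, 1, 0],
        )
        table = stay_table(s)
        assert table.probs[1, 0] == 1.0  # rewarded, common: 2/2
        assert table.probs[1, 1] == 1.0  # rewarded, rare: 1/1
        assert table.probs[0, 0] == 0.0  # unrewarded, common: 0/1
        assert table.probs[0, 1] == 0.0  # unrewarded, rare: 0/1
        np.testing.assert_array_equal(table.counts, [[1, 1], [2, 1]])
        assert table.counts.sum() == 5

    def test_always_repeating_agent_stays_everywhere(self):
        s = make_session(
            a1=[0] * 9,
            is_common=[1, 0, 1, 0, 1, 0, 1, 0, 1],
            s2=[0, 1, 0, 1, 0, 1, 0, 1, 0],
            a2=[0] * 9,
            r=[1, 1, 0, 0, 1, 1, 0, 0, 1],
        )
        table = stay_table(s)
        assert table.complete
        np.testing.assert_array_equal(table.probs, np.ones((2, 2)))

    def test_uniform_agent_near_half_everywhere(self):
        p = ParameterSet(0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0)
        s = simulate_session(p, TaskConfig(n_trials=10_000), seed=14)
        table = stay_table(s)
        assert np.all(np.abs(table.probs - 0.5) < 0.02)
        assert table.counts.sum() == 9_999

    def test_invalid_trials_break_pairs(self):
        s = make_session(
            a1=[0, -1, 0, 0], is_common=[1, 0, 1, 1], s2=[0, -1, 0, 0],
            a2=[0, -1, 0, 0], r=[1, -1, 1, 1], valid=[1, 0, 1, 1],
        )
        table = stay_table(s)
        assert table.counts.sum() == 1  # only the t2->t3 pair survives

    def test_relabeling_actions_leaves_effects_unchanged(self, session):
        flipped = make_session(
            a1=1 - session.a1, is_common=session.is_common, s2=session.s2,
            a2=session.a2, r=session.reward,
        )
        t0, t1 = stay_table(session), stay_table(flipped)
        assert reward_main_effect(t0) == pytest.approx(reward_main_effect(t1))
        assert mb_interaction(t0) == pytest.approx(mb_interaction(t1))


class TestEffectContrasts:
    def test_hand_arithmetic(self):
        t = table_from_cells(0.9, 0.9, 0.6, 0.6)
        assert reward_main_effect(t) == pytest.approx(0.3)
        assert mb_interaction(t) == pytest.approx(0.0)
        t2 = table_from_cells(0.9, 0.6, 0.6, 0.9)
        assert mb_interaction(t2) == pytest.approx(0.6)
        assert reward_main_effect(t2) == pytest.approx(0.0)
        flat = table_from_cells(0.7, 0.7, 0.7, 0.7)
        assert reward_main_effect(flat) == 0.0
        assert mb_interaction(flat) == 0.0

    def test_undefined_cell_raises(self):
        t = StayTable(
            probs=np.array([[0.5, np.nan], [0.5, 0.5]]),
            counts=np.array([[3, 0], [3, 3]]),
        )
        with pytest.raises(ValueError):
            reward_main_effect(t)
        with pytest.raises(ValueError):
            mb_interaction(t)


class TestMixedAnova:
    def _cohort(self, rng, n, reward_d=0.0, noise=0.05, base=0.6):
        tables = []
        for _ in range(n):
            cells = base + rng.normal(0, noise, size=(2, 2))
            cells[1] += reward_d  # rewarded rows
            tables.append(StayTable(np.clip(cells, 0, 1), np.full((2, 2), 40)))
        return tables

    def test_identical_groups_have_null_interactions(self, rng):
        tables = self._cohort(rng, 12)
        both = tables + [StayTable(t.probs.copy(), t.counts.copy()) for t in tables]
        groups = ["a"] * 12 + ["b"] * 12
        res = {r.effect: r for r in mixed_anova_2x2(both, groups)}
        for effect in ("reward_x_group", "state_x_group", "group"):
            assert res[effect].F == pytest.approx(0.0, abs=1e-12)

    def test_injected_reward_effect_detected(self, rng):
        tables = self._cohort(rng, 25, reward_d=0.3, noise=0.1) + self._cohort(
            rng, 25, reward_d=0.3, noise=0.1
        )
        groups = ["a"] * 25 + ["b"] * 25
        res = {r.effect: r for r in mixed_anova_2x2(tables, groups)}
        assert res["reward"].p < 0.001
        assert res["reward"].df2 == 48

    def test_between_effect_equals_squared_two_sample_t(self, rng):
        """The reward x group F must equal the square of an independently
        computed two-sample t on the subject-level reward contrasts."""
        ta = self._cohort(rng, 14, reward_d=0.25)
        tb = self._cohort(rng, 11, reward_d=0.10)
        groups = ["a"] * 14 + ["b"] * 11
        res = {r.effect: r for r in mixed_anova_2x2(ta + tb, groups)}
        ca = [reward_main_effect(t) for t in ta]
        cb = [reward_main_effect(t) for t in tb]
        t_ref = sp_stats.ttest_ind(ca, cb, equal_var=True).statistic
        assert res["reward_x_group"].F == pytest.approx(t_ref**2, abs=1e-8)

    def test_balanced_within_effect_equals_one_sample_t(self, rng):
        """With equal group sizes the within-subject reward F reduces to a
        one-sample t on the pooled contrasts (up to the pooled-error df)."""
        tables = self._cohort(rng, 16, reward_d=0.2) + self._cohort(
            rng, 16, reward_d=0.2
        )
        groups = ["a"] * 16 + ["b"] * 16
        res = {r.effect: r for r in mixed_anova_2x2(tables, groups)}
        c = np.array([reward_main_effect(t) for t in tables])
        ca, cb = c[:16], c[16:]
        s2p = 0.5 * (ca.var(ddof=1) + cb.var(ddof=1))
        t_ref = c.mean() / np.sqrt(s2p * (1 / 16 + 1 / 16) / 4)
        assert res["reward"].F == pytest.approx(t_ref**2, abs=1e-8)

    def test_incomplete_subjects_dropped_with_warning(self, rng):
        tables = self._cohort(rng, 6) + self._cohort(rng, 6)
        tables[0] = StayTable(
            probs=np.array([[np.nan, 0.5], [0.5, 0.5]]),
            counts=np.array([[0, 5], [5, 5]]),
        )
        with pytest.warns(RuntimeWarning, match="empty stay-table"):
            mixed_anova_2x2(tables, ["a"] * 6 + ["b"] * 6)


class TestManovaRoy:
    def test_matches_statsmodels(self, rng):
        """Roy's root, its F transform and p must match the independent
        general-purpose MANOVA in statsmodels on random data."""
        from statsmodels.multivariate.manova import MANOVA

        X = rng.normal(size=(40, 4))
        X[:18] += [0.4, -0.1, 0.2, 0.0]
        groups = ["hi"] * 18 + ["lo"] * 22
        ours = manova_roy(X, groups)
        df = pd.DataFrame(X, columns=["v1", "v2", "v3", "v4"])
        df["g"] = groups
        stat = MANOVA.from_formula("v1 + v2 + v3 + v4 ~ g", data=df).mv_test()
        ref = stat.results["g"]["stat"].loc["Roy's greatest root"]
        assert ours.roy_root == pytest.approx(ref["Value"], abs=1e-6)
        assert ours.F == pytest.approx(ref["F Value"], abs=1e-6)
        assert ours.p == pytest.approx(ref["Pr > F"], abs=1e-6)

    def test_equal_group_means_give_zero_root(self, rng):
        X = rng.normal(size=(15, 3))
        X = np.vstack([X, X])  # identical groups
        res = manova_roy(X, ["a"] * 15 + ["b"] * 15)
        assert res.roy_root == pytest.approx(0.0, abs=1e-12)

    def test_large_separation_is_significant(self, rng):
        X = rng.normal(size=(30, 4))
        X[:15, 0] += 5.0  # 5 SD shift on one coordinate
        res = manova_roy(X, ["a"] * 15 + ["b"] * 15)
        assert res.p < 1e-6

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_roy(rng.normal(size=(6, 4)), ["a"] * 3 + ["b"] * 3)


class TestGroupTtest:
    def test_identical_groups(self, rng):
        x = rng.normal(size=10)
        res = group_ttest(np.concatenate([x, x]), ["a"] * 10 + ["b"] * 10, tail="greater")
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5, abs=1e-12)

    def test_large_samples_match_effect_size(self, rng):
        x = np.concatenate([rng.normal(1, 1, 1000), rng.normal(0, 1, 1000)])
        groups = ["a"] * 1000 + ["b"] * 1000
        res = group_ttest(x, groups)
        # d = 1 -> t ~ sqrt(n/2) = 22.4
        assert 19 < res.t < 26

    def test_label_swap_flips_sign(self, rng):
        x = rng.normal(size=20)
        x[:10] += 1.0
        g = ["a"] * 10 + ["b"] * 10
        r1 = group_ttest(x, g, order=("a", "b"))
        r2 = group_ttest(x, g, order=("b", "a"))
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)

    def test_degenerate_zero_variance(self):
        res = group_ttest(np.zeros(8), ["a"] * 4 + ["b"] * 4)
        assert res.t == 0.0 and res.p == 1.0
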