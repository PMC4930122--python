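"""Tests of likelihoods, MAP fitting, the empirical prior, and evidence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from twostep import (
    EmpiricalPrior,
    ParameterSet,
    TaskConfig,
    fit_empirical_prior,
    fit_map,
    model_evidence,
    session_nll,
    simulate_session,
)
from twostep.fit import default_prior, free_params, to_native, to_unconstrained

from _helpers import make_session


class TestTransforms:
    @given(
        omega=st.floats(0.01, 0.99),
        alpha1=st.floats(0.01, 0.99),
        alpha2=st.floats(0.01, 0.99),
        lam=st.floats(0.01, 0.99),
        beta1=st.floats(0.01, 15.0),
        beta2=st.floats(0.01, 15.0),
        rho=st.floats(-3.0, 3.0),
        model=st.sampled_from(["mf", "mb", "hybrid"]),
    )
    def test_roundtrip_identity(self, model, **kwargs):
        p = ParameterSet(**kwargs)
        back = to_native(to_unconstrained(p, model), model)
        for name in free_params(model):
            assert getattr(back, name) == pytest.approx(getattr(p, name), abs=1e-10)

    def test_models_pin_expected_parameters(self):
        x = to_unconstrained(ParameterSet(0.3, 0.4, 0.5, 0.6, 2, 3, 0.1), "mb")
        p = to_native(x, "mb")
        assert (p.omega, p.alpha1, p.lam) == (1.0, 0.0, 0.0)
        assert to_native(to_unconstrained(p, "mf"), "mf").omega == 0.0


class TestSessionNll:
    def test_uniform_policy_baseline(self, session):
        """beta1 = beta2 = rho = 0 makes every choice probability 1/2, so a
        201-trial session has nll exactly 402 ln 2."""
        p = ParameterSet(0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0)
        assert session_nll(p, session) == pytest.approx(402 * math.log(2), abs=1e-9)

    def test_two_trial_hand_oracle(self):
        # Trial 1: a1=0 -> common (s2=0), a2=1, r=1. Trial 2: a1=1 -> common
        # (s2=1), a2=0, r=0. Propagated by hand below, independently of the
        # agents module.
        s = make_session([0, 1], [1, 1], [0, 1], [1, 0], [1, 0])
        p = ParameterSet(0.5, 0.4, 0.3, 0.6, 2.0, 1.5, 0.3)
        # trial 1: all values 0.5 -> both stages uniform
        nll_hand = -math.log(0.5) * 2
        # updates: d2 = 1 - 0.5; q2[0,1] = 0.5 + 0.3*0.5 = 0.65
        # q1[0] = 0.5 + 0.4*0 + 0.4*0.6*0.5 = 0.62
        qmb0 = 0.7 * 0.65 + 0.3 * 0.5
        qmb1 = 0.7 * 0.5 + 0.3 * 0.65
        v0 = 0.5 * qmb0 + 0.5 * 0.62
        v1 = 0.5 * qmb1 + 0.5 * 0.5
        l0, l1 = 2.0 * v0 + 0.3, 2.0 * v1  # rho on prev choice 0
        p1 = math.exp(l1) / (math.exp(l0) + math.exp(l1))
        nll_hand += -math.log(p1) - math.log(0.5)
        assert session_nll(p, s) == pytest.approx(nll_hand, abs=1e-10)

    def test_model_nesting(self, session):
        p = ParameterSet(0.0, 0.4, 0.5, 0.7, 3.0, 2.0, 0.1)
        assert session_nll(p, session, "hybrid") == pytest.approx(
            session_nll(p, session, "mf"), abs=1e-12
        )
        p_mb = ParameterSet(1.0, 0.0, 0.5, 0.0, 3.0, 2.0, 0.1)
        assert session_nll(p_mb, session, "hybrid") == pytest.approx(
            session_nll(p_mb, session, "mb"), abs=1e-12
        )

    def test_invalid_trials_contribute_nothing(self, params):
        s_full = make_session([0, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1], [1, 0, 1])
        s_miss = make_session(
            [0, -1, 0], [1, 0, 0], [0, -1, 1], [1, -1, 1], [1, -1, 1],
            valid=[1, 0, 1],
        )
        # with the middle trial removed entirely, values evolve identically
        s_two = make_session([0, 0], [1, 0], [0, 1], [1, 1], [1, 1])
        assert session_nll(params, s_miss) == pytest.approx(
            session_nll(params, s_two), abs=1e-12
        )
        assert session_nll(params, s_miss) != pytest.approx(
            session_nll(params, s_full), abs=1e-6
        )

    @pytest.mark.parametrize("model", ["mf", "mb", "hybrid"])
    def test_probability_over_all_choice_sequences_is_one(self, model):
        """On a 2-trial task with branch-fixed transitions and rewards, the
        model-implied probabilities of the 16 choice sequences sum to 1."""
        p = ParameterSet(0.55, 0.45, 0.6, 0.7, 3.0, 2.5, 0.4)
        trans = {0: 0, 1: 1}  # deterministic branch: a1 -> its common state
        rew = np.array([[[1, 0], [0, 1]], [[0, 1], [1, 0]]])  # trial, s2, a2
        total = 0.0
        for a11, a21, a12, a22 in itertools.product((0, 1), repeat=4):
            s2 = [trans[a11], trans[a12]]
            r = [rew[0][s2[0]][a21], rew[1][s2[1]][a22]]
            sess = make_session(
                [a11, a12], [1, 1], s2, [a21, a22], r
            )
            total += math.exp(-session_nll(p, sess, model))
        assert total == pytest.approx(1.0, abs=1e-8)


class TestFitMap:
    def test_tight_prior_dominates(self, session):
        x0 = to_unconstrained(
            ParameterSet(0.7, 0.3, 0.5, 0.6, 4.0, 3.0, 0.2), "hybrid"
        )
        prior = EmpiricalPrior("hybrid", x0, np.full(7, 1e-6))
        fit = fit_map(session, prior, n_restarts=2, seed=0)
        np.testing.assert_allclose(fit.x_map, x0, atol=1e-2)

    def test_no_signal_fits_stay_near_chance(self):
        """Fitting choices generated by a zero-temperature (uniform) agent
        must not infer decisive temperatures: the fit hugs the chance
        baseline instead of finding structure."""
        p = ParameterSet(0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0)
        chance = 402 * math.log(2)
        for seed in (9, 10):
            s = simulate_session(p, TaskConfig(), seed=seed)
            fit = fit_map(s, model="hybrid", n_restarts=4, seed=1)
            assert abs(fit.nll - chance) < 8.0
            assert fit.map_params.beta1 < 4.0
            assert fit.map_params.beta2 < 4.0

    def test_omega_recovery_with_crisp_temperatures(self):
        """A hybrid agent with decisive softmax (beta=5) yields omega MAPs
        within +-0.25 of truth in at least 80% of replicates."""
        truth = ParameterSet(0.7, 0.5, 0.6, 0.65, 5.0, 5.0, 0.2)
        prior = default_prior("hybrid")
        hits = 0
        n_rep = 20
        for i in range(n_rep):
            s = simulate_session(truth, seed=3000 + i)
            fit = fit_map(s, prior, n_restarts=4, seed=i)
            hits += abs(fit.map_params.omega - truth.omega) <= 0.25
        assert hits >= 0.8 * n_rep

    def test_nll_beats_uniform_baseline(self, session, params):
        fit = fit_map(session, n_restarts=4, seed=0)
        assert fit.nll <= 402 * math.log(2)
        assert fit.converged


class TestEmpiricalPrior:
    def test_single_subject_rejected(self, session):
        with pytest.raises(ValueError):
            fit_empirical_prior([session], "hybrid")

    def test_identical_subjects_shrink_variance(self, params):
        s = simulate_session(params, seed=31)
        prior, fits, _ = fit_empirical_prior(
            [s] * 5, "hybrid", max_iter=6, n_restarts=3, seed=0
        )
        # MAP scatter is zero; what remains is the shared posterior width,
        # far below the broad starting variance.
        assert np.all(prior.var < 0.2 * default_prior("hybrid").var)
        maps = np.array([f.x_map for f in fits])
        assert np.allclose(maps, maps[0], atol=1e-6)


class TestModelEvidence:
    def test_point_mass_prior_equals_negative_nll(self, session, params):
        x0 = to_unconstrained(params, "hybrid")
        prior = EmpiricalPrior("hybrid", x0, np.zeros(7))
        lev, se = model_evidence(session, prior, seed=0, n_samples=200)
        assert lev == pytest.approx(-session_nll(params, session), abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_chance_data_evidence_near_chance_bound(self):
        p = ParameterSet(0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 0.0)
        s = simulate_session(p, TaskConfig(), seed=13)
        lev, _ = model_evidence(s, default_prior("hybrid"), seed=0)
        assert lev <= -402 * math.log(2) + 5.0

    def test_mc_se_scales_with_sample_count(self, session, params):
        x0 = to_unconstrained(params, "hybrid")
        prior = EmpiricalPrior("hybrid", x0, np.full(7, 0.25))
        ses = {}
        for k in (100, 400, 1600):
            # average a few repeats so the 1/sqrt(K) trend is visible
            ses[k] = np.mean(
                [model_evidence(session, prior, n_samples=k, seed=s)[1]
                 for s in range(5)]
            )
        assert ses[1600] < ses[400] < ses[100]
        assert 2.0 < ses[100] / ses[1600] < 8.0
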