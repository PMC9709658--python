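import numpy as np
import pytest
from scipy.special import expit

import domhier as dh
from domhier.genetics import LOCUS
from domhier.hierarchy import init_learning, run_contest_phase

from conftest import make_group


def traits_array(G, S, **overrides):
    """(G, S, n_loci) trait array, zero except for the given trait values."""
    t = np.zeros((G, S, dh.N_LOCI))
    for name, value in overrides.items():
        t[..., LOCUS[name]] = value
    return t


class TestObservation:
    def test_noise_free_equal_quality_is_zero(self, params, rng):
        p = params.replace(sigma_obs=0.0)
        assert dh.observe_relative_quality(1.3, 1.3, 0, 0, p, rng) == 0.0

    def test_noise_free_scaling(self, params, rng):
        p = params.replace(sigma_obs=0.0)
        assert dh.observe_relative_quality(1.0, 0.0, 0, 0, p, rng) == pytest.approx(0.707)

    def test_damage_reduces_effective_ability(self, params, rng):
        p = params.replace(sigma_obs=0.0)
        # equal qualities, i damaged by 10 units: diff = -c0*10
        xi = dh.observe_relative_quality(0.0, 0.0, 10, 0, p, rng)
        assert xi == pytest.approx(-0.707 * 0.02 * 10)

    def test_signal_fraction_is_half_at_standard_values(self, params):
        # a0^2 * 2 sigma_q^2 / (a0^2 * 2 sigma_q^2 + sigma_obs^2) ~ 50%
        rng = np.random.default_rng(5)
        n = 200_000
        qi = rng.normal(0, params.sigma_q, n)
        qj = rng.normal(0, params.sigma_q, n)
        xi = dh.observe_relative_quality(qi, qj, 0.0, 0.0, params, rng)
        signal = np.var(params.a0 * (qi - qj))
        assert signal / np.var(xi) == pytest.approx(0.5, abs=0.01)


class TestActionAndValue:
    def test_symmetric_logit_gives_half(self):
        assert dh.action_probability(0.0, 1.0, 0.0) == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        assert dh.action_probability(5.0, 0.0, 7.7) == pytest.approx(0.99331, abs=1e-5)

    def test_monotone_in_observation(self):
        grid = np.linspace(-4, 4, 41)
        probs = dh.action_probability(0.3, 0.8, grid)
        assert np.all(np.diff(probs) > 0)

    @pytest.mark.parametrize("w_eff,g0,xi,expected", [
        (0.0, 1.0, 0.0, 0.0),
        (-0.07, 0.07, 1.0, 0.0),
        (0.5, 0.0, 99.0, 0.5),   # g0=0: independent of the observation
    ])
    def test_estimated_value_linear_form(self, w_eff, g0, xi, expected):
        assert dh.estimated_value(w_eff, g0, xi) == pytest.approx(expected)


class TestFightResolution:
    def test_equal_ability_is_fair_coin(self, params):
        rng = np.random.default_rng(3)
        wins = dh.resolve_fight(np.zeros(100_000), np.zeros(100_000), params, rng)
        assert wins.mean() == pytest.approx(0.5, abs=0.01)

    def test_ability_gap_closed_form(self, params):
        rng = np.random.default_rng(4)
        wins = dh.resolve_fight(np.full(100_000, 2.0), np.zeros(100_000), params, rng)
        assert wins.mean() == pytest.approx(expit(2.0), abs=0.01)  # ~0.8808

    def test_steep_scale_limit(self, params, rng):
        p = params.replace(winprob_scale=1e6)
        wins = dh.resolve_fight(np.full(1000, 0.1), np.zeros(1000), p, rng)
        assert wins.all()


class TestPerceivedRewards:
    def make_traits(self, v=0.8):
        arr = np.zeros(dh.N_LOCI)
        arr[LOCUS["v"]] = v
        return dh.TraitSet.from_array(arr)

    def test_double_submission_gives_zero(self, params, rng):
        out = dh.RoundOutcome("S", "S")
        assert dh.perceived_rewards(out, self.make_traits(), self.make_traits(), params, rng) == (0.0, 0.0)

    def test_lone_aggressor_wins_own_v(self, params, rng):
        out = dh.RoundOutcome("A", "S", winner="i")
        ri, rj = dh.perceived_rewards(out, self.make_traits(0.9), self.make_traits(0.1), params, rng)
        assert ri == 0.9 and rj == 0.0

    def test_fight_loser_penalty_is_exactly_one_without_noise(self, params, rng):
        p = params.replace(sigma_p=0.0)
        out = dh.RoundOutcome("A", "A", winner="j")
        ri, rj = dh.perceived_rewards(out, self.make_traits(), self.make_traits(0.7), p, rng)
        assert ri == -1.0 and rj == 0.7

    def test_penalty_noise_sd_matches_sigma_p(self, params):
        rng = np.random.default_rng(9)
        out = dh.RoundOutcome("A", "A", winner="j")
        t = self.make_traits()
        losses = np.array([dh.perceived_rewards(out, t, t, params, rng)[0]
                           for _ in range(100_000)])
        assert losses.std() == pytest.approx(0.25, abs=0.005)
        assert losses.mean() == pytest.approx(-1.0, abs=0.005)

    def test_ss_round_cannot_have_winner(self):
        with pytest.raises(ValueError):
            dh.RoundOutcome("S", "S", winner="i")


class TestLearningUpdates:
    def make_state(self, p, theta0=0.5, w0=-0.1, f=0.2):
        traits = traits_array(1, 4, theta0=theta0, w0=w0, f=f,
                              alpha_theta=0.1, alpha_w=0.05)
        return init_learning(traits, p), traits

    def test_zero_td_error_is_fixed_point(self, params):
        state, traits = self.make_state(params)
        before = state.copy()
        ts = dh.TraitSet.from_array(traits[0, 0])
        # reward exactly equals the estimate: no change anywhere
        dh.apply_learning_update(state, 0, 0, 1, True, 0.6, reward=0.25, w_hat=0.25, traits_i=ts)
        assert np.array_equal(state.theta_spec, before.theta_spec)
        assert np.array_equal(state.w_spec, before.w_spec)
        assert np.array_equal(state.theta_gen, before.theta_gen)
        assert np.array_equal(state.w_gen, before.w_gen)

    def test_full_generalization_leaves_specific_untouched(self, params):
        state, traits = self.make_state(params, f=1.0)
        t = traits[0, 0].copy()
        t[LOCUS["f"]] = 1.0
        ts = dh.TraitSet.from_array(t)
        before_spec = state.theta_spec.copy()
        dh.apply_learning_update(state, 0, 0, 1, True, 0.6, reward=1.0, w_hat=0.0, traits_i=ts)
        assert np.array_equal(state.theta_spec, before_spec)
        assert state.theta_gen[0, 0] != 0.0

    def test_critic_converges_to_constant_reward(self, params):
        # Robbins-Monro fixed point: with f=0, g0=0 and constant reward R,
        # w_spec converges to R
        p = params
        traits = traits_array(1, 2, alpha_w=0.05, alpha_theta=0.0, w0=0.0)
        state = init_learning(traits, p)
        ts = dh.TraitSet.from_array(traits[0, 0])
        R = 0.37
        for _ in range(2000):
            w_hat = state.w_spec[0, 0, 1]
            dh.apply_learning_update(state, 0, 0, 1, True, 0.5, reward=R, w_hat=w_hat, traits_i=ts)
        assert state.w_spec[0, 0, 1] == pytest.approx(R, abs=1e-4)


class TestBystander:
    def setup_state(self, params, beta):
        traits = traits_array(1, 4, alpha_theta=0.5, alpha_w=0.2, beta=beta,
                              gamma0=0.5, g0=0.1, v=0.8, f=0.3)
        state = init_learning(traits, params)
        qe = np.zeros((1, 4))
        return state, traits, qe

    def test_beta_zero_changes_nothing(self, params, rng):
        state, traits, qe = self.setup_state(params, beta=0.0)
        before = state.copy()
        dh.bystander_update(state, 0, 3, winner=0, loser=1, qe=qe, traits=traits, p=params, rng=rng)
        assert np.array_equal(state.theta_spec, before.theta_spec)
        assert np.array_equal(state.w_gen, before.w_gen)

    def test_bystander_cannot_be_contestant(self, params, rng):
        state, traits, qe = self.setup_state(params, beta=1.0)
        with pytest.raises(ValueError):
            dh.bystander_update(state, 0, 0, winner=0, loser=1, qe=qe, traits=traits, p=params, rng=rng)

    def test_observing_losses_raises_aggression_toward_loser(self, params):
        # after k watches j lose many fights, k's preference for A against j rises
        rng = np.random.default_rng(21)
        state, traits, qe = self.setup_state(params, beta=1.0)
        k, winner, loser = 3, 0, 1
        before = state.theta_spec[0, k, loser]
        for _ in range(200):
            dh.bystander_update(state, 0, k, winner, loser, qe=qe, traits=traits, p=params, rng=rng)
        assert state.theta_spec[0, k, loser] > before

    def test_bystanders_never_touch_damage(self, small_params):
        # damage equals AA rounds exactly even with strong bystander learning
        p = small_params
        rng = dh.replicate_rng(2)
        G, S = 3, p.group_size
        traits = traits_array(G, S, theta0=1.0, alpha_theta=0.3, alpha_w=0.1,
                              beta=2.0, gamma0=0.5, g0=0.05, v=0.8, f=0.2)
        q = rng.normal(0, p.sigma_q, (G, S))
        log, _ = run_contest_phase(q, traits, p, rng)
        assert log.damage.sum() == log.total_aa


class TestContestPhase:
    def test_zero_rounds_gives_empty_log_and_initial_state(self, params, rng):
        p = params.replace(rounds_per_generation=0)
        traits = traits_array(2, 4, theta0=1.5, w0=-0.2)
        q = np.zeros((2, 4))
        log, state = run_contest_phase(q, traits, p, rng)
        assert log.encounters.sum() == 0 and log.total_aa == 0
        assert np.all(state.theta_spec == 1.5)   # specific entries start at theta0
        assert np.all(state.w_spec == -0.2)
        assert np.all(state.theta_gen == 0.0)

    def test_initial_effective_logit_is_one_minus_f_theta0(self, params):
        traits = traits_array(1, 3, theta0=2.0, f=0.25)
        state = init_learning(traits, params)
        eff = (1 - 0.25) * state.theta_spec[0, 0, 1] + 0.25 * state.theta_gen[0, 0]
        assert eff == pytest.approx(0.75 * 2.0)

    def test_universal_submission_means_no_fights(self, params, rng):
        p = params.replace(rounds_per_generation=300)
        traits = traits_array(2, 8, theta0=-20.0)
        q = rng.normal(0, 0.5, (2, 8))
        log, _ = run_contest_phase(q, traits, p, rng)
        assert log.total_aa == 0
        assert log.damage.sum() == 0

    def test_damage_conservation_and_encounter_bookkeeping(self, params):
        rng = dh.replicate_rng(31)
        p = params.replace(rounds_per_generation=500)
        traits = traits_array(5, 8, theta0=0.5, alpha_theta=0.4, alpha_w=0.1,
                              gamma0=0.7, g0=0.05, v=0.8, f=0.1, beta=0.5)
        q = rng.normal(0, p.sigma_q, (5, 8))
        log, _ = run_contest_phase(q, traits, p, rng)
        # every fight damages exactly one individual by exactly 1
        assert log.damage.sum() == log.total_aa
        # every step is one encounter per group
        assert log.encounters.sum() // 2 == 5 * p.rounds_per_generation
        assert np.array_equal(log.aa, log.aa.transpose(0, 2, 1))
        wins_pair = log.wins + log.wins.transpose(0, 2, 1)
        assert np.all(wins_pair <= log.encounters)

    def test_reproducible_from_seed(self, params):
        p = params.replace(rounds_per_generation=200)
        traits = traits_array(3, 6, theta0=0.5, alpha_theta=0.4, alpha_w=0.1,
                              gamma0=0.7, g0=0.05, v=0.8, f=0.1, beta=0.5)
        q = np.linspace(-1, 1, 18).reshape(3, 6)
        log1, st1 = run_contest_phase(q, traits, p, dh.replicate_rng(99))
        log2, st2 = run_contest_phase(q, traits, p, dh.replicate_rng(99))
        assert np.array_equal(log1.wins, log2.wins)
        assert np.array_equal(log1.damage, log2.damage)
        assert np.array_equal(st1.theta_spec, st2.theta_spec)
        assert np.array_equal(st1.w_gen, st2.w_gen)

    def test_group_needs_two_members(self, params, rng):
        with pytest.raises(ValueError):
            run_contest_phase(np.zeros((1, 1)), np.zeros((1, 1, dh.N_LOCI)), params, rng)

    def test_individual_wrapper_matches_engine(self, params):
        p = params.replace(rounds_per_generation=100)
        group = make_group([0.5, -0.2, 0.1, -0.4], p=p)
        log, state = dh.run_group_contests(group, p, dh.replicate_rng(17))
        assert log.damage.shape == (1, 4)
        assert sum(m.damage for m in group) == log.total_aa


def brute_force_davids(P):
    """Published David's score formula, computed entry by entry."""
    S = P.shape[0]
    w = np.array([sum(P[i, j] for j in range(S) if j != i) for i in range(S)])
    l = np.array([sum(P[j, i] for j in range(S) if j != i) for i in range(S)])
    w2 = np.array([sum(P[i, j] * w[j] for j in range(S) if j != i) for i in range(S)])
    l2 = np.array([sum(P[j, i] * l[j] for j in range(S) if j != i) for i in range(S)])
    return w + w2 - l - l2


class TestRanks:
    def test_davids_score_matches_brute_force_oracle(self):
        wins = np.array([[0, 7, 2, 9],
                         [3, 0, 5, 1],
                         [8, 5, 0, 0],
                         [1, 9, 0, 0]], dtype=float)
        decided = wins + wins.T
        P = np.where(decided > 0, wins / np.where(decided > 0, decided, 1), 0.5)
        np.fill_diagonal(P, 0.0)
        assert np.allclose(dh.davids_scores(wins), brute_force_davids(P))

    def test_zero_encounter_pairs_contribute_half(self):
        # nobody ever met: all scores equal (and zero)
        wins = np.zeros((5, 5))
        assert np.allclose(dh.davids_scores(wins), 0.0)

    def test_transitive_matrix_ranks_in_order(self, rng):
        S = 6
        wins = np.zeros((1, S, S))
        for i in range(S):
            for j in range(i + 1, S):
                wins[0, i, j] = 10.0
        log = dh.ContestLog(encounters=np.full((1, S, S), 10.0), aa=wins + wins.transpose(0, 2, 1),
                            wins=wins, damage=np.zeros((1, S)), aa_rounds=np.zeros((1, S)))
        ranks = dh.assign_dominance_positions(log, rng)
        assert ranks[0].tolist() == list(range(1, S + 1))

    def test_rock_paper_scissors_scores_equal_and_ranks_uniform(self):
        wins = np.array([[0, 10, 0],
                         [0, 0, 10],
                         [10, 0, 0]], dtype=float)
        scores = dh.davids_scores(wins)
        assert np.allclose(scores, scores[0])
        # tie-break is uniform: each individual tops about 1/3 of the time
        log = dh.ContestLog(encounters=np.full((1, 3, 3), 10.0),
                            aa=np.zeros((1, 3, 3)), wins=wins[None],
                            damage=np.zeros((1, 3)), aa_rounds=np.zeros((1, 3)))
        rng = np.random.default_rng(8)
        tops = np.array([np.argmin(dh.assign_dominance_positions(log, rng)[0])
                         for _ in range(3000)])
        freq = np.bincount(tops, minlength=3) / 3000
        assert np.allclose(freq, 1 / 3, atol=0.03)
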