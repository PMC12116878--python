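import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import prefbandit as pb
from prefbandit.core_data import GambleTrial, PairId, Role, Stimulus, TaskType
from prefbandit.rl_models import (
    ParamSet,
    choice_prob,
    get_model,
    init_values,
    q_trajectory,
    session_loglik,
    simulate_session,
    update_q,
)
from prefbandit.synthetic_data import build_gamble_schedule


STIMULI = (
    Stimulus("H", Role.PREF_HIGH, 0.7),
    Stimulus("L", Role.PREF_LOW, 0.3),
    Stimulus("NH", Role.NOVEL_HIGH, 0.7),
    Stimulus("NL", Role.NOVEL_LOW, 0.3),
)


def oracle_loglik(alpha, beta, q0, steps):
    """Straight-line reference: steps are (chosen, other, reward) tuples."""
    q = dict(q0)
    total = 0.0
    for c, o, r in steps:
        total += math.log(1.0 / (1.0 + math.exp(-beta * (q[c] - q[o]))))
        q[c] = q[c] + alpha * (r - q[c])
    return total


def make_trials(steps, task=TaskType.PREF_HIGH_PROB):
    pair_of = {frozenset(("H", "NL")): PairId.HIGH_PREF_PAIR,
               frozenset(("L", "NH")): PairId.LOW_PREF_PAIR,
               frozenset(("NH", "NL")): PairId.NOVEL_PAIR,
               frozenset(("H", "L")): PairId.HIGH_PREF_PAIR}
    return [
        GambleTrial("p", task, pair_of[frozenset((c, o))], i + 1, c, o, c, r)
        for i, (c, o, r) in enumerate(steps)
    ]


class TestInitValues:
    @pytest.mark.parametrize("name,expected", [
        ("RL1", {"H": 0.5, "L": 0.5, "NH": 0.5, "NL": 0.5}),
        ("RL2", {"H": 0.8, "L": 0.5, "NH": 0.5, "NL": 0.5}),
        ("RL3", {"H": 0.8, "L": 0.5, "NH": 0.8, "NL": 0.8}),
        ("RL4", {"H": 0.8, "L": 0.5, "NH": 0.3, "NL": 0.3}),
    ])
    def test_eta_slot_assignment(self, name, expected):
        model = get_model(name)
        etas = {"RL1": (0.5,), "RL2": (0.8, 0.5), "RL3": (0.8, 0.5),
                "RL4": (0.8, 0.5, 0.3)}[name]
        state = init_values(model, ParamSet(0.3, 1.0, etas), STIMULI)
        assert state.q == expected
        assert state.t == 0

    def test_eta_count_enforced(self):
        with pytest.raises(ValueError):
            init_values(get_model("RL4"), ParamSet(0.3, 1.0, (0.5,)), STIMULI)

    def test_idm_only_excluded(self):
        stimuli = STIMULI + (Stimulus("X", Role.IDM_ONLY),)
        state = init_values(get_model("RL1"), ParamSet(0.3, 1.0, (0.5,)), stimuli)
        assert "X" not in state.q

    def test_rl4_with_tied_etas_equals_rl1(self):
        s4 = init_values(get_model("RL4"), ParamSet(0.3, 1.0, (0.6, 0.6, 0.6)),
                         STIMULI)
        s1 = init_values(get_model("RL1"), ParamSet(0.3, 1.0, (0.6,)), STIMULI)
        assert s4.q == s1.q


class TestElementaryOps:
    def test_update_q_hand_value(self):
        assert update_q(0.5, 1, 0.2) == pytest.approx(0.6, abs=1e-15)

    def test_update_q_no_learning_and_full_update(self):
        assert update_q(0.37, 0, 0.0) == 0.37
        assert update_q(0.37, 1, 1.0) == 1.0

    @pytest.mark.parametrize("q,r,a", [(-0.1, 1, 0.5), (0.5, 2, 0.5),
                                       (0.5, 1, 1.5)])
    def test_update_q_domain_errors(self, q, r, a):
        with pytest.raises(ValueError):
            update_q(q, r, a)

    def test_choice_prob_symmetric_cases(self):
        assert choice_prob(0.4, 0.4, 3.0) == 0.5
        assert choice_prob(0.9, 0.1, 0.0) == 0.5

    def test_choice_prob_logistic_value(self):
        assert choice_prob(1.0, 0.0, 1.0) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.0)), abs=1e-15)

    def test_choice_prob_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            choice_prob(0.5, 0.5, -1.0)

    @given(qa=st.floats(0, 1), qb=st.floats(0, 1), beta=st.floats(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_choice_prob_complementary(self, qa, qb, beta):
        assert choice_prob(qa, qb, beta) + choice_prob(qb, qa, beta) == \
            pytest.approx(1.0, abs=1e-12)

    def test_choice_prob_monotone_in_gap_and_beta(self):
        gaps = np.linspace(-1, 1, 21)
        probs = [choice_prob(0.5 + g / 2, 0.5 - g / 2, 2.0) for g in gaps]
        assert np.all(np.diff(probs) > 0)
        betas = np.linspace(0, 10, 21)
        probs_b = [choice_prob(0.8, 0.2, b) for b in betas]
        assert np.all(np.diff(probs_b) > 0)


class TestSessionLoglik:
    def test_single_trial_equal_values_is_log_half(self):
        trials = make_trials([("H", "L", 1)])
        ll = session_loglik(get_model("RL1"), ParamSet(0.3, 2.0, (0.5,)),
                            trials, STIMULI)
        assert ll == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_oracle_on_interleaved_session(self, rng):
        model = get_model("RL2")
        params = ParamSet(0.35, 3.0, (0.7, 0.4))
        steps = []
        pairs = [("H", "NL"), ("L", "NH"), ("NH", "NL")]
        for _ in range(60):
            a, b = pairs[rng.integers(3)]
            if rng.random() < 0.5:
                a, b = b, a
            steps.append((a, b, int(rng.random() < 0.5)))
        trials = make_trials(steps)
        q0 = init_values(model, params, STIMULI).q
        expected = oracle_loglik(params.alpha, params.beta, q0, steps)
        got = session_loglik(model, params, trials, STIMULI)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rl2_with_tied_etas_equals_rl1_exactly(self, rng):
        schedule = build_gamble_schedule(TaskType.PREF_HIGH_PROB, "H", "L",
                                         rng, ("P1", "P2", "N1", "N2"))
        trials = simulate_session(get_model("RL2"), ParamSet(0.3, 4.0, (0.7, 0.4)),
                                  schedule, rng)
        ll2 = session_loglik(get_model("RL2"), ParamSet(0.25, 2.0, (0.55, 0.55)),
                             trials, schedule.stimuli)
        ll1 = session_loglik(get_model("RL1"), ParamSet(0.25, 2.0, (0.55,)),
                             trials, schedule.stimuli)
        assert ll1 == ll2

    def test_unordered_trials_rejected(self):
        trials = make_trials([("H", "L", 1), ("H", "L", 0)])
        trials = [trials[1], trials[0]]
        with pytest.raises(ValueError):
            session_loglik(get_model("RL1"), ParamSet(0.3, 1.0, (0.5,)),
                           trials, STIMULI)

    @given(alpha=st.floats(0, 1), etas=st.tuples(st.floats(0, 1),
                                                 st.floats(0, 1)),
           seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_q_values_stay_in_unit_interval(self, alpha, etas, seed):
        """Convex-combination closure: 0/1 rewards keep every Q in [0, 1]."""
        rng = np.random.default_rng(seed)
        model = get_model("RL2")
        params = ParamSet(alpha, 4.0, etas)
        schedule = build_gamble_schedule(TaskType.PREF_LOW_PROB, "H", "L",
                                         rng, ("P1", "P2", "N1", "N2"))
        trials = simulate_session(model, params, schedule, rng)
        traj = q_trajectory(model, params, trials, schedule.stimuli)
        for series in traj.series.values():
            assert all(0.0 <= q <= 1.0 for q in series)


class TestSimulateSession:
    def test_deterministic_preference_limit(self, rng):
        schedule = build_gamble_schedule(TaskType.PREF_HIGH_PROB, "H", "L",
                                         rng, ("P1", "P2", "N1", "N2"))
        params = ParamSet(0.0, 500.0, (1.0, 0.0))
        trials = simulate_session(get_model("RL2"), params, schedule, rng)
        first = next(t for t in trials if t.pair_id is PairId.HIGH_PREF_PAIR)
        assert first.chosen_stim == "H"

    def test_indifferent_agent_chooses_half(self, rng):
        params = ParamSet(0.0, 4.0, (0.5, 0.5))
        count = total = 0
        for _ in range(30):
            schedule = build_gamble_schedule(TaskType.PREF_HIGH_PROB, "H", "L",
                                             rng, ("P1", "P2", "N1", "N2"))
            trials = simulate_session(get_model("RL2"), params, schedule, rng)
            count += sum(t.chosen_stim == t.left_stim for t in trials)
            total += len(trials)
        # alpha=0 keeps all values equal, so P(left) = 0.5 every trial
        assert abs(count / total - 0.5) < 3 * 0.5 / math.sqrt(total)

    def test_first_trial_rate_matches_softmax_closed_form(self, rng):
        eta1, eta2, beta = 0.7, 0.4, 4.0
        params = ParamSet(0.3, beta, (eta1, eta2))
        p_expected = choice_prob(eta1, eta2, beta)
        n, hits = 4000, 0
        schedule = build_gamble_schedule(TaskType.PREF_HIGH_PROB, "H", "L",
                                         rng, ("P1", "P2", "N1", "N2"))
        for _ in range(n):
            trials = simulate_session(get_model("RL2"), params, schedule, rng)
            first = next(t for t in trials
                         if t.pair_id is PairId.HIGH_PREF_PAIR)
            hits += first.chosen_stim == "H"
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hits / n - p_expected) < 4 * se

    def test_reproducible_from_seed(self):
        schedule = build_gamble_schedule(TaskType.PREF_HIGH_PROB, "H", "L",
                                         np.random.default_rng(3),
                                         ("P1", "P2", "N1", "N2"))
        params = ParamSet(0.3, 4.0, (0.7, 0.4))
        t1 = simulate_session(get_model("RL2"), params, schedule,
                              np.random.default_rng(11))
        t2 = simulate_session(get_model("RL2"), params, schedule,
                              np.random.default_rng(11))
        assert t1 == t2


class TestTrajectory:
    def test_never_chosen_stimulus_is_flat(self):
        steps = [("H", "L", 1), ("H", "L", 0), ("H", "L", 1)]
        traj = q_trajectory(get_model("RL2"), ParamSet(0.5, 1.0, (0.7, 0.4)),
                            make_trials(steps), STIMULI)
        assert traj.series["L"] == [0.4, 0.4, 0.4, 0.4]

    def test_full_learning_final_equals_last_reward(self):
        steps = [("H", "L", 1), ("H", "L", 0)]
        traj = q_trajectory(get_model("RL2"), ParamSet(1.0, 1.0, (0.7, 0.4)),
                            make_trials(steps), STIMULI)
        assert traj.final("H") == 0.0
        steps = [("H", "L", 0), ("H", "L", 1)]
        traj = q_trajectory(get_model("RL2"), ParamSet(1.0, 1.0, (0.7, 0.4)),
                            make_trials(steps), STIMULI)
        assert traj.final("H") == 1.0

    def test_three_trial_hand_sequence(self):
        # alpha=0.2, Q0(H)=0.5: 0.5 ->(r=1) 0.6 ->(r=0) 0.48 ->(r=1) 0.584
        steps = [("H", "L", 1), ("H", "L", 0), ("H", "L", 1)]
        traj = q_trajectory(get_model("RL1"), ParamSet(0.2, 1.0, (0.5,)),
                            make_trials(steps), STIMULI)
        assert traj.series["H"] == pytest.approx([0.5, 0.6, 0.48, 0.584],
                                                 abs=1e-12)
        assert traj.initial("H") == 0.5
        assert traj.final("H") == pytest.approx(0.584, abs=1e-12)

    def test_series_length_is_pair_trials_plus_initial(self, small_study):
        ds = small_study.datasets["P001"]
        pid = "P001"
        task = TaskType.PREF_HIGH_PROB
        trials = ds.gamble_trials_for(task)
        stimuli = small_study.stimulus_tables[pid][task]
        params = small_study.true_params[pid]
        traj = q_trajectory(get_model("RL2"), params, trials, stimuli)
        counts = {}
        for t in trials:
            for s in (t.left_stim, t.right_stim):
                counts[s] = counts.get(s, 0) + 1
        for sid, series in traj.series.items():
            assert len(series) == counts[sid] + 1
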