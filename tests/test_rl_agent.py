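"""Replay model mechanics: priorities, training, sleep replay, ensembles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fearcon.paradigm import (
    CANONICAL_PHASE_SPECS,
    CSType,
    ExperimentDesign,
    Phase,
    PhaseSpec,
    build_experiment,
    build_phase_sequence,
)
from fearcon.rl_agent import (
    DEFAULT_ENSEMBLE_SIZE,
    Agent,
    Experience,
    HyperParams,
    prediction_error,
    replay_probabilities,
    run_agent,
    run_ensemble,
    sleep_probabilities,
    sleep_replay,
    train_on_trial,
)

CSP, CSM = CSType.CSP, CSType.CSM


def mem(*spec):
    """Experiences from (r, delta, t_stored) triples."""
    from fearcon.rl_agent import STIMULUS_CODES

    return [
        Experience(s=STIMULUS_CODES[CSP], r=float(r), delta=float(d), t_stored=t)
        for r, d, t in spec
    ]


@pytest.mark.parametrize("r,v,expected", [(1.0, 1.0, 0.0), (1.0, 0.25, 0.75),
                                          (0.0, 1.0, -1.0), (0.0, 0.0, 0.0)])
def test_prediction_error(r, v, expected):
    assert prediction_error(r, v) == expected


class TestReplayProbabilities:
    def test_no_decay_is_uniform(self):
        p = replay_probabilities(mem((1, 0.5, 0), (0, 0.1, 1), (0, 0.2, 2)),
                                 t_now=3, lam=1.0, rpe=False)
        assert np.allclose(p, 1 / 3)

    def test_recency_hand_case(self):
        # tau = [2, 1, 0], lam = 0.5 -> priorities [0.25, 0.5, 1]
        p = replay_probabilities(mem((0, 0, 0), (0, 0, 1), (0, 0, 2)),
                                 t_now=2, lam=0.5, rpe=False)
        assert np.allclose(p, [1 / 7, 2 / 7, 4 / 7])

    def test_rpe_weighting_hand_case(self):
        p = replay_probabilities(mem((0, 0.0, 0), (0, 0.5, 0), (0, -0.5, 0)),
                                 t_now=0, lam=1.0, rpe=True)
        assert np.allclose(p, [0.0, 0.5, 0.5])

    def test_rpe_all_zero_falls_back_to_recency(self):
        p = replay_probabilities(mem((0, 0.0, 0), (0, 0.0, 1)),
                                 t_now=2, lam=0.5, rpe=True)
        assert np.allclose(p, [1 / 3, 2 / 3])

    def test_empty_memory_raises(self):
        with pytest.raises(ValueError):
            replay_probabilities([], 0, 0.5, False)

    @given(
        lam=st.floats(0.05, 1.0),
        taus=st.lists(st.integers(0, 50), min_size=1, max_size=20),
        rpe=st.booleans(),
    )
    def test_probabilities_sum_to_one(self, lam, taus, rpe):
        t_now = max(taus)
        m = mem(*[(k % 2, 0.1 + 0.01 * k, t_now - tau) for k, tau in enumerate(taus)])
        p = replay_probabilities(m, t_now, lam, rpe)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_recency_strictly_decreasing_in_tau(self):
        m = mem(*[(0, 0, t) for t in range(6)])
        p = replay_probabilities(m, t_now=6, lam=0.7, rpe=False)
        assert np.all(np.diff(p) > 0)  # older experiences strictly less likely


class TestSleepProbabilities:
    def test_zero_beta_uniform(self):
        p = sleep_probabilities(mem((1, 0, 0), (0, 0, 1), (0, 0, 2)), beta=0.0)
        assert np.allclose(p, 1 / 3)

    def test_hand_case_log2(self):
        p = sleep_probabilities(mem((1, 0, 0), (0, 0, 1), (0, 0, 2)), beta=np.log(2))
        assert np.allclose(p, [0.5, 0.25, 0.25])

    def test_large_beta_concentrates_on_reinforced(self):
        p = sleep_probabilities(mem((1, 0, 0), (1, 0, 1), (0, 0, 2)), beta=50.0)
        assert p[:2].sum() == pytest.approx(1.0, abs=1e-12)
        assert p[0] == pytest.approx(p[1])  # reinforced share equally


class TestTrainOnTrial:
    def test_zero_replays_leaves_weights_unchanged(self):
        agent = Agent.fresh(HyperParams(i=0), seed=0)
        w_before = agent.net.w1.copy()
        v, delta = train_on_trial(agent, CSP, True)
        assert np.array_equal(agent.net.w1, w_before)
        assert len(agent.memory) == 1
        assert delta == pytest.approx(1.0 - v)

    def test_prediction_read_before_update(self):
        agent = Agent.fresh(HyperParams(), seed=1)
        v_pre = agent.predict(CSP)
        v, _ = train_on_trial(agent, CSP, True)
        assert v == pytest.approx(v_pre)

    def test_single_experience_memory_degenerate_sampling(self):
        agent = Agent.fresh(HyperParams(), seed=2)
        train_on_trial(agent, CSP, True)
        p = replay_probabilities(agent.memory, agent.t, agent.hp.lam, agent.hp.rpe)
        assert p.tolist() == [1.0]

    @pytest.mark.parametrize("seed", range(3))
    def test_repeated_reinforcement_drives_v_up(self, seed):
        agent = Agent.fresh(HyperParams(), seed=seed)
        vs = [train_on_trial(agent, CSP, True)[0] for _ in range(25)]
        assert vs[-1] > 0.8
        assert vs[-1] > vs[0]


def _all_csminus_design():
    """Diagnostic design without any reinforcement (CS- only throughout)."""
    specs = [
        PhaseSpec(Phase.HABITUATION, 0, 0, 6),
        PhaseSpec(Phase.EXTINCTION, 0, 0, 32),
        PhaseSpec(Phase.RECALL, 0, 0, 24),
    ]
    day1, day2 = [], []
    for spec in specs:
        seq = build_phase_sequence(spec, 0)
        (day2 if spec.name is Phase.RECALL else day1).extend(seq)
    return ExperimentDesign(counterbalance_id="A", day1=tuple(day1), day2=tuple(day2))


class TestSleepReplay:
    def test_executes_exactly_100_batches(self):
        agent = Agent.fresh(HyperParams(), seed=0)
        train_on_trial(agent, CSP, True)
        sleep_replay(agent)
        assert agent.sleep_updates_done == 100
        assert agent.hp.sleep_batch_size == 64

    def test_no_reinforcement_history_no_recovery(self):
        """With an all-CS- history sleep replay cannot re-instate fear."""
        design = _all_csminus_design()
        tr = run_agent(design, HyperParams(beta=5.0), seed=0, sleep=True)
        recall_v = tr.v_series(Phase.RECALL, CSM)
        assert recall_v[0] < 0.1

    def test_empty_memory_raises(self):
        agent = Agent.fresh(HyperParams(), seed=0)
        with pytest.raises(ValueError):
            sleep_replay(agent)


class TestRunAgent:
    def test_trace_covers_all_94_trials(self, design_a):
        tr = run_agent(design_a, HyperParams(), seed=0)
        assert len(tr.table) == 94
        assert tr.table["v"].between(0, 1).all()

    def test_determinism(self, design_a):
        a = run_agent(design_a, HyperParams(), seed=3)
        b = run_agent(design_a, HyperParams(), seed=3)
        assert np.array_equal(a.table["v"].to_numpy(), b.table["v"].to_numpy())

    def test_all_csminus_design_stays_safe(self):
        design = _all_csminus_design()
        tr = run_agent(design, HyperParams(), seed=1)
        v = tr.table["v"].to_numpy()
        assert v[5:].max() < 0.2 and v[-1] < 0.05


class TestRunEnsemble:
    def test_single_agent_matches_run_agent(self, design_a):
        ens = run_ensemble(design_a, HyperParams(), n_agents=1, seed=4)
        ss = np.random.SeedSequence(4).spawn(1)[0]
        tr = run_agent(design_a, HyperParams(), ss)
        assert np.allclose(ens["v_mean"], tr.table["v"])

    def test_values_bounded_and_default_size(self, design_a):
        ens = run_ensemble(design_a, HyperParams(), n_agents=3, seed=0)
        assert ens["v_mean"].between(0, 1).all()
        assert ens["abs_delta_mean"].between(0, 1).all()
        assert DEFAULT_ENSEMBLE_SIZE == 25

    def test_ordinals_count_presentations_per_cs(self, design_a):
        ens = run_ensemble(design_a, HyperParams(), n_agents=1, seed=0)
        for cs in ("CS+", "CS-"):
            sub = ens[ens["cs_type"] == cs]
            assert sub["ordinal"].to_list() == list(range(1, 48))


def test_hyperparams_validation():
    with pytest.raises(ValueError):
        HyperParams(lam=0.0)
    with pytest.raises(ValueError):
        HyperParams(b=0)
    with pytest.raises(ValueError):
        Experience(s=np.zeros(8), r=0.5, delta=0.0, t_stored=0)
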