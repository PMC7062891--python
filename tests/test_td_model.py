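"""TD(0) learning, the consistency condition and the Q-value identity."""

import itertools

import numpy as np
import pytest

from foragebold import task_schedule as ts
from foragebold import td_model as td


def _repeat(chain, n):
    return itertools.repeat(chain, n)


def make_trial(level="high", n_targets=11, reward=20.0, gap=1.25):
    """Deterministic trial at onset 0 with evenly spaced targets."""
    targets = tuple(ts.TargetEvent(onset=5.0 + (i + 1) * gap, side="left",
                                   reward=reward)
                    for i in range(n_targets))
    return ts.Trial(index=0, reward_level=level, cue_onset=0.0,
                    interval_onset=2.0, patch_onset=5.0, iti_onset=19.5,
                    targets=targets)


class TestBuildChain:
    def test_exp3_chain_is_deterministic_with_eleven_targets(self):
        chain = td.build_episode_chain(make_trial(), 3)
        kinds = [e.kind for e in chain.episodes]
        assert kinds[:3] == ["pre_cue", "cue", "interval"]
        assert kinds[-2:] == ["iti", "terminal"]
        assert kinds.count("target") == 11
        # 14.5 s patch at 250 ms grain = 58 slots
        assert kinds.count("target") + kinds.count("non_target") == 58

    def test_no_targets_chain(self):
        chain = td.build_episode_chain(make_trial(n_targets=0), 1)
        assert all(e.reward == 0.0 for e in chain.episodes)
        assert {e.kind for e in chain.episodes} == {
            "pre_cue", "cue", "interval", "non_target", "iti", "terminal"}

    def test_high_trial_targets_carry_twenty_cents(self):
        chain = td.build_episode_chain(make_trial(), 1)
        for e in chain.episodes:
            assert e.reward == (20.0 if e.kind == "target" else 0.0)

    def test_exp2_context_state_encodes_level(self):
        chain = td.build_episode_chain(make_trial(level="low"), 2)
        assert chain.episodes[0].state == "pre_cue|low"
        chain1 = td.build_episode_chain(make_trial(level="low"), 1)
        assert chain1.episodes[0].state == "pre_cue"

    def test_unknown_variant_raises(self):
        with pytest.raises(ts.ScheduleError, match="variant"):
            td.build_episode_chain(make_trial(), 4)


class TestTrainValues:
    def test_first_target_state_value_is_remaining_reward(self):
        # 11 x 20 cents of undiscounted future reward from the first target
        chain = td.build_episode_chain(make_trial(), 3)
        table = td.train_values(_repeat(chain, 10_000), td.TDConfig())
        first = min(s for s in table.values
                    if s.startswith("patch|high") and s.endswith("T"))
        assert table[first] == pytest.approx(220.0, abs=1e-6)
        assert table.converged

    def test_alpha_one_converges_within_chain_length_sweeps(self):
        chain = td.build_episode_chain(make_trial(n_targets=3), 3)
        cfg = td.TDConfig(alpha=1.0, convergence_tol=1e-12)
        table = td.train_values(_repeat(chain, 1000), cfg)
        assert table.converged and table.sweeps_used <= len(chain) + 1
        oracle = td.backward_induction(chain)
        for s, v in oracle.items():
            assert table[s] == pytest.approx(v, abs=1e-9)

    def test_zero_rewards_stay_zero(self):
        chain = td.build_episode_chain(make_trial(reward=0.0), 3)
        table = td.train_values(_repeat(chain, 50), td.TDConfig())
        assert all(v == 0.0 for v in table.values.values())

    @pytest.mark.parametrize("n_targets,reward", [(2, 5.0), (7, 20.0)])
    def test_matches_backward_induction_oracle(self, n_targets, reward):
        # chains of <= 50 episodes against the dynamic-programming oracle
        trial = make_trial(n_targets=n_targets, reward=reward, gap=1.25)
        trial = ts.Trial(index=0, reward_level="high", cue_onset=0.0,
                         interval_onset=2.0, patch_onset=5.0, iti_onset=15.0,
                         targets=trial.targets)
        chain = td.build_episode_chain(trial, 3)
        assert len(chain) <= 50
        table = td.train_values(_repeat(chain, 10_000),
                                td.TDConfig(convergence_tol=1e-10))
        oracle = td.backward_induction(chain)
        for s, v in oracle.items():
            assert table[s] == pytest.approx(v, abs=1e-6)

    def test_monotone_updates_on_deterministic_chain(self):
        chain = td.build_episode_chain(make_trial(), 3)
        V: dict[str, float] = {}
        alpha = 0.3
        maxima = []
        for _ in range(60):
            max_upd = 0.0
            eps = chain.episodes
            for t in range(len(eps) - 1):
                delta = (V.get(eps[t + 1].state, 0.0)
                         - V.get(eps[t].state, 0.0) + eps[t].reward)
                V[eps[t].state] = V.get(eps[t].state, 0.0) + alpha * delta
                max_upd = max(max_upd, abs(alpha * delta))
            maxima.append(max_upd)
        assert all(a >= b - 1e-12 for a, b in zip(maxima, maxima[1:]))

    def test_nonconvergence_flagged(self):
        gen = td.ChainGenerator(experiment_variant=1,
                                td_config=td.TDConfig(seed=0))
        table = td.train_values(gen, td.TDConfig(n_train=50))
        assert not table.converged and table.sweeps_used == 50


class TestTrace:
    def test_prediction_error_identity_holds_exactly(self, exp1_sim):
        _, trace, _ = exp1_sim
        f = trace.frame
        recomputed = f.value_to - f.value_from + f.reward
        assert np.array_equal(recomputed.to_numpy(), f.delta.to_numpy())

    def test_telescoping_per_trial(self, exp1_sim):
        # undiscounted episodic chain: sum of delta over a trial equals
        # total reward minus the value of the start state
        values, trace, _ = exp1_sim
        for _, sub in trace.frame.groupby("trial"):
            lhs = sub.delta.sum()
            rhs = sub.reward.sum() - values[sub.state_from.iloc[0]]
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_cue_prediction_error_signs_exp1(self, exp1_sim):
        _, trace, _ = exp1_sim
        cue = trace.frame[trace.frame.kind_to == "cue"]
        assert cue[cue.trial_type == "high"].delta.mean() > 0
        assert cue[cue.trial_type == "low"].delta.mean() < 0

    def test_cue_prediction_error_vanishes_exp2(self, exp2_sim):
        # with the alternation encoded in the context state the cue carries
        # no new information; tolerance 5% of the high reward unit
        _, trace, _ = exp2_sim
        cue = trace.frame[trace.frame.kind_to == "cue"]
        for level in ("low", "high"):
            assert abs(cue[cue.trial_type == level].delta.mean()) < 1.0

    def test_foraging_delta_hovers_around_zero_exp1(self, exp1_sim):
        _, trace, _ = exp1_sim
        patch = td.consistency_residual(trace)
        assert abs(patch.mean) < 0.02 * 20.0

    def test_untrained_values_give_delta_equal_reward(self):
        chain = td.build_episode_chain(make_trial(), 1)
        zero = td.ValueTable({}, converged=False, sweeps_used=0)
        trace = td.record_trace(zero, _repeat(chain, 2),
                                td.TDConfig(n_record=2))
        f = trace.frame
        tgt = f[f.kind_from == "target"]
        assert np.array_equal(tgt.delta.to_numpy(), tgt.reward.to_numpy())
        assert (f[f.kind_from != "target"].delta == 0).all()

    def test_empty_phase_filter_raises(self, exp3_sim):
        _, trace, _ = exp3_sim
        with pytest.raises(ValueError, match="phase filter"):
            td.consistency_residual(trace, phase_filter=("nonexistent",))


@pytest.fixture(scope="module")
def q_setup():
    chain = td.build_episode_chain(make_trial(), 3)
    cfg = td.TDConfig(convergence_tol=1e-10)
    q = td.train_q_values(_repeat(chain, 10_000), cfg)
    v = td.train_values(_repeat(chain, 10_000), cfg)
    return chain, q, v


class TestQValues:
    def test_consistency_identity_under_optimal_policy(self, q_setup):
        chain, q, _ = q_setup
        assert q.converged
        assert td.q_consistency_residual(q, chain) <= 1e-6

    def test_greedy_values_match_state_values(self, q_setup):
        chain, q, v = q_setup
        for e in chain.episodes:
            a = td.CLICK if e.kind == "target" else td.NO_CLICK
            assert q.value(e.state, a) == pytest.approx(v[e.state], abs=1e-6)

    def test_zero_reward_chain_gives_zero_q(self):
        chain = td.build_episode_chain(make_trial(reward=0.0), 3)
        q = td.train_q_values(_repeat(chain, 100), td.TDConfig())
        assert all(val == 0.0 for val in q.values.values())


class TestCurves:
    def test_all_zero_trace_gives_zero_curves(self):
        chain = td.build_episode_chain(make_trial(reward=0.0), 3)
        zero = td.ValueTable({}, converged=True, sweeps_used=0)
        trace = td.record_trace(zero, _repeat(chain, 4),
                                td.TDConfig(n_record=4))
        curves = td.smooth_trace_to_curves(trace, ts.experiment_task_config(3))
        assert not any(c.any() for c in curves.delta.values())
        assert not any(c.any() for c in curves.reward_rate.values())

    def test_high_reward_curve_dominates_low(self, exp3_sim):
        _, _, curves = exp3_sim
        cfg = ts.experiment_task_config(3)
        start = cfg.cue_duration + cfg.interval_duration
        sel = (curves.time >= start + 2.0) & \
              (curves.time <= start + cfg.patch_duration)
        assert (curves.reward_rate["high"][sel]
                > curves.reward_rate["low"][sel]).all()

    def test_reward_rate_ratio_is_twenty(self, exp3_sim):
        _, _, curves = exp3_sim
        ratio = td.reward_rate_ratio(curves, ts.experiment_task_config(3))
        assert ratio == pytest.approx(20.0, abs=1e-9)
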