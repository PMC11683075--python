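"""Task environments and the episode/trial simulation loop."""

import numpy as np
import pytest

from hrlsim import (
    AgentParams,
    AgentState,
    HomeostaticSpace,
    build_intake_task,
    build_mountain_task,
    drive,
    run_episode,
    run_trial,
    trajectory_frame,
)


class TestIntakeTaskSpec:
    def test_structure(self, intake_task):
        assert intake_task.states == ("S0",)
        assert intake_task.actions_of["S0"] == ("do_nothing", "intake")
        assert intake_task.intake_of[("S0", "intake")] == 16.0
        assert intake_task.intake_of[("S0", "do_nothing")] == 0.0
        assert not intake_task.terminal

    def test_fixed_horizon(self, intake_task, space, rng):
        agent = AgentState.for_task(intake_task)
        traj, _ = run_episode(intake_task, space, AgentParams(), agent, rng)
        assert len(traj) == 100
        assert not traj.censored

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_intake_task(k_intake=0.0)
        with pytest.raises(ValueError):
            build_intake_task(episode_length=0)


class TestMountainTaskSpec:
    def test_two_actions_per_state(self, mountain_task):
        for s in mountain_task.states:
            assert len(mountain_task.actions_of[s]) == 2

    def test_chain_topology(self, mountain_task):
        t = mountain_task
        assert t.next_state[("S0", "small_intake")] == "S0"
        assert t.next_state[("S0", "move")] == "S1"
        assert t.next_state[("S1", "move")] == "S0"
        assert t.next_state[("S3", "climb")] == "S4"
        assert t.next_state[("S3", "descend")] == "S2"
        assert t.next_state[("S7", "large_intake")] == "S0"
        assert ("S7", "large_intake") in t.terminal

    def test_costs_only_on_climbs(self, mountain_task):
        t = mountain_task
        assert t.cost_of[("S5", "climb")] == 0.3
        assert t.cost_of[("S5", "descend")] == 0.0
        assert t.cost_of[("S0", "small_intake")] == 0.0
        assert t.cost_of[("S7", "large_intake")] == 0.0

    def test_shortest_path_to_summit_is_eight_steps(self, mountain_task):
        """Graph search: move, six climbs, large intake."""
        t = mountain_task
        dist = {t.initial_state: 0}
        frontier = [t.initial_state]
        steps_to_terminal = None
        while frontier:
            nxt = []
            for s in frontier:
                for a in t.actions_of[s]:
                    if (s, a) in t.terminal:
                        d = dist[s] + 1
                        steps_to_terminal = (d if steps_to_terminal is None
                                             else min(steps_to_terminal, d))
                        continue
                    s2 = t.next_state[(s, a)]
                    if s2 not in dist:
                        dist[s2] = dist[s] + 1
                        nxt.append(s2)
            frontier = nxt
        assert steps_to_terminal == 8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            build_mountain_task(step_cap=0)


class TestRunEpisode:
    def test_no_learning_leaves_tables_unchanged(self, intake_task, space, rng):
        params = AgentParams(alpha_q=0.0, alpha_k=0.0, beta=1e-5)
        agent = AgentState.for_task(intake_task)
        before_q, before_k = dict(agent.q), dict(agent.k_hat)
        traj, agent = run_episode(intake_task, space, params, agent, rng)
        assert agent.q == before_q and agent.k_hat == before_k

    def test_deterministic_for_fixed_seed(self, mountain_task, space):
        params = AgentParams(alpha_q=0.5, alpha_k=0.05, beta=1.5e-6,
                             gamma=0.95)
        results = []
        for _ in range(2):
            agent = AgentState.for_task(mountain_task)
            traj, agent = run_episode(mountain_task, space, params, agent,
                                      np.random.default_rng(5))
            results.append(([(t.state, t.action, t.H_after, t.reward)
                             for t in traj], dict(agent.q)))
        assert results[0] == results[1]

    def test_transition_identity_replayed(self, mountain_task, space, rng):
        """Every step satisfies H' = (1 - 1/tau) H + K - cost exactly."""
        params = AgentParams(alpha_q=0.5, alpha_k=0.05, beta=1.5e-6,
                             gamma=0.95)
        agent = AgentState.for_task(mountain_task)
        traj, _ = run_episode(mountain_task, space, params, agent, rng)
        for tr in traj:
            key = (tr.state, tr.action)
            expected = ((1 - 1 / space.tau) * tr.H_before
                        + mountain_task.intake_of[key]
                        - mountain_task.cost_of[key])
            assert tr.H_after == pytest.approx(expected, rel=1e-12)

    def test_episode_ends_at_terminal_action(self, mountain_task, space):
        params = AgentParams(alpha_q=0.5, alpha_k=0.05, beta=1.5e-6,
                             gamma=0.95)
        agent = AgentState.for_task(mountain_task)
        traj, _ = run_episode(mountain_task, space, params, agent,
                              np.random.default_rng(0))
        last = traj.transitions[-1]
        assert ((last.state, last.action) in mountain_task.terminal
                or traj.censored)

    def test_drive_columns_replayable_from_H(self, intake_task, space, rng):
        """Stored drives equal drive recomputed from the stored states."""
        params = AgentParams(alpha_q=0.05, alpha_k=0.5, beta=3.5e-5)
        agent = AgentState.for_task(intake_task)
        traj, _ = run_episode(intake_task, space, params, agent, rng)
        for tr in traj:
            assert tr.drive_before == pytest.approx(drive(tr.H_before, space))
            assert tr.drive_objective_before == pytest.approx(
                drive(tr.H_before, space.replace(eta=1.0)))


class TestRunTrial:
    @pytest.fixture
    def trial_result(self, mountain_task, space):
        params = AgentParams(alpha_q=0.5, alpha_k=0.05, beta=1.5e-6,
                             gamma=0.95)
        agent = AgentState.for_task(mountain_task)
        return run_trial(mountain_task, space, params, agent,
                         np.random.default_rng(11), n_episodes=15)

    def test_fifteen_trajectories(self, trial_result):
        trajectories, _ = trial_result
        assert len(trajectories) == 15
        for traj in trajectories:
            last = traj.transitions[-1]
            assert (last.state, last.action) == ("S7", "large_intake") \
                or traj.censored

    def test_internal_state_resets_each_episode(self, trial_result):
        trajectories, _ = trial_result
        for traj in trajectories:
            assert traj.transitions[0].H_before == 100.0
            assert traj.transitions[0].state == "S0"

    def test_values_carry_over_across_episodes(self, mountain_task, space):
        params = AgentParams(alpha_q=0.5, alpha_k=0.05, beta=1.5e-6,
                             gamma=0.95)
        agent = AgentState.for_task(mountain_task)
        rng = np.random.default_rng(11)
        _, agent = run_episode(mountain_task, space, params, agent, rng, 0)
        snapshot = dict(agent.q)
        # continuing the same agent must start from the carried-over tables
        traj2, agent = run_episode(mountain_task, space, params, agent, rng, 1)
        key = (traj2.transitions[0].state, traj2.transitions[0].action)
        # first update of episode 2 acted on the snapshot value
        assert agent.q[key] != snapshot[key] or params.alpha_q == 0


class TestTrajectoryFrame:
    def test_one_row_per_timestep_with_schema(self, intake_task, space, rng):
        params = AgentParams(alpha_q=0.05, alpha_k=0.5, beta=3.5e-5)
        agent = AgentState.for_task(intake_task)
        traj, _ = run_episode(intake_task, space, params, agent, rng)
        df = trajectory_frame(traj, trial=3)
        assert len(df) == 100
        for col in ("trial", "episode", "t", "state", "action", "H_before",
                    "H_after", "reward", "drive", "reward_objective",
                    "p_action0", "p_action1"):
            assert col in df.columns
        assert (df["trial"] == 3).all()
        assert df["t"].tolist() == list(range(100))
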