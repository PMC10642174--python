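"""Decisional-logic engine: perception, images, steps, attractors, predecessors."""

import numpy as np
import pytest

from biobehnet.logic_engine import (EngineError, LogicProgram, image,
                                    is_fixed_point, perceived_input,
                                    predecessors, step, trajectory)
from conftest import (make_net, oracle_image, oracle_perceived,
                      oracle_predecessors, oracle_step, oracle_all_states,
                      random_net, random_program, random_state)


@pytest.fixture
def maoa_motif():
    """Negative feedback through PTSD severity, positive through depression:
    MAOA reads an inhibitor perceived at moderate severity and an activator
    only perceived at high severity."""
    net = make_net([("PTSD", "MAOA", -1), ("Depression", "MAOA", 1),
                    ("MAOA", "PTSD", 1), ("MAOA", "Depression", -1)],
                   kinds={"PTSD": "behavioral", "Depression": "behavioral"})
    prog = LogicProgram({("PTSD", "MAOA"): (1, 1),
                         ("Depression", "MAOA"): (2, 2),
                         ("MAOA", "PTSD"): (1, 1),
                         ("MAOA", "Depression"): (1, 1)})
    return net, prog


class TestPerceivedInput:
    def test_weak_inhibitor_beats_imperceptible_activator(self, maoa_motif):
        net, prog = maoa_motif
        state = {"MAOA": 1, "PTSD": 1, "Depression": 1}
        assert perceived_input("MAOA", state, net, prog) == -1

    def test_strong_activator_once_perceptible(self, maoa_motif):
        net, prog = maoa_motif
        state = {"MAOA": 1, "PTSD": 1, "Depression": 2}
        assert perceived_input("MAOA", state, net, prog) == +1

    def test_all_sources_below_threshold(self, maoa_motif):
        net, prog = maoa_motif
        state = {"MAOA": 2, "PTSD": 0, "Depression": 0}
        assert perceived_input("MAOA", state, net, prog) == 0


class TestImage:
    def test_negative_drive_decreases(self, maoa_motif):
        net, prog = maoa_motif
        state = {"MAOA": 2, "PTSD": 1, "Depression": 1}
        assert image("MAOA", state, net, prog) == 1

    def test_floor_and_ceiling_clamp(self, maoa_motif):
        net, prog = maoa_motif
        assert image("MAOA", {"MAOA": 0, "PTSD": 3, "Depression": 0},
                     net, prog) == 0
        assert image("MAOA", {"MAOA": 3, "PTSD": 0, "Depression": 3},
                     net, prog) == 3

    def test_tie_rules(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)])
        hold = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)})
        decay = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)},
                             tie_rule="decay")
        state = {"A": 0, "B": 2}  # B sees nothing (A at 0)
        assert image("B", state, net, hold) == 2
        assert image("B", state, net, decay) == 1

    def test_stressor_holds_its_level(self):
        net = make_net([("S", "A", 1), ("A", "B", 1), ("B", "A", 1)],
                       kinds={"S": "stressor"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        assert image("S", {"S": 2, "A": 3, "B": 3}, net, prog) == 2


class TestStep:
    def test_fixed_point_unchanged(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)})
        s0 = {"A": 0, "B": 0}
        assert step(s0, two_node_feedback, prog) == s0
        assert is_fixed_point(s0, two_node_feedback, prog)

    def test_synchronous_two_node(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)})
        assert step({"A": 3, "B": 0}, two_node_feedback, prog) == {"A": 3, "B": 1}

    def test_asynchronous_moves_one_node_deterministically(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)},
                            update_scheme="asynchronous")
        s0 = {"A": 3, "B": 1}  # both A (inhibited by B) and B (activated) move
        succ = [step(s0, two_node_feedback, prog, rng=7) for _ in range(5)]
        assert all(s == succ[0] for s in succ)
        diff = [n for n in s0 if succ[0][n] != s0[n]]
        assert len(diff) == 1

    def test_clamp_pins_node(self):
        net = make_net([("S", "A", 1), ("A", "B", 1), ("B", "A", -1)],
                       kinds={"S": "stressor"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        s1 = step({"S": 0, "A": 0, "B": 0}, net, prog, clamps={"S": 3})
        assert s1["S"] == 3


class TestTrajectory:
    def test_start_at_fixed_point(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)})
        traj = trajectory({"A": 0, "B": 0}, two_node_feedback, prog)
        assert traj.transient_length == 0
        assert traj.is_fixed_point and traj.attractor == [{"A": 0, "B": 0}]

    @pytest.mark.parametrize("tie", ["hold", "decay"])
    def test_attractor_matches_naive_transition_graph(self, two_node_feedback, tie):
        """Attractors read off the full 16-state transition graph built with
        the naive oracle (the A->B, B-|A loop from (3,0) settles into the
        (0,3) fixed point under gradual +-1 kinetics)."""
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)},
                            tie_rule=tie)
        for a0 in range(4):
            start0 = {"A": a0, "B": 0}
            traj = trajectory(dict(start0), two_node_feedback, prog)
            seen = {}
            s = dict(start0)
            path = [s]
            while tuple(sorted(s.items())) not in seen:
                seen[tuple(sorted(s.items()))] = len(path) - 1
                s = oracle_step(s, two_node_feedback, prog)
                path.append(s)
            start = seen[tuple(sorted(s.items()))]
            assert traj.transient_length == start
            assert traj.attractor == path[start:-1]

    def test_period_two_cycle(self):
        """Mutual activation with decay ties oscillates: (0,1) <-> (1,0)."""
        net = make_net([("A", "B", 1), ("B", "A", 1)])
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)},
                            tie_rule="decay")
        traj = trajectory({"A": 0, "B": 1}, net, prog)
        assert traj.period == 2 and traj.transient_length == 0
        assert traj.attractor == [{"A": 0, "B": 1}, {"A": 1, "B": 0}]

    def test_no_inputs_every_state_fixed(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)])
        prog = LogicProgram({("A", "B"): (3, 1), ("B", "A"): (3, 1)})
        for a in range(3):  # below every threshold
            traj = trajectory({"A": a, "B": a}, net, prog)
            assert traj.is_fixed_point and traj.transient_length == 0

    def test_horizon_error(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)},
                            update_scheme="asynchronous")
        with pytest.raises(EngineError, match="horizon"):
            trajectory({"A": 3, "B": 0}, two_node_feedback, prog, max_steps=1,
                       rng=0)


class TestPredecessors:
    def test_fixed_point_is_own_predecessor(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 1), ("B", "A"): (1, 1)})
        p = {"A": 0, "B": 0}
        assert p in predecessors(p, two_node_feedback, prog)

    def test_matches_forward_enumeration(self, two_node_feedback):
        prog = LogicProgram({("A", "B"): (1, 2), ("B", "A"): (2, 1)})
        for target in oracle_all_states(two_node_feedback):
            got = predecessors(target, two_node_feedback, prog)
            expect = oracle_predecessors(target, two_node_feedback, prog)
            assert sorted(map(sorted, (g.items() for g in got))) == \
                sorted(map(sorted, (e.items() for e in expect)))

    def test_garden_of_eden_state(self):
        # clamp-free stressor keeps its level, so a state where the non-
        # stressor node sits 2 levels from anything reachable has no preimage
        net = make_net([("S", "A", 1), ("A", "B", 1), ("B", "A", 1)],
                       kinds={"S": "stressor"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        found = set()
        for y in oracle_all_states(net):
            found.add(tuple(sorted(oracle_step(y, net, prog).items())))
        unreachable = [s for s in oracle_all_states(net)
                       if tuple(sorted(s.items())) not in found]
        assert unreachable, "crafted net should have garden-of-eden states"
        for s in unreachable[:5]:
            assert predecessors(s, net, prog) == []

    def test_budget_error_and_candidate_mode(self):
        ids = [f"N{i}" for i in range(12)]
        edges = [(ids[i], ids[(i + 1) % 12], 1) for i in range(12)]
        net = make_net(edges)
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        zero = {i: 0 for i in ids}
        with pytest.raises(EngineError, match="candidate"):
            predecessors(zero, net, prog, max_states=4 ** 8)
        assert predecessors(zero, net, prog, candidates=[zero]) == [zero]


class TestOracleEquivalence:
    @pytest.mark.parametrize("chunk", range(10))
    def test_engine_matches_naive_oracle(self, chunk):
        """step/image/perceived/fixed-point equal a naive dict-based oracle
        on random (network, program, state) triples."""
        rng = np.random.default_rng(5000 + chunk)
        for _ in range(50):
            net = random_net(rng, with_stressor=bool(rng.integers(2)))
            prog = random_program(rng, net)
            state = random_state(rng, net)
            assert step(state, net, prog) == oracle_step(state, net, prog)
            for node in net.node_ids:
                assert image(node, state, net, prog) == \
                    oracle_image(node, state, net, prog)
                if net.nodes[node].kind != "stressor":
                    assert perceived_input(node, state, net, prog) == \
                        oracle_perceived(node, state, net, prog)
            assert is_fixed_point(state, net, prog) == \
                (oracle_step(state, net, prog) == state)

    @pytest.mark.parametrize("seed", range(20))
    def test_synchronous_transition_graph_is_total_function(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, n_nodes=int(rng.integers(2, 5)))
        prog = random_program(rng, net)
        for s in oracle_all_states(net):
            succ = step(s, net, prog)
            assert set(succ) == set(s)
            # determinism
            assert step(s, net, prog) == succ
            # fixed-point iff self-predecessor
            fp = is_fixed_point(s, net, prog)
            assert fp == (succ == s)
            if len(net.nodes) <= 3:
                assert fp == (s in predecessors(s, net, prog))

    @pytest.mark.parametrize("seed", range(30))
    def test_monotone_gating(self, seed):
        """Raising a source level never flips the sign of an edge's
        contribution; it only switches it on at the threshold."""
        rng = np.random.default_rng(200 + seed)
        net = random_net(rng)
        prog = random_program(rng, net)
        state = random_state(rng, net)
        for (src, tgt), e in net.edges.items():
            if net.nodes[tgt].kind == "stressor":
                continue
            contribs = []
            for lv in range(4):
                s = dict(state)
                s[src] = lv
                tau, w = prog.params[(src, tgt)]
                contribs.append(e.sign * w * (lv >= tau))
            mags = [abs(c) for c in contribs]
            assert mags == sorted(mags)  # off below tau, on at/above
            signs = {np.sign(c) for c in contribs if c != 0}
            assert len(signs) <= 1
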