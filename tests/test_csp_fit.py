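"""CSP fitter: imputation, program search, persistence, course prediction."""

import numpy as np
import pytest

from biobehnet.csp_fit import (FitConfig, FitError, fit, impute_hidden,
                               persistence_test, predict_course)
from biobehnet.logic_engine import LogicProgram, step
from biobehnet.profiles import SubjectProfile
from biobehnet.synthetic_data import make_bundle
from conftest import make_net, oracle_fit, oracle_min_departure


def _toy_instance(rng, n_subjects=2):
    """Random toy net (<=5 edges, <=4 hidden nodes) with observed nodes."""
    while True:
        n_hidden = int(rng.integers(1, 5))
        n_obs = int(rng.integers(1, 3))
        ids = [f"H{i}" for i in range(n_hidden)] + [f"O{i}" for i in range(n_obs)]
        kinds = {f"O{i}": "behavioral" for i in range(n_obs)}
        n_edges = int(rng.integers(1, 6))
        pairs = [(s, t) for s in ids for t in ids if s != t]
        take = rng.choice(len(pairs), size=min(n_edges, len(pairs)),
                          replace=False)
        edges = [(pairs[i][0], pairs[i][1],
                  1 if rng.random() < 0.7 else -1) for i in take]
        try:
            net = make_net(edges, kinds=kinds)
        except Exception:
            continue
        if not net.behavioral:
            continue
        subjects = [
            SubjectProfile(f"S{k}", {b: int(rng.integers(0, 4))
                                     for b in net.behavioral})
            for k in range(n_subjects)]
        control = {b: 0 for b in net.behavioral}
        return net, subjects, control


class TestImputeHidden:
    def test_unconstrained_hidden_nodes(self):
        # hidden node feeds nothing observed: any level appears among optima
        net = make_net([("H", "X", 1), ("X", "H", 1),
                        ("A", "B", 1), ("B", "A", 1)],
                       kinds={"A": "behavioral", "B": "behavioral"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        subj = SubjectProfile("s", {"A": 0, "B": 0})
        res = impute_hidden(net, prog, subj, cap=5000)
        assert res and all(d.absolute == 0 for _, d in res)
        h_levels = {s["H"] for s, _ in res}
        assert h_levels == {0, 1, 2, 3}

    def test_planted_state_among_optima_with_true_program(self):
        b = make_bundle(seed=5)
        for prof in b.observed:
            truth, _ = b.truth_states[prof.subject_id]
            res = impute_hidden(b.network, b.truth_program, prof, cap=100000)
            assert res
            assert min(d.absolute for _, d in res) == 0
            assert any(s == truth for s, _ in res)

    def test_mid_transient_state_has_no_fixed_point_completion(self):
        # B observed at 1 with its only regulator A observed at 3 via an
        # inhibitor: the forced negative drive contradicts holding level 1
        net = make_net([("A", "B", -1), ("B", "A", 1), ("A", "H", 1),
                        ("H", "A", 1)],
                       kinds={"A": "behavioral", "B": "behavioral"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        subj = SubjectProfile("s", {"A": 3, "B": 1})
        res = impute_hidden(net, prog, subj, consistency="fixed_point")
        # brute force: no completion with A=3,B=1 can be a fixed point
        from conftest import oracle_all_states, oracle_step
        assert not any(
            oracle_step(s, net, prog) == s
            for s in oracle_all_states(net)
            if s["A"] == 3 and s["B"] == 1)
        assert min((d.absolute for _, d in res), default=99) > 0

    @pytest.mark.parametrize("consistency", ["has_predecessor", "fixed_point"])
    @pytest.mark.parametrize("seed", range(15))
    def test_min_departure_matches_enumeration(self, consistency, seed):
        rng = np.random.default_rng(3000 + seed)
        net, subjects, _ = _toy_instance(rng)
        from conftest import random_program
        prog = random_program(rng, net, tie_rule="hold")
        for subj in subjects:
            res = impute_hidden(net, prog, subj, consistency=consistency,
                                cap=100000)
            expect = oracle_min_departure(net, prog, subj.observed, consistency)
            if expect is None:
                assert res == []
            else:
                assert res
                assert res[0][1].absolute == expect
                # every reported optimum passes an independent recheck
                for state, dep in res[:50]:
                    assert sum(abs(state[k] - v)
                               for k, v in subj.observed.items()) == dep.absolute
                    if consistency == "fixed_point":
                        assert step(state, net, prog) == state


class TestFitAgainstEnumeration:
    def test_tiny_two_edge_example(self):
        net = make_net([("H", "O", 1), ("O", "H", 1)],
                       kinds={"O": "behavioral"})
        subjects = [SubjectProfile("s1", {"O": 2})]
        control = {"O": 0}
        cfg = FitConfig(tau_domain=(1, 2), w_domain=(1,), search="exhaustive")
        r = fit(net, subjects, control, cfg)
        best, best_progs, feas = oracle_fit(net, subjects, control,
                                            cfg.pair_domain)
        assert r.departure.absolute == best
        assert {tuple(p.params[k] for k in sorted(net.edges))
                for p in r.programs} == best_progs
        assert r.feasible_count == len(feas)

    @pytest.mark.parametrize("seed", range(25))
    def test_exhaustive_fit_equals_naive_enumeration(self, seed):
        """Optimal departure, the full optimal-program set and the feasible
        count all match brute force over programs x completions."""
        rng = np.random.default_rng(4000 + seed)
        net, subjects, control = _toy_instance(rng)
        cfg = FitConfig(tau_domain=(1, 2), w_domain=(1, 2),
                        search="exhaustive", program_cap=100000)
        r = fit(net, subjects, control, cfg)
        best, best_progs, feas = oracle_fit(net, subjects, control,
                                            cfg.pair_domain)
        assert r.departure.absolute == best
        got = {tuple(p.params[k] for k in sorted(net.edges))
               for p in r.programs}
        assert got == best_progs
        assert r.feasible_count == len(feas)

    @pytest.mark.parametrize("seed", range(10))
    def test_backtracking_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(6000 + seed)
        net, subjects, control = _toy_instance(rng)
        cfg_e = FitConfig(search="exhaustive")
        cfg_b = FitConfig(search="backtracking_propagation")
        re_ = fit(net, subjects, control, cfg_e)
        rb = fit(net, subjects, control, cfg_b)
        assert re_.departure.absolute == rb.departure.absolute

    def test_domain_enlargement_never_hurts(self):
        rng = np.random.default_rng(99)
        net, subjects, control = _toy_instance(rng)
        small = fit(net, subjects, control,
                    FitConfig(tau_domain=(1,), w_domain=(1,),
                              search="exhaustive"))
        large = fit(net, subjects, control,
                    FitConfig(tau_domain=(1, 2, 3), w_domain=(1, 2),
                              search="exhaustive"))
        assert large.departure.absolute <= small.departure.absolute

    def test_planted_noiseless_reaches_zero(self):
        b = make_bundle(seed=4)
        r = fit(b.network, b.observed, b.control,
                FitConfig(search="backtracking_propagation"))
        assert r.feasible and r.departure.absolute == 0
        # stored departures re-derive from the stored states
        for sid, sf in r.per_subject.items():
            obs = next(p for p in b.observed if p.subject_id == sid).observed
            for st in sf.states[:20]:
                assert sum(abs(st[k] - v) for k, v in obs.items()) \
                    == sf.departure.absolute

    def test_empty_subjects_error(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)],
                       kinds={"B": "behavioral"})
        with pytest.raises(FitError):
            fit(net, [], {"B": 0})


class TestPersistence:
    def test_fixed_point_subjects_feasible(self):
        # subjects sitting exactly at a planted fixed point
        b = make_bundle(seed=4, snapshot_window=(30, 32))
        from biobehnet.logic_engine import trajectory
        feasible, count = persistence_test(b.network, b.observed, b.control,
                                           FitConfig())
        # construction: the planted trajectory has settled by t=30 only if
        # its attractor is a fixed point; verify premise, then feasibility
        traj = trajectory(b.trajectory_states[0], b.network, b.truth_program,
                          clamps=None, max_steps=4096)
        if all(b.truth_states[p.subject_id][0] ==
               step(b.truth_states[p.subject_id][0], b.network, b.truth_program)
               for p in b.observed):
            assert feasible and count > 0

    def test_conflicting_profile_infeasible(self):
        # two mutually inhibiting constructs at (3, 1): B's only regulator
        # drives it down, so no program stabilizes the pair; verified
        # exhaustively by the naive oracle
        net = make_net([("A", "B", -1), ("B", "A", 1)],
                       kinds={"A": "behavioral", "B": "behavioral"})
        subjects = [SubjectProfile("s", {"A": 3, "B": 1})]
        control = {"A": 0, "B": 0}
        cfg = FitConfig(search="exhaustive")
        feasible, count = persistence_test(net, subjects, control, cfg)
        _, _, feas = oracle_fit(net, subjects, control, cfg.pair_domain,
                                consistency="fixed_point", max_departure=0)
        assert feas == set() and not feasible and count == 0

    def test_zero_subjects_error(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)],
                       kinds={"B": "behavioral"})
        with pytest.raises(FitError):
            persistence_test(net, [], {"B": 0})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_on_toys(self, seed):
        rng = np.random.default_rng(7000 + seed)
        net, subjects, control = _toy_instance(rng, n_subjects=1)
        cfg = FitConfig(tau_domain=(1, 2), w_domain=(1, 2),
                        search="exhaustive", program_cap=100000)
        feasible, count = persistence_test(net, subjects, control, cfg)
        _, _, feas = oracle_fit(net, subjects, control, cfg.pair_domain,
                                consistency="fixed_point", max_departure=0)
        assert feasible == bool(feas)
        assert count == len(feas)


class TestPredictCourse:
    def test_fixed_point_start_is_flat(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)],
                       kinds={"B": "behavioral"})
        prog = LogicProgram({k: (1, 1) for k in net.edges})
        traj, labels = predict_course(net, prog, {"A": 0, "B": 0})
        assert set(labels.values()) == {"flat"}

    def test_decaying_cascade_labels_decreasing(self):
        # stressor withdrawn: downstream severities relax monotonically
        net = make_net([("S", "A", 1), ("A", "B", 1), ("B", "A", -1)],
                       kinds={"S": "stressor", "B": "behavioral"})
        prog = LogicProgram({k: (1, 2) for k in net.edges})
        # state reached mid-response with the stressor already back at 0
        state = {"S": 0, "A": 3, "B": 1}
        traj, labels = predict_course(net, prog, state)
        assert labels["S"] == "flat"
        assert labels["A"] in ("decreasing", "non-monotone")

    def test_two_cycle_is_non_monotone(self):
        net = make_net([("A", "B", 1), ("B", "A", 1)])
        prog = LogicProgram({k: (1, 1) for k in net.edges}, tie_rule="decay")
        traj, labels = predict_course(net, prog, {"A": 0, "B": 1})
        assert labels["A"] == "non-monotone" and labels["B"] == "non-monotone"
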