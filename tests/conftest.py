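"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (dict loops,
full-state enumeration, numpy vectorized transition tables) kept separate
from the package's compiled search machinery, so that agreement between the
two routes is meaningful.
"""

import itertools

import numpy as np
import pytest

from biobehnet.network_io import Edge, Network, Node

LEVELS = (0, 1, 2, 3)


# ---------------------------------------------------------------------------
# simple hand-built networks
# ---------------------------------------------------------------------------

def make_net(edges, kinds=None, polarities=None, allow_self_loops=False):
    """edges: list of (src, tgt, sign[, n_citations]); kinds: dict id->kind."""
    kinds = kinds or {}
    polarities = polarities or {}
    ids = sorted({e[0] for e in edges} | {e[1] for e in edges})
    nodes = [Node(i, kinds.get(i, "molecular"), polarities.get(i, "none"))
             for i in ids]
    es = [Edge(e[0], e[1], e[2], e[3] if len(e) > 3 else 0) for e in edges]
    return Network.from_parts(nodes, es, allow_self_loops=allow_self_loops)


@pytest.fixture
def three_cycle():
    return make_net([("A", "B", 1), ("B", "C", -1), ("C", "A", 1)])


@pytest.fixture
def two_node_feedback():
    # A activates B, B inhibits A: the canonical negative feedback loop
    return make_net([("A", "B", 1), ("B", "A", -1)])


# ---------------------------------------------------------------------------
# naive logic-engine oracle (pure dict arithmetic)
# ---------------------------------------------------------------------------

def oracle_perceived(node, state, net, prog):
    s = 0
    for (src, tgt), e in net.edges.items():
        if tgt != node:
            continue
        tau, w = prog.params[(src, tgt)]
        if state[src] >= tau:
            s += e.sign * w
    return s


def oracle_image(node, state, net, prog):
    if net.nodes[node].kind == "stressor":
        return state[node]
    s = oracle_perceived(node, state, net, prog)
    l = state[node]
    if s > 0:
        return min(l + 1, 3)
    if s < 0:
        return max(l - 1, 0)
    if prog.tie_rule == "hold":
        return l
    return max(l - 1, 0)


def oracle_step(state, net, prog):
    return {n: oracle_image(n, state, net, prog) for n in state}


def oracle_all_states(net):
    ids = sorted(net.nodes)
    for combo in itertools.product(LEVELS, repeat=len(ids)):
        yield dict(zip(ids, combo))


def oracle_predecessors(state, net, prog):
    return [y for y in oracle_all_states(net)
            if oracle_step(y, net, prog) == state]


def oracle_fixed_points(net, prog):
    return [s for s in oracle_all_states(net)
            if oracle_step(s, net, prog) == s]


# ---------------------------------------------------------------------------
# vectorized full-enumeration fit oracle (numpy transition tables)
# ---------------------------------------------------------------------------

def _state_matrix(n):
    """All 4^n states as an array of shape (4^n, n)."""
    grids = np.meshgrid(*([np.arange(4)] * n), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def oracle_step_matrix(net, prog, states=None):
    """Vectorized synchronous step applied to every row of ``states``."""
    ids = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    if states is None:
        states = _state_matrix(len(ids))
    img = states.copy()
    for i, nid in enumerate(ids):
        if net.nodes[nid].kind == "stressor":
            continue
        s = np.zeros(states.shape[0], dtype=int)
        for (src, tgt), e in net.edges.items():
            if tgt != nid:
                continue
            tau, w = prog.params[(src, tgt)]
            s += e.sign * w * (states[:, idx[src]] >= tau)
        lv = states[:, i]
        up = np.minimum(lv + 1, 3)
        down = np.maximum(lv - 1, 0)
        tie = lv if prog.tie_rule == "hold" else down
        img[:, i] = np.where(s > 0, up, np.where(s < 0, down, tie))
    return img


def oracle_min_departure(net, prog, observed, consistency):
    """Minimal Manhattan departure on observed nodes over all consistent
    full states, by complete enumeration.  Returns None if no state is
    consistent."""
    ids = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    states = _state_matrix(len(ids))
    img = oracle_step_matrix(net, prog, states)
    if consistency == "fixed_point":
        ok = np.all(img == states, axis=1)
        cand = states[ok]
    elif consistency == "has_predecessor":
        keys = {tuple(r) for r in img}
        cand = np.array([r for r in states if tuple(r) in keys])
    else:  # on_attractor_path: all synchronous states reach an attractor
        cand = states
    if cand.size == 0:
        return None
    cost = np.zeros(cand.shape[0], dtype=int)
    for nid, lv in observed.items():
        cost += np.abs(cand[:, idx[nid]] - lv)
    return int(cost.min())


def oracle_control_ok(net, prog, control):
    ids = sorted(net.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    states = _state_matrix(len(ids))
    img = oracle_step_matrix(net, prog, states)
    fixed = states[np.all(img == states, axis=1)]
    if fixed.size == 0:
        return False
    ok = np.ones(fixed.shape[0], dtype=bool)
    for nid, lv in control.items():
        ok &= fixed[:, idx[nid]] == lv
    return bool(ok.any())


def oracle_fit(net, subjects, control, pair_domain, tie_rule="hold",
               consistency="has_predecessor", max_departure=None):
    """Naive exhaustive fit: enumerate every program, evaluate exactly.

    Returns (best_cost, set of optimal programs, set of feasible programs).
    """
    from biobehnet.logic_engine import LogicProgram
    pairs = sorted(net.edges)
    best = None
    best_progs = set()
    feasible = set()
    for combo in itertools.product(pair_domain, repeat=len(pairs)):
        prog = LogicProgram(dict(zip(pairs, combo)), tie_rule=tie_rule)
        if not oracle_control_ok(net, prog, control):
            continue
        total = 0
        bad = False
        for p in subjects:
            c = oracle_min_departure(net, prog, p.observed, consistency)
            if c is None:
                bad = True
                break
            total += c
        if bad or (max_departure is not None and total > max_departure):
            continue
        feasible.add(combo)
        if best is None or total < best:
            best = total
            best_progs = {combo}
        elif total == best:
            best_progs.add(combo)
    return best, best_progs, feasible


def oracle_bh_adjust(pvals, q):
    """Textbook step-up: k* = max{k: p(k) <= kq/m}; adjusted p by the
    cumulative-minimum formula."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    srt = np.asarray(pvals)[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(srt <= thresh)[0]
    kstar = below[-1] + 1 if below.size else 0
    reject = np.zeros(m, bool)
    reject[order[:kstar]] = True
    adj_sorted = np.minimum.accumulate((srt * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, reject


# ---------------------------------------------------------------------------
# random generators for property tests
# ---------------------------------------------------------------------------

def random_net(rng, n_nodes=None, with_stressor=False, p_edge=0.35):
    n = n_nodes or int(rng.integers(2, 7))
    ids = [f"N{i}" for i in range(n)]
    kinds = {}
    if with_stressor:
        kinds[ids[0]] = "stressor"
    edges = []
    for s in ids:
        for t in ids:
            if s == t:
                continue
            if kinds.get(t) == "stressor":
                continue
            if rng.random() < p_edge:
                sign = 1 if rng.random() < 0.7 else -1
                edges.append((s, t, sign, int(rng.integers(1, 20))))
    if not edges:
        edges = [(ids[0], ids[-1], 1, 1)] if n > 1 else []
    return make_net(edges, kinds=kinds)


def random_program(rng, net, tau_domain=(1, 2, 3), w_domain=(1, 2),
                   tie_rule=None):
    from biobehnet.logic_engine import LogicProgram
    tie = tie_rule or ("hold" if rng.random() < 0.8 else "decay")
    params = {}
    for pair in sorted(net.edges):
        params[pair] = (int(rng.choice(tau_domain)), int(rng.choice(w_domain)))
    return LogicProgram(params, tie_rule=tie, w_max=max(w_domain))


def random_state(rng, net):
    return {nid: int(rng.integers(0, 4)) for nid in sorted(net.nodes)}
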