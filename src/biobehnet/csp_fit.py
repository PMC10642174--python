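"""Constraint-based identification of decisional-logic parameters and hidden states.

The fitting problem: given the network topology, per-edge sign, and partial
cross-sectional observations (behavioral constructs of each subject, plus an
idealized control that must sit at a stable resting state), find perception
thresholds and logic weights — one (tau, w) pair per edge — together with
full molecular completions of every subject's state, such that

* each subject's full state is dynamically consistent (by default: it has at
  least one synchronous predecessor, i.e. it could be a snapshot of an
  ongoing response; optionally: it is itself a fixed point), and
* the Manhattan departure between the predicted and observed behavioral
  levels, aggregated over subjects, is minimal.

Because the synchronous update decouples subjects once the program is fixed,
the search is organized as a branch-and-bound over programs with an inner
branch-and-bound over states per subject.  Key structural fact exploited
throughout: the departure depends only on the images of *observed* nodes, so
only the parameters of edges pointing into observed nodes can change the
optimum; the remaining parameters shape the imputed hidden levels and are
enumerated only when collecting optima.

The persistence test re-runs the fit demanding that every subject's full
state be a fixed point reproducing the observations exactly; feasibility of
that stricter problem distinguishes chronic self-sustaining pathology from a
transient snapshot of an active response.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np

from .logic_engine import (LEVELS, MAX_LEVEL, LogicProgram, Trajectory,
                           trajectory as run_trajectory)
from .network_io import Network
from .profiles import (Departure, SubjectProfile, aggregate_departure,
                       manhattan_departure)

CONSISTENCY_MODES = ("has_predecessor", "fixed_point", "on_attractor_path")
SEARCH_MODES = ("auto", "exhaustive", "backtracking_propagation", "local_search")


class FitError(ValueError):
    pass


@dataclass
class FitConfig:
    """Search-space and strategy configuration for the CSP fit."""

    tau_domain: tuple[int, ...] = (1, 2, 3)
    w_domain: tuple[int, ...] = (1, 2)
    tie_rule: str = "hold"
    consistency: str = "has_predecessor"
    search: str = "auto"
    seed: int = 0
    max_departure: int | None = None      # absolute aggregate budget
    exhaustive_cap: int = 100_000         # max program-space size for exhaustive
    solution_cap: int = 1000              # retained optima per subject
    program_cap: int = 1000               # retained optimal programs
    program_states_cap: int = 10          # optimal programs pooled for states
    local_restarts: int = 8

    def __post_init__(self) -> None:
        if not self.tau_domain or not self.w_domain:
            raise FitError("tau/w domains must be nonempty")
        if self.consistency not in CONSISTENCY_MODES:
            raise FitError(f"unknown consistency mode {self.consistency!r}")
        if self.search not in SEARCH_MODES:
            raise FitError(f"unknown search mode {self.search!r}")
        if any(t not in (1, 2, 3) for t in self.tau_domain):
            raise FitError("tau domain must lie in {1,2,3}")
        if any(w < 1 for w in self.w_domain):
            raise FitError("weights must be positive")

    @property
    def pair_domain(self) -> list[tuple[int, int]]:
        return [(t, w) for t in sorted(self.tau_domain) for w in sorted(self.w_domain)]


@dataclass
class SubjectFit:
    """Optimal imputation for one subject under the selected program(s)."""

    departure: Departure
    states: list[dict[str, int]]
    modal_state: dict[str, int]
    modal_agreement: dict[str, float]


@dataclass
class FitResult:
    programs: list[LogicProgram]
    feasible_count: int | None
    departure: Departure | None           # aggregate at the optimum
    per_subject: dict[str, SubjectFit]
    control_state: dict[str, int] | None
    search_mode: str
    seed: int
    config: FitConfig

    @property
    def feasible(self) -> bool:
        return bool(self.programs)

    def to_json_obj(self, net: Network) -> dict:
        return {
            "search_mode": self.search_mode,
            "seed": self.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "feasible_count": self.feasible_count,
            "aggregate_departure": None if self.departure is None else {
                "absolute": self.departure.absolute,
                "normalized": self.departure.normalized,
            },
            "programs": [p.to_json_obj(net) for p in self.programs[:25]],
            "n_programs_retained": len(self.programs),
            "control_state": self.control_state,
            "per_subject": {
                sid: {
                    "departure_absolute": sf.departure.absolute,
                    "departure_normalized": sf.departure.normalized,
                    "modal_state": sf.modal_state,
                    "n_optima_retained": len(sf.states),
                }
                for sid, sf in self.per_subject.items()
            },
        }

    def save(self, path: str, net: Network) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(net), fh, indent=1, sort_keys=True)


# -------------------------------------------------------------------------
# internal index-based model (program parameters kept symbolic)
# -------------------------------------------------------------------------

class _FitModel:
    __slots__ = ("order", "index", "n", "is_stressor", "in_edges",
                 "edge_pairs", "tie_hold")

    def __init__(self, net: Network, tie_rule: str):
        self.order = net.node_ids
        self.index = {nid: i for i, nid in enumerate(self.order)}
        self.n = len(self.order)
        self.is_stressor = [net.nodes[nid].kind == "stressor" for nid in self.order]
        self.edge_pairs = sorted(net.edges)
        self.tie_hold = tie_rule == "hold"
        self.in_edges: list[list[tuple[int, int, int]]] = [[] for _ in self.order]
        for e_i, (s, t) in enumerate(self.edge_pairs):
            self.in_edges[self.index[t]].append(
                (self.index[s], net.edges[(s, t)].sign, e_i))

    def image_node(self, i: int, levels, par) -> int:
        if self.is_stressor[i]:
            return levels[i]
        s = 0
        for j, sign, e in self.in_edges[i]:
            tau, w = par[e]
            if levels[j] >= tau:
                s += sign * w
        l = levels[i]
        if s > 0:
            return l + 1 if l < MAX_LEVEL else MAX_LEVEL
        if s < 0:
            return l - 1 if l > 0 else 0
        if self.tie_hold:
            return l
        return l - 1 if l > 0 else 0

    def image_all(self, levels, par) -> tuple[int, ...]:
        return tuple(self.image_node(i, levels, par) for i in range(self.n))

    def to_program(self, par, cfg: FitConfig) -> LogicProgram:
        params = {pair: par[e] for e, pair in enumerate(self.edge_pairs)}
        return LogicProgram(params, tie_rule="hold" if self.tie_hold else "decay",
                            w_max=max(cfg.w_domain))


def _greedy_order(varsets: list[set[int]], universe: list[int]) -> list[int]:
    """Order variables so small constraint scopes complete early."""
    order: list[int] = []
    placed: set[int] = set()
    for vs in sorted(varsets, key=len):
        for v in sorted(vs):
            if v not in placed:
                order.append(v)
                placed.add(v)
    for v in universe:
        if v not in placed:
            order.append(v)
            placed.add(v)
    return order


# -------------------------------------------------------------------------
# per-subject imputation (branch and bound over states)
# -------------------------------------------------------------------------

def _impute_pred(fm: _FitModel, par, obs: dict[int, int], *,
                 budget: int | None, cap: int, collect: bool):
    """Minimize departure over states that possess a synchronous predecessor.

    Searches the predecessor y directly; the imputed state is image(y), whose
    observed-node slice carries the cost.  Returns (min_cost, [state tuples])
    or (None, []) when no state fits the budget.
    """
    costed: list[int] = []   # nodes carrying a cost term
    relevant: set[int] = set()
    for t in obs:
        relevant.add(t)
        relevant |= {j for j, _, _ in fm.in_edges[t]}
        costed.append(t)
    varsets = [({t} | {j for j, _, _ in fm.in_edges[t]}) for t in costed]
    if collect:
        universe = list(range(fm.n))
    else:
        universe = sorted(relevant)
    order = _greedy_order(varsets, universe)
    pos = {v: k for k, v in enumerate(order)}
    trig: dict[int, list[int]] = {}
    for ti, t in enumerate(costed):
        last = max(pos[v] for v in varsets[ti])
        trig.setdefault(last, []).append(t)
    last_trigger = max(trig) if trig else -1

    assign = [0] * fm.n
    best: list = [None]
    coll: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()

    def bound() -> int | None:
        cands = [c for c in (best[0], budget) if c is not None]
        return min(cands) if cands else None

    def rec(k: int, cost: int):
        b = bound()
        if b is not None and cost > b:
            return
        if k > last_trigger and best[0] is not None and cost == best[0] \
                and (not collect or len(coll) >= cap):
            return
        if k == len(order):
            if best[0] is None or cost < best[0]:
                best[0] = cost
                coll.clear()
                seen.clear()
            if cost == best[0] and (collect and len(coll) < cap or not coll):
                x = fm.image_all(assign, par) if collect else ()
                if not collect:
                    coll.append(())
                elif x not in seen:
                    seen.add(x)
                    coll.append(x)
            return
        v = order[k]
        for val in LEVELS:
            assign[v] = val
            c = cost
            ok = True
            for t in trig.get(k, []):
                c += abs(fm.image_node(t, assign, par) - obs[t])
                b = bound()
                if b is not None and c > b:
                    ok = False
                    break
            if ok:
                rec(k + 1, c)
            if best[0] == 0 and ((not collect and coll) or
                                 (collect and len(coll) >= cap)):
                return

    rec(0, 0)
    if best[0] is None or (budget is not None and best[0] > budget):
        return None, []
    return best[0], (coll if collect else [])


_FIXED_EXPANSION_CAP = 300_000  # search-node budget for large networks


def _impute_fixed(fm: _FitModel, par, obs: dict[int, int], *,
                  budget: int | None, cap: int, collect: bool):
    """Minimize departure over fixed points: image(x) = x for every node.

    On networks beyond ~20 nodes the search is bounded by an expansion
    budget; exceeding it is reported as "no state found", so large-scale
    persistence verdicts are search-limited rather than proofs.
    """
    varsets = []
    for i in range(fm.n):
        if fm.is_stressor[i]:
            continue  # stressor holds its level: constraint always true
        varsets.append({i} | {j for j, _, _ in fm.in_edges[i]})
    order = _greedy_order(varsets, list(range(fm.n)))
    pos = {v: k for k, v in enumerate(order)}
    trig: dict[int, list[int]] = {}
    for i in range(fm.n):
        if fm.is_stressor[i]:
            continue
        vs = {i} | {j for j, _, _ in fm.in_edges[i]}
        last = max(pos[v] for v in vs)
        trig.setdefault(last, []).append(i)

    assign = [0] * fm.n
    best: list = [None]
    coll: list[tuple[int, ...]] = []
    n_found = [0]
    expansions = [0]
    exp_cap = _FIXED_EXPANSION_CAP if fm.n > 20 else None

    def bound() -> int | None:
        cands = [c for c in (best[0], budget) if c is not None]
        return min(cands) if cands else None

    def value_order(v: int):
        if v in obs:
            return sorted(LEVELS, key=lambda x: abs(x - obs[v]))
        return LEVELS

    def rec(k: int, cost: int):
        expansions[0] += 1
        if exp_cap is not None and expansions[0] > exp_cap:
            return
        b = bound()
        if b is not None and cost > b:
            return
        if k == len(order):
            x = tuple(assign)
            if best[0] is None or cost < best[0]:
                best[0] = cost
                coll.clear()
                n_found[0] = 0
            if cost == best[0]:
                n_found[0] += 1
                if collect and len(coll) < cap:
                    coll.append(x)
                elif not collect and not coll:
                    coll.append(())
            return
        v = order[k]
        for val in value_order(v):
            assign[v] = val
            c = cost + (abs(val - obs[v]) if v in obs else 0)
            b = bound()
            if b is not None and c > b:
                continue
            ok = True
            for t in trig.get(k, []):
                if fm.image_node(t, assign, par) != assign[t]:
                    ok = False
                    break
            if ok:
                rec(k + 1, c)
            if best[0] == 0 and ((not collect and coll) or
                                 (collect and len(coll) >= cap)):
                return

    rec(0, 0)
    if best[0] is None or (budget is not None and best[0] > budget):
        return None, []
    return best[0], (coll if collect else [])


def _impute_free(fm: _FitModel, par, obs: dict[int, int], *,
                 budget: int | None, cap: int, collect: bool):
    """No dynamical constraint (every synchronous state reaches an attractor):
    the optimum matches the observations exactly with free hidden levels."""
    if budget is not None and budget < 0:
        return None, []
    if not collect:
        return 0, [()]
    hidden = [i for i in range(fm.n) if i not in obs]
    coll = []
    for combo in itertools.product(LEVELS, repeat=len(hidden)):
        x = [0] * fm.n
        for t, lv in obs.items():
            x[t] = lv
        for h, lv in zip(hidden, combo):
            x[h] = lv
        coll.append(tuple(x))
        if len(coll) >= cap:
            break
    return 0, coll


def _impute_pred_local(fm: _FitModel, par, obs: dict[int, int], *,
                       budget: int | None, cap: int, collect: bool,
                       passes: int = 8):
    """Heuristic predecessor imputation for networks too large for exact
    branch-and-bound: coordinate descent on the predecessor levels.  The
    returned cost is an upper bound on the true optimum."""
    relevant = set(obs)
    for t in obs:
        relevant |= {j for j, _, _ in fm.in_edges[t]}
    rel = sorted(relevant)
    y = [0] * fm.n
    for t, lv in obs.items():
        y[t] = lv

    def cost_of() -> int:
        return sum(abs(fm.image_node(t, y, par) - obs[t]) for t in obs)

    cur = cost_of()
    for _ in range(passes):
        improved = False
        for v in rel:
            base = y[v]
            best_v, best_c = base, cur
            for val in LEVELS:
                if val == base:
                    continue
                y[v] = val
                c = cost_of()
                if c < best_c:
                    best_v, best_c = val, c
            y[v] = best_v
            if best_c < cur:
                cur = best_c
                improved = True
        if not improved or cur == 0:
            break
    if budget is not None and cur > budget:
        return None, []
    if not collect:
        return cur, [()]
    return cur, [fm.image_all(y, par)]


_LOCAL_VAR_LIMIT = 16  # beyond this many coupled levels, go heuristic


def _relevant_count(fm: _FitModel, obs: dict[int, int]) -> int:
    rel = set(obs)
    for t in obs:
        rel |= {j for j, _, _ in fm.in_edges[t]}
    return len(rel)


_IMPUTERS = {
    "has_predecessor": _impute_pred,
    "fixed_point": _impute_fixed,
    "on_attractor_path": _impute_free,
}


def impute_hidden(net: Network, prog: LogicProgram, subject: SubjectProfile,
                  consistency: str = "has_predecessor",
                  cap: int = 1000) -> list[tuple[dict[str, int], Departure]]:
    """All minimum-departure full states consistent with the dynamics.

    Returns up to ``cap`` optimal (state, departure) pairs; an empty list
    means no state satisfies the consistency requirement at all.
    """
    if consistency not in CONSISTENCY_MODES:
        raise FitError(f"unknown consistency mode {consistency!r}")
    fm = _FitModel(net, prog.tie_rule)
    par = [prog.params[pair] for pair in fm.edge_pairs]
    obs = {}
    for nid, lv in subject.observed.items():
        if nid not in fm.index:
            raise FitError(f"observed node {nid!r} not in network")
        obs[fm.index[nid]] = lv
    cost, states = _IMPUTERS[consistency](fm, par, obs, budget=None,
                                          cap=cap, collect=True)
    if cost is None:
        return []
    out = []
    for x in states:
        state = {nid: x[i] for i, nid in enumerate(fm.order)}
        out.append((state, manhattan_departure(state, subject)))
    return out


# -------------------------------------------------------------------------
# control handling
# -------------------------------------------------------------------------

def _control_obs(fm: _FitModel, control: dict[str, int]) -> dict[int, int]:
    return {fm.index[nid]: lv for nid, lv in control.items()}


def _control_trivial(fm: _FitModel, control_obs: dict[int, int]) -> bool:
    """All-zero resting state: with every tau >= 1 no edge is perceived, so
    the all-zero state is a fixed point of *any* program under either tie
    rule.  Holds whenever every control target is 0."""
    return all(lv == 0 for lv in control_obs.values())


def _control_feasible(fm: _FitModel, par, control_obs: dict[int, int]) -> bool:
    if _control_trivial(fm, control_obs):
        return True
    cost, _ = _impute_fixed(fm, par, control_obs, budget=0, cap=1, collect=False)
    return cost == 0


def _control_state(fm: _FitModel, par, control_obs: dict[int, int],
                   cap: int) -> dict[str, int] | None:
    """Canonical imputed control: among exact fixed-point completions, the
    one with minimal total activation (then lexicographically smallest)."""
    cost, states = _impute_fixed(fm, par, control_obs, budget=0, cap=cap,
                                 collect=True)
    if cost != 0 or not states:
        if _control_trivial(fm, control_obs):
            return {nid: 0 for nid in fm.order}
        return None
    pick = min(states, key=lambda x: (sum(x), x))
    return {nid: pick[i] for i, nid in enumerate(fm.order)}


# -------------------------------------------------------------------------
# program search
# -------------------------------------------------------------------------

def _subject_obs_list(fm: _FitModel, subjects: list[SubjectProfile]):
    out = []
    for p in subjects:
        obs = {}
        for nid, lv in p.observed.items():
            if nid not in fm.index:
                raise FitError(f"observed node {nid!r} not in network")
            obs[fm.index[nid]] = lv
        if not obs:
            raise FitError(f"subject {p.subject_id} has no observations")
        out.append(obs)
    return out


def _subjects_cost(fm: _FitModel, par, obs_list, consistency,
                   budget: int | None, imputer=None):
    """Aggregate minimal departure over subjects, or None above the budget."""
    imputer = imputer or _IMPUTERS[consistency]
    total = 0
    for obs in obs_list:
        rem = None if budget is None else budget - total
        c, _ = imputer(fm, par, obs, budget=rem, cap=1, collect=False)
        if c is None:
            return None
        total += c
    return total


def _eval_program(fm: _FitModel, par, obs_list, control_obs, consistency,
                  budget: int | None, imputer=None):
    """(aggregate_min_cost, control_ok) — aggregate is None if infeasible."""
    if not _control_feasible(fm, par, control_obs):
        return None, False
    total = _subjects_cost(fm, par, obs_list, consistency, budget, imputer)
    return total, True


def _search_exhaustive(fm: _FitModel, cfg: FitConfig, obs_list, control_obs):
    domain = cfg.pair_domain
    n_edges = len(fm.edge_pairs)
    best_cost = None
    best_pars: list[tuple] = []
    feasible = 0
    for combo in itertools.product(domain, repeat=n_edges):
        cost, _ = _eval_program(fm, combo, obs_list, control_obs,
                                cfg.consistency, cfg.max_departure)
        if cost is None:
            continue
        feasible += 1
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_pars = [combo]
        elif cost == best_cost and len(best_pars) < cfg.program_cap:
            best_pars.append(combo)
    return best_cost, best_pars, feasible


def _achievable_images(fm: _FitModel, t: int, par_t) -> set[int]:
    """Levels that node t's image can reach under these in-edge parameters,
    ranging over all local levels (the node itself and its in-neighbors)."""
    srcs = [j for j, _, _ in fm.in_edges[t]]
    out: set[int] = set()
    for own in LEVELS:
        for combo in itertools.product(LEVELS, repeat=len(srcs)):
            levels = {t: own}
            levels.update(dict(zip(srcs, combo)))
            s = 0
            for (j, sign, e), pw in zip(fm.in_edges[t], par_t):
                tau, w = pw
                if levels[j] >= tau:
                    s += sign * w
            l = own
            if s > 0:
                img = min(l + 1, MAX_LEVEL)
            elif s < 0:
                img = max(l - 1, 0)
            else:
                img = l if fm.tie_hold else max(l - 1, 0)
            out.add(img)
            if len(out) == 4:
                return out
    return out


def _term_min_cache(fm: _FitModel, t: int, par_t, obs_val: int) -> int:
    """min over local levels of |image_t - obs_t|: the best this node could
    possibly do under these in-edge parameters (admissible lower bound)."""
    return min(abs(a - obs_val) for a in _achievable_images(fm, t, tuple(par_t)))


def _vector_plan(fm: _FitModel, cfg: FitConfig, obs_list,
                 max_shared_states: int = 4 ** 9):
    """Precomputed cost tables for the vectorized predecessor search.

    For each observed node t the departure term depends only on the
    predecessor levels of t and its in-neighbors (its *scope*).  Variables
    private to one scope are minimized out per parameter combo; what remains
    is, per combo and per observed level, a compact cost array over the
    variables shared between scopes.  Summing these arrays and taking the
    minimum over the shared space yields the exact per-subject optimum for
    any candidate program — no inner search required.
    """
    domain = cfg.pair_domain
    observed_nodes = sorted({t for obs in obs_list for t in obs})
    node_edges = {t: [(j, sign, e) for j, sign, e in fm.in_edges[t]]
                  for t in observed_nodes}
    scopes = {t: sorted({t} | {j for j, _, _ in node_edges[t]})
              for t in observed_nodes}
    counts: dict[int, int] = {}
    for t in observed_nodes:
        for v in scopes[t]:
            counts[v] = counts.get(v, 0) + 1
    shared = sorted(v for v, c in counts.items() if c >= 2)
    if 4 ** len(shared) > max_shared_states:
        return None
    shape = (4,) * len(shared) if shared else (1,)
    spos = {v: k for k, v in enumerate(shared)}

    groups = []
    for t in observed_nodes:
        scope = scopes[t]
        npriv_axes = [k for k, v in enumerate(scope) if v not in spos]
        edges = node_edges[t]
        own_pos = scope.index(t)
        # all local assignments, one axis per scope variable
        if len(domain) ** len(edges) > 50_000:
            return None  # combo table itself would be unmanageable
        grids = np.meshgrid(*([np.arange(4)] * len(scope)), indexing="ij")
        combo_rows = []
        for combo in itertools.product(domain, repeat=len(edges)):
            s = np.zeros(grids[0].shape, dtype=np.int16)
            for (j, sign, e), (tau, w) in zip(edges, combo):
                s = s + sign * w * (grids[scope.index(j)] >= tau)
            own = grids[own_pos]
            up = np.minimum(own + 1, MAX_LEVEL)
            down = np.maximum(own - 1, 0)
            tie = own if fm.tie_hold else down
            img = np.where(s > 0, up, np.where(s < 0, down, tie))
            # scope and shared are both ascending, so after minimizing out
            # the private axes the kept axes already align with the shared
            # axis order; singleton axes fill the scopes this group lacks
            kept = {v_ for v_ in scope if v_ in spos}
            expand = tuple(4 if shared and v_ in kept else 1
                           for v_ in (shared or [0]))
            per_val = []
            for v in LEVELS:
                cost = np.abs(img - v).astype(np.int16)
                if npriv_axes:
                    cost = cost.min(axis=tuple(npriv_axes))
                per_val.append(cost.reshape(expand))
            combo_rows.append((combo, per_val))
        edge_ids = [e for _, _, e in edges]
        groups.append((t, edge_ids, combo_rows))
    return {"groups": groups, "shape": shape, "observed_nodes": observed_nodes}


def _search_backtracking_vec(fm: _FitModel, cfg: FitConfig, obs_list,
                             control_obs, plan):
    """Vectorized exact search (has_predecessor consistency)."""
    domain = cfg.pair_domain
    n_edges = len(fm.edge_pairs)
    shape = plan["shape"]
    zeros = np.zeros(shape, dtype=np.int16)
    n_subj = len(obs_list)

    # per group, per combo: (combo, per-subject compact cost array, bound)
    groups = []
    for t, edge_ids, combo_rows in plan["groups"]:
        rows = []
        for combo, per_val in combo_rows:
            arrs = []
            bound = 0
            for obs in obs_list:
                if t in obs:
                    a = per_val[obs[t]]
                else:
                    a = None
                arrs.append(a)
                bound += 0 if a is None else int(a.min())
            rows.append((combo, arrs, bound))
        rows.sort(key=lambda r: r[2])
        groups.append((t, edge_ids, rows))
    groups.sort(key=lambda g: (len(g[2]), len(g[1])))

    cost_edge_set = {e for _, edge_ids, _ in groups for e in edge_ids}
    free_edges = [e for e in range(n_edges) if e not in cost_edge_set]
    par = [domain[0]] * n_edges

    # per-subject admissible bound for the remaining groups
    suffix = [np.zeros(n_subj, dtype=int)]
    for t, edge_ids, rows in reversed(groups):
        per_subj = np.array([
            min(int(r[1][si].min()) if r[1][si] is not None else 0
                for r in rows) for si in range(n_subj)])
        suffix.append(suffix[-1] + per_subj)
    suffix.reverse()

    max_total = 3 * sum(len(obs) for obs in obs_list)
    d_cap = cfg.max_departure if cfg.max_departure is not None else max_total

    for d_budget in range(0, d_cap + 1):
        best_pars: list[tuple] = []
        found_cost: list = [None]

        def rec(g: int, acc: list):
            if len(best_pars) >= cfg.program_cap:
                return
            if g == len(groups):
                total = sum(int(a.min()) for a in acc)
                if total > d_budget:
                    return
                if _control_trivial(fm, control_obs):
                    best_pars.append(tuple(par))
                else:
                    placed = False
                    for free_combo in itertools.product(domain,
                                                        repeat=len(free_edges)):
                        for e, v in zip(free_edges, free_combo):
                            par[e] = v
                        if _control_feasible(fm, tuple(par), control_obs):
                            best_pars.append(tuple(par))
                            placed = True
                            break
                    for e in free_edges:
                        par[e] = domain[0]
                    if not placed:
                        return
                found_cost[0] = total if found_cost[0] is None \
                    else min(found_cost[0], total)
                return
            t, edge_ids, rows = groups[g]
            rest = suffix[g + 1]
            for combo, arrs, _ in rows:
                new_acc = [a if c is None else a + c
                           for a, c in zip(acc, arrs)]
                partial = sum(int(a.min()) for a in new_acc)
                if partial + int(rest.sum()) > d_budget:
                    continue
                for e, v in zip(edge_ids, combo):
                    par[e] = v
                rec(g + 1, new_acc)
                if len(best_pars) >= cfg.program_cap:
                    break
            for e in edge_ids:
                par[e] = domain[0]

        rec(0, [zeros] * n_subj)
        if best_pars:
            return found_cost[0], best_pars, len(best_pars)
    return None, [], 0


def _search_backtracking(fm: _FitModel, cfg: FitConfig, obs_list, control_obs):
    if cfg.consistency == "has_predecessor":
        plan = _vector_plan(fm, cfg, obs_list)
        if plan is not None:
            return _search_backtracking_vec(fm, cfg, obs_list, control_obs,
                                            plan)
    return _search_backtracking_bb(fm, cfg, obs_list, control_obs)


def _search_backtracking_bb(fm: _FitModel, cfg: FitConfig, obs_list,
                            control_obs):
    """Depth-first search over the parameters of edges feeding observed
    nodes (only those can change the departure), grouped by target node.

    As each node's in-edge group completes, two admissible lower bounds
    prune the prefix: a cheap per-(subject, node) local optimum, then an
    exact per-subject branch-and-bound over the observed nodes completed so
    far (a restriction of the full problem, hence a valid bound).  The
    remaining edge parameters are fixed to the first domain value and
    refined only when control feasibility requires it.  The departure
    budget escalates from 0 until a program fits, which makes the first
    feasible budget the optimum.
    """
    domain = cfg.pair_domain
    n_edges = len(fm.edge_pairs)
    observed_nodes = sorted({t for obs in obs_list for t in obs})
    node_edges = {t: [e for _, _, e in fm.in_edges[t]] for t in observed_nodes}
    groups = [t for t in observed_nodes if node_edges[t]]
    cost_edges = [e for t in groups for e in node_edges[t]]
    free_edges = [e for e in range(n_edges) if e not in set(cost_edges)]
    no_edge_nodes = [t for t in observed_nodes if not node_edges[t]]

    max_total = 3 * sum(len(obs) for obs in obs_list)
    d_cap = cfg.max_departure if cfg.max_departure is not None else max_total
    par = [domain[0]] * n_edges
    consistency = cfg.consistency
    imputer = _IMPUTERS[consistency]

    # per-group parameter-combo tables: every joint (tau, w) assignment to a
    # node's in-edges, with the per-subject local optima it allows
    combos: dict[int, list[tuple[tuple, tuple[int, ...], int]]] = {}
    for t in groups:
        rows = []
        for combo in itertools.product(domain, repeat=len(node_edges[t])):
            imgs = _achievable_images(fm, t, combo)
            mins = tuple(
                min(abs(a - obs[t]) for a in imgs) if t in obs else 0
                for obs in obs_list)
            rows.append((combo, mins, sum(mins)))
        rows.sort(key=lambda r: r[2])  # most promising combos first
        combos[t] = rows
    # groups with the fewest viable combos first (fail fast)
    groups.sort(key=lambda t: (len(combos[t]), len(node_edges[t])))
    base_mins = tuple(
        sum(_term_min_cache(fm, t, [], obs[t]) if t in obs else 0
            for t in no_edge_nodes)
        for obs in obs_list)

    for d_budget in range(0, d_cap + 1):
        best_pars: list[tuple] = []
        found_cost: list = [None]
        # per-subject sum over remaining groups of the best local optimum:
        # an admissible completion bound
        suffix: list[tuple[int, ...]] = [tuple([0] * len(obs_list))]
        for t in reversed(groups):
            best_per_subj = tuple(
                min(r[1][si] for r in combos[t]) for si in range(len(obs_list)))
            suffix.append(tuple(a + b for a, b in zip(suffix[-1], best_per_subj)))
        suffix.reverse()  # suffix[g] = bound over groups g..end

        def joint_subject_costs(upto: int, budget: int):
            """Exact per-subject optima restricted to the first ``upto``
            groups (plus edgeless nodes), already tightened by the suffix
            bound of the remaining groups; None above the budget."""
            done = set(groups[:upto]) | set(no_edge_nodes)
            total = 0
            rest = sum(suffix[upto])
            for si, obs in enumerate(obs_list):
                sub = {t: lv for t, lv in obs.items() if t in done}
                if not sub:
                    continue
                c, _ = imputer(fm, tuple(par), sub,
                               budget=budget - rest - total, cap=1,
                               collect=False)
                if c is None:
                    return None
                total += c
            return total

        def rec(g: int, local_lb: tuple[int, ...]):
            if len(best_pars) >= cfg.program_cap:
                return
            if g == len(groups):
                total = joint_subject_costs(len(groups), d_budget)
                if total is None:
                    return
                if _control_trivial(fm, control_obs):
                    best_pars.append(tuple(par))
                else:
                    # refine the free-edge parameters until the control's
                    # fixed-point constraint is satisfiable
                    placed = False
                    for free_combo in itertools.product(domain,
                                                        repeat=len(free_edges)):
                        for e, v in zip(free_edges, free_combo):
                            par[e] = v
                        if _control_feasible(fm, tuple(par), control_obs):
                            best_pars.append(tuple(par))
                            placed = True
                            break
                    for e in free_edges:
                        par[e] = domain[0]
                    if not placed:
                        return
                found_cost[0] = total if found_cost[0] is None \
                    else min(found_cost[0], total)
                return
            t = groups[g]
            for combo, mins, _ in combos[t]:
                new_lb = tuple(a + b for a, b in zip(local_lb, mins))
                if sum(a + b for a, b in zip(new_lb, suffix[g + 1])) > d_budget:
                    continue  # combos are sorted, but per-subject sums are not
                for e, v in zip(node_edges[t], combo):
                    par[e] = v
                if joint_subject_costs(g + 1, d_budget) is not None:
                    rec(g + 1, new_lb)
                if len(best_pars) >= cfg.program_cap:
                    break
            for e in node_edges[t]:
                par[e] = domain[0]

        rec(0, base_mins)
        if best_pars:
            return found_cost[0], best_pars, len(best_pars)
    return None, [], 0


def _search_local(fm: _FitModel, cfg: FitConfig, obs_list, control_obs):
    """Seeded first-improvement hill climbing with random restarts."""
    rng = np.random.default_rng(cfg.seed)
    domain = cfg.pair_domain
    n_edges = len(fm.edge_pairs)
    imputer = _local_imputer(fm, cfg, obs_list)
    # only edges feeding observed nodes can move the departure under the
    # predecessor consistency; fixed-point feasibility can hinge on any edge
    if cfg.consistency == "has_predecessor":
        observed_nodes = {t for obs in obs_list for t in obs}
        sweep = sorted({e for t in observed_nodes for _, _, e in fm.in_edges[t]})
    else:
        sweep = list(range(n_edges))

    def objective(par):
        cost, _ = _eval_program(fm, tuple(par), obs_list, control_obs,
                                cfg.consistency, cfg.max_departure, imputer)
        return cost

    best_cost, best_par = None, None
    for _ in range(cfg.local_restarts):
        par = [domain[int(rng.integers(len(domain)))] for _ in range(n_edges)]
        cur = objective(par)
        tries = 0
        while cur is None and tries < 20:
            par = [domain[int(rng.integers(len(domain)))] for _ in range(n_edges)]
            cur = objective(par)
            tries += 1
        if cur is None:
            continue
        improved = True
        while improved and cur > 0:
            improved = False
            for e in rng.permutation(sweep):
                base = par[e]
                for v in domain:
                    if v == base:
                        continue
                    par[e] = v
                    c = objective(par)
                    if c is not None and c < cur:
                        cur = c
                        base = v
                        improved = True
                par[e] = base
                if cur == 0:
                    break
        if best_cost is None or cur < best_cost:
            best_cost, best_par = cur, list(par)
        if best_cost == 0:
            break
    if best_par is None:
        return None, [], None
    if cfg.max_departure is not None and best_cost > cfg.max_departure:
        return None, [], None
    return best_cost, [tuple(best_par)], None


def _local_imputer(fm: _FitModel, cfg: FitConfig, obs_list):
    """Imputer used under local search: exact below the coupling limit,
    coordinate-descent heuristic above it (predecessor consistency only)."""
    if cfg.consistency == "has_predecessor" and \
            max(_relevant_count(fm, obs) for obs in obs_list) > _LOCAL_VAR_LIMIT:
        return _impute_pred_local
    return _IMPUTERS[cfg.consistency]


def _bb_tractable(fm: _FitModel, cfg: FitConfig, obs_list) -> bool:
    observed_nodes = {t for obs in obs_list for t in obs}
    max_combo = max((len(cfg.pair_domain) ** len(fm.in_edges[t])
                     for t in observed_nodes), default=1)
    return max_combo <= 8000 and \
        max(_relevant_count(fm, obs) for obs in obs_list) <= _LOCAL_VAR_LIMIT


def _pick_search(fm: _FitModel, cfg: FitConfig, obs_list) -> str:
    if cfg.search != "auto":
        if cfg.search == "exhaustive":
            space = len(cfg.pair_domain) ** len(fm.edge_pairs)
            if space > cfg.exhaustive_cap:
                raise FitError(
                    f"program space {space} exceeds exhaustive_cap "
                    f"{cfg.exhaustive_cap}")
        return cfg.search
    space = len(cfg.pair_domain) ** len(fm.edge_pairs)
    if space <= cfg.exhaustive_cap:
        return "exhaustive"
    if cfg.consistency == "has_predecessor" and \
            _vector_plan(fm, cfg, obs_list) is not None:
        return "backtracking_propagation"
    if _bb_tractable(fm, cfg, obs_list):
        return "backtracking_propagation"
    return "local_search"


def _modal(states: list[tuple[int, ...]], order: list[str]):
    arr = np.asarray(states)
    modal = {}
    agreement = {}
    for i, nid in enumerate(order):
        counts = np.bincount(arr[:, i], minlength=4)
        lv = int(np.argmax(counts))  # ties -> lowest level
        modal[nid] = lv
        agreement[nid] = float(counts[lv] / arr.shape[0])
    return modal, agreement


def fit(net: Network, subjects: list[SubjectProfile],
        control: dict[str, int], cfg: FitConfig | None = None) -> FitResult:
    """Identify the decisional-logic program(s) minimizing aggregate departure.

    The control must admit an exact fixed-point completion (a stable resting
    state); each subject's full state must satisfy ``cfg.consistency``.  All
    optimal programs (up to ``program_cap``) and, for the first optimal
    program, all optimal imputations per subject (up to ``solution_cap``)
    are retained; ties in the imputed levels are summarized by the per-node
    modal level.
    """
    cfg = cfg or FitConfig()
    if not subjects:
        raise FitError("at least one subject is required")
    fm = _FitModel(net, cfg.tie_rule)
    obs_list = _subject_obs_list(fm, subjects)
    control_obs = _control_obs(fm, control)
    mode = _pick_search(fm, cfg, obs_list)
    searcher = {"exhaustive": _search_exhaustive,
                "backtracking_propagation": _search_backtracking,
                "local_search": _search_local}[mode]
    best_cost, best_pars, feasible_count = searcher(fm, cfg, obs_list, control_obs)

    if best_cost is None or not best_pars:
        return FitResult([], feasible_count if mode != "local_search" else None,
                         None, {}, None, mode, cfg.seed, cfg)

    programs = [fm.to_program(p, cfg) for p in best_pars]
    par0 = best_pars[0]
    per_subject: dict[str, SubjectFit] = {}
    imputer = _local_imputer(fm, cfg, obs_list) if mode == "local_search" \
        else _IMPUTERS[cfg.consistency]
    per_costs = []
    pool_pars = best_pars[:max(1, cfg.program_states_cap)]
    for prof, obs in zip(subjects, obs_list):
        c0, states = imputer(fm, par0, obs, budget=None, cap=cfg.solution_cap,
                             collect=True)
        pooled = list(dict.fromkeys(states))
        # the optimum is degenerate across tied programs too: pool the
        # imputations (up to the same cap each) of other optimal programs
        # that assign this subject the same departure
        for par_k in pool_pars[1:]:
            ck, states_k = imputer(fm, par_k, obs, budget=c0,
                                   cap=cfg.solution_cap, collect=True)
            if ck == c0:
                seen = set(pooled)
                pooled.extend(x for x in states_k if x not in seen)
        modal, agree = _modal(pooled, fm.order)
        dep = Departure(absolute=c0, n_compared=len(obs),
                        nodes=tuple(sorted(prof.observed)))
        per_subject[prof.subject_id] = SubjectFit(
            departure=dep,
            states=[{nid: x[i] for i, nid in enumerate(fm.order)} for x in pooled],
            modal_state=modal,
            modal_agreement=agree,
        )
        per_costs.append(dep)
    agg = aggregate_departure(per_costs) if len({d.nodes for d in per_costs}) == 1 \
        else Departure(absolute=sum(d.absolute for d in per_costs),
                       n_compared=per_costs[0].n_compared,
                       n_subjects=len(per_costs))
    ctrl_state = _control_state(fm, par0, control_obs, cfg.solution_cap)
    return FitResult(programs, feasible_count, agg, per_subject, ctrl_state,
                     mode, cfg.seed, cfg)


def persistence_test(net: Network, subjects: list[SubjectProfile],
                     control: dict[str, int],
                     cfg: FitConfig | None = None) -> tuple[bool, int]:
    """Can the observed profiles be chronic, self-sustaining states?

    Requires a program under which every subject's observations extend to a
    full fixed point *exactly* (departure 0) while the control also rests at
    a fixed point.  Returns (feasible, number of satisfying programs found).
    """
    cfg = cfg or FitConfig()
    if not subjects:
        raise FitError("at least one subject is required")
    pcfg = FitConfig(
        tau_domain=cfg.tau_domain, w_domain=cfg.w_domain, tie_rule=cfg.tie_rule,
        consistency="fixed_point", search=cfg.search, seed=cfg.seed,
        max_departure=0, exhaustive_cap=cfg.exhaustive_cap,
        solution_cap=cfg.solution_cap, program_cap=cfg.program_cap,
        local_restarts=cfg.local_restarts,
    )
    res = fit(net, subjects, control, pcfg)
    count = res.feasible_count if res.feasible_count is not None else len(res.programs)
    return res.feasible, count


def predict_course(net: Network, prog: LogicProgram, full_state: dict[str, int],
                   horizon: int = 4096) -> tuple[Trajectory, dict[str, str]]:
    """Forward trajectory from an imputed state plus per-node monotonicity.

    Labels (over the transient and one full attractor period): ``flat``,
    ``increasing``, ``decreasing``, or ``non-monotone``.
    """
    traj = run_trajectory(full_state, net, prog, max_steps=horizon)
    series = traj.states + traj.attractor + [traj.attractor[0]]
    labels = {}
    for nid in full_state:
        vals = [s[nid] for s in series]
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        if all(d == 0 for d in diffs):
            labels[nid] = "flat"
        elif all(d >= 0 for d in diffs):
            labels[nid] = "increasing"
        elif all(d <= 0 for d in diffs):
            labels[nid] = "decreasing"
        else:
            labels[nid] = "non-monotone"
    return traj, labels
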