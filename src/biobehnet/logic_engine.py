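"""The discrete decisional-logic dynamical system.

Every node of the regulatory network occupies one of four qualitative levels
— Low (0), Moderate (1), Severe/High (2), Very Severe/Very High (3).  Each
edge carries a perception threshold tau (the minimum source level at which
the target perceives the edge) and a positive integer weight (how much
influence the edge exerts once perceived).  A node sums the signed weighted
contributions of its perceived in-edges and moves one level toward that net
drive on the next iteration: up if positive, down if negative, and on a tie
either holds its level (default) or decays one step toward baseline.

The exogenous stressor node has no regulators; it keeps its level unless a
clamp schedule changes it.  The default update scheme is synchronous (all
nodes move at once), which makes the dynamics a deterministic total function
of the state and makes dynamical predecessors well defined; an asynchronous
scheme (one randomly chosen non-quiescent node per step) is available for
fidelity to the classical multilevel logical formalism.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .network_io import Network

LEVELS = (0, 1, 2, 3)
MAX_LEVEL = 3


class EngineError(ValueError):
    """Raised for ill-posed dynamical queries (budget/horizon violations)."""


@dataclass
class LogicProgram:
    """Per-edge decisional kinetics plus the global update conventions.

    ``params`` maps the ordered pair (source, target) to ``(tau, weight)``:
    tau in {1,2,3} is the perception threshold, weight a strictly positive
    integer influence magnitude (default domain {1,..,w_max}).
    """

    params: dict[tuple[str, str], tuple[int, int]]
    tie_rule: str = "hold"            # "hold" | "decay"
    update_scheme: str = "synchronous"  # "synchronous" | "asynchronous"
    w_max: int = 2

    def __post_init__(self) -> None:
        if self.tie_rule not in ("hold", "decay"):
            raise ValueError(f"unknown tie rule {self.tie_rule!r}")
        if self.update_scheme not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update scheme {self.update_scheme!r}")
        for pair, (tau, w) in self.params.items():
            if tau not in (1, 2, 3):
                raise ValueError(f"edge {pair}: tau must be in 1..3, got {tau}")
            if w < 1:
                raise ValueError(f"edge {pair}: weight must be positive, got {w}")

    # -- JSON serialization ----------------------------------------------
    def to_json_obj(self, net: Network) -> dict:
        return {
            "edges": [
                {"source": s, "target": t, "sign": net.edges[(s, t)].sign,
                 "tau": tau, "weight": w}
                for (s, t), (tau, w) in sorted(self.params.items())
            ],
            "tie_rule": self.tie_rule,
            "update_scheme": self.update_scheme,
            "w_max": self.w_max,
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "LogicProgram":
        params = {(e["source"], e["target"]): (int(e["tau"]), int(e["weight"]))
                  for e in obj["edges"]}
        return cls(params, obj.get("tie_rule", "hold"),
                   obj.get("update_scheme", "synchronous"),
                   int(obj.get("w_max", 2)))

    def save(self, path: str, net: Network) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(net), fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "LogicProgram":
        with open(path) as fh:
            return cls.from_json_obj(json.load(fh))


@dataclass
class Trajectory:
    """A simulated course: transient states followed by the attractor.

    ``states`` holds the visited states from the initial condition up to (and
    excluding) the first repeat; ``attractor`` is the periodic part — a single
    state for a fixed point, an ordered cycle otherwise.
    """

    states: list[dict[str, int]]
    attractor: list[dict[str, int]]
    transient_length: int

    @property
    def is_fixed_point(self) -> bool:
        return len(self.attractor) == 1

    @property
    def period(self) -> int:
        return len(self.attractor)


# -- compiled internal form ------------------------------------------------

class CompiledModel:
    """Index-based form of (network, program) used by the hot loops.

    States become tuples of ints ordered by ``self.order`` (sorted node ids);
    per node we precompute the in-edge list as (source index, sign*weight,
    tau) triples.  Stressor nodes are marked so their image is their current
    level.
    """

    __slots__ = ("order", "index", "in_params", "is_stressor", "tie_hold", "n")

    def __init__(self, net: Network, prog: LogicProgram):
        self.order: list[str] = net.node_ids
        self.index = {nid: i for i, nid in enumerate(self.order)}
        self.n = len(self.order)
        self.is_stressor = [net.nodes[nid].kind == "stressor" for nid in self.order]
        self.tie_hold = prog.tie_rule == "hold"
        self.in_params: list[list[tuple[int, int, int]]] = [[] for _ in self.order]
        for (s, t), e in net.edges.items():
            if (s, t) not in prog.params:
                raise ValueError(f"program lacks parameters for edge {(s, t)}")
            tau, w = prog.params[(s, t)]
            self.in_params[self.index[t]].append((self.index[s], e.sign * w, tau))
        for pair in prog.params:
            if pair not in net.edges:
                raise ValueError(f"program parametrizes unknown edge {pair}")
        for lst in self.in_params:
            lst.sort()

    # state conversion
    def to_tuple(self, state: dict[str, int]) -> tuple[int, ...]:
        try:
            levels = tuple(int(state[nid]) for nid in self.order)
        except KeyError as exc:
            raise ValueError(f"state is missing node {exc.args[0]!r}") from None
        for l in levels:
            if l not in LEVELS:
                raise ValueError(f"level {l} outside 0..3")
        return levels

    def to_dict(self, levels: tuple[int, ...]) -> dict[str, int]:
        return {nid: levels[i] for i, nid in enumerate(self.order)}

    def perceived(self, i: int, levels: tuple[int, ...]) -> int:
        s = 0
        for j, coeff, tau in self.in_params[i]:
            if levels[j] >= tau:
                s += coeff
        return s

    def image_one(self, i: int, levels: tuple[int, ...]) -> int:
        if self.is_stressor[i]:
            return levels[i]
        s = self.perceived(i, levels)
        l = levels[i]
        if s > 0:
            return l + 1 if l < MAX_LEVEL else MAX_LEVEL
        if s < 0:
            return l - 1 if l > 0 else 0
        if self.tie_hold:
            return l
        return l - 1 if l > 0 else 0

    def image_all(self, levels: tuple[int, ...],
                  clamps_idx: dict[int, int] | None = None) -> tuple[int, ...]:
        img = [self.image_one(i, levels) for i in range(self.n)]
        if clamps_idx:
            for i, v in clamps_idx.items():
                img[i] = v
        return tuple(img)


def _compile(net: Network, prog: LogicProgram) -> CompiledModel:
    return CompiledModel(net, prog)


def _clamps_to_idx(comp: CompiledModel, net: Network,
                   clamps: dict[str, int] | None) -> dict[int, int]:
    if not clamps:
        return {}
    out = {}
    for nid, v in clamps.items():
        if nid not in comp.index:
            raise ValueError(f"clamp on unknown node {nid!r}")
        if int(v) not in LEVELS:
            raise ValueError(f"clamp level {v} outside 0..3")
        out[comp.index[nid]] = int(v)
    return out


# -- public operations -----------------------------------------------------

def perceived_input(node: str, state: dict[str, int], net: Network,
                    prog: LogicProgram) -> int:
    """Net signed weighted drive on ``node``: sum of sign*w over in-edges
    whose source level meets the edge's perception threshold."""
    comp = _compile(net, prog)
    return comp.perceived(comp.index[node], comp.to_tuple(state))


def image(node: str, state: dict[str, int], net: Network,
          prog: LogicProgram) -> int:
    """The level ``node`` moves to on the next iteration (one step toward the
    net drive, clamped to 0..3; stressor nodes keep their level)."""
    comp = _compile(net, prog)
    return comp.image_one(comp.index[node], comp.to_tuple(state))


def step(state: dict[str, int], net: Network, prog: LogicProgram,
         clamps: dict[str, int] | None = None,
         rng: np.random.Generator | int | None = None) -> dict[str, int]:
    """One update of the whole network.

    Synchronous: every node is replaced by its image simultaneously.
    Asynchronous: exactly one node whose image differs from its level is
    updated, drawn uniformly with the supplied seeded generator.
    Clamped nodes are pinned to their clamp value either way.
    """
    comp = _compile(net, prog)
    levels = comp.to_tuple(state)
    cidx = _clamps_to_idx(comp, net, clamps)
    img = comp.image_all(levels, cidx)
    if prog.update_scheme == "synchronous":
        return comp.to_dict(img)
    moving = [i for i in range(comp.n) if img[i] != levels[i]]
    if not moving:
        return comp.to_dict(levels)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    i = moving[int(gen.integers(len(moving)))]
    nxt = list(levels)
    nxt[i] = img[i]
    return comp.to_dict(tuple(nxt))


def trajectory(state0: dict[str, int], net: Network, prog: LogicProgram,
               clamps: dict[str, int] | None = None,
               max_steps: int = 4096,
               rng: np.random.Generator | int | None = None) -> Trajectory:
    """Iterate the update rule until a state repeats; classify the attractor.

    Returns the transient prefix and the periodic part (period 1 = fixed
    point).  Raises if no repeat occurs within ``max_steps`` (only possible
    under the asynchronous scheme or an exhausted horizon).
    """
    if max_steps < 1:
        raise EngineError("max_steps must be >= 1")
    comp = _compile(net, prog)
    cidx = _clamps_to_idx(comp, net, clamps)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cur = comp.to_tuple(state0)
    if cidx:
        cur = tuple(cidx.get(i, v) for i, v in enumerate(cur))
    seen: dict[tuple[int, ...], int] = {cur: 0}
    states = [cur]
    for _ in range(max_steps):
        if prog.update_scheme == "synchronous":
            nxt = comp.image_all(cur, cidx)
        else:
            nxt = comp.to_tuple(step(comp.to_dict(cur), net, prog,
                                     clamps, rng=gen))
        if nxt in seen:
            start = seen[nxt]
            return Trajectory(
                states=[comp.to_dict(s) for s in states[:start]],
                attractor=[comp.to_dict(s) for s in states[start:]],
                transient_length=start,
            )
        seen[nxt] = len(states)
        states.append(nxt)
        cur = nxt
    raise EngineError(f"horizon exceeded: no repeat within {max_steps} steps")


def is_fixed_point(state: dict[str, int], net: Network,
                   prog: LogicProgram) -> bool:
    """True iff every node's image equals its current level."""
    comp = _compile(net, prog)
    levels = comp.to_tuple(state)
    return comp.image_all(levels) == levels


def predecessors(state: dict[str, int], net: Network, prog: LogicProgram,
                 candidates: list[dict[str, int]] | None = None,
                 max_states: int = 4 ** 9) -> list[dict[str, int]]:
    """All states mapped onto ``state`` by one synchronous step.

    An empty list marks a garden-of-eden state (no dynamical history).  The
    full search enumerates by backtracking over node levels; when 4**N
    exceeds ``max_states`` a candidate set must be supplied instead.
    """
    if prog.update_scheme != "synchronous":
        raise EngineError("predecessors are defined for the synchronous scheme")
    comp = _compile(net, prog)
    target = comp.to_tuple(state)
    if candidates is not None:
        out = []
        for cand in candidates:
            lv = comp.to_tuple(cand)
            if comp.image_all(lv) == target:
                out.append(comp.to_dict(lv))
        return out
    if 4 ** comp.n > max_states:
        raise EngineError(
            f"4^{comp.n} states exceed the budget of {max_states}; "
            "supply a candidate set instead"
        )
    found = [comp.to_dict(y) for y in iter_predecessor_tuples(comp, target)]
    found.sort(key=lambda d: tuple(d[nid] for nid in comp.order))
    return found


# -- backtracking predecessor enumeration (shared with the CSP fitter) -----

def _pred_order(comp: CompiledModel) -> tuple[list[int], list[tuple[int, list[int]]]]:
    """Static variable order for predecessor search.

    Each node i contributes the constraint image_i(y) = target_i over the
    variables {i} + in-neighbors(i).  Variables are ordered so constraints
    complete (and prune) as early as possible; returns (order, triggers)
    where triggers[k] lists the constraints fully assigned once position k
    is set.
    """
    varsets = []
    for i in range(comp.n):
        vs = {i} | {j for j, _, _ in comp.in_params[i]}
        varsets.append(vs)
    order: list[int] = []
    placed: set[int] = set()
    remaining = sorted(range(comp.n), key=lambda i: len(varsets[i]))
    for i in remaining:
        for v in sorted(varsets[i]):
            if v not in placed:
                order.append(v)
                placed.add(v)
    pos = {v: k for k, v in enumerate(order)}
    triggers: list[tuple[int, list[int]]] = [(k, []) for k in range(len(order))]
    trig_map: dict[int, list[int]] = {k: [] for k in range(len(order))}
    for i in range(comp.n):
        last = max(pos[v] for v in varsets[i])
        trig_map[last].append(i)
    return order, [(k, trig_map[k]) for k in range(len(order))]


def iter_predecessor_tuples(comp: CompiledModel, target: tuple[int, ...]):
    """Yield every y (as a level tuple) with image(y) == target."""
    order, triggers = _pred_order(comp)
    n = comp.n
    assign = [0] * n

    def rec(k: int):
        if k == len(order):
            yield tuple(assign)
            return
        v = order[k]
        _, constraints = triggers[k]
        for val in LEVELS:
            assign[v] = val
            ok = True
            for c in constraints:
                if _image_partial(comp, c, assign) != target[c]:
                    ok = False
                    break
            if ok:
                yield from rec(k + 1)

    yield from rec(0)


def _image_partial(comp: CompiledModel, i: int, assign: list[int]) -> int:
    # assumes node i and its in-neighbors are already assigned
    if comp.is_stressor[i]:
        return assign[i]
    s = 0
    for j, coeff, tau in comp.in_params[i]:
        if assign[j] >= tau:
            s += coeff
    l = assign[i]
    if s > 0:
        return l + 1 if l < MAX_LEVEL else MAX_LEVEL
    if s < 0:
        return l - 1 if l > 0 else 0
    if comp.tie_hold:
        return l
    return l - 1 if l > 0 else 0


def enumerate_states(node_ids: list[str]):
    """All 4^N states over the given nodes (testing/enumeration helper)."""
    for combo in itertools.product(LEVELS, repeat=len(node_ids)):
        yield dict(zip(node_ids, combo))
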