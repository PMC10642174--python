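"""Read, validate, write and summarize signed directed regulatory networks.

The networks handled here link molecular mediators (cytokines, neurotrophic
factors, neurotransmitters, ...) to behavioral constructs (neuropsychological
severity scales) through signed regulatory interactions mined from the
literature, plus at most one exogenous stressor node.  Each interaction
carries a direction, a mode of action (activation or inhibition) and a count
of supporting publications.

Structural contract: every molecular or behavioral node must sit on at least
one directed feedback cycle — no isolated sources or terminal sinks — while
the stressor node may only have out-going edges.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

NODE_KINDS = ("molecular", "behavioral", "stressor")
POLARITIES = ("severity", "function", "none")

_SIGN_TOKENS = {
    "1": 1, "+1": 1, "+": 1, "activate": 1, "activates": 1, "activation": 1,
    "-1": -1, "−1": -1, "-": -1, "inhibit": -1, "inhibits": -1, "inhibition": -1,
}


class NetworkError(ValueError):
    """Raised for malformed networks or network files."""


@dataclass(frozen=True)
class Node:
    """A network node: a molecular mediator, a behavioral construct, or the stressor.

    ``polarity`` records whether a higher level means worse symptoms
    (``severity``) or better function (``function``, behavioral nodes only).
    """

    id: str
    kind: str = "molecular"
    polarity: str = "none"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("node id must be nonempty")
        if self.kind not in NODE_KINDS:
            raise NetworkError(f"unknown node kind {self.kind!r} for {self.id!r}")
        if self.polarity not in POLARITIES:
            raise NetworkError(f"unknown polarity {self.polarity!r} for {self.id!r}")
        if self.polarity == "function" and self.kind != "behavioral":
            raise NetworkError(
                f"polarity 'function' is only allowed on behavioral nodes ({self.id!r})"
            )


@dataclass(frozen=True)
class Edge:
    """A directed signed interaction with its literature support.

    ``n_citations == 0`` means the support count is unknown.  An edge backed
    by exactly one publication is flagged low-confidence.
    """

    source: str
    target: str
    sign: int
    n_citations: int = 0

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise NetworkError(
                f"edge ({self.source},{self.target}): sign must be +1 or -1"
            )
        if self.n_citations < 0:
            raise NetworkError(
                f"edge ({self.source},{self.target}): negative citation count"
            )

    @property
    def low_confidence(self) -> bool:
        return self.n_citations == 1


@dataclass
class EvidenceSummary:
    """Distributional summary of per-edge citation support."""

    median_citations: float
    n_ge5: int
    n_eq1: int
    n_total: int


@dataclass
class Network:
    """A directed signed regulatory network.

    ``nodes`` maps node id -> :class:`Node`; ``edges`` maps the ordered pair
    ``(source, target)`` -> :class:`Edge` (at most one edge per ordered pair).
    """

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_parts(cls, nodes: list[Node], edges: list[Edge],
                   allow_self_loops: bool = False) -> "Network":
        net = cls()
        for n in nodes:
            if n.id in net.nodes:
                raise NetworkError(f"duplicate node id {n.id!r}")
            net.nodes[n.id] = n
        for e in edges:
            net._add_edge(e, allow_self_loops=allow_self_loops)
        net.validate()
        return net

    def _add_edge(self, e: Edge, allow_self_loops: bool = False) -> None:
        for end in (e.source, e.target):
            if end not in self.nodes:
                raise NetworkError(f"edge references unknown node {end!r}")
        if e.source == e.target and not allow_self_loops:
            raise NetworkError(f"self-loop on {e.source!r} (not enabled)")
        key = (e.source, e.target)
        if key in self.edges:
            raise NetworkError(f"duplicate edge for pair {key}")
        self.edges[key] = e

    def validate(self) -> None:
        stressors = [n for n in self.nodes.values() if n.kind == "stressor"]
        if len(stressors) > 1:
            raise NetworkError("at most one stressor node is allowed")
        for s in stressors:
            incoming = [k for k in self.edges if k[1] == s.id]
            if incoming:
                raise NetworkError(
                    f"stressor {s.id!r} may have out-edges only; found in-edges {incoming}"
                )

    # -- accessors --------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.kind == kind)

    @property
    def behavioral(self) -> list[str]:
        return self.nodes_of_kind("behavioral")

    @property
    def molecular(self) -> list[str]:
        return self.nodes_of_kind("molecular")

    @property
    def stressor(self) -> str | None:
        ids = self.nodes_of_kind("stressor")
        return ids[0] if ids else None

    def in_edges(self, node: str) -> list[Edge]:
        return [e for (s, t), e in sorted(self.edges.items()) if t == node]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for nid, n in self.nodes.items():
            g.add_node(nid, kind=n.kind, polarity=n.polarity)
        for (s, t), e in self.edges.items():
            g.add_edge(s, t, sign=e.sign, n_citations=e.n_citations)
        return g


# -- reading ---------------------------------------------------------------

def _parse_sign(token) -> int:
    s = str(token).strip().lower()
    if s not in _SIGN_TOKENS:
        raise NetworkError(f"cannot parse interaction sign {token!r}")
    return _SIGN_TOKENS[s]


def read_node_table(path: str) -> dict[str, Node]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise NetworkError(f"node table {path} lacks an 'id' column")
    nodes: dict[str, Node] = {}
    for _, row in df.iterrows():
        nid = str(row[cols["id"]]).strip()
        kind = str(row[cols["kind"]]).strip() if "kind" in cols and row[cols["kind"]] else "molecular"
        pol = str(row[cols["polarity"]]).strip() if "polarity" in cols and row[cols["polarity"]] else "none"
        if nid in nodes:
            raise NetworkError(f"duplicate node id {nid!r} in node table")
        nodes[nid] = Node(nid, kind, pol)
    return nodes


def read_network(path: str, node_table: str | None = None, *,
                 collapse: str = "sum",
                 allow_self_loops: bool = False) -> Network:
    """Load a network from a delimited edge list (CSV/TSV) or a SIF file.

    Duplicate rows for the same ordered pair with the same sign are collapsed
    (citation counts summed, or ``collapse="max"``); the same pair with
    conflicting signs is a hard error.  Node kinds/polarities come from the
    optional node table and default to molecular/none.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if collapse not in ("sum", "max"):
        raise NetworkError(f"unknown collapse rule {collapse!r}")
    if path.endswith(".sif"):
        rows = _read_sif_rows(path)
    else:
        rows = _read_delimited_rows(path)

    declared = read_node_table(node_table) if node_table else {}
    nodes: dict[str, Node] = dict(declared)
    merged: dict[tuple[str, str], list[int]] = {}  # pair -> [sign, citations]
    for src, tgt, sign, ncit in rows:
        for end in (src, tgt):
            if end not in nodes:
                if declared:
                    raise NetworkError(
                        f"edge references node {end!r} absent from the node table"
                    )
                nodes[end] = Node(end)
        key = (src, tgt)
        if key in merged:
            if merged[key][0] != sign:
                raise NetworkError(
                    f"conflicting signs for interaction pair {key}"
                )
            if collapse == "sum":
                merged[key][1] += ncit
            else:
                merged[key][1] = max(merged[key][1], ncit)
        else:
            merged[key] = [sign, ncit]

    edges = [Edge(s, t, sg, nc) for (s, t), (sg, nc) in merged.items()]
    return Network.from_parts(list(nodes.values()), edges,
                              allow_self_loops=allow_self_loops)


def _read_delimited_rows(path: str):
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("source", "target", "sign"):
        if req not in cols:
            raise NetworkError(f"{path}: missing required column {req!r}")
    rows = []
    for _, row in df.iterrows():
        ncit = 0
        if "n_citations" in cols and not pd.isna(row[cols["n_citations"]]):
            ncit = int(row[cols["n_citations"]])
        rows.append((str(row[cols["source"]]).strip(),
                     str(row[cols["target"]]).strip(),
                     _parse_sign(row[cols["sign"]]), ncit))
    return rows


def _read_sif_rows(path: str):
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise NetworkError(f"malformed SIF line: {line!r}")
            src, rel = parts[0], parts[1]
            for tgt in parts[2:]:
                rows.append((src, tgt, _parse_sign(rel), 0))
    return rows


# -- structural validation -------------------------------------------------

def validate_feedback_closure(net: Network) -> list[str]:
    """Return every molecular/behavioral node that lies on no directed cycle.

    An empty list means the network satisfies the no-source/no-sink rule;
    the exogenous stressor is exempt (it is allowed to be a pure source).
    """
    g = net.to_networkx()
    on_cycle: set[str] = set()
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1:
            on_cycle |= comp
    on_cycle |= {u for u in g.nodes if g.has_edge(u, u)}
    violating = [n.id for n in net.nodes.values()
                 if n.kind != "stressor" and n.id not in on_cycle]
    return sorted(violating)


def summarize_evidence(net: Network) -> EvidenceSummary:
    """Summarize per-edge citation support (median, >=5 count, ==1 count).

    Edges with unknown support (count 0) are excluded from the median.
    """
    counts = [e.n_citations for e in net.edges.values() if e.n_citations > 0]
    if not counts:
        raise NetworkError("no edge has a known citation count")
    return EvidenceSummary(
        median_citations=float(np.median(counts)),
        n_ge5=int(sum(c >= 5 for c in counts)),
        n_eq1=int(sum(c == 1 for c in counts)),
        n_total=len(net.edges),
    )


# -- writing ---------------------------------------------------------------

def write_network(net: Network, path: str, format: str = "edge-csv",
                  node_path: str | None = None) -> str:
    """Write a network as an edge CSV or a SIF file (optionally a node table too).

    The edge-CSV round trip is lossless for nodes, edges, signs and citation
    counts (node kinds require re-supplying the node table on read); SIF
    drops citation counts by design of the format.
    """
    if not net.edges:
        raise NetworkError("refusing to write an empty network")
    if format == "edge-csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "sign", "n_citations"])
            for (s, t), e in sorted(net.edges.items()):
                w.writerow([s, t, e.sign, e.n_citations])
    elif format == "sif":
        with open(path, "w") as fh:
            for (s, t), e in sorted(net.edges.items()):
                rel = "activate" if e.sign == 1 else "inhibit"
                fh.write(f"{s}\t{rel}\t{t}\n")
    else:
        raise NetworkError(f"unknown format {format!r}")
    if node_path is not None:
        write_node_table(net, node_path)
    return path


def write_node_table(net: Network, path: str) -> str:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "kind", "polarity"])
        for nid in net.node_ids:
            n = net.nodes[nid]
            w.writerow([n.id, n.kind, n.polarity])
    return path
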