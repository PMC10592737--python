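"""Cross-complex network comparison.

Because contact nodes are named by generic residue numbers, networks learned
for different complexes share a label space and can be compared directly:

1. each directed network is *moralized* (co-parents married, directions
   dropped) to a simple undirected graph;
2. edges recurring in at least ``min_support`` of the moralized graphs form
   the common edge set, whose largest connected component is the largest
   common subnetwork G*;
3. for each complex the full empirical joint distribution of the subnetwork's
   nodes is estimated from its fingerprint matrix, and complexes are compared
   pairwise by the Jensen-Shannon divergence (natural log, so bounded by
   ln 2) of those joints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import rel_entr

from .io import (
    ContactNodeId,
    FingerprintMatrix,
    InsufficientDataError,
    LimitError,
    UsageError,
)
from .bn import BayesianNetwork


# ---------------------------------------------------------------------------
# Moralization
# ---------------------------------------------------------------------------

@dataclass
class MoralGraph:
    """Undirected, unweighted, simple graph derived from a directed BN."""

    nodes: list[str]
    edges: set[frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise UsageError("moral-graph edges must join two distinct nodes")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g


def moralize(net: BayesianNetwork | nx.DiGraph, source: str = "") -> MoralGraph:
    """Moralize a DAG in three steps.

    1. identify each node's parents;
    2. add an undirected edge between every pair of parents not already
       connected ("marrying" the co-parents);
    3. drop the directions of all original edges.
    """
    if isinstance(net, BayesianNetwork):
        g = net.to_networkx()
    else:
        g = net
    edges: set[frozenset[str]] = set()
    for u, v in g.edges():
        if u != v:
            edges.add(frozenset((u, v)))
    for child in g.nodes():
        parents = sorted(g.predecessors(child))
        for p1, p2 in itertools.combinations(parents, 2):
            edges.add(frozenset((p1, p2)))
    return MoralGraph(nodes=list(g.nodes()), edges=edges, source=source)


# ---------------------------------------------------------------------------
# Largest common subnetwork
# ---------------------------------------------------------------------------

@dataclass
class CommonSubgraph:
    """Largest connected component of edges recurring in >= min_support graphs."""

    nodes: list[str]
    edges: set[frozenset[str]]
    support: dict[frozenset[str], int] = field(default_factory=dict)
    min_support: int = 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            u, v = sorted(e)
            g.add_edge(u, v, support=self.support.get(e, 0))
        return g


def common_subgraph(
    graphs: Sequence[MoralGraph], min_support: int
) -> CommonSubgraph:
    """Support-filter edges across moralized graphs, keep the largest component.

    Node identity is textual (generic-number labels), so this is a label
    intersection, not subgraph isomorphism.  The largest component is
    chosen by edge count, then node count, then lexicographically smallest
    node.  Isolated nodes are dropped.
    """
    if len(graphs) < 2:
        raise UsageError("common_subgraph needs at least 2 graphs")
    if not 1 <= min_support <= len(graphs):
        raise UsageError(
            f"min_support must be in [1, {len(graphs)}], got {min_support}"
        )
    support: dict[frozenset[str], int] = {}
    for g in graphs:
        for e in g.edges:
            support[e] = support.get(e, 0) + 1
    kept = {e for e, c in support.items() if c >= min_support}
    if not kept:
        return CommonSubgraph(nodes=[], edges=set(), support={}, min_support=min_support)
    g = nx.Graph()
    g.add_edges_from(tuple(sorted(e)) for e in kept)
    components = [g.subgraph(c) for c in nx.connected_components(g)]
    top = max((sg.number_of_edges(), sg.number_of_nodes()) for sg in components)
    best = min(
        (sg for sg in components
         if (sg.number_of_edges(), sg.number_of_nodes()) == top),
        key=lambda sg: min(sg.nodes()),
    )
    edges = {frozenset(e) for e in best.edges()}
    return CommonSubgraph(
        nodes=sorted(best.nodes()),
        edges=edges,
        support={e: support[e] for e in edges},
        min_support=min_support,
    )


def markov_neighborhood(net: BayesianNetwork, node: ContactNodeId | str) -> set[str]:
    """Nodes directly connected to ``node``: its parents and children.

    This is plain adjacency — not the Markov blanket, which would also
    include co-parents.
    """
    text = node if isinstance(node, str) else node.canonical_text
    if text not in net.node_texts:
        raise LookupError(f"node {text!r} is not in the network")
    out: set[str] = set()
    for u, v in net.edges:
        if u.canonical_text == text:
            out.add(v.canonical_text)
        elif v.canonical_text == text:
            out.add(u.canonical_text)
    return out


# ---------------------------------------------------------------------------
# Joint distributions and Jensen-Shannon divergence
# ---------------------------------------------------------------------------

@dataclass
class JointDistribution:
    """Empirical joint over the binary states of an ordered node subset.

    States are indexed 0 .. 2^m - 1, node j contributing bit j (node order
    as given).  ``probabilities`` sum to 1.
    """

    nodes: list[str]
    probabilities: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != (2 ** len(self.nodes),):
            raise UsageError("probability vector must have 2^m entries")
        if (self.probabilities < 0).any():
            raise UsageError("probabilities must be nonnegative")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-12:
            raise UsageError("probabilities must sum to 1")


def empirical_joint(
    data: FingerprintMatrix,
    nodes: Sequence[ContactNodeId | str],
    pseudocount: float = 0.0,
    state_cap: int = 2 ** 20,
) -> JointDistribution:
    """Joint probabilities of the node subset, directly from the observations.

    probability(state) = (count + pseudocount) / (n_frames + pseudocount * 2^m).
    """
    texts = [n if isinstance(n, str) else n.canonical_text for n in nodes]
    m = len(texts)
    if m == 0:
        raise UsageError("empirical_joint needs at least one node")
    if 2 ** m > state_cap:
        raise LimitError(
            f"state space 2^{m} exceeds the cap {state_cap}; reduce the subgraph"
        )
    cols = np.column_stack([data.column(t) for t in texts]).astype(np.int64)
    idx = cols @ (1 << np.arange(m, dtype=np.int64))
    counts = np.bincount(idx, minlength=2 ** m).astype(np.float64)
    denom = data.n_frames + pseudocount * 2 ** m
    if denom == 0:
        raise UsageError("no frames and zero pseudocount: joint undefined")
    return JointDistribution(
        nodes=texts,
        probabilities=(counts + pseudocount) / denom,
        pseudocount=pseudocount,
    )


def jsd(p: JointDistribution, q: JointDistribution) -> float:
    """Jensen-Shannon divergence, natural log: 0 <= JSD <= ln 2.

    JSD(P, Q) = 0.5 KL(P || M) + 0.5 KL(Q || M) with M = (P + Q)/2; states
    with zero probability contribute zero to their KL term.
    """
    if p.nodes != q.nodes:
        raise UsageError("JSD requires identical node subsets in identical order")
    pv, qv = p.probabilities, q.probabilities
    m = 0.5 * (pv + qv)
    return float(rel_entr(pv, m).sum() * 0.5 + rel_entr(qv, m).sum() * 0.5)


def jsd_matrix(
    datasets: Mapping[str, FingerprintMatrix] | Sequence[FingerprintMatrix],
    subgraph: CommonSubgraph | Sequence[str],
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pairwise JSD of empirical joints over the common subgraph's nodes.

    Datasets lacking a subgraph node are excluded and reported in the third
    return value (names of omitted datasets).  Returns (matrix, kept names,
    omitted names); the matrix is symmetric with a zero diagonal.
    """
    if isinstance(subgraph, CommonSubgraph):
        node_texts = list(subgraph.nodes)
    else:
        node_texts = list(subgraph)
    if isinstance(datasets, Mapping):
        items = list(datasets.items())
    else:
        items = [(f"dataset_{i}", d) for i, d in enumerate(datasets)]
    kept, omitted = [], []
    for name, d in items:
        if set(node_texts) <= set(d.node_texts):
            kept.append((name, d))
        else:
            omitted.append(name)
    if len(kept) < 2:
        raise InsufficientDataError(
            f"need >= 2 datasets containing all subgraph nodes; omitted: {omitted}"
        )
    joints = [
        empirical_joint(d, node_texts, pseudocount=pseudocount) for _, d in kept
    ]
    n = len(joints)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jsd(joints[i], joints[j])
    return mat, [name for name, _ in kept], omitted
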