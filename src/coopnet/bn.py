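"""Bayesian-network structure learning over binary contact variables.

The network is a directed acyclic graph whose nodes are interface contacts
and whose edges mark direct (non-transitive) statistical dependencies between
contacts across trajectory frames.  Structure selection is greedy
search-and-score: hill climbing over single-edge add / delete / reverse
moves, restarted from random seed graphs, keeping the highest-scoring
network found.

Scoring uses the Dirichlet-multinomial marginal likelihood (BDeu): for a
binary node X with parent set Pa, q = 2^|Pa| parent configurations and
hyperparameters alpha_jk = ess / (2 q),

    log P(x | Pa) = sum_j [ lnG(a_j) - lnG(a_j + N_j) ]
                  + sum_jk [ lnG(a_jk + N_jk) - lnG(a_jk) ]

with a_j = ess / q, N_jk the contingency counts and lnG the log-gamma.
The score is decomposable (a sum over node families) and score-equivalent
(Markov-equivalent DAGs tie).  All reported strengths are divided by the
number of frames so they live on a per-observation scale and remain
comparable across data sets of different length.

The strength of an edge u -> v is the log marginal-likelihood ratio of the
network with the edge to the one without it (all else fixed):

    strength(u -> v) = [ score(v | Pa) - score(v | Pa \\ {u}) ] / n_frames
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .io import (
    ContactNodeId,
    DegenerateDataError,
    FingerprintMatrix,
    LimitError,
    UsageError,
)

logger = logging.getLogger("coopnet.bn")

Edge = tuple[ContactNodeId, ContactNodeId]


# ---------------------------------------------------------------------------
# Family scoring
# ---------------------------------------------------------------------------

class FamilyScoreCache:
    """Memoized BDeu family scores over one fingerprint matrix.

    Keyed by (child index, sorted parent indices); hits are bit-identical to
    recomputation because the score is a pure function of those inputs.
    """

    def __init__(self, data: FingerprintMatrix, ess: float, max_parents: int | None = None):
        if ess <= 0:
            raise UsageError("ess must be > 0")
        self.values = np.asarray(data.values, dtype=np.int64)
        self.n_frames = self.values.shape[0]
        self.ess = float(ess)
        self.max_parents = max_parents
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def score(self, child: int, parents: Iterable[int]) -> float:
        ptup = tuple(sorted(parents))
        if child in ptup:
            raise UsageError("a node cannot be its own parent")
        if self.max_parents is not None and len(ptup) > self.max_parents:
            raise LimitError(
                f"parent set of size {len(ptup)} exceeds max_parents={self.max_parents}"
            )
        key = (child, ptup)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        val = self._compute(child, ptup)
        self._cache[key] = val
        return val

    def _compute(self, child: int, ptup: tuple[int, ...]) -> float:
        if self.n_frames == 0:
            return 0.0
        k = len(ptup)
        q = 1 << k
        if k:
            weights = 1 << np.arange(k, dtype=np.int64)
            cfg = self.values[:, list(ptup)] @ weights
            idx = cfg * 2 + self.values[:, child]
        else:
            idx = self.values[:, child]
        counts = np.bincount(idx, minlength=2 * q).reshape(q, 2).astype(np.float64)
        a_jk = self.ess / (2.0 * q)
        a_j = self.ess / q
        nj = counts.sum(axis=1)
        score = float(
            (gammaln(a_j) - gammaln(a_j + nj)).sum()
            + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
        )
        return score


def family_score(
    data: FingerprintMatrix,
    node: ContactNodeId | str | int,
    parents: Iterable[ContactNodeId | str | int],
    ess: float = 1.0,
    max_parents: int | None = None,
) -> float:
    """Log marginal likelihood of one node's column given its parents."""
    cache = FamilyScoreCache(data, ess, max_parents)
    ci = _col_index(data, node)
    pi = [_col_index(data, p) for p in parents]
    return cache.score(ci, pi)


def _col_index(data: FingerprintMatrix, node) -> int:
    if isinstance(node, (int, np.integer)):
        return int(node)
    text = node if isinstance(node, str) else node.canonical_text
    try:
        return data.node_texts.index(text)
    except ValueError:
        raise LookupError(f"node {text!r} is not a column of the data") from None


# ---------------------------------------------------------------------------
# The learned network
# ---------------------------------------------------------------------------

@dataclass
class BayesianNetwork:
    """A learned DAG over contact nodes with per-edge strengths.

    ``total_score`` is the sum of BDeu family scores (raw log marginal
    likelihood); ``edge_strengths`` are per-observation log likelihood
    ratios (see module docstring).
    """

    nodes: list[ContactNodeId]
    edges: list[Edge]
    edge_strengths: dict[Edge, float] = field(default_factory=dict)
    total_score: float = float("nan")
    learn_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise UsageError("BayesianNetwork edges must form a DAG")
        if self.edge_strengths and set(self.edge_strengths) != set(self.edges):
            raise UsageError("edge_strengths must cover exactly the edge set")

    @property
    def node_texts(self) -> list[str]:
        return [n.canonical_text for n in self.nodes]

    def parents_of(self, node: ContactNodeId) -> set[ContactNodeId]:
        return {u for u, v in self.edges if v == node}

    def children_of(self, node: ContactNodeId) -> set[ContactNodeId]:
        return {v for u, v in self.edges if u == node}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_texts)
        for (u, v) in self.edges:
            attrs = {}
            if (u, v) in self.edge_strengths:
                attrs["strength"] = float(self.edge_strengths[(u, v)])
            g.add_edge(u.canonical_text, v.canonical_text, **attrs)
        return g

    def to_dict(self) -> dict:
        return {
            "nodes": self.node_texts,
            "edges": [
                {
                    "from": u.canonical_text,
                    "to": v.canonical_text,
                    "strength": self.edge_strengths.get((u, v)),
                }
                for u, v in self.edges
            ],
            "total_score": self.total_score,
            "learn_metadata": self.learn_metadata,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "BayesianNetwork":
        nodes = [ContactNodeId.parse(t) for t in payload["nodes"]]
        by_text = {n.canonical_text: n for n in nodes}
        edges, strengths = [], {}
        for e in payload["edges"]:
            edge = (by_text[e["from"]], by_text[e["to"]])
            edges.append(edge)
            if e.get("strength") is not None:
                strengths[edge] = float(e["strength"])
        return cls(
            nodes=nodes, edges=edges, edge_strengths=strengths,
            total_score=float(payload.get("total_score", float("nan"))),
            learn_metadata=dict(payload.get("learn_metadata", {})),
        )


# ---------------------------------------------------------------------------
# Hill-climbing search with random restarts
# ---------------------------------------------------------------------------

class _Search:
    """One hill-climbing run over index-based parent sets."""

    IMPROVEMENT_EPS = 1e-10

    def __init__(self, cache: FamilyScoreCache, active: list[int], max_parents: int):
        self.cache = cache
        self.active = active            # indices allowed to carry edges
        self.max_parents = max_parents

    def _has_path(self, parents: list[set[int]], src: int, dst: int) -> bool:
        """True if dst is reachable from src following child edges."""
        if src == dst:
            return True
        children: dict[int, list[int]] = {}
        for v, ps in enumerate(parents):
            for u in ps:
                children.setdefault(u, []).append(v)
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            for v in children.get(u, ()):
                if v == dst:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def climb(self, parents: list[set[int]]) -> tuple[float, list[set[int]]]:
        fs = self.cache.score
        fam = {v: fs(v, parents[v]) for v in range(len(parents))}
        while True:
            best_delta = self.IMPROVEMENT_EPS
            best_move = None
            for u in self.active:
                for v in self.active:
                    if u == v:
                        continue
                    if u in parents[v]:
                        # delete u -> v
                        d = fs(v, parents[v] - {u}) - fam[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("del", u, v)
                        # reverse u -> v  (becomes v -> u)
                        if len(parents[u]) < self.max_parents:
                            trial = [set(p) for p in parents]
                            trial[v].discard(u)
                            if not self._has_path(trial, u, v):
                                d2 = (
                                    d
                                    + fs(u, parents[u] | {v})
                                    - fam[u]
                                )
                                if d2 > best_delta:
                                    best_delta, best_move = d2, ("rev", u, v)
                    else:
                        # add u -> v
                        if len(parents[v]) >= self.max_parents:
                            continue
                        if self._has_path(parents, v, u):
                            continue
                        d = fs(v, parents[v] | {u}) - fam[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("add", u, v)
            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                parents[v] = parents[v] | {u}
                fam[v] = fs(v, parents[v])
            elif kind == "del":
                parents[v] = parents[v] - {u}
                fam[v] = fs(v, parents[v])
            else:
                parents[v] = parents[v] - {u}
                parents[u] = parents[u] | {v}
                fam[v] = fs(v, parents[v])
                fam[u] = fs(u, parents[u])
        return sum(fam.values()), parents


def _random_dag_parents(
    rng: np.random.Generator, active: list[int], n_total: int, max_parents: int
) -> list[set[int]]:
    """Random DAG on the active indices: random order, forward edges with
    probability 2/(n-1), parents truncated to max_parents."""
    parents: list[set[int]] = [set() for _ in range(n_total)]
    n = len(active)
    if n < 2:
        return parents
    order = [active[i] for i in rng.permutation(n)]
    p = min(1.0, 2.0 / (n - 1))
    for j in range(1, n):
        candidates = [order[i] for i in range(j) if rng.random() < p]
        if len(candidates) > max_parents:
            candidates = list(rng.choice(candidates, size=max_parents, replace=False))
        parents[order[j]] = set(int(c) for c in candidates)
    return parents


def learn_structure(
    data: FingerprintMatrix,
    restarts: int = 50,
    seed: int = 0,
    ess: float = 1.0,
    max_parents: int = 5,
    cache: FamilyScoreCache | None = None,
) -> BayesianNetwork:
    """Greedy hill climbing with random restarts; returns the best network.

    Restart 0 starts from the empty graph; restarts 1..R-1 from random DAGs.
    Constant columns are kept as isolated nodes (flagged in metadata) and
    never acquire edges.  Deterministic given (data, seed, restarts, ess,
    max_parents).
    """
    if restarts < 1:
        raise UsageError("restarts must be >= 1")
    n = data.n_nodes
    const = set(data.constant_columns())
    active = [i for i, t in enumerate(data.node_texts) if t not in const]
    if len(active) < 2:
        raise DegenerateDataError(
            "structure learning needs at least 2 non-constant columns"
        )
    if data.n_frames < 10:
        logger.warning("learn_structure: only %d frames; estimates will be noisy",
                       data.n_frames)
    cache = cache or FamilyScoreCache(data, ess)
    search = _Search(cache, active, max_parents)

    best_score = -math.inf
    best_parents: list[set[int]] | None = None
    for r in range(restarts):
        if r == 0:
            init: list[set[int]] = [set() for _ in range(n)]
        else:
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, r])
            init = _random_dag_parents(rng, active, n, max_parents)
        score, parents = search.climb(init)
        if score > best_score + 1e-12:
            best_score, best_parents = score, parents

    assert best_parents is not None
    edges: list[Edge] = []
    strengths: dict[Edge, float] = {}
    nodes = list(data.node_labels)
    for v, ps in enumerate(best_parents):
        for u in sorted(ps):
            edge = (nodes[u], nodes[v])
            edges.append(edge)
            delta = cache.score(v, ps) - cache.score(v, ps - {u})
            strengths[edge] = delta / max(data.n_frames, 1)
    edges.sort(key=lambda e: (e[0].canonical_text, e[1].canonical_text))
    meta = {
        "restarts": restarts,
        "seed": int(seed),
        "ess": float(ess),
        "max_parents": max_parents,
        "n_frames": data.n_frames,
        "data_digest": data.digest(),
        "constant_columns": sorted(const),
    }
    return BayesianNetwork(
        nodes=nodes, edges=edges, edge_strengths=strengths,
        total_score=best_score, learn_metadata=meta,
    )


# ---------------------------------------------------------------------------
# Scores on fixed structures
# ---------------------------------------------------------------------------

def edge_strength(
    net: BayesianNetwork,
    data: FingerprintMatrix,
    edge: Edge,
    ess: float = 1.0,
) -> float:
    """Per-observation log marginal-likelihood ratio for one edge of ``net``."""
    if edge not in net.edges:
        raise UsageError(
            f"edge {edge[0].canonical_text} -> {edge[1].canonical_text} is not in the network"
        )
    parent, child = edge
    cache = FamilyScoreCache(data, ess)
    ci = _col_index(data, child)
    pidx = {_col_index(data, p) for p in net.parents_of(child)}
    delta = cache.score(ci, pidx) - cache.score(ci, pidx - {_col_index(data, parent)})
    return delta / max(data.n_frames, 1)


def network_score(
    net: BayesianNetwork | nx.DiGraph,
    data: FingerprintMatrix,
    ess: float = 1.0,
    cache: FamilyScoreCache | None = None,
) -> float:
    """Sum of family scores of every node given its parents (raw log ML)."""
    if isinstance(net, nx.DiGraph):
        if not nx.is_directed_acyclic_graph(net):
            raise UsageError("cannot score a cyclic graph")
        families = {v: set(net.predecessors(v)) for v in net.nodes}
    else:
        families = {
            v.canonical_text: {p.canonical_text for p in net.parents_of(v)}
            for v in net.nodes
        }
    cache = cache or FamilyScoreCache(data, ess)
    total = 0.0
    for v, ps in families.items():
        total += cache.score(_col_index(data, v), {_col_index(data, p) for p in ps})
    return total


# ---------------------------------------------------------------------------
# Exhaustive enumeration (small n) — used as an oracle and for tiny inputs
# ---------------------------------------------------------------------------

def enumerate_dags(n: int) -> list[frozenset[tuple[int, int]]]:
    """All labeled DAGs on n nodes as frozensets of (parent, child) edges.

    Enumerates every topological order x every subset of forward edges and
    deduplicates; practical up to n = 5 (29,281 DAGs).
    """
    import itertools

    seen: set[frozenset[tuple[int, int]]] = set()
    pairs_per_order = list(itertools.combinations(range(n), 2))
    for order in itertools.permutations(range(n)):
        forward = [(order[i], order[j]) for i, j in pairs_per_order]
        m = len(forward)
        for mask in range(1 << m):
            edges = frozenset(forward[k] for k in range(m) if mask >> k & 1)
            seen.add(edges)
    return sorted(seen, key=lambda s: (len(s), sorted(s)))


def best_dag_exhaustive(
    data: FingerprintMatrix, ess: float = 1.0
) -> tuple[float, frozenset[tuple[int, int]]]:
    """Globally best-scoring DAG by enumeration (n <= 5)."""
    n = data.n_nodes
    if n > 5:
        raise LimitError("exhaustive search is limited to 5 nodes")
    cache = FamilyScoreCache(data, ess)
    best = (-math.inf, frozenset())
    for edges in enumerate_dags(n):
        parents: list[set[int]] = [set() for _ in range(n)]
        for u, v in edges:
            parents[v].add(u)
        s = sum(cache.score(v, parents[v]) for v in range(n))
        if s > best[0]:
            best = (s, edges)
    return best


def data_digest(data: FingerprintMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data.values).tobytes())
    return h.hexdigest()[:16]
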