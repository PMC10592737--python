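"""Allosteric edge classification and network-robustness protocols.

*Edge classification.*  A BN edge links two contact nodes, i.e. four
residues.  Using Calpha coordinates of a reference structure, the edge
distance is (by default) the minimum over the four cross-pairs of residues
of the two nodes; edges within 10 A are *neighboring*, farther ones
*allosteric* — dependencies the network found between spatially distant
parts of the interface.

*Robustness.*  Two protocols probe whether a learned topology is a stable
optimum of the data:

* perturbation test — many trials of a few random add/remove edge moves,
  each perturbed DAG rescored on the same data; a robust model outscores
  nearly all perturbations;
* sensitivity test — the frames are bootstrap-resampled many times and the
  fixed topology rescored; the original score should fall inside the
  empirical confidence interval of the resampled scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    ContactNodeId,
    DegenerateDataError,
    FingerprintMatrix,
    UsageError,
)
from .bn import BayesianNetwork, Edge, FamilyScoreCache, _col_index

NEIGHBORING = "neighboring"
ALLOSTERIC = "allosteric"


# ---------------------------------------------------------------------------
# Edge classification
# ---------------------------------------------------------------------------

@dataclass
class EdgeDistanceReport:
    """Per-edge Calpha distance and neighboring/allosteric class."""

    distances: dict[Edge, float] = field(default_factory=dict)
    classes: dict[Edge, str] = field(default_factory=dict)
    cutoff: float = 10.0
    mode: str = "min"

    def counts(self) -> dict[str, int]:
        out = {NEIGHBORING: 0, ALLOSTERIC: 0}
        for c in self.classes.values():
            out[c] += 1
        return out


def _edge_residues(edge: Edge) -> tuple[list[str], list[str]]:
    u, v = edge
    return (
        [u.receptor_label.generic_id, u.gprotein_label.generic_id],
        [v.receptor_label.generic_id, v.gprotein_label.generic_id],
    )


def classify_edges(
    net: BayesianNetwork,
    ca_coords: Mapping[str, np.ndarray],
    cutoff: float = 10.0,
    mode: str = "min",
) -> EdgeDistanceReport:
    """Classify every network edge as neighboring (<= cutoff) or allosteric.

    ``ca_coords`` maps generic residue ids to Calpha coordinates of the
    reference structure.  For an edge (u, v), the candidate distances are
    the four cross-pairs between u's residues and v's residues, excluding
    pairs of identical residues; ``mode`` aggregates them as min (default),
    mean, or centroid (distance between the two nodes' residue centroids).
    A distance of exactly ``cutoff`` is neighboring ("within").
    """
    if mode not in ("min", "mean", "centroid"):
        raise UsageError(f"unknown edge-distance mode {mode!r}")
    missing = sorted({
        gid
        for e in net.edges
        for side in _edge_residues(e)
        for gid in side
        if gid not in ca_coords
    })
    if missing:
        raise LookupError(f"no Calpha coordinate for residues: {missing}")
    report = EdgeDistanceReport(cutoff=cutoff, mode=mode)
    for e in net.edges:
        res_u, res_v = _edge_residues(e)
        if mode == "centroid":
            cu = np.mean([ca_coords[g] for g in res_u], axis=0)
            cv = np.mean([ca_coords[g] for g in res_v], axis=0)
            dist = float(np.linalg.norm(cu - cv))
        else:
            cross = [
                float(np.linalg.norm(ca_coords[a] - ca_coords[b]))
                for a in res_u for b in res_v if a != b
            ]
            if not cross:
                dist = 0.0
            else:
                dist = min(cross) if mode == "min" else float(np.mean(cross))
        report.distances[e] = dist
        report.classes[e] = NEIGHBORING if dist <= cutoff else ALLOSTERIC
    return report


def ca_coords_from_frame(
    frame: Mapping[tuple[str, int], "object"],
    mapping,
) -> dict[str, np.ndarray]:
    """Extract generic-id -> Calpha coordinates from a structure frame."""
    out: dict[str, np.ndarray] = {}
    for (chain, resid), res in frame.items():
        if "CA" not in res.atoms or (chain, resid) not in mapping:
            continue
        out[mapping.lookup(chain, resid).generic_id] = res.atoms["CA"]
    return out


# ---------------------------------------------------------------------------
# Robustness protocols
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    """Outcome of a perturbation or sensitivity run."""

    protocol: str
    n_trials: int
    original_score: float
    trial_scores: list[float]
    fraction_below_original: float
    ci_level: float
    ci_bounds: tuple[float, float]
    original_within_ci: bool
    seed: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_bounds"] = list(self.ci_bounds)
        return d


def _ci_bounds(scores: np.ndarray, ci: float) -> tuple[float, float]:
    lo = float(np.quantile(scores, (1.0 - ci) / 2.0))
    hi = float(np.quantile(scores, 1.0 - (1.0 - ci) / 2.0))
    return lo, hi


def perturbation_test(
    net: BayesianNetwork,
    data: FingerprintMatrix,
    n: int = 1000,
    seed: int = 0,
    move_budget: int = 2,
    ess: float = 1.0,
    ci: float = 0.99,
) -> RobustnessReport:
    """Score ``n`` randomly perturbed topologies against the original.

    Each trial applies ``move_budget`` random add-or-remove edge moves
    (acyclicity preserved; illegal draws are resampled) and rescores the
    perturbed DAG on the same data.  Reports the fraction of trials scoring
    strictly below the original.
    """
    if n < 1:
        raise UsageError("perturbation_test needs n >= 1")
    if move_budget < 0:
        raise UsageError("move_budget must be >= 0")
    cache = FamilyScoreCache(data, ess)
    texts = net.node_texts
    idx = {t: i for i, t in enumerate(texts)}
    base_parents: list[set[int]] = [set() for _ in texts]
    for u, v in net.edges:
        base_parents[idx[v.canonical_text]].add(idx[u.canonical_text])
    base_fam = [cache.score(v, ps) for v, ps in enumerate(base_parents)]
    original = float(sum(base_fam))
    nnodes = len(texts)
    if nnodes < 2:
        raise DegenerateDataError("network too small to perturb")

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 101])
    scores = np.empty(n)
    for t in range(n):
        parents = [set(ps) for ps in base_parents]
        applied = 0
        guard = 0
        while applied < move_budget:
            guard += 1
            if guard > 1000 * max(move_budget, 1):
                raise DegenerateDataError("no legal perturbation move found")
            u = int(rng.integers(nnodes))
            v = int(rng.integers(nnodes))
            if u == v:
                continue
            if u in parents[v]:
                parents[v].discard(u)
                applied += 1
            else:
                if _creates_cycle(parents, u, v):
                    continue
                parents[v].add(u)
                applied += 1
        score = 0.0
        for vtx, ps in enumerate(parents):
            if ps == base_parents[vtx]:
                score += base_fam[vtx]
            else:
                score += cache.score(vtx, ps)
        scores[t] = score

    lo, hi = _ci_bounds(scores, ci)
    return RobustnessReport(
        protocol="perturbation",
        n_trials=n,
        original_score=original,
        trial_scores=scores.tolist(),
        fraction_below_original=float(np.mean(scores < original - 1e-12)),
        ci_level=ci,
        ci_bounds=(lo, hi),
        original_within_ci=bool(lo - 1e-12 <= original <= hi + 1e-12),
        seed=int(seed),
    )


def _creates_cycle(parents: list[set[int]], u: int, v: int) -> bool:
    """Would adding u -> v close a directed cycle?"""
    stack, seen = [v], {v}
    children: dict[int, list[int]] = {}
    for child, ps in enumerate(parents):
        for p in ps:
            children.setdefault(p, []).append(child)
    while stack:
        x = stack.pop()
        if x == u:
            return True
        for c in children.get(x, ()):
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def sensitivity_test(
    net: BayesianNetwork,
    data: FingerprintMatrix,
    n: int = 1000,
    seed: int = 0,
    ci: float = 0.99,
    ess: float = 1.0,
    block_size: int | None = None,
) -> RobustnessReport:
    """Bootstrap the frames and rescore the fixed topology ``n`` times.

    Scores are per observation so resamples are comparable.  ``block_size``
    switches to block (moving-block) resampling for autocorrelated frames;
    plain per-frame resampling is the default.  Requires ci strictly inside
    (0, 1) — an empirical interval needs both tails.
    """
    if not 0.0 < ci < 1.0:
        raise UsageError("ci must lie strictly inside (0, 1)")
    if n < 1:
        raise UsageError("sensitivity_test needs n >= 1")
    if data.n_frames < 10:
        raise UsageError("sensitivity_test needs at least 10 frames")
    texts = net.node_texts
    families = [
        ( _col_index(data, v.canonical_text),
          tuple(sorted(_col_index(data, p.canonical_text) for p in net.parents_of(v))) )
        for v in net.nodes
    ]
    nf = data.n_frames
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 202])
    original = _score_values(data.values, families, ess) / nf
    scores = np.empty(n)
    for t in range(n):
        if block_size:
            starts = rng.integers(0, nf, size=int(np.ceil(nf / block_size)))
            rows = np.concatenate(
                [np.arange(s, s + block_size) % nf for s in starts]
            )[:nf]
        else:
            rows = rng.integers(0, nf, size=nf)
        scores[t] = _score_values(data.values[rows], families, ess) / nf
    lo, hi = _ci_bounds(scores, ci)
    return RobustnessReport(
        protocol="sensitivity",
        n_trials=n,
        original_score=float(original),
        trial_scores=scores.tolist(),
        fraction_below_original=float(np.mean(scores < original - 1e-12)),
        ci_level=ci,
        ci_bounds=(lo, hi),
        original_within_ci=bool(lo - 1e-12 <= original <= hi + 1e-12),
        seed=int(seed),
    )


def _score_values(
    values: np.ndarray, families: Sequence[tuple[int, tuple[int, ...]]], ess: float
) -> float:
    from scipy.special import gammaln

    vals = np.asarray(values, dtype=np.int64)
    total = 0.0
    for child, ptup in families:
        k = len(ptup)
        q = 1 << k
        if k:
            cfg = vals[:, list(ptup)] @ (1 << np.arange(k, dtype=np.int64))
            idx = cfg * 2 + vals[:, child]
        else:
            idx = vals[:, child]
        counts = np.bincount(idx, minlength=2 * q).reshape(q, 2).astype(np.float64)
        a_jk = ess / (2.0 * q)
        a_j = ess / q
        nj = counts.sum(axis=1)
        total += float(
            (gammaln(a_j) - gammaln(a_j + nj)).sum()
            + (gammaln(a_jk + counts) - gammaln(a_jk)).sum()
        )
    return total
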