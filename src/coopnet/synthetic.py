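"""Synthetic fingerprint data with a known planted dependency structure.

Real inputs are MD-derived binary contact fingerprints; those are not
desk-reproducible, so every stage of the pipeline is exercised against
fixtures sampled from a *planted model*: a random DAG over named contact
nodes with explicit conditional probability tables, sampled ancestrally.
The default CPT makes a child a noisy-OR of its parents with a 0.1 flip
probability — strong enough to be identifiable at a few thousand frames,
noisy enough not to be deterministic.

:func:`make_interface_fixture` additionally fabricates the surrounding
context a real complex would bring: residue labels in generic numbering,
round-robin region assignments, lattice Calpha coordinates (so both
neighboring and allosteric edge classes occur), a planted high-degree hub
node, and alternating conservation flags.  Coordinates are abstract lattice
points, not protein geometry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import (
    GPROTEIN,
    GPROTEIN_REGIONS,
    RECEPTOR,
    RECEPTOR_REGIONS,
    ContactNodeId,
    FingerprintMatrix,
    ResidueLabel,
    UsageError,
)


@dataclass
class PlantedModel:
    """A DAG with per-node CPTs, the ground truth behind a fixture.

    ``cpts[node]`` maps each parent configuration (tuple of 0/1 in the
    order of ``parents[node]``) to P(node = 1).
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, dict[tuple[int, ...], float]]
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for node, table in self.cpts.items():
            for cfg, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise UsageError(f"CPT probability out of [0,1] for {node}: {p}")
        self.topological_order()  # raises on cycles

    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.edges()}

    def topological_order(self) -> list[str]:
        order: list[str] = []
        placed: set[str] = set()
        remaining = list(self.nodes)
        while remaining:
            ready = [n for n in remaining if set(self.parents.get(n, ())) <= placed]
            if not ready:
                raise UsageError("planted model graph is cyclic")
            order.extend(ready)
            placed.update(ready)
            remaining = [n for n in remaining if n not in placed]
        return order


def sample_random_dag(
    n_nodes: int,
    edge_prob: float,
    max_parents: int = 5,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Random DAG: uniform node order, each forward edge kept with edge_prob.

    Returns a child -> parents mapping over nodes named ``n00``, ``n01``, ...
    Parent sets exceeding ``max_parents`` are truncated at random.
    """
    if n_nodes < 1:
        raise UsageError("n_nodes must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise UsageError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 11])
    names = [f"n{i:02d}" for i in range(n_nodes)]
    order = [names[i] for i in rng.permutation(n_nodes)]
    parents: dict[str, tuple[str, ...]] = {n: () for n in names}
    for j in range(1, n_nodes):
        ps = [order[i] for i in range(j) if rng.random() < edge_prob]
        if len(ps) > max_parents:
            ps = sorted(rng.choice(ps, size=max_parents, replace=False).tolist())
        parents[order[j]] = tuple(ps)
    return parents


def noisy_or_cpts(
    parents: Mapping[str, tuple[str, ...]],
    flip: float = 0.1,
    root_p: float = 0.5,
) -> dict[str, dict[tuple[int, ...], float]]:
    """Default "strong" CPTs: child = OR(parents), flipped with prob ``flip``."""
    cpts: dict[str, dict[tuple[int, ...], float]] = {}
    for node, ps in parents.items():
        table: dict[tuple[int, ...], float] = {}
        if not ps:
            table[()] = root_p
        else:
            for cfg in itertools.product((0, 1), repeat=len(ps)):
                on = any(cfg)
                table[cfg] = (1.0 - flip) if on else flip
        cpts[node] = table
    return cpts


def planted_model(
    n_nodes: int = 15,
    edge_prob: float = 0.15,
    n_frames: int = 5000,
    seed: int = 0,
    flip: float = 0.1,
    max_parents: int = 5,
) -> PlantedModel:
    parents = sample_random_dag(n_nodes, edge_prob, max_parents, seed)
    nodes = sorted(parents)
    return PlantedModel(
        nodes=nodes,
        parents=parents,
        cpts=noisy_or_cpts(parents, flip=flip),
        n_frames=n_frames,
        seed=seed,
    )


def sample_fingerprints(
    model: PlantedModel, node_labels: Sequence[ContactNodeId] | None = None
) -> FingerprintMatrix:
    """Ancestral sampling of n_frames independent binary state vectors."""
    rng = np.random.default_rng([int(model.seed) & 0x7FFFFFFF, 23])
    n = model.n_frames
    cols: dict[str, np.ndarray] = {}
    for node in model.topological_order():
        ps = model.parents.get(node, ())
        table = model.cpts[node]
        if not ps:
            p = np.full(n, table[()])
        else:
            stacked = np.column_stack([cols[p] for p in ps])
            p = np.empty(n)
            for cfg, prob in table.items():
                mask = (stacked == np.asarray(cfg)).all(axis=1)
                p[mask] = prob
        cols[node] = (rng.random(n) < p).astype(np.uint8)
    if node_labels is None:
        node_labels = [_toy_node(name) for name in model.nodes]
    else:
        node_labels = list(node_labels)
        if len(node_labels) != len(model.nodes):
            raise UsageError("node_labels must match the model's node count")
    values = np.column_stack([cols[name] for name in model.nodes])
    return FingerprintMatrix(
        node_labels=node_labels, values=values,
        provenance=f"planted model seed={model.seed}",
    )


def _toy_node(name: str) -> ContactNodeId:
    """Stable synthetic contact-node label for a bare model node name."""
    i = int(name.lstrip("n"))
    return ContactNodeId.from_labels(
        ResidueLabel(RECEPTOR, f"{i % 7 + 1}×{40 + i}", i + 1, "R"),
        ResidueLabel(GPROTEIN, f"G.H5.{i + 1:02d}", i + 101, "A"),
    )


# ---------------------------------------------------------------------------
# Full interface fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Everything a pipeline run needs, generated from one seed."""

    fingerprints: FingerprintMatrix
    model: PlantedModel
    ca_coords: dict[str, np.ndarray]
    regions: dict[str, str]
    conserved_flags: dict[str, bool]
    hub: ContactNodeId = field(default=None)  # type: ignore[assignment]

    @property
    def nodes(self) -> list[ContactNodeId]:
        return self.fingerprints.node_labels


def make_interface_fixture(
    n_receptor_res: int = 10,
    n_gprot_res: int = 8,
    n_nodes: int = 20,
    n_frames: int = 5000,
    seed: int = 0,
    flip: float = 0.1,
    hub_degree: int = 4,
    extra_edge_prob: float = 0.1,
) -> FixtureBundle:
    """Build a synthetic complex: planted BN + labels, regions, coordinates.

    Node i is the contact of receptor residue (i mod R) with G-protein
    residue (i mod G), so distinct nodes share residues the way real
    interface contacts do.  Node 0 is the hub, given ``hub_degree`` strong
    children; remaining dependencies come from a sparse random DAG over the
    other nodes.  Calpha coordinates sit on a 6 A lattice: consecutive
    residues are neighboring (< 10 A), distant ones allosteric (> 10 A).
    Every second G-protein residue is flagged unconserved.
    """
    if n_nodes > n_receptor_res * n_gprot_res:
        raise UsageError("n_nodes must not exceed n_receptor_res * n_gprot_res")
    if n_nodes < hub_degree + 1:
        raise UsageError("n_nodes must exceed hub_degree")

    rec_ids = [f"{i % 7 + 1}×{50 + i}" for i in range(n_receptor_res)]
    gp_ids = [f"G.H5.{i + 1:02d}" for i in range(n_gprot_res)]
    rec_labels = [
        ResidueLabel(RECEPTOR, gid, 100 + i, "R") for i, gid in enumerate(rec_ids)
    ]
    gp_labels = [
        ResidueLabel(GPROTEIN, gid, 300 + i, "A") for i, gid in enumerate(gp_ids)
    ]
    node_labels = [
        ContactNodeId.from_labels(
            rec_labels[i % n_receptor_res], gp_labels[i % n_gprot_res]
        )
        for i in range(n_nodes)
    ]

    # planted structure: hub children + sparse random DAG over the rest
    names = [f"n{i:02d}" for i in range(n_nodes)]
    rest = sample_random_dag(
        n_nodes - hub_degree - 1, extra_edge_prob, max_parents=3,
        seed=seed + 1,
    )
    rename = {f"n{i:02d}": names[i + hub_degree + 1] for i in range(len(rest))}
    parents: dict[str, tuple[str, ...]] = {names[0]: ()}
    for i in range(1, hub_degree + 1):
        parents[names[i]] = (names[0],)
    # cap non-hub degrees below the hub's so the hub has the unique maximal
    # planted degree by construction
    degree = {n: 0 for n in names}
    for i in range(1, hub_degree + 1):
        degree[names[0]] += 1
        degree[names[i]] += 1
    for child, ps in rest.items():
        kept: list[str] = []
        c = rename[child]
        for p in ps:
            pr = rename[p]
            if degree[c] < hub_degree - 1 and degree[pr] < hub_degree - 1:
                kept.append(pr)
                degree[c] += 1
                degree[pr] += 1
        parents[c] = tuple(kept)
    model = PlantedModel(
        nodes=names,
        parents=parents,
        cpts=noisy_or_cpts(parents, flip=flip),
        n_frames=n_frames,
        seed=seed,
    )
    fingerprints = sample_fingerprints(model, node_labels=node_labels)

    # lattice coordinates: receptor on y=0, G protein on y=3.5 (close enough
    # for Calpha-Calpha vdW contact), 6 A spacing along x
    ca: dict[str, np.ndarray] = {}
    for i, gid in enumerate(rec_ids):
        ca[gid] = np.array([6.0 * i, 0.0, 0.0])
    for i, gid in enumerate(gp_ids):
        ca[gid] = np.array([6.0 * i, 3.5, 0.0])

    regions: dict[str, str] = {}
    for i, gid in enumerate(rec_ids):
        regions[gid] = RECEPTOR_REGIONS[i % len(RECEPTOR_REGIONS)]
    for i, gid in enumerate(gp_ids):
        regions[gid] = GPROTEIN_REGIONS[i % len(GPROTEIN_REGIONS)]

    conserved = {gid: (i % 2 == 0) for i, gid in enumerate(gp_ids)}

    return FixtureBundle(
        fingerprints=fingerprints,
        model=model,
        ca_coords=ca,
        regions=regions,
        conserved_flags=conserved,
        hub=node_labels[0],
    )


def skeleton_f1(
    learned_edges: set[tuple[str, str]] | set[frozenset[str]],
    true_skeleton: set[frozenset[str]],
) -> float:
    """F1 of the learned undirected skeleton against the planted one."""
    learned = {
        e if isinstance(e, frozenset) else frozenset(e) for e in learned_edges
    }
    tp = len(learned & true_skeleton)
    if tp == 0:
        return 0.0
    precision = tp / len(learned)
    recall = tp / len(true_skeleton)
    return 2 * precision * recall / (precision + recall)


def write_fixture_directory(bundle: FixtureBundle, outdir) -> None:
    """Emit the fixture as the on-disk formats the CLI consumes."""
    import json
    from pathlib import Path

    from .io import write_fingerprint_table, write_region_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fingerprint_table(bundle.fingerprints, outdir / "fingerprints.tsv")
    write_region_table(bundle.regions, outdir / "regions.tsv")
    with open(outdir / "flags.tsv", "w") as fh:
        fh.write("generic_id\tconserved\n")
        for gid, flag in bundle.conserved_flags.items():
            fh.write(f"{gid}\t{int(flag)}\n")
    with open(outdir / "mapping.tsv", "w") as fh:
        fh.write("chain\tresid\trole\tgeneric_id\n")
        seen = set()
        for n in bundle.nodes:
            for lab in (n.receptor_label, n.gprotein_label):
                key = (lab.pdb_chain, lab.pdb_resid)
                if key not in seen:
                    seen.add(key)
                    fh.write(
                        f"{lab.pdb_chain}\t{lab.pdb_resid}\t{lab.chain_role}\t{lab.generic_id}\n"
                    )
    with open(outdir / "coordinates.pdb", "w") as fh:
        serial = 1
        id_to_label: dict[str, ResidueLabel] = {}
        for n in bundle.nodes:
            id_to_label[n.receptor_label.generic_id] = n.receptor_label
            id_to_label[n.gprotein_label.generic_id] = n.gprotein_label
        for gid, xyz in bundle.ca_coords.items():
            lab = id_to_label.get(gid)
            chain = lab.pdb_chain if lab else "X"
            resid = lab.pdb_resid if lab else serial
            fh.write(
                f"ATOM  {serial:5d}  CA  ALA {chain}{resid:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
            serial += 1
        fh.write("END\n")
    with open(outdir / "model.json", "w") as fh:
        json.dump(
            {
                "nodes": bundle.model.nodes,
                "parents": {k: list(v) for k, v in bundle.model.parents.items()},
                "cpts": {
                    k: {"".join(map(str, cfg)): p for cfg, p in t.items()}
                    for k, t in bundle.model.cpts.items()
                },
                "n_frames": bundle.model.n_frames,
                "seed": bundle.model.seed,
                "hub": bundle.hub.canonical_text,
            },
            fh,
            indent=2,
        )
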