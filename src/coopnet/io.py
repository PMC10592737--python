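"""Core domain types, run configuration, and file I/O.

The unit of analysis throughout the package is the *contact node*: one
receptor-residue x G-protein-residue pairwise interaction, treated as a
binary random variable per trajectory frame.  Contact nodes are named by
generic residue numbers (Ballesteros-Weinstein on the receptor side,
Common G-protein Numbering on the G-alpha side) so that the same physical
interaction compares equal across different complexes.

File formats handled here:

* fingerprint TSV  — header row of contact-node labels, one row of 0/1
  values per frame;
* mapping TSV      — columns ``chain  resid  role  generic_id`` translating
  author (PDB) numbering into generic numbering;
* region TSV       — columns ``generic_id  region``;
* flags TSV        — columns ``generic_id  conserved`` (0/1);
* coupling TSV     — columns ``region  dlogec50``;
* network export   — GraphML / SIF / edge list, via :mod:`networkx`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("coopnet")

RECEPTOR = "receptor"
GPROTEIN = "gprotein"

#: Receptor structural regions (GPCR helices/loops) and G-protein regions.
RECEPTOR_REGIONS = (
    "TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8",
    "ICL1", "ICL2", "ICL3",
)
GPROTEIN_REGIONS = (
    "N-term", "b1", "b2b3", "b6", "hgh4", "hns1", "core-other",
    "a5-core", "a5-tip",
)


class FormatError(ValueError):
    """A file violated the expected format."""


class UsageError(ValueError):
    """The caller violated an operation's contract."""


class ConsistencyError(ValueError):
    """Two inputs that must agree did not."""


class InsufficientDataError(ValueError):
    """Too few data points for the requested statistic."""


class LimitError(ValueError):
    """A configured tractability cap (parent count, state space) was exceeded."""


class DegenerateDataError(ValueError):
    """The data carry no signal the operation could use (e.g. all-constant)."""


# ---------------------------------------------------------------------------
# Residue and contact-node identity
# ---------------------------------------------------------------------------

def normalize_generic_id(generic_id: str, chain_role: str = RECEPTOR) -> str:
    """Normalize a generic residue id.

    The multiplication sign in BW numbers ("7x55" -> "7×55") is the canonical
    form; the ASCII letter ``x`` is accepted as an alias on input.  CGN ids
    (e.g. ``G.H5.24``) pass through unchanged.
    """
    gid = generic_id.strip()
    if not gid:
        raise FormatError("empty generic_id")
    if chain_role == RECEPTOR and "×" not in gid and "x" in gid:
        head, _, tail = gid.partition("x")
        if head and tail and head[-1].isdigit() and tail[0].isdigit():
            gid = head + "×" + tail
    return gid


@dataclass(frozen=True, order=True)
class ResidueLabel:
    """One residue, identified both by author numbering and generic numbering.

    ``chain_role`` decides the numbering dialect of ``generic_id``:
    Ballesteros-Weinstein (``7×55``) for the receptor, Common G-protein
    Numbering (``G.H5.24``) for the G-alpha subunit.
    """

    chain_role: str
    generic_id: str
    pdb_resid: int = 0
    pdb_chain: str = ""

    def __post_init__(self) -> None:
        if self.chain_role not in (RECEPTOR, GPROTEIN):
            raise UsageError(f"unknown chain_role {self.chain_role!r}")
        if not self.generic_id:
            raise FormatError("generic_id must be non-empty")


@dataclass(frozen=True, order=True)
class ContactNodeId:
    """A receptor-residue x G-protein-residue interaction, the network node.

    Identity is by ``canonical_text`` — ``<receptor_generic>_<gprotein_generic>``
    (e.g. ``7×55_G.H5.24``) — which is what makes nodes from different
    complexes comparable.
    """

    receptor_label: ResidueLabel = field(compare=False)
    gprotein_label: ResidueLabel = field(compare=False)
    canonical_text: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        expect = f"{self.receptor_label.generic_id}_{self.gprotein_label.generic_id}"
        if not self.canonical_text:
            object.__setattr__(self, "canonical_text", expect)
        elif self.canonical_text != expect:
            raise ConsistencyError(
                f"canonical_text {self.canonical_text!r} does not match labels {expect!r}"
            )

    @classmethod
    def from_labels(cls, receptor: ResidueLabel, gprotein: ResidueLabel) -> "ContactNodeId":
        return cls(receptor_label=receptor, gprotein_label=gprotein)

    @classmethod
    def parse(cls, text: str) -> "ContactNodeId":
        """Inverse of formatting: split on the first underscore.

        CGN ids contain dots, never underscores, so the first ``_`` always
        separates the receptor part from the G-protein part.
        """
        head, sep, tail = text.partition("_")
        if not sep or not head or not tail:
            raise FormatError(f"cannot parse contact-node label {text!r}")
        return cls.from_labels(
            ResidueLabel(RECEPTOR, normalize_generic_id(head, RECEPTOR)),
            ResidueLabel(GPROTEIN, normalize_generic_id(tail, GPROTEIN)),
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_text


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    Distances are in Angstrom, angles in degrees, thresholds as fractions.
    """

    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    hbond_angle: float = 70.0
    pistack_cutoff: float = 7.0
    pistack_angle: float = 30.0
    cationpi_cutoff: float = 6.0
    cationpi_angle: float = 60.0
    vdw_tolerance: float = 0.5      # added to the Bondi radius sum
    vdw_mode: str = "radius_sum"    # or "gap": inter-atom gap < vdw_gap
    vdw_gap: float = 2.0
    persistence_threshold: float = 0.20
    restarts: int = 50
    seed: int = 0
    ess: float = 1.0                # equivalent sample size of the Dirichlet prior
    max_parents: int = 5
    allosteric_cutoff: float = 10.0
    n_perturbations: int = 1000
    n_resamples: int = 1000
    ci_level: float = 0.99
    quartile_fraction: float = 0.25
    jsd_pseudocount: float = 0.5
    state_cap: int = 2 ** 20
    edge_distance_mode: str = "min"  # min | mean | centroid

    def __post_init__(self) -> None:
        for name in ("salt_bridge_cutoff", "hbond_cutoff", "pistack_cutoff",
                     "cationpi_cutoff", "allosteric_cutoff", "ess"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be > 0")
        if not 0.0 <= self.persistence_threshold <= 1.0:
            raise UsageError("persistence_threshold must be in [0, 1]")
        if not 0.0 < self.ci_level < 1.0:
            raise UsageError("ci_level must be in the open interval (0, 1)")
        if not 0.0 < self.quartile_fraction <= 1.0:
            raise UsageError("quartile_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Fingerprint matrix
# ---------------------------------------------------------------------------

@dataclass
class FingerprintMatrix:
    """Frames x contact-nodes binary matrix: 1 = contact present in frame."""

    node_labels: list[ContactNodeId]
    values: np.ndarray                      # (n_frames, n_nodes) uint8
    frames: list[int] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise UsageError("fingerprint values must be a 2-D matrix")
        if self.values.shape[1] != len(self.node_labels):
            raise ConsistencyError("column count does not match node_labels")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("fingerprint values must be binary")
        texts = [n.canonical_text for n in self.node_labels]
        if len(set(texts)) != len(texts):
            raise FormatError("duplicate contact-node labels")
        if not self.frames:
            self.frames = list(range(self.values.shape[0]))

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def node_texts(self) -> list[str]:
        return [n.canonical_text for n in self.node_labels]

    def column(self, node: ContactNodeId | str) -> np.ndarray:
        text = node if isinstance(node, str) else node.canonical_text
        try:
            idx = self.node_texts.index(text)
        except ValueError:
            raise KeyError(f"node {text!r} not in fingerprint") from None
        return self.values[:, idx]

    def constant_columns(self) -> list[str]:
        """Labels of all-0 or all-1 columns (legal, but flagged)."""
        if self.n_frames == 0:
            return []
        mins = self.values.min(axis=0)
        maxs = self.values.max(axis=0)
        return [t for t, lo, hi in zip(self.node_texts, mins, maxs) if lo == hi]

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update("\t".join(self.node_texts).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.node_texts)


def read_fingerprint_table(path: str | Path) -> FingerprintMatrix:
    """Read a tab-separated binary fingerprint file.

    First row: contact-node labels (``<bw>_<cgn>``); each later row: one
    frame of 0/1 values.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise FormatError(f"{path}: empty fingerprint file")
    headers = header_line.rstrip("\n").split("\t")
    if len(set(headers)) != len(headers):
        dupes = sorted({h for h in headers if headers.count(h) > 1})
        raise FormatError(f"{path}: duplicate column header(s) {dupes}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    labels = [ContactNodeId.parse(h) for h in headers]
    values = np.empty((len(df), len(headers)), dtype=np.uint8)
    for j, col in enumerate(df.columns):
        cell = df[col].astype(str).str.strip()
        bad = ~cell.isin(("0", "1"))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-binary cell {cell.iloc[i]!r} at row {i}, column {headers[j]!r}"
            )
        values[:, j] = (cell == "1").to_numpy()
    return FingerprintMatrix(node_labels=labels, values=values, provenance=str(path))


def write_fingerprint_table(matrix: FingerprintMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mapping / region / flag / coupling tables
# ---------------------------------------------------------------------------

class ResidueMapping:
    """Total mapping from (pdb_chain, pdb_resid) to :class:`ResidueLabel`.

    Queries of residues absent from the table raise, listing the residue —
    silent drops would corrupt cross-complex comparisons downstream.
    """

    def __init__(self, entries: Iterable[ResidueLabel]):
        self._by_key: dict[tuple[str, int], ResidueLabel] = {}
        for lab in entries:
            key = (lab.pdb_chain, lab.pdb_resid)
            if key in self._by_key:
                raise FormatError(f"duplicate mapping entry for chain/resid {key}")
            self._by_key[key] = lab

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_key

    def lookup(self, pdb_chain: str, pdb_resid: int) -> ResidueLabel:
        try:
            return self._by_key[(pdb_chain, pdb_resid)]
        except KeyError:
            raise LookupError(
                f"residue chain={pdb_chain!r} resid={pdb_resid} has no generic-number mapping"
            ) from None

    def missing(self, keys: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
        return sorted(k for k in set(keys) if k not in self._by_key)


def read_mapping_table(path: str | Path) -> ResidueMapping:
    """Read a ``chain  resid  role  generic_id`` TSV into a ResidueMapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"chain", "resid", "role", "generic_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: mapping table needs columns {sorted(required)}")
    entries = []
    for i, row in df.iterrows():
        gid = "" if pd.isna(row["generic_id"]) else str(row["generic_id"]).strip()
        if not gid:
            raise FormatError(f"{path}: empty generic_id at row {i}")
        role = str(row["role"]).strip().lower()
        if role not in (RECEPTOR, GPROTEIN):
            raise FormatError(f"{path}: role must be receptor|gprotein, got {role!r} at row {i}")
        entries.append(ResidueLabel(
            chain_role=role,
            generic_id=normalize_generic_id(gid, role),
            pdb_resid=int(row["resid"]),
            pdb_chain=str(row["chain"]).strip(),
        ))
    return ResidueMapping(entries)


def read_region_table(path: str | Path) -> dict[str, str]:
    """Read ``generic_id  region`` TSV; every id maps to exactly one region."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"generic_id", "region"}.issubset(df.columns):
        raise FormatError(f"{path}: region table needs columns generic_id, region")
    out: dict[str, str] = {}
    for i, row in df.iterrows():
        gid = normalize_generic_id(str(row["generic_id"]))
        if gid in out and out[gid] != str(row["region"]):
            raise FormatError(f"{path}: generic_id {gid!r} mapped to two regions")
        out[gid] = str(row["region"]).strip()
    return out


def write_region_table(regions: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"generic_id": list(regions), "region": [regions[k] for k in regions]}
    ).to_csv(path, sep="\t", index=False)


def read_flags_table(path: str | Path) -> dict[str, bool]:
    """Read ``generic_id  conserved`` TSV (1/0, true/false)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"generic_id", "conserved"}.issubset(df.columns):
        raise FormatError(f"{path}: flags table needs columns generic_id, conserved")
    truthy = {"1", "true", "yes"}
    falsy = {"0", "false", "no"}
    out: dict[str, bool] = {}
    for _, row in df.iterrows():
        val = str(row["conserved"]).strip().lower()
        if val not in truthy | falsy:
            raise FormatError(f"{path}: conserved flag must be boolean, got {val!r}")
        out[normalize_generic_id(str(row["generic_id"]))] = val in truthy
    return out


def read_coupling_table(path: str | Path) -> dict[str, float]:
    """Read ``region  dlogec50`` TSV of experimental coupling changes."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"region", "dlogec50"}.issubset(df.columns):
        raise FormatError(f"{path}: coupling table needs columns region, dlogec50")
    return {str(r): float(v) for r, v in zip(df["region"], df["dlogec50"])}


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def _as_nx(net) -> nx.Graph | nx.DiGraph:
    """Convert a BayesianNetwork / MoralGraph / networkx graph to networkx."""
    if isinstance(net, (nx.Graph, nx.DiGraph)):
        return net
    if hasattr(net, "to_networkx"):
        return net.to_networkx()
    raise UsageError(f"cannot export object of type {type(net).__name__}")


def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Export a directed BN (with ``strength`` edge attributes) or a moral
    graph (unweighted) for Cytoscape and friends."""
    g = _as_nx(net)
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        kind = "dep" if g.is_directed() else "assoc"
        with open(path, "w") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\t{kind}\t{v}\n")
            for n in nx.isolates(g):
                fh.write(f"{n}\n")
    elif format == "edge-list":
        with open(path, "w") as fh:
            for u, v, d in g.edges(data=True):
                s = d.get("strength")
                fh.write(f"{u}\t{v}" + (f"\t{s:.8g}" if s is not None else "") + "\n")
    else:
        raise UsageError(f"unknown network format {format!r}; use graphml|sif|edge-list")


def read_network_graphml(path: str | Path) -> nx.Graph | nx.DiGraph:
    return nx.read_graphml(path)


def write_json_report(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if math.isnan(float(o)) else float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, ContactNodeId):
            return o.canonical_text
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
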