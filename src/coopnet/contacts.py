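"""Interface contact detection and binary fingerprint construction.

Contacts between receptor and G-protein residues are detected from heavy-atom
geometry with five interaction types and the standard cutoffs used for
protein interaction fingerprinting:

* salt bridge  — anion-atom to cation-atom distance < 4.0 A
* hydrogen bond — donor-acceptor distance < 3.5 A and a donor-H...acceptor
  deviation from linearity < 70 deg (idealized H direction when the structure
  has no hydrogens)
* van der Waals — heavy-atom distance < r_vdw(i) + r_vdw(j) + 0.5 A
  (Bondi radii; a literal "gap < 2 A" mode is selectable)
* pi stacking  — aromatic centroid distance < 7.0 A, ring-normal angle < 30 deg
* cation-pi    — cation to aromatic centroid < 6.0 A and an angle < 60 deg
  between the ring normal and the centroid-to-cation vector

A residue pair in a frame is a single contact-node observation no matter how
many interaction types fire; the per-type records are kept only to classify
nodes as polar or non-polar.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import (
    GPROTEIN,
    RECEPTOR,
    ConsistencyError,
    ContactNodeId,
    FingerprintMatrix,
    ResidueLabel,
    ResidueMapping,
    RunConfig,
    UsageError,
)

logger = logging.getLogger("coopnet.contacts")

SALT_BRIDGE = "salt_bridge"
HYDROGEN_BOND = "hydrogen_bond"
VDW = "vdw"
PI_STACK = "pi_stack"
CATION_PI = "cation_pi"

#: polar interaction types; everything else is non-polar
POLAR_TYPES = frozenset({SALT_BRIDGE, HYDROGEN_BOND, CATION_PI})
#: tie-break priority for the dominant interaction type of a node
TYPE_PRIORITY = (SALT_BRIDGE, HYDROGEN_BOND, CATION_PI, PI_STACK, VDW)

# Bondi (1964) van der Waals radii, Angstrom, by element.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

# --- atom typing (heavy-atom names, standard amino acids) -------------------

ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
CATION_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NH1", "NH2", "NE"},
}
DONOR_ATOMS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
BACKBONE_DONOR = "N"
BACKBONE_ACCEPTORS = {"O", "OXT"}


@dataclass(frozen=True)
class ContactRecord:
    """One detected interaction of one residue pair in one frame."""

    frame_index: int
    node: ContactNodeId
    interaction_type: str

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise UsageError("frame_index must be >= 0")
        if self.interaction_type not in TYPE_PRIORITY:
            raise UsageError(f"unknown interaction type {self.interaction_type!r}")


@dataclass
class Residue:
    """Minimal residue view used by the geometric criteria."""

    chain: str
    resid: int
    resname: str
    atoms: dict[str, np.ndarray]            # atom name -> xyz

    def heavy_atoms(self) -> list[tuple[str, np.ndarray]]:
        return [(n, xyz) for n, xyz in self.atoms.items() if _element(n) != "H"]

    def hydrogens_bonded_to(self, donor_name: str, cutoff: float = 1.25) -> list[np.ndarray]:
        d = self.atoms[donor_name]
        return [
            xyz for n, xyz in self.atoms.items()
            if _element(n) == "H" and np.linalg.norm(xyz - d) < cutoff
        ]

    def heavy_neighbors_of(self, name: str, cutoff: float = 1.8) -> list[np.ndarray]:
        a = self.atoms[name]
        return [
            xyz for n, xyz in self.atoms.items()
            if n != name and _element(n) != "H"
            and np.linalg.norm(xyz - a) < cutoff
        ]


def _element(atom_name: str) -> str:
    """Infer the element from a PDB atom name (heavy-atom conventions)."""
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():           # e.g. 1HB2
        name = name.lstrip("0123456789")
    if name[:2].upper() in ("CL", "BR"):
        return name[:2].upper()
    return name[0].upper()


def _vdw_radius(atom_name: str) -> float:
    return BONDI_RADII.get(_element(atom_name), 1.70)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _ring_geometry(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    names = AROMATIC_RINGS.get(res.resname)
    if not names:
        return None
    pts = [res.atoms[n] for n in names if n in res.atoms]
    if len(pts) < 3:
        return None
    pts = np.asarray(pts)
    centroid = pts.mean(axis=0)
    # normal = smallest-variance direction of the ring atoms
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[-1]


# ---------------------------------------------------------------------------
# Per-pair criteria
# ---------------------------------------------------------------------------

def _salt_bridge(a: Residue, b: Residue, cfg: RunConfig) -> bool:
    for r1, r2 in ((a, b), (b, a)):
        anions = ANION_ATOMS.get(r1.resname, set()) & r1.atoms.keys()
        cations = CATION_ATOMS.get(r2.resname, set()) & r2.atoms.keys()
        for an, ca in itertools.product(anions, cations):
            if np.linalg.norm(r1.atoms[an] - r2.atoms[ca]) < cfg.salt_bridge_cutoff:
                return True
    return False


def _donor_directions(res: Residue, donor: str) -> list[np.ndarray]:
    """Unit direction(s) of the donor's hydrogen(s).

    With explicit hydrogens the real D->H vectors are used; otherwise the H is
    idealized as pointing away from the mean of the donor's bonded heavy
    neighbours.  A donor with no resolvable neighbours passes the distance
    criterion alone (direction unconstrained).
    """
    d = res.atoms[donor]
    hs = res.hydrogens_bonded_to(donor)
    if hs:
        return [h - d for h in hs]
    neigh = res.heavy_neighbors_of(donor)
    if donor == BACKBONE_DONOR and not neigh:
        neigh = res.heavy_neighbors_of(donor, cutoff=2.0)
    if not neigh:
        return []
    return [d - np.mean(neigh, axis=0)]


def _hydrogen_bond(a: Residue, b: Residue, cfg: RunConfig) -> bool:
    for don_res, acc_res in ((a, b), (b, a)):
        donors = set(DONOR_ATOMS.get(don_res.resname, set()))
        if BACKBONE_DONOR in don_res.atoms:
            donors.add(BACKBONE_DONOR)
        donors &= don_res.atoms.keys()
        acceptors = set(ACCEPTOR_ATOMS.get(acc_res.resname, set()))
        acceptors |= BACKBONE_ACCEPTORS
        acceptors &= acc_res.atoms.keys()
        for dn, an in itertools.product(donors, acceptors):
            dpos, apos = don_res.atoms[dn], acc_res.atoms[an]
            if np.linalg.norm(dpos - apos) >= cfg.hbond_cutoff:
                continue
            dirs = _donor_directions(don_res, dn)
            if not dirs:
                return True
            for hdir in dirs:
                if _angle_deg(hdir, apos - dpos) < cfg.hbond_angle:
                    return True
    return False


def _vdw_contact(a: Residue, b: Residue, cfg: RunConfig) -> bool:
    for (n1, p1), (n2, p2) in itertools.product(a.heavy_atoms(), b.heavy_atoms()):
        dist = float(np.linalg.norm(p1 - p2))
        if cfg.vdw_mode == "gap":
            limit = _vdw_radius(n1) + _vdw_radius(n2) + cfg.vdw_gap
        else:
            limit = _vdw_radius(n1) + _vdw_radius(n2) + cfg.vdw_tolerance
        if dist < limit:
            return True
    return False


def _pi_stack(a: Residue, b: Residue, cfg: RunConfig) -> bool:
    ga, gb = _ring_geometry(a), _ring_geometry(b)
    if ga is None or gb is None:
        return False
    (c1, n1), (c2, n2) = ga, gb
    if np.linalg.norm(c1 - c2) >= cfg.pistack_cutoff:
        return False
    ang = _angle_deg(n1, n2)
    return min(ang, 180.0 - ang) < cfg.pistack_angle


def _cation_pi(a: Residue, b: Residue, cfg: RunConfig) -> bool:
    for ring_res, cat_res in ((a, b), (b, a)):
        geom = _ring_geometry(ring_res)
        if geom is None:
            continue
        centroid, normal = geom
        for cn in CATION_ATOMS.get(cat_res.resname, set()) & cat_res.atoms.keys():
            vec = cat_res.atoms[cn] - centroid
            if np.linalg.norm(vec) >= cfg.cationpi_cutoff:
                continue
            ang = _angle_deg(normal, vec)
            if min(ang, 180.0 - ang) < cfg.cationpi_angle:
                return True
    return False


_CRITERIA = (
    (SALT_BRIDGE, _salt_bridge),
    (HYDROGEN_BOND, _hydrogen_bond),
    (VDW, _vdw_contact),
    (PI_STACK, _pi_stack),
    (CATION_PI, _cation_pi),
)


# ---------------------------------------------------------------------------
# Structure reading and detection
# ---------------------------------------------------------------------------

def read_structure_frames(path: str | Path) -> list[dict[tuple[str, int], Residue]]:
    """Read a (possibly multi-model) PDB file into frames of residues.

    Frames follow model order; frame ids are 0-based.  Returns, per frame,
    a mapping (chain, resid) -> :class:`Residue`.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    frames = []
    for model in st:
        residues: dict[tuple[str, int], Residue] = {}
        for chain in model:
            for res in chain:
                if res.name in ("HOH", "WAT"):   # waters never count
                    continue
                key = (chain.name, res.seqid.num)
                atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
                residues[key] = Residue(chain.name, res.seqid.num, res.name, atoms)
        frames.append(residues)
    return frames


def _label_for(residue: Residue, role: str, mapping: ResidueMapping | None) -> ResidueLabel:
    if mapping is None:
        return ResidueLabel(role, f"{residue.chain}:{residue.resid}",
                            residue.resid, residue.chain)
    return mapping.lookup(residue.chain, residue.resid)


def detect_contacts(
    frame: Mapping[tuple[str, int], Residue],
    selection_receptor: Sequence[str],
    selection_gprotein: Sequence[str],
    config: RunConfig | None = None,
    mapping: ResidueMapping | None = None,
    frame_index: int = 0,
    prefilter: float = 14.0,
) -> list[ContactRecord]:
    """Detect all receptor x G-protein residue contacts in one frame.

    ``selection_receptor`` / ``selection_gprotein`` are chain ids.  Residue
    pairs whose closest heavy atoms exceed ``prefilter`` are skipped before
    the per-type criteria (no criterion reaches that far).
    """
    cfg = config or RunConfig()
    rec = [r for r in frame.values() if r.chain in set(selection_receptor)]
    gpr = [r for r in frame.values() if r.chain in set(selection_gprotein)]
    if not rec or not gpr:
        raise UsageError("empty receptor or G-protein selection")
    records: list[ContactRecord] = []
    for r1 in rec:
        pts1 = np.asarray([p for _, p in r1.heavy_atoms()])
        if pts1.size == 0:
            continue
        for r2 in gpr:
            pts2 = np.asarray([p for _, p in r2.heavy_atoms()])
            if pts2.size == 0:
                continue
            dmin = np.sqrt(
                ((pts1[:, None, :] - pts2[None, :, :]) ** 2).sum(-1)
            ).min()
            if dmin > prefilter:
                continue
            node: ContactNodeId | None = None
            for type_name, criterion in _CRITERIA:
                try:
                    hit = criterion(r1, r2, cfg)
                except KeyError as exc:  # missing atom for this criterion
                    logger.warning(
                        "skipping %s for %s%d-%s%d: missing atom %s",
                        type_name, r1.chain, r1.resid, r2.chain, r2.resid, exc,
                    )
                    continue
                if hit:
                    if node is None:
                        node = ContactNodeId.from_labels(
                            _label_for(r1, RECEPTOR, mapping),
                            _label_for(r2, GPROTEIN, mapping),
                        )
                    records.append(ContactRecord(frame_index, node, type_name))
    return records


def detect_contacts_trajectory(
    frames: Sequence[Mapping[tuple[str, int], Residue]],
    selection_receptor: Sequence[str],
    selection_gprotein: Sequence[str],
    config: RunConfig | None = None,
    mapping: ResidueMapping | None = None,
) -> list[ContactRecord]:
    records: list[ContactRecord] = []
    for i, fr in enumerate(frames):
        records.extend(detect_contacts(
            fr, selection_receptor, selection_gprotein, config, mapping, frame_index=i,
        ))
    return records


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def contact_frequencies(
    records: Iterable[ContactRecord], n_frames: int
) -> dict[ContactNodeId, float]:
    """Fraction of frames in which each node has at least one record.

    Multiple interaction types in one frame count once.
    """
    if n_frames < 1:
        raise UsageError("n_frames must be >= 1")
    seen: dict[ContactNodeId, set[int]] = defaultdict(set)
    for r in records:
        if r.frame_index >= n_frames:
            raise ConsistencyError(
                f"record frame index {r.frame_index} >= n_frames {n_frames}"
            )
        seen[r.node].add(r.frame_index)
    return {node: len(fr) / n_frames for node, fr in seen.items()}


def filter_persistent(
    freqs: Mapping[ContactNodeId, float], threshold: float = 0.20
) -> set[ContactNodeId]:
    """Nodes with frequency strictly greater than the persistence threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise UsageError("threshold must be in [0, 1]")
    return {node for node, f in freqs.items() if f > threshold}


def encode_fingerprints(
    records: Iterable[ContactRecord],
    node_universe: Sequence[ContactNodeId],
    n_frames: int,
    provenance: str = "",
) -> FingerprintMatrix:
    """One-hot encode per-frame contact records over a fixed node universe.

    Records for nodes outside the universe are ignored (counted in a
    warning); constant columns are legal and can be inspected via
    :meth:`FingerprintMatrix.constant_columns`.
    """
    if n_frames < 1:
        raise UsageError("n_frames must be >= 1")
    universe = list(node_universe)
    index = {n.canonical_text: j for j, n in enumerate(universe)}
    values = np.zeros((n_frames, len(universe)), dtype=np.uint8)
    ignored = 0
    for r in records:
        j = index.get(r.node.canonical_text)
        if j is None:
            ignored += 1
            continue
        if r.frame_index >= n_frames:
            raise ConsistencyError(
                f"record frame index {r.frame_index} >= n_frames {n_frames}"
            )
        values[r.frame_index, j] = 1
    if ignored:
        logger.warning("encode_fingerprints: ignored %d records outside the node universe", ignored)
    m = FingerprintMatrix(node_labels=universe, values=values, provenance=provenance)
    const = m.constant_columns()
    if const:
        logger.info("encode_fingerprints: %d constant column(s): %s", len(const), const[:5])
    return m


def classify_polarity(
    node: ContactNodeId, records: Iterable[ContactRecord]
) -> str:
    """``polar`` or ``nonpolar`` by the node's dominant interaction type.

    The most frequent type across frames wins; ties break in the order
    salt_bridge > hydrogen_bond > cation_pi > pi_stack > vdw.  Salt bridges,
    hydrogen bonds and cation-pi contacts are polar.
    """
    counts: Counter[str] = Counter(
        r.interaction_type for r in records if r.node == node
    )
    if not counts:
        raise UsageError(f"node {node.canonical_text} has no contact records")
    best = max(counts, key=lambda t: (counts[t], -TYPE_PRIORITY.index(t)))
    return "polar" if best in POLAR_TYPES else "nonpolar"


def classify_all_polarities(
    records: Sequence[ContactRecord],
) -> dict[ContactNodeId, str]:
    by_node: dict[ContactNodeId, list[ContactRecord]] = defaultdict(list)
    for r in records:
        by_node[r.node].append(r)
    return {n: classify_polarity(n, rs) for n, rs in by_node.items()}


def write_contact_records(records: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\treceptor\tgprotein\ttype\n")
        for r in records:
            fh.write(
                f"{r.frame_index}\t{r.node.receptor_label.generic_id}"
                f"\t{r.node.gprotein_label.generic_id}\t{r.interaction_type}\n"
            )


def pooled_contact_nodes(
    node_sets: Iterable[Iterable[ContactNodeId]],
) -> set[str]:
    """Union of canonical node texts across complexes of one G-protein subtype."""
    out: set[str] = set()
    for nodes in node_sets:
        out |= {n.canonical_text for n in nodes}
    return out
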