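import numpy as np
import pytest

import coopnet as cn
from coopnet.contacts import (
    BONDI_RADII,
    _cation_pi,
    _hydrogen_bond,
    _pi_stack,
    _salt_bridge,
    _vdw_contact,
)
from coopnet.io import ConsistencyError, RunConfig, UsageError
from conftest import make_residue


CFG = RunConfig()


class TestGeometricCriteria:
    def test_salt_bridge_within_cutoff(self, salt_bridge_pair):
        asp, arg = salt_bridge_pair
        assert _salt_bridge(asp, arg, CFG)
        assert _salt_bridge(arg, asp, CFG)  # orientation-symmetric

    def test_salt_bridge_beyond_cutoff(self, salt_bridge_pair):
        asp, arg = salt_bridge_pair
        shifted = make_residue(arg.chain, arg.resid, arg.resname,
                               {n: p + np.array([1.0, 0, 0])
                                for n, p in arg.atoms.items()})
        assert not _salt_bridge(asp, shifted, CFG)

    @pytest.mark.parametrize("offset,expect", [(-0.1, True), (0.6, False)])
    def test_vdw_boundary_from_radius_table(self, offset, expect):
        # two Leu CD1 carbons separated by r_sum + tolerance + offset
        sep = 2 * BONDI_RADII["C"] + CFG.vdw_tolerance + offset
        a = make_residue("R", 1, "LEU", {"CD1": (0, 0, 0)})
        b = make_residue("A", 2, "LEU", {"CD1": (sep, 0, 0)})
        assert _vdw_contact(a, b, CFG) is expect

    def test_vdw_literal_gap_mode(self):
        cfg = RunConfig(vdw_mode="gap")
        sep = 2 * BONDI_RADII["C"] + 1.9
        a = make_residue("R", 1, "LEU", {"CD1": (0, 0, 0)})
        b = make_residue("A", 2, "LEU", {"CD1": (sep, 0, 0)})
        assert _vdw_contact(a, b, cfg)
        assert not _vdw_contact(a, b, CFG)

    def test_hydrogen_bond_idealized_direction(self):
        # Ser OG donor pointing (away from CB) straight at a backbone O
        ser = make_residue("R", 1, "SER", {"CB": (-1.4, 0, 0), "OG": (0, 0, 0)})
        acc = make_residue("A", 2, "GLY", {"O": (3.0, 0, 0), "C": (3.8, 1.0, 0)})
        assert _hydrogen_bond(ser, acc, CFG)
        # same distance but the acceptor 90 deg off the idealized H direction
        acc_side = make_residue("A", 2, "GLY", {"O": (0, 3.0, 0), "C": (1.0, 3.8, 0)})
        assert not _hydrogen_bond(ser, acc_side, CFG)

    def test_hydrogen_bond_distance_cutoff(self):
        ser = make_residue("R", 1, "SER", {"CB": (-1.4, 0, 0), "OG": (0, 0, 0)})
        acc = make_residue("A", 2, "GLY", {"O": (3.6, 0, 0), "C": (4.4, 1.0, 0)})
        assert not _hydrogen_bond(ser, acc, CFG)

    def test_pi_stack_parallel_rings(self):
        ring = {"CG": (1.4, 0, 0), "CD1": (0.7, 1.21, 0), "CE1": (-0.7, 1.21, 0),
                "CZ": (-1.4, 0, 0), "CE2": (-0.7, -1.21, 0), "CD2": (0.7, -1.21, 0)}
        a = make_residue("R", 1, "PHE", ring)
        b = make_residue("A", 2, "PHE",
                         {n: np.asarray(p) + np.array([0, 0, 4.0])
                          for n, p in ring.items()})
        assert _pi_stack(a, b, CFG)
        far = make_residue("A", 2, "PHE",
                           {n: np.asarray(p) + np.array([0, 0, 8.0])
                            for n, p in ring.items()})
        assert not _pi_stack(a, far, CFG)

    def test_cation_pi_above_ring(self):
        ring = {"CG": (1.4, 0, 0), "CD1": (0.7, 1.21, 0), "CE1": (-0.7, 1.21, 0),
                "CZ": (-1.4, 0, 0), "CE2": (-0.7, -1.21, 0), "CD2": (0.7, -1.21, 0)}
        phe = make_residue("R", 1, "PHE", ring)
        lys = make_residue("A", 2, "LYS", {"NZ": (0, 0, 4.0)})
        assert _cation_pi(phe, lys, CFG)
        # in-plane cation: angle to the normal ~90 deg
        lys_side = make_residue("A", 2, "LYS", {"NZ": (4.0, 0, 0)})
        assert not _cation_pi(phe, lys_side, CFG)


class TestDetectContacts:
    def _frame(self, salt_bridge_pair):
        asp, arg = salt_bridge_pair
        return {("R", asp.resid): asp, ("A", arg.resid): arg}

    def test_detects_salt_bridge_record(self, salt_bridge_pair):
        frame = self._frame(salt_bridge_pair)
        records = cn.detect_contacts(frame, ["R"], ["A"])
        types = {r.interaction_type for r in records}
        assert "salt_bridge" in types
        assert all(r.node.canonical_text == "R:10_A:50" for r in records)

    def test_empty_selection_rejected(self, salt_bridge_pair):
        frame = self._frame(salt_bridge_pair)
        with pytest.raises(UsageError):
            cn.detect_contacts(frame, ["Z"], ["A"])

    def test_rigid_motion_invariance(self, salt_bridge_pair):
        """Distances and angles are preserved under rotation + translation."""
        asp, arg = salt_bridge_pair
        # pull the pair 0.2 A closer so no distance sits on a cutoff
        arg = make_residue(arg.chain, arg.resid, arg.resname,
                           {n: p - np.array([0.2, 0, 0])
                            for n, p in arg.atoms.items()})
        frame = {("R", asp.resid): asp, ("A", arg.resid): arg}
        base = {(r.node.canonical_text, r.interaction_type)
                for r in cn.detect_contacts(frame, ["R"], ["A"])}
        rng = np.random.default_rng(11)
        for _ in range(3):
            q = rng.normal(size=(3, 3))
            rot, _ = np.linalg.qr(q)
            shift = rng.normal(scale=20.0, size=3)
            moved = {
                key: make_residue(res.chain, res.resid, res.resname,
                                  {n: rot @ p + shift for n, p in res.atoms.items()})
                for key, res in frame.items()
            }
            got = {(r.node.canonical_text, r.interaction_type)
                   for r in cn.detect_contacts(moved, ["R"], ["A"])}
            assert got == base

    def test_mapping_converts_to_generic_numbers(self, salt_bridge_pair, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text(
            "chain\tresid\trole\tgeneric_id\n"
            "R\t10\treceptor\t3×50\nA\t50\tgprotein\tG.H5.23\n"
        )
        mapping = cn.read_mapping_table(p)
        frame = self._frame(salt_bridge_pair)
        records = cn.detect_contacts(frame, ["R"], ["A"], mapping=mapping)
        assert {r.node.canonical_text for r in records} == {"3×50_G.H5.23"}


class TestFrequenciesAndEncoding:
    def _records(self):
        node_a = cn.ContactNodeId.parse("3×50_G.H5.23")
        node_b = cn.ContactNodeId.parse("7×55_G.H5.24")
        return node_a, node_b, [
            cn.ContactRecord(0, node_a, "vdw"),
            cn.ContactRecord(0, node_a, "hydrogen_bond"),  # same frame, 2nd type
            cn.ContactRecord(2, node_b, "vdw"),
        ]

    def test_frequency_deduplicates_types(self):
        node_a, node_b, recs = self._records()
        freqs = cn.contact_frequencies(recs, n_frames=5)
        assert freqs[node_a] == pytest.approx(0.2)
        assert freqs[node_b] == pytest.approx(0.2)

    def test_no_records_empty_table(self):
        assert cn.contact_frequencies([], 5) == {}

    def test_frame_index_out_of_range(self):
        node_a, _, _ = self._records()
        with pytest.raises(ConsistencyError):
            cn.contact_frequencies([cn.ContactRecord(9, node_a, "vdw")], 5)

    def test_persistence_threshold_is_strict(self):
        a, b, c = (cn.ContactNodeId.parse(t) for t in
                   ("1×50_G.H5.01", "2×50_G.H5.02", "3×50_G.H5.03"))
        freqs = {a: 0.21, b: 0.20, c: 0.19}
        assert cn.filter_persistent(freqs, 0.20) == {a}
        assert cn.filter_persistent(freqs, 0.0) == {a, b, c}
        assert cn.filter_persistent({}, 0.2) == set()

    def test_encode_columns_and_zero_rows(self):
        node_a, node_b, recs = self._records()
        m = cn.encode_fingerprints(recs, [node_a, node_b], n_frames=3)
        assert np.array_equal(m.values, [[1, 0], [0, 0], [0, 1]])

    def test_encode_ignores_outside_universe_and_flags_constant(self):
        node_a, node_b, recs = self._records()
        m = cn.encode_fingerprints(recs, [node_a], n_frames=3)
        assert m.n_nodes == 1
        m2 = cn.encode_fingerprints(
            [r for r in recs if r.node == node_a], [node_a, node_b], 3)
        assert m2.constant_columns() == [node_b.canonical_text]

    def test_encode_then_frequencies_matches_direct(self, bundle):
        """Column means of the encoded matrix are the direct frequencies."""
        m = bundle.fingerprints
        recs = [
            cn.ContactRecord(f, m.node_labels[j], "vdw")
            for f in range(m.n_frames)
            for j in range(m.n_nodes)
            if m.values[f, j]
        ]
        direct = cn.contact_frequencies(recs, m.n_frames)
        for j, node in enumerate(m.node_labels):
            assert direct.get(node, 0.0) == pytest.approx(m.values[:, j].mean())


class TestPolarity:
    def _node(self):
        return cn.ContactNodeId.parse("3×50_G.H5.23")

    def test_dominant_type_wins(self):
        n = self._node()
        recs = [cn.ContactRecord(i, n, "hydrogen_bond") for i in range(4)]
        recs.append(cn.ContactRecord(4, n, "vdw"))
        assert cn.classify_polarity(n, recs) == "polar"

    def test_only_vdw_is_nonpolar(self):
        n = self._node()
        assert cn.classify_polarity(n, [cn.ContactRecord(0, n, "vdw")]) == "nonpolar"

    def test_tie_breaks_toward_salt_bridge(self):
        n = self._node()
        recs = [cn.ContactRecord(0, n, "salt_bridge"), cn.ContactRecord(1, n, "vdw")]
        assert cn.classify_polarity(n, recs) == "polar"

    def test_no_records_rejected(self):
        with pytest.raises(UsageError):
            cn.classify_polarity(self._node(), [])


class TestStructureReading:
    PDB = (
        "MODEL        1\n"
        "ATOM      1  CB  SER R   1      -1.400   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  OG  SER R   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "ATOM      3  C   GLY A   2       3.800   1.000   0.000  1.00  0.00           C\n"
        "ATOM      4  O   GLY A   2       3.000   0.000   0.000  1.00  0.00           O\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  CB  SER R   1      -1.400   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  OG  SER R   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "ATOM      3  C   GLY A   2      23.800   1.000   0.000  1.00  0.00           C\n"
        "ATOM      4  O   GLY A   2      23.000   0.000   0.000  1.00  0.00           O\n"
        "ENDMDL\nEND\n"
    )

    def test_multimodel_frames_in_order(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(self.PDB)
        frames = cn.read_structure_frames(p)
        assert len(frames) == 2
        records = cn.detect_contacts_trajectory(frames, ["R"], ["A"])
        # contact exists in frame 0 only (frame 1 is 20 A away)
        assert {r.frame_index for r in records} == {0}
        freqs = cn.contact_frequencies(records, len(frames))
        assert set(freqs.values()) == {0.5}
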