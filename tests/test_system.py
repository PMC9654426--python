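"""Unit schemes: segments, CO/PO3-shifted fragments, subunit labels, groups."""

import numpy as np
import pytest

from pienet.system import (
    AtomRecord,
    MolecularSystem,
    assign_segments,
    default_group_scheme,
    fragments_to_segments,
    label_subunits,
    normalize_atom_name,
    read_json_topology,
    shift_to_fragments,
    write_json_topology,
)


def _mini_chain(residues):
    """Build a MolecularSystem from [(chain, resname, resseq, [atom names])]."""
    atoms = []
    for chain, resname, resseq, names in residues:
        for name in names:
            atoms.append(
                AtomRecord(
                    atom_id=len(atoms),
                    name=name,
                    element="H" if name.startswith("H") else name[0],
                    residue_key=(chain, resname, resseq),
                )
            )
    return MolecularSystem(atoms=atoms)


AA_NAMES = ["N", "H", "CA", "HA", "C", "O", "CB"]
GLY_NAMES = ["N", "H", "CA", "HA2", "HA3", "C", "O"]
NUC_NAMES = ["P", "OP1", "OP2", "O5'", "C1'", "N1", "C2", "N6", "H61"]


class TestAssignSegments:
    def test_one_unit_per_residue_with_categories_and_charges(self, toy):
        scheme = toy.segments
        assert scheme.n_units == toy.config.n_nuc_pairs * 2 + toy.config.n_aa
        nuc_units = [u for u, c in scheme.unit_category.items() if c == "nuc"]
        assert len(nuc_units) == toy.config.n_nuc_pairs * 2
        # every nucleotide is a -1 anion
        assert all(scheme.formal_charge[u] == -1 for u in nuc_units)

    def test_totality(self, toy):
        counted = sum(len(toy.segments.atoms_of(u)) for u in toy.segments.unit_ids)
        assert counted == toy.system.n_atoms

    def test_single_residue_has_no_covalent_pairs(self):
        system = _mini_chain([("A", "ALA", 1, AA_NAMES)])
        scheme = assign_segments(system)
        assert scheme.n_units == 1
        assert scheme.covalent_pairs == set()

    def test_four_unit_chain_has_three_covalent_pairs(self):
        system = _mini_chain(
            [("A", "ALA", i, AA_NAMES) for i in range(1, 5)]
        )
        scheme = assign_segments(system)
        assert len(scheme.covalent_pairs) == 3

    def test_unrecognized_residue_named_in_error(self):
        system = _mini_chain([("A", "XXX", 1, ["C1"])])
        with pytest.raises(KeyError, match="XXX"):
            assign_segments(system)

    def test_duplicate_atom_in_residue_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _mini_chain([("A", "ALA", 1, ["CA", "CA"])])


class TestShiftToFragments:
    def _protein(self):
        return _mini_chain([("A", "GLY", 78, GLY_NAMES), ("A", "TYR", 79, AA_NAMES)])

    def test_carbonyl_moves_to_next_residue(self):
        system = self._protein()
        seg = assign_segments(system)
        frag = shift_to_fragments(seg, system)
        gly = [u for u, l in seg.unit_labels.items() if l == "Gly78"][0]
        nxt = [u for u, l in seg.unit_labels.items() if l == "Tyr79"][0]
        for a in system.atoms:
            if a.residue_key[2] == 78 and a.name in ("C", "O"):
                assert frag.unit_of[a.atom_id] == nxt
            elif a.residue_key[2] == 78:
                assert frag.unit_of[a.atom_id] == gly

    def test_phosphate_moves_to_previous_nucleotide(self):
        system = _mini_chain(
            [("D", "DC", 9, NUC_NAMES), ("D", "DG", 10, NUC_NAMES)]
        )
        seg = assign_segments(system)
        frag = shift_to_fragments(seg, system)
        c9 = [u for u, l in seg.unit_labels.items() if l == "C9"][0]
        for a in system.atoms:
            if a.residue_key[2] == 10 and a.name in ("P", "OP1", "OP2"):
                assert frag.unit_of[a.atom_id] == c9

    def test_termini_unshifted(self):
        system = _mini_chain(
            [("D", "DC", 9, NUC_NAMES), ("D", "DG", 10, NUC_NAMES)]
        )
        seg = assign_segments(system)
        frag = shift_to_fragments(seg, system)
        # 5'-terminal nucleotide keeps its own phosphate
        for a in system.atoms:
            if a.residue_key[2] == 9:
                assert frag.unit_of[a.atom_id] == seg.unit_of[a.atom_id]

    def test_missing_backbone_atom_is_an_error(self):
        system = _mini_chain(
            [("A", "ALA", 1, ["N", "CA", "O", "CB"]), ("A", "ALA", 2, AA_NAMES)]
        )
        seg = assign_segments(system)
        with pytest.raises(ValueError, match="Ala1.*'C'"):
            shift_to_fragments(seg, system)

    def test_conservation_and_roundtrip(self, toy):
        seg = toy.segments
        frag = shift_to_fragments(seg, toy.system)
        assert frag.unit_of.shape == seg.unit_of.shape
        assert frag.total_formal_charge() == seg.total_formal_charge()
        # per-unit atom multiset is repartitioned but the union is unchanged
        assert sorted(np.concatenate([frag.atoms_of(u) for u in frag.unit_ids]).tolist()) \
            == list(range(toy.system.n_atoms))
        # charges are conserved exactly under the shift
        q = toy.system.charges
        assert q.sum() == pytest.approx(
            sum(q[frag.atoms_of(u)].sum() for u in frag.unit_ids), abs=1e-9
        )
        back = fragments_to_segments(frag, toy.system)
        assert np.array_equal(back.unit_of, seg.unit_of)
        # and the shift actually moved something
        assert not np.array_equal(frag.unit_of, seg.unit_of)


class TestLabelSubunits:
    def test_partition_per_unit(self, toy):
        lab = toy.labeling
        for u in toy.segments.unit_ids:
            atoms = toy.segments.atoms_of(u)
            b = set(lab.backbone_atoms(toy.segments, u).tolist())
            f = set(lab.functional_atoms(toy.segments, u).tolist())
            assert b | f == set(atoms.tolist())
            assert not (b & f)

    def test_glycine_has_empty_functional_set(self):
        system = _mini_chain([("A", "GLY", 78, GLY_NAMES)])
        seg = assign_segments(system)
        lab = label_subunits(seg, system)
        assert len(lab.functional_atoms(seg, 0)) == 0

    def test_nucleotide_rules(self):
        system = _mini_chain([("D", "DA", 1, NUC_NAMES)])
        seg = assign_segments(system)
        lab = label_subunits(seg, system)
        by_name = {a.name: lab.label_of[a.atom_id] for a in system.atoms}
        assert by_name["OP1"] == "b" and by_name["O5'"] == "b"
        assert by_name["N6"] == "f" and by_name["H61"] == "f"

    def test_fragment_scheme_rejected(self, toy):
        frag = shift_to_fragments(toy.segments, toy.system)
        with pytest.raises(ValueError, match="segment"):
            label_subunits(frag, toy.system)

    def test_legacy_phosphate_names_normalized(self):
        assert normalize_atom_name("O1P") == "OP1"
        assert normalize_atom_name("C1*") == "C1'"


class TestGroupScheme:
    def test_at_probe_atoms(self):
        gs = default_group_scheme(("A", "T"))
        assert gs.probe_atoms["HB1"] == ("N6", "O4")
        assert gs.probe_atoms["HB2"] == ("N1", "N3")
        assert gs.probe_atoms["CO..H"] == ("C2", "O2")

    def test_cg_has_three_hydrogen_bonds(self):
        gs = default_group_scheme(("C", "G"))
        assert {"HB1", "HB2", "HB3"} <= set(gs.named_groups)
        assert gs.probe_atoms["HB2"] == ("O6", "N4")

    def test_gt_wobble_has_co_h_contact(self):
        gs = default_group_scheme(("G", "T"))
        assert "CO..H" in gs.named_groups
        assert gs.probe_atoms["CO..H"] == ("C7", "O6")

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            default_group_scheme(("A", "C"))

    def test_overrides_replace_provisional_es_groups(self):
        gs = default_group_scheme(
            ("C", "G"),
            extra_groups={"ES1": (frozenset({"H5"}), frozenset({"N9"}))},
            extra_probes={"ES1": ("C5", "N9")},
        )
        assert gs.named_groups["ES1"] == (frozenset({"H5"}), frozenset({"N9"}))


def test_json_topology_roundtrip(tmp_path, toy):
    path = tmp_path / "topology.json"
    nb = {
        "exclusions": sorted(map(tuple, toy.rules.excluded_pairs)),
        "scaled14": sorted(map(tuple, toy.rules.scaled14_pairs)),
        "scee": toy.rules.scee,
        "scnb": toy.rules.scnb,
    }
    write_json_topology(toy.system, nb, path)
    system2, nb2 = read_json_topology(path)
    assert system2.n_atoms == toy.system.n_atoms
    assert np.allclose(system2.charges, toy.system.charges)
    assert set(map(frozenset, nb2["exclusions"])) == toy.rules.excluded_pairs
    assert np.allclose(system2.snapshots.coords, toy.system.snapshots.coords)


PDB_TWO_MODEL = """\
MODEL        1
ATOM      1  N   GLY A  78       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A  78       1.400   0.300   0.000  1.00  0.00           C
ATOM      3  C   GLY A  78       2.200  -0.500   1.000  1.00  0.00           C
ATOM      4  O   GLY A  78       2.100  -1.700   1.100  1.00  0.00           O
ATOM      5  P   DG  D  10       8.000   1.000   0.000  1.00  0.00           P
ATOM      6  O1P DG  D  10       9.000   2.000   0.500  1.00  0.00           O
ATOM      7  C1* DG  D  10       7.500   0.200  -1.200  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A  78       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A  78       1.500   0.300   0.000  1.00  0.00           C
ATOM      3  C   GLY A  78       2.300  -0.500   1.000  1.00  0.00           C
ATOM      4  O   GLY A  78       2.200  -1.700   1.100  1.00  0.00           O
ATOM      5  P   DG  D  10       8.100   1.000   0.000  1.00  0.00           P
ATOM      6  O1P DG  D  10       9.100   2.000   0.500  1.00  0.00           O
ATOM      7  C1* DG  D  10       7.600   0.200  -1.200  1.00  0.00           C
ENDMDL
END
"""


def test_read_pdb_multimodel_and_scheme_export(tmp_path):
    from pienet.system import export_scheme_tsv, read_pdb

    path = tmp_path / "mini.pdb"
    path.write_text(PDB_TWO_MODEL)
    system = read_pdb(path, frame_spacing_ps=10.0)
    assert system.n_atoms == 7
    assert system.snapshots.n_frames == 2
    assert list(system.snapshots.times) == [0.0, 10.0]
    # legacy names canonicalized on read
    assert "OP1" in system.names and "C1'" in system.names
    # models differ by the 0.1 Å x shift
    assert system.snapshots.coords[1, 0, 0] - system.snapshots.coords[0, 0, 0] \
        == pytest.approx(0.1, abs=1e-6)

    seg = assign_segments(system)
    assert seg.n_units == 2
    assert seg.unit_category[0] == "aa" and seg.unit_category[1] == "nuc"
    lab = label_subunits(seg, system)
    frame = export_scheme_tsv(system, seg, labeling=lab,
                              path=tmp_path / "scheme.tsv")
    assert (tmp_path / "scheme.tsv").exists()
    assert list(frame.columns) == ["atom_id", "atom_name", "residue",
                                   "unit_segment", "unit_fragment", "subunit"]
    by_name = frame.set_index("atom_name")
    assert by_name.loc["OP1", "subunit"] == "b"
    assert by_name.loc["CA", "subunit"] == "b"
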