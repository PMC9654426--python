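"""Force-field pair energies against a brute-force double-loop oracle."""

import math

import numpy as np
import pytest

from pienet.mm import (
    COULOMB_CONSTANT,
    NonbondedRules,
    atom_pair_matrix,
    elec_energy,
    group_decompose,
    subunit_decompose,
    unit_pair_table,
    vdw_energy,
)
from pienet.system import (
    AtomRecord,
    GroupScheme,
    MolecularSystem,
    SnapshotSet,
    SubunitLabeling,
    UnitScheme,
)


def naive_pair_energy(system, atoms_i, atoms_j, coords, rules):
    """Scalar evaluation of the Coulomb + LJ pair sums (the independent oracle)."""
    elec = vdw = 0.0
    for a in atoms_i:
        for b in atoms_j:
            pair = frozenset((int(a), int(b)))
            if pair in rules.excluded_pairs:
                continue
            w_e = w_v = 1.0
            if pair in rules.scaled14_pairs:
                w_e, w_v = 1.0 / rules.scee, 1.0 / rules.scnb
            r = math.dist(coords[a], coords[b])
            qa, qb = system.atoms[a].charge, system.atoms[b].charge
            elec += w_e * rules.coulomb_constant * qa * qb / (rules.dielectric * r)
            rstar = system.atoms[a].lj_rmin_half + system.atoms[b].lj_rmin_half
            eps = math.sqrt(system.atoms[a].lj_epsilon * system.atoms[b].lj_epsilon)
            c12, c6 = eps * rstar ** 12, 2 * eps * rstar ** 6
            vdw += w_v * (c12 / r ** 12 - c6 / r ** 6)
    return elec, vdw


def _two_atom_system(q1, q2, r, rmin=0.0, eps=0.0):
    atoms = [
        AtomRecord(0, "X1", "C", ("A", "ALA", 1), q1, rmin, eps),
        AtomRecord(1, "X2", "C", ("A", "GLY", 2), q2, rmin, eps),
    ]
    coords = np.array([[[0.0, 0.0, 0.0], [r, 0.0, 0.0]]])
    return MolecularSystem(atoms, SnapshotSet(times=[0.0], coords=coords))


class TestElec:
    def test_zero_charges_zero_energy(self):
        s = _two_atom_system(0.0, 0.0, 3.0)
        assert elec_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules()) == 0.0

    def test_unit_charges_at_k_over_r_100(self):
        # R chosen so k/R = 100 => E = -100 for +1/-1
        r = COULOMB_CONSTANT / 100.0
        s = _two_atom_system(1.0, -1.0, r)
        e = elec_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules())
        assert e == pytest.approx(-100.0, rel=1e-12)

    def test_dielectric_scaling(self):
        r = COULOMB_CONSTANT / 100.0
        s = _two_atom_system(1.0, -1.0, r)
        e2 = elec_energy(s, [0], [1], s.snapshots.coords[0],
                         NonbondedRules(dielectric=2.0))
        assert e2 == pytest.approx(-50.0, rel=1e-12)

    def test_coincident_atoms_rejected(self):
        s = _two_atom_system(1.0, -1.0, 0.0)
        with pytest.raises(ValueError, match="coincident"):
            elec_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules())


class TestVdw:
    def test_zero_parameters_zero_energy(self):
        s = _two_atom_system(0.0, 0.0, 3.0)
        assert vdw_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules()) == 0.0

    def test_zero_crossing_at_sigma(self):
        # C12/r^12 == C6/r^6 at r = (C12/C6)^(1/6) = rstar / 2^(1/6)
        rmin_half, eps = 1.7, 0.1
        rstar = 2 * rmin_half
        r = rstar / 2 ** (1 / 6)
        s = _two_atom_system(0.0, 0.0, r, rmin=rmin_half, eps=eps)
        v = vdw_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules())
        assert v == pytest.approx(0.0, abs=1e-10)

    def test_tabulated_pair_matches_formula(self):
        rmin_half, eps, r = 1.5, 0.2, 3.3
        s = _two_atom_system(0.0, 0.0, r, rmin=rmin_half, eps=eps)
        rstar = 2 * rmin_half
        expected = eps * rstar ** 12 / r ** 12 - 2 * eps * rstar ** 6 / r ** 6
        v = vdw_energy(s, [0], [1], s.snapshots.coords[0], NonbondedRules())
        assert v == pytest.approx(expected, rel=1e-12)

    def test_per_pair_coefficient_override(self):
        r = 3.0
        s = _two_atom_system(0.0, 0.0, r, rmin=1.7, eps=0.1)
        rules = NonbondedRules(lj_pair_coeffs={frozenset((0, 1)): (5e4, 2e2)})
        v = vdw_energy(s, [0], [1], s.snapshots.coords[0], rules)
        assert v == pytest.approx(5e4 / r ** 12 - 2e2 / r ** 6, rel=1e-12)


def _random_toy(rng, n_atoms):
    """Random two-unit blob with random exclusions and 1-4 pairs."""
    atoms = []
    half = n_atoms // 2
    for i in range(n_atoms):
        resseq = 1 if i < half else 2
        atoms.append(
            AtomRecord(
                i, f"X{i}", "C", ("A", "ALA", resseq),
                charge=float(rng.normal(0, 0.5)),
                lj_rmin_half=float(rng.uniform(0.5, 2.0)),
                lj_epsilon=float(rng.uniform(0.01, 0.3)),
            )
        )
    coords = rng.uniform(0, 20, size=(1, n_atoms, 3))
    # keep atoms apart
    coords += np.arange(n_atoms)[None, :, None] * 0.01
    system = MolecularSystem(atoms, SnapshotSet(times=[0.0], coords=coords))
    cross = [(a, b) for a in range(half) for b in range(half, n_atoms)]
    rng.shuffle(cross)
    n_excl = rng.integers(0, 6)
    n_14 = rng.integers(0, 6)
    rules = NonbondedRules(
        excluded_pairs=set(map(frozenset, cross[:n_excl])),
        scaled14_pairs=set(map(frozenset, cross[n_excl:n_excl + n_14])),
        dielectric=float(rng.uniform(0.5, 4.0)),
    )
    scheme = UnitScheme(
        scheme_name="segment",
        unit_of=np.array([0] * half + [1] * (n_atoms - half)),
        unit_labels={0: "u0", 1: "u1"},
        unit_category={0: "aa", 1: "aa"},
        formal_charge={0: 0, 1: 0},
    )
    return system, scheme, rules


@pytest.mark.parametrize("case", range(100))
def test_oracle_equivalence_randomized(case):
    """unit_pair_table matches the naive double loop to 1e-10 relative."""
    rng = np.random.default_rng(10_000 + case)
    n_atoms = int(rng.integers(6, 40))
    system, scheme, rules = _random_toy(rng, n_atoms)
    table = unit_pair_table(system, scheme, rules)
    row = table.iloc[0]
    elec_o, vdw_o = naive_pair_energy(
        system, scheme.atoms_of(0), scheme.atoms_of(1),
        system.snapshots.coords[0], rules,
    )
    assert row["elec"] == pytest.approx(elec_o, rel=1e-10, abs=1e-12)
    assert row["vdw"] == pytest.approx(vdw_o, rel=1e-10, abs=1e-12)


def test_oracle_equivalence_full_toy(toy):
    """Spot-check the generated complex against the oracle on 3 unit pairs."""
    rng = np.random.default_rng(7)
    units = toy.segments.unit_ids
    coords = toy.system.snapshots.coords[0]
    for _ in range(3):
        ui, uj = rng.choice(units, size=2, replace=False)
        e = elec_energy(toy.system, toy.segments.atoms_of(ui),
                        toy.segments.atoms_of(uj), coords, toy.rules)
        v = vdw_energy(toy.system, toy.segments.atoms_of(ui),
                       toy.segments.atoms_of(uj), coords, toy.rules)
        e_o, v_o = naive_pair_energy(toy.system, toy.segments.atoms_of(ui),
                                     toy.segments.atoms_of(uj), coords, toy.rules)
        assert e == pytest.approx(e_o, rel=1e-10, abs=1e-12)
        assert v == pytest.approx(v_o, rel=1e-10, abs=1e-12)


class TestUnitPairTable:
    def test_covalent_pairs_flagged(self, toy_mm_table, toy):
        cov = toy_mm_table[toy_mm_table.is_covalent]
        assert len(cov) > 0
        for _, row in cov.drop_duplicates(["unit_i", "unit_j"]).iterrows():
            assert toy.segments.is_covalent_pair(int(row.unit_i), int(row.unit_j))

    def test_symmetry_under_pair_swap(self, toy):
        t_fwd = unit_pair_table(toy.system, toy.segments, toy.rules,
                                snapshots=[0], pairs=[(0, 1)])
        t_rev = unit_pair_table(toy.system, toy.segments, toy.rules,
                                snapshots=[0], pairs=[(1, 0)])
        assert t_fwd["total"].iloc[0] == pytest.approx(t_rev["total"].iloc[0], rel=1e-12)

    def test_disabling_exclusions_changes_linked_pair(self, toy):
        # diagnostic mode: computing the Coulomb sum over *all* atom pairs of a
        # covalently linked pair shifts its electrostatics
        pair = sorted(next(iter(toy.segments.covalent_pairs)))
        with_excl = unit_pair_table(toy.system, toy.segments, toy.rules,
                                    snapshots=[0], pairs=[tuple(pair)])
        no_excl = unit_pair_table(toy.system, toy.segments,
                                  toy.rules.without_exclusions(),
                                  snapshots=[0], pairs=[tuple(pair)])
        assert with_excl["elec"].iloc[0] != pytest.approx(
            no_excl["elec"].iloc[0], abs=1e-6
        )


class TestDecompositions:
    def test_all_backbone_labeling_puts_total_in_bb(self, toy):
        m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0, 0, 1)
        lab = SubunitLabeling(label_of=np.full(toy.system.n_atoms, "b"))
        dec = subunit_decompose(m, lab)
        assert dec["bb"] == pytest.approx(m.total, rel=1e-12)
        assert dec["bf"] is None and dec["fb"] is None and dec["ff"] is None

    @pytest.mark.parametrize("seed", range(10))
    def test_random_labeling_partition_closure(self, toy, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["b", "f"], size=toy.system.n_atoms)
        lab = SubunitLabeling(label_of=labels)
        m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0, 2, 5)
        dec = subunit_decompose(m, lab)
        total = sum(v for v in dec.values() if v is not None)
        assert total == pytest.approx(m.total, rel=1e-10, abs=1e-10)
        # oracle: re-sum atom contributions by label
        grand = m.elec + m.vdw
        for key in ("bb", "bf", "fb", "ff"):
            sel_i = labels[m.atoms_i] == key[0]
            sel_j = labels[m.atoms_j] == key[1]
            if sel_i.any() and sel_j.any():
                assert dec[key] == pytest.approx(
                    float(grand[np.ix_(sel_i, sel_j)].sum()), rel=1e-10, abs=1e-10
                )

    def test_glycine_partner_reports_absent_cells(self, toy):
        # synthetic glycine-like labeling: unit 9 (an aa) gets all-backbone
        labels = toy.labeling.label_of.copy()
        aa_units = [u for u, c in toy.segments.unit_category.items() if c == "aa"]
        gly = aa_units[0]
        labels[toy.segments.atoms_of(gly)] = "b"
        lab = SubunitLabeling(label_of=labels)
        m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0,
                             aa_units[0], aa_units[1])
        dec = subunit_decompose(m, lab)
        assert dec["fb"] is None and dec["ff"] is None
        assert dec["bb"] is not None and dec["bf"] is not None

    def test_empty_group_scheme_puts_everything_in_rest(self, toy):
        (ui, uj) = next(iter(toy.base_pair_types))
        gs = GroupScheme(pair_key=("A", "T"), named_groups={}, probe_atoms={})
        m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0, ui, uj)
        gd = group_decompose(m, gs, toy.labeling)
        dec = subunit_decompose(m, toy.labeling)
        assert gd == {"rest": pytest.approx(dec["ff"], rel=1e-12)}

    def test_named_groups_plus_rest_close_to_ff(self, toy):
        from pienet.system import default_group_scheme

        for (ui, uj), pt in toy.base_pair_types.items():
            gs = default_group_scheme(pt)
            m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0, ui, uj)
            gd = group_decompose(m, gs, toy.labeling)
            dec = subunit_decompose(m, toy.labeling)
            assert sum(gd.values()) == pytest.approx(dec["ff"], rel=1e-10, abs=1e-10)

    def test_unknown_group_atom_is_an_error(self, toy):
        (ui, uj) = next(iter(toy.base_pair_types))
        gs = GroupScheme(
            pair_key=("A", "T"),
            named_groups={"HBX": (frozenset({"ZZ9"}), frozenset({"O4"}))},
            probe_atoms={},
        )
        m = atom_pair_matrix(toy.system, toy.segments, toy.rules, 0, ui, uj)
        with pytest.raises(KeyError, match="HBX"):
            group_decompose(m, gs, toy.labeling)


def test_additivity_of_pair_sums():
    """Sum over unit pairs + intra-unit terms = total nonbonded energy."""
    rng = np.random.default_rng(5)
    atoms = []
    for i in range(12):
        atoms.append(
            AtomRecord(i, f"X{i}", "C", ("A", "ALA", 1 + i // 4),
                       charge=float(rng.normal(0, 0.3)),
                       lj_rmin_half=1.0, lj_epsilon=0.05)
        )
    coords = rng.uniform(0, 15, size=(1, 12, 3))
    system = MolecularSystem(atoms, SnapshotSet(times=[0.0], coords=coords))
    rules = NonbondedRules()
    unit_of = np.array([0] * 4 + [1] * 4 + [2] * 4)
    scheme = UnitScheme(
        "segment", unit_of, {0: "a", 1: "b", 2: "c"},
        {0: "aa", 1: "aa", 2: "aa"}, {0: 0, 1: 0, 2: 0},
    )
    table = unit_pair_table(system, scheme, rules)
    inter = table["total"].sum()
    intra = 0.0
    for u in (0, 1, 2):
        ids = scheme.atoms_of(u)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                e, v = naive_pair_energy(system, [ids[ai]], [ids[bi]],
                                         coords[0], rules)
                intra += e + v
    total = 0.0
    for a in range(12):
        for b in range(a + 1, 12):
            e, v = naive_pair_energy(system, [a], [b], coords[0], rules)
            total += e + v
    assert inter + intra == pytest.approx(total, rel=1e-10)


PARM7_MINI = """%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/01  00:00:00
%FLAG POINTERS
%FORMAT(10I8)
       3       2       2       1       0       0       1       0       0       0
       4       1       0       0       0       1       1       0       2       0
       0       0       0       0       0       0       0       1       0       0
       0
%FLAG ATOM_NAME
%FORMAT(20a4)
N   CA  C
%FLAG CHARGE
%FORMAT(5E16.8)
 -7.57556024E+00  6.14105510E-01  1.08836298E+01
%FLAG ATOM_TYPE_INDEX
%FORMAT(10I8)
       1       2       2
%FLAG NONBONDED_PARM_INDEX
%FORMAT(10I8)
       1       2       2       3
%FLAG RESIDUE_LABEL
%FORMAT(20a4)
ALA
%FLAG RESIDUE_POINTER
%FORMAT(10I8)
       1
%FLAG NUMBER_EXCLUDED_ATOMS
%FORMAT(10I8)
       2       1       1
%FLAG EXCLUDED_ATOMS_LIST
%FORMAT(10I8)
       2       3       3       0
%FLAG LENNARD_JONES_ACOEF
%FORMAT(5E16.8)
  9.44293233E+05  8.00000000E+05  6.00000000E+05
%FLAG LENNARD_JONES_BCOEF
%FORMAT(5E16.8)
  8.01323529E+02  7.00000000E+02  6.00000000E+02
"""


class TestParm7Reader:
    def test_reads_charges_names_and_exclusions(self, tmp_path):
        from pienet.mm import read_parm7

        path = tmp_path / "mini.parm7"
        path.write_text(PARM7_MINI)
        system, rules = read_parm7(path)
        assert [a.name for a in system.atoms] == ["N", "CA", "C"]
        # AMBER internal charges are scaled by 18.2223
        assert system.atoms[0].charge == pytest.approx(-0.4157, abs=1e-4)
        assert rules.excluded_pairs == {
            frozenset((0, 1)), frozenset((0, 2)), frozenset((1, 2))
        }
        assert system.atoms[0].residue_key == ("A", "ALA", 1)

    def test_per_pair_lj_coefficients_from_acoef_bcoef(self, tmp_path):
        from pienet.mm import read_parm7

        path = tmp_path / "mini.parm7"
        path.write_text(PARM7_MINI)
        _, rules = read_parm7(path)
        # type pair (1,2) maps through NONBONDED_PARM_INDEX to entry 2
        assert rules.lj_pair_coeffs.get(frozenset((0, 1))) == (8.0e5, 7.0e2)
        # type pair (2,2) maps to entry 3
        assert rules.lj_pair_coeffs.get(frozenset((1, 2))) == (6.0e5, 6.0e2)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(eps=st.floats(0.2, 10.0), q=st.floats(-2.0, 2.0), r=st.floats(1.0, 20.0))
    def test_elec_scales_exactly_as_inverse_dielectric(eps, q, r):
        s = _two_atom_system(q, -q, r, rmin=1.5, eps=0.1)
        coords = s.snapshots.coords[0]
        e1 = elec_energy(s, [0], [1], coords, NonbondedRules(dielectric=1.0))
        ee = elec_energy(s, [0], [1], coords, NonbondedRules(dielectric=eps))
        assert ee == pytest.approx(e1 / eps, rel=1e-12, abs=1e-12)
        # vdW is invariant under the dielectric
        v1 = vdw_energy(s, [0], [1], coords, NonbondedRules(dielectric=1.0))
        ve = vdw_energy(s, [0], [1], coords, NonbondedRules(dielectric=eps))
        assert ve == pytest.approx(v1, rel=1e-12)
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass
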