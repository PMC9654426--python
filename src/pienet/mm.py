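"""Force-field pairwise interaction energies between units.

The pair interaction energy between two units i and j is the sum over their
atom pairs of a Coulomb term

    E_elec = sum_{A in i, B in j} k * Q_A * Q_B / (eps * R_AB)

and a Lennard-Jones term

    E_vdw = sum_{A in i, B in j} C12_AB / R_AB^12 - C6_AB / R_AB^6

subject to the AMBER bookkeeping conventions: 1-2 and 1-3 bonded atom pairs
are excluded, 1-4 (dihedral-terminal) pairs are down-weighted by 1/SCEE and
1/SCNB, and the Coulomb constant k = 332.0522173 kcal Å mol^-1 e^-2.
C12/C6 come from Lorentz-Berthelot combination of per-atom (Rmin/2, eps)
unless a per-pair override table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .system import MolecularSystem, SubunitLabeling, UnitScheme, GroupScheme

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedRules",
    "AtomPairEnergyMatrix",
    "elec_energy",
    "vdw_energy",
    "atom_pair_matrix",
    "unit_pair_table",
    "subunit_decompose",
    "group_decompose",
    "read_parm7",
]

#: AMBER electrostatic conversion constant, kcal Å mol^-1 e^-2.
COULOMB_CONSTANT = 332.0522173

AtomPair = FrozenSet[int]


def _pairset(pairs: Iterable[Sequence[int]]) -> Set[AtomPair]:
    return {frozenset((int(a), int(b))) for a, b in pairs}


@dataclass
class NonbondedRules:
    """Exclusions, 1-4 scaling, dielectric, and optional per-pair LJ tables."""

    excluded_pairs: Set[AtomPair] = field(default_factory=set)
    scaled14_pairs: Set[AtomPair] = field(default_factory=set)
    scee: float = 1.2   # elec 1-4 divisor -> weight 1/1.2
    scnb: float = 2.0   # vdW 1-4 divisor -> weight 1/2.0
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    #: optional per-pair LJ coefficients {frozenset(a,b): (C12, C6)}
    lj_pair_coeffs: Optional[Dict[AtomPair, Tuple[float, float]]] = None

    def __post_init__(self):
        self.excluded_pairs = _pairset(self.excluded_pairs)
        self.scaled14_pairs = _pairset(self.scaled14_pairs)
        if self.excluded_pairs & self.scaled14_pairs:
            raise ValueError("excluded and 1-4 scaled pair sets must be disjoint")
        if self.dielectric <= 0:
            raise ValueError("dielectric constant must be positive")

    @classmethod
    def from_topology_dict(cls, nb: Dict, **kwargs) -> "NonbondedRules":
        return cls(
            excluded_pairs=_pairset(nb.get("exclusions", [])),
            scaled14_pairs=_pairset(nb.get("scaled14", [])),
            scee=float(nb.get("scee", 1.2)),
            scnb=float(nb.get("scnb", 2.0)),
            **kwargs,
        )

    def without_exclusions(self) -> "NonbondedRules":
        """Diagnostic copy with every atom pair at full weight."""
        return NonbondedRules(
            excluded_pairs=set(),
            scaled14_pairs=set(),
            scee=self.scee,
            scnb=self.scnb,
            dielectric=self.dielectric,
            coulomb_constant=self.coulomb_constant,
            lj_pair_coeffs=self.lj_pair_coeffs,
        )


def _weights(atoms_i: np.ndarray, atoms_j: np.ndarray, rules: NonbondedRules
             ) -> Tuple[np.ndarray, np.ndarray]:
    """(w_elec, w_vdw) matrices over atoms_i x atoms_j."""
    w_elec = np.ones((len(atoms_i), len(atoms_j)))
    w_vdw = np.ones_like(w_elec)
    if rules.excluded_pairs or rules.scaled14_pairs:
        for a_idx, a in enumerate(atoms_i):
            for b_idx, b in enumerate(atoms_j):
                pair = frozenset((int(a), int(b)))
                if pair in rules.excluded_pairs:
                    w_elec[a_idx, b_idx] = w_vdw[a_idx, b_idx] = 0.0
                elif pair in rules.scaled14_pairs:
                    w_elec[a_idx, b_idx] = 1.0 / rules.scee
                    w_vdw[a_idx, b_idx] = 1.0 / rules.scnb
    return w_elec, w_vdw


def _distances(coords: np.ndarray, atoms_i: np.ndarray, atoms_j: np.ndarray) -> np.ndarray:
    diff = coords[atoms_i][:, None, :] - coords[atoms_j][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    overlap = (r == 0.0)
    if np.any(overlap):
        a_idx, b_idx = np.nonzero(overlap)
        raise ValueError(
            f"coincident atoms: ids {int(atoms_i[a_idx[0]])} and "
            f"{int(atoms_j[b_idx[0]])} at zero distance"
        )
    return r


def _lj_coeffs(system: MolecularSystem, atoms_i: np.ndarray, atoms_j: np.ndarray,
               rules: NonbondedRules) -> Tuple[np.ndarray, np.ndarray]:
    rmin = np.array([a.lj_rmin_half for a in system.atoms])
    eps = np.array([a.lj_epsilon for a in system.atoms])
    rstar = rmin[atoms_i][:, None] + rmin[atoms_j][None, :]
    epsab = np.sqrt(eps[atoms_i][:, None] * eps[atoms_j][None, :])
    c12 = epsab * rstar ** 12
    c6 = 2.0 * epsab * rstar ** 6
    if rules.lj_pair_coeffs:
        for a_idx, a in enumerate(atoms_i):
            for b_idx, b in enumerate(atoms_j):
                over = rules.lj_pair_coeffs.get(frozenset((int(a), int(b))))
                if over is not None:
                    c12[a_idx, b_idx], c6[a_idx, b_idx] = over
    return c12, c6


@dataclass
class AtomPairEnergyMatrix:
    """Atom-resolved elec/vdW energies for one unit pair at one snapshot."""

    unit_i: int
    unit_j: int
    atoms_i: np.ndarray   # atom ids of unit i
    atoms_j: np.ndarray
    names_i: List[str]
    names_j: List[str]
    elec: np.ndarray      # (len(atoms_i), len(atoms_j)) kcal/mol
    vdw: np.ndarray

    @property
    def elec_total(self) -> float:
        return float(self.elec.sum())

    @property
    def vdw_total(self) -> float:
        return float(self.vdw.sum())

    @property
    def total(self) -> float:
        return self.elec_total + self.vdw_total

    def transpose(self) -> "AtomPairEnergyMatrix":
        return AtomPairEnergyMatrix(
            unit_i=self.unit_j, unit_j=self.unit_i,
            atoms_i=self.atoms_j, atoms_j=self.atoms_i,
            names_i=self.names_j, names_j=self.names_i,
            elec=self.elec.T, vdw=self.vdw.T,
        )


def elec_energy(system: MolecularSystem, atoms_i: Sequence[int], atoms_j: Sequence[int],
                coords: np.ndarray, rules: NonbondedRules) -> float:
    """Coulomb energy (kcal/mol) between two atom sets at one snapshot."""
    atoms_i = np.asarray(atoms_i, dtype=int)
    atoms_j = np.asarray(atoms_j, dtype=int)
    q = system.charges
    if not np.all(np.isfinite(q[atoms_i])) or not np.all(np.isfinite(q[atoms_j])):
        raise ValueError("missing or non-finite charge")
    r = _distances(coords, atoms_i, atoms_j)
    w_elec, _ = _weights(atoms_i, atoms_j, rules)
    qq = q[atoms_i][:, None] * q[atoms_j][None, :]
    k = rules.coulomb_constant / rules.dielectric
    return float(np.sum(w_elec * k * qq / r))


def vdw_energy(system: MolecularSystem, atoms_i: Sequence[int], atoms_j: Sequence[int],
               coords: np.ndarray, rules: NonbondedRules) -> float:
    """Lennard-Jones energy (kcal/mol) between two atom sets at one snapshot."""
    atoms_i = np.asarray(atoms_i, dtype=int)
    atoms_j = np.asarray(atoms_j, dtype=int)
    r = _distances(coords, atoms_i, atoms_j)
    _, w_vdw = _weights(atoms_i, atoms_j, rules)
    c12, c6 = _lj_coeffs(system, atoms_i, atoms_j, rules)
    return float(np.sum(w_vdw * (c12 / r ** 12 - c6 / r ** 6)))


def atom_pair_matrix(system: MolecularSystem, scheme: UnitScheme, rules: NonbondedRules,
                     snapshot: int, unit_i: int, unit_j: int) -> AtomPairEnergyMatrix:
    """Atom-resolved energy matrix for one unit pair (no summation)."""
    if system.snapshots is None:
        raise ValueError("system carries no snapshots")
    coords = system.snapshots.coords[snapshot]
    atoms_i = scheme.atoms_of(unit_i)
    atoms_j = scheme.atoms_of(unit_j)
    r = _distances(coords, atoms_i, atoms_j)
    w_elec, w_vdw = _weights(atoms_i, atoms_j, rules)
    q = system.charges
    k = rules.coulomb_constant / rules.dielectric
    elec = w_elec * k * (q[atoms_i][:, None] * q[atoms_j][None, :]) / r
    c12, c6 = _lj_coeffs(system, atoms_i, atoms_j, rules)
    vdw = w_vdw * (c12 / r ** 12 - c6 / r ** 6)
    names = system.names
    return AtomPairEnergyMatrix(
        unit_i=unit_i, unit_j=unit_j,
        atoms_i=atoms_i, atoms_j=atoms_j,
        names_i=[names[a] for a in atoms_i],
        names_j=[names[a] for a in atoms_j],
        elec=elec, vdw=vdw,
    )


def unit_pair_table(system: MolecularSystem, scheme: UnitScheme, rules: NonbondedRules,
                    snapshots: Optional[Sequence[int]] = None,
                    pairs: Optional[Sequence[Tuple[int, int]]] = None,
                    cutoff: Optional[float] = None) -> pd.DataFrame:
    """MM pair-energy table over unit pairs and snapshots.

    Columns: unit_i, unit_j, snapshot, level, scheme, elec, vdw, total,
    is_covalent.  By default all unit pairs (no distance cutoff) and all
    snapshots are evaluated; ``cutoff`` (Å, minimum atom-atom distance)
    restricts pairs per snapshot.
    """
    if system.snapshots is None:
        raise ValueError("system carries no snapshots")
    if snapshots is None:
        snapshots = range(system.snapshots.n_frames)
    unit_ids = scheme.unit_ids
    if pairs is None:
        pairs = [(unit_ids[a], unit_ids[b])
                 for a in range(len(unit_ids)) for b in range(a + 1, len(unit_ids))]
    rows = []
    for snap in snapshots:
        coords = system.snapshots.coords[snap]
        for ui, uj in pairs:
            atoms_i = scheme.atoms_of(ui)
            atoms_j = scheme.atoms_of(uj)
            if cutoff is not None:
                r = _distances(coords, atoms_i, atoms_j)
                if r.min() > cutoff:
                    continue
            try:
                e = elec_energy(system, atoms_i, atoms_j, coords, rules)
                v = vdw_energy(system, atoms_i, atoms_j, coords, rules)
            except ValueError as exc:
                raise ValueError(
                    f"pair {scheme.unit_labels[ui]}:{scheme.unit_labels[uj]} "
                    f"snapshot {snap}: {exc}"
                ) from exc
            rows.append(
                {
                    "unit_i": ui, "unit_j": uj, "snapshot": int(snap),
                    "level": "MM", "scheme": scheme.scheme_name,
                    "elec": e, "vdw": v, "total": e + v,
                    "is_covalent": scheme.is_covalent_pair(ui, uj),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["unit_i", "unit_j", "snapshot", "level", "scheme",
                 "elec", "vdw", "total", "is_covalent"],
    )


def subunit_decompose(matrix: AtomPairEnergyMatrix, labeling: SubunitLabeling
                      ) -> Dict[str, Optional[float]]:
    """Split a pair energy into backbone/functional blocks {bb, bf, fb, ff}.

    ``bf`` is backbone of the first unit against functional of the second.
    Blocks with an empty atom set on either side (e.g. a glycine partner)
    are reported as ``None`` (absent), not zero; the defined blocks still
    sum exactly to the pair total.
    """
    li = labeling.label_of[matrix.atoms_i]
    lj = labeling.label_of[matrix.atoms_j]
    out: Dict[str, Optional[float]] = {}
    total = matrix.elec + matrix.vdw
    for key in ("bb", "bf", "fb", "ff"):
        sel_i = li == key[0]
        sel_j = lj == key[1]
        if not sel_i.any() or not sel_j.any():
            out[key] = None
        else:
            out[key] = float(total[np.ix_(sel_i, sel_j)].sum())
    return out


def group_decompose(matrix: AtomPairEnergyMatrix, groups: GroupScheme,
                    labeling: SubunitLabeling) -> Dict[str, float]:
    """Split the functional-functional (ff) block among named bond groups.

    Each named group sums the energies between its atom-name sets (resolved
    on either side of the pair); the remainder of the ff block is reported
    under "rest", so named groups + rest equal the ff total exactly.
    """
    li = labeling.label_of[matrix.atoms_i]
    lj = labeling.label_of[matrix.atoms_j]
    f_i = li == "f"
    f_j = lj == "f"
    total = matrix.elec + matrix.vdw
    ff_total = float(total[np.ix_(f_i, f_j)].sum())

    names_i = np.array(matrix.names_i)
    names_j = np.array(matrix.names_j)
    out: Dict[str, float] = {}
    named_sum = 0.0
    for label, (set_a, set_b) in groups.named_groups.items():
        # resolve each set on whichever side contains it
        in_i_a = np.isin(names_i, list(set_a)) & f_i
        in_j_a = np.isin(names_j, list(set_a)) & f_j
        in_i_b = np.isin(names_i, list(set_b)) & f_i
        in_j_b = np.isin(names_j, list(set_b)) & f_j
        if in_i_a.any() and in_j_b.any():
            sel_i, sel_j = in_i_a, in_j_b
        elif in_i_b.any() and in_j_a.any():
            sel_i, sel_j = in_i_b, in_j_a
        else:
            missing = set_a if not (in_i_a.any() or in_j_a.any()) else set_b
            raise KeyError(
                f"group {label!r}: atoms {sorted(missing)} not found in the "
                f"functional subunits of pair ({matrix.unit_i}, {matrix.unit_j})"
            )
        value = float(total[np.ix_(sel_i, sel_j)].sum())
        out[label] = value
        named_sum += value
    out["rest"] = ff_total - named_sum
    return out


# ---------------------------------------------------------------------------
# AMBER parm7 reader (text format, %FLAG sections)
# ---------------------------------------------------------------------------

def _parse_parm7_sections(text: str) -> Dict[str, List[str]]:
    sections: Dict[str, List[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("%FLAG"):
            current = line.split()[1]
            sections[current] = []
        elif line.startswith("%"):
            continue
        elif current is not None:
            sections[current].append(line)
    return sections


def _ints(lines: List[str]) -> List[int]:
    return [int(tok) for line in lines for tok in line.split()]


def _floats(lines: List[str]) -> List[float]:
    return [float(tok) for line in lines for tok in line.split()]


def read_parm7(path, chain: str = "A") -> Tuple[MolecularSystem, NonbondedRules]:
    """Read an AMBER parm7/prmtop topology (charges, LJ, exclusions, 1-4).

    Returns a coordinate-less :class:`MolecularSystem` plus the
    :class:`NonbondedRules` derived from the exclusion list and the
    dihedral-terminal (1-4) pairs.  Charges are converted from AMBER
    internal units (multiples of 18.2223) to elementary charges; LJ
    ACOEF/BCOEF are exposed as per-pair C12/C6 overrides.
    """
    from .system import AtomRecord, normalize_atom_name, _guess_element

    with open(path) as fh:
        sections = _parse_parm7_sections(fh.read())

    pointers = _ints(sections["POINTERS"])
    natom, ntypes = pointers[0], pointers[1]
    # atom names: fixed 4-char fields across lines
    raw = "".join(line.ljust(80) for line in sections["ATOM_NAME"])
    names = [raw[i * 4:(i + 1) * 4].strip() for i in range(natom)]
    charges = [c / 18.2223 for c in _floats(sections["CHARGE"])]
    type_index = _ints(sections["ATOM_TYPE_INDEX"])
    nb_index = _ints(sections["NONBONDED_PARM_INDEX"])
    acoef = _floats(sections["LENNARD_JONES_ACOEF"])
    bcoef = _floats(sections["LENNARD_JONES_BCOEF"])
    res_labels = "".join(line.ljust(80) for line in sections["RESIDUE_LABEL"])
    res_ptr = _ints(sections["RESIDUE_POINTER"])
    nres = len(res_ptr)
    res_names = [res_labels[i * 4:(i + 1) * 4].strip() for i in range(nres)]

    res_of = np.zeros(natom, dtype=int)
    for r in range(nres):
        start = res_ptr[r] - 1
        end = res_ptr[r + 1] - 1 if r + 1 < nres else natom
        res_of[start:end] = r

    atoms = [
        AtomRecord(
            atom_id=i,
            name=normalize_atom_name(names[i]),
            element=_guess_element(names[i]),
            residue_key=(chain, res_names[res_of[i]], int(res_of[i]) + 1),
            charge=charges[i],
        )
        for i in range(natom)
    ]

    # per-pair LJ table from ACOEF/BCOEF
    def pair_coeff(a: int, b: int) -> Tuple[float, float]:
        ta, tb = type_index[a], type_index[b]
        idx = nb_index[ntypes * (ta - 1) + tb - 1]
        if idx <= 0:  # 10-12 pairs not supported; treat as zero LJ
            return 0.0, 0.0
        return acoef[idx - 1], bcoef[idx - 1]

    # 1-4 pairs from dihedral lists (k>=0 and l>=0 terms)
    scaled14: Set[AtomPair] = set()
    for key in ("DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN"):
        vals = _ints(sections.get(key, []))
        for t in range(0, len(vals), 5):
            i4, _, k4, l4, _ = vals[t:t + 5]
            if k4 >= 0 and l4 >= 0:
                a, b = abs(i4) // 3, abs(l4) // 3
                if a != b:
                    scaled14.add(frozenset((a, b)))

    # exclusion list holds 1-2/1-3/1-4 partners; drop the 1-4 ones
    n_excl = _ints(sections["NUMBER_EXCLUDED_ATOMS"])
    excl_list = _ints(sections["EXCLUDED_ATOMS_LIST"])
    excluded: Set[AtomPair] = set()
    pos = 0
    for a in range(natom):
        for b in excl_list[pos:pos + n_excl[a]]:
            if b > 0:
                excluded.add(frozenset((a, b - 1)))
        pos += n_excl[a]
    excluded -= scaled14

    scee = _floats(sections.get("SCEE_SCALE_FACTOR", ["1.2"])) or [1.2]
    scnb = _floats(sections.get("SCNB_SCALE_FACTOR", ["2.0"])) or [2.0]

    system = MolecularSystem(atoms=atoms)
    rules = NonbondedRules(
        excluded_pairs=excluded,
        scaled14_pairs=scaled14,
        scee=float(np.mean(scee)),
        scnb=float(np.mean(scnb)),
        lj_pair_coeffs=_Parm7LJTable(pair_coeff),
    )
    return system, rules


class _Parm7LJTable(dict):
    """Dict-like view over parm7 ACOEF/BCOEF, computed on demand."""

    def __init__(self, pair_coeff):
        super().__init__()
        self._pair_coeff = pair_coeff

    def get(self, key, default=None):
        a, b = tuple(key)
        return self._pair_coeff(int(a), int(b))

    def __bool__(self):
        return True
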