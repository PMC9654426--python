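"""Atoms, snapshots, and the unit schemes every downstream analysis aggregates over.

The central objects are:

* :class:`MolecularSystem` — a list of :class:`AtomRecord` (names, partial
  charges, Lennard-Jones parameters, residue assignment) together with a
  :class:`SnapshotSet` of per-frame coordinates.
* :class:`UnitScheme` — a total partition of the atoms into interaction
  units.  Two conventions are supported: *segments* (conventional amino-acid
  and nucleotide residues, as read from a PDB file) and *fragments* (the
  same atom counts, but with each peptide carbonyl CO shifted to the next
  residue and each nucleotide phosphate PO3 shifted to the previous one —
  the unit convention used by fragment-based QM codes).
* :class:`SubunitLabeling` — a backbone ("b") / functional ("f") split of
  each segment: peptide main chain vs. side chain for amino acids,
  phosphate+pentose vs. nucleobase for nucleotides.
* :class:`GroupScheme` — named functional groups inside a base pair
  (hydrogen bonds HB1..HB3, CO...H contacts, weak electrostatic contacts)
  with probe heavy atoms for bond-length statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

__all__ = [
    "AtomRecord",
    "SnapshotSet",
    "MolecularSystem",
    "UnitScheme",
    "SubunitLabeling",
    "GroupScheme",
    "ResidueDictionary",
    "DEFAULT_RESIDUE_DICTIONARY",
    "assign_segments",
    "shift_to_fragments",
    "fragments_to_segments",
    "label_subunits",
    "default_group_scheme",
    "read_pdb",
    "read_json_topology",
    "write_json_topology",
    "export_scheme_tsv",
]

ResidueKey = Tuple[str, str, int]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, and nonbonded parameters.

    ``charge`` is the fixed partial charge in elementary-charge units
    (the Q_A of the Coulomb pair sum); ``lj_rmin_half`` / ``lj_epsilon``
    are the AMBER-convention Lennard-Jones parameters (Rmin/2 in Å and the
    well depth in kcal/mol) combined with Lorentz–Berthelot rules into the
    per-pair C12/C6 coefficients.
    """

    atom_id: int
    name: str
    element: str
    residue_key: ResidueKey
    charge: float = 0.0
    lj_rmin_half: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.atom_id} ({self.name}): charge not finite")
        if self.lj_rmin_half < 0 or self.lj_epsilon < 0:
            raise ValueError(
                f"atom {self.atom_id} ({self.name}): LJ size/well parameters must be >= 0"
            )

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class SnapshotSet:
    """Per-snapshot coordinates (Å) aligned to a fixed atom ordering."""

    times: np.ndarray  # (n_frames,) ps
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times and coords disagree on the number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class MolecularSystem:
    """Atoms plus their snapshot ensemble."""

    atoms: List[AtomRecord]
    snapshots: Optional[SnapshotSet] = None

    def __post_init__(self):
        seen: Set[Tuple[ResidueKey, str]] = set()
        for a in self.atoms:
            key = (a.residue_key, a.name)
            if key in seen:
                raise ValueError(
                    f"duplicate atom name {a.name!r} in residue {a.residue_key}"
                )
            seen.add(key)
        if self.snapshots is not None and self.snapshots.n_atoms != len(self.atoms):
            raise ValueError("snapshot atom count does not match atom list")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def names(self) -> List[str]:
        return [a.name for a in self.atoms]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms])

    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class UnitScheme:
    """A total partition of atoms into interaction units.

    ``scheme_name`` is "segment" (conventional residues) or "fragment"
    (CO/PO3-shifted units).  ``unit_of`` maps every atom id to a unit id;
    ``covalent_pairs`` holds the unit-id pairs joined by a covalent bond
    (sequence-adjacent residues on the same chain).
    """

    scheme_name: str
    unit_of: np.ndarray  # (n_atoms,) int unit id per atom
    unit_labels: Dict[int, str]
    unit_category: Dict[int, str]  # "nuc" | "aa"
    formal_charge: Dict[int, int]
    covalent_pairs: Set[FrozenSet[int]] = field(default_factory=set)

    def __post_init__(self):
        self.unit_of = np.asarray(self.unit_of, dtype=int)
        units = set(self.unit_of.tolist())
        for name, mapping in (
            ("unit_labels", self.unit_labels),
            ("unit_category", self.unit_category),
            ("formal_charge", self.formal_charge),
        ):
            missing = units - set(mapping)
            if missing:
                raise ValueError(f"{name} missing entries for units {sorted(missing)}")
        bad = {c for c in self.unit_category.values()} - {"nuc", "aa"}
        if bad:
            raise ValueError(f"unit categories must be 'nuc' or 'aa', got {bad}")

    @property
    def unit_ids(self) -> List[int]:
        return sorted(set(self.unit_of.tolist()))

    @property
    def n_units(self) -> int:
        return len(set(self.unit_of.tolist()))

    def atoms_of(self, unit_id: int) -> np.ndarray:
        return np.nonzero(self.unit_of == unit_id)[0]

    def total_formal_charge(self) -> int:
        return sum(self.formal_charge[u] for u in self.unit_ids)

    def is_covalent_pair(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.covalent_pairs


@dataclass
class SubunitLabeling:
    """Backbone ("b") / functional ("f") label for every atom of a segment scheme."""

    label_of: np.ndarray  # (n_atoms,) '<U1'
    scheme_name: str = "segment"

    def __post_init__(self):
        self.label_of = np.asarray(self.label_of)
        bad = set(self.label_of.tolist()) - {"b", "f"}
        if bad:
            raise ValueError(f"subunit labels must be 'b' or 'f', got {bad}")

    def backbone_atoms(self, scheme: UnitScheme, unit_id: int) -> np.ndarray:
        atoms = scheme.atoms_of(unit_id)
        return atoms[self.label_of[atoms] == "b"]

    def functional_atoms(self, scheme: UnitScheme, unit_id: int) -> np.ndarray:
        atoms = scheme.atoms_of(unit_id)
        return atoms[self.label_of[atoms] == "f"]


@dataclass
class GroupScheme:
    """Named functional groups across one base pair.

    ``named_groups`` maps a bond label (e.g. "HB1", "CO..H", "ES1") to the
    atom-name sets participating on each side; ``probe_atoms`` names one
    heavy atom per side used for bond-length statistics.  Probe atoms are
    resolved in whichever of the two units actually contains the name, so
    the (A, B) order follows the printed convention rather than strict
    first-unit/second-unit membership.
    """

    pair_key: Tuple[str, str]
    named_groups: Dict[str, Tuple[FrozenSet[str], FrozenSet[str]]]
    probe_atoms: Dict[str, Tuple[str, str]]

    def __post_init__(self):
        for side in (0, 1):
            used: Set[str] = set()
            for label, sides in self.named_groups.items():
                overlap = used & set(sides[side])
                if overlap:
                    raise ValueError(
                        f"group {label}: atoms {sorted(overlap)} appear in more than "
                        "one named group on the same side"
                    )
                used |= set(sides[side])


# ---------------------------------------------------------------------------
# Residue dictionaries
# ---------------------------------------------------------------------------

_AA_FORMAL: Dict[str, int] = {
    "ALA": 0, "ARG": 1, "ASN": 0, "ASP": -1, "CYS": 0, "GLN": 0, "GLU": -1,
    "GLY": 0, "HIS": 0, "ILE": 0, "LEU": 0, "LYS": 1, "MET": 0, "PHE": 0,
    "PRO": 0, "SER": 0, "THR": 0, "TRP": 0, "TYR": 0, "VAL": 0,
    # common protonation / disulfide variants
    "HID": 0, "HIE": 0, "HIP": 1, "ASH": 0, "GLH": 0, "CYX": 0, "LYN": 0,
}

_NUC_FORMAL: Dict[str, int] = {}
for _base in ("A", "C", "G", "T", "U"):
    for _name in (_base, "D" + _base, "D" + _base + "5", "D" + _base + "3",
                  "R" + _base, _base + "5", _base + "3"):
        _NUC_FORMAL[_name] = -1


@dataclass
class ResidueDictionary:
    """Recognized residue names with formal charges.

    All nucleotides carry a formal charge of −1 (phosphate); Asp/Glu are −1,
    Lys/Arg +1, histidine defaults to neutral but is configurable via
    ``aa_charges``.
    """

    aa_charges: Dict[str, int] = field(default_factory=lambda: dict(_AA_FORMAL))
    nuc_charges: Dict[str, int] = field(default_factory=lambda: dict(_NUC_FORMAL))

    def category(self, resname: str) -> str:
        name = resname.upper()
        if name in self.aa_charges:
            return "aa"
        if name in self.nuc_charges:
            return "nuc"
        raise KeyError(f"unrecognized residue name {resname!r}")

    def formal_charge(self, resname: str) -> int:
        name = resname.upper()
        if name in self.aa_charges:
            return self.aa_charges[name]
        if name in self.nuc_charges:
            return self.nuc_charges[name]
        raise KeyError(f"unrecognized residue name {resname!r}")


DEFAULT_RESIDUE_DICTIONARY = ResidueDictionary()

_NUC_ONE_LETTER = {"A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}


def _default_label(resname: str, resseq: int, category: str) -> str:
    if category == "nuc":
        base = resname.upper().lstrip("DR").rstrip("35")
        letter = _NUC_ONE_LETTER.get(base, base)
        return f"{letter}{resseq}"
    return f"{resname.capitalize()}{resseq}"


# ---------------------------------------------------------------------------
# Atom-name normalization (legacy phosphate dialects)
# ---------------------------------------------------------------------------

_NAME_ALIASES = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3", "*": "'"}


def normalize_atom_name(name: str) -> str:
    """Canonicalize PDB atom names: O1P/O2P -> OP1/OP2, star primes -> '."""
    name = name.strip().replace("*", "'")
    return _NAME_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Segment / fragment schemes
# ---------------------------------------------------------------------------

def assign_segments(
    system: MolecularSystem,
    dictionary: ResidueDictionary = DEFAULT_RESIDUE_DICTIONARY,
) -> UnitScheme:
    """Partition atoms into conventional residues (one unit per PDB residue).

    Units are numbered in order of first appearance.  Covalent pairs are all
    sequence-adjacent residue pairs on the same chain (consecutive order of
    appearance).  Raises ``KeyError`` for unrecognized residue names.
    """
    unit_of = np.empty(system.n_atoms, dtype=int)
    order: List[ResidueKey] = []
    index: Dict[ResidueKey, int] = {}
    for a in system.atoms:
        if a.residue_key not in index:
            index[a.residue_key] = len(order)
            order.append(a.residue_key)
        unit_of[a.atom_id] = index[a.residue_key]

    labels, cats, formal = {}, {}, {}
    for uid, (chain, resname, resseq) in enumerate(order):
        cat = dictionary.category(resname)
        cats[uid] = cat
        labels[uid] = _default_label(resname, resseq, cat)
        formal[uid] = dictionary.formal_charge(resname)

    covalent: Set[FrozenSet[int]] = set()
    for uid in range(1, len(order)):
        if order[uid][0] == order[uid - 1][0]:  # same chain
            covalent.add(frozenset((uid - 1, uid)))

    return UnitScheme(
        scheme_name="segment",
        unit_of=unit_of,
        unit_labels=labels,
        unit_category=cats,
        formal_charge=formal,
        covalent_pairs=covalent,
    )


_AMINO_SHIFT_ATOMS = ("C", "O")
_NUC_SHIFT_ATOMS = ("P", "OP1", "OP2")


def _chains_in_order(system: MolecularSystem, scheme: UnitScheme) -> Dict[str, List[int]]:
    """Unit ids per chain, in order of appearance."""
    chains: Dict[str, List[int]] = {}
    seen: Set[int] = set()
    for a in system.atoms:
        uid = int(scheme.unit_of[a.atom_id])
        if uid not in seen:
            seen.add(uid)
            chains.setdefault(a.residue_key[0], []).append(uid)
    return chains


def shift_to_fragments(segments: UnitScheme, system: MolecularSystem) -> UnitScheme:
    """Reassign peptide CO groups forward and nucleotide PO3 groups backward.

    For every non-C-terminal amino-acid residue i the carbonyl atoms {C, O}
    move to unit i+1; for every non-5'-terminal nucleotide i the phosphate
    atoms {P, OP1, OP2} move to unit i−1.  Bridging O3'/O5' stay with their
    sugars.  Atom count, per-unit labels and the total formal charge are
    conserved; terminal residues are never shifted.
    """
    if segments.scheme_name != "segment":
        raise ValueError("shift_to_fragments expects a segment scheme")
    unit_of = segments.unit_of.copy()
    name_index: Dict[Tuple[int, str], int] = {}
    for a in system.atoms:
        name_index[(int(segments.unit_of[a.atom_id]), normalize_atom_name(a.name))] = a.atom_id

    for chain_units in _chains_in_order(system, segments).values():
        for pos, uid in enumerate(chain_units):
            cat = segments.unit_category[uid]
            if cat == "aa" and pos < len(chain_units) - 1:
                target = chain_units[pos + 1]
                for atom_name in _AMINO_SHIFT_ATOMS:
                    aid = name_index.get((uid, atom_name))
                    if aid is None:
                        raise ValueError(
                            f"residue {segments.unit_labels[uid]}: missing backbone "
                            f"atom {atom_name!r} required for the CO shift"
                        )
                    unit_of[aid] = target
            elif cat == "nuc" and pos > 0:
                target = chain_units[pos - 1]
                for atom_name in _NUC_SHIFT_ATOMS:
                    aid = name_index.get((uid, atom_name))
                    if aid is None:
                        raise ValueError(
                            f"nucleotide {segments.unit_labels[uid]}: missing backbone "
                            f"atom {atom_name!r} required for the PO3 shift"
                        )
                    unit_of[aid] = target

    return UnitScheme(
        scheme_name="fragment",
        unit_of=unit_of,
        unit_labels=dict(segments.unit_labels),
        unit_category=dict(segments.unit_category),
        formal_charge=dict(segments.formal_charge),
        covalent_pairs=set(segments.covalent_pairs),
    )


def fragments_to_segments(fragments: UnitScheme, system: MolecularSystem) -> UnitScheme:
    """Invert the CO/PO3 shift by restoring each atom to its residue of record."""
    if fragments.scheme_name != "fragment":
        raise ValueError("fragments_to_segments expects a fragment scheme")
    segments = assign_segments(system)
    # keep the fragment scheme's label/category tables (identical by construction)
    return replace(
        segments,
        unit_labels=dict(fragments.unit_labels),
        unit_category=dict(fragments.unit_category),
        formal_charge=dict(fragments.formal_charge),
    )


# ---------------------------------------------------------------------------
# Backbone / functional subunits
# ---------------------------------------------------------------------------

_AA_BACKBONE_NAMES = {
    "N", "CA", "C", "O", "OXT",
    "H", "H1", "H2", "H3", "HN",      # amide / N-terminal hydrogens
    "HA", "HA1", "HA2", "HA3",        # alpha hydrogens (two for glycine)
}
_NUC_BACKBONE_EXTRA = {"P", "OP1", "OP2", "OP3"}


def label_subunits(scheme: UnitScheme, system: MolecularSystem) -> SubunitLabeling:
    """Split every segment into backbone (b) and functional (f) atoms.

    Amino acids: backbone is the peptide main chain {N, H*, CA, HA*, C, O,
    OXT}; everything else (the side chain) is functional — empty for glycine.
    Nucleotides: backbone is the phosphate+pentose (every primed atom name
    plus P/OP1/OP2); the remaining base atoms are functional.  Only segment
    schemes are split.
    """
    if scheme.scheme_name != "segment":
        raise ValueError(
            "subunit labeling is defined for segment schemes only "
            "(fragments are not split)"
        )
    labels = np.full(system.n_atoms, "f", dtype="<U1")
    for a in system.atoms:
        uid = int(scheme.unit_of[a.atom_id])
        cat = scheme.unit_category[uid]
        name = normalize_atom_name(a.name)
        if cat == "aa":
            if name in _AA_BACKBONE_NAMES:
                labels[a.atom_id] = "b"
        else:
            if "'" in name or name in _NUC_BACKBONE_EXTRA:
                labels[a.atom_id] = "b"
    return SubunitLabeling(label_of=labels, scheme_name=scheme.scheme_name)


# ---------------------------------------------------------------------------
# Base-pair group schemes
# ---------------------------------------------------------------------------

def _fs(*names: str) -> FrozenSet[str]:
    return frozenset(names)


def default_group_scheme(
    pair_type: Tuple[str, str],
    extra_groups: Optional[Mapping[str, Tuple[FrozenSet[str], FrozenSet[str]]]] = None,
    extra_probes: Optional[Mapping[str, Tuple[str, str]]] = None,
) -> GroupScheme:
    """Default hydrogen-bond / contact groups for A:T, C:G and G:T pairs.

    Probe atoms follow the standard Watson–Crick (and G:T wobble) geometry:
    A:T — HB1 (N6|O4), HB2 (N1|N3), CO..H (C2|O2); C:G — HB1 (N1|N3),
    HB2 (O6|N4), HB3 (O2|N2); G:T — HB1 (O4|N1), HB2 (O4|N2), CO..H (C7|O6).
    The weak electrostatic contacts ES1/ES2 default to provisional
    second-sphere placeholders and should be overridden via ``extra_groups``
    when a specific convention is required.
    """
    key = tuple(b.upper() for b in pair_type)
    if key == ("A", "T"):
        groups = {
            "HB1": (_fs("N6", "H61", "H62"), _fs("O4")),
            "HB2": (_fs("N1"), _fs("N3", "H3")),
            "CO..H": (_fs("C2", "H2"), _fs("O2")),
        }
        probes = {"HB1": ("N6", "O4"), "HB2": ("N1", "N3"), "CO..H": ("C2", "O2")}
    elif key == ("C", "G"):
        groups = {
            "HB1": (_fs("N3"), _fs("N1", "H1")),
            "HB2": (_fs("N4", "H41", "H42"), _fs("O6")),
            "HB3": (_fs("O2"), _fs("N2", "H21", "H22")),
            # provisional weak-ES placeholders; override for a specific convention
            "ES1": (_fs("C5", "H5"), _fs("C8", "H8")),
            "ES2": (_fs("C6", "H6"), _fs("N7")),
        }
        probes = {
            "HB1": ("N1", "N3"), "HB2": ("O6", "N4"), "HB3": ("O2", "N2"),
            "ES1": ("C5", "C8"), "ES2": ("C6", "N7"),
        }
    elif key == ("G", "T"):
        groups = {
            "HB1": (_fs("N1", "H1"), _fs("O4")),
            "HB2": (_fs("N2", "H21", "H22"), _fs("O2")),
            "CO..H": (_fs("O6"), _fs("C7", "H71", "H72", "H73")),
            # provisional weak-ES placeholder
            "ES1": (_fs("C8", "H8"), _fs("N3", "H3")),
        }
        probes = {
            "HB1": ("O4", "N1"), "HB2": ("O4", "N2"), "CO..H": ("C7", "O6"),
            "ES1": ("C8", "N3"),
        }
    else:
        raise ValueError(
            f"unsupported base-pair type {pair_type!r}; "
            "supported: ('A','T'), ('C','G'), ('G','T')"
        )
    if extra_groups:
        groups.update({k: (frozenset(v[0]), frozenset(v[1])) for k, v in extra_groups.items()})
    if extra_probes:
        probes.update(dict(extra_probes))
    return GroupScheme(pair_key=key, named_groups=groups, probe_atoms=probes)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ELEMENT_GUESS = {"OP1": "O", "OP2": "O", "OP3": "O"}


def _guess_element(name: str) -> str:
    name = normalize_atom_name(name)
    if name in _ELEMENT_GUESS:
        return _ELEMENT_GUESS[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper() if ch.upper() != "D" else "H"
    return name[:1].upper()


def read_pdb(path, model_ids: Optional[Sequence[int]] = None,
             frame_spacing_ps: float = 10.0) -> MolecularSystem:
    """Read a (possibly multi-model) PDB file into a MolecularSystem.

    Each MODEL becomes one snapshot; snapshot times are ``frame_spacing_ps``
    apart starting at 0.  Only the first altloc of each atom is kept and
    insertion codes are folded into the residue sequence number.  Charges and
    LJ parameters are zero until a topology is merged in.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("system", str(path))
    models = list(structure.get_models())
    if model_ids is not None:
        models = [models[i] for i in model_ids]
    if not models:
        raise ValueError(f"no models found in {path}")

    atoms: List[AtomRecord] = []
    order: List = []
    for residue in models[0].get_residues():
        if residue.id[0].strip():  # skip HETATM/water
            continue
        chain = residue.get_parent().id
        resname = residue.get_resname().strip()
        resseq = residue.id[1]
        for atom in residue.get_atoms():
            if atom.get_altloc() not in (" ", "A"):
                continue
            name = normalize_atom_name(atom.get_name())
            element = atom.element.strip() or _guess_element(name)
            atoms.append(
                AtomRecord(
                    atom_id=len(atoms),
                    name=name,
                    element=element,
                    residue_key=(chain, resname, resseq),
                )
            )
            order.append((chain, residue.id, atom.get_name()))

    coords = np.empty((len(models), len(atoms), 3))
    for f, model in enumerate(models):
        for k, (chain, resid, atom_name) in enumerate(order):
            coords[f, k] = model[chain][resid][atom_name].get_coord()
    times = np.arange(len(models)) * float(frame_spacing_ps)
    return MolecularSystem(atoms=atoms, snapshots=SnapshotSet(times=times, coords=coords))


def read_json_topology(path) -> Tuple[MolecularSystem, dict]:
    """Read the documented JSON topology (atoms + nonbonded bookkeeping).

    Schema::

        {"atoms": [{"id", "name", "element", "chain", "resname", "resseq",
                    "charge", "rmin_half", "epsilon"}, ...],
         "exclusions": [[a, b], ...],        # 1-2 / 1-3 atom-id pairs
         "scaled14": [[a, b], ...],          # 1-4 atom-id pairs
         "scee": 1.2, "scnb": 2.0,
         "coords": [[[x,y,z]...]...],        # optional snapshots
         "times_ps": [...]}                  # optional

    Returns the system and a dict with the nonbonded bookkeeping, suitable
    for :func:`pienet.mm.NonbondedRules.from_topology_dict`.
    """
    with open(path) as fh:
        data = json.load(fh)
    atoms = [
        AtomRecord(
            atom_id=int(a["id"]),
            name=normalize_atom_name(a["name"]),
            element=a.get("element", _guess_element(a["name"])),
            residue_key=(a.get("chain", "A"), a["resname"], int(a["resseq"])),
            charge=float(a.get("charge", 0.0)),
            lj_rmin_half=float(a.get("rmin_half", 0.0)),
            lj_epsilon=float(a.get("epsilon", 0.0)),
        )
        for a in data["atoms"]
    ]
    atoms.sort(key=lambda a: a.atom_id)
    snapshots = None
    if "coords" in data:
        coords = np.asarray(data["coords"], dtype=float)
        times = np.asarray(
            data.get("times_ps", np.arange(coords.shape[0], dtype=float)), dtype=float
        )
        snapshots = SnapshotSet(times=times, coords=coords)
    system = MolecularSystem(atoms=atoms, snapshots=snapshots)
    nb = {
        "exclusions": [tuple(p) for p in data.get("exclusions", [])],
        "scaled14": [tuple(p) for p in data.get("scaled14", [])],
        "scee": float(data.get("scee", 1.2)),
        "scnb": float(data.get("scnb", 2.0)),
    }
    return system, nb


def write_json_topology(system: MolecularSystem, nb: Mapping, path) -> None:
    """Write the JSON topology format read by :func:`read_json_topology`."""
    data = {
        "atoms": [
            {
                "id": a.atom_id,
                "name": a.name,
                "element": a.element,
                "chain": a.residue_key[0],
                "resname": a.residue_key[1],
                "resseq": a.residue_key[2],
                "charge": a.charge,
                "rmin_half": a.lj_rmin_half,
                "epsilon": a.lj_epsilon,
            }
            for a in system.atoms
        ],
        "exclusions": [list(p) for p in sorted(map(tuple, nb.get("exclusions", [])))],
        "scaled14": [list(p) for p in sorted(map(tuple, nb.get("scaled14", [])))],
        "scee": nb.get("scee", 1.2),
        "scnb": nb.get("scnb", 2.0),
    }
    if system.snapshots is not None:
        data["coords"] = system.snapshots.coords.tolist()
        data["times_ps"] = system.snapshots.times.tolist()
    with open(path, "w") as fh:
        json.dump(data, fh)


def export_scheme_tsv(
    system: MolecularSystem,
    segments: UnitScheme,
    fragments: Optional[UnitScheme] = None,
    labeling: Optional[SubunitLabeling] = None,
    path=None,
):
    """Tabulate atom -> unit assignments (segment, fragment, subunit) as TSV."""
    import pandas as pd

    rows = []
    for a in system.atoms:
        rows.append(
            {
                "atom_id": a.atom_id,
                "atom_name": a.name,
                "residue": f"{a.residue_key[0]}/{a.residue_key[1]}{a.residue_key[2]}",
                "unit_segment": int(segments.unit_of[a.atom_id]),
                "unit_fragment": int(fragments.unit_of[a.atom_id]) if fragments is not None else "",
                "subunit": str(labeling.label_of[a.atom_id]) if labeling is not None else "",
            }
        )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
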