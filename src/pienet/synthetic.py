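"""Seeded generators for toy complexes and reference-style QM component tables.

The toy complex is a schematic DNA-duplex-plus-peptide system: two strands
of "nucleotides" (anionic phosphate+pentose backbone carrying about -0.78 e,
a base carrying the remaining -0.22 e) paired across strands with
hydrogen-bond contact geometry near 2.9-3.0 Å, plus a short peptide chain
with neutral and ±1-charged side chains facing the DNA.  Geometry is
schematic (no sugar ring); what matters downstream is atom naming, unit
topology, charges, and contact distances.  Snapshots are the ideal
coordinates plus isotropic Gaussian jitter.

The synthetic QM tables reproduce the statistical structure reported for
real fragment-based QM against the force field:

* ES tracks the MM electrostatics with a slope slightly below 1
  (``es_slope``, default 0.95 — MM overestimates by a few percent);
* solvent screening opposes ES for pairs involving formally charged units
  (``screening_fraction`` of ES is cancelled, default 0.9), so ionic pairs
  that are repulsive as solutes become attractive in solution;
* dispersion is drawn independently of the force-field vdW term when
  ``dispersion_decoupled`` is set (no DI-vs-vdW correlation);
* unit charges are fractional, deviating a few percent from the formal
  integers (``charge_transfer_scale``).

Every generated object is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .mm import NonbondedRules
from .system import (
    AtomRecord,
    MolecularSystem,
    SnapshotSet,
    SubunitLabeling,
    UnitScheme,
    assign_segments,
    label_subunits,
)

__all__ = [
    "GeneratorConfig",
    "ToyComplex",
    "generate_toy_complex",
    "generate_qm_tables",
    "pair_min_distances",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study system (defaults are the study conditions)."""

    n_nuc_pairs: int = 4
    n_aa: int = 6
    n_snapshots: int = 100
    jitter_sigma: float = 0.05          # Å, per-coordinate Gaussian jitter
    charge_transfer_scale: float = 0.05  # fractional-charge deviation scale (e)
    es_slope: float = 0.95              # alpha: ES = alpha * elec + noise
    screening_fraction: float = 0.9     # beta: solv = -beta * ES for ionic pairs
    dispersion_decoupled: bool = True
    t_start_ps: float = 20000.0
    stride_ps: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nuc_pairs < 1 or self.n_aa < 0:
            raise ValueError("need at least one base pair and n_aa >= 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if not 0 < self.es_slope <= 1.2:
            raise ValueError("es_slope must be in (0, 1.2]")
        if not 0 <= self.screening_fraction <= 1:
            raise ValueError("screening_fraction must be in [0, 1]")
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")


# ---------------------------------------------------------------------------
# Atom templates.  Local frames: for a strand-D base +y points toward the
# partner base; contact (H-bond) atoms sit on matched lattice x-slots so the
# probe distance equals the pair gap.  Charges: the atom marked None absorbs
# the remainder so each backbone sums to -0.78 and each base to -0.22 exactly.
# ---------------------------------------------------------------------------

_NUC_BACKBONE: List[Tuple[str, str, Tuple[float, float, float], Optional[float]]] = [
    ("P",   "P", (0.0, -3.0, 0.0), 1.20),
    ("OP1", "O", (-1.2, -3.6, 0.6), -0.80),
    ("OP2", "O", (1.2, -3.6, 0.6), -0.80),
    ("O5'", "O", (0.0, -2.4, 1.2), -0.45),
    ("C5'", "C", (0.6, -1.8, 0.0), 0.05),
    ("C4'", "C", (0.0, -1.2, -0.9), 0.12),
    ("C3'", "C", (1.0, -0.9, -1.8), 0.08),
    ("O3'", "O", (0.9, -1.8, -2.8), -0.52),
    ("C1'", "C", (0.0, 0.0, 0.0), 0.10),
    ("H1'", "H", (-0.9, 0.2, -0.5), None),
]

# base templates: (name, element, local xyz, charge); None charge = filler.
# Hydrogen-bond contact heavy atoms all sit at local y = _CONTACT_LY on
# matched (x, z) slots, so the probe distance across the pair equals the gap.
_CONTACT_LY = 2.6

_BASES: Dict[str, List[Tuple[str, str, Tuple[float, float, float], Optional[float]]]] = {
    "A": [
        ("N9",  "N", (0.0, 0.9, 0.0), None),
        ("C8",  "C", (1.2, 1.1, 0.6), 0.05),
        ("H8",  "H", (2.0, 0.7, 1.1), 0.05),
        ("N1",  "N", (0.0, 2.45, -1.0), -0.45),  # HB2 acceptor (N..N bonds are longer)
        ("C2",  "C", (-1.1, 2.1, -1.6), 0.25),   # CO..H slot (set back 0.5)
        ("H2",  "H", (-1.3, 2.75, -2.2), 0.05),
        ("N6",  "N", (1.1, 2.6, 0.6), -0.35),    # HB1 donor slot
        ("H61", "H", (1.1, 3.0, 0.6), 0.38),
        ("H62", "H", (1.9, 2.3, 1.1), 0.25),
    ],
    "T": [
        ("N1",  "N", (0.0, 0.9, 0.0), None),
        ("O4",  "O", (1.1, 2.6, 0.6), -0.50),    # HB1 acceptor slot
        ("N3",  "N", (0.0, 2.6, -1.0), -0.30),   # HB2 donor slot
        ("H3",  "H", (0.0, 3.0, -1.0), 0.38),
        ("O2",  "O", (-1.1, 2.1, -1.6), -0.50),  # CO..H acceptor slot (set back)
        ("C7",  "C", (2.3, 1.4, 1.2), 0.00),
        ("H71", "H", (3.0, 1.9, 0.7), 0.07),
        ("H72", "H", (2.5, 0.4, 1.2), 0.07),
        ("C6",  "C", (-2.2, 1.2, -1.0), 0.20),
    ],
    "C": [
        ("N1",  "N", (0.0, 0.9, 0.0), None),
        ("N3",  "N", (0.0, 2.30, -1.0), -0.45),  # HB1 acceptor (N..N bonds are longer)
        ("N4",  "N", (1.1, 2.6, 0.6), -0.35),    # HB2 donor slot
        ("H41", "H", (1.1, 3.0, 0.6), 0.38),
        ("H42", "H", (1.9, 2.3, 1.1), 0.30),
        ("O2",  "O", (-1.1, 2.6, -1.6), -0.50),  # HB3 acceptor slot
        ("C5",  "C", (2.1, 1.3, 1.1), 0.00),
        ("H5",  "H", (2.9, 0.9, 1.6), 0.07),
        ("C6",  "C", (-2.2, 1.2, -1.0), 0.20),
        ("H6",  "H", (-2.9, 1.7, -1.5), 0.07),
    ],
    "G": [
        ("N9",  "N", (0.0, 0.9, 0.0), None),
        ("N1",  "N", (0.0, 2.6, -1.0), -0.35),   # HB1 donor slot
        ("H1",  "H", (0.0, 3.0, -1.0), 0.38),
        ("O6",  "O", (1.1, 2.6, 0.6), -0.55),    # HB2 acceptor slot
        ("N2",  "N", (-1.1, 2.6, -1.6), -0.35),  # HB3 donor slot
        ("H21", "H", (-1.1, 3.0, -1.6), 0.38),
        ("H22", "H", (-1.9, 2.2, -2.1), 0.30),
        ("N7",  "N", (2.1, 1.3, 1.1), -0.45),
        ("C8",  "C", (1.3, 0.6, 0.6), 0.25),
        ("H8",  "H", (1.5, -0.3, 0.5), 0.10),
    ],
}

_AA_BACKBONE: List[Tuple[str, str, Tuple[float, float, float], Optional[float]]] = [
    ("N",  "N", (0.0, 0.0, 0.0), -0.4157),
    ("H",  "H", (-0.6, -0.6, 0.4), 0.2719),
    ("CA", "C", (1.0, 0.6, 0.0), 0.0337),
    ("HA", "H", (1.0, 1.4, -0.7), 0.0823),
    ("C",  "C", (2.2, -0.2, 0.2), 0.5973),
    ("O",  "O", (2.3, -1.3, -0.2), None),
]

_AA_SIDES: Dict[str, Tuple[int, List[Tuple[str, str, Tuple[float, float, float], Optional[float]]]]] = {
    "ALA": (0, [
        ("CB",  "C", (0.9, 1.4, 1.2), -0.18),
        ("HB1", "H", (0.3, 2.2, 1.4), 0.06),
        ("HB2", "H", (1.8, 1.8, 1.0), 0.06),
        ("HB3", "H", (1.0, 0.8, 2.1), None),
    ]),
    "SER": (0, [
        ("CB", "C", (0.9, 1.4, 1.2), 0.21),
        ("OG", "O", (0.6, 2.2, 2.2), -0.66),
        ("HG", "H", (0.9, 3.1, 2.0), None),
    ]),
    "LEU": (0, [
        ("CB",  "C", (0.9, 1.4, 1.2), -0.10),
        ("CG",  "C", (0.7, 2.6, 2.0), 0.02),
        ("CD1", "C", (-0.4, 3.4, 1.5), -0.04),
        ("CD2", "C", (1.9, 3.3, 2.3), None),
    ]),
    "LYS": (1, [
        ("CB",  "C", (0.9, 1.4, 1.2), -0.01),
        ("CG",  "C", (0.7, 2.6, 2.0), -0.05),
        ("NZ",  "N", (0.5, 3.8, 2.8), -0.30),
        ("HZ1", "H", (0.0, 4.5, 2.4), 0.45),
        ("HZ2", "H", (1.3, 4.2, 3.2), 0.45),
        ("HZ3", "H", (-0.1, 3.5, 3.6), None),
    ]),
    "ASP": (-1, [
        ("CB",  "C", (0.9, 1.4, 1.2), -0.10),
        ("CG",  "C", (0.7, 2.6, 2.0), 0.70),
        ("OD1", "O", (-0.3, 3.3, 1.9), -0.80),
        ("OD2", "O", (1.6, 2.9, 2.9), None),
    ]),
    "ARG": (1, [
        ("CB",   "C", (0.9, 1.4, 1.2), -0.01),
        ("CZ",   "C", (0.7, 2.8, 2.1), 0.64),
        ("NH1",  "N", (-0.3, 3.6, 2.0), -0.60),
        ("HH11", "H", (-1.0, 3.3, 1.4), 0.44),
        ("HH12", "H", (-0.3, 4.5, 2.5), 0.44),
        ("NH2",  "N", (1.7, 3.2, 2.9), -0.60),
        ("HH21", "H", (2.4, 2.6, 3.1), 0.44),
        ("HH22", "H", (1.8, 4.1, 3.3), None),
    ]),
}

_LJ = {"C": (1.908, 0.1094), "N": (1.824, 0.17), "O": (1.6612, 0.21),
       "P": (2.1, 0.2), "H": (0.6, 0.0157)}

_PAIR_CYCLE = [("C", "G"), ("A", "T"), ("G", "T")]

_NUC_BACKBONE_SUM = -0.78
_NUC_BASE_SUM = -0.22

_RISE = 6.5        # Å between consecutive base pairs along x
_BASE_PLANE = 3.0  # strand-D base frame origin y


@dataclass
class ToyComplex:
    """Generated system plus its schemes, nonbonded rules and ground truth."""

    system: MolecularSystem
    rules: NonbondedRules
    segments: UnitScheme
    labeling: SubunitLabeling
    config: GeneratorConfig
    pair_gaps: Dict[Tuple[int, int], float] = field(default_factory=dict)
    base_pair_types: Dict[Tuple[int, int], Tuple[str, str]] = field(default_factory=dict)


def _fill(template, target_sum: float):
    """Resolve the None placeholder charge so the set sums to target exactly."""
    fixed = sum(q for *_, q in template if q is not None)
    return [
        (name, elem, xyz, q if q is not None else target_sum - fixed)
        for name, elem, xyz, q in template
    ]


def generate_toy_complex(config: GeneratorConfig) -> ToyComplex:
    """Build the schematic duplex+peptide system with jittered snapshots."""
    rng = np.random.default_rng(config.seed)
    atoms: List[AtomRecord] = []
    ideal: List[Tuple[float, float, float]] = []

    def add_atom(name, elem, xyz, charge, chain, resname, resseq):
        rmin, eps = _LJ[elem]
        atoms.append(AtomRecord(
            atom_id=len(atoms), name=name, element=elem,
            residue_key=(chain, resname, resseq), charge=float(charge),
            lj_rmin_half=rmin, lj_epsilon=eps,
        ))
        ideal.append(tuple(xyz))
        return len(atoms) - 1

    # Pair gaps vary across base pairs (drives the bond-length/energy ranking)
    gaps = 2.85 + 0.15 * rng.random(config.n_nuc_pairs) * 2.0  # 2.85..3.15 Å
    backbone = _fill(_NUC_BACKBONE, _NUC_BACKBONE_SUM)

    atom_index: Dict[Tuple[str, int, str], int] = {}  # (chain, resseq, name) -> id
    pair_types: List[Tuple[str, str]] = [
        _PAIR_CYCLE[k % len(_PAIR_CYCLE)] for k in range(config.n_nuc_pairs)
    ]

    for k, (fwd, rev) in enumerate(pair_types):
        x0 = k * _RISE
        gap = float(gaps[k])
        # strand D (forward): base frame at (x0, _BASE_PLANE, 0), +y toward partner
        for name, elem, (lx, ly, lz), q in backbone + _fill(_BASES[fwd], _NUC_BASE_SUM):
            aid = add_atom(name, elem, (x0 + lx, _BASE_PLANE + ly, lz),
                           q, "D", "D" + fwd, k + 1)
            atom_index[("D", k + 1, name)] = aid
        # strand E (reverse): mirrored in y through the pairing plane, so the
        # contact slots at local y=_CONTACT_LY face each other across `gap`
        y_mirror = _BASE_PLANE + 2 * _CONTACT_LY + gap
        for name, elem, (lx, ly, lz), q in backbone + _fill(_BASES[rev], _NUC_BASE_SUM):
            aid = add_atom(name, elem, (x0 + lx, y_mirror - ly, lz),
                           q, "E", "D" + rev, k + 1)
            atom_index[("E", k + 1, name)] = aid

    # peptide chain alongside strand D's backbone (y < 0)
    aa_names = list(_AA_SIDES)
    for j in range(config.n_aa):
        resname = aa_names[j % len(aa_names)]
        _, side = _AA_SIDES[resname]
        x0 = j * 4.8 + 1.5
        for name, elem, (lx, ly, lz), q in _fill(_AA_BACKBONE, 0.0):
            aid = add_atom(name, elem, (x0 + lx, -7.5 + ly, lz), q, "P", resname, j + 1)
            atom_index[("P", j + 1, name)] = aid
        formal, _ = _AA_SIDES[resname]
        for name, elem, (lx, ly, lz), q in _fill(side, float(formal)):
            aid = add_atom(name, elem, (x0 + lx, -7.5 + ly, lz), q, "P", resname, j + 1)
            atom_index[("P", j + 1, name)] = aid

    ideal_arr = np.asarray(ideal)
    n_frames = config.n_snapshots
    jitter = rng.normal(0.0, config.jitter_sigma, size=(n_frames, len(atoms), 3)) \
        if config.jitter_sigma > 0 else np.zeros((n_frames, len(atoms), 3))
    coords = ideal_arr[None, :, :] + jitter
    times = config.t_start_ps + config.stride_ps * np.arange(n_frames)
    system = MolecularSystem(
        atoms=atoms, snapshots=SnapshotSet(times=times, coords=coords)
    )

    # nonbonded bookkeeping across covalent unit junctions
    excluded, scaled14 = set(), set()

    def link(chain, i, names_i, j, names_j, excl_pairs, s14_pairs):
        for a, b in excl_pairs:
            ai, bj = atom_index.get((chain, i, a)), atom_index.get((chain, j, b))
            if ai is not None and bj is not None:
                excluded.add(frozenset((ai, bj)))
        for a, b in s14_pairs:
            ai, bj = atom_index.get((chain, i, a)), atom_index.get((chain, j, b))
            if ai is not None and bj is not None:
                scaled14.add(frozenset((ai, bj)))

    for j in range(1, config.n_aa):
        link("P", j, None, j + 1, None,
             excl_pairs=[("C", "N"), ("C", "H"), ("C", "CA"), ("O", "N"), ("CA", "N")],
             s14_pairs=[("CA", "CA"), ("O", "H"), ("O", "CA"), ("CA", "H")])
    for chain in ("D", "E"):
        for k in range(1, config.n_nuc_pairs):
            link(chain, k, None, k + 1, None,
                 excl_pairs=[("O3'", "P"), ("O3'", "OP1"), ("O3'", "OP2"), ("C3'", "P")],
                 s14_pairs=[("C3'", "OP1"), ("C3'", "OP2"), ("C4'", "P")])

    rules = NonbondedRules(excluded_pairs=excluded, scaled14_pairs=scaled14)
    segments = assign_segments(system)
    labeling = label_subunits(segments, system)

    # record which unit pairs are the Watson-Crick/wobble partners
    pair_gaps, bp_types = {}, {}
    unit_by_residue: Dict[Tuple[str, int], int] = {}
    for a in atoms:
        unit_by_residue[(a.residue_key[0], a.residue_key[2])] = int(
            segments.unit_of[a.atom_id]
        )
    for k, (fwd, rev) in enumerate(pair_types):
        ui = unit_by_residue[("D", k + 1)]
        uj = unit_by_residue[("E", k + 1)]
        pair_gaps[(ui, uj)] = float(gaps[k])
        bp_types[(ui, uj)] = (fwd, rev)

    return ToyComplex(
        system=system, rules=rules, segments=segments, labeling=labeling,
        config=config, pair_gaps=pair_gaps, base_pair_types=bp_types,
    )


def pair_min_distances(toy: "ToyComplex", frame: int = 0) -> Dict[Tuple[int, int], float]:
    """Minimum interatomic distance (Å) per unit pair at one snapshot."""
    coords = toy.system.snapshots.coords[frame]
    scheme = toy.segments
    units = scheme.unit_ids
    out: Dict[Tuple[int, int], float] = {}
    for a in range(len(units)):
        for b in range(a + 1, len(units)):
            ai = scheme.atoms_of(units[a])
            aj = scheme.atoms_of(units[b])
            diff = coords[ai][:, None, :] - coords[aj][None, :, :]
            out[(units[a], units[b])] = float(
                np.sqrt((diff ** 2).sum(axis=-1)).min()
            )
    return out


def generate_qm_tables(
    mm_table: pd.DataFrame,
    scheme: UnitScheme,
    config: GeneratorConfig,
    proximity: Optional[Dict[Tuple[int, int], float]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, float]]:
    """Synthesize PA-level component and unit-charge tables from an MM table.

    ``proximity`` optionally maps (unit_i, unit_j) to the pair's closest
    contact distance (Å); when given, dispersion decays with separation the
    way a contact interaction should (distant pairs get DI near zero), which
    makes the unscreened MM graph much denser than the screened one.
    Returns ``(components, charges, truth)`` where ``truth`` records the
    generating parameters (for parameter-recovery tests).
    """
    rng = np.random.default_rng(config.seed + 1)
    alpha = config.es_slope
    beta = config.screening_fraction

    pairs = mm_table[["unit_i", "unit_j"]].drop_duplicates().itertuples(index=False)
    di_base: Dict[Tuple[int, int], float] = {}
    for ui, uj in pairs:
        weight = 1.0
        if proximity is not None:
            d = proximity.get((ui, uj), proximity.get((uj, ui), np.inf))
            weight = float(np.clip(np.exp(-(d - 3.0) / 1.5), 0.0, 1.0))
        di_base[(ui, uj)] = weight * float(rng.normal(-2.5, 0.8))

    rows = []
    for _, row in mm_table.iterrows():
        ui, uj = int(row["unit_i"]), int(row["unit_j"])
        es = alpha * row["elec"] + rng.normal(0.0, 0.3)
        if config.dispersion_decoupled:
            di = di_base[(ui, uj)] + rng.normal(0.0, 0.1)
        else:
            di = 0.9 * row["vdw"] + rng.normal(0.0, 0.1)
        ionic = scheme.formal_charge[ui] != 0 or scheme.formal_charge[uj] != 0
        solv = -beta * es + rng.normal(0.0, 0.3) if ionic else rng.normal(0.0, 0.2)
        rows.append({
            "unit_i": ui, "unit_j": uj, "snapshot": int(row["snapshot"]),
            "level": "PA", "scheme": scheme.scheme_name,
            "is_covalent": bool(row["is_covalent"]),
            "ES": float(es), "DI": float(di), "solv": float(solv),
        })
    components = pd.DataFrame(rows)

    snapshots = sorted(mm_table["snapshot"].unique())
    charge_rows = []
    for uid in scheme.unit_ids:
        formal = scheme.formal_charge[uid]
        # charge transfer pulls charged units a few percent toward neutrality
        drift = config.charge_transfer_scale * (1 if formal < 0 else -1 if formal > 0 else 0)
        mean_total = formal + drift
        for snap in snapshots:
            total = mean_total + rng.normal(0.0, 0.02)
            if scheme.unit_category[uid] == "nuc":
                funct = -0.17 + rng.normal(0.0, 0.02)
            elif formal != 0:
                funct = 0.95 * total
            else:
                funct = rng.normal(0.03, 0.01)
            charge_rows.append({
                "unit_id": uid, "label": scheme.unit_labels[uid],
                "snapshot": int(snap), "total_charge": float(total),
                "functional_charge": float(funct), "formal_charge": int(formal),
            })
    charges = pd.DataFrame(charge_rows)
    truth = {"alpha": alpha, "beta": beta,
             "dispersion_decoupled": float(config.dispersion_decoupled)}
    return components, charges, truth
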