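"""Reference ensemble-averaged results for the MutS-DNA mismatch complex.

These small tables hold published ensemble averages (mean ± population std
over 100 MD snapshots) for a truncated MutS enzyme bound to a 30-nucleotide
DNA duplex containing a G:T mismatch (PDB 2o8b; Amber ff14SB/parmbsc1 force
field, fragment-based DFTB3/PCM quantum chemistry).  They serve as worked
inputs for the regression, decomposition-closure and charge-bookkeeping
analyses in this package: the statistics recomputed from them (e.g. the
MM-vs-QM solute R² of 0.993) are properties of the numbers themselves.

All energies are kcal/mol, charges in elementary-charge units (a.u.),
distances in Å.  Empty cells (glycine has no side chain) parse as NaN.
"""

from __future__ import annotations

import io
from functools import lru_cache

import pandas as pd

__all__ = [
    "load_pair_energies",
    "load_component_energies",
    "load_residue_charges",
    "load_subunit_contributions",
    "load_group_energies",
    "load_bond_geometry",
    "DNA_FORWARD",
    "DNA_REVERSE",
]

#: Forward/reverse strands of the bound duplex; X:Y is the G:T mismatch site.
DNA_FORWARD = "GAACCGCGCGCTAGG"
DNA_REVERSE = "CCTAGCGTGCGGTTC"

_PAIR_ENERGIES = """\
pair,category,is_covalent,mm_mean,mm_std,pa_solute_mean,pa_solute_std,pa_solution_res_mean,pa_solution_res_std,pa_solution_frag_mean,pa_solution_frag_std,fmo_solution_frag_mean,fmo_solution_frag_std
C7:G24,nuc-nuc,False,-8.3,1.8,-13.7,2.7,-21.3,2.3,-21.3,2.3,-21.7,2.1
A13:T18,nuc-nuc,False,8.8,1.4,10.1,1.8,-8.8,1.4,-8.8,1.4,-8.9,1.1
G6:C25,nuc-nuc,False,-9.0,1.6,-13.7,2.8,-22.8,2.1,-22.7,2.1,-23.4,1.6
A3:T28,nuc-nuc,False,8.8,1.3,9.9,1.9,-8.8,1.2,-8.7,1.2,-8.9,1.2
A2:T29,nuc-nuc,False,9.1,1.3,10.4,1.7,-8.9,1.2,-8.8,1.2,-8.9,1.1
G8:T23,nuc-nuc,False,7.8,1.2,5.3,1.8,-13.4,1.6,-13.5,1.6,-13.0,1.5
G10:Arg180,nuc-aa,False,-70.6,2.6,-64.7,4.0,-20.2,3.0,1.9,0.5,-1.5,0.5
C9:Arg180,nuc-aa,False,-53.6,2.7,-50.5,3.2,-12.6,2.0,-33.3,2.9,-32.9,2.8
G24:Phe101,nuc-aa,False,-5.3,0.6,-5.8,1.1,-4.2,0.6,-3.9,0.6,-4.1,0.5
C7:Phe101,nuc-aa,False,-0.6,0.4,-1.0,1.1,-0.6,0.3,-0.6,0.3,0.1,0.5
Gly78:Tyr96,aa-aa,False,-4.9,1.6,-7.0,1.7,-6.7,1.8,-0.6,0.2,-0.6,0.3
Trp82:Lys86,aa-aa,False,-12.4,1.2,-15.7,2.8,-12.3,1.5,-6.1,0.9,-4.8,1.0
Trp82:Met107,aa-aa,False,-0.7,0.6,-1.4,0.3,-1.3,0.3,-1.4,0.3,-1.2,0.2
Lys86:Asp108,aa-aa,False,-105.1,3.2,-104.9,4.0,-40.2,3.7,-40.2,3.7,-43.1,3.9
Met107:Asp108,aa-aa,True,-27.6,1.6,-4.9,2.3,-5.4,0.8,-5.9,0.9,-394.0,14.5
"""

_COMPONENTS = """\
pair,is_covalent,elec_mean,elec_std,vdw_mean,vdw_std,ES_mean,ES_std,DI_mean,DI_std,solv_mean,solv_std
C7:G24,False,-8.6,2.8,0.2,1.9,-10.1,2.7,-3.7,0.2,-7.6,1.7
A13:T18,False,9.5,1.9,-0.8,1.2,13.1,1.7,-2.9,0.3,-18.9,1.2
G6:C25,False,-9.3,2.8,0.2,1.8,-10.0,2.8,-3.7,0.2,-9.0,1.5
A3:T28,False,9.4,1.7,-0.6,1.2,12.8,1.8,-2.9,0.2,-18.7,1.4
A2:T29,False,9.9,1.9,-0.9,1.3,13.3,1.7,-2.9,0.3,-19.3,1.4
G8:T23,False,8.5,1.5,-0.7,1.1,8.0,1.8,-2.7,0.3,-18.7,1.5
G10:Arg180,False,-70.7,3.2,0.1,1.3,-61.4,3.9,-3.2,0.3,44.4,2.3
C9:Arg180,False,-52.6,2.7,-1.0,0.3,-49.3,3.2,-1.2,0.2,37.9,2.2
G24:Phe101,False,-1.9,0.3,-3.4,0.5,-1.9,0.9,-3.8,0.5,1.6,0.9
C7:Phe101,False,0.0,0.3,-0.6,0.3,-0.5,1.0,-0.5,0.2,0.4,1.0
Gly78:Tyr96,False,-4.7,1.9,-0.2,0.9,-5.8,1.7,-1.2,0.2,0.2,0.5
Trp82:Lys86,False,-9.5,1.2,-2.9,0.8,-11.1,2.7,-4.6,0.6,3.4,2.0
Trp82:Met107,False,-0.2,0.1,-0.5,0.6,-0.2,0.1,-1.2,0.2,0.1,0.1
Lys86:Asp108,False,-106.5,4.4,1.5,1.7,-102.9,3.9,-1.9,0.2,64.6,3.3
Met107:Asp108,True,-26.8,1.5,-0.8,0.8,-0.4,2.3,-4.5,0.3,-0.5,1.8
"""

_CHARGES = """\
label,category,formal_charge,mm_total,qm_res_total_mean,qm_res_total_std,qm_frag_total_mean,qm_frag_total_std,mm_funct,qm_res_funct_mean,qm_res_funct_std
A2,nuc,-1,-1.0,-0.990,0.035,-0.988,0.023,-0.105,-0.155,0.017
A3,nuc,-1,-1.0,-0.986,0.033,-0.987,0.022,-0.105,-0.153,0.016
G6,nuc,-1,-1.0,-1.025,0.034,-1.024,0.021,-0.089,-0.195,0.018
C7,nuc,-1,-1.0,-0.967,0.036,-0.956,0.027,-0.063,-0.141,0.018
G8,nuc,-1,-1.0,-1.012,0.034,-1.014,0.022,-0.089,-0.191,0.016
C9,nuc,-1,-1.0,-0.957,0.035,-0.918,0.024,-0.063,-0.148,0.016
G10,nuc,-1,-1.0,-0.955,0.033,-0.970,0.029,-0.089,-0.189,0.017
A13,nuc,-1,-1.0,-0.990,0.033,-0.983,0.023,-0.105,-0.154,0.016
T18,nuc,-1,-1.0,-1.018,0.027,-1.018,0.018,-0.127,-0.205,0.014
T23,nuc,-1,-1.0,-0.986,0.032,-0.985,0.022,-0.127,-0.193,0.016
G24,nuc,-1,-1.0,-0.994,0.037,-0.967,0.028,-0.089,-0.195,0.020
C25,nuc,-1,-1.0,-0.941,0.030,-0.964,0.022,-0.063,-0.144,0.018
T28,nuc,-1,-1.0,-1.012,0.034,-1.015,0.021,-0.127,-0.204,0.017
T29,nuc,-1,-1.0,-1.017,0.033,-1.009,0.022,-0.127,-0.205,0.017
Gly78,aa,0,0.0,-0.014,0.038,-0.015,0.019,,,
Trp82,aa,0,0.0,0.016,0.040,0.009,0.018,0.029,0.038,0.010
Lys86,aa,1,1.0,0.956,0.037,0.929,0.027,1.026,0.981,0.018
Tyr96,aa,0,0.0,-0.009,0.037,-0.020,0.022,0.028,0.010,0.013
Phe101,aa,0,0.0,-0.003,0.033,-0.012,0.019,0.019,0.014,0.009
Met107,aa,0,0.0,-0.003,0.034,-0.007,0.023,0.050,0.041,0.010
Asp108,aa,-1,-1.0,-0.921,0.035,-0.917,0.022,-0.858,-0.911,0.015
Arg180,aa,1,1.0,0.924,0.043,0.914,0.025,1.036,0.943,0.015
"""

_SUBUNITS = """\
pair,is_covalent,mm_bb,mm_bf,mm_fb,mm_ff,qm_solute_bb,qm_solute_bf,qm_solute_fb,qm_solute_ff,qm_solution_bb,qm_solution_bf,qm_solution_fb,qm_solution_ff
C7:G24,False,14.9,0.4,2.9,-26.4,10.6,2.6,3.4,-30.4,0.1,0.2,0.0,-21.7
A13:T18,False,12.6,3.8,2.4,-9.9,10.4,4.9,2.7,-7.9,0.1,0.0,-0.2,-8.8
G6:C25,False,14.2,3.2,0.3,-26.7,10.2,3.9,2.3,-30.2,0.1,-0.1,0.2,-23.0
A3:T28,False,12.6,3.8,2.4,-10.0,10.4,4.8,2.6,-7.9,0.1,0.0,-0.2,-8.8
A2:T29,False,12.8,3.8,2.5,-10.0,10.6,4.9,2.8,-7.9,0.1,0.0,-0.2,-8.9
G8:T23,False,14.4,3.3,3.4,-13.3,10.9,4.1,5.5,-15.4,0.1,0.1,0.1,-13.8
G10:Arg180,False,1.8,-69.9,0.1,-2.6,-0.1,-57.8,-0.0,-6.8,-0.1,-20.1,0.0,-0.1
C9:Arg180,False,5.1,-54.9,0.4,-4.2,-0.4,-41.9,-0.0,-8.1,0.0,-11.8,0.0,-0.8
G24:Phe101,False,-0.8,-2.3,-0.2,-1.9,-0.8,-1.4,-0.2,-3.3,-0.1,-1.0,-0.1,-2.9
C7:Phe101,False,0.7,0.0,-0.6,-0.7,0.0,-0.2,-0.5,-0.3,0.0,-0.1,-0.1,-0.4
Gly78:Tyr96,False,-0.2,-4.5,,,-0.3,-6.7,,,0.0,-6.7,,
Trp82:Lys86,False,-3.9,-4.8,-0.7,-3.0,-6.9,-5.5,-0.8,-2.4,-6.2,-1.5,-0.6,-3.9
Trp82:Met107,False,0.0,0.0,-0.1,-0.6,0.0,0.0,-0.3,-1.1,0.0,0.0,-0.2,-1.1
Lys86:Asp108,False,0.1,1.3,-4.7,-101.8,0.0,0.5,4.3,-109.7,0.0,0.0,1.3,-41.5
Met107:Asp108,True,-23.0,-1.6,-1.5,-1.5,-0.9,-0.1,-1.6,-2.2,-1.7,-1.8,-1.7,-0.1
"""

_GROUPS = """\
pair,bond,mean,std
A13:T18,HB1,-3.7,1.2
A13:T18,HB2,-4.3,0.6
A13:T18,CO..H,-0.8,0.4
A13:T18,rest,0.0,0.5
A13:T18,total,-8.8,1.4
C7:G24,HB1,-4.8,1.1
C7:G24,HB2,-4.4,0.6
C7:G24,HB3,-4.9,0.9
C7:G24,ES1,-2.2,0.4
C7:G24,ES2,-1.0,0.5
C7:G24,rest,-4.4,1.2
C7:G24,total,-21.7,2.3
G8:T23,HB1,-3.5,1.1
G8:T23,HB2,-4.3,0.9
G8:T23,CO..H,-1.1,0.4
G8:T23,ES1,-2.7,0.4
G8:T23,rest,-2.2,0.9
G8:T23,total,-13.8,1.6
"""

_GEOMETRY = """\
pair,bond,atom_a,atom_b,mean,std
A13:T18,HB1,N6,O4,3.04,0.22
A13:T18,HB2,N1,N3,2.95,0.11
A13:T18,CO..H,C2,O2,3.59,0.26
C7:G24,HB1,N1,N3,2.96,0.10
C7:G24,HB2,O6,N4,2.90,0.13
C7:G24,HB3,O2,N2,2.88,0.13
G8:T23,HB1,O4,N1,3.03,0.18
G8:T23,HB2,O4,N2,2.87,0.11
G8:T23,CO..H,C7,O6,3.47,0.29
"""


def _load(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))


@lru_cache(maxsize=None)
def load_pair_energies() -> pd.DataFrame:
    """Per-pair total interaction energies at five method/unit conventions.

    Columns: MM, QM solute (residues), QM in solution (residues and
    fragments, fractional charges), and fragment-based QM in solution with
    integer charges.  The Met107:Asp108 row is the covalently linked pair.
    """
    return _load(_PAIR_ENERGIES)


@lru_cache(maxsize=None)
def load_component_energies() -> pd.DataFrame:
    """MM (elec, vdw) and QM (ES, DI, solv) components per residue pair."""
    return _load(_COMPONENTS)


@lru_cache(maxsize=None)
def load_residue_charges() -> pd.DataFrame:
    """Formal vs. fractional residue charges, total and functional-unit."""
    return _load(_CHARGES)


@lru_cache(maxsize=None)
def load_subunit_contributions() -> pd.DataFrame:
    """Backbone/functional (bb, bf, fb, ff) blocks of each pair energy.

    ``bf`` is the backbone of the first unit against the functional unit of
    the second.  Glycine has no side chain, so its fb/ff cells are empty.
    """
    return _load(_SUBUNITS)


@lru_cache(maxsize=None)
def load_group_energies() -> pd.DataFrame:
    """Per-hydrogen-bond / contact-group energies in three base pairs.

    Long format (pair, bond, mean, std); the "total" rows equal the ff
    blocks of :func:`load_subunit_contributions` and the named bonds plus
    "rest" re-sum to them.
    """
    return _load(_GROUPS)


@lru_cache(maxsize=None)
def load_bond_geometry() -> pd.DataFrame:
    """Closest-heavy-atom bond lengths (Å) for the base-pair contact groups."""
    return _load(_GEOMETRY)
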