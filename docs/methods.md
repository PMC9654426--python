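# Methods

## Model and scope

`pienet` computes and compares residue–residue pair interaction energies
(PIEs) in protein–DNA complexes at two levels of description.

At the **force-field level**, the PIE between two units i and j is the sum
over their atom pairs of a Coulomb term k·Q_A·Q_B/(ε·R_AB) and a
Lennard-Jones term C12/R¹² − C6/R⁶.  The AMBER bookkeeping applies: atom
pairs separated by one or two bonds are excluded, dihedral-terminal (1–4)
pairs are down-weighted by 1/SCEE (elec) and 1/SCNB (vdW), and C12/C6 come
from Lorentz–Berthelot combination of per-atom (Rmin/2, ε_LJ) unless a
topology supplies per-pair coefficients.  Only *inter*-unit pair sums are
computed — intra-unit energies are not part of a pair quantity — and
inter-unit exclusions matter only across covalently adjacent units.  No
distance cutoff and no periodic images are applied by default: the analysis
target is a single non-periodic complex; both are available as options.

At the **QM level** the package is purely bookkeeping: it validates,
stores, and algebraically combines externally produced component tables.
Three component conventions are supported — MM (elec, vdw), partition
analysis PA (ES, DI, solv) and fragment-based FMO (ES, E0, CT·ES, DI,
solv).  The solute PIE is ES + DI; the in-solution PIE adds the remaining
terms.  Covalently linked fragment pairs carry boundary artifacts of order
−300 kcal/mol and are flagged so every regression can exclude them by rule.
Evaluating the damped DFTB electrostatics or any PCM solvent model is out
of scope; no quantum engine is invoked.

## Unit schemes

*Segments* are conventional residues read from a PDB/topology.  *Fragments*
reproduce the unit convention of fragment-based QM codes: the carbonyl
{C, O} of every non-C-terminal amino acid belongs to the next residue, and
the phosphate {P, OP1, OP2} of every non-5′-terminal nucleotide to the
previous one.  Bridging O3′/O5′ atoms stay with their sugars, so the shift
is an exact permutation: atom count, per-chain atom sets, and total charge
are conserved, and the inverse shift (reassignment by residue of record)
restores the segment scheme exactly.  Terminal residues are never shifted
(there is no adjacent unit to receive the group).

The backbone/functional split applies to segments only.  Amino acids:
backbone = {N, H*, CA, HA*, C, O, OXT}; the side chain is functional —
empty for glycine, whose decomposition cells involving its functional set
are reported as *absent* (None), never as zero.  Nucleotides: backbone =
every primed atom name plus {P, OP1, OP2}; the base is functional.  Both
`OP1/OP2` and the legacy `O1P/O2P` spellings are accepted and canonicalized.

Base-pair group schemes name the individual hydrogen bonds and contacts
with probe heavy atoms for bond-length statistics: A:T — HB1 (N6|O4), HB2
(N1|N3), CO⋯H (C2|O2); C:G — HB1 (N1|N3), HB2 (O6|N4), HB3 (O2|N2); G:T
wobble — HB1 (O4|N1), HB2 (O4|N2), CO⋯H (C7|O6).  Probe atoms are resolved
in whichever unit of the pair contains the name, since some names (N1, O2)
occur on both sides.  The weak-electrostatic ES1/ES2 groups have no
standard atom membership; the defaults are provisional placeholder contacts
and should be overridden through `default_group_scheme(extra_groups=...)`
when a specific convention is required.

## Decomposition identities

Every decomposition is a re-partition of the same atom-pair matrix, so the
identities hold to machine precision and are asserted at 1e−10 relative in
the tests: bb + bf + fb + ff equals the pair total (absent cells excluded),
and named bond groups + "rest" equal the ff block.  The atom-level
implementation is vectorized NumPy; an independent scalar double-loop
oracle in the test suite checks it on randomized ≤200-atom systems.

## Ensemble statistics

Snapshot selection uses a half-open window [t_start, t_end) with a stride,
nearest-frame matched within half the frame spacing; the half-open choice
makes the standard production policy (10 ps frames, 20–50 ns window,
300 ps stride) yield exactly 100 frames rather than 101.  RMSD uses Kabsch
superposition (SVD, via `scipy.spatial.transform.Rotation.align_vectors`)
by default — standard MD practice, and a flag disables it.  The RMSD
histogram's modality flag counts local maxima whose height *and* prominence
exceed a threshold (default 25% of the tallest bin) so shot noise on one
broad peak does not read as extra conformers.  Ensemble aggregation reports
the arithmetic mean and the population (ddof = 0) standard deviation by
default; a flag switches to the sample convention.  Population was chosen
so that zero-jitter synthetic ensembles give exactly zero spread.

## Residue interaction networks and their comparison

A network keeps an edge for every unit pair whose ensemble-mean interaction
is attractive and at least as strong as E_lim (−1 kcal/mol by convention),
weighted by that mean.  Two networks over the same node universe are
compared through the joint histogram of their edge weights: each pair with
an edge in either graph contributes one count at (bin in graph 1, bin in
graph 2); n_bins (default 40) left-closed energy bins span [min weight,
E_lim], and a dedicated no-edge bin per axis receives pairs absent from
that graph.  From the normalized histogram: MI = Σ p·log(p/(p_x·p_y)) with
0·log 0 := 0, marginal entropies H1/H2, and coefficients of constraint
C(1|2) = MI/H1, C(2|1) = MI/H2 (a switch flips which label normalizes
which).  Natural logarithms by default; the base is configurable and no
result in this package depends on the absolute MI scale.  Degenerate case:
if a marginal distribution is concentrated in one bin its entropy is 0 and
MI is 0; the corresponding coefficient is reported as 1 (the trivial
distribution is perfectly predictable).  Per-snapshot graph comparisons can
be averaged with `average_comparisons`.

## The synthetic generator

The generator stands in for the study's MD/QM raw data; its defaults *are*
the emulated study conditions.  The toy complex is schematic — no sugar
rings, no realistic dihedrals — because downstream code consumes only atom
names, charges, unit topology, contact geometry, and exclusions:

* two "DNA" strands of 4 base pairs (C:G, A:T, G:T wobble cycling) whose
  atomic charges sum to exactly −1 per nucleotide, split −0.78 backbone /
  −0.22 base (the reported phosphate+pentose vs. base division);
* hydrogen-bond donor/acceptor heavy atoms on matched lattice slots facing
  each other across per-pair gaps drawn in 2.85–3.15 Å (N⋯N acceptor slots
  set back so those contacts are longer, as in real pairs);
* a 6-residue peptide (Ala/Ser/Leu/Lys/Asp/Arg templates, integer side
  chain charges) alongside the duplex forming salt bridges;
* 100 snapshots (default) = ideal coordinates + isotropic Gaussian jitter
  of σ = 0.05 Å, timestamped 300 ps apart from 20 ns — with this σ, strong
  pair energies fluctuate by a few percent of their means.

Synthetic QM tables are built from the MM table with the reported
statistical structure: ES = α·elec + noise with α = 0.95 (MM slightly
overestimates); solv = −β·ES + noise with β = 0.9 for pairs involving a
formally charged unit, near zero otherwise — so anionic base pairs flip
from repulsive solutes to attractive in solution; DI is drawn independently
of vdW when the decoupling flag is set (the default), optionally attenuated
by contact distance (`proximity=`) so that far-apart pairs carry no
dispersion and the unscreened network is denser than the screened one;
fractional unit charges deviate from their formal integers by the
charge-transfer scale (0.05 e) toward neutrality.  Ground-truth parameters
are returned with every table for recovery tests.  All randomness flows
from one integer seed; equal seeds give byte-identical CSV output.

What passing on this generator does **not** show: transferability to real
force fields (no torsional strain, no solvent molecules, no conformational
transitions), realistic absolute energies, or the behaviour of the QM
components beyond the linear-plus-noise structure imposed here.

## Numerical and design choices

* Coulomb constant 332.0522173 kcal·Å·mol⁻¹·e⁻²; ε = 1; SCEE = 1.2,
  SCNB = 2.0 — the AMBER conventions, all configurable.
* Regressions are ordinary least squares of QM on MM (direction recorded in
  the result), R² = squared Pearson correlation, reported to 3 decimals;
  energies render at 1 decimal as "mean±std".  Covalent pairs are excluded
  by rule; rows with absent cells (glycine) drop listwise per analysis.
* The parm7 reader parses only the sections the energy model needs
  (charges, LJ coefficient tables, exclusion list, dihedral-derived 1–4
  pairs, residue pointers); 10–12 hydrogen-bond potentials are not
  supported and read as zero LJ.
* Pipeline outputs are stamped with a SHA-256 config hash; a rerun against
  an output directory holding the same hash reloads the cached tables.

## Limitations

No bonded terms, no Ewald/PME, no implicit-solvent energies, no
protonation-state prediction, no trajectory clustering, and no graph
visualization.  Parsing raw quantum-chemistry output files is not
implemented; QM tables enter through the documented CSV schema.  Absolute
mutual-information values for a real complex would require its full QM pair
tables and are out of scope; the network comparison here is validated
through its exact information-theoretic identities and controlled synthetic
orderings.
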