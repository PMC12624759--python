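# Methods

This note documents the models and conventions the package implements,
the defaults that matter, and the limits of what its tests demonstrate.

## Coordinate model and geometry

Structures are ordered atom tables (Å coordinates, 1-based PDB residue
numbering); trajectories are frame lists sharing one atom table, read and
written as multi-model PDB. Binary trajectory formats are out of scope:
the synthetic systems control problem size, so a text format keeps every
input inspectable.

Van der Waals radii come from a fixed Bondi-style element table (H 1.20,
C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown elements fall back to 1.70 Å
with a warning) and mass weighting uses standard atomic weights. Rigid
superposition is a Kabsch SVD fit (optionally mass-weighted) with a
determinant correction guaranteeing a proper rotation; fits require at
least three non-collinear atoms. Selections are a small conjunctive
grammar (`chain`, `resid` closed ranges, `name`, `backbone`,
`sidechain`, `heavy`, with `and`/`or`/`not`).

## Cavity detection

The detector follows the grid / buriedness / morphology family of pocket
algorithms. Defaults: spacing 1.0 Å, probe 1.2 Å, 14 scan directions,
buriedness threshold 9, scan range 10 Å, one erosion + one dilation,
minimum volume 30 ų. Three choices deserve comment:

- Occupancy is geometric (vdW + probe inflation). Energy-field probes
  used by commercial implementations are proprietary; the geometric
  surrogate reproduces the probe's role in defining cavity shape without
  any force-field dependency, and volumes should be compared on that
  basis only.
- The buriedness threshold is a convention, not a published value; it is
  exposed on the CLI (`--burial-threshold`). Thresholding precedes
  morphology.
- Hydrophobic ranking scores the fraction of lining residues in
  {A,V,L,I,M,F,W,P}. This is a residue-class surrogate for a hydrophobic
  molecular-interaction field and is documented as non-equivalent to one.

With ~0.9 Å shell-point spacing in the synthetic cavity substrate, the
voxelized cavity radius overshoots the nominal radius by
2.9 − sqrt(2.9² − (g/2)²) ≈ 0.03 Å, and measured volumes land within a
few percent of (4/3)πr³; the planted-sphere acceptance band is ±10%.

## Surface areas

Shrake–Rupley uses a deterministic golden-section spiral (default 960
points, probe 1.4 Å) rather than random sampling, so results are exactly
reproducible and the pose filter has a stable decision boundary.
Hydrogens are excluded by default (united-atom convention, matching the
LCPO usage); side-chain SASA sums non-backbone heavy atoms (backbone =
N, CA, C, O; glycine reports 0).

LCPO computes per-atom area as P1·S1 + P2·ΣA_ij + P3·ΣΣA_jk +
P4·Σ(A_ij·ΣA_jk) over neighbor overlaps, clamping negatives to zero.
Fitted P-coefficients are accepted per atom via the topology table. The
synthetic topologies default to (1, −1, 0, 0), which is exact for
isolated atoms and two-body overlaps (A_ij is the exact buried-cap area)
and adequate for sparse toys; for dense protein-like packing a fitted
coefficient set should be supplied, as the two-body coefficients
overcount triple overlaps.

## Pose triage

The filter excludes poses whose designated aromatic side-chain SASA is
strictly greater than 20 Å² — a pose at exactly 20 Å² is retained, with a
`strict_less` flag to flip the boundary. Probe radius and point count are
recorded with the audit table because the 20 Å² decision is only
meaningful for a stated SASA parameterization. Selection keeps one top
pose per score (Vina argmin; CNN score and CNN affinity argmax),
deliberately without consensus ranking; ties break by lexicographic pose
id, an artifact convention.

## Trajectory statistics

- Ligand RMSD: each frame is mass-weight fitted to the reference on the
  receptor selection (typically secondary-structure Cα), then the ligand
  RMSD is taken without refitting. A φ/ψ-window assignment (helix
  φ∈[−100,−30], ψ∈[−80,−5]; strand φ∈[−180,−90], ψ∈[90,180]; runs ≥ 4) is
  provided for choosing fit atoms when no external assignment is given;
  it is a coarse surrogate for hydrogen-bond-based assignments.
- Interface RMSD: interface residues are those of either partner with a
  heavy atom within 10 Å of the other partner in the reference (the
  CAPRI convention); the fit and the RMSD both use the interface
  backbone. An empty interface is an error, never a silent zero.
- Bound fraction: site residues are receptor residues within 5 Å of the
  peptide in the reference; the site centroid uses Cα atoms only, the
  peptide centroid is mass-weighted over heavy atoms, and a frame is
  bound when the distance is ≤ 6 Å. The 5 Å site radius and 6 Å cutoff
  are distinct, independently settable parameters.
- Contacts: hydrogen bond = N/O–N/O ≤ 3.5 Å (donor–H–acceptor angle
  ≥ 120° only when hydrogens exist; distance-only otherwise); salt
  bridge = Arg/Lys/His side-chain N to Asp/Glu carboxylate O ≤ 4.0 Å;
  van der Waals = heavy-atom distance ≤ r_i + r_j + 0.5 Å; cation–π =
  charged N within 6.0 Å of an aromatic ring centroid and ≤ 60° off the
  ring normal. Frequencies ≤ 25% are dropped from the filtered view; the
  full table is always retained for audit.

## Ensemble clustering

Frames are superposed once onto the first frame on the clustering
selection, so Euclidean feature distance = sqrt(n_sel) × selection RMSD.
This single-reference convention matches standard trajectory-clustering
tools and approximates true pairwise-fit RMSD; for the loop-scale motions
the pipeline targets the difference is negligible, but it grows with
global conformational change. K-means uses k-means++ starts, 10 restarts,
and a fixed seed; hierarchical clustering uses average linkage cut where
the merge distance exceeds the RMSD cutoff (2.5 Å default). Quality
metrics: DBI with mean distance-to-centroid scatter, pseudo-F in the
Calinski–Harabasz form — the specific normalization is an adopted
convention — and R² = 1 − SSE/SST. Ties for the most populated cluster go
to the lowest cluster id.

## MM/GBSA-lite

Single-trajectory protocol: complex, receptor, and ligand are evaluated
on the same frame, so internal bonded energies cancel and no conformational
relaxation is modeled; the solute entropy is neglected, making ΔG a
relative binding energy for ranking, not an absolute affinity.

- MM terms: Coulomb 332.0637·q_iq_j/r with no cutoff;
  Lennard-Jones with Lorentz–Berthelot combination.
- Polar term: pairwise-descreening effective Born radii with OBC tanh
  rescaling (α = 1.0, β = 0.8, γ = 4.85) and Still's f_GB including self
  terms, prefactor 166.0319·(1/ε_in − 1/ε_solv), ε_in = 1, ε_solv = 78.5,
  zero ionic strength. The dielectric offset is 0 rather than the AMBER
  0.09 Å so an isolated ion's effective radius equals its intrinsic
  radius and the Born closed form is exact — a deliberate simplification
  for a toy-system rescoring tool.
- Nonpolar term: γ·SASA_LCPO + β with γ = 0.0072 kcal/mol/Å² and β = 0.
- Missing topology values fall back to mbondi-style radii and
  element-typical descreening factors, and are logged.

Frame averages report SEM = s/√n over frames; frames from one trajectory
are correlated, so the SEM understates the true uncertainty unless frames
are pre-decimated to independence.

## Peptide masses and crosslink search

Monoisotopic masses are residue-table sums plus water, with −0.984016 amu
for C-terminal amidation; fixed carbamidomethylation (+57.02146, Cys) and
up to one Met oxidation (+15.99491) are the default modifications.
Digestion cleaves after K/R (suppressed before Pro), with per-residue
missed-cleavage caps (K ≤ 3, R ≤ 2) and a joint cap of 3.

m/z uses the hydrogen-atom mass (1.007825) per charge rather than the
proton mass (1.007276). For the four-decimal peak tables this pipeline
consumes, the atom convention reproduces the recorded calculated m/z to
under 1 ppm where the proton convention drifts by ~0.6 mDa per charge;
the convention is a per-call option. The crosslinker Δmass is consumed as
a given constant; its chemical decomposition is not modeled, and
candidate matching is mass-level only (no fragment-ion scoring).

## Experiment tables

SPR summaries are unweighted column means of per-concentration kinetic
fits. Rows whose kd/ka disagrees with the printed KD by more than 10% are
reported as diagnostics, never corrected — inconsistencies of that kind
usually trace to the source table. GEM normalizes STD integrals to the
strongest proton (exactly 100%); ties all report 100.

## Synthetic systems: what they do and do not show

The generators are pure functions of their arguments (seed included) and
every planted value is re-derivable from the emitted coordinates:

- Cavity substrate: a three-layer carbon shell (≈0.9 Å point spacing)
  around an empty sphere, with a mouth narrower than two probe diameters
  so voxel occupancy seals it; enclosure is verified by flood fill and
  non-enclosing parameter choices are refused.
- Binding trajectories: a frozen 8-residue receptor and a rigid
  Arg-Tyr-Arg peptide translating between scripted bound (4 Å) and
  unbound (9 Å) center-of-mass distances with 0.2 Å isotropic jitter
  truncated at 3σ. Truncation makes the separability precondition
  (bound + 3σ < 6 Å < unbound − 3σ) a guarantee, so planted bound
  fractions are recovered exactly. A salt bridge, a hydrogen bond, and a
  cation–π pair hold in exactly the bound frames.
- Pose sets: a Gly-Tyr-Gly peptide inside concentric carbon cages whose
  aperture is bisected until the measured side-chain SASA is within 2 Å²
  of the request (typically much closer).
- Energy toys: a two-atom host and one-atom guest at the LJ contact
  distance, complementary charges for the true binder and like charges
  for the decoy.

Passing on these systems demonstrates that the statistics, filters, and
energies compute what they claim on inputs with unambiguous truth. It
does not demonstrate performance on real proteins: the toys have no
flexibility, no solvent structure, no force-field realism, and planted
margins far wider than real decision boundaries. Quantities that depend
on microsecond sampling of real complexes (bound percentages, absolute
MM/GBSA values) are outside what any desk-scale rerun can reproduce; the
statistics, not those values, are the deliverable.

## Problem sizes

Default test and reproduction runs use 100–1000 frame trajectories,
~3000-atom cavity shells, ~600-atom pose complexes, and 80-point
clustering sets — sizes chosen so every planted-truth check runs
comfortably on a laptop while keeping discretization effects (voxel
volume bias, SASA point density) well inside the stated tolerances.

## Known limitations

- The pocket detector's absolute volumes depend on the geometric-probe
  surrogate; they are comparable across structures processed with the
  same settings, not to alpha-shape volumes from other tools.
- The GB variant is one fixed OBC-style parameterization; no salt,
  no PB cross-check.
- Contact detection is distance/angle heuristics on heavy atoms; with
  hydrogens absent, hydrogen-bond counts are upper bounds.
- The secondary-structure assignment is φ/ψ-window only.
- D-stereochemistry is metadata: masses and charges are
  stereochemistry-independent, and no operation in scope consumes 3D
  chirality.
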