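# Methods

This note documents the models behind each analysis stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Ensembles and superposition

A conformational ensemble is a frames × atoms × 3 stack of Å
coordinates over one residue-level topology. Author residue numbering
is kept verbatim (the KID convention runs 689–768); frames are 0-based
internally, with an optional ps time axis. Multi-model PDB is the only
coordinate format (read/write via biotite, MODEL/ENDMDL delimited,
occupancy/B-factor written as 1.00/0.00); binary trajectory formats
are out of scope. A cheap structural pre-scan rejects files whose
models disagree in atom count, naming the offending model, and names
the line of an unparsable coordinate field.

Rigid-body motion is removed with the Kabsch algorithm (SVD with
determinant correction, proper rotations only). The default fitting
selection is all Cα atoms and the default reference is frame 0, the
initial conformation. When replicas are analysed together the pipeline
fits all of them to a single shared reference (frame 0 of the first
replica) so that RMSD-based coordinates are comparable across
replicas; this is configurable. Superposition preserves intra-frame
distances to ≤1e-9 Å and is idempotent; the test suite checks it
against an independent quaternion (Horn) superposition oracle.

## Descriptors

- **RMSD** is computed on the superposed coordinates without
  re-fitting, against the initial frame.
- **RMSF** defaults to fluctuation about the time-averaged position
  (the standard definition); an `about_reference` mode measuring
  deviation about the initial model is also provided, because both
  conventions are in circulation for ensemble work and the choice
  changes the profile. A single-frame ensemble yields a zero profile
  with a warning flag rather than an error.
- **Rg** implements √(Σmᵢrᵢ²/Σmᵢ) about the selection's centre of
  mass. The default for landscape work is Cα-only and unweighted
  (mᵢ = 1), matching the convention of computing reaction coordinates
  on Cα atoms; the mass-weighted all-atom form is available.
- **SASA** uses Shrake–Rupley sphere sampling with Fibonacci-spiral
  test points (default 960/atom), probe radius 1.4 Å and vdW radii
  C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å. An isolated atom is exact
  by construction; two-sphere overlap matches the spherical-cap closed
  form to ~2% and the biotite implementation to ~3%. Analyses that
  used an LCPO-based SASA will differ by a few per cent; since SASA
  only serves as a relative reaction coordinate this offset is
  immaterial.
- **Compactness classes** use the closed Rg intervals 11.2–11.6
  (compact), 11.7–12.2 (semi-compact) and 12.3–12.8 Å (loose). The
  printed bins leave 0.1 Å gaps; a value falling in a gap is assigned
  to the nearer bin by the gap midpoint so that every in-range Rg gets
  a label; outside 11.2–12.8 Å the label is `out-of-range`.
- **Distance geometry** reports Cα–Cα edge series in lexicographic
  residue-pair order — 6 edges for the 4-tyrosine tetrahedron
  (Y703/Y721/Y730/Y747), 3 for a rigid-residue triangle.

## Secondary structure

Assignment follows DSSP: backbone H-bonds are scored with the
Kabsch–Sander electrostatic energy
E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol (bond if
E < −0.5), n-turns map to G/H/I, bridges to E/B, and T/S/C follow the
canonical priority. The per-frame assignment is delegated to mdtraj's
DSSP implementation (a port of the reference algorithm that
reconstructs amide hydrogens internally); the package exposes its own
Kabsch–Sander energy routine, with hydrogens placed 1.01 Å from N
along the outward C(prev)–N–Cα bisector, and the tests verify the
assigned helices directly against the i→i+3 / i→i+4 bond patterns of
that energy oracle. Byte parity with any particular DSSP binary is not
promised — consistency with the energy patterns is the contract.

Hfp counts states {H, G} by default; π-helix is excluded because only
α and 3₁₀ helices interconvert in the systems of interest, and the
state set is configurable. Helix segments are maximal per-frame H/G
runs of ≥3 residues, merged across frames when their residue spans
overlap by at least one residue, labelled H1…Hn from the N-terminus;
lifetime is the fraction of frames in which a merged segment appears
at or above the minimum length. Turns and bends are never folded into
segment statistics. Tracks can also be loaded from TSV ('-' accepted
for coil), enabling interop with external DSSP output.

## Interactions

Contact maps count frames with Cα–Cα distance strictly below the
cutoff (default 10 Å), normalised by the frame count. The trivial
sequence band |i−j| ≤ 2 is masked by default so occurrence statistics
stay informative; setting the exclusion to 0 restores the strict full
map. H-bonds require donor/acceptor heavy atoms in {N, O, S},
heavy-atom distance ≤ 3.6 Å and a D–H⋯A angle (measured at the
hydrogen) ≥ 120°; explicit hydrogens are used where present, backbone
amide hydrogens are reconstructed otherwise and such records carry a
`geometry_inferred` flag. Covalent 1-2/1-3 pairs (bond graph inferred
from frame-0 distances) and intra-residue pairs are excluded.
Side-chain O/S donors without an explicit hydrogen act as acceptors
only. Hydrophobic contacts take the minimum side-chain heavy-atom
distance ≤ 4 Å between residues in {A, V, L, I, P, F, M, W}; glycine
in the set is an error since it has no side-chain heavy atom. Segment
filtering keeps interactions with at least one endpoint inside an
origin span and occurrence strictly greater than the threshold
(default 0.80). Neighbour searches use a k-d tree; the contract —
checked in tests — is exact agreement with the all-pairs oracle.

## Ensemble clustering

The reference-harvesting procedure: draw a frame uniformly from the
remaining pool, record it as a reference, remove every frame within
RMSD r of it, repeat until the pool is empty; then assign every frame
to its nearest reference, ties to the lower reference index. Removed
frames never become references. The RNG protocol is part of the
contract (one `default_rng(seed).integers(len(pool))` draw per
reference, in order) so an independent implementation replays it
exactly. The analysis stride is configurable (conventionally a 100
ps-equivalent). Cluster count is non-increasing in r on a fixed seed
stream, checked over r ∈ {3, 4, 5} Å.

## Free-energy landscapes

ΔG(R₁,R₂) = −k_B·T·ln(P/P_max) with k_B = 0.0019872041 kcal/(mol·K)
and T defaulting to 310 K (the simulation temperature of the target
systems). P is a k-nearest-neighbour density, density = k/(N·π·d_k²),
evaluated in the per-axis z-scored plane because RMSD (Å), Hfp (%) and
SASA (Å²) have incommensurate scales; ΔG differences are therefore
invariant under affine rescaling of either raw coordinate (tested).
k defaults to ⌈√N⌉ — the usual bias/variance compromise, validated
against Gaussian and histogram closed forms. Duplicated points with
d_k = 0 get a capped density and a warning.

The grid (default 100×100 over the 5%-padded bounding box) is
evaluated everywhere for well detection, but cells containing no
samples are reported as undefined. Wells are found by a persistence
watershed: cells are flooded in order of increasing ΔG; when a cell
first connects two basins the shallower basin is merged if its
persistence (saddle ΔG minus its minimum) is below `min_well_depth`
(default 0.5 kcal/mol, ~0.8 k_BT at 310 K — the scale below which a
minimum in a sampled landscape is indistinguishable from estimator
noise). Wells are ranked by depth; rank 1 is the global minimum at
exactly 0. Basin membership maps each frame's coordinate cell to its
watershed basin; the representative conformation is the frame nearest
the minimum in standardised coordinates.

One quantitative caveat, relevant when validating against mixture
closed forms: for a 0.7/0.3 two-Gaussian mixture with unit component σ
and modes 4σ apart, the minor well's persistence is
k_B·T·(2 + ln 0.3) ≈ 0.49 kcal/mol at 310 K — *below* the default
merge threshold, so with defaults that configuration legitimately
reports one well. Resolving both wells needs either a larger mode
separation (5σ gives a ~1.2 kcal/mol barrier) or an explicitly lower
threshold; the validation suite does both, deliberately.

Point queries of ΔG carry sampling noise with standard error
≈ 2·k_B·T/√k; closed-form validations therefore average queries over
rings and, for the mode, subtract the exact radial offset k_B·T·r²/2
of a standard Gaussian rather than trusting one noisy point.

## Folding dynamics

Per residue, consecutive-frame (lag configurable; 1 by default)
transitions over the 8-state alphabet are counted and rows are
normalised after adding a Jeffreys pseudo-count α = 0.5, so
never-visited source states give uniform-ish rows instead of
divisions by zero; with α = 0 an unoccupied row falls back to the
identity row. Row occupancies are kept alongside.

The Fisher–Rao distance between two categorical rows is the geodesic
2·arccos Σ√(pₛqₛ) (twice the Bhattacharyya angle, bounded by π).
Aggregation over a replica pair is an open design point: here row
distances are averaged per residue weighted by combined row occupancy
— rarely-visited rows carry little information and would otherwise
dominate through smoothing noise — then uniformly over residues.
Identical rows are snapped to exactly zero to avoid ~1e-8 arccos
floating-point residue. The aggregate is symmetric, bounded by π and
satisfies the triangle inequality on the tested random ensembles.

Replica distance matrices are embedded with classical (Torgerson) MDS:
B = −½·J·D²·J, eigendecomposition, negative eigenvalues clipped;
deterministic and eigen-based, unlike SMACOF. The reported stress is
the relative Frobenius error of the reconstructed distances. Exactly
Euclidean matrices (planar point sets, the 3-4-5 triangle) are
reproduced to 1e-8.

## Synthetic data

The generators emulate the statistical structure of the undeposited
trajectories, not their physics:

- `simulate_ss_chain` runs independent per-residue 8-state Markov
  chains (ground-truth matrices retained). Independence is deliberate:
  it suffices for validating estimators. It does *not* reproduce
  cooperative helix formation, so coordinate ensembles built from
  these tracks have lower DSSP-recovered helicity than the chain's
  stationary value — isolated one-residue helical states cannot form
  i→i+4 H-bonds.
- `build_peptide_ensemble` grows backbones by NeRF internal-coordinate
  extension (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; ideal angles;
  ω = 180°), with φ/ψ = (−57°, −47°) for H, (−49°, −26°) for G,
  (−57°, −70°) for I and coil dihedrals drawn from φ ~ N(−120°, 30°),
  ψ ~ N(130°, 30°) — non-helical without requiring sheet partners.
  Cβ and amide H are placed by ideal geometry; optional isotropic
  Gaussian jitter roughens the coordinates. No side chains beyond Cβ,
  no sterics.
- `gaussian_mixture_samples` and `multi_basin_ensemble` provide
  reaction-coordinate and coordinate-space fixtures with ground-truth
  component/basin labels; template separations of several Å reproduce
  the bimodal RMSD distributions characteristic of trajectories
  hopping between conformational families.
- The default domain-like fixture is an 80-residue chain numbered
  689–768 (poly-Ala with F689, D768 and tyrosines 703/721/730/747
  substituted) in 8 replicas grouped 4+2+2. The groups differ in their
  helical-segment layout and propensity, giving stationary helicities
  of roughly 52%, 26% and 40% — inside the 25–56% range such domains
  exhibit — and group-distinct transition matrices that the
  Fisher–Rao/MDS pipeline must separate.

Every generator is a pure function of spec + seed, and ground-truth
labels are always returned, so downstream tests are parameter-recovery
tests. Passing them shows the estimators are correct on data matching
their assumptions; it does not show that real MD ensembles satisfy
those assumptions.

## Problem sizes

The shipped validation suite uses 20,000-point reaction-coordinate
fixtures, a 50,000-frame Markov chain, 1,500-frame state tracks for
the 8-replica comparison, and coordinate ensembles of some tens to
hundreds of frames (30–120 per replica in the integration pipeline,
with SASA computed on a 5-frame stride). These sizes keep the full
suite and the acceptance script to a few minutes on one CPU while
leaving all statistical tolerances comfortably met; all are parameters
and scale up unchanged.

## Known limitations

- No binary trajectory formats, solvent, ions or force-field
  awareness; ensembles must fit in memory.
- DSSP parity is defined against the Kabsch–Sander energy patterns,
  not against any specific DSSP executable's output bytes.
- H-bond detection with reconstructed hydrogens is geometric
  inference; records are flagged accordingly. Side-chain hydroxyl
  donors without explicit H are treated as acceptors only.
- The Fisher–Rao aggregation (occupancy-weighted rows, uniform
  residues) is one defensible choice among several; alternatives
  (uniform rows, stationary-weighted) would scale distances
  differently, though orderings proved stable in testing.
- The kNN landscape estimator needs a few thousand frames per basin
  before well depths stabilise to ~0.05 kcal/mol; well *counts* from
  short trajectories should be read with the persistence threshold in
  mind.
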