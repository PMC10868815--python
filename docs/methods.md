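# Methods

This note documents the models, conventions and numerical choices behind
solvdna, in the order data flows through the package.

## Units and conventions

Structure coordinates are stored in Angstrom; all quantum-mechanical
quantities (exponents, grids, densities, potentials, dipole integrals)
are in Hartree atomic units, converted at 1 A = 1.8897261254578281 Bohr.
Dipole magnitudes are reported in Debye (1 a.u. = 2.541746 D).  Real
solid harmonics are ordered m = -l..+l with no Condon-Shortley phase:
l=1 components are (y, z, x); l=2 are (sqrt(3)xy, sqrt(3)yz,
(3z^2-r^2)/2, sqrt(3)xz, sqrt(3)/2 (x^2-y^2)).  The supported maximum
degree is l = 2, matching the shipped basis.  Degree-l rotation matrices
are obtained numerically by solving the exact linear relation
S_l(R r) = D S_l(r) over sampled directions.

## Auxiliary density basis

Each basis function is a solid-harmonic Gaussian normalised to unit
self-overlap; for an s shell this gives N = (2a/pi)^(3/4).  Closed forms
used throughout: an l=0 function of coefficient C holds
C N (pi/a)^(3/2) electrons; an l=1 function contributes
C N (pi/a)^(3/2) / (2a) to the corresponding first-moment component;
l >= 1 functions integrate to zero.  "Population normalisation"
multiplies each coefficient by N (pi/a)^(3/2) (2a)^(-l/2), so l=0
entries become electron populations and higher-l entries are O(1); the
transform is exactly invertible and is the storage convention for
training targets.

The shipped `synthetic_jfit` basis is a synthetic even-tempered s/p/d
set (4-6 s shells, 3 p, 1 d per element; 1 p for H).  Exponents are
capped near 16 Bohr^-2 so that every basis density is fully resolved by
midpoint quadrature on the 0.2 Bohr analysis grid (the quadrature error
of a Gaussian scales as exp(-pi^2/(a h^2))).  A production Coulomb-fitting
set would add much steeper core functions and higher angular momenta;
nothing in the algebra depends on that, but absolute densities near
nuclei are smoother here than in a real calculation.

Grid defaults: fields cover the structure's bounding box plus 5 Bohr of
padding; 0.2 Bohr spacing for density-error metrics, 0.1 Bohr for
dipole integration (6 Bohr padding around the molecule).  The most
diffuse H shell (a = 0.12) retains ~0.03% of its norm outside the 5 Bohr
padding; analyses that need tighter closure (e.g. grid-convergence
studies) use 8 Bohr.

Projection of a gridded reference density onto the basis minimises the
voxel-wise squared residual via normal equations accumulated in chunks;
an ill-conditioned system (condition number above 1e12) is solved with a
small Tikhonov term and a warning.  This is a grid-metric fit, not a
Coulomb-metric fit: the difference is absorbed into the reported RMS
residual.

## Electrostatic potentials

The potential of the fitted density is closed-form.  With
g(R) = (pi/a)^(3/2) erf(sqrt(a) R)/R the potential of a unit s function,
solid-harmonic derivatives give the higher shells:
V_1m follows from f'(R)/R times (y, z, x) with prefactor -1/(2a), and
V_2m from (f'' - f'/R)/R^2 times S_2m(r) with prefactor 1/(4a^2), both
with series expansions below R ~ 1e-3 Bohr for numerical stability.
Nuclear terms Z/|r - R_A| are included by default; evaluation at a
nucleus raises.  A grid-quadrature fallback (self-voxel softened at half
a spacing) exists for validation only and is accurate away from nuclei
(>~ 2 Bohr).

Isodensity surfaces are marching-cubes vertex sets (trilinear edge
interpolation); r-bar is the mean distance of surface points to the
nearest DNA atom.  ESP comparisons subtract each series' mean before the
RMSD, making the measure invariant to constant offsets.  Axis profiles
shift the global potential mean to zero, assign every surface point to
the nearest cross-strand P-P midpoint, and report per-bin means with
standard deviations as the spread.

## Fragmentation

Bonds are detected geometrically (d < 1.2 x sum of Cordero covalent
radii), which keeps the cutter independent of residue topology
dictionaries.  A base-pair step yields, under the `dna_only` scheme,
2 base-pair + 2 base-stacking + 4 nucleotide fragments (8 per step;
bases are cut at glycosidic bonds, nucleotides at the inter-residue
O3'-P junctions); under `dna_with_solvent`, one fragment per distinct
base and one sugar-phosphate fragment per residue, each with its 12
nearest whole waters (nearest-N by minimum O-to-solute distance, ties
broken by input order), backbone fragments flagged — and the ion
included — when an Mg2+ sits within 2.0 A of a phosphate oxygen.
Solvent-only training classes (Mg2+ shell, Cl- shell, water cluster; 15
waters each) are generated directly.  Every severed heavy-heavy bond is
capped with H along the former bond at the kept atom's standard X-H
length (C-H 1.09, N-H 1.01, O-H 0.96 A); a cap landing within 0.7 A of
an existing atom is an error, and caps carry provenance (which parent
atom they replaced).  Watson-Crick partners are identified by the
purine-N1 / pyrimidine-N3 distance (paired ~2.9 A, all other residue
pairs > 3.4 A in B-form geometry).

Step symmetry: reading the complementary strand 5'->3' maps step XY to
its reverse complement, so the 16 sequences collapse to 10 classes
(canonical form = lexicographic minimum of the pair); AT, TA, GC, CG are
self-complementary.

## Idealized B-DNA generator

The builder produces geometrically coherent, chemically bonded B-form
duplexes rather than crystallographic replicas.  Bases are planar with
regular-polygon rings (side 1.37 A) and standard exocyclic bond lengths.
Each Watson-Crick pair is assembled by solving the in-plane orientation
of both bases from two hydrogen-bond constraints (N1...N3 and the C6/C4
substituent pair, both 2.9 A), choosing the solution branch with the
largest covalent-bond safety margin between the bases.  Pairs stack with
a 3.38 A rise and 36 deg twist; C1'-C1' separation is 10.4 A with
glycosidic bonds at 54.5 deg.  The sugar is a flat pentagon template
whose exocyclic O3'/C5'/O5' directions were fixed once by requiring that
geometric bond detection on assembled duplexes reproduces exactly the
intended covalent topology (correct valences everywhere, inter-residue
bonds only at O3'-P).  Every nucleotide carries a 5'-phosphate; the
bridging P is placed equidistant (1.59 A) from O3'(i) and O5'(i+1),
terminal phosphates complete to PO4, terminal O3' gets a hydroxyl H, and
sugar CH hydrogens are added by tetrahedral completion.  Waters (rigid
gas-phase geometry: O-H 0.9572 A, H-O-H 104.52 deg) are packed by seeded
rejection sampling with O-O >= 2.5 A and solute clearance >= 2.2 A; the
optional bound Mg2+ sits 1.9 A from a phosphate OP1.

## Mock-DFT oracle

The oracle supplies ground-truth coefficients with exact analytic
properties; it is a physics-flavoured stand-in, not a DFT emulator.
Per atom, it distributes Z (minus the formal ionic charge) electrons
over the element's s shells with weights proportional to sqrt(a)
(tighter shells hold more charge), conserving electrons to machine
precision.  Each water O carries an intrinsic l=1 term along the HOH
bisector calibrated so the monomer dipole is exactly 1.85 D.  A one-shot
induced dipole mu = alpha * E_local is added on water oxygens
(alpha = 9.8 a.u., the experimental water polarizability) and on
non-water heavy atoms (alpha = 6 a.u.), where E_local sums the Coulomb
fields of ions (point charges) and of other waters' intrinsic dipoles.
The induction is deliberately not self-consistent (single shot) for
determinism and speed.  Consequences worth knowing: polarization decays
as 1/r^2 from an ion and is twice as strong around Mg2+ as around Cl-,
so shell-averaged water dipoles reproduce the qualitative
first-shell > second-shell > bulk ordering around cations once averaged
over snapshots — single snapshots are noisy because water orientations
are random rather than thermally relaxed, which is a fidelity limit of
the generator, not of the analyses.  Charge-transfer effects are outside
the oracle's scope.

## Coefficient model

The predictor is an equivariant linear model in the atomic-cluster-
expansion family rather than a deep message-passing network: per-atom
degree-l features are sums over neighbours (within a 3.5 A cutoff by
default) of 8 Gaussian radial basis functions under a cosine envelope
times the solid harmonics of the bond direction, resolved by neighbour
element (7-type general vocabulary, or 9-type with water H/O as distinct
channels); each element's auxiliary shells get an independent scalar
weight vector (plus a bias for l=0).  Equivariance under rotation,
translation and permutation is exact by construction.  The design choice
is deliberate: with one linear interaction the coefficient-MSE loss is
quadratic and can be minimised exactly per output block by ridge
normal equations (`solver="lstsq"`, the default — deterministic and
fast), while a hand-written seeded minibatch Adam (`solver="adam"`)
provides the iterative route with a per-epoch loss history.  The linear
model represents the oracle's intrinsic water term exactly and its
induced term approximately; held-out density errors on oracle datasets
are therefore near zero for monomers and a fraction of a percent for
clusters, decreasing with training-set size while the feature space is
unsaturated.  Checkpoints store the config, basis and a vocabulary hash
and refuse to load on mismatch.

## Problem sizes used in validation

Tests and the acceptance script run at desk scale: water monomers and
small clusters (1-20 waters) for oracle-equivalence and training checks,
two-base-pair steps with up to 30 waters for fragmentation, 200 monomers
for parameter recovery, training sizes (4, 16, 64) trimer clusters
averaged over 5 seeds for the learning curve, and 20 snapshots of
20-water ion shells for the dipole analysis.  The combined-model test
manifest (110 solvated steps of 100 waters) is enumerated structurally;
full-scale density-error statistics over such sets require an ab initio
reference corpus and are out of scope.

## Known limitations

* lmax = 2 in basis, harmonics and ESP; no steep core functions.
* The B-DNA geometry is idealized (planar bases, flat sugars, no
  sequence-dependent structure, no thermal sampling).
* Water orientations are random, not Boltzmann-sampled; induced dipoles
  are single-shot.
* Projection uses the grid metric, not the Coulomb metric.
* The model is linear; systems whose coefficients depend nonlinearly on
  many-body geometry set its accuracy floor.
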