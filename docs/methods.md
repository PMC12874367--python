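# Methods

## Scope and model

`cageconform` analyses the conformational dynamics and charge
preparation of lantern-shaped [Pd2L4]4+ metallacages. Two analogs are
supported: *endo-C*, whose ligand is
1,3-bis(pyridin-3-ylethynyl)benzene (C20H12N2), and *endo-N*, whose
ligand is 2,6-bis(pyridin-3-ylethynyl)pyridine (C19H11N3) — the endo
position of the central ring presents a C–H or a nitrogen lone pair
into the cavity. The package operates purely on post-simulation
artifacts: structures and trajectories, per-atom charge tables,
per-structure energy tables and 2-D scan grids. It never evaluates
forces or quantum chemistry.

## Topology perception

Bonds are perceived by distance: atoms i, j are bonded iff
d(i,j) ≤ 1.15 × (r_cov(i) + r_cov(j)), with Cordero covalent radii.
The 1.15 tolerance recovers aromatic (1.39 Å), alkyne (1.20 Å) and
Pd–N coordination (2.02 Å against a 2.42 Å cutoff) contacts without
reaching van-der-Waals range. Lantern recognition requires exactly two
Pd atoms whose removal leaves four components of identical elemental
composition; per ligand, the central ring is the unique perceived ring
(minimum cycle basis — the ligands contain only isolated six-rings, so
any correct ring finder agrees) containing neither Pd-coordinating
nitrogen, and the endo atom is the central-ring member bonded to both
arm-bearing ring atoms. Counterions and solvent are removed before
detection via an element allow/deny list or, for PDB input, residue
names; how the original study stripped frames is not recorded, so this
selection mechanism is this package's own convention. Atom indices are
0-based internally and 1-based in JSON reports (stated in-band).

## Symmetry grouping

Equivalence classes are computed by colour refinement
(Morgan/1-dimensional Weisfeiler–Lehman): initial colour = element;
each round recolours an atom by the hash of its colour plus the sorted
multiset of neighbour colours; the partition is stable when the class
count stops growing. Refinement never splits a true automorphism
orbit, so classes are unions of orbits; on every graph in the test
battery (and on both ligand graphs, cross-checked against RDKit's
canonical ranking and explicit VF2 automorphism enumeration) the two
coincide. Grouping is computed on a single ligand including hydrogens
with Pd excluded — this is the convention that yields 19 classes for
endo-C and 18 for endo-N; including the metal would add one class per
element environment (the full cage gives 20/19). Hydrogens always form
their own classes. Class labels (element + counter in canonical colour
order) are invariant under input atom permutation.

Charge averaging replaces every atom's charge by its class mean; class
sums are redistributed rather than re-rounded, so the total charge is
conserved to machine precision (tested at 1e-12). Model comparison
reports per-class means per model, the cross-model range per class and
each model's min–max spread over class means (its polarization).

## Conformational states

θ is the acute angle between best-fit planes (least-variance singular
vector of the centred ring coordinates) of the central rings of two
adjacent ligands; adjacency is consecutive azimuthal order of the ring
centroids about the Pd–Pd axis, giving four pairs per frame. Plane
normals are sign-ambiguous, hence the acute convention θ ∈ [0°, 90°].
The three states have characteristic angles ≈90° (closed), ≈60–70°
(semiopen, one stacked pair) and ≈40–50° (open, two stacked pairs); the
default class boundaries 55° and 80° sit midway between those ranges
and are configurable because the underlying description gives ranges,
not cutoffs. Per-frame classification uses the minimum pair angle by
default (the stacking pair is the extreme one); a pair-count rule
(open requires ≥2 pairs at or below the open boundary) is selectable.
Whether a published angle trace follows one fixed pair or the minimum
over pairs is not derivable from the figures alone; both are computed
and θ_min is the default trace.

## Populations

Residence fractions are frame counts per state after an optional
burn-in (default 0 — equilibration is reported, never silently
discarded); replicas pool by frame-weighted counting. The θ_min density
is a normalized histogram by default (bin edges always include the
state thresholds, making density integration per state *identical* to
frame counting) or a Gaussian KDE evaluated on a 0.1° grid and
renormalized over [0°, 90°]; the original figures do not state their
estimator, so both are provided. Boltzmann populations use
w_i = exp(−(E_i − E_min)/k_B T) with k_B = 0.0019872041 kcal/(mol·K)
and default T = 298.15 K (the reference analysis does not print its
temperature; room temperature is the natural choice). Centering at
E_min is underflow-safe and analytically identical (shift invariance is
tested to 1e-12).

## Scan surfaces

Scan grids are scattered (d1, d2, E) points; a grid is rectangular when
the distinct d1 and d2 values form a full Cartesian product. Minima use
Moore (8-neighbour) connectivity — 4-connectivity would report spurious
minima along diagonal valleys on coarse scans; ragged point sets fall
back to a symmetrized 8-nearest-neighbour graph. A point is a minimum
iff strictly below all neighbours; equal-energy plateaus whose entire
boundary is higher collapse to the lexicographically smallest (d1, d2)
representative. Gaps are E(state) − E(reference) with the reference
being the lowest minimum's state; duplicate labels are reported with a
warning and the lower-energy minimum is used. In the workflow, labelled
scans additionally get Boltzmann populations over *all* grid points,
each point assigned to the basin of its nearest labelled minimum — a
deliberate proxy for classifying every scan structure geometrically,
which would require the per-point geometries.

## Cross-method energetics

E_rel is referenced per method and globally across states (the
near-zero closed-state relative energies across methods imply a shared
per-method minimum; a per-state reference is available by filtering
the table first). Box statistics follow the Tukey convention:
linear-interpolation quartiles, whiskers at the most extreme points
within 1.5 × IQR, the rest listed as outliers. Agreement against a
reference method reports per-state median absolute differences of
E_rel and Spearman rank correlations over shared frame ids (missing,
not zero, when undefined).

## Synthetic fixtures

The generators define the conditions under which the package is
validated:

* **Ideal cages.** Planar idealized ligands (regular 1.39 Å hexagons,
  1.43/1.20 Å arm bonds, 2.02 Å Pd–N) are placed at azimuths
  0/90/180/270° about the Pd–Pd axis; the one free arm-tilt parameter
  is solved numerically so both pyridine nitrogens coordinate the axial
  Pd sites exactly. Angle targets are realized by hinging each central
  ring about the vertical chord through its two arm-bearing carbons:
  the adjacent-pair plane angle is then exactly 90° − |Δβ| for hinge
  angles β, so a four-target pattern is feasible iff the deficits
  90° − θ_k admit a signed cyclic sum of zero. Patterns violating that
  constraint (e.g. exactly one non-90° pair) are geometrically
  impossible for any rigid four-plane cycle and raise an error; the
  semiopen/open fixtures therefore use two equal off-90° pairs. The
  geometry parameters are textbook values, not fitted; only the graph
  topology and the ring-plane angles matter downstream, and the
  resulting Pd–Pd separation (~16 Å) is longer than in a relaxed cage.
* **Trajectories.** A three-state Markov chain (default
  P = 0.9·I + 0.1·1πᵀ with π = (0.70, 0.20, 0.10) — mostly closed with
  sticky excursions, emulating a DMSO-like run) drives per-frame θ_min
  draws from state Gaussians (means 88/65/45°, σ = 3°, truncated to
  [1°, 90°]); each frame's geometry is built at pattern (t, 90, 90, t).
  Markov switching is a surrogate for MD kinetics — no transition rates
  are claimed — and statistical checks use the Markov-chain CLT
  standard error computed from the fundamental matrix, not the iid
  binomial formula.
* **Scan surfaces.** Sums of Gaussian wells on a 15 × 15 grid; with
  wells separated by more than three widths the analytic minima are the
  centers (residual tail cross-talk ~1e-5 kcal/mol). The default wells
  place the semiopen and open minima 2.76 and 4.85 kcal/mol above the
  closed one.
* **Charge tables.** Class means plus Gaussian within-class noise; the
  residual to the target net charge (+4 for the assembled cage) is
  spread uniformly so the sum is exact while class means stay
  recoverable to their standard error.

All generators are deterministic under a fixed seed (byte-identical
output files, tested).

What passing these fixtures does **not** show: the generators contain
no solvent, no counterions, no thermal geometric distortion beyond the
hinge angle, harmonic-free ring planarity, and Markov rather than
physical kinetics. Success on them validates the analysis chain's
correctness and determinism, not force-field quality or real residence
times; published MD population percentages and DFT gap values require
the original trajectories and quantum-chemical energies and are out of
reach at desk scale (the test suite substitutes the property checks
listed below).

## Numerical choices and problem sizes

Best-fit planes reject rings whose second singular value is below
1e-8 of the first (collinear input). Azimuthal adjacency raises a
degeneracy error when two ring centroids coincide in azimuth within
1e-9 rad. The classifier's boundary convention is closed-right
(θ_min = 55° is open, 80° is semiopen); histogram identity tests avoid
exact-boundary samples, which numpy's right-open binning would assign
to the upper state. Default suite problem sizes — 400–500-frame
geometry trajectories, a 100 000-step label-level Markov chain, 50
random oracle surfaces — were chosen so the whole suite runs in a few
seconds while keeping Monte-Carlo bands (3 SE) meaningful.

## Known limitations

* Topology detection assumes the lantern architecture; other cage
  stoichiometries (Pd3L6, Pd4L8) are rejected rather than handled.
* Ragged-scan minima depend on the symmetrized kNN neighbourhood, which
  is a convention, not a theorem; rectangular grids are exact.
* The mol2 charge substitution rewrites only the last whitespace field
  of ATOM records and assumes charges are that final column.
* KDE densities are renormalized over [0°, 90°] rather than
  boundary-corrected; near-boundary modes (closed state at 90°) are
  slightly flattened relative to the histogram estimator.
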