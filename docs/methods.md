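# Methods

## Scientific setting

Angiogenin (ANG) is a 123-residue RNase-superfamily protein whose
angiogenic function requires two separable activities: ribonucleolytic
activity, conferred by the catalytic triad His13/Lys40/His114, and nuclear
translocation, driven by the surface nuclear localization signal (NLS)
whose core is the arginine triplet ³¹RRR³³.  Several ALS-associated ANG
missense variants (K17I, S28N, P112L, V113I) and two additional mutants
(L35P, K60E) lose one or both activities.  Molecular-dynamics studies of
these variants explain the losses through three trajectory observables,
all of which this package computes from multi-model PDB trajectories:

1. **His114 side-chain switching.**  The HA-CA-CB-CG dihedral of His114
   occupies a native state centered at −80° in the wild type and an
   altered state at −179° in loss-of-function variants — a 99° switch.
   The fraction of simulation time spent in the altered state tracks the
   degree of ribonucleolytic impairment.
2. **Hydrogen-bond networks.**  Residues linked by donor–acceptor
   contacts at ≤ 3.2 Å form a graph in which the shortest path from the
   mutation site to His114 describes how a distal substitution reaches
   the catalytic site.  Paths are scored by the sum of per-step
   hydrogen-bond occupancies (percent of frames bonded); for the K17I
   path this sum is 280.39 versus 187.99 for the wild type, with the
   His114–Ala106 and Ala106–Val113 steps 50.88 and 38.48 percentage
   points higher.
3. **NLS packing.**  The solvent-accessible surface area (SASA) of
   ³¹RRR³³, averaged over the final 10 ns, separates translocating
   variants (totals ≳ 385 Å²) from non-translocating ones (≲ 15 Å²) by
   more than 350 Å².  The volume of the sphere whose diameter is the
   widest atom–atom distance across the triplet corroborates the same
   open/closed distinction.

## Hydrogen-bond criterion

A bond is scored purely on the donor-heavy-atom → acceptor distance with
an inclusive 3.2 Å cutoff.  Many MD analysis tools add a D–H···A angle
term; an optional angle filter exists (`HBondCriterion.angle_min`) but is
off by default so that the stated distance-only criterion is what the
occupancies mean.  Donor/acceptor roles come from a residue+atom-name
table covering standard side chains, with an element fallback (N → donor,
O → acceptor); atoms with no role are skipped silently.  Occupancy is
reported at two granularities: per atom pair, and per residue pair (the
percentage of frames with ≥ 1 bonded atom pair, which is therefore ≥ any
of its atom-pair values).  Path sums use residue-pair occupancies.

## Network analysis

Residue graphs are undirected and unweighted; shortest paths are
minimum-hop (breadth-first via networkx), because the underlying
adjacency analysis is binary — occupancy enters only as a post-hoc path
score.  All tied minimum-hop paths are returned, sorted lexicographically
by residue sequence, and the report records the multiplicity.  The
extension of a path beyond His114 to Ala106 and Val113 is an explicit
parameter (`path_extension`), applied only where those edges exist, since
including the two post-catalytic residues is an analysis choice rather
than a graph property.  Graphs can be built from a single frame
("snapshot" mode, edges labelled with the measured bond length) or from
occupancies with a minimum-occupancy threshold; the pipeline uses the
threshold mode at 0%, i.e. any pair bonded in at least one frame.

## Dihedral states

Angles follow the IUPAC sign convention, range (−180°, 180°].  Frames are
labelled native/altered when the circular distance to the corresponding
center (−80°/−179°) is within a 45° tolerance; the nearer center wins
when both qualify, exact ties go native, and everything else is
unassigned.  45° splits the 99° separation without overlap; both centers
and the tolerance are configurable.  The altered-state fraction is taken
over assigned frames only, and switch events are native↔altered label
changes ignoring unassigned gaps.

## SASA

Shrake–Rupley quadrature: each atom's sphere is expanded by the probe
radius (default 1.4 Å, water), covered with a deterministic golden-section
spiral of `n_sphere_points` (default 960) test points — no RNG, so values
are bit-reproducible — and the accessible fraction is the share of points
outside every other atom's expanded sphere.  Occluders are all atoms of
the frame, not only the selection.  Van der Waals radii are Bondi values;
unknown elements fall back to 1.70 Å with a logged warning.  At 960
points, doubling the quadrature moves any atom by less than 0.5% of its
expanded-sphere area (the discretization scale of the method); heavily
occluded atoms can show a larger *relative* change because their absolute
area is small.  Windowed means use half-open windows of `window_ns`
(default 10 ns) over the frame timestamps, with the final window
supplying the classification quantity; a window longer than the
trajectory degrades to a single window with a warning.

## Enclosing sphere

The reported volume uses the diameter-of-maximum-pairwise-distance
construction over all atoms of the NLS selection — the most conservative
reading of "the maximum distance between the extremities of R31 and R33",
since the exact atom set meant by "extremities" is not stated.  An exact
minimal enclosing sphere (Welzl's algorithm) is available as a cross-check
mode; its radius can exceed half the maximum pairwise distance by up to
√(3/2) (Jung's bound in 3D), so the diameter-mode volume is a lower
bound.

## Classification

* Ribonucleolytic: `lost` when the altered fraction is ≥ 0.5, `partial`
  in [0.1, 0.5), else `retained`.  The source studies rank variants only
  qualitatively (severe/mild/insignificant loss by how often the dihedral
  leaves −80°); the 0.1/0.5 cutpoints are this package's convention to
  reproduce that ordering, and are exposed in `Thresholds`.
* Translocation: `lost` when the final-window NLS SASA total is ≤ 15 Å²,
  `retained` at ≥ 385 Å², else `indeterminate`.  The sphere volume is
  recorded as corroborating evidence, not an independent trigger: the
  published volume bound of 804 Å³ is contradicted by the tabulated
  V113I mean (804.55 Å³), whereas the SASA bounds are unambiguous.
* In the qualitative per-variant grid, "ribonucleolytically impaired"
  groups `lost` and `partial`: L35P's altered fraction (≈ 0.4 under the
  default scenario) falls in the partial band while its reported loss is
  severe; the grid therefore distinguishes impaired from retained rather
  than lost from partial, except for K17I where the strict `lost` verdict
  is asserted.

## Synthetic trajectories

The generator emulates only the three observables above, at labelled
sites placed far apart so they cannot interact:

* **Dihedral quad** (residue 114: HA, CA, CB, CG with ideal internal
  coordinates): per-frame states are drawn from a two-state Markov chain
  whose stationary altered fraction matches the scenario and whose mean
  altered dwell is 50 frames, so switching happens in realistic segments
  rather than frame-by-frame coin flips; Gaussian noise (sd 10°) is added
  to the state center and the CG atom is rebuilt by NeRF placement.
* **Hydrogen-bond pairs**: one donor (N) / acceptor (O) atom pair per
  labelled residue pair, at 2.9 Å when bonded and 4.5 Å when not —
  safely inside/outside the 3.2 Å cutoff — with i.i.d. Bernoulli bond
  indicators at the target occupancy.
* **NLS triplet**: three Arg-like residues (Cα + 7 side-chain atoms)
  extending radially from a common centroid when open; when closed, all
  atoms contract toward the centroid (factor 0.18) and a quasi-uniform
  shell of 128 occluding carbons at 5 Å radius seals the assembly, which
  drives the Shrake–Rupley SASA to essentially zero without modelling
  real folding.  The same shell is parked 60 Å away in open frames
  (topology must be constant across frames).

Named scenarios fix these knobs per variant: altered fractions 0 (WT,
K60E, V113I), 0.8 (K17I), 0.5 (S28N), 0.4 (L35P), 0.2 (P112L); NLS open
for WT/K17I/K60E and collapsing after 10 ns (2 ns for V113I) for the
rest; per-pair occupancies along each variant's published path, and the
Thr44–Thr80 / Asp116–Ser118 occupancies for every variant.  The published
time traces exist only graphically, so the altered fractions — and the
mutation-site chains of the variants whose paths are not tabulated
(S28N, P112L, K60E, V113I) — are qualitative stand-ins, not fitted
values.  Default problem size is 2000 frames at 25 ps (the 50 ns study
window at a desk-scale frame count; the original analyses sampled every
1 ps, and the frame stride is a configuration parameter throughout).

What passing tests on this generator do show: the analysis stack measures
what it claims (occupancies, state fractions, SASA separations recovered
against known truth) and the classifier reproduces the qualitative
per-variant outcome table.  What they do not show: anything about real
force-field dynamics, absolute SASA or volume magnitudes for real ANG
(the synthetic open-state NLS is more exposed than a real protein
surface), or transferability of the 0.1/0.5 dihedral cutpoints beyond
these scenarios.

## Numerical choices and degenerate inputs

Kabsch superposition uses SVD with a determinant correction so the
rotation is always proper; < 3 points or collinear point sets are
rejected.  RMSF aligns every frame to frame 0 on the selection by default
(`fit=False` for pre-aligned input).  B-factor conversion is
B = (8π²/3)·RMSF².  Dihedrals reject coincident consecutive points and
collinear triples.  Selection syntax errors name the offending token;
empty selections are valid results, not errors.  PDB coordinates that
cannot fit the 8.3 fixed-width column raise before writing.  Occupancy
tables store residue pairs symmetrically; querying an absent pair returns
0 rather than raising, while path sums over a missing step *do* raise and
name the pair.

## Known limitations

* Multi-model PDB is the only trajectory format; there are no timestamps
  in the format, so frame times are `i × frame_dt`.
* The donor/acceptor table covers standard amino-acid atoms only;
  exotic protonation states and ligands rely on the element fallback.
* The enclosing-sphere "diameter" construction underestimates the true
  minimal enclosing sphere for non-degenerate point sets (by design —
  it mirrors the published construction; use `mode="welzl"` for the
  exact sphere).
* Classifier cutpoints are calibrated to this variant panel's reported
  qualitative outcomes, not to any biophysical first principle.
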