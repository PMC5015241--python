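# Methods

## Geometric model

A molecule is a set of weighted points: atom *i* contributes its center
*pᵢ* (Å) and weight *wᵢ = (rᵢ + r_probe)²* (Å²), the squared radius of the
solvent-expanded sphere.  Radii come from the Bondi table (unknown elements
fall back to 1.7 Å, configurable); the probe radius defaults to 1.4 Å
(water).  Hydrogens and waters are excluded: molecular alpha-shape models
conventionally use heavy atoms, and hydrogens added for dynamics would
otherwise dominate the surface.

The regular (weighted Delaunay) triangulation is computed via the classical
lifting map *p ↦ (p, |p|² − w)* and the lower convex hull in 4-D
(`scipy.spatial.ConvexHull`).  The alpha complex at filtration value α
keeps every tetrahedron whose squared orthoradius (the squared radius of
the ball orthogonal, in power distance, to its four weighted vertices) is
at most α.  The default α = 0 is the "zero-shape" of the solvent-expanded
molecule — the standard alpha-shape model of a molecular surface; it is
exposed as a parameter for sensitivity analyses.

Classification of one frame's complex:

* **member tetrahedra** — squared orthoradius ≤ α; they are the molecule's
  body.
* **boundary triangles** — faces incident to exactly one member
  tetrahedron; their vertices are the **surface atoms**.
* **singular atoms** — triangulation vertices with no incident member
  tetrahedron (isolated atoms, thin protrusions); also surface.
* **hidden atoms** — weighted points swallowed by a neighbour's power cell;
  they are not vertices of the triangulation and are treated as buried.

### Degeneracy handling

Lattice fixtures (and crystallographic coordinates generally) contain many
cospherical point subsets, for which the lifted lower hull is not
simplicial.  Ties are resolved by a deterministic
symbolic-perturbation-style rule: the lifted heights receive a lexicographic
nudge of 10⁻⁹ × (height scale) × (index + 1) before the hull is taken, so
the triangulation is simplicial and conforming, while membership tests keep
the exact weights.  Perturbed cospherical-and-coplanar clusters yield
zero-volume "gasket" tetrahedra; these are retained (they glue
differently-split square faces, keeping the boundary watertight) and are
assigned the limit filtration value of their common orthoball via a
consistent least-squares solve.  They subtend zero solid angle, so
curvature is unaffected.  If the whole lifted set is co-hyperplanar (all
weighted points on one common orthosphere), every triangulation is regular
and the plain Delaunay triangulation is used.  Inputs that remain
degenerate (coplanar point sets) raise an error, or — in the
trajectory-processing path — are retried once with seeded 10⁻⁶ Å jitter.

## Solid-angle curvature

For a surface atom, Ω_int is the solid angle subtended at its center by its
incident member tetrahedra (Van Oosterom–Strackee atan2 formula per
tetrahedron; triangles coplanar with the apex contribute 0).  The curvature
score is

    SA = 1 − Ω_int / 2π,  clamped to [−1, 1].

An isolated atom sees no interior (SA = +1); a flat local surface sees a
half-space (SA = 0); a pocket-floor atom sees more (SA < 0); a fully buried
atom would see 4π (SA = −1).  Non-surface atoms are assigned SA = 0 with a
false surface flag.  Floating-point sums beyond ±(1 + 10⁻⁶) raise an
internal-consistency error rather than being clamped silently.

For a trajectory, the complex of **all** protein heavy atoms is rebuilt at
every frame (curvature at the site depends on the surrounding protein, not
only on site atoms), and only the binding-site atoms are scored.  The bound
drug is excluded from the shape: pocket curvature is a property of the
protein, whose complementarity to the drug is the quantity of interest.
This is configurable by simply including ligand atoms in the topology.

The analytic SA is validated against an independent Monte Carlo oracle
(uniform directions on a small sphere around the atom, containment in
member tetrahedra; Ω_int ≈ 4π × hit fraction) to within 0.02 at 10⁵
samples, and against closed forms (octant π/2; regular-tetrahedron vertex
arccos 23/27).

## Binding site

The site is defined once on a reference structure — either an explicit
(chain, residue id) list or every residue with a heavy atom within a cutoff
(default 5.0 Å, a common heavy-atom contact criterion) of any ligand heavy
atom — and then re-applied *by residue key* to every frame and every
mutant, mirroring the convention that all variants of a protein are scored
at the reference pocket.

## Knob levels and classification

The average convex degree of an SA vector at threshold t is the mean SA
over atoms with SA > t (strictly; convexity is the open interval (0, 1]).
The threshold removes near-zero values that would otherwise swamp the mean;
the conventional set {0, 0.01, 0.02} is exposed, with 0.01 the default (it
gives the best grouping).  An empty convex set yields 0 and a logged
warning.  Per-mutant knob level: method A averages per-frame convex
degrees; method B takes the convex degree of the per-atom trajectory mean
("average site").  For one frame, or frame-constant profiles, A = B (up to
mean round-off).

The classifier is a decision stump on the knob level: candidate boundaries
are the midpoints of consecutive distinct training values plus ±∞, both
orientations are scored, and the accuracy-maximizing boundary is kept.
Ties prefer the Response-below orientation (responding pockets sit at lower
knob levels) and then the smallest boundary; a value exactly on the
boundary goes to the Response side.  Whether the original analysis chose
its boundary by optimization or inspection is not documented; optimization
is implemented because it is reproducible and at least as accurate.
Clinical response levels (1 complete response … 4 progressive disease) are
merged to Response (RL ≤ 2) vs No-response (RL ≥ 3); patient-level tables
are aggregated per mutant by the lower median (even-count ties round down).

## Synthetic data

The generator replaces two heavyweight upstream stages (mutant structure
modelling and solvated molecular dynamics) with the minimal objects that
exercise the geometry:

* **Pocket**: an 8×8×4 cubic lattice of carbon-like pseudo-atoms
  (radius 1.7 Å) at 3.4 Å spacing with a hemispherical cavity (radius
  6.0 Å) carved from the top face.  The spacing is chosen below the
  closure bound 2(r + r_probe)/√3 ≈ 3.58 Å, so every lattice-cell
  tetrahedron (squared circumradius 3a²/4 = 8.67 Å²) is a member at α = 0
  and the slab interior is solid; wider spacings would leave an
  all-singular point cloud with no surface.
* **Knobs**: `knob_count` cavity-wall atoms displaced `knob_height` Å
  toward the cavity centre.  Positions are a seeded greedy pick preferring
  pairwise separation ≥ 1.5 spacings — adjacent knobs shield each other and
  never become convex.  Displaced knobs become individually convex
  (SA > 0) from about 3.2 Å of protrusion, the height used by the
  convex-knob fixtures; lower knobs still raise the site's convex degree
  collectively, which is the regime the cohort generator uses.
* **Trajectory**: frame 0 is the base structure; subsequent frames add
  i.i.d. Gaussian noise per coordinate (default 0.3 Å, large enough to vary
  SA values while keeping the alpha-shape topology mostly stable).  This
  emulates thermal fluctuation amplitudes only — no inertia, correlation
  times, force field, or conformational transitions.
* **Cohort**: all members share one fixed knob placement (mutant cohorts of
  one protein share its pocket scaffold); the Response group (RL 1, 2
  round-robin) gets base knob height 1.6 Å, the No-response group (RL 3, 4)
  is raised by `effect / 0.0266` Å, where 0.0266 per Å is the measured
  sensitivity of the method-A knob level to knob height on this scaffold
  (6 knobs, threshold 0.01, 0.3 Å jitter, near-linear for h ∈ [1.6,
  3.6] Å).  Per-member variability is knob-height jitter scaled to a target
  knob-level SD (default 0.010) plus the thermal frame noise.  Default
  effect 0.05 therefore separates the groups by ≈ 5 within-group SDs.

What passing tests on these fixtures do **not** show: robustness to real
side-chain packing, induced fit, correlated backbone motion, crystallography
artefacts, or binding sites whose residues change identity between mutants.
They do show that the geometric machinery — triangulation, surface
classification, curvature, knob statistics, boundary fitting — is correct
and that a planted convexity difference of realistic magnitude survives the
whole pipeline.

## Problem sizes and numerics

Default analyses rebuild the alpha complex of ~240 atoms for 50 frames per
mutant and 30 mutants per cohort (≈ 15 s per cohort on one CPU);
the acceptance script repeats this for five cohorts.  Power-distance
predicates use a relative tolerance of 10⁻⁹; membership uses
r² ≤ α + 10⁻⁹(1 + |α|).  All generators are pure functions of their
specs (seeds included), so pipeline reruns are byte-identical apart from
the configuration echo, which records the output directory.

## Known limitations

* The solid-angle curvature definition (SA = 1 − Ω_int/2π over member
  tetrahedra) matches the documented range, sign convention and limiting
  cases of the quantity it models, but other definitions with the same
  limits exist (e.g. over a fixed-radius neighbourhood ball).
* At α = 0 a protruding atom chain can be singular (SA = +1 exactly),
  which makes the convex-degree statistics sensitive to knobs detaching
  from the surface at large protrusions; the cohort generator stays in the
  attached regime.
* The threshold classifier is intentionally univariate; no cross-validation
  is built in, and the reported accuracy is a training accuracy, as in the
  protocol it reproduces.
* mmCIF and binary trajectory formats (DCD/XTC) are out of scope; adapters
  can convert to multi-model PDB.
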