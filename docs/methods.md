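# Methods

This note documents the models and numerical choices behind alphapocket:
what each stage assumes, which parameters matter, what the synthetic
generators do and do not emulate, and where the design was genuinely
open.

## Geometric model

Atoms are weighted points `(c_i, w_i)` with `w_i` the squared effective
radius. Two radius conventions coexist:

* **accessible** (default): `w_i = (r_vdw,i + r_probe)^2`. The union of
  these expanded balls is the space a water-sized probe cannot enter;
  pockets detected on it correspond to solvent-accessible cavities.
* **molecular**: `w_i = r_vdw,i^2`, the bare molecular body.

Detection and flow run on one triangulation per mode (accessible by
default). Molecular volume is then measured against the *vdW* balls
inside the detected tetrahedra, and solvent-accessible area against the
*expanded* balls — so MV quantifies empty space while SAA quantifies
probe-accessible wall surface for the same pocket. The two numbers use
different ball sets by design; the convention is recorded in every run
report.

### Regular triangulation

The regular (power/weighted Delaunay) triangulation is obtained by the
classical lifting: each point maps to `(x, y, z, |x|^2 − w)` in 4-D and
the lower convex hull (facets whose outward normal points down in the
4th coordinate) projects to the triangulation. Qhull computes the hull;
no exact predicates are used. Instead:

* A deterministic jitter of magnitude 1e−6 Å, drawn from a generator
  seeded by `jitter_seed`, breaks cospherical/coplanar degeneracies.
  This perturbs coordinates by far less than any physically meaningful
  scale, and invariant tests (hull tiling to 1e−6 relative, equivalence
  with a brute-force empty-circumsphere oracle at equal weights) guard
  correctness.
* Inputs whose third singular value after centering is below 1e−4 Å are
  rejected as coplanar rather than triangulated into slivers.
* Points hidden in the power diagram ("redundant": a tiny ball inside a
  large one) carry no tetrahedra and are excluded from the complex.

Orthocenters and sizes solve the linear system "equal power to all
vertices"; for sub-simplices the solve is restricted to the affine hull.
Size ≤ 0 means the simplex's orthosphere is imaginary, i.e. the simplex
is covered by the union of balls.

### Dual complex at α = 0

A simplex belongs to the complex iff its size is ≤ 0 and it is
unattached, or it is a face of a member. α is fixed at zero — the dual
complex of the union of balls — and never varied. Attachment is tested
against the vertices of cofacing tetrahedra with a tolerance of 1e−12 on
the power comparison; tests verify the result against a brute-force
evaluation that checks *all* points, on random weighted instances.

### Discrete flow

Empty (non-member) tetrahedra drain to infinity through *obtuse* facets:
facet F of tetrahedron t is obtuse when t's orthocenter lies strictly on
the far side of F's plane from the opposite vertex (an orthocenter
exactly on the plane — measure zero after jitter — is non-obtuse). A
tetrahedron escapes if some obtuse facet that is not a dual-complex
triangle borders the hull exterior or an already-escaped tetrahedron.
The iteration is a FIFO queue seeded at the hull boundary; because
escape is monotone the fixpoint is order-independent, which a
randomized-sweep reimplementation asserts in the tests.

Trapped tetrahedra are grouped into connected components across shared
non-dual facets. A component with at least one non-dual facet onto
escaped space (or the exterior) is a **pocket** and those facets,
grouped into edge-connected patches, are its **mouths** (`n_entrances` =
number of patches); a component with none is a **void**. Pockets with
MV below `min_pocket_volume` (default 10 Å³) are dropped to suppress
sliver artifacts.

### Measurement

* **MV** — stratified Monte Carlo: samples are allocated to tetrahedra
  proportionally to volume (largest-remainder rounding, ≥ 1 each), drawn
  uniformly via Dirichlet barycentric weights, and tested against all
  vdW balls. The estimate carries a binomial standard error; default
  1e5 samples per pocket (SE well under 1 % of a ~1000 Å³ pocket), seeded
  and deterministic. An analytic inclusion–exclusion volume would be a
  welcome extension; the rejection-sampling oracle in the tests defines
  correctness.
* **SAA** — each wall atom's expanded sphere is sampled with a
  deterministic Fibonacci lattice (default 256 points/atom); a point
  counts iff no other expanded ball covers it and it lies inside the
  pocket's tetrahedra. Whole-structure per-atom SASA uses the same
  sampler without the pocket scope and is cross-checked in the tests
  against the closed-form two-sphere solution and biotite's
  implementation.

## Ensemble statistics

* **Superposition** is Kabsch least squares with a reflection guard
  (det = +1 enforced); pairwise RMSD matrices use a batched SVD over all
  frame pairs, which leaves a numerical floor of ~1e−8 Å on identical
  frames.
* **Clustering**: the frame set is refined through the descending cutoff
  schedule (default 3.5, 3.0, 2.5, 2.0, 1.5 Å); at each cutoff every
  current group is split by complete-linkage agglomeration at that
  threshold. The procedure is deterministic and
  permutation-equivariant. The **representative** of a subclass is the
  frame whose mean RMSD to co-members is closest to the subclass's mean
  pairwise RMSD (ties → lowest frame index) — the "middle RMSD" frame.
* **RMSF** is computed against the ensemble mean structure, iterated
  twice (mean → fit → new mean), selection default Cα. For an atom with
  isotropic per-coordinate Gaussian displacement σ the expected RMSF is
  σ√3. Note that superposing frames onto a noisy mean transfers variance
  between residues (low-σ residues inflate when neighbors are highly
  mobile); recovery tests therefore disable superposition, which is
  exact for the generator's regime of no rigid-body motion. With real
  trajectories, superposition should stay on.
* **Segmentation**: residues above the RMSF cutoff (default 3 Å) are
  "high", runs of equal class become segments, and runs shorter than
  `min_length` merge into the neighbor with the closer mean RMSF (ties →
  preceding segment) until stable. Labels S1…Sk follow sequence order.

## Pocket dynamics

Per-frame detection re-runs the full geometric pipeline with seed
`base_seed + frame`. The main pocket starts as the largest-MV pocket of
the first frame that has one; in later frames the candidate (voids
excluded by default) with the highest wall-residue Jaccard overlap to
the last tracked state is accepted if the overlap reaches `jaccard_min`
(default 0.3; ties → larger MV), otherwise the frame is ABSENT and
tracking resumes against the last non-absent state. Residue-set overlap
was chosen over spatial overlap because it is robust to re-triangulation
noise between frames.

φ counts, per residue, the frames in which it lines the tracked pocket,
divided by n. ABSENT frames contribute p = 0 and are included in n by
default — φ then measures joint openness × membership over the whole
trajectory; a switch excludes them, making φ conditional on the pocket
being open, and another widens membership to any detected pocket. p_sum
and n are integers, so φ·n is always exact.

## Surface characterization

* Residues are **pocket** if they line any detected cavity wall, else
  **surface** if relative accessibility (residue SASA over its
  theoretical maximum ASA, Tien-style reference values) reaches 0.05,
  else **interior**. The 0.05 threshold is a conventional choice; no
  canonical value exists.
* The electrostatic patch potential is deliberately a screened
  Coulomb surrogate, `V(x) = Σ q_i / (4 r_i · r_i)` with a
  distance-dependent dielectric ε(r) = 4r, dimensionless. It preserves
  sign, antisymmetry and linearity — enough to characterize a patch as
  positive or negative — and replaces a full Poisson–Boltzmann solve,
  which is out of scope. Charges: Asp/Glu −1 (carboxylate midpoint),
  Lys/Arg +1 (terminal N / guanidinium C), His 0; sites fall back to the
  side-chain centroid when named atoms are absent.
* Triad search (e.g. Arg–Gly–Asp patches) measures pairwise
  side-chain-centroid distances (Cα for Gly) against a 12 Å cutoff — a
  generous "spatially clustered" criterion; no deduplication, hits
  sorted by maximal pairwise distance.
* Variant strings use 1-letter codes with author numbering; wild-type
  mismatches and unparseable strings become per-record error rows, never
  exceptions. Cross-species numbering offsets are the caller's
  responsibility.

## Synthetic data: what it emulates, what it does not

The generators produce the statistical structure the analysis assumes,
with planted ground truth:

* **cup / cavity** — two concentric Fibonacci-lattice shells (default
  inner radius 8 Å, atom radius 1.8 Å, spacing 2.6 Å < 2r so the shell
  is sealed); the cup removes a cone (default 15 % of the solid angle)
  as the mouth. Truth records the inner-shell wall atoms, the deep
  ("core") half of the wall, and the outer-shell back face.
* **shallow / blob** — convex lattice balls, the former with a wide
  spherical bite whose depth (2 Å) is well under the probe-expanded
  radius, so it drains.
* **perturbed trajectories** — i.i.d. isotropic Gaussian displacement
  per atom with per-residue σ; 300 frames at 100 ps spacing (a 30 ns
  span) by default.
* **gated trajectories** — a plug pseudo-residue of lattice atoms seals
  the cup's mouth in closed frames and is displaced 15 Å outward in open
  frames; open frames are drawn without replacement to hit
  round(f·n) exactly (a Bernoulli mode exists for stochastic checks).
* **multi-state ensembles** — k reference conformations made by a hinge
  motion of the z > 0 half. A single hinge axis with growing angles
  cannot separate six states by ≥ 6 Å RMSD (the rotation wraps around
  before the pairwise minimum reaches the target), so each state uses
  its own in-plane hinge axis, fanned across the xy-plane, with one
  common angle grown until every pair meets the target; larger base
  structures extend the reachable separation.

These fixtures are *not* physical: displacements are i.i.d. (no
covariance structure, no bonded constraints), pseudo-residues have one
atom (or four, for selection tests), there is no solvent and no
force field. Passing tests therefore demonstrates that the geometric and
statistical machinery recovers planted truth under the stated noise
model — not that any particular protein's pocket volumes or occupancy
values are reproduced. Real MD trajectories bring correlated motion,
side-chain rearrangement and conformational drift that the generator
deliberately omits.

## Numerical details and degenerate inputs

* All randomness flows from explicit seeds; the CLI derives per-stage
  seeds from one base seed via a stage-name hash. Identical config +
  seed gives byte-identical outputs.
* Tolerances: attachment/power comparisons 1e−12; point-in-tetrahedron
  barycentric tests 1e−9; coplanarity rejection 1e−4 Å; hull-tiling
  verification 1e−6 relative.
* Four non-degenerate points are triangulated directly (the 4-D hull
  would be degenerate); fewer than four, or a coplanar set, is an error.
* Alternate locations resolve to the highest occupancy (ties → first in
  file); waters, non-protein heteroatoms and hydrogens are excluded by
  default, with flags to retain each. Unknown elements take the default
  radius (1.70 Å) with a warning.
* PDB numeric columns are validated before parsing so malformed
  coordinate fields fail loudly with a line number instead of being
  silently truncated.

## Known limitations

* Volumes are Monte-Carlo estimates with standard errors, not analytic;
  areas use a fixed spherical lattice whose discretization error
  (~0.5 % at 256 points/atom, shrinking with more points) slightly
  breaks exact rotation invariance.
* No exact geometric predicates: pathological near-degenerate inputs
  beyond what the jitter handles could misclassify simplices.
* The clustering schedule operationalizes an under-specified refinement
  procedure; subclass counts on real trajectories depend on the cutoff
  schedule, which is exposed as configuration.
* Mouth patches are counted on the triangulation's boundary triangles;
  very wide mouths crossed by sliver facets can split into more than one
  patch.
* The potential surrogate ranks and signs patches; it produces no
  energies, units or pKa shifts.
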