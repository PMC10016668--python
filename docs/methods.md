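# Methods

This note documents the models, numerical choices and limitations behind
`castmetric`. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external measurements.

## The accuracy model

A surface comparison between two scans of nominally identical casts has
three stages, each with an explicit contract:

**Registration.** The test mesh is mapped into the reference frame by a
proper rigid motion (no scaling, no deformation) found by trimmed
point-to-surface ICP. A fixed uniform-area random sample of the test
surface (default 25,000 points, seeded) is projected onto the reference
surface; correspondences farther than the cutoff (default 2 mm, the same
value as the measurement tolerance) are discarded; the incremental
least-squares rigid motion is solved in closed form (Kabsch: SVD of the
cross-covariance with reflection correction, translation from centroids).
Iteration stops when the relative RMS improvement falls below 1e-6 or
after 100 iterations. Because each update is the exact minimiser for the
current correspondences, the RMS trace is non-increasing; the
`IcpResult` records it. A coarse initialisation (centroid + principal
axes, the four proper sign combinations scored by probe RMS — the arch's
anterior/posterior asymmetry makes the score decisive) precedes ICP and
can be disabled. The reference object is never moved.

**Trimming and measurement.** Both registered meshes are cut by one plane;
triangles crossing it are clipped exactly at the intersection. Measurement
points are the *trimmed test-mesh vertices* — the point count is therefore
a property of the test scan; at the generator's default density one
comparison yields ≈300,000 points. Each point's deviation is the exact
unsigned distance to the nearest point of the reference surface (face
interior, edge or vertex), signed positive when the point lies on the
outward-normal side of the nearest reference facet. Ties between facets
within 1e-12 mm resolve to the smaller face index; this makes the sign
deterministic, though at concave edges where two facets are genuinely
equidistant the sign is tie-dependent (the magnitude never is).
Deviations beyond the tolerance (default 2 mm) are discarded and counted.

**Summaries.** Signed deviations are quantile-trimmed — by default the
99/1 quantile, i.e. the `floor(0.01·n)` smallest and largest signed values
are removed, rank-based with stable ordering (so lower=0/upper=1 is the
identity). Statistics are then computed on absolute values: absolute mean,
RMSE = sqrt(mean(d²)), median, SD, min, max, all converted from mm to µm
at this reporting boundary only. RMSE ≥ absolute mean always
(power-mean inequality); the dataclass enforces it. An alternative
magnitude-ranked trim is available behind `trim_on_absolute`.

**Designs.** Trueness: each of a group's scans against the designated
reference object, aggregated as min/max/mean ± SD/median over the per-scan
absolute means (and RMSEs). A paired variant compares group B's replicate
i against group A's replicate i with A as the reference object (used for
the print-vs-intraoral pairing). Precision: all n(n−1)/2 unordered pairs
within a group, the lower-index scan acting as reference — 45
superimpositions for n = 10. The aggregation over pairs mirrors the
trueness row shape; this choice (mean ± SD over per-pair summaries) is the
package's own convention.

**Group comparison.** Both samples pass through a Shapiro–Wilk gate at
α = 0.05 (the gate's α is a package choice): both normal → t-test (paired
or independent); otherwise Mann–Whitney U (independent) or Wilcoxon
signed-rank (paired), all two-tailed. The p-value is multiplied by an
explicit Bonferroni factor (the family size is passed, never inferred; 3
for the digital-workflow trueness family) and capped at 1. Identical
paired samples return the conventional p = 1. A constant sample is not
rejected as non-normal (Shapiro–Wilk is undefined there).

## The synthetic arch

The generator stands in for physical casts and their scans. It builds a
watertight solid in a canonical frame (midline x = 0, anterior at maximal
y, base plate in z = 0): a parabolic arch centerline (default width 56 mm,
depth 42 mm), an occlusal ridge with one smooth Gaussian bump per tooth
(14 teeth, 6 mm high, 2.2 mm radius, stations equally spaced in arc
length), extruded to a flat base 8 mm below. A structured (u, v) grid
gives the occlusal surface; a mirrored grid the base; a wall strip closes
the solid. Construction is purely deterministic. The surface is *not*
anatomical — smooth bumps are enough to lock ICP rotationally and to
distinguish molar from anterior regions, which is all the analysis needs.

Closedness is deliberate: for an open, predominantly upward-facing sheet a
uniform normal offset is partially absorbed by the rigid best fit (the
area-mean normal is far from zero, so a translation lowers the RMS), which
would corrupt offset-recovery checks. Over a closed surface the integral
of the outward normal vanishes and a uniform inflation is rigid-orthogonal
to first order.

Deformation modes, applied in canonical-frame order (widening →
compression → noise → rigid misalignment), with exact ground truth per
mesh:

* **Molar widening** — transverse displacement `m · s(y) · sign(x)` with a
  smoothstep ramp s from 0 at the anterior midpoint to 1 at the posterior
  ends: the stitching-error signature of intraoral full-arch scans. Purely
  transverse, hence exactly invertible by −m.
* **Compression** — transverse coordinates scaled by a factor near 1 about
  the midline: polymerisation shrinkage narrowing a printed arch.
* **Surface noise** — independent zero-mean Gaussian displacement of each
  vertex along its (area-weighted) vertex normal: a line-of-sight scanner
  error model, not isotropic jitter.
* **Rigid misalignment** — a random proper rotation (uniform axis, bounded
  angle) plus bounded translation; ground truth stores the deformed
  canonical-frame vertices *before* the misalignment, so recovery checks
  can undo it exactly.

Per-mesh seeds derive from SHA-256 of (master seed, group name, replicate,
salt), so a study set is bit-reproducible and adding a group never changes
the other groups' meshes.

The default study plan emulates three scan workflows with magnitudes
chosen once so that group summaries land in the tens of µm, the scale at
which real cast studies report, with distinct separations between groups:
intraoral-like (widening 0.02 mm, noise SD 0.010 mm), print-like (the same
widening carried through the workflow, then compression 0.9985 — an
overshoot of the widening at the posterior ends — and noise SD 0.020 mm),
and gypsum-like (no systematic deformation, noise SD 0.050 mm).
Perturbation bounds default to ≤5°/3 mm. These synthetic summaries are
*scale* analogues of physical-cast measurements, not predictions of them:
the generator has no anatomy, no stitching simulation, no per-region error
structure beyond the single widening ramp, and noise that is iid per
vertex where real scanner error is spatially correlated. What the passing
tests show is that the *pipeline* — registration, measurement, trimming,
summaries, test logic — recovers known inputs at µm accuracy and
reproduces the qualitative structure (group ordering; opposite-signed
molar deviations between the intraoral and print stages; the print stage
deviating more from the reference than the intraoral stage while both
partially cancel). They cannot show that any physical workflow meets a
clinical threshold.

## Numerical choices

* **Closest-point queries** are exact, not approximate: a kd-tree over
  triangle centroids proposes candidates (k = 16), exact point-to-triangle
  distances (Ericson's barycentric-region algorithm; numba-jitted scalar
  kernel with an equivalent vectorised numpy fallback) rank them, and any
  query where `best + max_circumradius > k-th centroid distance` cannot
  exclude a closer triangle is re-resolved with widened candidate sets and
  finally a guaranteed ball search. Long or large triangles are bisected
  along their longest edge (index-internal only, mapped back to parent
  faces) until their centroid-to-corner radius is below twice the median,
  keeping the bound tight. Meshes under 64 pieces skip the tree entirely.
  Exactness is asserted against exhaustive search and an independent
  implementation on random meshes.
* **Welding**: STL is a triangle soup; vertices are merged on a grid of
  pitch 1e-6 mm (configurable), keeping first-occurrence coordinates so
  welding is idempotent; degenerate and duplicate faces are dropped and
  counted. Facet normals from files are never trusted — always recomputed
  from winding.
* **Quantile trim rank rule**: `floor(q·n)` with a 1e-9 epsilon guarding
  binary-float artifacts (e.g. (1−0.8)·5 = 0.999…); ties keep original
  order (stable argsort).
* **Trim plane default**: half the base height (z = 4 mm), cutting the
  *vertical walls* of the solid. Cutting through the shallow occlusal
  skirt instead would let a small normal offset displace the cut contour
  laterally by much more than the offset itself, inflating boundary
  deviations; wall cuts have no such artifact.
* **Degenerate inputs**: fewer than 3 or collinear correspondence pairs →
  `DegenerateGeometryError`; fewer than 3 correspondences within the ICP
  cutoff → `AlignmentError`; trimming away everything → `EmptyResultError`.
* **Units**: all geometry in mm; all reported statistics in µm, converted
  once at the summary boundary.

## Problem sizes

Synthetic density is a free parameter. Defaults: 600,000 total vertices
(occlusal grid + base plate), giving ≈315,000 retained measurement points
per comparison. The test suite and the acceptance script run most checks
at reduced sizes chosen as the package's own trade-off between resolution
and turnaround: 5,000–8,000-vertex meshes with 1,500–2,000 ICP samples for
replicated whole-study checks (each replicate = 9 trueness + 9 precision
superimpositions), 60,000 vertices with 10,000 ICP samples for the
constant-offset recovery (faceting error must sit well under 1 µm), and
one default-density comparison to confirm the measurement-point count.

## Known limitations

* Registration is rigid only — no scale or deformation compensation; a
  globally scaled test mesh will show its scale error as deviation.
* The sign convention at exactly equidistant concave edges follows the
  face-index tie-break and is not invariant under rotations of the input
  coordinates (magnitudes are).
* The ICP objective is non-convex; initialisation by principal axes
  assumes the arch's inertia axes are distinct, which holds for any
  realistic arch but not for synthetic near-symmetric solids.
* Precision aggregation treats the n(n−1)/2 pair summaries as exchangeable
  observations; they are correlated (each scan appears in n−1 pairs), so
  the aggregate SD understates sampling variance. The same convention is
  common in cast-accuracy reporting and is kept for comparability.
* `apply_scan_noise` displaces vertices independently; it models sensor
  noise amplitude, not spatially correlated stitching drift (the widening
  mode exists precisely because the latter dominates real intraoral
  full-arch error).
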