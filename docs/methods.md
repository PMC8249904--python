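# Methods

This note documents the estimators implemented in `sbci`, the numerical
choices behind them, and what the synthetic fixtures do and do not emulate.

## Domain and discretization

All connectomes live on Ω = S²_left ∪ S²_right, the two unit registration
spheres cortical hemispheres are inflated to.  An analysis grid is a pair of
triangulated sphere meshes plus a boolean mask removing medial-wall
vertices; every connectivity matrix is indexed by the masked-in vertices,
left hemisphere first.  Two quadrature schemes coexist:

* **vertex-lumped areas** (a third of each incident spherical-triangle solid
  angle) weight fields sampled at grid vertices — positive, mesh-exact
  (they sum to 4π to machine precision), first-order accurate;
* the **edge-midpoint triangle rule** (`SphereMesh.surface_integral`) is
  used when the integrand can be evaluated anywhere on the sphere; it is
  second-order and integrates a heat kernel with h = 0.002 on a level-5
  icosphere to ~1e-5, versus ~5e-3 for vertex lumping.

Analysis grids are built by greedy decimation of a full-resolution mesh:
repeatedly delete the vertex whose removal (with local convex-hull
retriangulation — for points on a sphere the hull is the spherical Delaunay
triangulation) moves the surface least, ties broken toward the lowest
index.  The error of a candidate removal is its exact point-to-triangle
distance to the retriangulated hole, and only the neighbors of a removed
vertex are re-scored (the removal error is local).  The symmetric Hausdorff
distance between full and decimated surfaces is estimated by dense
barycentric sampling (default 15-point lattice per triangle plus all
vertices) with exact point-to-triangle projection; the same estimator at
higher density is the oracle in the tests.  Retained vertices keep their
full-resolution coordinates and indices, so grid vertices stay identifiable
in the original mesh.  Whether the Hausdorff criterion should be evaluated
on the white surface or on the sphere is left to the caller: the function
decimates whatever mesh it is given.

## Structural connectivity

Streamline termini are snapped to the nearest full-resolution surface
vertex, carried to that vertex's registered spherical coordinate, and
tagged with the nearest hemisphere; termini farther than a configurable
distance from both surfaces drop their streamline (counted on the result).
The endpoint pair density is estimated with the product heat kernel

    ĈSC(x, y) = N⁻¹ Σᵢ ½ [f_h(x, xᵢ) f_h(y, yᵢ) + f_h(x, yᵢ) f_h(y, xᵢ)].

Design choices:

* **Symmetrization.**  Streamlines are unordered, so each contributes half
  its mass to both endpoint orderings; this makes ĈSC exactly symmetric.  A
  consequence worth knowing: in the h → ∞ limit a purely interhemispheric
  sample tends to (4π)⁻²/2 on each cross block (the two blocks share the
  mass), while same-hemisphere samples tend to (4π)⁻².  The synthetic
  ground-truth density uses the identical convention, so estimator and
  oracle agree.
* **Series truncation.**  The Legendre series is cut at the smallest M with
  (2M+3)·exp(−(M+1)(M+2)h) below `tail_tol` (default 1e-8; M ≈ 67 at
  h = 0.005).  Truncation can leave negative values of at most `tail_tol`;
  they are clipped to zero.
* **Diagonal.**  The KDE is positive at x = y but the connectome is defined
  with a zero diagonal; the diagonal is zeroed after evaluation and the
  matrix is *not* renormalized, so off-diagonal values keep their density
  scale.
* **Computation.**  Endpoints are optionally binned to the vertices of a
  fine "snap" mesh (a level-5 icosphere by default in the examples;
  half-spacing ~0.016 rad, well under the kernel scale √(2h)); the KDE then
  reduces to two dense kernel-matrix products against the occupied anchor
  vertices and a sparse pair-count matrix, block-diagonal by hemisphere.
* **Mass.**  ∫∫ ĈSC = 1 analytically before diagonal removal.  On the grid,
  vertex-area quadrature reproduces the mass to within a few percent; at
  the smallest bandwidth of the sweep (h = 0.002, kernel scale comparable to
  the level-3 grid spacing) the quadrature can overshoot 1 by up to ~0.5%
  depending on where the density mass sits relative to grid vertices.

The bandwidth is a dimensionless length² on the unit sphere; the study
sweep {0, 0.002, 0.005, 0.01, 0.02} is adopted as the default candidate
list, with h = 0 meaning the unsmoothed endpoint histogram (pair counts
binned to grid vertices, normalized by N and the receiving vertex areas so
the values remain densities).

## Functional connectivity

Confound removal is ordinary least squares of every vertex series on
[intercept | confounds], with rank-deficient confound tables reduced to an
independent column subset (warned).  The module accepts any confound table;
the conventional set (top WM/CSF components, six motion parameters, global
signal) is the caller's choice, not hard-coded.  The stated "partial
correlation controlling for confounds" is implemented as
residualize-then-Pearson, which is the construction the defining equation
actually describes.

Interpolation onto the grid uses the bi-weight kernel
w(d) ∝ (1 − (d/σ)²)² truncated at geodesic radius σ (truncated Gaussian
available), restricted to same-hemisphere vertices, with weights
renormalized to sum to one (Nadaraya–Watson), so constant signals are
preserved and the kernel's normalizing constant is irrelevant.  σ is in
radians; `fwhm_mm_to_radians` converts the conventional mm-FWHM on a
radius-100 registration sphere (5 mm FWHM ≈ 0.046 rad bandwidth for the
bi-weight).  Weights depend only on geometry and are assembled once as a
sparse matrix applied to all time points.  A grid vertex with no field
vertex within σ is an error naming the vertex — the signal that σ is too
small for the mesh resolution.  Grid FC is the Pearson correlation matrix
of the interpolated series with the diagonal forced to zero; constant
series get zeroed rows with a warning.

## Coupling measures

Surface integrals in all coupling definitions are discretized with the
vertex-area weights, which keeps values stable under mesh refinement; the
point s = x₀ is excluded from the inner products (both rows are zero there
by definition anyway).  The Fisher-z parcel average is area-weighted over
vertex pairs, excludes the zero diagonal pairs for within-parcel entries,
and clips |r| at 1 − 1e-7 before artanh.  The per-parcel discrete coupling
correlates off-diagonal SC and FC rows, excluding the self pair; a constant
row (a disconnected parcel) yields NaN with a warning rather than a fake
value.  All coupling values are clipped to [−1, 1] (they satisfy
Cauchy–Schwarz up to rounding).

## Reliability

The distance-based ICC uses squared Frobenius distances over all
measurement pairs: d̄²_ws averages same-subject pairs (all of them —
within- and between-session pairs of a subject are not distinguished),
d̄²_bs averages different-subject pairs.  The bootstrap resamples subjects
with replacement (sessions travel with the subject; distances between two
copies of the same subject count as between-copy pairs), reporting the
replicate median, the 75th−25th percentile range, and P(dICC < 0.5);
replicates with a single distinct subject are redrawn and tallied.  The
implementation precomputes per-subject-pair distance sums, making each
replicate a quadratic form in the multiplicity vector, so 10,000 replicates
cost milliseconds.  Node-wise reliability is the one-way random-effects
ICC(1,1) with the unbalanced-design correction k₀; sessions are treated as
exchangeable measurements, which is why the one-way form is used rather
than a two-way crossed-rater form.  Outlier handling is a generic
`exclude(subjects)` on the feature set rather than an automatic rule.

Bandwidth selection computes ĈSC per session per candidate h, tabulates the
dICC, and returns the argmax with ties to the smallest h.

## Group inference

Vertex-wise two-sample t-tests default to pooled variance (Welch by flag);
a vertex with zero variance in both groups records t = 0, p = 1.  Clusters
are connected components, under mesh-edge adjacency, of vertices with
two-sided p at or below the forming threshold (0.05).  Group labels are
permuted — distinct relabelings sampled without replacement, the observed
labeling always in the null set, full enumeration with a warning when fewer
than `n_perm` relabelings exist — and the maximal cluster size per
relabeling forms the null distribution.  The critical size is the smallest
size whose null exceedance probability is ≤ α, and every vertex in an
observed cluster at or above it is significant.  Cluster size is a vertex
count by default, or a steradian sum when vertex areas are supplied.  The
permutation loop is vectorized: group moments for a block of permutations
are two matrix products.

## Synthetic fixtures

* **Parcellations**: farthest-point seeds and nearest-seed assignment per
  hemisphere give geodesically convex, connected parcels of roughly equal
  size — a structural stand-in for anatomical atlases (merging them via
  `Parcellation.merge` emulates lobar groupings).
* **BOLD**: exact block covariance (r_within inside parcels, r_between
  across, unit variances) built from shared/parcel/private Gaussian
  factors; positive definite iff 0 ≤ r_between ≤ r_within < 1, enforced
  with the offending eigenvalue in the message.  Defaults r_within = 0.6,
  r_between = 0.1, T = 1200 — a block contrast and run length typical of
  resting-state data.  No hemodynamic convolution, autocorrelation, or
  spatial noise structure is simulated, so tests certify estimator
  correctness under the assumed correlation model, not robustness to
  realistic BOLD artifacts.
* **Endpoints**: mixtures of product von Mises–Fisher components between
  parcel centroids (exact inverse-CDF sampler; closed-form density is the
  ISE oracle).  Default concentration κ = 50 gives bundles of angular scale
  1/√κ ≈ 0.14 rad, a plausible footprint for a cortical ending zone on the
  registration sphere.  Real endpoint densities are not mixture-smooth and
  have gyral structure; the fixture tests KDE consistency, not tractography
  realism.
* **Cohorts**: subject-level variation jitters component directions
  (tangent Gaussian, default 0.05 rad) and weights; sessions redraw
  endpoints.  Feature-level cohorts plant exact variance components
  b_i + e_ij; their ground truth records both analytic values,
  ICC = σ²_b/(σ²_b+σ²_w) and dICC = (σ²_b+σ²_w)/(σ²_b+2σ²_w) — note these
  differ for the same components, so "a 3:1 ratio" pins 0.75 for the ICC
  via σ²_b = 3σ²_w but for the dICC via σ²_b = 2σ²_w (which makes the mean
  squared between-distance three times the within).

## Problem sizes and determinism

The test suite and the acceptance script run on level-2/level-3 icosphere
grids (162/642 vertices per hemisphere), streamline counts 500–50,000,
cohorts of 4–20 subjects, 500–2,000 permutations/replicates — sizes chosen
so each scientific check resolves its effect with comfortable statistical
margin on a single CPU.  Every stochastic routine takes an explicit seed
and is bit-reproducible under it; the acceptance script derives all its
seeds from the single `--seed` argument.

## Known limitations

* The greedy decimation re-hulls globally per candidate evaluation; it is
  meant for building analysis grids (hundreds to a few thousand vertices),
  not interactive decimation of 160k-vertex meshes.
* Dense grid matrices scale as n²; a 3,668-vertex joint grid (~100 MB per
  matrix) is comfortable, 16k vertices is not.
* Spherical registration across subjects is assumed done upstream; nothing
  here aligns spheres.
* The direct-connection threshold (default 1e-7) is a density cut whose
  interpretation depends on the streamline budget; it is exposed, not
  tuned.
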