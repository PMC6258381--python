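# Methods

This note documents the statistical and geometric procedures implemented in
`dendreg`, the assumptions behind them, the parameters that matter, and the
choices made where the design was genuinely open.

## The regularity index

For a finite point cloud *C* of *N* points, the observed mean
nearest-neighbor (NN) distance is r̄₀ = (1/N) Σᵢ minⱼ d(i, j).  The
regularity index is R = r̄₀ / r̄_E, where r̄_E is the mean NN distance of *N*
points placed uniformly at random in the same supporting volume.  Under an
unbounded homogeneous Poisson process of density ρ,

- 2D: r̄_E = 1 / (2 √ρ),
- 3D: r̄_E = Γ(4/3) · (4πρ/3)^(−1/3) ≈ 0.55396 · ρ^(−1/3)

(`expected_nn_analytic`).  Interpretation: R = 1 is complete spatial
randomness; R < 1 clustering (R = 0 exactly when every point coincides with
another — note R cannot distinguish all-coincident from pairwise-coincident
configurations); R > 1 regularity, with the 2D ceiling 2·√(2/√3) ≈ 2.1491
attained by the triangular lattice.  R is invariant under rigid motions and
uniform scaling, so clouds (and cells) of different absolute size are
comparable.

## Supporting volume: α-shape tight hulls

The denominator requires the measure of the region actually supporting the
points.  Convex hulls overestimate it whenever the support is non-convex, as
dendritic territories usually are.  We therefore use α-shapes built on the
Delaunay triangulation: the shape at scale α is the union of Delaunay
simplices with circumradius ≤ α.  The *α-spectrum* is the finite increasing
sequence of circumradius thresholds at which the shape changes; its last
entry reproduces the convex hull and its *critical* entry is the smallest
one whose shape is connected and contains every input point.  The *tight
hull* (default) selects the spectrum entry halfway (index rounded up, i.e.
toward the convex end) between the critical index and the convex end; the
fraction `q` exposes the whole family (q = 0 convex, q = 1 tightest, q = 0.9
the very tight hulls appropriate for synapse clouds strung along bare
neurites).  Only connected, all-containing spectrum entries are eligible;
an ineligible selection is bumped upward.

Implementation notes:

- Containment and connectivity over the whole spectrum are evaluated in a
  single union-find pass over simplices sorted by circumradius, so selecting
  any spectrum member costs one triangulation plus O(m α(m)).
- Degenerate (zero-measure) simplices receive an effectively infinite
  circumradius and enter only at the convex end.  Near-coincident points
  that break qhull's topology checks are retried with joggled input.
- Measures are sums of simplex areas/volumes; 2D shapes are taken as filled
  boundaries (no hole carving), which is adequate at the center-α for
  dendrite-like clouds.
- Coplanar-in-3D clouds are not triangulated in 3D; trees detected as planar
  (smallest principal extent < 10⁻⁶ of the largest) are projected onto
  their two dominant principal axes before any hull computation.

The index-space midpoint is deliberately the same rule used by the standard
shrink-factor hull constructions in common morphometry toolchains.  Its
absolute accuracy as an area estimator is modest for a uniform sample of a
square (the hull hugs the points and loses the boundary margin; averaged
over samples the density estimate N/V is within ~10% of truth at N = 2000)
— the Monte-Carlo estimator below is constructed precisely so that this
bias cancels.

## Monte-Carlo estimation of R with volume correction

Analytic edge corrections exist only for convex planar supports, so r̄_E is
estimated by simulation (`estimate_R_mc`, default M = 100 iterations):

1. compute r̄₀ and the tight hull of *C* (measure V);
2. draw M uniform clouds of N points inside the hull (rejection sampling
   from the bounding box);
3. **volume correction**: rescale each sampled cloud isotropically about its
   centroid so that its *own* tight hull (same q) has measure V.  Because
   the α-complex selection is scale-invariant, the rescaling
   s = (V/V_sample)^(1/d) is exact in one step; the code iterates up to 10
   times as a guard and warns if the 1% tolerance is not met.  Without this
   step the estimator is positively biased — the reference clouds' own hulls
   shrink inside V, making their effective density too high — especially for
   small N (reproduced in the test suite at N = 30: uncorrected mean R ≈
   1.24, corrected ≈ 1.00);
4. r̄_E is the mean of the M per-cloud mean NN distances r̄_E,ᵢ.  No further
   edge correction is applied: observed and simulated distances are subject
   to the same boundary effects, which cancel in the ratio;
5. per iteration, a percentile bootstrap (default B = 1000 resamples of the
   N NN distances) gives an interval [c⁻ᵢ, c⁺ᵢ]; their means [c⁻, c⁺] give
   the confidence interval [r̄₀/c⁺, r̄₀/c⁻] for R (default level 95%).

One seeded generator drives hull sampling, correction and bootstrap, so a
fixed seed reproduces the full `RegularityResults` bit-for-bit.  Clouds with
r̄₀ = 0 and a degenerate support are assigned R = 0 with a flag rather than
an error, since pairwise-coincident configurations have R = 0 regardless of
the denominator.  Estimates with N < 20 trigger a warning: intervals are
then wide and the point estimate unreliable.

The CSR test (`csr_test` / `RegularityResults.csr_test`) reuses the same M
simulated means as the null distribution of r̄₀:
p_clustered = (1 + #{r̄_E,ᵢ ≤ r̄₀})/(M+1), p_regular analogously, and the
two-sided p doubles the smaller one (capped at 1).  The +1 correction keeps
finite-simulation p-values strictly positive (minimum 1/(M+1)).

Open choices resolved here: the bootstrap resamples NN *distances* (not
points) within each iteration; percentile intervals were chosen for
robustness at small N; the two-sided construction is the doubling rule.

## Target-R point-pattern generator

`generate_pattern` starts from N uniform points in a square/cube of side
200 µm (the default region used throughout the simulations) and iterates:
estimate R by Monte Carlo, stop if |R − target| ≤ tolerance (default 0.02),
otherwise move every point along the direction to its current NN — toward
it when the target is below the current R, away when above — by
`gain · |R − target| · (mean NN distance)`.  All points move simultaneously;
moves are clamped to the region.  Engineering choices (the procedure's
proportionality constant and stopping rule are inherently free parameters):
gain defaults to 1, steps are capped at half the mean NN distance to prevent
oscillation, contraction steps are additionally capped at 45% of each
point's own NN distance to prevent overshooting past the neighbor, and the
in-loop estimate uses a reduced budget (M = 20, no bootstrap) with a final
full-budget verification estimate (M = 100) attached to the result.
Convergence typically takes a handful of iterations for targets near 1 and
tens of iterations for extreme targets (0.2, 1.8); hitting `max_iterations`
(500) returns the best iterate with a non-convergence flag rather than
failing.

A hard-core exclusion distance ε (modelling the physical extent of synapses;
0.5 µm in the recalculated morphological models) is enforced by symmetric
pair separation after every step; configuration validation rejects packings
beyond a crude feasibility bound.

## Extended MST dendrite models

`grow_mst` grows a binary tree over target points by greedily attaching the
(unconnected target, tree node) pair minimizing
`‖t − v‖ + bf · (pathlength(root → v) + ‖t − v‖)` — the incremental form of
`total cost = cable cost + bf · path cost`, which reduces to Prim's
algorithm at bf = 0.  Multifurcations are not allowed: every node including
the root accepts at most two children (a saturated node simply becomes
ineligible).  Ties break deterministically (lowest target index, then
lowest node index); coincident targets attach with zero-length edges; no
post-hoc smoothing or jitter is applied.  The root defaults to the center
of the targets' bounding box, matching the region-center root used in the
simulations.  With uniform targets in a fixed volume, total cable length
scales as N^(1−1/d) (the 2/3 power in 3D), with higher input regularity
adding an offset in cable length at matched N.

## Morphometry conventions

- Branch points are nodes with exactly two children; termination points are
  leaves; the root is a distinguished node and never counts as either.  The
  binary-tree identity #TP = #BP + 1 therefore holds exactly when the root
  carries a single stem.
- Branch order of a node counts the BPs strictly on its root path, averaged
  over **all** nodes; mean path length averages over non-root nodes (a
  single-node tree reports 0).
- Branch angles use the immediate daughter segment directions at each BP
  (not the full daughter-branch chords).
- Asymmetry at a BP is v₁/(v₁+v₂) with v₁ the smaller daughter termination
  count; a balanced BP scores exactly 0.5, so the statistic lives in
  (0, 0.5].
- SWC preprocessing drops regions {1, 2, 5, 10} (soma, axon, custom),
  re-joins orphaned fragments by attaching each fragment root to the
  geometrically nearest node of the main component (straight edge,
  minimal-cable intent; ties by lowest node id; the main component is the
  one holding the lowest node id), then splits every m-furcation into a
  cascade of m − 1 binary nodes at identical coordinates, children kept in
  input order.  The procedure is idempotent.

## Synthetic data and what the tests show

All test inputs are generated programmatically: uniform (Poisson) clouds,
triangular and square lattices (analytic R = 2.1491 and 2), L-shaped
supports (true area 3, convex closure 3.5 — the canonical demonstration
that convex hulls overestimate non-convex supports while tight hulls land
within ~10%), duplicated-pair clouds (R = 0), and generator outputs with
prescribed R.  These fixtures emulate the *local* spatial statistics of
dendritic point sets but not their global anisotropy, spatially varying
density, or reconstruction noise; passing tests therefore validate the
estimator, generator and tree model under homogeneous conditions, not the
biological conclusions one might draw on any particular real cell class.
Real SWC reconstructions are an optional input path exercised only through
the same preprocessing and estimation code.

Problem sizes in the validation suite are the package's own desk-scale
choices: the Poisson calibration uses 20 clouds of N = 1000 with M = 100;
coverage uses 100 clouds of N = 100; the bias comparison uses 200 replicates
at N = 30; the input-regularity sweep uses 5 replicates per target
(3D, N = 100, bf = 0.5) — large enough for the monotone relationships, which
are strong effects, to be statistically unambiguous; the cable-scaling fit
uses 20 replicates per N ∈ {50, 100, 200, 400}.

## Known limitations

- The tight hull's absolute measure is a biased estimator of the true
  support area/volume for boundary-rough samples; only the *ratio* R is
  debiased by construction.  The spectrum-midpoint rule is also not
  guaranteed to equal any particular toolbox's shrink-factor
  parameterization.
- Single-neighbor statistics cannot separate configurations with identical
  NN-distance distributions (k ≥ 2 neighborhoods, G- and K-functions are
  out of scope).
- The generator targets a single global R; spatially inhomogeneous targets
  are not supported.
- The confidence interval propagates denominator (r̄_E) uncertainty only;
  r̄₀ is treated as fixed for the cloud at hand.
- Rejection sampling of reference clouds assumes the hull occupies a
  non-negligible fraction of its bounding box; pathologically thin supports
  raise an error instead of looping forever.
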