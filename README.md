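# dendreg

**A regularity index for dendrites and spatial point clouds.**

Neurons collect synaptic inputs with branched dendritic trees, and the
spatial organization of those inputs — tightly clustered, random, or
grid-like — leaves a signature in the positions of the tree's branch points
(BPs) and termination points (TPs).  `dendreg` quantifies that organization
with the *regularity index*

```
R = r̄₀ / r̄_E
```

the ratio of the observed mean nearest-neighbor (NN) distance r̄₀ of a point
set to the mean NN distance r̄_E expected for the same number of points
placed uniformly at random in the same supporting volume.  R = 1 indicates
complete spatial randomness (CSR), R < 1 clustering (R = 0 when every point
coincides with another), and R > 1 regularity, up to 2.1491 for a planar
triangular lattice.  For an unbounded Poisson process of density ρ the
expectation is analytic — r̄_E = 1/(2√ρ) in 2D and Γ(4/3)·(4πρ/3)^(−1/3) in
3D — but real dendrites live in bounded, non-convex volumes where a naive
plug-in estimate is badly biased by edge effects.

The package is aimed at quantitative neuroanatomists and spatial-statistics
users and provides:

- **Boundary-corrected estimation of R** by Monte Carlo: the supporting
  volume is a *tight hull* (the α-shape at the center of the cloud's
  α-spectrum, between the critical and the convex end), M uniform reference
  clouds are drawn inside it, each rescaled so its own tight-hull measure
  matches the reference volume (*volume correction*), and observed and
  simulated NN distances — biased by the same edge effects — are compared in
  the ratio.  Bootstrap percentile intervals per iteration aggregate into a
  confidence interval for R, and the same simulated null yields a Monte-Carlo
  CSR test.
- **SWC morphometry**: reading/writing 7-column SWC reconstructions,
  preprocessing (soma/axon removal, fragment re-joining, multifurcation
  repair), BP/TP extraction, and the classical branching statistics (cable
  length, branch order, branch angle, tree asymmetry, path length, cable and
  BP densities).
- **A target-R point-pattern generator**: iteratively moves points toward or
  away from their nearest neighbors until the estimated R reaches a
  prescribed value, optionally with a hard-core exclusion distance ε.
- **Extended minimum-spanning-tree dendrite models**: binary trees grown
  greedily over target points minimizing
  `cable length + bf · path length to the root`.
- **Experiment drivers**: R_Input × bf × N sweeps, correlation matrices and
  log–log scaling fits, plus fixture clouds with analytically known R.

## Worked example

Generate a clustered 3D input cloud (target R = 0.5), grow a dendrite over
it, and ask how regular the resulting branch points are:

```python
import numpy as np
from dendreg import GeneratorConfig, MSTConfig, RegularityIndex, generate_pattern, grow_mst

config = GeneratorConfig(n_points=100, target_r=0.5, dim=3, seed=42)
pattern = generate_pattern(config)
print("generator converged:", pattern.converged, "after", pattern.iterations, "iterations")

tree = grow_mst(pattern.cloud, MSTConfig(bf=0.5, root=np.full(3, 100.0)))

res = RegularityIndex.from_tree(tree, "branch").fit(seed=0)
print(res.summary())
```

```
generator converged: True after 4 iterations
Regularity index (Monte-Carlo, volume-corrected)
================================================
points (N)                         33   dim 3
supporting measure (V)     1.8056e+06   tight hull q=0.5
observed mean NN (r0)         24.9901
expected mean NN (rE)         32.4867   M=100
R = r0/rE                    0.769239
95% CI for R            [0.673579, 0.890781]
CSR test p-values        two-sided 0.0198, clustered 0.009901, regular 1
```

The tree grown over clustered inputs (R_Input = 0.5) has 33 branch points
whose estimated regularity R_BP ≈ 0.77 sits between the input regularity and
1 — branch points track the input organization but are smoothed toward
randomness by the wiring — and the CSR test rejects a uniform arrangement in
favor of clustering (p ≈ 0.01).  Termination points
(`RegularityIndex.from_tree(tree, "termination")`) land even closer to 1.

The same operations are available from the shell:

```bash
dendreg gen-pattern --n 100 --dim 3 --target-r 0.5 --seed 42 --out inputs.tsv
dendreg grow-tree --targets inputs.tsv --bf 0.5 --out tree.swc
dendreg estimate-r inputs.tsv --seed 0
dendreg sweep --dim 3 --r-grid 0.2,1.0,1.8 --replicates 5 --seed 1 --out sweep.tsv
```

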