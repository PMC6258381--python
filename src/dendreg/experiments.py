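"""End-to-end synthetic experiments: target-R patterns -> MST dendrites ->
regularity of branch/termination points and branching statistics.

The central experiment sweeps a grid of input regularities (R_Input), MST
balancing factors and point counts; for each cell a target pattern is
generated, a tree grown, and R of the tree's branch points (R_BP) and
termination points (R_TP) estimated alongside the classical branching
statistics.  Correlation matrices and log-log scaling fits summarize the
resulting tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fixtures import make_fixtures  # noqa: F401  (re-exported: fixture op lives here too)
from .hulls import DegenerateCloudError, tight_hull
from .morphometry import summarize_tree
from .mst import MSTConfig, grow_mst
from .patterns import GeneratorConfig, generate_pattern
from .regularity import estimate_R_mc
from .trees import extract_points

__all__ = ["sweep_experiment", "correlation_matrix", "scaling_fit", "make_fixtures", "ScalingFit"]


def _estimate_tree_r(tree, which: str, m: int, rng) -> dict:
    """R estimate for a tree's BPs or TPs; NaNs when too few points."""
    prefix = {"branch": "r_bp", "termination": "r_tp"}[which]
    cloud = extract_points(tree, which)
    out = {prefix: np.nan, f"{prefix}_ci_low": np.nan, f"{prefix}_ci_high": np.nan}
    if cloud.n < cloud.dim + 2:
        return out
    try:
        est = estimate_R_mc(cloud, m=m, rng=rng)
    except (DegenerateCloudError, ValueError):
        return out
    out[prefix] = est.r
    out[f"{prefix}_ci_low"] = est.ci_low
    out[f"{prefix}_ci_high"] = est.ci_high
    return out


def sweep_experiment(
    dim: int,
    n_grid,
    r_grid,
    bf_grid,
    replicates: int,
    side: float = 200.0,
    seed: int = 0,
    epsilon: float = 0.0,
    mc_iterations: int = 100,
    generator_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Grid sweep: one generated pattern per (n, r_input, replicate), one
    grown tree and one record per balancing factor.

    All randomness derives from ``seed`` through a per-cell counter, so the
    full table is reproducible.  Generator non-convergence is recorded in
    the ``converged`` column, never fatal.
    """
    gen_kwargs = dict(generator_kwargs or {})
    records = []
    cell = 0
    for n, r_input, rep in itertools.product(n_grid, r_grid, range(replicates)):
        # one independent, reproducible stream per grid cell
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(cell,)))
        cell += 1
        config = GeneratorConfig(
            n_points=int(n), target_r=float(r_input), dim=dim, side=side,
            epsilon=epsilon, **gen_kwargs,
        )
        pattern = generate_pattern(config, rng=rng)
        center = np.full(dim, side / 2.0)
        for bf in bf_grid:
            tree = grow_mst(pattern.cloud, MSTConfig(bf=float(bf), root=center))
            row = {
                "dim": dim,
                "n_points": int(n),
                "r_input": float(r_input),
                "r_input_estimated": pattern.estimate.r,
                "bf": float(bf),
                "replicate": rep,
                "seed": seed,
                "converged": pattern.converged,
            }
            row.update(_estimate_tree_r(tree, "branch", mc_iterations, rng))
            row.update(_estimate_tree_r(tree, "termination", mc_iterations, rng))
            try:
                hull = tight_hull(extract_points(tree, "all"))
                stats = summarize_tree(tree, hull)
                row.update({c: getattr(stats, c) for c in stats.COLUMNS})
            except (DegenerateCloudError, ValueError):
                pass
            records.append(row)
    return pd.DataFrame.from_records(records)


def correlation_matrix(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between the given columns.

    Constant columns yield NaN entries (undefined correlation), matching
    pandas semantics; the diagonal is 1 wherever defined.
    """
    if columns is not None:
        table = table[list(columns)]
    table = table.select_dtypes(include=[np.number])
    if len(table) < 3:
        raise ValueError("need at least 3 records for a correlation matrix")
    return table.corr(method="pearson")


@dataclass
class ScalingFit:
    """Ordinary least squares on (log x, log y): a power-law exponent."""

    slope: float
    intercept: float
    stderr: float
    r_value: float

    def predict(self, x):
        return np.exp(self.intercept) * np.asarray(x, float) ** self.slope


def scaling_fit(table: pd.DataFrame, x: str, y: str) -> ScalingFit:
    """Log-log OLS fit of column ``y`` against column ``x``.

    Both columns must be strictly positive; rows with missing values are
    dropped pairwise.
    """
    sub = table[[x, y]].dropna()
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.any(xv <= 0) or np.any(yv <= 0):
        raise ValueError("scaling_fit requires strictly positive values")
    res = sps.linregress(np.log(xv), np.log(yv))
    return ScalingFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_value=float(res.rvalue),
    )
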