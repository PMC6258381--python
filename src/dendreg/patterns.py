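"""Point-pattern generator with a target regularity index.

Starting from a uniform random cloud in a square or cube, points are moved
iteratively toward their nearest neighbor (to lower R) or away from it (to
raise R), with a step proportional to the gap between the current estimate
and the target, until the Monte-Carlo estimated R is within tolerance.  An
optional hard-core exclusion distance epsilon keeps all pairwise distances
at or above a physical minimum (the spatial extent of a synapse).

During iteration R is re-estimated with a reduced Monte-Carlo budget for
speed; a final full-budget estimate verifies the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .regularity import RegularityResults, estimate_R_mc, nn_distances
from .trees import PointCloud

__all__ = [
    "GeneratorConfig",
    "PatternResult",
    "ExclusionError",
    "generate_pattern",
    "generator_step",
    "enforce_exclusion",
]


class ExclusionError(ValueError):
    """Raised when the hard-core exclusion constraint cannot be satisfied."""


def _ball_volume(radius: float, dim: int) -> float:
    return math.pi * radius**2 if dim == 2 else 4.0 / 3.0 * math.pi * radius**3


@dataclass
class GeneratorConfig:
    """Parameters of the target-R pattern generator.

    The region is an axis-aligned square (2D) or cube (3D) with side
    ``side`` micrometers; ``epsilon`` is the minimal allowed pairwise
    distance (0 disables the hard core); ``gain`` scales the per-iteration
    displacement (step = gain * |R - target| * mean NN distance, capped at
    half the mean NN distance); iteration stops when |R - target| <=
    ``tolerance``.
    """

    n_points: int
    target_r: float
    dim: int = 2
    side: float = 200.0
    epsilon: float = 0.0
    gain: float = 1.0
    tolerance: float = 0.02
    max_iterations: int = 500
    mc_iterations: int = 20  # reduced in-loop MC budget
    final_mc_iterations: int = 100  # full-budget verification estimate
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.target_r <= 0:
            raise ValueError("target_r must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.epsilon > 0:
            # crude packing feasibility: hard-core balls of radius eps/2 must
            # fit well below the densest packing of the region
            packing = self.n_points * _ball_volume(self.epsilon / 2.0, self.dim)
            if packing > 0.5 * self.side**self.dim:
                raise ValueError(
                    f"epsilon={self.epsilon} infeasible for {self.n_points} points "
                    f"in a side-{self.side} region"
                )


@dataclass
class PatternResult:
    """Generated cloud, per-iteration R trace, and the verification estimate."""

    cloud: PointCloud
    trace: pd.DataFrame  # columns: iteration, r
    converged: bool
    estimate: RegularityResults = field(repr=False)

    @property
    def iterations(self) -> int:
        return int(self.trace.shape[0])


def enforce_exclusion(
    points: PointCloud | np.ndarray,
    epsilon: float,
    side: float,
    rng: np.random.Generator,
    max_passes: int = 200,
) -> PointCloud:
    """Push apart all point pairs closer than epsilon (symmetric displacement
    along the pair axis) until the hard-core constraint holds; points are
    clamped to the region.  Raises :class:`ExclusionError` if the packing
    does not settle within ``max_passes``."""
    pts = (points.points if isinstance(points, PointCloud) else np.asarray(points, float)).copy()
    if epsilon <= 0:
        return PointCloud(pts)
    for _ in range(max_passes):
        pairs = cKDTree(pts).query_pairs(epsilon * (1.0 - 1e-12), output_type="ndarray")
        if pairs.size == 0:
            return PointCloud(pts)
        for i, j in pairs:
            delta = pts[j] - pts[i]
            dist = float(np.linalg.norm(delta))
            if dist == 0.0:
                u = rng.standard_normal(pts.shape[1])
                u /= np.linalg.norm(u)
            else:
                u = delta / dist
            push = 0.5 * (epsilon * (1.0 + 1e-9) - dist)
            pts[i] -= push * u
            pts[j] += push * u
        np.clip(pts, 0.0, side, out=pts)
    raise ExclusionError(f"could not reach min pairwise distance {epsilon} in {max_passes} passes")


def generator_step(
    points: PointCloud | np.ndarray,
    current_r: float,
    target_r: float,
    gain: float,
    side: float,
    epsilon: float,
    rng: np.random.Generator,
) -> PointCloud:
    """One simultaneous displacement pass of the pattern generator.

    Every point moves along the direction to its current nearest neighbor —
    toward it when the target is below the current R, away when above — by
    gain * |current - target| * (mean NN distance), capped at half the mean
    NN distance (overshoot guard) and, when moving toward, at 45% of the
    individual NN distance.  Points are clamped to the region and the
    hard-core constraint re-enforced.
    """
    pts = (points.points if isinstance(points, PointCloud) else np.asarray(points, float)).copy()
    n, d = pts.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    dist, idx = cKDTree(pts).query(pts, k=2)
    d_nn = dist[:, 1]
    nn = pts[idx[:, 1]]
    mean_nn = float(d_nn.mean())
    diff = current_r - target_r
    step = min(gain * abs(diff) * mean_nn, 0.5 * mean_nn)
    if step > 0.0 and mean_nn > 0.0:
        direction = nn - pts
        norms = np.linalg.norm(direction, axis=1)
        ok = norms > 0
        direction[ok] /= norms[ok, None]
        # coincident pairs moving apart need an arbitrary axis
        if not np.all(ok) and diff < 0:
            rand = rng.standard_normal((int((~ok).sum()), d))
            rand /= np.linalg.norm(rand, axis=1, keepdims=True)
            direction[~ok] = rand
        if diff > 0:  # too regular: contract toward the nearest neighbor
            per_point = np.minimum(step, 0.45 * d_nn)
            pts += per_point[:, None] * direction
        else:  # too clustered: expand away from the nearest neighbor
            pts -= step * direction
    np.clip(pts, 0.0, side, out=pts)
    if epsilon > 0:
        return enforce_exclusion(pts, epsilon, side, rng)
    return PointCloud(pts)


def generate_pattern(
    config: GeneratorConfig, rng: np.random.Generator | int | None = None
) -> PatternResult:
    """Iterate the generator until the Monte-Carlo R estimate reaches the
    target (within tolerance), from a uniform random start.

    Returns the best iterate with its per-iteration R trace; when
    ``max_iterations`` is exhausted the closest iterate seen is returned
    with ``converged=False``.  The returned ``estimate`` is a full-budget
    verification fit of the final cloud.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    pts = rng.uniform(0.0, config.side, size=(config.n_points, config.dim))
    if config.epsilon > 0:
        pts = enforce_exclusion(pts, config.epsilon, config.side, rng).points

    best_pts = pts
    best_gap = math.inf
    rows = []
    converged = False
    for it in range(config.max_iterations):
        est = estimate_R_mc(
            PointCloud(pts), m=config.mc_iterations, bootstrap_b=0, rng=rng
        )
        r = est.r
        rows.append((it, r))
        gap = abs(r - config.target_r)
        if gap < best_gap:
            best_gap, best_pts = gap, pts
        if gap <= config.tolerance:
            converged = True
            break
        pts = generator_step(
            pts, r, config.target_r, config.gain, config.side, config.epsilon, rng
        ).points

    cloud = PointCloud(best_pts)
    final = estimate_R_mc(cloud, m=config.final_mc_iterations, rng=rng)
    trace = pd.DataFrame(rows, columns=["iteration", "r"])
    return PatternResult(cloud=cloud, trace=trace, converged=converged, estimate=final)
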