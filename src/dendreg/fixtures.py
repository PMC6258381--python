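"""Reference point clouds with known ground truth.

Every generator returns ``(PointCloud, meta)`` where ``meta`` records the
analytically known properties — true supporting measure, analytic regularity
index where one exists — so tests and validation experiments never depend on
external data.
"""

from __future__ import annotations

import math

import numpy as np

from .trees import PointCloud

__all__ = ["make_fixtures", "TRIANGULAR_LATTICE_R", "SQUARE_LATTICE_R"]

#: Analytic R of an infinite triangular lattice: NN distance = spacing s,
#: density 2/(sqrt(3) s^2), so R = s * 2 sqrt(rho) = 2 sqrt(2/sqrt(3)).
TRIANGULAR_LATTICE_R = 2.0 * math.sqrt(2.0 / math.sqrt(3.0))

#: Analytic R of an infinite square lattice: NN distance s, density 1/s^2.
SQUARE_LATTICE_R = 2.0


def _poisson(n: int, side: float, dim: int, rng: np.random.Generator):
    pts = rng.uniform(0.0, side, size=(n, dim))
    return PointCloud(pts), {"true_r": 1.0, "true_measure": side**dim, "side": side}


def _triangular_lattice(rows: int, cols: int, spacing: float):
    xs = np.arange(cols) * spacing
    ys = np.arange(rows) * (spacing * math.sqrt(3.0) / 2.0)
    pts = np.empty((rows * cols, 2))
    k = 0
    for r, y in enumerate(ys):
        offset = 0.5 * spacing if r % 2 else 0.0
        pts[k : k + cols, 0] = xs + offset
        pts[k : k + cols, 1] = y
        k += cols
    density = 2.0 / (math.sqrt(3.0) * spacing**2)
    return PointCloud(pts), {
        "true_r": TRIANGULAR_LATTICE_R,
        "spacing": spacing,
        "density": density,
    }


def _square_lattice(rows: int, cols: int, spacing: float):
    gx, gy = np.meshgrid(np.arange(cols) * spacing, np.arange(rows) * spacing)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return PointCloud(pts), {
        "true_r": SQUARE_LATTICE_R,
        "spacing": spacing,
        "density": 1.0 / spacing**2,
    }


def _l_shape(n: int, rng: np.random.Generator, side: float = 1.0):
    """Uniform points on an L of three unit squares:
    [0,2s]x[0,s] union [0,s]x[s,2s]; true area 3 s^2, convex closure 4.5 s^2."""
    pts = np.empty((n, 2))
    # the two rectangles have areas 2 and 1: sample membership accordingly
    in_bottom = rng.uniform(size=n) < 2.0 / 3.0
    nb = int(in_bottom.sum())
    pts[in_bottom] = rng.uniform([0, 0], [2 * side, side], size=(nb, 2))
    pts[~in_bottom] = rng.uniform([0, side], [side, 2 * side], size=(n - nb, 2))
    return PointCloud(pts), {
        "true_measure": 3.0 * side**2,
        "convex_measure": 4.5 * side**2,
        "side": side,
    }


def _duplicated_pairs(n: int, side: float, dim: int, rng: np.random.Generator):
    if n % 2:
        raise ValueError("duplicated_pairs needs an even n")
    base = rng.uniform(0.0, side, size=(n // 2, dim))
    pts = np.repeat(base, 2, axis=0)
    return PointCloud(pts), {"true_r": 0.0, "true_measure": side**dim}


def make_fixtures(kind: str, params: dict | None = None, seed: int | None = 0):
    """Build a reference cloud of the given kind with its ground truth.

    Kinds: ``poisson`` (n, side, dim), ``triangular_lattice`` (rows, cols,
    spacing), ``square_lattice`` (rows, cols, spacing), ``l_shape`` (n,
    side), ``duplicated_pairs`` (n, side, dim), ``known_r`` (n, target_r,
    dim, side, plus any :class:`~dendreg.patterns.GeneratorConfig` field).

    Returns ``(cloud, meta)``; deterministic for a given seed.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "poisson":
        return _poisson(params.get("n", 100), params.get("side", 1.0), params.get("dim", 2), rng)
    if kind == "triangular_lattice":
        return _triangular_lattice(
            params.get("rows", 50), params.get("cols", 50), params.get("spacing", 1.0)
        )
    if kind == "square_lattice":
        return _square_lattice(
            params.get("rows", 50), params.get("cols", 50), params.get("spacing", 1.0)
        )
    if kind == "l_shape":
        return _l_shape(params.get("n", 1000), rng, params.get("side", 1.0))
    if kind == "duplicated_pairs":
        return _duplicated_pairs(
            params.get("n", 50), params.get("side", 1.0), params.get("dim", 2), rng
        )
    if kind == "known_r":
        from .patterns import GeneratorConfig, generate_pattern

        target = params.pop("target_r")
        config = GeneratorConfig(
            n_points=params.pop("n", 100), target_r=target, **params
        )
        result = generate_pattern(config, rng=rng)
        return result.cloud, {
            "true_r": target,
            "converged": result.converged,
            "estimate": result.estimate,
        }
    raise ValueError(f"unknown fixture kind {kind!r}")
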