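"""Diffusion-map pseudotime and LOESS expression curves.

Cells are ordered along a single differentiation trajectory: a Gaussian
kernel with locally adaptive bandwidth (distance to the kernel_scale-th
neighbour) on Euclidean distances between expression profiles is
density-normalized, and the leading non-trivial eigenvector of the
resulting transition operator (DC1) serves as the trajectory axis. The
axis is oriented so an anchor gene (e.g. an embryonic haemoglobin)
increases along it, and pseudotime is the rank of DC1 rescaled to
exactly [0, 1]. Smoothed curves are tricube-weighted local linear
regressions evaluated on a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PseudotimeOrdering",
    "SmoothCurve",
    "diffusion_map",
    "orient_and_scale",
    "loess_curve",
]


@dataclass
class PseudotimeOrdering:
    coordinates: np.ndarray  # cells x diffusion components
    pseudotime: np.ndarray  # in [0, 1], rank-based along DC1
    anchor_gene: str | None = None


@dataclass
class SmoothCurve:
    grid: np.ndarray
    values: np.ndarray
    span: float

    def __post_init__(self):
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fitted values must be finite")


def diffusion_map(
    X: np.ndarray, n_components: int = 10, kernel_scale: int = 10
) -> tuple:
    """Diffusion components of an expression matrix.

    Returns (coordinates, eigenvalues): the top ``n_components``
    non-trivial eigenvectors of the density-normalized transition
    operator, scaled by their eigenvalues, with signs fixed by making
    each vector's largest-magnitude entry positive. Raises when the
    kernel graph is disconnected (advice: larger kernel_scale).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    kernel_scale = min(kernel_scale, n - 1)
    d = squareform(pdist(X))
    # local scale: distance to the kernel_scale-th neighbour (self = 0th)
    s = np.sort(d, axis=1)[:, kernel_scale]
    s = np.maximum(s, 1e-12)
    K = np.exp(-(d**2) / (s[:, None] * s[None, :]))
    graph = (K > 1e-12).astype(float)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"kernel graph has {n_comp} disconnected components; "
            "increase kernel_scale"
        )
    # anticipated-density normalization removes sampling-density bias
    q = K.sum(axis=1)
    K1 = K / np.outer(q, q)
    d1 = K1.sum(axis=1)
    A = K1 / np.sqrt(np.outer(d1, d1))
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d1)[:, None]
    n_components = min(n_components, n - 1)
    comps = psi[:, 1 : n_components + 1] * evals[1 : n_components + 1]
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(comps.shape[1])])
    flip[flip == 0] = 1.0
    return comps * flip, evals[1 : n_components + 1]


def orient_and_scale(
    coordinates: np.ndarray,
    anchor_expression: np.ndarray,
    anchor_gene: str | None = None,
) -> PseudotimeOrdering:
    """Orient DC1 so the anchor gene increases, then rank-scale to [0,1]."""
    coords = np.asarray(coordinates, float)
    anchor = np.asarray(anchor_expression, float)
    if not np.any(anchor != 0):
        raise ValueError("anchor gene is unexpressed in all cells")
    dc1 = coords[:, 0]
    rho = stats.spearmanr(dc1, anchor).statistic
    if np.isnan(rho):
        rho = 0.0
    sign = -1.0 if rho < 0 else 1.0
    ranks = stats.rankdata(sign * dc1, method="average") - 1.0
    pt = ranks / (len(dc1) - 1)
    return PseudotimeOrdering(coords, pt, anchor_gene)


def loess_curve(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.5,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> SmoothCurve:
    """Tricube-weighted local linear regression on a fixed grid.

    At each grid point the ``span`` fraction of nearest data points is
    used, weighted by the tricube kernel of their scaled distance; the
    fit degenerates gracefully to a weighted mean when the local design
    is singular.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    m = int(np.ceil(span * n))
    if span * n < 3:
        raise ValueError("span * n must be at least 3")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, float)
    values = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        nearest = np.argpartition(d, min(m, n) - 1)[:m]
        h = d[nearest].max()
        if h == 0:
            values[i] = y[nearest].mean()
            continue
        u = d[nearest] / h
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
        if w.sum() <= 0:
            values[i] = y[nearest].mean()
            continue
        xs, ys = x[nearest], y[nearest]
        sw = w.sum()
        xm = (w * xs).sum() / sw
        ym = (w * ys).sum() / sw
        sxx = (w * (xs - xm) ** 2).sum()
        if sxx <= 1e-12:
            values[i] = ym
        else:
            beta = (w * (xs - xm) * (ys - ym)).sum() / sxx
            values[i] = ym + beta * (x0 - xm)
    return SmoothCurve(grid, values, span)
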