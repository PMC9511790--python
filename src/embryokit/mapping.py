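"""Reference-atlas mapping and cell-type label transfer.

Query cells are embedded jointly with the reference: highly variable
genes are selected on the pooled log-normalized expression, cells are
cosine-normalized and reduced by PCA, the technical offset between the
two batches is removed by matching mutual nearest neighbours (MNN), and
each query cell receives the majority-vote cell type of its k nearest
reference cells (k = 30 by default). Majority voting is the mode of a
Dirichlet posterior over the neighbour type counts — with a +1
pseudo-count per observed type the argmax is unchanged, so the vote is
implemented as a plain argmax with deterministic tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix
from .qc import NormalizationModel, normalize_log, size_factors

__all__ = [
    "MappingParams",
    "MappingResult",
    "select_hvgs",
    "joint_pca",
    "mnn_correct",
    "transfer_labels",
    "highlight_neighbors",
    "map_query",
]


@dataclass
class MappingParams:
    n_hvgs: int = 2000
    n_pcs: int = 50
    k_neighbors: int = 30
    mnn_k: int = 20
    mnn_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_pcs > self.n_hvgs:
            raise ValueError("n_pcs must not exceed n_hvgs")


@dataclass
class MappingResult:
    """Corrected coordinates plus per-query-cell label transfer."""

    ref_coords: np.ndarray
    query_coords: np.ndarray
    ref_cell_ids: np.ndarray
    query_cell_ids: np.ndarray
    ref_labels: np.ndarray
    neighbor_indices: np.ndarray  # query x k, indices into reference
    neighbor_distances: np.ndarray
    assignments: pd.DataFrame  # cell_id, cell_type, confidence

    def neighbor_ref_ids(self, i: int) -> np.ndarray:
        return self.ref_cell_ids[self.neighbor_indices[i]]


def select_hvgs(X_log: np.ndarray, n_hvgs: int, gene_ids=None):
    """Rank genes by variance in excess of the mean–variance trend.

    The trend is a lowess fit of per-gene variance against mean
    log-expression, refitted once after trimming the strongest positive
    outliers so genuinely variable genes do not drag the trend up;
    residuals rank the genes and the top ``n_hvgs`` are returned (as
    indices, or ids when ``gene_ids`` is given). Constant-expression
    genes are never selected.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    X_log = np.asarray(X_log)
    n_genes = X_log.shape[1]
    if n_hvgs > n_genes:
        warnings.warn("n_hvgs exceeds the number of genes; returning all genes")
        n_hvgs = n_genes
    mean = X_log.mean(axis=0)
    var = X_log.var(axis=0, ddof=1)
    # strictly positive variance beyond float cancellation error
    informative = var > 1e-12 * np.maximum(mean**2, 1.0)
    if informative.sum() >= 10:
        def _trend(mask):
            fit = lowess(var[mask], mean[mask], frac=0.3, return_sorted=True)
            return np.interp(mean, fit[:, 0], fit[:, 1])

        trend = _trend(informative)
        resid0 = var - trend
        cutoff = np.quantile(resid0[informative], 0.9)
        keep = informative & (resid0 <= cutoff)
        if keep.sum() >= 10:
            trend = _trend(keep)
    else:
        trend = np.full(n_genes, var[informative].mean() if informative.any() else 0.0)
    resid = np.where(informative, var - trend, -np.inf)
    order = np.argsort(-resid, kind="mergesort")
    n_take = min(n_hvgs, int(informative.sum()))
    idx = np.sort(order[:n_take])
    if gene_ids is not None:
        return np.asarray(gene_ids, dtype=object)[idx]
    return idx


def _fix_signs(components: np.ndarray, coords_list):
    """Make each loading vector's largest-magnitude entry positive."""
    flip = np.sign(components[np.abs(components).argmax(axis=0),
                              np.arange(components.shape[1])])
    flip[flip == 0] = 1.0
    return [c * flip for c in coords_list]


def _cosine_normalize(X):
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def joint_pca(
    ref_log: np.ndarray,
    query_log: np.ndarray,
    hvg_idx,
    n_pcs: int,
    seed: int = 0,
):
    """PCA on the concatenated, cosine-normalized, centred HVG matrices.

    Deterministic up to component sign; signs are fixed by making each
    loading vector's largest-magnitude entry positive. Returns
    (ref_coords, query_coords, explained_variance).
    """
    hvg_idx = np.asarray(hvg_idx)
    X = np.vstack([np.asarray(ref_log)[:, hvg_idx],
                   np.asarray(query_log)[:, hvg_idx]])
    X = _cosine_normalize(X)
    n_cells = X.shape[0]
    if n_pcs > min(n_cells, X.shape[1]):
        warnings.warn("fewer cells/genes than n_pcs; reducing n_pcs")
        n_pcs = min(n_cells, X.shape[1])
    solver = "full" if min(X.shape) <= 500 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=seed)
    coords = pca.fit_transform(X)
    (coords,) = _fix_signs(pca.components_.T, [coords])
    n_ref = ref_log.shape[0]
    return coords[:n_ref], coords[n_ref:], pca.explained_variance_


def mnn_correct(
    ref_coords: np.ndarray,
    query_coords: np.ndarray,
    mnn_k: int = 20,
    mnn_sigma: float = 0.1,
):
    """Shift query cells onto the reference using mutual nearest pairs.

    Mutual nearest neighbours are found between the two batches in PCA
    space; each query cell's correction vector is the Gaussian-kernel-
    weighted (bandwidth ``mnn_sigma``) average of the pair difference
    vectors (reference minus query), weighted by the query cell's
    distance to each pair's query member. Reference coordinates are
    returned unchanged.
    """
    ref_coords = np.asarray(ref_coords, float)
    query_coords = np.asarray(query_coords, float)
    k_rq = min(mnn_k, len(ref_coords), len(query_coords))
    nn_in_ref = NearestNeighbors(n_neighbors=k_rq).fit(ref_coords)
    nn_in_query = NearestNeighbors(n_neighbors=k_rq).fit(query_coords)
    _, q2r = nn_in_ref.kneighbors(query_coords)  # per query: its refs
    _, r2q = nn_in_query.kneighbors(ref_coords)  # per ref: its queries
    ref_sets = [set(row) for row in r2q]
    pairs = [
        (r, q)
        for q in range(len(query_coords))
        for r in q2r[q]
        if q in ref_sets[r]
    ]
    if not pairs:
        raise ValueError("no mutual nearest-neighbour pairs found; "
                         "increase mnn_k")
    pair_r = np.array([p[0] for p in pairs])
    pair_q = np.array([p[1] for p in pairs])
    vectors = ref_coords[pair_r] - query_coords[pair_q]
    anchors = query_coords[pair_q]
    # Gaussian kernel weights on distance to each pair's query member
    from scipy.spatial.distance import cdist

    d2 = cdist(query_coords, anchors, "sqeuclidean")
    w = np.exp(-d2 / (2.0 * mnn_sigma**2))
    wsum = w.sum(axis=1, keepdims=True)
    degenerate = wsum[:, 0] <= 1e-300
    if degenerate.any():
        # numerically zero kernel mass: fall back to the nearest pair
        nearest = d2[degenerate].argmin(axis=1)
        w[degenerate] = 0.0
        w[np.flatnonzero(degenerate), nearest] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    correction = (w @ vectors) / wsum
    return ref_coords, query_coords + correction, pd.DataFrame(
        {"ref_index": pair_r, "query_index": pair_q}
    )


def transfer_labels(
    ref_coords: np.ndarray,
    query_coords: np.ndarray,
    ref_labels,
    k_neighbors: int = 30,
    ref_cell_ids=None,
    query_cell_ids=None,
) -> MappingResult:
    """Majority-vote label transfer from the k nearest reference cells.

    Ties are broken toward the type with the smaller summed neighbour
    distance, then lexicographically. Confidence is max count / k.
    """
    ref_coords = np.asarray(ref_coords, float)
    query_coords = np.asarray(query_coords, float)
    ref_labels = np.asarray(ref_labels, dtype=object)
    if k_neighbors > len(ref_coords):
        raise ValueError("k_neighbors exceeds the number of reference cells")
    if ref_cell_ids is None:
        ref_cell_ids = np.array([f"ref_{i}" for i in range(len(ref_coords))],
                                dtype=object)
    if query_cell_ids is None:
        query_cell_ids = np.array([f"query_{i}" for i in range(len(query_coords))],
                                  dtype=object)
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(ref_coords)
    dist, idx = nn.kneighbors(query_coords)
    assigned, confidence = [], []
    for i in range(len(query_coords)):
        types = ref_labels[idx[i]]
        uniq, counts = np.unique(types, return_counts=True)
        best = counts.max()
        cands = uniq[counts == best]
        if len(cands) > 1:
            sums = {c: dist[i][types == c].sum() for c in cands}
            smin = min(sums.values())
            cands = sorted(c for c in cands if sums[c] == smin)
        assigned.append(cands[0])
        confidence.append(best / k_neighbors)
    assignments = pd.DataFrame(
        {
            "cell_id": np.asarray(query_cell_ids, dtype=object),
            "cell_type": assigned,
            "confidence": confidence,
        }
    )
    return MappingResult(
        ref_coords=ref_coords,
        query_coords=query_coords,
        ref_cell_ids=np.asarray(ref_cell_ids, dtype=object),
        query_cell_ids=np.asarray(query_cell_ids, dtype=object),
        ref_labels=ref_labels,
        neighbor_indices=idx,
        neighbor_distances=dist,
        assignments=assignments,
    )


def highlight_neighbors(result: MappingResult, query_groups: dict) -> pd.DataFrame:
    """Flag reference cells that neighbour any query cell, per group.

    ``query_groups`` maps a group name to a boolean mask or an index
    array over query cells. This is how reference 2-D embeddings are
    annotated: the artifact only flags neighbours on supplied
    coordinates, it computes no embedding.
    """
    out = pd.DataFrame({"cell_id": result.ref_cell_ids})
    for name, sel in query_groups.items():
        sel = np.asarray(sel)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        flagged = np.zeros(len(result.ref_cell_ids), dtype=bool)
        if len(sel):
            flagged[np.unique(result.neighbor_indices[sel])] = True
        out[name] = flagged
    return out


def map_query(
    reference: CountMatrix,
    ref_labels,
    query: CountMatrix,
    params: MappingParams | None = None,
    correct_batch: bool = True,
) -> MappingResult:
    """End-to-end mapping: normalize jointly, HVG → PCA → MNN → vote."""
    params = params or MappingParams()
    if not np.array_equal(reference.gene_ids, query.gene_ids):
        raise ValueError("reference and query gene spaces differ")
    ref_log = normalize_log(reference, size_factors(reference, "library"))
    query_log = normalize_log(query, size_factors(query, "library"))
    hvgs = select_hvgs(np.vstack([ref_log, query_log]), params.n_hvgs)
    ref_pcs, query_pcs, _ = joint_pca(
        ref_log, query_log, hvgs, params.n_pcs, seed=params.seed
    )
    if correct_batch:
        ref_pcs, query_pcs, _ = mnn_correct(
            ref_pcs, query_pcs, params.mnn_k, params.mnn_sigma
        )
    return transfer_labels(
        ref_pcs,
        query_pcs,
        ref_labels,
        params.k_neighbors,
        ref_cell_ids=reference.cell_ids,
        query_cell_ids=query.cell_ids,
    )
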