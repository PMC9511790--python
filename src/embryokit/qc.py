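"""Per-platform cell quality control and size-factor normalization.

QC gates follow the study design: droplet (10x-style) cells need at
least 1500 UMIs with at most 30% mitochondrial and 35% ribosomal reads;
plate (Smart-seq-style) cells need at least 4000 reads with at most 10%
mitochondrial and 20% ribosomal reads. Methylation cells need >=5000
covered CpGs with a global methylation rate of at least 50%;
accessibility cells need >=10000 GpCs with a global rate between 10 and
40%. All threshold comparisons are inclusive.

A cell's global methylation is the mean of per-site *binarized* rates:
a site with meth/(meth+unmeth) >= 0.5 counts as methylated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg

from .io import CountMatrix, MethCallSet

__all__ = ["QCParams", "NormalizationModel", "qc_rna", "qc_nmt", "size_factors",
           "normalize_log"]


@dataclass
class QCParams:
    min_counts_droplet: int = 1500
    min_counts_plate: int = 4000
    max_mito_pct_droplet: float = 30.0
    max_mito_pct_plate: float = 10.0
    max_ribo_pct_droplet: float = 35.0
    max_ribo_pct_plate: float = 20.0
    meth_min_sites: int = 5000
    acc_min_sites: int = 10000
    meth_global_min: float = 50.0
    acc_global_range: tuple = (10.0, 40.0)

    def __post_init__(self):
        pcts = [
            self.max_mito_pct_droplet, self.max_mito_pct_plate,
            self.max_ribo_pct_droplet, self.max_ribo_pct_plate,
            self.meth_global_min, *self.acc_global_range,
        ]
        if any(not (0.0 <= p <= 100.0) for p in pcts):
            raise ValueError("percentage thresholds must lie in [0, 100]")
        if self.min_counts_droplet <= 0 or self.min_counts_plate <= 0:
            raise ValueError("min_counts must be positive")

    def rna_thresholds(self, platform: str):
        if platform == "droplet":
            return (self.min_counts_droplet, self.max_mito_pct_droplet,
                    self.max_ribo_pct_droplet)
        if platform == "plate":
            return (self.min_counts_plate, self.max_mito_pct_plate,
                    self.max_ribo_pct_plate)
        raise ValueError(f"unknown platform {platform!r}")


@dataclass
class NormalizationModel:
    """Per-cell size factors (positive, rescaled to mean 1)."""

    size_factors: np.ndarray
    method: str

    def __post_init__(self):
        self.size_factors = np.asarray(self.size_factors, float)
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def qc_rna(
    counts: CountMatrix,
    mito_genes,
    ribo_genes,
    params: QCParams,
    platform: str = "droplet",
) -> pd.DataFrame:
    """Per-cell QC metrics and pass flag.

    A cell passes iff total >= min_counts AND mito% <= max AND
    ribo% <= max (inclusive comparisons).
    """
    mito_genes = set(mito_genes)
    ribo_genes = set(ribo_genes)
    unknown = (mito_genes | ribo_genes) - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"flag genes absent from matrix: {sorted(unknown)[:5]}")
    if not mito_genes:
        warnings.warn("empty mitochondrial gene set; mito%% defined as 0")
    if not ribo_genes:
        warnings.warn("empty ribosomal gene set; ribo%% defined as 0")
    total = counts.total_counts().astype(float)
    safe_total = np.where(total > 0, total, 1.0)

    def _pct(genes):
        if not genes:
            return np.zeros(counts.n_cells)
        mask = np.array([g in genes for g in counts.gene_ids])
        s = np.asarray(counts.values[:, mask].sum(axis=1)).ravel()
        return 100.0 * s / safe_total

    mito_pct = _pct(mito_genes)
    ribo_pct = _pct(ribo_genes)
    min_counts, max_mito, max_ribo = params.rna_thresholds(platform)
    passed = (total >= min_counts) & (mito_pct <= max_mito) & (ribo_pct <= max_ribo)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "total_counts": total.astype(int),
            "mito_pct": mito_pct,
            "ribo_pct": ribo_pct,
            "pass": passed,
        }
    )


def qc_nmt(calls: MethCallSet, params: QCParams) -> dict:
    """QC one methylation/accessibility cell.

    Returns a dict with cell_id, context, n_sites, global_rate (in %)
    and the pass flag. The context determines the threshold set.
    """
    n_sites = calls.n_sites
    rate = 100.0 * calls.binary_rates().mean() if n_sites else float("nan")
    if calls.context == "CpG":
        ok = n_sites >= params.meth_min_sites and rate >= params.meth_global_min
    elif calls.context == "GpC":
        lo, hi = params.acc_global_range
        ok = n_sites >= params.acc_min_sites and lo <= rate <= hi
    else:  # pragma: no cover - MethCallSet validates context
        raise ValueError(f"unknown context {calls.context!r}")
    return {
        "cell_id": calls.cell_id,
        "context": calls.context,
        "n_sites": n_sites,
        "global_rate": rate,
        "pass": bool(ok),
    }


def size_factors(
    counts: CountMatrix, method: str = "library", seed: int = 0
) -> NormalizationModel:
    """Estimate per-cell size factors, rescaled to mean 1.

    method "library": factor proportional to total counts.
    method "pooled": pool-and-deconvolve estimator — cells are arranged
    on a ring ordered by library size, pools of sizes {5, 10, 20}
    (capped by the number of cells) are summed, each pool's factor sum
    is estimated by the median count ratio to the average-cell
    reference profile, and the per-cell factors solve the resulting
    sparse least-squares system. Falls back to "library" below 50 cells.
    """
    totals = counts.total_counts().astype(float)
    if counts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if (totals == 0).any():
        raise ValueError("cell with zero total counts (should have failed QC)")
    if method == "library":
        f = totals / totals.mean()
        return NormalizationModel(f, "library")
    if method != "pooled":
        raise ValueError(f"unknown method {method!r}")
    n = counts.n_cells
    if n < 50:
        warnings.warn("pooled deconvolution needs >=50 cells; using library sizes")
        return NormalizationModel(totals / totals.mean(), "library")

    Y = np.asarray(counts.values.todense(), float)
    ref = Y.mean(axis=0)
    usable = ref > 0
    order = np.argsort(totals, kind="mergesort")  # ring ordered by depth
    rows, cols, vals, b = [], [], [], []
    eq = 0
    for pool_size in (5, 10, 20):
        s = min(pool_size, n)
        for start in range(n):
            members = order[(start + np.arange(s)) % n]
            pooled = Y[members].sum(axis=0)
            ratio = np.median(pooled[usable] / ref[usable])
            for c in members:
                rows.append(eq)
                cols.append(c)
                vals.append(1.0)
            b.append(ratio)
            eq += 1
    # low-weight ridge toward library-size factors keeps the system full rank
    lib = totals / totals.mean()
    w = 0.01
    for c in range(n):
        rows.append(eq)
        cols.append(c)
        vals.append(w)
        b.append(w * lib[c])
        eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    f = scipy.sparse.linalg.lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10)[0]
    f = np.maximum(f, 1e-8)
    return NormalizationModel(f / f.mean(), "pooled")


def normalize_log(counts: CountMatrix, model: NormalizationModel) -> np.ndarray:
    """log1p of size-factor-normalized counts (dense, cells × genes)."""
    X = np.asarray(counts.values.todense(), float)
    return np.log1p(X / model.size_factors[:, None])
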