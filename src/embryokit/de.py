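"""Pseudobulk negative-binomial differential expression and marker genes.

The unit of replication is the embryo: within one cell type, counts are
summed per embryo into pseudobulk samples, normalized by median-of-
ratios factors, and tested gene-wise under a negative-binomial
generalized linear model with a log link and offset log(size factor).

Dispersion estimation follows the standard empirical-Bayes recipe:
tagwise dispersions solve the Pearson moment equation, a lowess trend
is fitted against mean abundance in log space, and tagwise values are
shrunk toward the trend with weights given by the residual degrees of
freedom against a prior df. Two test modes are available:

* ``"qlf"`` (default) — quasi-likelihood F-test: the deviance drop of
  the group coefficient is referred to an F distribution whose
  denominator is the gene's moderated quasi-dispersion (deviance-based,
  squeezed across genes limma-style).
* ``"lrt"`` — NB likelihood-ratio test against chi-squared(1).

Significance: Benjamini–Hochberg FDR 1% and |log2FC| >= 1. Marker genes
of a cell type are those upregulated (same significance contract) in
more than 75% of its pairwise comparisons against the other types —
strictly more than, so 3 of 4 comparisons does not qualify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix

__all__ = [
    "DEParams",
    "MarkerParams",
    "PseudobulkMatrix",
    "make_pseudobulk",
    "median_of_ratios",
    "bh_adjust",
    "nb_test",
    "find_markers",
    "de_by_marker_identity",
    "gene_set_summary",
]


@dataclass
class DEParams:
    fdr: float = 0.01
    min_abs_log2fc: float = 1.0
    min_cells_per_sample: int = 10
    min_samples_per_group: int = 2
    method: str = "qlf"  # or "lrt"
    prior_count: float = 0.125  # per sample, stabilizes log2FC
    prior_df: float = 10.0  # dispersion-shrinkage prior df

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if self.method not in ("qlf", "lrt"):
            raise ValueError("method must be 'qlf' or 'lrt'")


@dataclass
class MarkerParams:
    pairwise_fraction: float = 0.75

    def __post_init__(self):
        if not (0.0 < self.pairwise_fraction <= 1.0):
            raise ValueError("pairwise_fraction must lie in (0, 1]")


@dataclass
class PseudobulkMatrix:
    """Summed counts per sample × gene within one cell type."""

    counts: np.ndarray  # samples x genes, integer sums
    sample_ids: np.ndarray
    gene_ids: np.ndarray
    factors: np.ndarray  # median-of-ratios normalization factors
    groups: np.ndarray  # per-sample group label (e.g. genotype)
    cell_type: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


def median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """DESeq-style factors: per sample, the median over genes (with an
    all-sample-nonzero geometric mean) of count / geometric mean."""
    Y = np.asarray(counts, float)
    usable = (Y > 0).all(axis=0)
    if not usable.any():
        raise ValueError("no gene is nonzero in every sample")
    logg = np.log(Y[:, usable]).mean(axis=0)
    return np.exp(np.median(np.log(Y[:, usable]) - logg, axis=1))


def make_pseudobulk(
    counts: CountMatrix,
    annotations: pd.DataFrame,
    cell_type: str,
    group_col: str = "genotype",
    sample_col: str = "embryo_id",
    cell_type_col: str = "cell_type",
    min_cells_per_sample: int = 10,
) -> PseudobulkMatrix:
    """Sum counts per sample over the cells of one type.

    Samples contributing fewer than ``min_cells_per_sample`` cells are
    dropped.
    """
    ann = annotations.set_index("cell_id").loc[list(counts.cell_ids)]
    mask = (ann[cell_type_col] == cell_type).to_numpy()
    sub_ann = ann[mask]
    samples = sorted(sub_ann[sample_col].unique())
    rows, keep_ids, groups = [], [], []
    for s in samples:
        cells = np.flatnonzero(mask & (ann[sample_col] == s).to_numpy())
        if len(cells) < min_cells_per_sample:
            continue
        rows.append(np.asarray(counts.values[cells].sum(axis=0)).ravel())
        keep_ids.append(s)
        groups.append(sub_ann.loc[sub_ann[sample_col] == s, group_col].iloc[0])
    if not rows:
        raise ValueError(f"no samples with >= {min_cells_per_sample} cells "
                         f"of type {cell_type!r}")
    Y = np.vstack(rows)
    return PseudobulkMatrix(
        counts=Y,
        sample_ids=np.array(keep_ids, dtype=object),
        gene_ids=np.asarray(counts.gene_ids, dtype=object),
        factors=median_of_ratios(Y),
        groups=np.array(groups, dtype=object),
        cell_type=cell_type,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# NB GLM machinery (vectorized across genes)
# ---------------------------------------------------------------------------

def _fit_means(Y, f, phi, design):
    """Solve the NB score equations for per-group means with offsets.

    ``design`` is a list of sample-index arrays (one per coefficient
    group); returns mu (samples x genes). Fixed-point iteration on
    m = sum(y/(1+phi f m)) / sum(f/(1+phi f m)), exact for phi = 0.
    """
    S, G = Y.shape
    mu = np.zeros_like(Y, dtype=float)
    for idx in design:
        y = Y[idx]
        fs = f[idx][:, None]
        m = y.sum(axis=0) / fs.sum()
        m = np.maximum(m, 1e-12)
        for _ in range(50):
            denom = 1.0 + phi[None, :] * fs * m[None, :]
            m_new = (y / denom).sum(axis=0) / (fs / denom).sum(axis=0)
            m_new = np.maximum(m_new, 1e-12)
            if np.max(np.abs(np.log(m_new) - np.log(m))) < 1e-10:
                m = m_new
                break
            m = m_new
        mu[idx] = fs * m[None, :]
    return mu


def _pearson_dispersion(Y, mu, df):
    """Per-gene dispersion solving sum((y-mu)^2/(mu+phi mu^2)) = df."""
    G = Y.shape[1]
    phi = np.zeros(G)
    resid2 = (Y - mu) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        x2_at = lambda ph: np.where(
            mu > 0, resid2 / (mu * (1.0 + ph * mu)), 0.0
        ).sum(axis=0)
    x2_0 = x2_at(np.zeros(G))
    need = x2_0 > df
    lo = np.zeros(G)
    hi = np.full(G, 1e-4)
    # expand upper bracket until X^2(hi) <= df
    for _ in range(40):
        x2_hi = x2_at(hi)
        todo = need & (x2_hi > df)
        if not todo.any():
            break
        hi[todo] *= 4.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        high = x2_at(mid) > df
        lo = np.where(need & high, mid, lo)
        hi = np.where(need & ~high, mid, hi)
    phi[need] = 0.5 * (lo + hi)[need]
    return phi


def _shrink_dispersion(phi, abundance, resid_df, prior_df):
    """Lowess trend in log space + EB shrinkage toward the trend."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    eps = 1e-4
    logphi = np.log(phi + eps)
    loga = np.log(abundance + 1e-8)
    if len(phi) >= 20:
        fit = lowess(logphi, loga, frac=0.5, return_sorted=True)
        trend = np.interp(loga, fit[:, 0], fit[:, 1])
    else:
        trend = np.full(len(phi), logphi.mean())
    w = resid_df / (resid_df + prior_df)
    shrunk = np.exp(w * logphi + (1.0 - w) * trend) - eps
    return np.maximum(shrunk, 0.0), np.maximum(np.exp(trend) - eps, 0.0)


def _nb_deviance(Y, mu, phi):
    """Per-gene NB deviance (Poisson when phi = 0)."""
    Y = np.asarray(Y, float)
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Y > 0, Y * np.log(Y / mu), 0.0)
    phi_b = np.broadcast_to(phi[None, :], Y.shape)
    pos = phi_b > 0
    term2 = np.empty_like(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        term2[pos] = (Y[pos] + 1.0 / phi_b[pos]) * np.log(
            (1.0 + phi_b[pos] * Y[pos]) / (1.0 + phi_b[pos] * mu[pos])
        )
    term2[~pos] = Y[~pos] - mu[~pos]
    return 2.0 * (term1 - term2).sum(axis=0)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in limma)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _squeeze_var(s2, df):
    """Moment-match a scaled F prior to the quasi-dispersions.

    Returns (s2_post, prior_df). Infinite prior df collapses all values
    onto the prior mean.
    """
    s2 = np.maximum(s2, 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0 or not np.isfinite(evar):
        d0 = np.inf
        s02 = np.exp(e.mean())
        return np.full_like(s2, s02), d0
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def nb_test(
    pb: PseudobulkMatrix,
    params: DEParams | None = None,
    group_order=None,
) -> pd.DataFrame:
    """Two-group NB differential expression on pseudobulk samples.

    The reported log2 fold change is target vs baseline (second vs
    first entry of ``group_order``), computed from normalized group
    means with a prior count of ``params.prior_count`` per sample.
    All-zero genes are excluded from testing and from the BH family.

    Returns a DataFrame indexed by gene with columns log2fc, dispersion,
    statistic, pvalue, padj, significant, direction.
    """
    params = params or DEParams()
    labels = list(dict.fromkeys(pb.groups)) if group_order is None else list(group_order)
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g0 = np.flatnonzero(pb.groups == labels[0])
    g1 = np.flatnonzero(pb.groups == labels[1])
    if min(len(g0), len(g1)) < params.min_samples_per_group:
        raise ValueError(
            f"need >= {params.min_samples_per_group} samples per group "
            f"(got {len(g0)} vs {len(g1)})"
        )
    Y_all = np.asarray(pb.counts, float)
    f = np.asarray(pb.factors, float)
    tested = Y_all.sum(axis=0) > 0
    Y = Y_all[:, tested]
    genes = pb.gene_ids[tested]
    S, G = Y.shape
    df_full = S - 2
    if df_full < 1:
        raise ValueError("no residual degrees of freedom (need > 2 samples)")

    # 1. initial means (Poisson solution of the score equations)
    mu0 = _fit_means(Y, f, np.zeros(G), [g0, g1])
    # 2. tagwise dispersion by Pearson moment matching, then trend + EB
    phi_tag = _pearson_dispersion(Y, mu0, df_full)
    abundance = (Y / f[:, None]).mean(axis=0)
    phi, _ = _shrink_dispersion(phi_tag, abundance, df_full, params.prior_df)
    # 3. final NB fits under the shrunk dispersion
    mu_full = _fit_means(Y, f, phi, [g0, g1])
    mu_null = _fit_means(Y, f, phi, [np.arange(S)])
    dev_full = _nb_deviance(Y, mu_full, phi)
    dev_null = _nb_deviance(Y, mu_null, phi)
    lr = np.maximum(dev_null - dev_full, 0.0)

    if params.method == "lrt":
        pvalues = stats.chi2.sf(lr, 1)
        stat = lr
    else:
        s2 = dev_full / df_full
        s2_post, d0 = _squeeze_var(s2, df_full)
        stat = lr / np.maximum(s2_post, 1e-10)
        df2 = df_full + (d0 if np.isfinite(d0) else 1e6)
        pvalues = stats.f.sf(stat, 1, df2)

    # shrunk log2 fold change: normalized group means + prior counts
    z = Y / f[:, None]
    c = params.prior_count
    m0 = (z[g0].sum(axis=0) + c * len(g0)) / len(g0)
    m1 = (z[g1].sum(axis=0) + c * len(g1)) / len(g1)
    log2fc = np.log2(m1 / m0)

    padj = bh_adjust(pvalues)
    significant = (padj <= params.fdr) & (np.abs(log2fc) >= params.min_abs_log2fc)
    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "dispersion": phi,
            "statistic": stat,
            "pvalue": pvalues,
            "padj": padj,
            "significant": significant,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        },
        index=pd.Index(genes, name="gene"),
    )
    res.attrs["groups"] = (labels[0], labels[1])
    res.attrs["excluded_all_zero"] = list(pb.gene_ids[~tested])
    return res


# ---------------------------------------------------------------------------
# marker genes and summaries
# ---------------------------------------------------------------------------

def find_markers(
    counts: CountMatrix,
    annotations: pd.DataFrame,
    de_params: DEParams | None = None,
    marker_params: MarkerParams | None = None,
    cell_type_col: str = "cell_type",
    sample_col: str = "embryo_id",
    min_cells_per_sample: int = 10,
) -> dict:
    """Marker genes per cell type via the pairwise-DE fraction rule.

    For each unordered pair of cell types, pseudobulk samples (one per
    embryo per type) are tested; a gene marks a type when it is
    significantly upregulated in that type in strictly more than
    ``pairwise_fraction`` of its C-1 comparisons. A gene may mark
    several types.
    """
    de_params = de_params or DEParams()
    marker_params = marker_params or MarkerParams()
    ann = annotations
    types = sorted(ann[cell_type_col].dropna().unique())
    C = len(types)
    if C < 3:
        raise ValueError("need at least 3 cell types for the fraction rule")
    up_counts = {t: pd.Series(0, index=pd.Index(counts.gene_ids, name="gene"))
                 for t in types}
    compared = {t: 0 for t in types}
    for i in range(C):
        for j in range(i + 1, C):
            a, b = types[i], types[j]
            try:
                pb = _pair_pseudobulk(
                    counts, ann, a, b, cell_type_col, min_cells_per_sample
                )
                res = nb_test(pb, de_params, group_order=(a, b))
            except ValueError:
                continue
            compared[a] += 1
            compared[b] += 1
            sig = res[res["significant"]]
            up_in_b = sig[sig["log2fc"] > 0].index
            up_in_a = sig[sig["log2fc"] < 0].index
            up_counts[a].loc[up_counts[a].index.isin(up_in_a)] += 1
            up_counts[b].loc[up_counts[b].index.isin(up_in_b)] += 1
    markers = {}
    for t in types:
        need = marker_params.pairwise_fraction * (C - 1)
        markers[t] = set(up_counts[t].index[up_counts[t] > need])
    return markers


def _pair_pseudobulk(counts, ann, type_a, type_b, cell_type_col, min_cells):
    """Pseudobulk for one pairwise comparison: samples are (embryo, type)."""
    cid_pos = {c: k for k, c in enumerate(counts.cell_ids)}
    rows, ids, groups = [], [], []
    for t in (type_a, type_b):
        sub = ann[ann[cell_type_col] == t]
        for emb, cells in sub.groupby("embryo_id")["cell_id"]:
            if len(cells) < min_cells:
                continue
            idx = [cid_pos[c] for c in cells]
            rows.append(np.asarray(counts.values[idx].sum(axis=0)).ravel())
            ids.append(f"{emb}|{t}")
            groups.append(t)
    groups = np.array(groups, dtype=object)
    if (groups == type_a).sum() < 2 or (groups == type_b).sum() < 2:
        raise ValueError("fewer than 2 pseudobulk samples in a group")
    Y = np.vstack(rows)
    return PseudobulkMatrix(
        counts=Y,
        sample_ids=np.array(ids, dtype=object),
        gene_ids=np.asarray(counts.gene_ids, dtype=object),
        factors=median_of_ratios(Y),
        groups=groups,
    )


def de_by_marker_identity(de_results: dict, marker_sets: dict) -> pd.DataFrame:
    """Cross-tabulate DE genes by the cell type they mark.

    ``de_results`` maps tested cell type -> nb_test DataFrame;
    ``marker_sets`` maps marker cell type -> gene set. A gene marking
    several types increments each of them.
    """
    rows = []
    for tested, res in de_results.items():
        sig = res[res["significant"]]
        for direction in ("up", "down"):
            genes = set(sig.index[sig["direction"] == direction])
            for marker_of, mset in marker_sets.items():
                rows.append(
                    {
                        "cell_type": tested,
                        "direction": direction,
                        "marker_of": marker_of,
                        "n_genes": len(genes & set(mset)),
                    }
                )
    return pd.DataFrame(rows)


def gene_set_summary(de_results: dict, gene_sets: dict) -> tuple:
    """Restrict DE output to user-supplied gene sets.

    Returns (summary, heatmap, untested): per-set/per-cell-type up and
    down counts; a genes × cell types log2FC table per set; and the set
    genes absent from the tested universe, reported separately rather
    than as zeros.
    """
    summary_rows, heat_rows, untested = [], [], {}
    for set_name, genes in gene_sets.items():
        genes = list(genes)
        untested[set_name] = []
        for ct, res in de_results.items():
            present = [g for g in genes if g in res.index]
            sub = res.loc[present]
            sig = sub[sub["significant"]]
            summary_rows.append(
                {
                    "gene_set": set_name,
                    "cell_type": ct,
                    "n_up": int((sig["direction"] == "up").sum()),
                    "n_down": int((sig["direction"] == "down").sum()),
                    "n_tested": len(present),
                }
            )
            for g in present:
                heat_rows.append(
                    {"gene_set": set_name, "gene": g, "cell_type": ct,
                     "log2fc": res.loc[g, "log2fc"]}
                )
        tested_any = set().union(*(set(r.index) for r in de_results.values())) \
            if de_results else set()
        untested[set_name] = sorted(set(genes) - tested_any)
    heat = (
        pd.DataFrame(heat_rows)
        .pivot_table(index=["gene_set", "gene"], columns="cell_type",
                     values="log2fc")
        if heat_rows
        else pd.DataFrame()
    )
    return pd.DataFrame(summary_rows), heat, untested
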