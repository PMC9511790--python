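"""Cell-type composition shifts and embryo staging.

Composition phenotyping compares per-embryo cell-type proportions
between knockout and wildtype embryos as log2 ratios, either against
the mean wildtype composition or — for chimaeras — against the matched
host embryo. Staging projects query and staged reference embryos
jointly into PCA space of their proportion vectors and scores each
stage by inverse distance, minmax-normalized to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProportionTable", "StageAssignment", "proportions", "log2_shift",
           "stage_embryos"]


@dataclass
class ProportionTable:
    """Embryos × cell types proportions plus per-embryo metadata.

    ``proportions`` is indexed by embryo_id; ``meta`` carries at least a
    ``genotype`` column and, for chimaera designs, ``host_embryo_id``.
    """

    proportions: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        p = self.proportions
        if (p.to_numpy() < 0).any():
            raise ValueError("negative proportion")
        if not np.allclose(p.sum(axis=1).to_numpy(), 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")


@dataclass
class StageAssignment:
    """Per-query-embryo stage scores in [0, 1] with argmax stage."""

    scores: pd.DataFrame  # query embryos x stages, minmax in [0, 1]
    assigned: pd.Series  # argmax stage per query embryo
    distances: pd.DataFrame  # query embryos x reference embryos


def proportions(
    annotations: pd.DataFrame,
    pseudocount: float = 1.0,
    cell_types=None,
    cell_type_col: str = "cell_type",
) -> ProportionTable:
    """Per-embryo cell-type proportions over a shared vocabulary.

    proportion = (count + pseudocount) / sum(count + pseudocount). The
    default pseudocount of 1 keeps downstream log2 ratios finite for
    cell types absent from an embryo. Embryos with zero cells are
    dropped with a warning.
    """
    ann = annotations
    if cell_types is None:
        cell_types = sorted(ann[cell_type_col].dropna().unique())
    counts = (
        ann.dropna(subset=[cell_type_col])
        .groupby(["embryo_id", cell_type_col], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cell_types, fill_value=0)
    )
    empty = set(ann["embryo_id"].unique()) - set(counts.index)
    if empty:
        warnings.warn(f"embryos with no typed cells dropped: {sorted(empty)}")
    padded = counts + pseudocount
    props = padded.div(padded.sum(axis=1), axis=0)
    meta_cols = [c for c in ("genotype", "host_embryo_id", "stage_label")
                 if c in ann.columns]
    meta = ann.groupby("embryo_id")[meta_cols].first().reindex(props.index)
    return ProportionTable(props, meta)


def log2_shift(
    table: ProportionTable,
    mode: str = "ko_vs_wt_mean",
    baseline_genotype: str = "WT",
) -> pd.DataFrame:
    """Per-(embryo, cell type) log2 proportion ratios against a baseline.

    mode "ko_vs_wt_mean": each non-baseline embryo vs the arithmetic
    mean of the baseline-genotype embryo proportions. mode
    "chimaera_host_matched": each embryo vs its matched host embryo
    (requires a ``host_embryo_id`` metadata column).
    """
    props, meta = table.proportions, table.meta
    if mode == "ko_vs_wt_mean":
        wt = props[meta["genotype"] == baseline_genotype]
        if wt.empty:
            raise ValueError(f"no {baseline_genotype} embryos for the baseline")
        baseline = wt.mean(axis=0)
        query = props[meta["genotype"] != baseline_genotype]
        shifts = np.log2(query.div(baseline, axis=1))
    elif mode == "chimaera_host_matched":
        if "host_embryo_id" not in meta.columns or meta["host_embryo_id"].isna().all():
            raise ValueError("chimaera mode requires host_embryo_id links")
        rows = []
        query = props[meta["host_embryo_id"].notna()]
        for embryo_id, row in query.iterrows():
            host = meta.loc[embryo_id, "host_embryo_id"]
            if host not in props.index:
                raise ValueError(f"host embryo {host!r} missing from table")
            rows.append(np.log2(row / props.loc[host]))
        shifts = pd.DataFrame(rows, index=query.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    shifts = shifts.reset_index().melt(
        id_vars="embryo_id", var_name="cell_type", value_name="log2_shift"
    )
    return shifts


def stage_embryos(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    reference_stages: pd.Series,
    n_pcs: int | None = None,
) -> StageAssignment:
    """Assign each query embryo a stage by compositional similarity.

    PCA is fitted on the row-stacked (query + reference) proportion
    matrix, centred but not scaled. For each query embryo the Euclidean
    distance to every reference embryo is measured in PC space; a
    stage's raw score is the mean of 1/distance over that stage's
    reference embryos, and scores are minmax-normalized across stages.
    A zero distance (identical composition) sends that stage's score to
    the maximum before minmax. When all stage scores coincide (e.g. a
    single reference stage) every stage scores 1. Argmax ties break
    toward the earliest stage in reference order.
    """
    query = query.copy()
    reference = reference.reindex(columns=query.columns)
    stages = list(dict.fromkeys(reference_stages))  # preserve reference order
    if n_pcs is None:
        n_pcs = max(len(stages) - 1, 1)
    X = np.vstack([query.to_numpy(float), reference.to_numpy(float)])
    Xc = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(Xc.shape))
    # deterministic full SVD; these matrices are tiny (tens of embryos)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    pcs = Xc @ (vt.T * flip)[:, :n_pcs]
    qp, rp = pcs[: len(query)], pcs[len(query):]
    d = np.sqrt(((qp[:, None, :] - rp[None, :, :]) ** 2).sum(axis=2))
    distances = pd.DataFrame(d, index=query.index, columns=reference.index)

    stage_arr = np.asarray(list(reference_stages))
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), np.inf)
    raw = np.column_stack(
        [inv[:, stage_arr == s].mean(axis=1) for s in stages]
    )
    scores = np.empty_like(raw)
    for i in range(raw.shape[0]):
        row = raw[i].copy()
        finite = np.isfinite(row)
        if not finite.all():
            # zero distance: pin that stage at the maximum before minmax
            row[~finite] = row[finite].max() if finite.any() else 1.0
        lo, hi = row.min(), row.max()
        scores[i] = 1.0 if hi == lo else (row - lo) / (hi - lo)
    scores_df = pd.DataFrame(scores, index=query.index, columns=stages)
    assigned = pd.Series(
        [stages[int(np.argmax(scores[i]))] for i in range(len(scores))],
        index=query.index,
        name="assigned_stage",
    )
    return StageAssignment(scores_df, assigned, distances)
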