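"""Methylation/accessibility quantification over genomic features.

All quantities derive from *binarized* site rates (a covered site is
methylated when meth/(meth+unmeth) >= 0.5) aggregated under a binomial
model: for a feature, the number of trials is the number of covered
sites and the number of successes the number of methylated ones. The
same code path serves CpG methylation and GpC accessibility — the
context only changes which call set is supplied.

Coordinate bridge: features are 0-based half-open [start, end), call
positions 1-based; a site at position p lies in a feature iff
start < p <= end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import FeatureSet, MethCallSet

__all__ = [
    "ProfileParams",
    "aggregate_features",
    "feature_rate_matrix",
    "global_rate",
    "profile",
    "compare_groups",
]


@dataclass
class ProfileParams:
    window_size: int = 50
    flank: int = 2000

    def __post_init__(self):
        if self.flank % self.window_size != 0:
            raise ValueError("flank must be divisible by window_size")

    @property
    def n_windows(self) -> int:
        return 2 * self.flank // self.window_size

    def offsets(self) -> np.ndarray:
        """Left edge of each window relative to the feature centre."""
        return np.arange(-self.flank, self.flank, self.window_size)


def _chrom_arrays(calls: MethCallSet):
    """Per-chrom sorted positions, binarized rates and their prefix sums."""
    out = {}
    binary = calls.binary_rates()
    rec = calls.records
    for chrom, sub in rec.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        b = binary[sub.index.to_numpy()]
        prefix = np.concatenate([[0.0], np.cumsum(b)])
        out[chrom] = (pos, b, prefix)
    return out


def aggregate_features(calls: MethCallSet, features: FeatureSet) -> pd.DataFrame:
    """One cell's binomial rate per feature.

    Returns a DataFrame (cell_id, feature name, class, n_total, n_meth,
    rate); features with zero covered sites are *missing* from it, never
    reported as zero. A site inside several overlapping features
    contributes to each of them.
    """
    per_chrom = _chrom_arrays(calls)
    rows = []
    for _, f in features.intervals.iterrows():
        entry = per_chrom.get(f["chrom"])
        if entry is None:
            continue
        pos, _, prefix = entry
        # feature [start, end) 0-based <-> sites start < pos <= end
        lo = np.searchsorted(pos, f["start"] + 1, side="left")
        hi = np.searchsorted(pos, f["end"], side="right")
        n_total = int(hi - lo)
        if n_total == 0:
            continue
        n_meth = int(round(prefix[hi] - prefix[lo]))
        rows.append(
            {
                "cell_id": calls.cell_id,
                "feature": f["name"],
                "class_label": f["class_label"],
                "n_total": n_total,
                "n_meth": n_meth,
                "rate": n_meth / n_total,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "feature", "class_label", "n_total", "n_meth", "rate"]
    )


def feature_rate_matrix(calls_by_cell: dict, features: FeatureSet) -> pd.DataFrame:
    """Long-format cells × features rate table (missing entries absent)."""
    parts = [aggregate_features(c, features) for c in calls_by_cell.values()]
    if not parts:
        return pd.DataFrame(
            columns=["cell_id", "feature", "class_label", "n_total", "n_meth", "rate"]
        )
    return pd.concat(parts, ignore_index=True)


def global_rate(calls: MethCallSet) -> float:
    """Genome-wide mean of binarized site rates for one cell."""
    if calls.n_sites == 0:
        raise ValueError("cell has no covered sites")
    return float(calls.binary_rates().mean())


def profile(
    calls_by_cell: dict,
    features: FeatureSet,
    params: ProfileParams | None = None,
) -> pd.DataFrame:
    """Feature-centred metaprofile: running averages in 50 bp windows.

    Sites within ±flank of each feature centre (centre =
    floor((start+end)/2), windows half-open [c+o, c+o+w)) are pooled
    over all features of the set per cell; the group mean and standard
    deviation are then taken across cells, excluding from each window
    the cells with no sites there.

    Returns a DataFrame with columns offset, mean, sd, n_cells.
    """
    params = params or ProfileParams()
    if not calls_by_cell:
        raise ValueError("empty cell group")
    w, flank = params.window_size, params.flank
    nwin = params.n_windows
    centers = (
        (features.intervals["start"].to_numpy() + features.intervals["end"].to_numpy())
        // 2
    )
    chroms = features.intervals["chrom"].to_numpy()
    per_cell = np.full((len(calls_by_cell), nwin), np.nan)
    for ci, calls in enumerate(calls_by_cell.values()):
        sums = np.zeros(nwin)
        counts = np.zeros(nwin)
        per_chrom = _chrom_arrays(calls)
        for chrom, c in zip(chroms, centers):
            entry = per_chrom.get(chrom)
            if entry is None:
                continue
            pos, b, _ = entry
            # site pos (1-based) -> 0-based pos-1; window span [c-flank, c+flank)
            lo = np.searchsorted(pos, c - flank + 1, side="left")
            hi = np.searchsorted(pos, c + flank, side="right")
            if hi == lo:
                continue
            off = (pos[lo:hi] - 1) - c
            widx = (off + flank) // w
            np.add.at(sums, widx, b[lo:hi])
            np.add.at(counts, widx, 1.0)
        has = counts > 0
        per_cell[ci, has] = sums[has] / counts[has]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        mean = np.nanmean(per_cell, axis=0)
        sd = np.nanstd(per_cell, axis=0, ddof=1)
    n_cells = np.sum(~np.isnan(per_cell), axis=0)
    return pd.DataFrame(
        {"offset": params.offsets(), "mean": mean, "sd": sd, "n_cells": n_cells}
    )


def compare_groups(
    rate_table: pd.DataFrame,
    cell_groups: dict,
    group_order: tuple | None = None,
) -> pd.DataFrame:
    """Per-feature-class group comparison of per-cell mean rates.

    ``rate_table`` is the long-format output of
    :func:`feature_rate_matrix`; ``cell_groups`` maps group name ->
    iterable of cell ids (exactly two groups). For each class the
    per-cell mean rate over observed features is computed, and the
    difference of group medians (second minus first group) is reported
    with a Wilcoxon rank-sum p-value, BH-adjusted across classes. The
    test is skipped (NaN p) when a group has fewer than 3 cells; the
    effect size is still reported.
    """
    if group_order is None:
        group_order = tuple(cell_groups)
    if len(group_order) != 2:
        raise ValueError("exactly two groups are required")
    ga, gb = group_order
    sets = {g: set(cell_groups[g]) for g in group_order}
    cell_means = (
        rate_table.groupby(["class_label", "cell_id"], observed=True)["rate"]
        .mean()
        .reset_index()
    )
    rows = []
    for cls, sub in cell_means.groupby("class_label"):
        a = sub.loc[sub["cell_id"].isin(sets[ga]), "rate"].to_numpy()
        b = sub.loc[sub["cell_id"].isin(sets[gb]), "rate"].to_numpy()
        med_a = float(np.median(a)) if len(a) else np.nan
        med_b = float(np.median(b)) if len(b) else np.nan
        if len(a) >= 3 and len(b) >= 3:
            p = float(stats.ranksums(b, a).pvalue)
        else:
            p = np.nan
        rows.append(
            {
                "class_label": cls,
                f"median_{ga}": med_a,
                f"median_{gb}": med_b,
                "median_difference": med_b - med_a,
                "n_cells_a": len(a),
                "n_cells_b": len(b),
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    tested = out["pvalue"].notna()
    out["padj"] = np.nan
    if tested.any():
        out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out
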