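"""Binomial feature aggregation, global rates, metaprofiles, comparisons."""

import numpy as np
import pandas as pd
import pytest

from embryokit.epigenome import (
    ProfileParams,
    aggregate_features,
    compare_groups,
    feature_rate_matrix,
    global_rate,
    profile,
)
from embryokit.io import FeatureSet, MethCallSet


def _features(rows):
    return FeatureSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "class_label"]
    ))


def test_aggregate_binarization_example(meth_calls_factory):
    # sites (meth,total): (3,3),(0,2),(1,1) -> binarized {1,0,1} -> 2/3
    calls = meth_calls_factory(
        [("chr1", 101, 3, 0), ("chr1", 150, 0, 2), ("chr1", 199, 1, 0)]
    )
    feats = _features([("chr1", 100, 200, "f1", "enh")])
    out = aggregate_features(calls, feats)
    assert out.iloc[0]["n_total"] == 3
    assert out.iloc[0]["n_meth"] == 2
    assert out.iloc[0]["rate"] == pytest.approx(2 / 3)


def test_aggregate_zero_coverage_missing(meth_calls_factory):
    calls = meth_calls_factory([("chr1", 50, 1, 0)])
    feats = _features([("chr1", 100, 200, "f1", "enh"),
                       ("chr2", 0, 100, "f2", "enh")])
    out = aggregate_features(calls, feats)
    assert len(out) == 0  # missing, never zero


def test_aggregate_halfopen_boundaries(meth_calls_factory):
    # feature [100, 200) 0-based <-> 1-based positions 101..200 inclusive
    calls = meth_calls_factory(
        [("chr1", 100, 1, 0), ("chr1", 101, 1, 0), ("chr1", 200, 1, 0),
         ("chr1", 201, 1, 0)]
    )
    feats = _features([("chr1", 100, 200, "f1", "enh")])
    out = aggregate_features(calls, feats)
    assert out.iloc[0]["n_total"] == 2


def test_aggregate_matches_bruteforce_oracle(meth_calls_factory):
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 100_000), 1000, replace=False))
    meth = rng.integers(0, 4, 1000)
    unmeth = rng.integers(0, 4, 1000)
    keep = (meth + unmeth) > 0
    records = [("chr1", int(p), int(m), int(u))
               for p, m, u in zip(pos[keep], meth[keep], unmeth[keep])]
    calls = meth_calls_factory(records)
    starts = rng.integers(0, 95_000, 50)
    feats = _features(
        [("chr1", int(s), int(s + rng.integers(100, 5000)), f"f{i}", "enh")
         for i, s in enumerate(starts)]
    )
    out = aggregate_features(calls, feats).set_index("feature")
    # oracle: per-site interval scan
    for _, f in feats.intervals.iterrows():
        hits = [
            (m, u)
            for _, p, m, u in records
            if f["start"] < p <= f["end"]
        ]
        n_total = len(hits)
        n_meth = sum(1 for m, u in hits if m / (m + u) >= 0.5)
        if n_total == 0:
            assert f["name"] not in out.index
        else:
            assert out.loc[f["name"], "n_total"] == n_total
            assert out.loc[f["name"], "n_meth"] == n_meth
            assert 0.0 <= out.loc[f["name"], "rate"] <= 1.0


def test_overlapping_features_share_sites(meth_calls_factory):
    calls = meth_calls_factory([("chr1", 150, 1, 0)])
    feats = _features([("chr1", 100, 200, "f1", "a"),
                       ("chr1", 140, 160, "f2", "b")])
    out = aggregate_features(calls, feats)
    assert set(out["feature"]) == {"f1", "f2"}


def test_global_rate(meth_calls_factory):
    calls = meth_calls_factory([("chr1", 1, 1, 0), ("chr1", 2, 2, 0)])
    assert global_rate(calls) == 1.0
    calls2 = meth_calls_factory([("chr1", 1, 1, 0), ("chr1", 2, 0, 1)])
    assert global_rate(calls2) == 0.5
    empty = MethCallSet("CpG", "x", pd.DataFrame(
        columns=["chrom", "pos", "meth", "unmeth"]))
    with pytest.raises(ValueError, match="no covered sites"):
        global_rate(empty)


def test_profile_window_arithmetic(meth_calls_factory):
    params = ProfileParams()
    assert params.n_windows == 80
    assert params.offsets()[0] == -2000
    assert params.offsets()[-1] == 1950
    with pytest.raises(ValueError, match="divisible"):
        ProfileParams(window_size=60, flank=2000)


def test_profile_centre_dip_and_symmetry(meth_calls_factory):
    # plant a symmetric dip: sites within +-500 of the centre unmethylated,
    # outside fully methylated
    feats = _features([("chr1", 9_000, 11_000, "f1", "enh")])
    centre = 10_000
    records = []
    for off in range(-1975, 2000, 50):
        p = centre + off + 1  # 1-based
        meth = 0 if abs(off) <= 500 else 1
        records.append(("chr1", p, meth, 1 - meth if meth == 0 else 0))
    records = [("chr1", p, m, 1 - m) for _, p, m, _ in records]
    cells = {f"cell{i}": meth_calls_factory(records, cell_id=f"cell{i}")
             for i in range(3)}
    prof = profile(cells, feats)
    centre_mean = prof[(prof.offset >= -200) & (prof.offset < 200)]["mean"].mean()
    edge_mean = prof[(prof.offset < -1500) | (prof.offset >= 1500)]["mean"].mean()
    assert edge_mean - centre_mean >= 0.9
    sym = prof.set_index("offset")["mean"]
    for off in (250, 1000, 1800):
        left = sym.loc[-off - 50]  # window [-off-50, -off) mirrors [off, off+50)
        right = sym.loc[off]
        assert left == pytest.approx(right, abs=1e-9)


def test_profile_requires_cells():
    feats = _features([("chr1", 0, 100, "f1", "enh")])
    with pytest.raises(ValueError, match="empty cell group"):
        profile({}, feats)


def test_gpc_pipeline_same_code_path_empty_on_cpg_free(meth_calls_factory):
    # accessibility is the same computation parameterized by context; with
    # no GpC sites recorded the rate matrix is simply empty
    empty = MethCallSet("GpC", "cell0", pd.DataFrame(
        columns=["chrom", "pos", "meth", "unmeth"]))
    feats = _features([("chr1", 0, 1000, "f1", "enh")])
    out = feature_rate_matrix({"cell0": empty}, feats)
    assert len(out) == 0


def test_compare_groups_identical():
    rng = np.random.default_rng(1)
    rows = []
    for cid in range(10):
        for feat in range(5):
            rows.append(
                {"cell_id": f"c{cid}", "feature": f"f{feat}",
                 "class_label": "enh", "n_total": 4, "n_meth": 2, "rate": 0.5}
            )
    table = pd.DataFrame(rows)
    groups = {"WT": [f"c{i}" for i in range(5)],
              "TetTKO": [f"c{i}" for i in range(5, 10)]}
    out = compare_groups(table, groups, ("WT", "TetTKO"))
    assert out.iloc[0]["median_difference"] == 0.0
    assert out.iloc[0]["pvalue"] > 0.9


def test_compare_groups_small_group_skips_test():
    rows = [
        {"cell_id": c, "feature": "f", "class_label": "enh",
         "n_total": 2, "n_meth": 1, "rate": r}
        for c, r in [("a", 0.2), ("b", 0.3), ("c", 0.8), ("d", 0.9)]
    ]
    out = compare_groups(pd.DataFrame(rows), {"g1": ["a", "b"], "g2": ["c", "d"]})
    assert np.isnan(out.iloc[0]["pvalue"])
    assert out.iloc[0]["median_difference"] == pytest.approx(0.6)


def test_tiling_features_conserve_sites(meth_calls_factory):
    # non-overlapping features tiling the covered region: total trials equal
    # the number of covered sites
    records = [("chr1", p, 1, 0) for p in range(1, 301)]
    calls = meth_calls_factory(records)
    feats = _features([("chr1", i * 100, (i + 1) * 100, f"f{i}", "t")
                       for i in range(3)])
    out = aggregate_features(calls, feats)
    assert out["n_total"].sum() == 300
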