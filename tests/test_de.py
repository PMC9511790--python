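"""Pseudobulk construction, NB testing, BH, and the marker rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from embryokit import simulate
from embryokit.de import (
    DEParams,
    MarkerParams,
    PseudobulkMatrix,
    bh_adjust,
    de_by_marker_identity,
    find_markers,
    gene_set_summary,
    make_pseudobulk,
    median_of_ratios,
    nb_test,
)
from embryokit.io import CountMatrix


def _pb(Y, groups, factors=None):
    Y = np.asarray(Y)
    return PseudobulkMatrix(
        counts=Y,
        sample_ids=np.array([f"s{i}" for i in range(Y.shape[0])], dtype=object),
        gene_ids=np.array([f"g{i}" for i in range(Y.shape[1])], dtype=object),
        factors=np.asarray(factors) if factors is not None else median_of_ratios(Y),
        groups=np.asarray(groups, dtype=object),
    )


def _nb_counts(rng, mu, phi):
    n = 1.0 / phi
    return rng.negative_binomial(n, n / (n + mu))


def test_median_of_ratios_examples():
    Y = np.array([[10, 20, 5], [10, 20, 5]])
    assert np.allclose(median_of_ratios(Y), 1.0)  # identical samples
    Y2 = np.array([[10, 20, 5], [20, 40, 10]])
    f = median_of_ratios(Y2)
    assert f[1] / f[0] == pytest.approx(2.0)  # doubled sample doubles factor


def test_make_pseudobulk_sums_and_filters():
    counts = CountMatrix(
        np.array([[1, 0], [2, 1], [3, 0], [9, 9]]),
        ["c1", "c2", "c3", "c4"],
        ["g1", "g2"],
    )
    ann = pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "embryo_id": ["e1", "e1", "e1", "e2"],
            "genotype": ["WT", "WT", "WT", "KO"],
            "cell_type": ["A", "A", "A", "A"],
        }
    )
    pb = make_pseudobulk(counts, ann, "A", min_cells_per_sample=2)
    assert list(pb.sample_ids) == ["e1"]  # e2 has only 1 cell
    assert list(pb.counts[0]) == [6, 1]


@settings(max_examples=30, deadline=None)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
)
def test_bh_matches_stepup_oracle(pvals):
    p = np.asarray(pvals)
    adj = bh_adjust(p)
    # brute-force step-up: adj_i = min_{j: p_j >= p_i} p_j * n / rank_j
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    oracle = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        oracle[i] = running
    assert np.allclose(adj, oracle)


def _simulated_pb(seed, n_genes=400, n_de=0, lfc=2.0, phi=0.1):
    rng = np.random.default_rng(seed)
    mean = rng.lognormal(4, 1, n_genes)
    libs = rng.lognormal(0, 0.3, 8)
    mu = np.outer(libs, mean)
    if n_de:
        mu[4:, :n_de] *= 2.0 ** lfc
    Y = _nb_counts(rng, mu, phi)
    return _pb(Y, ["A"] * 4 + ["B"] * 4)


@pytest.mark.parametrize("method", ["qlf", "lrt"])
def test_nb_test_null_calibration_and_power(method):
    params = DEParams(method=method)
    fps = []
    for seed in range(3):
        res = nb_test(_simulated_pb(seed), params, group_order=("A", "B"))
        fps.append(res["significant"].mean())
    assert np.mean(fps) <= 0.03
    res = nb_test(_simulated_pb(99, n_de=60), params, group_order=("A", "B"))
    power = res["significant"].to_numpy()[:60].mean()
    assert power >= 0.8
    planted = res.iloc[:60]["log2fc"].median()
    assert abs(planted - 2.0) < 0.5


def test_nb_test_identical_counts_not_significant():
    Y = np.tile([50, 7, 0, 100], (6, 1))
    pb = _pb(Y, ["A"] * 3 + ["B"] * 3, factors=np.ones(6))
    res = nb_test(pb, DEParams(), group_order=("A", "B"))
    assert np.allclose(res["log2fc"], 0.0, atol=1e-9)
    assert not res["significant"].any()
    # all-zero gene excluded from the tested family
    assert "g2" not in res.index
    assert "g2" in res.attrs["excluded_all_zero"]


def test_nb_test_invariant_to_orders():
    pb = _simulated_pb(5, n_genes=100, n_de=10)
    res = nb_test(pb, DEParams(), group_order=("A", "B"))
    rng = np.random.default_rng(0)
    sperm = rng.permutation(pb.counts.shape[0])
    gperm = rng.permutation(pb.counts.shape[1])
    pb2 = PseudobulkMatrix(
        pb.counts[np.ix_(sperm, gperm)],
        pb.sample_ids[sperm],
        pb.gene_ids[gperm],
        pb.factors[sperm],
        pb.groups[sperm],
    )
    res2 = nb_test(pb2, DEParams(), group_order=("A", "B"))
    joined = res.join(res2, rsuffix="_p")
    assert np.allclose(joined["pvalue"], joined["pvalue_p"], rtol=1e-6, atol=1e-12)
    assert np.allclose(joined["log2fc"], joined["log2fc_p"], rtol=1e-6)


def test_nb_test_scale_invariance_of_log2fc():
    pb = _simulated_pb(6, n_genes=80, n_de=10)
    res = nb_test(pb, DEParams(), group_order=("A", "B"))
    pb2 = PseudobulkMatrix(
        pb.counts * 2, pb.sample_ids, pb.gene_ids, pb.factors * 2, pb.groups
    )
    res2 = nb_test(pb2, DEParams(), group_order=("A", "B"))
    assert np.allclose(res["log2fc"], res2["log2fc"], atol=1e-6)


def test_nb_test_requires_two_groups_with_replicates():
    pb = _pb(np.ones((4, 5), dtype=int), ["A", "A", "A", "B"])
    with pytest.raises(ValueError, match="samples per group"):
        nb_test(pb, DEParams())


def _marker_atlas(seed=0):
    """5 types, 4 embryos; gene 0 is high in types A and E (so DE in only
    3 of A's 4 comparisons), gene 1 is high only in A (4 of 4)."""
    rng = np.random.default_rng(seed)
    types = ["A", "B", "C", "D", "E"]
    n_genes, n_cells = 60, 40
    base = rng.lognormal(2, 0.3, n_genes)
    profiles = {t: base.copy() for t in types}
    profiles["A"][0] *= 16
    profiles["E"][0] *= 16
    profiles["A"][1] *= 16
    rows, ann_rows = [], []
    cid = 0
    for t in types:
        for e in range(4):
            mu = np.tile(profiles[t], (n_cells, 1))
            rows.append(_nb_counts(rng, mu, 0.05))
            for _ in range(n_cells):
                ann_rows.append(
                    {"cell_id": f"c{cid}", "embryo_id": f"e{e}", "cell_type": t}
                )
                cid += 1
    counts = CountMatrix(
        np.vstack(rows),
        [f"c{i}" for i in range(cid)],
        [f"g{i}" for i in range(n_genes)],
    )
    return counts, pd.DataFrame(ann_rows)


def test_marker_rule_strict_threshold():
    counts, ann = _marker_atlas()
    markers = find_markers(counts, ann, DEParams(), MarkerParams())
    # gene 0: upregulated vs only 3 of A's 4 partners (tied with E) -> 3/4
    # comparisons = 0.75 exactly, which is NOT "more than 75%"
    assert "g0" not in markers["A"]
    assert "g1" in markers["A"]  # 4/4 comparisons
    assert "g0" not in markers["E"]
    # a gene can mark several types: make sure sets are allowed to overlap
    assert isinstance(markers["A"], set)


def test_marker_rule_needs_three_types():
    counts, ann = _marker_atlas()
    ann2 = ann[ann["cell_type"].isin(["A", "B"])]
    counts2 = counts.subset_cells(ann2["cell_id"].to_numpy())
    with pytest.raises(ValueError, match="3 cell types"):
        find_markers(counts2, ann2, DEParams(), MarkerParams())


def test_planted_markers_recovered_jaccard(small_atlas):
    spec, counts, ann, _ = small_atlas
    markers = find_markers(counts, ann, DEParams(), MarkerParams(),
                           min_cells_per_sample=10)
    truth = spec.marker_sets()
    for t in spec.cell_type_names:
        inter = len(markers[t] & truth[t])
        union = len(markers[t] | truth[t])
        assert inter / union >= 0.8


def test_de_by_marker_identity_counting():
    res = pd.DataFrame(
        {
            "log2fc": [2.0, 3.0, -2.0],
            "padj": [0.001, 0.001, 0.5],
            "significant": [True, True, False],
            "direction": ["up", "up", "down"],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    markers = {"erythroid": {"g1", "g2"}, "neural": {"g2"}, "gut": {"g9"}}
    cross = de_by_marker_identity({"blood": res}, markers)
    up = cross[(cross.direction == "up")].set_index("marker_of")["n_genes"]
    assert up["erythroid"] == 2
    assert up["neural"] == 1  # g2 counted once per set it belongs to
    assert up["gut"] == 0
    down = cross[(cross.direction == "down")]["n_genes"]
    assert (down == 0).all()


def test_gene_set_summary_untested_reported():
    res = pd.DataFrame(
        {
            "log2fc": [1.5, -0.2],
            "padj": [0.001, 0.9],
            "significant": [True, False],
            "direction": ["up", "down"],
        },
        index=pd.Index(["Hoxa9", "Pou5f1"], name="gene"),
    )
    summary, heat, untested = gene_set_summary(
        {"NMP": res}, {"hox": ["Hoxa9", "Hoxb9", "Pou5f1"]}
    )
    row = summary.iloc[0]
    assert row["n_up"] == 1 and row["n_down"] == 0 and row["n_tested"] == 2
    assert untested["hox"] == ["Hoxb9"]  # absent gene listed, not zeroed
    assert heat.shape[0] == 2
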