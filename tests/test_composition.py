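"""Proportion tables, log2 shifts, and embryo staging."""

import numpy as np
import pandas as pd
import pytest

from embryokit.composition import ProportionTable, log2_shift, proportions, stage_embryos


def _ann(rows):
    return pd.DataFrame(rows, columns=["cell_id", "embryo_id", "genotype", "cell_type"])


def test_proportions_basic():
    rows = [(f"c{i}", "e1", "WT", "A") for i in range(50)]
    rows += [(f"d{i}", "e1", "WT", "B") for i in range(50)]
    table = proportions(_ann(rows), pseudocount=0)
    assert np.allclose(table.proportions.loc["e1"], [0.5, 0.5])


def test_proportions_pseudocount_arithmetic():
    rows = [(f"c{i}", "e1", "WT", "A") for i in range(10)]
    table = proportions(_ann(rows), pseudocount=1, cell_types=["A", "B"])
    assert np.allclose(table.proportions.loc["e1"], [11 / 12, 1 / 12])


def test_proportions_rows_sum_to_one():
    rng = np.random.default_rng(0)
    rows = [
        (f"c{i}", f"e{rng.integers(3)}", "WT", f"t{rng.integers(4)}")
        for i in range(200)
    ]
    table = proportions(_ann(rows))
    assert np.allclose(table.proportions.sum(axis=1), 1.0)


def test_log2_shift_examples_and_antisymmetry():
    props = pd.DataFrame(
        {"A": [0.05, 0.10], "B": [0.95, 0.90]},
        index=pd.Index(["wt1", "ko1"], name="embryo_id"),
    )
    meta = pd.DataFrame({"genotype": ["WT", "Dnmt1KO"]}, index=props.index)
    shifts = log2_shift(ProportionTable(props, meta))
    a = shifts[(shifts.embryo_id == "ko1") & (shifts.cell_type == "A")][
        "log2_shift"
    ].iloc[0]
    assert a == pytest.approx(1.0)  # 0.10 vs 0.05
    # swapping query and baseline flips the sign
    meta2 = pd.DataFrame({"genotype": ["Dnmt1KO", "WT"]}, index=props.index)
    shifts2 = log2_shift(ProportionTable(props, meta2))
    b = shifts2[(shifts2.embryo_id == "wt1") & (shifts2.cell_type == "A")][
        "log2_shift"
    ].iloc[0]
    assert b == pytest.approx(-a)


def test_log2_shift_zero_for_equal_proportions():
    props = pd.DataFrame(
        {"A": [0.3, 0.3], "B": [0.7, 0.7]},
        index=pd.Index(["wt1", "ko1"], name="embryo_id"),
    )
    meta = pd.DataFrame({"genotype": ["WT", "TetTKO"]}, index=props.index)
    shifts = log2_shift(ProportionTable(props, meta))
    assert np.allclose(shifts["log2_shift"], 0.0)


def test_log2_shift_chimaera_host_matched():
    props = pd.DataFrame(
        {"A": [0.2, 0.05], "B": [0.8, 0.95]},
        index=pd.Index(["host1", "tko1"], name="embryo_id"),
    )
    meta = pd.DataFrame(
        {"genotype": ["WT", "TetTKO"], "host_embryo_id": [None, "host1"]},
        index=props.index,
    )
    shifts = log2_shift(ProportionTable(props, meta), "chimaera_host_matched")
    a = shifts[(shifts.embryo_id == "tko1") & (shifts.cell_type == "A")][
        "log2_shift"
    ].iloc[0]
    assert a == pytest.approx(-2.0)


def test_log2_shift_chimaera_requires_links():
    props = pd.DataFrame({"A": [1.0]}, index=pd.Index(["e1"], name="embryo_id"))
    meta = pd.DataFrame({"genotype": ["TetTKO"]}, index=props.index)
    with pytest.raises(ValueError, match="host"):
        log2_shift(ProportionTable(props, meta), "chimaera_host_matched")


def test_planted_depletion_recovered():
    # x0.25 depletion of one type across 10 KO embryos: median shift ~ -2
    # after the renormalization correction
    rng = np.random.default_rng(1)
    base = np.array([0.1, 0.3, 0.3, 0.3])
    dep = base * [0.25, 1, 1, 1]
    dep = dep / dep.sum()
    rows = []
    for e in range(10):
        for geno, comp in (("WT", base), ("Dnmt1KO", dep)):
            counts = rng.multinomial(400, comp)
            for t, n in enumerate(counts):
                rows += [
                    (f"{geno}{e}_{t}_{i}", f"{geno}_e{e}", geno, f"t{t}")
                    for i in range(n)
                ]
    table = proportions(_ann(rows), pseudocount=1)
    shifts = log2_shift(table)
    dep_shift = shifts[shifts.cell_type == "t0"]["log2_shift"].median()
    expected = np.log2(dep[0] / base[0])  # -1.93 after renormalization
    assert abs(dep_shift - expected) < 0.3
    for t in ("t1", "t2", "t3"):
        other = shifts[shifts.cell_type == t]["log2_shift"].median()
        assert abs(other) < 0.3


def _stage_reference(rng, n_per_stage=4):
    comps = {"E7.5": [0.7, 0.2, 0.1], "E8.0": [0.4, 0.4, 0.2], "E8.5": [0.1, 0.5, 0.4]}
    rows, stages = [], []
    for s, c in comps.items():
        for e in range(n_per_stage):
            p = rng.dirichlet(np.array(c) * 300)
            rows.append(p)
            stages.append(s)
    ref = pd.DataFrame(rows, columns=["A", "B", "C"],
                       index=[f"r{i}" for i in range(len(rows))])
    return ref, pd.Series(stages, index=ref.index), comps


def test_stage_assignment_recovers_generating_stage():
    rng = np.random.default_rng(2)
    ref, stages, comps = _stage_reference(rng)
    query = pd.DataFrame([comps["E8.0"]], columns=["A", "B", "C"], index=["q1"])
    out = stage_embryos(query, ref, stages)
    assert out.assigned.loc["q1"] == "E8.0"
    assert out.scores.loc["q1"].max() == 1.0
    assert out.scores.loc["q1"].min() == 0.0


def test_stage_two_score_minmax():
    rng = np.random.default_rng(3)
    ref = pd.DataFrame([[0.9, 0.1], [0.1, 0.9]], columns=["A", "B"],
                       index=["r1", "r2"])
    stages = pd.Series(["E7.5", "E8.5"], index=ref.index)
    query = pd.DataFrame([[0.8, 0.2]], columns=["A", "B"], index=["q"])
    out = stage_embryos(query, ref, stages, n_pcs=1)
    assert sorted(out.scores.loc["q"]) == [0.0, 1.0]
    assert out.assigned.loc["q"] == "E7.5"


def test_stage_invariant_to_reference_order():
    rng = np.random.default_rng(4)
    ref, stages, comps = _stage_reference(rng)
    query = pd.DataFrame([comps["E8.5"]], columns=["A", "B", "C"], index=["q"])
    out1 = stage_embryos(query, ref, stages)
    perm = rng.permutation(len(ref))
    out2 = stage_embryos(query, ref.iloc[perm], stages.iloc[perm])
    assert out1.assigned.loc["q"] == out2.assigned.loc["q"]
    for s in out1.scores.columns:
        assert out1.scores.loc["q", s] == pytest.approx(out2.scores.loc["q", s])
    # column reordering is also irrelevant
    out3 = stage_embryos(query[["C", "A", "B"]], ref, stages)
    assert out3.assigned.loc["q"] == out1.assigned.loc["q"]


def test_stage_single_reference_stage_degenerate():
    ref = pd.DataFrame([[0.6, 0.4], [0.5, 0.5]], columns=["A", "B"],
                       index=["r1", "r2"])
    stages = pd.Series(["E8.0", "E8.0"], index=ref.index)
    query = pd.DataFrame([[0.7, 0.3]], columns=["A", "B"], index=["q"])
    out = stage_embryos(query, ref, stages, n_pcs=1)
    assert out.scores.loc["q", "E8.0"] == 1.0


def test_stage_exact_match_distance_zero():
    ref = pd.DataFrame([[0.9, 0.1], [0.2, 0.8]], columns=["A", "B"],
                       index=["r1", "r2"])
    stages = pd.Series(["E7.5", "E8.5"], index=ref.index)
    query = ref.iloc[[0]].rename(index={"r1": "q"})
    out = stage_embryos(query, ref, stages, n_pcs=1)
    assert out.assigned.loc["q"] == "E7.5"
    assert out.scores.loc["q", "E7.5"] == 1.0
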