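"""Generators: distributional contracts, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryokit import simulate
from embryokit.simulate import (
    AtlasSpec,
    EpigenomeSpec,
    PerturbationSpec,
    expected_feature_rate,
    simulate_atlas,
    simulate_nmt_cells,
    simulate_query_embryos,
    simulate_trajectory_rna,
)


def test_atlas_type_counts_within_binomial_envelope():
    # 3 equal types, 3000 cells in one stage: each type count should sit
    # inside the 99% binomial envelope around 1000 (Dirichlet noise is
    # suppressed by a huge concentration)
    spec = AtlasSpec(
        n_cell_types=3,
        n_genes=60,
        n_markers_per_type=5,
        stages=("E8.5",),
        stage_composition={"E8.5": [1 / 3] * 3},
        n_embryos_per_stage=1,
        n_cells_per_embryo=3000,
        composition_concentration=1e7,
        seed=5,
    )
    _, ann, _ = simulate_atlas(spec)
    lo, hi = stats.binom.ppf([0.005, 0.995], 3000, 1 / 3)
    counts = ann["cell_type"].value_counts()
    for t in spec.cell_type_names:
        assert lo <= counts[t] <= hi


def test_poisson_limit_variance_mean_ratio():
    spec = AtlasSpec(
        n_cell_types=2, n_genes=100, n_markers_per_type=5,
        stages=("E8.5",), n_embryos_per_stage=1, n_cells_per_embryo=2000,
        nb_dispersion=0.0, library_size_sigma=0.0, seed=2,
    )
    counts, ann, _ = simulate_atlas(spec)
    one_type = (ann["cell_type"] == spec.cell_type_names[0]).to_numpy()
    X = np.asarray(counts.values[one_type].todense(), float)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    keep = mean > 1.0
    ratio = (var[keep] / mean[keep]).mean()
    assert abs(ratio - 1.0) < 0.1


def test_atlas_deterministic_under_seed():
    spec = AtlasSpec(n_genes=80, n_markers_per_type=5, n_cells_per_embryo=50,
                     n_embryos_per_stage=1, seed=7)
    a1, _, _ = simulate_atlas(spec)
    a2, _, _ = simulate_atlas(spec)
    assert (a1.values != a2.values).nnz == 0


def test_marker_budget_validated():
    with pytest.raises(ValueError, match="disjoint"):
        AtlasSpec(n_cell_types=5, n_genes=50, n_markers_per_type=20)


def test_query_depletion_matches_renormalization():
    spec = AtlasSpec(
        n_cell_types=4, n_genes=80, n_markers_per_type=5,
        stages=("E8.5",), stage_composition={"E8.5": [0.25] * 4},
        composition_concentration=1e7, seed=3,
    )
    pert = PerturbationSpec(
        fold_changes_on_proportions={spec.cell_type_names[0]: 0.25}, seed=4
    )
    _, ann = simulate_query_embryos(spec, pert, 5, 2000)
    frac = (ann["true_cell_type"] == spec.cell_type_names[0]).mean()
    expected = 0.25 * 0.25 / (0.25 * 0.25 + 3 * 0.25)  # closed-form renorm
    assert abs(frac - expected) < 0.01


def test_query_unknown_cell_type_rejected():
    spec = AtlasSpec(n_genes=80, n_markers_per_type=5)
    with pytest.raises(ValueError, match="unknown cell type"):
        simulate_query_embryos(
            spec, PerturbationSpec(fold_changes_on_proportions={"nope": 0.5}), 1, 10
        )


def test_delay_shift_uses_earlier_stage_composition():
    spec = AtlasSpec(n_genes=80, n_markers_per_type=5, seed=9,
                     composition_concentration=1e7)
    pert = PerturbationSpec(delay_shift=1, seed=1)
    _, ann = simulate_query_embryos(spec, pert, 4, 3000)
    observed = ann["true_cell_type"].value_counts(normalize=True)
    earlier = np.asarray(spec.stage_composition[spec.stages[-2]])
    for t, p in zip(spec.cell_type_names, earlier):
        assert abs(observed.get(t, 0.0) - p) < 0.02


def test_empty_perturbation_matches_atlas_composition():
    spec = AtlasSpec(n_genes=80, n_markers_per_type=5, seed=9,
                     composition_concentration=1e7)
    _, ann = simulate_query_embryos(
        spec, PerturbationSpec(batch_effect_sigma=0.0, seed=2), 4, 3000
    )
    observed = ann["true_cell_type"].value_counts(normalize=True)
    target = np.asarray(spec.stage_composition[spec.stages[-1]])
    for t, p in zip(spec.cell_type_names, target):
        assert abs(observed.get(t, 0.0) - p) < 0.02


# ---------------------------------------------------------------------------
# scNMT generator
# ---------------------------------------------------------------------------

def _infeature_fraction(calls, features, class_label):
    """Read-level methylated fraction over sites inside class features."""
    rec = calls.records
    sub = features.of_class(class_label).intervals
    meth = unmeth = 0
    for _, f in sub.iterrows():
        hit = (
            (rec["chrom"] == f["chrom"])
            & (rec["pos"] > f["start"])
            & (rec["pos"] <= f["end"])
        )
        meth += rec.loc[hit, "meth"].sum()
        unmeth += rec.loc[hit, "unmeth"].sum()
    return meth / (meth + unmeth) if meth + unmeth else np.nan


def test_nmt_endpoint_rates(enhancer_features):
    # binomial mean oracle: the read-level methylated fraction over
    # in-feature sites equals the planted rate
    epi = EpigenomeSpec(seed=0)
    cpg, _, truth = simulate_nmt_cells(
        epi, enhancer_features, 30, np.ones(30), ["WT"] * 15 + ["TetTKO"] * 15
    )
    wt = [
        _infeature_fraction(cpg[c], enhancer_features, "erythroid_enhancers")
        for c in truth.loc[truth.genotype == "WT", "cell_id"]
    ]
    tko = [
        _infeature_fraction(cpg[c], enhancer_features, "erythroid_enhancers")
        for c in truth.loc[truth.genotype == "TetTKO", "cell_id"]
    ]
    assert np.nanmean(wt) == pytest.approx(0.2, abs=0.05)
    assert np.nanmean(tko) == pytest.approx(0.8, abs=0.05)
    assert expected_feature_rate(epi, "erythroid_enhancers", 1.0, "WT") == pytest.approx(0.2)
    assert expected_feature_rate(epi, "erythroid_enhancers", 1.0, "TetTKO") == pytest.approx(0.8)


def test_nmt_time_zero_genotypes_identical_rates(enhancer_features):
    epi = EpigenomeSpec(seed=0)
    for cls in epi.feature_classes:
        assert expected_feature_rate(epi, cls, 0.0, "WT") == expected_feature_rate(
            epi, cls, 0.0, "TetTKO"
        )


def test_nmt_latent_time_validated(enhancer_features):
    epi = EpigenomeSpec(seed=0)
    with pytest.raises(ValueError, match="latent time"):
        simulate_nmt_cells(epi, enhancer_features, 2, [0.5, 1.5], "WT")


def test_nmt_deterministic(enhancer_features):
    epi = EpigenomeSpec(seed=3)
    t = np.linspace(0, 1, 5)
    a = simulate_nmt_cells(epi, enhancer_features, 5, t, "WT")
    b = simulate_nmt_cells(epi, enhancer_features, 5, t, "WT")
    for cid in a[0]:
        pd.testing.assert_frame_equal(a[0][cid].records, b[0][cid].records)


def test_trajectory_rna_anchor_increases():
    t = np.linspace(0, 1, 120)
    cm = simulate_trajectory_rna(120, t, seed=1)
    anchor = np.asarray(cm.values[:, 0].todense()).ravel()
    rho = stats.spearmanr(anchor, t).statistic
    assert rho > 0.5
    assert cm.gene_ids[0] == "Hba-x"
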