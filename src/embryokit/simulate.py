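"""Synthetic fixtures emulating the structure of a knockout-embryo study.

Three generators cover the data the pipeline consumes:

* :func:`simulate_atlas` — a labelled multi-stage reference atlas of
  single-cell RNA counts (negative-binomial, cell-type mean profiles
  with up-shifted markers, per-embryo compositional noise).
* :func:`simulate_query_embryos` — knockout/wildtype query embryos with
  planted cell-type proportion shifts, marker dysregulation, an optional
  developmental delay, and a per-gene log-normal batch effect relative
  to the atlas.
* :func:`simulate_nmt_cells` — coupled CpG-methylation / GpC-
  accessibility calls for cells along a differentiation trajectory, with
  planted TET-dependent enhancer demethylation (wildtype enhancers
  demethylate toward an endpoint as latent time advances; triple-
  knockout cells stay at baseline) over a background that loses
  methylation passively in both genotypes.

Every cell carries hidden ground truth (type, latent time, planted
effects) so downstream recovery can be tested. All generators are
bit-reproducible under their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, FeatureSet, MethCallSet

__all__ = [
    "AtlasSpec",
    "PerturbationSpec",
    "EpigenomeSpec",
    "simulate_atlas",
    "simulate_query_embryos",
    "simulate_nmt_cells",
    "simulate_trajectory_rna",
]


def _default_stage_composition(stages, n_types):
    """Deterministic, smoothly drifting per-stage proportion vectors.

    Each cell type's log-abundance moves linearly across stages with a
    type-specific slope spread over [-2, 2], so consecutive stages have
    distinct but related compositions — the property embryo staging
    exploits.
    """
    slopes = np.linspace(-2.0, 2.0, n_types)
    out = {}
    for i, stage in enumerate(stages):
        x = i / max(len(stages) - 1, 1)
        w = np.exp(slopes * (x - 0.5))
        out[stage] = w / w.sum()
    return out


@dataclass
class AtlasSpec:
    """Parameters of the synthetic reference atlas.

    Defaults give a compact but realistic atlas: 5 cell types across 3
    stages, 4 embryos per stage with ~400 cells each, library sizes
    around 5000 counts, and a shared NB dispersion of 0.1 (squared
    biological CV ~ 10%, typical for pseudobulk-scale scRNA-seq).
    """

    n_cell_types: int = 5
    n_genes: int = 600
    n_markers_per_type: int = 20
    stages: tuple = ("E7.5", "E8.0", "E8.5")
    stage_composition: Mapping[str, Sequence[float]] | None = None
    n_embryos_per_stage: int = 4
    n_cells_per_embryo: int = 400
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.3
    nb_dispersion: float = 0.1
    marker_log2fc: float = 3.0
    composition_concentration: float = 300.0
    cell_type_names: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError(
                "n_markers_per_type * n_cell_types exceeds n_genes; "
                "marker sets must be disjoint"
            )
        if self.cell_type_names is None:
            self.cell_type_names = tuple(
                f"type_{i}" for i in range(self.n_cell_types)
            )
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length != n_cell_types")
        if self.stage_composition is None:
            self.stage_composition = _default_stage_composition(
                self.stages, self.n_cell_types
            )
        for stage in self.stages:
            p = np.asarray(self.stage_composition[stage], float)
            if p.shape != (self.n_cell_types,) or (p < 0).any():
                raise ValueError(f"invalid proportion vector for stage {stage}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"stage {stage} proportions do not sum to 1")

    @property
    def gene_ids(self) -> np.ndarray:
        return np.array([f"gene_{i:04d}" for i in range(self.n_genes)], dtype=object)

    def marker_sets(self) -> dict:
        """Ground-truth marker genes: disjoint blocks, one per cell type."""
        m = self.n_markers_per_type
        gids = self.gene_ids
        return {
            name: set(gids[i * m : (i + 1) * m])
            for i, name in enumerate(self.cell_type_names)
        }


@dataclass
class PerturbationSpec:
    """Planted knockout effects applied to query embryos."""

    fold_changes_on_proportions: dict = field(default_factory=dict)
    #: gene_id -> (log2 effect, tuple of affected cell-type names)
    dysregulated_genes: dict = field(default_factory=dict)
    delay_shift: int = 0
    batch_effect_sigma: float = 0.15
    seed: int = 0


def _gene_profiles(spec: AtlasSpec) -> np.ndarray:
    """Per-cell-type mean expression profiles (rows sum to 1).

    A shared log-normal baseline across genes, with each type's marker
    block multiplied by 2**marker_log2fc. Deterministic in spec.seed so
    atlas and query generation share identical profiles.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    profiles = np.tile(base, (spec.n_cell_types, 1))
    m = spec.n_markers_per_type
    for t in range(spec.n_cell_types):
        profiles[t, t * m : (t + 1) * m] *= 2.0 ** spec.marker_log2fc
    return profiles / profiles.sum(axis=1, keepdims=True)


def _sample_counts(rng, mu, dispersion):
    """NB(mean mu, var mu + dispersion*mu^2); Poisson in the limit."""
    if dispersion <= 1e-8:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def _draw_embryo_cells(rng, spec, composition, n_cells, profiles, mu_scale=None):
    """Draw (types, counts) for one embryo with the given composition."""
    comp = rng.dirichlet(np.maximum(composition, 1e-12) * spec.composition_concentration)
    types = rng.choice(spec.n_cell_types, size=n_cells, p=comp)
    sigma = spec.library_size_sigma
    libs = rng.lognormal(
        mean=np.log(spec.library_size_mean) - 0.5 * sigma**2, sigma=sigma, size=n_cells
    )
    mu = libs[:, None] * profiles[types]
    if mu_scale is not None:
        mu = mu * mu_scale(types)
    counts = _sample_counts(rng, mu, spec.nb_dispersion)
    return types, counts


def simulate_atlas(spec: AtlasSpec):
    """Generate the labelled multi-stage reference atlas.

    Returns
    -------
    counts : CountMatrix
    annotation : DataFrame
        One row per cell with the standard annotation columns; reference
        cells carry their true ``cell_type`` and ``stage_label``.
    embryos : DataFrame
        Per-embryo table: embryo_id, stage_label, n_cells and realized
        per-type cell counts.
    """
    rng = np.random.default_rng([1, spec.seed])
    profiles = _gene_profiles(spec)
    blocks, ann_rows, emb_rows = [], [], []
    cell_counter = 0
    for stage in spec.stages:
        comp = np.asarray(spec.stage_composition[stage], float)
        for e in range(spec.n_embryos_per_stage):
            embryo_id = f"ref_{stage}_{e}"
            types, counts = _draw_embryo_cells(
                rng, spec, comp, spec.n_cells_per_embryo, profiles
            )
            blocks.append(counts)
            emb_row = {"embryo_id": embryo_id, "stage_label": stage,
                       "n_cells": spec.n_cells_per_embryo}
            for t, name in enumerate(spec.cell_type_names):
                emb_row[f"n_{name}"] = int((types == t).sum())
            emb_rows.append(emb_row)
            for t in types:
                ann_rows.append(
                    {
                        "cell_id": f"atlas_cell_{cell_counter:06d}",
                        "embryo_id": embryo_id,
                        "genotype": "WT",
                        "stage_label": stage,
                        "platform": "droplet",
                        "cell_type": spec.cell_type_names[t],
                        "host_flag": False,
                    }
                )
                cell_counter += 1
    ann = pd.DataFrame(ann_rows)
    cm = CountMatrix(
        np.vstack(blocks), ann["cell_id"].to_numpy(object), spec.gene_ids
    )
    return cm, ann, pd.DataFrame(emb_rows)


def simulate_query_embryos(
    atlas_spec: AtlasSpec,
    perturbation: PerturbationSpec,
    n_embryos: int,
    n_cells_per_embryo: int,
    stage: str | None = None,
    genotype: str = "other",
    embryo_prefix: str = "query",
    host_flag: bool = False,
):
    """Generate perturbed query embryos sharing the atlas gene profiles.

    The composition starts from the (optionally delay-shifted) stage
    vector, is multiplied by the planted fold changes and renormalized.
    Dysregulated genes are shifted only in their affected cell types. A
    per-gene log-normal batch factor (shared by all query cells drawn
    with this perturbation seed) separates query from atlas data.

    True cell types and the generating stage are recorded in
    ``true_cell_type`` / ``true_stage`` annotation columns; ``cell_type``
    is left empty for the mapping stage to fill.
    """
    spec = atlas_spec
    for ct in perturbation.fold_changes_on_proportions:
        if ct not in spec.cell_type_names:
            raise ValueError(f"unknown cell type in fold_changes: {ct!r}")
    for g, (_, cts) in perturbation.dysregulated_genes.items():
        for ct in cts:
            if ct not in spec.cell_type_names:
                raise ValueError(f"unknown cell type for dysregulated gene {g!r}")
    if stage is None:
        stage = spec.stages[-1]
    stage_idx = list(spec.stages).index(stage)
    src_idx = max(0, stage_idx - perturbation.delay_shift)
    comp = np.asarray(spec.stage_composition[spec.stages[src_idx]], float).copy()
    for ct, mult in perturbation.fold_changes_on_proportions.items():
        comp[spec.cell_type_names.index(ct)] *= mult
    comp = comp / comp.sum()

    profiles = _gene_profiles(spec)
    rng = np.random.default_rng([2, perturbation.seed, spec.seed])
    batch = np.exp(
        np.random.default_rng([3, perturbation.seed, spec.seed]).normal(
            0.0, perturbation.batch_effect_sigma, size=spec.n_genes
        )
    )
    gid_index = {g: i for i, g in enumerate(spec.gene_ids)}
    # per-type multiplicative gene effects (dysregulation x batch)
    effects = np.tile(batch, (spec.n_cell_types, 1))
    for g, (log2fc, cts) in perturbation.dysregulated_genes.items():
        gi = gid_index[g]
        for ct in cts:
            effects[spec.cell_type_names.index(ct), gi] *= 2.0 ** log2fc

    blocks, ann_rows = [], []
    cell_counter = 0
    for e in range(n_embryos):
        embryo_id = f"{embryo_prefix}_{e}"
        types, counts = _draw_embryo_cells(
            rng, spec, comp, n_cells_per_embryo, profiles,
            mu_scale=lambda t: effects[t],
        )
        blocks.append(counts)
        for t in types:
            ann_rows.append(
                {
                    "cell_id": f"{embryo_prefix}_cell_{cell_counter:06d}",
                    "embryo_id": embryo_id,
                    "genotype": genotype,
                    "stage_label": None,
                    "platform": "droplet",
                    "cell_type": None,
                    "host_flag": host_flag,
                    "true_cell_type": spec.cell_type_names[t],
                    "true_stage": stage,
                }
            )
            cell_counter += 1
    ann = pd.DataFrame(ann_rows)
    cm = CountMatrix(np.vstack(blocks), ann["cell_id"].to_numpy(object), spec.gene_ids)
    return cm, ann


# ---------------------------------------------------------------------------
# scNMT-style epigenome simulation
# ---------------------------------------------------------------------------

@dataclass
class EpigenomeSpec:
    """Rates and coverage of the synthetic methylome/accessibility data.

    ``feature_classes`` maps class label -> (baseline CpG methylation
    rate, baseline GpC accessibility rate). ``trajectory_demethylation``
    maps class label -> {genotype: endpoint methylation rate at latent
    time 1}; a genotype absent from the map keeps the baseline (this is
    how the TET-knockout is planted: its endpoint equals baseline at
    lineage enhancers). ``trajectory_accessibility`` endpoints apply to
    all genotypes — accessibility gain is TET-independent.

    Sites fall into three compartments: *feature* (inside a feature
    body; class rate), *flank* (within ±flank of a feature centre but
    outside the body; constant ``flank_meth_rate``, defaulting to the
    global baseline), and *background* (a genome-wide compartment on
    its own chromosome) whose methylation starts at
    ``global_meth_baseline`` and declines by
    ``global_demethylation_slope`` over the trajectory in every
    genotype — the passive loss that dominates a cell's global rate.
    Background and flank accessibility are flat at ``global_acc_rate``.
    """

    feature_classes: dict = field(
        default_factory=lambda: {
            "promoters": (0.10, 0.35),
            "erythroid_enhancers": (0.80, 0.15),
            "other_enhancers": (0.80, 0.15),
        }
    )
    trajectory_demethylation: dict = field(
        default_factory=lambda: {"erythroid_enhancers": {"WT": 0.20}}
    )
    trajectory_accessibility: dict = field(
        default_factory=lambda: {"erythroid_enhancers": 0.35}
    )
    global_meth_baseline: float = 0.80
    global_demethylation_slope: float = 0.25
    global_acc_rate: float = 0.25
    flank_meth_rate: float | None = None
    n_background_sites: int = 3000
    background_chrom: str = "chrB"
    sites_per_kb: float = 12.0
    site_detection_prob: float = 0.20
    # most covered sites in single-cell bisulfite data carry a single read;
    # near-unit depth also keeps the binarized site rate unbiased
    reads_per_site_mean: float = 1.2
    flank: int = 2000
    seed: int = 0

    def __post_init__(self):
        rates = [r for pair in self.feature_classes.values() for r in pair]
        rates += [
            r for d in self.trajectory_demethylation.values() for r in d.values()
        ]
        rates += list(self.trajectory_accessibility.values())
        rates += [self.global_meth_baseline, self.global_acc_rate]
        if self.flank_meth_rate is None:
            self.flank_meth_rate = self.global_meth_baseline
        rates.append(self.flank_meth_rate)
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.reads_per_site_mean < 1:
            raise ValueError("reads_per_site_mean must be >= 1")


def expected_feature_rate(
    spec: EpigenomeSpec, class_label: str, latent_time: float, genotype: str
) -> float:
    """Planted in-feature CpG methylation rate (linear interpolation)."""
    r0 = spec.feature_classes[class_label][0]
    end = spec.trajectory_demethylation.get(class_label, {}).get(genotype, r0)
    return float(np.clip(r0 + latent_time * (end - r0), 0.0, 1.0))


def _candidate_sites(spec: EpigenomeSpec, features: FeatureSet, context_tag: int):
    """Deterministic candidate site positions per feature window.

    Sites are placed uniformly in the ±flank window around each feature
    centre (compartment "feature" inside the body, "flank" outside),
    plus a genome-wide "background" compartment on its own chromosome
    that carries the passive global demethylation signal.
    """
    rng = np.random.default_rng([4, context_tag, spec.seed])
    rows = []
    for _, f in features.intervals.iterrows():
        center = (int(f["start"]) + int(f["end"])) // 2
        lo, hi = center - spec.flank, center + spec.flank
        n_cand = max(int(round(spec.sites_per_kb * (hi - lo) / 1000.0)), 1)
        pos0 = np.sort(rng.choice(np.arange(lo, hi), size=min(n_cand, hi - lo),
                                  replace=False))
        pos0 = pos0[pos0 >= 0]
        in_feat = (pos0 >= f["start"]) & (pos0 < f["end"])
        for p, inf_ in zip(pos0, in_feat):
            rows.append(
                (f["chrom"], int(p) + 1, f["class_label"],
                 "feature" if inf_ else "flank")
            )
    bg_pos = np.sort(
        rng.choice(np.arange(1, 50_000_000), size=spec.n_background_sites,
                   replace=False)
    )
    for p in bg_pos:
        rows.append((spec.background_chrom, int(p), "__background__", "background"))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "class_label", "compartment"])
    # if feature windows overlap, keep a single record per genomic position
    sites = sites.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return sites


def simulate_nmt_cells(
    epi_spec: EpigenomeSpec,
    feature_set: FeatureSet,
    n_cells: int,
    latent_time: Sequence[float],
    genotype: Sequence[str] | str,
    cell_prefix: str = "nmt",
):
    """Generate per-cell CpG and GpC call sets along the trajectory.

    Returns ``(cpg_calls, gpc_calls, truth)`` where the call dicts map
    cell_id -> :class:`MethCallSet` and ``truth`` records each cell's
    genotype, latent time and planted per-class in-feature rates.
    """
    t = np.asarray(latent_time, float)
    if t.shape != (n_cells,):
        raise ValueError("latent_time must have length n_cells")
    if (t < 0).any() or (t > 1).any():
        raise ValueError("latent time outside [0, 1]")
    if isinstance(genotype, str):
        genotype = [genotype] * n_cells
    genotype = list(genotype)
    if len(genotype) != n_cells:
        raise ValueError("genotype must have length n_cells")

    cpg_sites = _candidate_sites(epi_spec, feature_set, context_tag=0)
    gpc_sites = _candidate_sites(epi_spec, feature_set, context_tag=1)
    rng = np.random.default_rng([5, epi_spec.seed])

    def site_rates(sites, ti, g, context):
        cls = sites["class_label"].to_numpy()
        comp = sites["compartment"].to_numpy()
        in_feat = comp == "feature"
        r = np.empty(len(sites))
        if context == "CpG":
            r[comp == "flank"] = epi_spec.flank_meth_rate
            r[comp == "background"] = (
                epi_spec.global_meth_baseline
                - epi_spec.global_demethylation_slope * ti
            )
            for c in np.unique(cls[in_feat]):
                mask = (cls == c) & in_feat
                r[mask] = expected_feature_rate(epi_spec, c, ti, g)
        else:
            r[:] = epi_spec.global_acc_rate
            for c in np.unique(cls[in_feat]):
                mask = (cls == c) & in_feat
                a0 = epi_spec.feature_classes[c][1]
                end = epi_spec.trajectory_accessibility.get(c, a0)
                r[mask] = a0 + ti * (end - a0)
        return np.clip(r, 0.0, 1.0)

    cpg_calls, gpc_calls, truth_rows = {}, {}, []
    for i in range(n_cells):
        cid = f"{cell_prefix}_cell_{i:04d}"
        for context, sites, store in (
            ("CpG", cpg_sites, cpg_calls),
            ("GpC", gpc_sites, gpc_calls),
        ):
            keep = rng.random(len(sites)) < epi_spec.site_detection_prob
            sub = sites[keep]
            total = 1 + rng.poisson(epi_spec.reads_per_site_mean - 1.0, size=len(sub))
            rates = site_rates(sub, t[i], genotype[i], context)
            meth = rng.binomial(total, rates)
            store[cid] = MethCallSet(
                context=context,
                cell_id=cid,
                records=pd.DataFrame(
                    {
                        "chrom": sub["chrom"].to_numpy(),
                        "pos": sub["pos"].to_numpy(),
                        "meth": meth,
                        "unmeth": total - meth,
                    }
                ),
            )
        row = {"cell_id": cid, "genotype": genotype[i], "latent_time": t[i]}
        for c in epi_spec.feature_classes:
            row[f"meth_{c}"] = expected_feature_rate(epi_spec, c, t[i], genotype[i])
        truth_rows.append(row)
    return cpg_calls, gpc_calls, pd.DataFrame(truth_rows)


def simulate_trajectory_rna(
    n_cells: int,
    latent_time: Sequence[float],
    n_genes: int = 200,
    anchor_gene: str = "Hba-x",
    library_size_mean: float = 4000.0,
    nb_dispersion: float = 0.05,
    slope_sigma: float = 1.5,
    seed: int = 0,
) -> CountMatrix:
    """RNA counts varying smoothly along a 1-D latent trajectory.

    Each gene's log-mean moves linearly with latent time with a gene-
    specific slope (N(0, slope_sigma)); the anchor gene (first column)
    gets a strong positive slope so pseudotime can be oriented the way a
    haemoglobin gene orients an erythroid trajectory.
    """
    t = np.asarray(latent_time, float)
    if t.shape != (n_cells,):
        raise ValueError("latent_time must have length n_cells")
    if (t < 0).any() or (t > 1).any():
        raise ValueError("latent time outside [0, 1]")
    rng = np.random.default_rng([6, seed])
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    slopes = rng.normal(0.0, slope_sigma, size=n_genes)
    slopes[0] = 3.0  # anchor gene increases along the trajectory
    logmu = np.log(base)[None, :] + np.outer(t - 0.5, slopes)
    profile = np.exp(logmu)
    profile /= profile.sum(axis=1, keepdims=True)
    libs = rng.lognormal(np.log(library_size_mean), 0.2, size=n_cells)
    counts = _sample_counts(rng, libs[:, None] * profile, nb_dispersion)
    gene_ids = np.array(
        [anchor_gene] + [f"traj_gene_{i:03d}" for i in range(1, n_genes)], dtype=object
    )
    cell_ids = np.array([f"traj_cell_{i:04d}" for i in range(n_cells)], dtype=object)
    return CountMatrix(counts, cell_ids, gene_ids)


def make_enhancer_catalogue(
    classes: Sequence[str] = ("promoters", "erythroid_enhancers", "other_enhancers"),
    n_per_class: int = 20,
    feature_width: int = 600,
    spacing: int = 20000,
    chrom: str = "chr1",
) -> FeatureSet:
    """A synthetic catalogue of regulatory elements, evenly spaced so the
    ±2 kb profile windows never overlap."""
    rows = []
    pos = spacing
    for cls in classes:
        for i in range(n_per_class):
            rows.append((chrom, pos, pos + feature_width, f"{cls}_{i}", cls))
            pos += spacing
    return FeatureSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class_label"])
    )
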