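"""End-to-end driver chaining the analysis stages on synthetic fixtures.

Stage order mirrors the study workflow: fixtures → QC/normalization →
atlas mapping → composition & staging → differential expression and
markers → epigenome quantification → pseudotime. Each stage writes TSV
outputs plus an entry in a JSON manifest (parameters, output hashes,
row counts). Stages are resumable: a rerun skips a stage whose
parameter hash matches and whose outputs still exist; changing the seed
or any upstream parameter invalidates everything downstream.

All floating-point output uses a fixed format so two runs with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, de, epigenome, mapping, pseudotime, qc, simulate
from .config import PipelineConfig, validate_config
from .io import (
    read_annotation,
    read_bed,
    read_counts,
    read_meth_calls,
    write_annotation,
    write_bed,
    write_counts,
    write_meth_calls,
)

__all__ = ["run_pipeline", "generate_fixtures"]

FLOAT_FORMAT = "%.10g"


def _write_tsv(df: pd.DataFrame, path, index=False):
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def stage_current(self, name: str, phash: str, outdir: Path) -> bool:
        entry = self.data.get(name)
        if not entry or entry["params_hash"] != phash:
            return False
        return all((outdir / f).exists() for f in entry["outputs"])

    def record(self, name: str, phash: str, outputs: list, outdir: Path,
               row_counts: dict):
        self.data[name] = {
            "params_hash": phash,
            "outputs": sorted(outputs),
            "output_sha256": {f: _sha256(outdir / f) for f in sorted(outputs)},
            "row_counts": row_counts,
        }

    def save(self):
        self.path.write_text(json.dumps(self.data, sort_keys=True, indent=1))


def _atlas_spec(cfg: PipelineConfig) -> simulate.AtlasSpec:
    fx = cfg.fixtures
    return simulate.AtlasSpec(
        n_cell_types=fx.n_cell_types,
        n_genes=fx.n_genes,
        n_markers_per_type=fx.n_markers_per_type,
        n_embryos_per_stage=fx.n_embryos_per_stage,
        n_cells_per_embryo=fx.n_cells_per_embryo,
        seed=cfg.seed,
    )


def generate_fixtures(cfg: PipelineConfig, outdir: Path) -> dict:
    """Simulate and write every input the pipeline stages consume."""
    fx = cfg.fixtures
    spec = _atlas_spec(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}

    atlas_counts, atlas_ann, atlas_embryos = simulate.simulate_atlas(spec)
    write_counts(atlas_counts, outdir / "atlas_matrix.mtx",
                 outdir / "atlas_barcodes.tsv", outdir / "atlas_features.tsv")
    write_annotation(atlas_ann, outdir / "atlas_annotation.tsv")
    _write_tsv(atlas_embryos, outdir / "atlas_embryos.tsv")

    wt_pert = simulate.PerturbationSpec(batch_effect_sigma=0.15, seed=cfg.seed)
    wt_counts, wt_ann = simulate.simulate_query_embryos(
        spec, wt_pert, fx.n_query_embryos, fx.n_query_cells_per_embryo,
        genotype="WT", embryo_prefix="wt",
    )
    depleted = spec.cell_type_names[fx.depleted_cell_type_index]
    ko_pert = simulate.PerturbationSpec(
        fold_changes_on_proportions={depleted: fx.depletion_factor},
        batch_effect_sigma=0.15,
        seed=cfg.seed + 1,
    )
    ko_counts, ko_ann = simulate.simulate_query_embryos(
        spec, ko_pert, fx.n_query_embryos, fx.n_query_cells_per_embryo,
        genotype=fx.ko_genotype, embryo_prefix="ko",
    )
    query_ann = pd.concat([wt_ann, ko_ann], ignore_index=True)
    query_counts = simulate.CountMatrix(
        np.vstack([np.asarray(wt_counts.values.todense()),
                   np.asarray(ko_counts.values.todense())]),
        np.concatenate([wt_counts.cell_ids, ko_counts.cell_ids]),
        spec.gene_ids,
    )
    write_counts(query_counts, outdir / "query_matrix.mtx",
                 outdir / "query_barcodes.tsv", outdir / "query_features.tsv")
    write_annotation(query_ann, outdir / "query_annotation.tsv")

    features = simulate.make_enhancer_catalogue(
        n_per_class=fx.n_features_per_class
    )
    write_bed(features, outdir / "features.bed")
    _write_tsv(features.intervals, outdir / "feature_classes.tsv")

    epi = simulate.EpigenomeSpec(seed=cfg.seed)
    n_per = fx.n_nmt_cells_per_genotype
    rng = np.random.default_rng([7, cfg.seed])
    times = rng.uniform(0, 1, size=2 * n_per)
    genos = ["WT"] * n_per + ["TetTKO"] * n_per
    cpg, gpc, truth = simulate.simulate_nmt_cells(
        epi, features, 2 * n_per, times, genos
    )
    meth_dir = outdir / "meth_calls"
    meth_dir.mkdir(exist_ok=True)
    for cid, calls in cpg.items():
        write_meth_calls(calls, meth_dir / f"{cid}.CpG.tsv")
    for cid, calls in gpc.items():
        write_meth_calls(calls, meth_dir / f"{cid}.GpC.tsv")
    _write_tsv(truth, outdir / "nmt_truth.tsv")

    traj = simulate.simulate_trajectory_rna(
        2 * n_per, times, n_genes=min(fx.n_genes, 200), seed=cfg.seed
    )
    write_counts(traj, outdir / "trajectory_matrix.mtx",
                 outdir / "trajectory_barcodes.tsv",
                 outdir / "trajectory_features.tsv")
    return outputs


def run_pipeline(config, force: bool = False) -> dict:
    """Run all stages; returns the manifest dict.

    ``config`` may be a PipelineConfig, a YAML path, a mapping or None.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    eff = cfg.effective()

    def stage(name, params, outputs, fn):
        phash = _params_hash({"seed": cfg.seed, "params": params, "stage": name})
        if not force and manifest.stage_current(name, phash, outdir):
            return
        try:
            row_counts = fn() or {}
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest.record(name, phash, outputs, outdir, row_counts)
        manifest.save()

    # ------------------------------------------------------------------ 1
    fixture_outputs = [
        "atlas_matrix.mtx", "atlas_barcodes.tsv", "atlas_features.tsv",
        "atlas_annotation.tsv", "atlas_embryos.tsv",
        "query_matrix.mtx", "query_barcodes.tsv", "query_features.tsv",
        "query_annotation.tsv", "features.bed", "feature_classes.tsv",
        "nmt_truth.tsv", "trajectory_matrix.mtx", "trajectory_barcodes.tsv",
        "trajectory_features.tsv",
    ]

    def do_fixtures():
        generate_fixtures(cfg, outdir)
        return {"atlas_cells": cfg.fixtures.n_cells_per_embryo
                * cfg.fixtures.n_embryos_per_stage * 3}

    stage("fixtures", eff["fixtures"], fixture_outputs, do_fixtures)

    # ------------------------------------------------------------------ 2
    def do_qc():
        rows = {}
        for tag in ("atlas", "query"):
            counts = read_counts(outdir / f"{tag}_matrix.mtx",
                                 outdir / f"{tag}_barcodes.tsv",
                                 outdir / f"{tag}_features.tsv")
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                table = qc.qc_rna(counts, set(), set(), cfg.qc, "droplet")
            model = qc.size_factors(counts, "library")
            table["size_factor"] = model.size_factors
            _write_tsv(table, outdir / f"{tag}_qc.tsv")
            rows[f"{tag}_cells"] = len(table)
        return rows

    stage("qc_norm", eff["qc"], ["atlas_qc.tsv", "query_qc.tsv"], do_qc)

    # ------------------------------------------------------------------ 3
    def do_mapping():
        atlas = read_counts(outdir / "atlas_matrix.mtx",
                            outdir / "atlas_barcodes.tsv",
                            outdir / "atlas_features.tsv")
        query = read_counts(outdir / "query_matrix.mtx",
                            outdir / "query_barcodes.tsv",
                            outdir / "query_features.tsv")
        atlas_ann = read_annotation(outdir / "atlas_annotation.tsv")
        labels = atlas_ann.set_index("cell_id").loc[
            list(atlas.cell_ids), "cell_type"
        ].to_numpy(object)
        result = mapping.map_query(atlas, labels, query, cfg.mapping)
        _write_tsv(result.assignments, outdir / "mapping.tsv")
        query_ann = read_annotation(outdir / "query_annotation.tsv")
        groups = {
            g: (query_ann["genotype"] == g).to_numpy()
            for g in query_ann["genotype"].unique()
        }
        flags = mapping.highlight_neighbors(result, groups)
        _write_tsv(flags, outdir / "reference_highlight.tsv")
        return {"query_cells": len(result.assignments)}

    stage("mapping", eff["mapping"], ["mapping.tsv", "reference_highlight.tsv"],
          do_mapping)

    # ------------------------------------------------------------------ 4
    def do_composition():
        query_ann = read_annotation(outdir / "query_annotation.tsv")
        assigned = pd.read_csv(outdir / "mapping.tsv", sep="\t")
        query_ann = query_ann.drop(columns=["cell_type"]).merge(
            assigned[["cell_id", "cell_type"]], on="cell_id"
        )
        table = composition.proportions(
            query_ann, pseudocount=cfg.staging.pseudocount
        )
        props = table.proportions.reset_index()
        _write_tsv(props, outdir / "proportions.tsv")
        shifts = composition.log2_shift(table, "ko_vs_wt_mean")
        _write_tsv(shifts, outdir / "log2_shifts.tsv")

        ref_embryos = pd.read_csv(outdir / "atlas_embryos.tsv", sep="\t")
        type_cols = [c for c in ref_embryos.columns if c.startswith("n_")
                     and c != "n_cells"]
        ref_counts = ref_embryos[type_cols].to_numpy(float) + cfg.staging.pseudocount
        ref_props = pd.DataFrame(
            ref_counts / ref_counts.sum(axis=1, keepdims=True),
            index=ref_embryos["embryo_id"],
            columns=[c[2:] for c in type_cols],
        )
        staged = composition.stage_embryos(
            table.proportions, ref_props,
            ref_embryos.set_index("embryo_id")["stage_label"],
            n_pcs=cfg.staging.n_pcs,
        )
        out = staged.scores.copy()
        out["assigned_stage"] = staged.assigned
        _write_tsv(out.reset_index(), outdir / "staging.tsv")
        return {"embryos": len(props)}

    stage("composition", {**eff["staging"], "mapping": eff["mapping"]},
          ["proportions.tsv", "log2_shifts.tsv", "staging.tsv"], do_composition)

    # ------------------------------------------------------------------ 5
    def do_de():
        atlas = read_counts(outdir / "atlas_matrix.mtx",
                            outdir / "atlas_barcodes.tsv",
                            outdir / "atlas_features.tsv")
        atlas_ann = read_annotation(outdir / "atlas_annotation.tsv")
        query = read_counts(outdir / "query_matrix.mtx",
                            outdir / "query_barcodes.tsv",
                            outdir / "query_features.tsv")
        query_ann = read_annotation(outdir / "query_annotation.tsv")
        assigned = pd.read_csv(outdir / "mapping.tsv", sep="\t")
        query_ann = query_ann.drop(columns=["cell_type"]).merge(
            assigned[["cell_id", "cell_type"]], on="cell_id"
        )
        ko = cfg.fixtures.ko_genotype
        results = {}
        de_rows = []
        for ct in sorted(query_ann["cell_type"].dropna().unique()):
            try:
                pb = de.make_pseudobulk(
                    query, query_ann, ct,
                    min_cells_per_sample=cfg.de.min_cells_per_sample,
                )
                res = de.nb_test(pb, cfg.de, group_order=("WT", ko))
            except ValueError as exc:
                de_rows.append({"cell_type": ct, "n_de": -1, "skipped": str(exc)})
                continue
            results[ct] = res
            _write_tsv(res.reset_index(), outdir / f"de_{ct}.tsv")
            de_rows.append({"cell_type": ct,
                            "n_de": int(res["significant"].sum()),
                            "skipped": ""})
        markers = de.find_markers(
            atlas, atlas_ann, cfg.de, cfg.markers,
            min_cells_per_sample=cfg.de.min_cells_per_sample,
        )
        marker_df = pd.DataFrame(
            [(t, g) for t, gs in markers.items() for g in sorted(gs)],
            columns=["cell_type", "gene"],
        )
        _write_tsv(marker_df, outdir / "markers.tsv")
        cross = de.de_by_marker_identity(results, markers)
        _write_tsv(cross, outdir / "de_by_marker_identity.tsv")
        _write_tsv(pd.DataFrame(de_rows), outdir / "de_summary.tsv")
        return {"tested_cell_types": len(results)}

    de_outputs = ["markers.tsv", "de_by_marker_identity.tsv", "de_summary.tsv"]
    stage("de", {**eff["de"], **eff["markers"]}, de_outputs, do_de)

    # ------------------------------------------------------------------ 6
    def do_epigenome():
        features = read_bed(outdir / "features.bed")
        classes = pd.read_csv(outdir / "feature_classes.tsv", sep="\t")
        feats = features.intervals.drop(columns=["class_label"]).merge(
            classes[["name", "class_label"]], on="name"
        )
        from .io import FeatureSet

        features = FeatureSet(feats)
        truth = pd.read_csv(outdir / "nmt_truth.tsv", sep="\t")
        meth_dir = outdir / "meth_calls"
        cpg = {
            cid: read_meth_calls(meth_dir / f"{cid}.CpG.tsv", "CpG", cell_id=cid)
            for cid in truth["cell_id"]
        }
        rate_table = epigenome.feature_rate_matrix(cpg, features)
        _write_tsv(rate_table, outdir / "feature_rates_cpg.tsv")
        glob = pd.DataFrame(
            {
                "cell_id": list(cpg),
                "global_rate": [epigenome.global_rate(c) for c in cpg.values()],
            }
        ).merge(truth[["cell_id", "genotype", "latent_time"]], on="cell_id")
        _write_tsv(glob, outdir / "global_methylation.tsv")
        profs = []
        for geno in ("WT", "TetTKO"):
            cells = truth.loc[truth["genotype"] == geno, "cell_id"]
            sub = {c: cpg[c] for c in cells}
            for cls in features.classes:
                p = epigenome.profile(sub, features.of_class(cls), cfg.profile)
                p.insert(0, "class_label", cls)
                p.insert(0, "genotype", geno)
                profs.append(p)
        _write_tsv(pd.concat(profs, ignore_index=True),
                   outdir / "profiles_cpg.tsv")
        groups = {
            g: truth.loc[truth["genotype"] == g, "cell_id"].tolist()
            for g in ("WT", "TetTKO")
        }
        comp = epigenome.compare_groups(rate_table, groups, ("WT", "TetTKO"))
        _write_tsv(comp, outdir / "group_comparison_cpg.tsv")
        return {"nmt_cells": len(cpg)}

    stage(
        "epigenome", eff["profile"],
        ["feature_rates_cpg.tsv", "global_methylation.tsv", "profiles_cpg.tsv",
         "group_comparison_cpg.tsv"],
        do_epigenome,
    )

    # ------------------------------------------------------------------ 7
    def do_pseudotime():
        traj = read_counts(outdir / "trajectory_matrix.mtx",
                           outdir / "trajectory_barcodes.tsv",
                           outdir / "trajectory_features.tsv")
        X = qc.normalize_log(traj, qc.size_factors(traj, "library"))
        hvgs = mapping.select_hvgs(X, min(100, traj.n_genes))
        coords, _ = pseudotime.diffusion_map(X[:, hvgs], n_components=5)
        anchor_idx = int(np.flatnonzero(traj.gene_ids == "Hba-x")[0])
        ordering = pseudotime.orient_and_scale(
            coords, X[:, anchor_idx], "Hba-x"
        )
        pt = pd.DataFrame({"cell_id": traj.cell_ids,
                           "pseudotime": ordering.pseudotime})
        truth = pd.read_csv(outdir / "nmt_truth.tsv", sep="\t")
        glob = pd.read_csv(outdir / "global_methylation.tsv", sep="\t")
        merged = glob.copy()
        merged["pseudotime"] = pt["pseudotime"].to_numpy()[: len(merged)]
        _write_tsv(pt, outdir / "pseudotime.tsv")
        curves = []
        for geno in ("WT", "TetTKO"):
            sub = merged[merged["genotype"] == geno]
            curve = pseudotime.loess_curve(
                sub["pseudotime"].to_numpy(), sub["global_rate"].to_numpy(),
                span=0.5, n_grid=50,
            )
            curves.append(pd.DataFrame({"genotype": geno, "grid": curve.grid,
                                        "fitted": curve.values}))
        _write_tsv(pd.concat(curves, ignore_index=True),
                   outdir / "global_methylation_curves.tsv")
        return {"trajectory_cells": len(pt)}

    stage("pseudotime", {"n_grid": 50, "span": 0.5},
          ["pseudotime.tsv", "global_methylation_curves.tsv"], do_pseudotime)

    manifest.save()
    return manifest.data
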