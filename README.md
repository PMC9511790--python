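# embryokit

Analysis toolkit for knockout-vs-wildtype single-cell multi-omics studies of
early mouse organogenesis — the setting where DNA-methylation machinery
mutants (*Dnmt1*, *Dnmt3a*, *Dnmt3b*, *Tet1/2/3* triple knockout) are profiled
at E8.5 with scRNA-seq and scNMT-seq and compared against a staged wildtype
reference atlas.

It is written for computational biologists who have count matrices and
per-cell methylation calls in hand (alignment and methylation calling are out
of scope) and need the downstream statistics:

* **Cell-type label transfer** — query cells are embedded jointly with the
  reference (HVG selection → cosine normalization → PCA), the batch offset is
  removed by matching mutual nearest neighbours (MNN), and each query cell
  receives the majority vote of its *k* = 30 nearest reference cells, with the
  vote being the mode of a Dirichlet posterior over neighbour type counts.
* **Composition phenotyping and embryo staging** — per-embryo cell-type
  proportions, log2 shifts vs the mean wildtype composition (or the matched
  host embryo for chimaeras), and probabilistic stage assignment: PCA on the
  proportion vectors, inverse Euclidean distance to staged reference embryos,
  minmax-normalized to [0, 1].
* **Pseudobulk differential expression** — embryos are the unit of
  replication; counts are summed per embryo within a cell type, normalized by
  median-of-ratios factors, and tested gene-wise under a negative-binomial GLM
  with trended, empirical-Bayes-shrunk dispersions and a quasi-likelihood
  F-test (an NB likelihood-ratio mode is also available). Significance:
  Benjamini–Hochberg FDR 1% and |log2FC| ≥ 1. Marker genes of a cell type are
  those upregulated in **more than** 75% of its pairwise comparisons.
* **scNMT-style epigenome quantification** — binary site rates (a covered
  CpG/GpC is methylated when meth/(meth+unmeth) ≥ 0.5) aggregated under a
  binomial model over BED features, global per-cell rates, feature-centred
  metaprofiles (50 bp windows, ±2 kb), and WT-vs-TKO group comparisons per
  feature class.
* **Pseudotime** — diffusion maps with a locally adaptive Gaussian kernel;
  DC1 is oriented by an anchor gene (e.g. *Hba-x*) and rank-scaled to [0, 1];
  LOESS curves summarize expression and methylation along the trajectory.

A first-class synthetic-data module generates everything with planted ground
truth: a labelled multi-stage atlas, perturbed KO embryos, and coupled
RNA + CpG + GpC cells along a differentiation trajectory with TET-dependent
enhancer demethylation — so every claim the pipeline makes is testable.

## Worked example

```python
import numpy as np
from embryokit import simulate, mapping

spec = simulate.AtlasSpec(n_cell_types=5, n_genes=400,
                          n_embryos_per_stage=3, n_cells_per_embryo=200, seed=1)
atlas, ann, embryos = simulate.simulate_atlas(spec)
pert = simulate.PerturbationSpec(
    fold_changes_on_proportions={"type_0": 0.25},  # deplete one lineage x0.25
    batch_effect_sigma=0.2, seed=3,
)
query, qann = simulate.simulate_query_embryos(spec, pert, 4, 200)

res = mapping.map_query(atlas, ann["cell_type"].to_numpy(object), query,
                        mapping.MappingParams(n_hvgs=300, n_pcs=30))
acc = (res.assignments["cell_type"].to_numpy()
       == qann["true_cell_type"].to_numpy()).mean()
print(f"label transfer accuracy: {acc:.3f}")
```

prints

```
label transfer accuracy: 1.000
```

meaning every one of the 800 query cells — drawn with a planted batch effect
and a 4-fold depletion of one lineage — was assigned its true cell type after
MNN correction and 30-nearest-neighbour voting.

The full chain (fixtures → QC → mapping → composition/staging → DE/markers →
epigenome → pseudotime) runs from one config:

```bash
embryokit pipeline run --config cfg.yaml   # resumable; TSV outputs + manifest
embryokit pipeline fixtures --seed 1 --out fixtures/
```

Two runs with the same config and seed produce byte-identical outputs.

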