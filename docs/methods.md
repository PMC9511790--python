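# Methods

This note documents the models and procedures embryokit implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was open.

## Quality control and normalization

RNA QC applies fixed per-platform gates with **inclusive** comparisons: a
droplet cell passes with ≥ 1500 UMIs, ≤ 30% mitochondrial and ≤ 35% ribosomal
reads; a plate (Smart-seq-style) cell with ≥ 4000 reads, ≤ 10% and ≤ 20%.
Methylation cells need ≥ 5000 covered CpGs and a global methylation of at
least 50%; accessibility cells ≥ 10 000 GpCs with a global rate in [10, 40]%.

A cell's global rate is the mean of per-site *binarized* rates: a site with
meth/(meth+unmeth) ≥ 0.5 counts as methylated, ties counted as methylated so
the rule is deterministic. This site-level binarization is used everywhere
downstream (feature aggregation, profiles, global rates).

Size factors come in two modes. `library` is proportional to total counts.
`pooled` is a pool-and-deconvolve estimator: cells are placed on a ring
ordered by library size, pools of sizes {5, 10, 20} (capped by the number of
cells) are summed, each pool's factor sum is estimated by the median count
ratio against the average-cell reference profile, and per-cell factors solve
the sparse least-squares system with a low-weight (0.01) ridge toward library
factors to keep it full rank. Below 50 cells the pooled mode falls back to
library sizes, since pools would span most of the data. Both modes rescale to
mean 1.

## Label transfer

1. **HVGs** — genes ranked by variance of log1p-normalized expression in
   excess of a lowess mean–variance trend (frac 0.3). The trend is refitted
   once after trimming the top decile of positive residuals so genuinely
   variable genes do not inflate it. Default n = 2000.
2. **Joint PCA** — reference and query are normalized and log-transformed
   together, rows cosine-normalized (stabilizes the MNN kernel scale),
   columns centred, PCA to 50 components. Component signs are fixed by making
   each loading vector's largest-magnitude entry positive, so results are
   fully deterministic.
3. **MNN correction** — mutual nearest neighbours (k = 20) across the two
   batches in PC space; each query cell is shifted by the Gaussian-kernel-
   weighted (σ = 0.1 in cosine-normalized units) average of pair difference
   vectors, anchored at each pair's query member. Reference coordinates are
   never moved. If kernel mass underflows, the nearest pair is used. The
   residual after correcting a pure translation scales with the within-
   cluster spread, not the offset norm — the correction is exact only when
   the technical offset is large relative to local biological variation,
   which is the regime the method is designed for.
4. **Voting** — the k = 30 nearest reference cells are counted by type and
   the argmax is assigned; this equals the mode of a Dirichlet posterior with
   a +1 pseudo-count per observed type, which is why plain majority voting
   implements it. Ties break toward the type with smaller summed neighbour
   distance, then lexicographically. Confidence = max count / k.

k = 30 is a study constant; n_hvgs, n_pcs, mnn_k and the kernel bandwidth are
config-exposed defaults, not asserted constants.

## Composition and staging

Proportions use a pseudocount of 1 cell per type so log2 ratios stay finite
for types absent from an embryo. Shifts are log2(p_query / p_baseline) with
the baseline either the arithmetic mean of wildtype embryo proportions or the
matched host embryo (chimaera mode). Note the renormalization effect: a ×f
depletion of a type with baseline proportion p yields a true shift of
log2(f / (1 − p + f·p)), which approaches log2 f only for rare types.

Staging fits PCA on the row-stacked query + reference proportion matrix
(centred, not scaled — proportions share a scale and scaling would inflate
rare-type noise; default n_pcs = n_stages − 1). A stage's raw score for a
query embryo is the mean over that stage's reference embryos of the inverse
Euclidean distance in PC space (mean rather than min, for robustness to one
outlier embryo), then scores are minmax-normalized across stages. A zero
distance pins that stage's score at the maximum; all-equal scores map to 1;
argmax ties break toward the earliest stage in reference order.

## Differential expression

Counts are summed per embryo within one cell type (samples with < 10 cells
dropped); normalization factors are DESeq-style median-of-ratios over genes
nonzero in every sample, not rescaled (two identical samples get factor 1).

Per gene, a negative-binomial GLM with log link and offset log(factor) is
fitted by solving the score equations per group with a damped fixed-point
iteration (exact for the Poisson case, tolerance 1e-10 on log means).
Dispersion estimation: tagwise values solve the Pearson moment equation
Σ(y−μ)²/(μ+φμ²) = residual df by bisection; a lowess trend of log dispersion
against log mean abundance (frac 0.5) is shrunk against the tagwise values in
log space with weights df/(df + prior_df), prior_df = 10. Two tests share
these fits:

* **qlf** (default): the deviance drop of the group coefficient divided by a
  moderated quasi-dispersion. Quasi-dispersions (deviance/df) are squeezed by
  moment-matching a scaled-F prior on the log scale (trigamma-inverse for the
  prior df, as in standard empirical-Bayes variance moderation); the statistic
  is referred to F(1, df + d0).
* **lrt**: NB likelihood ratio against χ²(1).

Both modes satisfy the same calibration bounds on simulated NB pseudobulk
(null false-positive fraction ≤ 3% at FDR 1% + |log2FC| ≥ 1; power ≥ 80% at
planted log2FC = 2 with 4 vs 4 samples). log2FC is computed from normalized
group means with a prior count of 0.125 per sample, keeping estimates finite
for zero groups. All-zero genes are excluded from the test and from the BH
family. BH adjustment is an exact step-up implementation, property-tested
against a brute-force oracle.

Markers: for C cell types, each type has C − 1 pairwise pseudobulk
comparisons; a gene marks a type when significantly **up** in strictly more
than 75% of them (3 of 4 does not qualify). C < 3 is rejected as degenerate.
A gene may mark several types; cross-tabulations count it once per set.

## Epigenome quantification

Features are 0-based half-open BED intervals; call positions are 1-based
(Bismark dialect); the two conventions are bridged exactly once by the rule
start < pos ≤ end. Per feature, trials = covered sites, successes = sites
with binarized rate 1; zero-coverage features are *missing*, never zero. A
site inside overlapping features contributes to each.

Profiles use the feature centre floor((start+end)/2) and half-open 50 bp
windows over ±2 kb. Within a cell, sites are pooled over all features of a
class (site-weighted) before the window rate is formed; the mean and standard
deviation are then taken **across cells** (matching a per-cell dispersion
display), excluding cells with no sites in a window.

Group comparisons reduce each cell to its mean rate over a class's observed
features, report the difference of group medians first (effect size is the
primary readout) with a Wilcoxon rank-sum p-value BH-adjusted across classes;
groups under 3 cells get the effect without the test. Accessibility runs
through the identical code path with the GpC call set.

## Pseudotime

The diffusion map uses a Gaussian kernel on Euclidean distances with a
locally adaptive scale (distance to the 10th neighbour), anticipated-density
normalization K/(q qᵀ), and a symmetrized eigendecomposition; the trivial
constant eigenvector is dropped and components are scaled by their
eigenvalues with deterministic sign fixing. A disconnected kernel graph is an
error (advice: larger kernel scale). DC1 is the trajectory axis — the sorted
populations are a single lineage, branching inference is out of scope. The
axis is oriented so the Spearman correlation between DC1 and an anchor gene
(an embryonic haemoglobin in the erythroid application) is positive, and
pseudotime is rank(DC1)/(n−1), spanning exactly [0, 1].

LOESS curves are tricube-weighted local *linear* fits using the span fraction
of nearest points at each of 100 grid points (span default 0.5; span·n < 3 is
an error); a singular local design degrades to a weighted mean. Each grid
value equals the closed-form weighted-least-squares solution, which is how
it is tested.

## Synthetic data: what it emulates, and what it does not

**Atlas / query RNA.** Cells are drawn per embryo: embryo composition ~
Dirichlet(stage composition × concentration), cell types multinomial within
the embryo, library sizes log-normal (mean 5000, σ = 0.3), counts negative-
binomial with dispersion 0.1 around cell-type mean profiles (a shared
log-normal baseline with disjoint marker blocks up-shifted by 2³). The NB
family matches the DE model, so calibration and power tests are well-posed.
Queries share the atlas profiles, apply proportion fold changes with
renormalization, an optional stage delay, per-(gene, cell-type) dysregulation,
and a per-gene log-normal batch factor (σ = 0.15) that gives the MNN step
real work. The default Dirichlet concentration (300; 1000 in the composition-
recovery experiment) makes embryo-to-embryo proportion variability a few
tenths of a log2 unit for mid-abundance types — tight enough that staging by
composition is meaningful, looser than a pure multinomial.

**Epigenome.** Sites live in three compartments: *feature* bodies carry the
class rate — for TET-dependent classes the wildtype rate interpolates
linearly from baseline (0.8) to the endpoint (0.2) along latent time while
the knockout stays at baseline; *flank* sites within ±2 kb of a feature stay
at a constant high local rate; a *background* compartment on its own
chromosome carries the passive global decline (0.8 → 0.55 over the
trajectory) in **both** genotypes and dominates the per-cell global rate.
This separation reflects that genome-average methylation loss need not move
the immediate neighbourhood of regulatory elements, and it is what makes the
knockout profile flat while global methylation still falls. Accessibility
gain at lineage enhancers applies to both genotypes (TET-independent).
Coverage is sparse: each candidate site is observed per cell with probability
0.2, with 1 + Poisson(0.2) reads — most sites carry a single read, as in real
single-cell bisulfite data, which also keeps the binarized site rate an
unbiased estimator of the planted rate.

**Not emulated:** doublets, ambient RNA, read-level errors, genome sequence,
imprinting, repeat elements, branching trajectories, and any coupling between
RNA noise and methylation noise beyond the shared latent time. Passing tests
therefore demonstrate that the estimators recover their targets under the
stated generative families at realistic sizes — not that those families
capture every failure mode of real embryos.

**Problem sizes.** The packaged experiments use 5000 reference + 2000 query
cells for label transfer, 10 + 10 embryos × 2000 cells for composition,
2000 genes × (4 vs 4) pseudobulk samples × 5 seeds for DE calibration, 60
cells per genotype per cohort for the epigenome analyses, and 200 cells for
pseudotime — sizes at which every planted effect is comfortably identifiable
while the full suite runs in well under a minute per experiment.

## Determinism

Every generator draws from `numpy.random.default_rng` seeded by its spec;
derived streams use seed sequences so atlas and query share gene profiles
bit-exactly. PCA sign fixing, mergesort-based rankings, explicit tie-breaks
and fixed float formatting (`%.10g`) in TSV output make two pipeline runs
with the same config byte-identical; the pipeline manifest records parameter
hashes and output SHA-256 digests, and stages resume only when both match.

## Known limitations

* The MNN correction supports exactly two batches and a translation-like
  offset; strongly non-linear batch distortions are out of scope.
* The quasi-likelihood machinery is a contract-level reimplementation, not a
  numerical clone of any particular package; p-values agree in calibration,
  not to the digit.
* The pooled size-factor estimator assumes a largely shared expression
  profile across cells; it is applied per dataset, not per cluster.
* Strand collapsing of symmetric CpGs is an opt-in reader flag because the
  strandedness of upstream calls is data-dependent.
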