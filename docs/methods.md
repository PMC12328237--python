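# Methods

This package re-implements, as reusable and tested library code, a set of
statistical procedures used to mine an organism-wide single-cell RNA-seq
atlas: cell-type differential splicing from junction counts, a chemokine
ligand–receptor interaction network, three-criteria cell-type marker
calling with a modified silhouette score, transcriptional phenotyping of
nonsense mutations through allele-specific expression, and cross-species
expression-conservation scoring. Every stage runs on synthetic inputs
with known ground truth, so each procedure's operating characteristics
(calibration, power, recovery) are measured rather than assumed.

## Data model and normalization

Counts are sparse cell × feature UMI matrices with per-cell annotations
(cell type, tissue, individual, compartment, profiling method).
Normalized expression is ln(UP10K + 1) = ln(UMI_gene / UMI_total × 10⁴ + 1),
natural log throughout. Cells with zero total counts normalize to
all-zero rows (with a warning) and are retained in the matrix but carry
no weight in means. By default only droplet-method cells enter
quantitative stages; plate cells are admitted by a config flag. No
doublet removal is performed by default.

Genomic coordinates are 0-based half-open internally and 1-based
inclusive in all files read or written (the GTF/VCF dialect); conversion
is localized to the readers and writers. Annotated splice junctions are
derived from a GTF by pairing adjacent exon boundaries per transcript,
with junction positions given as the first and last intronic bases.

## Differential splicing

For each gene with junction set J and cell set C, with n_m^(i) reads on
junction i in cell m:

    f_m^(i) = n_m^(i) / Σ_j n_m^(j)
    f^(i)   = Σ_c n_c^(i) / Σ_c Σ_j n_c^(j)
    z_m^(i) = sqrt(Σ_j n_m^(j)) · (f_m^(i) − f^(i)) / sqrt(f^(i)(1 − f^(i)))

The square-root depth factor and binomial denominator standardize the
per-cell usage deviation, so under a multinomial null z has mean ≈ 0 and
variance ≈ 1 per junction (verified empirically; pooled over 5,000 null
cells the per-junction mean lies in (−0.1, 0.1) and variance in
(0.8, 1.2)). A MANOVA of the z matrix on cell type yields one p-value
per gene for the null that all cell types share the same multivariate
mean junctional usage; p-values are Benjamini–Hochberg corrected across
genes and calls use a stringent corrected threshold of 1e-16.

Filters, applied per tissue and in this order: cell types with < 10
cells are removed; junctions present in < 2 cells are removed; genes are
tested only if every remaining cell type carries ≥ 2 junctional reads on
the gene; junctions with dataset fraction exactly 0 or 1 are excluded
(their z is undefined and they carry no contrast — a single-junction
gene is therefore untestable). Adding cells of existing cell types never
removes a previously retained junction (a monotonicity property the
tests exercise).

Numerical choices:

- Test statistic: Pillai's trace with the standard F approximation
  (the most robust of the classical MANOVA statistics); Wilks' lambda is
  available by config. "Two-tailed" has no standard meaning for an
  F-based multivariate test, so the ordinary upper-tail p-value is used.
- Junction fractions sum to one per cell, so the z columns are exactly
  collinear; the last junction column is dropped before the fit. With
  two junctions this leaves one response, where Pillai's trace reduces
  to the ordinary one-way ANOVA F test and is computed as such.
- Singular within-group covariance after the column drop skips the gene
  with a logged reason; fewer than two cell types or fewer than two
  cells per type yields a typed "untestable" outcome.

Junction novelty categories relative to an annotation: A — annotated
donor–acceptor pair; B — both sites annotated but never paired
(e.g. unannotated exon skipping); C — exactly one annotated site; D —
both sites novel but contained within the span of a single annotated
gene (junctions straddling two genes fall to E); E — overlapping no
annotated gene.

## Chemokine ligand–receptor network

Per (cell type, gene): the absolute filter requires non-zero expression
in ≥ 5% of the type's cells AND mean ln(UP10K+1) ≥ 0.5 (inclusive, "at
least"). The ceiling is the 99th percentile — linear interpolation, the
numpy default; the convention is configurable since none is canonical —
of the means of passing cell types, computed per gene over passing types
only. The relative thresholds are strict: receptors are called when the
mean exceeds 5% of the ceiling, ligands 20% (ligands are diffusible and
must be abundant to act).

Edges are directed (ligand-expressing type → receptor-expressing type),
deduplicated per ordered node pair across all cognate pairs, with
self-loops allowed. Cross-organ edges are excluded unless either
endpoint's organ is blood: circulating cells contact every organ, so
edges touching a blood-derived node are never organ-filtered. Density is
N_edges / N_nodes²; partition densities use each subnetwork's own
denominator, with the immune/non-immune cross network counting edges in
both directions over 2 · N_immune · N_non-immune. Empty partitions
report a null density, not 0.

## Marker (DE-uTAR/DEG) calling and silhouette

Within one (tissue, individual) dataset, a feature is differentially
expressed in a cell type when all three hold: Bonferroni-corrected
two-tailed Wilcoxon rank-sum P < 0.05 against all other cells of the
tissue; non-zero expression in ≥ 25% of the type's cells; and cell-type
mean expression ≥ e^0.5 (≈ 1.65) times the mean over the rest of the
tissue. The Bonferroni family is all (feature × cell type) tests in the
dataset. The fold criterion is applied to mean normalized ln(UP10K+1)
values by default (e^0.5 reads naturally as a 0.5 log-unit gap); a
config switch applies it to linear-scale means instead — the choice is
genuinely open and both are supported. Wilcoxon uses the exact tie-free
null for groups of ≤ 8 and the tie-corrected normal approximation
otherwise.

The silhouette is the modified form s(i) = (b(i) − a(i)) / max{b(i), a(i)}
where a(i) is the mean in-group distance and b(i) is the minimal distance
of cell i to ANY cell of a different type — deliberately not the
textbook minimum over per-cluster mean distances. The two agree exactly
when every out-group cluster is a single cell, and the minimal-distance
form is more pessimistic whenever a foreign cluster has a nearby
straggler. Singleton cell types score 0 by convention.

## Nonsense-mutation phenotyping

Reads covering the variant position in a heterozygote are split by
allele. Depletion is estimated as d̂ = 1 − Σmut/Σwt pooled over tissues
(clamped to [0, 1]; tissues with zero coverage are omitted, and zero WT
reads make the estimate undefined rather than infinite). The one-tailed
binomial test P(X ≤ Σmut | n, ½) quantifies departure from the balanced
transcription expected of autosomal alleles.

The generative model behind both the simulator and the regime calls: in
a heterozygote the WT allele carries weight c·t and the mutant 1 − d,
where d ∈ [0, 1] is NMD depletion, c ≥ 1 a compensatory transcriptional
upregulation factor, and t ∈ (0, 1] a trans factor modelling reduction
of the WT transcript (or attenuated positive feedback). Expected mutant
read fraction: (1 − d) / ((1 − d) + c·t); expected heterozygote total
expression relative to WT individuals: (c·t + (1 − d)) / 2. The simple
model (c = t = 1) gives the identity r_exp = d/2 — 90% depletion
predicts 45% fewer transcripts.

The heterozygote-vs-WT comparison averages the gene per (cell type,
individual), pooling cell types across tissues, excluding cell types
with < 35 droplet cells in any profiled individual and cell types whose
WT mean ln(UP10K+1) < 0.3 (the filter is defined on WT expression only
and removes the cell type for all individuals symmetrically). Values
are normalized to the mean over all WT cells, and the two sets of
cell-type values are compared by Welch's two-tailed t-test (the
unequal-variance form, since group variances are not exchangeable).
The observed reduction r_obs = 1 − mean(het)/mean(WT) is computed on
linear-scale mean UP10K by default: the d/2 identity concerns relative
transcript counts, and ratios of ln-transformed means would depend on
expression magnitude and systematically understate the reduction. A
config switch computes the ratio on the log scale instead.

Regime classification with tolerance band tol = 0.10 (absolute,
configurable; the source analyses classify qualitatively): a last-exon
stop with d̂ < 0.5 escapes NMD; otherwise |r_obs − d̂/2| ≤ tol is simple
NMD, r_obs > d̂/2 + tol is trans-reduction/feedback, and
r_obs < d̂/2 − tol is compensatory upregulation.

## Cross-species conservation

A human gene is primate-selective (PS) when at least one lemur
orthologue is assigned by NCBI or Ensembl and no mouse orthologue is
assigned by NCBI, Ensembl or MGI. PS genes, genes with a mouse
orthologue and genes with no lemur orthologue partition the human gene
universe (tested against a brute-force oracle). PS counts are database-
version-dependent and are not treated as fixed quantities.

Conservation of a gene pair is the Pearson correlation of mean cell-type
expression profiles over curated matched cell types (≥ 3), after
normalizing each species' profile by its E_max (mean expression in the
maximally expressing cell type). Genes first pass the magnitude filter:
E_max > 0.5 in each species, or E_max > 0.1 in each with E_max > 1.5 in
at least one. Correlation is invariant to the E_max normalization
composed with any positive scaling; it is computed here directly over
matched profiles rather than through a joint cross-species manifold —
a deliberate simplification that keeps the triad logic exact while
dropping the manifold machinery. Triads with all three pairwise
correlations strictly above 0.3 are expression homologues, classified as
named orthologue (all pairs orthologous, lemur gene named), unnamed
orthologue (all orthologous, lemur gene has only a locus identifier) or
non-orthologue (≥ 1 pair unassigned, regardless of naming). When NCBI
and Ensembl disagree on one-to-one mapping, NCBI is preferred, retaining
pairs with identical symbols or descriptions.

## Synthetic data generator

One global seed is stream-split per stage (numpy SeedSequence spawn
keys), so stages are independently reproducible and byte-identical under
a fixed seed. What each generator emulates — and what it does not:

- **Expression**: negative binomial with mean/dispersion parametrization
  (var = μ + μ²/θ), cell-type-structured means, markers up-shifted by a
  fold change in their target type. Defaults: dispersion 2, base mean
  0.5 per gene, marker fold 8 on a base mean of 0.4 (≈ 30% expressing
  fraction). No ambient RNA, doublets or batch effects.
- **Junctions**: per cell, a Poisson junctional depth (default mean 20
  reads) split multinomially by the cell type's usage vector — the
  matched null of the z-score's binomial variance stabilization. Null
  designs share one usage vector across types; the switch design uses
  0.9/0.1 vs 0.1/0.9 between two types.
- **Alleles**: per-heterozygote allele reads (default 3,000 per variant,
  typical of the per-gene read depth an atlas provides for abundantly
  expressed genes) drawn binomially at the model's mutant fraction and
  split over tissues; matched expression for 4 individuals (2 WT, 2 het)
  over 40 cell types × 60 cells with lognormal cell-type baselines.
- **Ligand–receptor**: planted expressing types receive counts whose
  normalized means clear both thresholds with ≥ 2× margin; other types
  are zero. The planted truth is the edge list implied by the design
  under the organ rule.
- **Cross-species**: per gene, both species' profiles share a latent
  standard-normal cell-type component with weight sqrt(r) plus
  independent noise with weight sqrt(1 − r), shifted and scaled to
  positive means (baseline 2, scale 0.5; the rare negative value is left
  untouched since correlation is affine-invariant). Profiles are emitted
  directly as gene × cell-type mean-expression tables, the unit the
  conservation scorer consumes.

Passing tests on these fixtures demonstrates correctness of the
procedures under their assumed noise models — multinomial junctional
sampling, NB expression, binomial allele sampling — not robustness to
the artefacts of real atlas data (batch effects, ambient contamination,
annotation errors, doublets).

## Problem sizes used in the checks

Calibration and recovery runs use desk-scale designs chosen to make the
Monte-Carlo error small relative to each acceptance band: 500 null genes
at 50 cells/type for MANOVA type-I error (binomial 95% CI half-width
≈ 0.019 at α = 0.05); 5,000 cells per junction for z calibration; 100
seeds for switch power; 200 seeds × 4 depletion levels at 3,000 allele
reads for depletion recovery (at 3,000 reads the estimator's sd at
d = 0.5 is ≈ 0.02, so the ±0.05 band holds in ≥ 95% of seeds; at a few
hundred reads it would not); 200 null replicates for the marker caller's
family-wise error; 50 random graphs for the density oracle.

## Known limitations

- The MANOVA F approximation is asymptotic; with very small cell types
  (near the 10-cell floor) and low junctional depth, discreteness of the
  multinomial can make the test slightly conservative or liberal.
- Junction classification matches sites by exact genomic position and
  ignores strand when testing site membership.
- The depletion estimator ignores mapping bias between alleles; real
  allele-specific pipelines must correct reference bias upstream.
- Conservation scoring assumes the matched cell-type curation is given;
  no cross-species integration or manifold alignment is performed.
- The marker caller treats genes and unannotated transcribed regions
  identically; discovery of those regions is upstream of this package.
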