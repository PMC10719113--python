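# Methods

This note documents the models and procedures implemented in `mcatlas`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Cell QC and pre-cluster screening

Primary QC uses strict thresholds on per-cell summaries: bisulfite
non-conversion proxy mCCC < 0.05, global mCH < 0.2, global mCG > 0.5,
500,000 < final reads < 10,000,000, mapping rate > 0.5, and for joint
methylome+3C cells more than 50,000 cis-long-range contacts (anchors
> 2,500 bp apart). These are deliberately loose; cluster-level screening
catches the remainder.

The PNCC screen divides each cell's final reads by the mean of its 384-well
plate, since plate-mates share library-preparation batch conditions. For
each pre-cluster a null distribution of PNCC mean and s.d. is built by
drawing cell sets of the same size and the same per-plate composition
(10,000 draws by default — the FDR resolution of the permutation P values
needs this many to clear the 0.01 flag threshold over tens of clusters).
The mean is tested two-tailed, the s.d. one-tailed (larger), P values are
BH-corrected, and a pre-cluster is flagged when |log2 mean PNCC| > 0.8 and
either FDR < 0.01. Sampling is with replacement within plates; for
pre-clusters far smaller than their plates this is indistinguishable from
without-replacement sampling and keeps the null generation vectorized.

## Posterior fractions and feature selection

Raw bin fractions mc/cov at ~1–30 basecalls per 100-kb bin are noisy, so a
Beta prior is fitted per cell by method of moments to that cell's bin
fractions and the posterior mean (mc+α)/(cov+α+β) is used; zero-coverage
bins fall back to the prior mean, and a degenerate prior (zero variance, or
moments outside the Beta family) falls back to raw fractions with a
warning. Posterior fractions are divided by the cell's global level (so
values are enrichment relative to the cell's baseline) and capped at 10.

Highly variable features are ranked by Z-normalized dispersion
(variance/mean) of the posterior fractions after removing
blacklist-overlapping bins and bins whose mean coverage falls outside
0.05–20× the median bin. Normalization is global by default; the
mean-quantile-binned variant used for count data is available via
`n_dispersion_bins` but is counterproductive for fraction matrices where
marker bins concentrate in the low-mean bins. Cluster-enriched features use
a one-vs-rest AUROC of *hypomethylation* (lower fraction = enriched,
mirroring expression), with significance from a membership-permutation null
(2,000 draws by default; the BH-adjusted minimum attainable FDR must sit
below the 0.01 cut-off) and the top 200 significant features per cluster.

## Consensus clustering

Leiden clustering runs n (default 200 in production, 30–50 on the test
fixtures) times with distinct seeds at a deliberately low resolution (0.25
first round, 0.2–0.5 later); cells with identical label vectors across runs
form preliminary clusters, tiny ones (< 10 cells) being reassigned to the
nearest large cluster centroid. A multinomial logistic-regression model on
the PC embedding then predicts labels under cross-validation; the most
confusable pair under row/column-normalized (R1/R2) confusion is merged
repeatedly until held-out accuracy reaches the target (0.95 round 1, 0.9
later). Rounds recurse into clusters that are both large (> 20 cells) and
well-predicted (per-cluster accuracy > 0.9). Final labels are split by
dissection region into cell groups; regions with < 20 cells merge into the
nearest region by mean Euclidean distance in PC space. The logistic model
was chosen over boosted trees for determinism and speed; any calibrated
classifier fits the contract.

## DMS/DMR calling

Coverage is first downsampled proportionally (per-sample cap 50, total cap
3,000) with nearest-integer rounding — deterministic by design so repeated
runs agree exactly; a stochastic (hypergeometric) mode is not needed for
the statistics and is omitted. The per-site statistic is the root mean
square of observed minus expected counts over the samples × (methylated,
unmethylated) table, with expected counts from the pooled fraction. The
null reassigns the pooled methylated calls to samples with both margins
fixed (sequential multivariate hypergeometric), so the permutation P value
is exact up to Monte Carlo error; BH correction with a default cut-off of
FDR < 0.01. Significant sites chain left-to-right into DMRs when
consecutive sites are ≤ 250 bp apart *and* their per-sample fractions
correlate with PCC > 0.3; 251 bp or anti-correlated neighbours split.
Overlapping DMR sets from multiple runs merge at distance 0, the
representative being the record with the largest |key| (|statistic| by
default, |PCC| or motif score for value-bearing analyses).

## Integration

Features are Z-scored per dataset (clipped at ±10) and the mC sign is
reversed upstream where methylation anti-correlates with the paired
modality. CCA solves SVD(X_ref Y_refᵀ) on a seeded (optionally
cluster-stratified) reference subsample; queries are projected by
`U_qry = X_qry (Y_refᵀ V_ref)/S`, which reduces exactly to full CCA when
the reference covers all cells (this identity is tested to 1e-8). Rows are
L2-normalized before neighbour search. Anchors are mutual 5-nearest
neighbours; the anchor score counts shared members of the two cells'
30-neighbourhoods in the joint space, min-max rescaled — the
shared-neighbour form follows the batch-integration lineage this module
extends, and both k values are exposed. Correction moves each query cell by
a weighted mean of the bias vectors (reference minus query coordinates) of
its 100 nearest anchors, distances measured in the query embedding to the
anchors' query cells, with a Gaussian kernel on rank-normalized distances
(σ = 0.3); the reference embedding is never touched.

For 5-kb-bin integration the hypomethylation score is the binomial tail
P(X > mc) with X ~ Bin(cov, p_cell); scores > 0.95 binarize to 1, columns
need > 5 non-zeros and Z-scored log2 column sums within ±2. LSI uses log
term frequency (`log(TF×1e5 + 1) × IDF`, IDF = log(1 + n/colsum)); the SVD
factors and IDF are stored so the second modality is transformed with the
reference model.

Cluster correspondence uses the overlap score
OS(a,b) = Σ_k min(frac of a in co-cluster k, frac of b in k) over Leiden
co-clusters of the integrated embedding; the OS matrix, as a weighted
bipartite graph, is Leiden-clustered (resolution 1) into integration
groups, and integration recurses per group until a stop criterion (single
group, single cluster on a side, < 30 mC cells, < 100 droplet RNA cells or
< 30 full-length RNA cells). The alignment score uses
k = max(20, 1% of region cells) neighbours: with x̄ the mean count of
same-dataset neighbours and N datasets, score = 1 − (x̄ − k/N)/(k − k/N);
values slightly above 1 occur when mixing is better than expectation.
MERFISH cells pass QC with volume in (30, 2000) µm³, counts in (10, 4000),
density in (0.05, 5), ≥ 3 genes and ≤ 5 blank probes; spatial locations of
sequenced cells are the centroids of their 10 nearest imaged neighbours in
the joint embedding.

## Chromatin conformation

Per-cell maps are imputed by Gaussian convolution (σ = 1, kernel half-width
pad = 1) followed by random walk with restart on the row-normalized graph,
iterating R ← (1−α) R W + α W from R₀ = W to tolerance 1e-6 (α = 0.5
default). This formulation makes α = 1 return the convolved, row-normalized
matrix exactly — a useful degenerate check. Output is band-masked at fine
resolutions, row-normalized and symmetrized.

Compartments: bins outside the blacklist with per-group coverage between
2·median − q99 and q99 are retained; each group's map is
distance-normalized (each diagonal divided by its mean), its correlation
matrix feeds one IncrementalPCA fitted across all groups, and all groups
are transformed with the shared loadings so scores are comparable. The
score is PC1 or PC2, whichever better correlates with CpG density, signed
so CpG-rich (A) is positive on every chromosome.

Boundaries: the TopDom window signal (mean contact between the w = 5 bins
up- and downstream) proposes local minima, filtered by a one-sided
rank-sum test (cross-boundary vs within-flank contacts, P < 0.05).
Differential boundaries use an n×2 chi-square per 25-kb bin (no continuity
correction — the 80/100-vs-20/100 table gives exactly χ² = 72) at
FDR < 1e-3. Highly variable interactions are one-way ANOVA F > 3 (and
FDR < 1e-3) across groups on imputed strengths within 50 kb–5 Mb anchor
distance; raw strengths by default with a log1p flag, since imputed values
are already smoothed and the two-group case must reduce exactly to t².

All methylation–conformation correlations share one permutation null:
matrices are quantile-normalized along samples (single-column matrices are
left as-is — one value per sample cannot be normalized), item values are
shuffled within each sample (destroying the genomic correspondence while
preserving sample-level distributions), and the pooled null PCCs — at
least n_perm of them, accumulated over ⌈n_perm/n_pairs⌉ matrix shuffles —
are summarized by a Gaussian for tail P values, then BH-corrected at
FDR < 1e-3. Transcripts overlapping reciprocally by > 90% are grouped to
their union span; transcripts < 100 kb are labelled short. Interactions
classify into intragenic/upstream/downstream combinations by strand-aware
anchor position; the anchor-overlap gate that assigns interactions to genes
is a flag so flanking-only configurations can also be classified.

## Regulatory networks

Motif occurrences come from a log-odds PWM scan (pseudocount 1e-3, uniform
0-order background, both strands, N = background odds); per DMR and motif
the maximum score is kept. This replaces an HMM-based multi-motif scanner
with a deterministic, dependency-free equivalent for the same ranking role.
Enrichment follows the recovery-curve approach: DMRs ranked by motif score,
AUC of the query-recovery curve over the top 3% of the ranking (wider on
the small fixtures), NES = (AUC − mean)/s.d. across the motif collection,
enriched at NES > 3. Note NES > 3 is only attainable when the collection
has ≳ 11 motifs ((n−1)/√n > 3); the fixtures use 33. Leading-edge DMRs are
the query members ranked above the point of maximal excess recovery.

Edges: DMR–target candidates are DMRs inside anchors of the gene's
positively correlated variable interactions, correlated (DMR mCG vs gene
mCH) across subclasses with the shuffle null at FDR < 1e-3, overlapping
DMRs collapsing to the max-|PCC| representative; TF–target edges correlate
gene-body mCH of TF and CEF genes (self-edges excluded); TF–DMR edges
additionally require an enriched motif of the TF in the correspondingly
signed DMR set and a leading-edge occurrence in the specific DMR. Triples
join on shared gene and DMR ids; S_d is the PCC of target mCH with the
gene–DMR contact strength (most negative when several), and
S_all = |S_a S_b S_c S_d|^(1/4), which is sign-invariant and zero iff any
component is zero. PageRank (damping 0.85, tolerance 1e-8) runs per
subclass on the TF/gene node network with personalization proportional to
inverted, robust-scaled (quantile range 0.1–0.9), quantile-normalized gene
mCH (W) and edge weights e = mean over connecting DMRs of S_all × inverted
DMR mCG (V). No S_all floor is applied before PageRank; weak triples simply
carry little weight.

## Isoform prediction

Targets are highly variable transcripts (mean TPM > 0.2, s.d. > 0.3, body
> 30 kb) and exons (PSI s.d. > 0.02, q90 − q10 > 0.05); PSI is the
TPM-weighted fraction of a gene's transcripts containing the exon, NaN when
the gene is silent (missing entries are dropped per target, not imputed).
Features per gene are exon bodies, ±300-bp exon flanks, intragenic DMR mCG
and intragenic variable-interaction strengths; features with variance
< 0.01 are removed and features with > 90% reciprocal interval overlap are
averaged. Univariate F-regression picks the top 100 features per target,
the union over the gene's targets feeds a 300-tree random forest under
5-fold CV (selection nested inside each training fold by default — the
leak-free variant; a flag gives the simpler once-per-gene selection), and
performance is the PCC of out-of-fold predictions. The control shuffles
feature values within each cell group with the same folds and seeds:
group-level (shared) signal survives the shuffle, so
ΔPCC = PCC_true − PCC_shuffled isolates information tied to *which*
intragenic feature carries the value.

## Synthetic data: what it does and does not emulate

The generator plants, per seed and bit-reproducibly: K near-balanced cell
clusters with disjoint hypomethylated marker bins (binomial basecalls at
Poisson coverage around per-cell global levels drawn near mCG 0.75 ± 0.03
and mCH 0.04 ± 0.01, neuron-like); contact maps as multinomial draws from
an intensity surface combining (d/bin)⁻¹ distance decay, alternating A/B
blocks (×2 within-block), domains (×3), and loop pixels whose strength
decreases linearly with the coupled gene's cluster-level methylation; RNA
and ATAC profiles anti-correlated with gene mCH / DMR mCG at a configurable
strength; DMR sequences carrying exact consensus occurrences of their
regulon TF's PWM; and subclass-level profile matrices in which each
subclass has one clearly dominant regulon. Default fixture scale is one
50-Mb chromosome, 100-kb primary bins, 300–1,000 cells — sized so every
stage runs in seconds to minutes.

It does **not** emulate read-level data (no FASTQ, no bisulfite-conversion
error model), chromosomal heterogeneity (one synthetic chromosome),
cell-cycle or depth confounders beyond plate structure, trans contacts,
overlapping genes, or realistic motif redundancy. Passing tests therefore
demonstrate correctness of the statistics and recoverability of planted
structure at realistic noise levels, not performance on the full
complexity of tissue atlases.

## Numerical choices and limitations

- All coordinates are 0-based half-open (BED convention); ALLC-style
  tables are written 1-based as in that lineage.
- Random streams are derived from one master seed via named
  `SeedSequence` spawn keys (CRC32 of the stream name), so adding a
  generator never perturbs the others.
- Permutation P values use the (1 + exceed)/(1 + n) estimator; two-tailed
  mean tests double the smaller tail and cap at 1.
- Contact containers are scipy sparse upper-triangles plus plain triplet
  TSV; bedGraph/BEDPE-style tables are plain TSV.
- The iterative-RWR tolerance (1e-6), TopDom window (5) and rank-sum cut
  (0.05), CCA clip (±10), correction kernel σ (0.3) and forest size (300)
  are exposed as keyword arguments; defaults follow the respective
  tool lineages where one exists.
- `shuffle_null_correlation` pools null PCCs across pairs; with very few
  pairs the Gaussian null is wide and P values conservative — the
  minimum attainable P is bounded by the sample count, not by n_perm.
- The chi-square boundary test is asymptotic; bins called in very few
  cells have low power but are still counted, matching the contract that
  never-called bins get statistic 0.
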