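# Methods

This note documents the models, parameter choices and numerical details
behind `neotcr`, and what the synthetic-data tests do and do not establish
about real data.

## Clonotype identity and QC

A clonotype is a paired-chain identity: (α CDR3 amino acids, β CDR3 amino
acids, TRAV/TRAJ/TRBV/TRBJ genes). The nucleotide CDR3 is stored but does
not enter identity, and known-TCR matching defaults to the CDR3 amino-acid
pair alone — convergent clonotypes that share CDR3s but differ in V/J are
all reported as matches, and a stricter `cdr3_pair_plus_vj` mode is
available.

Two QC universes are supported and must not be mixed within one
comparison:

* **strict** — exactly one productive α and one productive β contig per
  barcode. This is the universe for candidate selection, where both
  chains must be known to synthesize a receptor.
* **any-defined** — at least one productive chain, and no chain type
  present more than once. A superset of strict, useful for repertoire
  overviews. We require productivity for the single defined chain; a
  non-productive contig is not a defined receptor chain.

Duplicated contig rows that are identical in (chain, CDR3, V, J,
productivity) are collapsed before filtering: they are sequencing/assembly
artifacts and should not disqualify a cell as "multi-chain". Chains other
than TRA/TRB are ignored. Frequencies are always computed over the cells
that passed the same filter, so the two universes have different totals by
construction.

## Enrichment ranking

Fold change uses one pseudocount cell added to the count and the total on
both sides. Nothing in the underlying procedure defines how a clonotype
absent before stimulation should be ranked; additive smoothing is the
minimal rule that keeps post-only clonotypes finite and rankable, and it
converges to the raw frequency ratio as counts grow (a tested property).
Reported `freq_pre` / `freq_post` are raw.

Two ranks are assigned among non-known clonotypes: descending fold change
and descending restimulated frequency. Ties break by descending
restimulated count, then by the canonical key string, making the ranking
a deterministic total order. The candidate selection is the union of the
top-k lists of the two metrics (k configurable, default 2): the two
metrics capture different discovery modes — rare clonotypes that expand
sharply, and clonotypes that dominate the restimulated repertoire — and
the union keeps both. No significance test is attached: the procedure
ranks candidates for experimental validation, it does not test hypotheses.

## Expression processing

Thresholds for cell QC are: at least 200 and fewer than 6000 detected
genes (boundary semantics: 200 kept, 6000 removed), and mitochondrial
fraction at most 0.18 (0.18 kept), with the fraction computed over genes
carrying the `MT-` name prefix. Genes must be detected in at least 3
cells of the **raw** matrix; the gene filter runs before the cell filters,
mirroring the usual object-construction order, and the combination is
idempotent (no re-iteration).

Log-normalization is `ln(1 + count / total * 10^4)`.

Variable genes follow the variance-stabilizing approach: a local
regression (lowess, span 0.3) of log10 variance on log10 mean over genes
with positive variance predicts each gene's expected SD; raw counts are
standardized by it, clipped at √n_cells, and genes are scored by the
variance of the clipped values. The top 2000 genes are kept by default.
The span, clip and n_top are configuration; defaults are the values in
common use, since nothing in the procedure depends delicately on them.

Scaling regresses each gene's normalized expression on intercept + UMI
count + mitochondrial fraction (OLS), standardizes the residuals to unit
variance, and clips at ±10. Genes whose residual SD is below 1e-10 of the
gene's scale (constant genes, or genes exactly linear in a covariate) are
set to zero rather than amplifying rounding noise.

**Batch handling.** Anchor-based integration (CCA) is a large external
algorithm and is not reimplemented. Instead, regression and
standardization can be run within each sample (`batch_key="sample"`)
before the joint PCA. This removes per-sample location/scale differences
but not nonlinear batch structure; users comparing across strongly
batched samples should treat cross-sample cluster identity with caution.

Clustering: exact-SVD PCA (30 components by default), undirected kNN
graph (15 neighbors, Euclidean distance in PC space), Leiden modularity
optimization with a configurable resolution (default 0.8 — the resolution
is data-dependent and deliberately exposed rather than fixed) and a fixed
seed. Cluster ids are relabeled by decreasing size so runs are comparable;
named cluster labels on any particular dataset are annotations, not
outputs.

**Module scores.** All genes are ranked by mean expression and cut into
24 equal-size bins; each signature gene contributes 100 control draws
(with replacement, seeded) from its bin **excluding the signature genes
themselves**; the score is mean signature expression minus mean control
expression per cell. Excluding the signature from the control pool
matters: with signatures concentrated in one bin, bin-mate draws that
include signature genes attenuate a true shift by the signature's share
of its bin. Under exchangeability of signature and bin-mates the score's
expectation is zero (tested empirically with the signature redrawn per
replicate). Cell-cycle phase is G1 when neither the S nor the G2M score
is positive, otherwise the phase of the larger score (S wins exact ties).

## Linking and differential expression

Cells are joined on (sample, barcode); transcriptome cells without TCR
are retained with an empty clonotype so they stay available as
background. Cluster composition is reported as percent of the group's
cells, only for groups with **strictly more than** 25 cells; smaller
groups are listed separately with their counts.

Differential expression is a two-sided Wilcoxon rank-sum per gene with
Bonferroni correction over the tested genes. Genes enter the test when
detected in ≥10% of either group and when |log2 fold change| ≥ 0.25,
where the fold change compares group means of `expm1`-back-transformed
normalized expression with a +1 pseudocount (both thresholds are
configuration; they follow common single-cell practice and are recorded
with the results).

The p-value is exact — the full null distribution of the rank sum by
dynamic programming — when the pooled size is ≤12 and there are no ties;
otherwise a normal approximation with tie correction and continuity
correction (numerically identical to scipy's asymptotic Mann–Whitney p).
The approximation is accurate to ~0.01 against a 10^5-draw permutation
reference under moderate ties; under extreme discreteness (a handful of
distinct values across all cells, as in very shallow counts) any normal
approximation can deviate by up to ~0.05 from the permutation p, which is
a known property of the approximation rather than of this implementation.

## Assays

* Specific cytolysis: `100 − (CI_x / CI_non-transduced) × 100`, affine in
  CI_x and ≤100; negative values (outgrowth) are returned flagged, not
  clipped. The normalized Cell Index is taken as input; the normalization
  time point is metadata.
* k_off: nonlinear least squares of `plateau + amplitude·e^(−kt)` with
  plateau ≥ 0, initialized from the signal extremes and a log-linear
  slope; tight optimizer tolerances (1e-14) so noiseless round-trips
  recover parameters to 1e-6. t½ = ln2/k holds exactly by construction.
  Traces are fit as exported (dye/backbone normalization happens
  upstream).
* EC50: 4-parameter logistic on log10 concentration. Fits are
  canonicalized to bottom ≤ top, hill > 0; flat curves return a flagged
  degenerate result instead of a number, and EC50 outside the tested
  range is flagged extrapolated.
* Cytokine ratios: `log2((num + floor)/(den + floor))` with an additive
  floor (default 1 pg/mL; set it to the assay's lower detection limit).
* Peptide m/z: explicit monoisotopic residue-mass table (standard
  unmodified amino acids), water 18.0105647 Da, proton 1.00727646 Da;
  `mz = (Σ residues + water + z·proton)/z`, reported to 4 decimals. Only
  unmodified peptides are supported by design; an element-composition
  engine is out of scope.

## Bulk normalization

Median-of-ratios size factors: per gene with positive counts in all
samples, the geometric mean across samples; per sample, the median over
those genes of count/geometric-mean, taken in natural space (the median
of an even number of ratios is the arithmetic mean of the middle two —
taking it in log space is a different estimator and was rejected by the
brute-force oracle). Control normalization divides each sample's
normalized counts (+1 pseudocount) by the mean of its mapped control
samples (+1); when several control replicates exist in a condition ×
timepoint group their mean is the denominator. Ratios are emitted on both
the natural and log2 scales. For PCA the package uses log2(x+1) on
normalized counts — a documented, simple substitute for a full
variance-stabilizing transform — and reports the first two components.

## Synthetic data: what it emulates

Pre-stimulation clonal frequencies follow a discrete power law
p_i ∝ i^(−α), the standard heavy-tailed repertoire assumption; the
exponent is exposed (default 1.5) because real repertoires vary and the
source experiment reports only a single clonotype's baseline frequency.
Post-stimulation probabilities multiply spiked clonotypes by their
enrichment factor and renormalize; cells are multinomial draws.
Per-cell corruption reproduces what the QC must remove: chain dropout
(10%), an extra α or β copied from another clonotype (5%), non-productive
contigs (5%).

Expression counts are Poisson with per-cell rate = library size ×
softmax(gene weights); program genes get a log-weight shift (+1 by
default over 15-gene blocks for four programs: naive, effector,
inhibitory, proliferative), mitochondrial genes receive the cell's true
mitochondrial fraction of the rate mass (Beta(2, 23), mean 0.08), and
library sizes are lognormal (ln 2500, 0.35). Default sizes (2000
clonotypes, 5000 cells/sample, 300 genes) give per-clonotype counts and
per-gene depths comparable to a single 10x lane after QC while keeping
simulation-heavy tests fast; the acceptance checks run 20 replicates at
the full 5000-cell scale.

One RNG stream per artifact (clonotype definitions, each sample's cells,
expression), all derived from the single config seed, so repertoire and
expression are independently byte-reproducible.

**What passing synthetic tests does not show:** the generator has no
doublets, no ambient RNA, no batch structure beyond location/scale, no
UMI saturation, Poisson (not over-dispersed) counts given the cell, and
programs are mutually exclusive single labels. Results on real data
depend on QC and batch choices that these tests cannot validate. The
clonotype-universe sizes printed in the source study come from
controlled-access data and are not asserted anywhere; the synthetic
end-to-end test plays that role with generator truth.

## Known limitations

* CDR3-pair matching cannot distinguish convergent clonotypes that share
  both CDR3s but differ in V/J unless the V/J mode is used.
* The DE module compares two groups at a time; one-vs-rest marker scans
  are a thin loop the user writes.
* The 4PL fit reports a single EC50; biphasic dose–response curves are
  flagged only through a poor RSS, not detected explicitly.
* `pct_mito` is a fraction in [0,1] throughout ("18%" ⇒ 0.18); mixing
  percent-scaled metadata into the QC thresholds will silently keep
  everything.
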