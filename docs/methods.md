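# Methods

`dcisibc` implements a subtype-stratified comparison of ductal carcinoma in
situ (DCIS) and invasive breast cancer (IBC) across three molecular layers —
gene expression, DNA methylation and DNA copy number — together with a
synthetic cohort generator that makes the whole analysis runnable and
testable without patient data. This note documents the models, the
parameters that matter, the numerical conventions, and the limits of what
the synthetic cohort can show.

## Coordinate and data conventions

Genomic intervals are 1-based inclusive everywhere in memory. BED-like
files are 0-based half-open on disk and converted by the readers; SEG-like
segment files are stored 1-based inclusive as written. Expression is
log2-scale, genes x samples. Methylation is a CpGs x samples matrix of
beta-values (fraction of methylated molecules, in [0, 1]) with a parallel
detection p-value matrix.

## Intrinsic subtyping

Samples are assigned to intrinsic subtypes (basal-like, HER2-enriched,
luminal A, luminal B) by nearest-centroid classification: Spearman rank
correlation (mid-ranks for ties) between a sample's centered expression
vector and each subtype centroid, over the genes shared between matrix and
centroid set; the argmax wins, exact ties break by centroid column order
and are logged. The second-best subtype is reported alongside.

Centroid classifiers of this family assume the cohort has the ER-positive
fraction of the original training population (about 60%). The package
therefore centers each gene at

    m_g = w * mean(ER+) + (1 - w) * mean(ER-),    w = 0.6 by default

rather than at the plain cohort mean, which makes centering invariant to
the cohort's ER composition. ER (and PR) status is itself called from the
marker gene's expression (ESR1, PGR), which is strongly bimodal in breast
cohorts: a two-component equal-variance Gaussian mixture is fitted by EM
with 10 random restarts, and the cutoff is the equal-posterior point
between components; a sample is positive iff strictly above the cutoff. If
the two components are separated by less than one common standard
deviation the fit is treated as degenerate and a user-supplied fallback
cutoff is required.

*Core basal* samples are those whose correlation to the basal-like
centroid is strictly greater than 0.6. The flag is computed for every
sample; its biological reading (an aggressive, 5q-deleted invasive
phenotype) applies to invasive tumors, and reports filter accordingly.

## Signature scores

A signature is a set of (gene, weight) pairs, weights typically +1/-1. Each
gene is standardized across the full cohort (sample standard deviation,
n-1; configurable to population), and a sample's score is the mean of
weight x z over the signature genes found in the matrix. Genes absent from
the matrix are dropped and counted; zero-variance genes score zero with a
warning. The bundled synthetic signatures are an 11-gene proliferation set
(unit weights) and an EMT set with positively weighted EMT genes and
negatively weighted adhesion genes. Real signature memberships are supplied
by the user as a TSV — the scorer is generic and does not hard-code any
published gene list.

## Copy number

The pipeline consumes pre-segmented integer copy-number profiles
(sample, chrom, start, end, cn), non-overlapping per sample and
chromosome.

* **Gene copy number** is the cn of the segment with maximal base-pair
  overlap with the gene interval; equal overlap breaks toward the segment
  with the smaller start. The HER2 copy-number readout is simply this
  lookup at the ERBB2 locus.
* **Genomic instability index (GII)** is the fraction of the covered
  genome (sum of segment lengths — uncovered regions carry no information)
  whose copy number differs from the baseline. The default baseline is the
  diploid cn = 2; a per-sample baseline equal to the nearest integer of a
  supplied ploidy is available for aneuploid cohorts where ploidy has been
  estimated upstream.
* **Aberration frequencies** report, per locus and group, the fraction of
  samples with a gain (cn > baseline) and with a loss (cn < baseline);
  a sample contributes to at most one of the two at a locus, so the two
  frequencies sum to at most 1.

## Methylation

QC follows the standard 450K recipe: beta-values with detection p strictly
above 0.05 are set missing; CpGs with strictly more than 25% missing
values are removed; remaining gaps are imputed by k-nearest-neighbour
rows (k = 10). The imputation matches the semantics of the classical
`impute.knn` approach: distances between CpG rows are Euclidean over
jointly observed samples, scaled by the fraction observed; a missing entry
is the mean of the target sample's values over the k nearest rows observed
there, with a row-mean fallback when no neighbour qualifies, and imputed
values are clipped to [0, 1]. Rows entirely missing are an error.

**Per-gene methylation profiles.** For each gene, the CpGs within the gene
body plus a 50 kb flank on each side are collected (a CpG inside several
overlapping genes' neighbourhoods contributes to each of them — inherent
double counting in gene-dense regions such as protocadherin clusters, and
documented as such). Each CpG is centered across samples and the first
principal component of the samples x CpGs submatrix is computed on the
covariance (beta-values share a scale, so no per-CpG standardization); the
profile is the per-sample PC1 score. The PC1 sign is not identifiable, so
the orientation is fixed by requiring non-negative correlation with the
per-sample mean beta over the gene's CpGs — hypermethylated samples get
higher profile values. Single-CpG genes use the centered beta directly;
genes without CpGs are absent; zero-variance neighbourhoods yield a zero
profile with a warning.

**Differential methylation.** Within each subtype, profiles are compared
between DCIS and IBC with a two-sided Mann-Whitney U test, BH-adjusted
across genes within the subtype. The effect size is the absolute
difference of group medians. A gene is called significant when q < 0.05
*and* its effect size lies strictly above the 80th percentile of effect
sizes among the subtype's tested genes — the joint criterion filters
statistically solid but tiny differences. The percentile is recomputed per
analysis rather than frozen to any particular cohort's numeric cutoff.
Subtypes where either group has fewer than 2 samples are skipped with a
notice. The test is exact (full enumeration) when the combined n is at
most 20 and the data are tie-free, otherwise the tie-corrected normal
approximation with continuity correction is used.

**Window score (long-range epigenetic silencing).** Coordinated
hypermethylation across a multi-gene window — e.g. the 800 kb region
spanning the clustered protocadherins on 5q31 — is scored per sample as
the mean of per-CpG standard scores over all window CpGs, z-scored across
all supplied samples (tumors and normals pooled). A Spearman association
between the window score and tumor purity is provided to check that low
scores are not a normal-cell-content artifact.

## Group statistics

Categorical compositions (subtype distribution, ER status) are compared
between tumor types with Fisher-type exact tests: the classical two-sided
2x2 test (sum of hypergeometric probabilities not exceeding the observed
table's), the Freeman-Halton generalisation for 2xK tables enumerated
exactly up to total n = 200, and a seeded Monte-Carlo version (1e5 draws
from the margin-conditional distribution) beyond that, always reported as
such. Continuous features are compared per subtype with the same
Mann-Whitney engine as above. No multiplicity correction is applied across
the handful of stratified feature comparisons; FDR control applies only in
the gene-level differential methylation, where thousands of tests occur.

## Synthetic cohort generator

The generator emulates the statistical structure that every downstream
stage relies on, with defaults chosen once as plausible study conditions:

* **Design:** 4 subtypes x {DCIS, IBC} x 25 samples, plus 10 normal
  tissue samples; purity Uniform(0.3, 0.9) for tumors (recorded but not
  used to mix signals — an association with purity is exactly what the
  window-score check should *not* find).
* **Expression:** 50 synthetic centroid genes; centroids are per-gene
  subtype deviations (standard normal, row-centered), and a sample's value
  is its subtype's centroid value plus Gaussian noise (`centroid_sd`,
  default 0.5 log2 units). ESR1/PGR are drawn from a two-mode mixture
  (means 6 and 10, sd 0.8 log2) tied to ER/PR truth; luminal samples take
  the high mode with probability 0.9, others 0.15. Proliferation genes are
  shifted upward in basal-like/HER2-enriched/luminal-B tumors with an
  extra shift in invasive basal-like; EMT genes up and adhesion genes down
  in invasive tumors.
* **Methylation:** 5000 CpGs with bimodal baseline means (Beta mixtures,
  as on real arrays); per-sample values from a truncated Gaussian around
  the CpG mean (sd 0.05), or optionally a Beta distribution with matched
  mean (concentration 30) — the field provides no canonical generative
  model for beta-values, so both are offered and the clipped-Gaussian is
  the default. 698 window CpGs span an 800 kb window on the synthetic
  chr5; designated samples (invasive basal-like by default) get a +0.3
  beta shift there, clipped to [0, 1]. Ten genes carry a +0.2 planted
  profile shift between basal DCIS and IBC — the plant count is kept below
  the top-20% effect-filter capacity of the tested gene set, mirroring
  real analyses where significant genes are a small fraction of those
  tested. Detection p-values exceed 0.05 for a configured 0.225% of
  entries, plus 0.5% independent missingness.
* **Copy number:** a 100 Mb synthetic genome over four named chromosomes;
  per-sample segments tile it exactly without overlap. Recurrent events
  follow the canonical subtype lesions (5q loss covering the window in
  invasive basal-like, 17q12 gain containing the ERBB2 model in
  HER2-enriched, 16q loss in luminal tumors), and a filler aberration is
  sized so the realized aberrant genome fraction matches the configured
  target per cohort cell (DCIS cells below their invasive counterparts).
* **Truth record:** every planted effect (window samples, differential
  genes, aberrant fractions, ER truth, generating subtypes, signature
  genes) is written to `truth.json`, sufficient to score recovery.

Fixed seed implies byte-identical outputs; all randomness flows from one
`numpy` generator seeded by `config.seed`.

### What the generator does not emulate

Probe-level array chemistry and intensities, the correlation structure of
the real 450K manifest, linkage between CpGs beyond the planted window,
realistic gene density or chromosome arms, batch effects across cohorts,
and purity-driven signal mixing (off by default). Passing tests therefore
demonstrate the correctness and statistical behaviour of the *methods* —
exact test conventions, FDR control, detection power at planted effect
sizes, coordinate arithmetic — not performance on real arrays.

## Numerical choices

* Quantile normalization maps each sample's ranks onto the across-sample
  mean of sorted vectors; tied values receive the mean of the reference
  quantiles across their tied ranks (ties stay tied, idempotent).
* Boundary semantics are strict throughout: positive receptor status is
  strictly above the cutoff; core basal is correlation strictly > 0.6;
  masking at detection p strictly > 0.05; CpG removal at missing fraction
  strictly > 0.25; the effect-size filter is strictly above the 80th
  percentile (`numpy` linear-interpolation quantile), which caps the
  number of passing genes at ceil(0.2 m).
* Spearman uses mid-ranks; a zero-variance vector makes the correlation
  undefined and is an error naming the sample.
* The kNN imputation falls back to the row mean when fewer than one
  eligible neighbour exists, and logs rows with fewer than k.
* PCA uses SVD of the centered submatrix; the orientation rule above makes
  the reported sign unique except in the measure-zero case of exactly zero
  correlation with mean beta, where the positive sign is kept.

## Test and verification scale

The test suite verifies each operation against independent oracles
(enumeration for rank tests and Fisher tables, per-basepair counters for
copy-number summaries, direct eigen-decomposition for profiles, a step-up
construction for FDR) and checks the statistical properties on simulated
data: null FDR behaviour on 100 replicates of 200 genes x 40 samples,
silencing-window detection power on 50 replicates of 10 vs 10 samples at a
planted shift of 0.3, and full-pipeline determinism on a small demo
cohort. These sizes were chosen so the complete suite runs in a few
minutes on one core while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* The package consumes segments, purity and ploidy from upstream tools;
  it does not re-implement segmentation or allele-specific copy-number
  estimation.
* Published centroids, signature memberships and external predictor scores
  (differentiation, immune/stromal infiltration) are inputs, not bundled
  constants.
* Quantile normalization is applied to the pooled cohort with no further
  batch adjustment; cohorts with strong batch structure need upstream
  correction.
* CpGs shared by overlapping genes are intentionally double-counted across
  those genes' profiles, so profile-level results for overlapping gene
  clusters are not independent between genes.
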