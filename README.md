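# dcisibc

Subtype-stratified comparison of ductal carcinoma in situ (DCIS) and
invasive breast cancer (IBC) across gene expression, DNA methylation and
DNA copy number.

## The problem

DCIS is a non-invasive breast lesion with highly variable invasive
potential, and unstratified DCIS-vs-IBC comparisons find surprisingly few
genomic differences because they are confounded by intrinsic subtype
composition. This package implements the analysis machinery needed to make
that comparison *within* each intrinsic subtype (basal-like, HER2-enriched,
luminal A, luminal B):

* **Centroid subtyping with ER-balanced centering.** Each gene is centered
  at `m_g = 0.6·mean(ER+) + 0.4·mean(ER−)` — matching the ~60% ER-positive
  composition of the classifier's training population rather than the
  cohort at hand — and each sample is assigned the subtype whose centroid
  has the highest Spearman correlation with its centered expression
  vector. ER/PR status is called from the bimodal ESR1/PGR expression by a
  two-component Gaussian mixture. *Core basal* tumors are flagged at basal
  correlation > 0.6 (strict).
* **Signature scores.** Per-sample scores as the mean of per-gene standard
  scores over a signed gene list (e.g. an 11-gene proliferation score; an
  EMT score with adhesion genes weighted negatively).
* **Copy-number summaries.** From segmented integer profiles: gene-level
  copy number by maximal segment overlap, the genomic instability index
  `GII = aberrant_bp / covered_bp`, and per-group gain/loss frequencies.
* **Methylation.** 450K-style QC (mask β at detection p > 0.05, drop CpGs
  with > 25% failures, kNN imputation), per-gene methylation profiles as
  the first principal component of the CpGs within the gene ± 50 kb,
  subtype-stratified differential methylation (Mann–Whitney, BH FDR < 0.05
  *and* effect size — |Δ median| — in the top 20%), and a windowed mean-Z
  score for long-range epigenetic silencing such as the hypermethylated
  800 kb protocadherin-cluster window on 5q31.
* **Group statistics.** Exact Fisher / Freeman–Halton tests for subtype
  and receptor-status composition; two-sided Mann–Whitney tests per
  subtype for continuous features; a joined per-sample summary table.

Because the patient cohorts behind such studies are access-restricted, the
package ships a fully specified synthetic multi-omic cohort generator
(`dcisibc.synthetic`) whose planted effects — a hypermethylated window in
invasive basal-like samples, per-gene DCIS/IBC methylation differences,
subtype-specific copy-number events with target aberrant fractions,
bimodal ESR1 — are recorded in a truth file so every downstream method can
be scored for recovery. See `docs/methods.md` for models, parameter
defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (4 subtypes × {DCIS, IBC} × 25 samples + 10 normals),
writing tables under `results/`:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_subtype.py
python analysis/03_signatures.py
python analysis/04_copy_number.py
python analysis/05_methylation.py
python analysis/06_compare.py
```

`02_subtype.py` prints

```
subtype recovery: 100.0%
basal DCIS: median basal correlation 0.859, core basal 25/25
basal IBC: median basal correlation 0.865, core basal 25/25
subtype distribution DCIS vs IBC: p = 1 (freeman-halton)
ER distribution DCIS vs IBC:      p = 1 (fisher-2x2)
```

— every sample recovers its generating subtype, and since the generator
draws DCIS and IBC with identical subtype composition and centroid noise,
the composition tests are null and DCIS/IBC basal correlations coincide
(on real data these diverge; here they verify the machinery).

`05_methylation.py` prints

```
masked 0.223% of beta-values; dropped 0 CpGs; 5000 retained
differentially methylated genes per subtype:
Basal    13
Her2      0
LumA      0
LumB      0
window mean-Z basal DCIS vs IBC: U = 0, p = 1.416e-09
window mean-Z vs purity: rho = 0.026, p = 0.71
```

— the joint FDR + effect-size criterion recovers exactly the planted
basal-specific genes (the 10 planted differential genes plus the 3
protocadherin-cluster genes inside the silencing window) and nothing in
the other subtypes; the window score separates basal DCIS from basal IBC
decisively and shows no purity association. `04_copy_number.py` reports
the planted instability contrast (basal DCIS median GII 0.080 vs basal
IBC 0.350) and the ERBB2 gain in HER2-enriched tumors (median copy
number 4).

The same pipeline is scriptable from a YAML config, either via the
library (`dcisibc.compare.run_pipeline`) or the CLI:

```bash
dcisibc run --config configs/demo.yaml --outdir out/
dcisibc simulate --seed 2 --outdir cohort/   # just the synthetic data
```

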