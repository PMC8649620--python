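# pairedprog

Paired analysis of initial versus recurrent/progressive tumors: what
changes in a patient's cancer when it comes back?

Pediatric brain tumor cohorts often profile both a patient's first-resected
(initial) tumor and one or more later tumors from the same patient, taken
at recurrence (regrowth after treatment) or progression (continued growth).
Because every contrast in this package is *within one patient* —
recurrent-minus-initial — between-patient and between-histology variation
cancels by design, which is what makes a pan-histology analysis of small,
heterogeneous cohorts possible. `pairedprog` implements that paired
analysis end to end, for anyone who wants to run it on their own paired
cohort or to study its statistical behavior on simulated data:

* **Somatic event integration** — per-sample DNA alteration calls from
  MAF-like variant tables (hotspot / inactivating rules by gene role),
  thresholded gene-level copy number (±2 calls on COSMIC genes), and
  structural-variant breakpoints within 1 Mb of a gene start with
  expression deviating >0.4 SD from the cohort median in the gene's
  associated direction; plus per-patient tabulation of events *gained*
  (present in a later tumor, absent initially) and *lost*, with a paired
  t-test on the counts.
* **Moderated paired differential expression** — per gene, the paired
  differences d_g are tested with an empirical-Bayes moderated t:
  the variance of differences s²_g is shrunk toward a cohort-wide prior,
  s̃² = (d₀s₀² + df·s²_g)/(d₀ + df), with (d₀, s₀²) fitted by moment
  matching on log variances, and t = d̄_g / (s̃/√n) referred to a
  t-distribution on d₀ + df degrees of freedom. Chance expectations
  (n·α) contextualize significant-gene counts; a regression with tumor
  purity as covariate checks that purity cannot explain the differences.
* **Enrichment** — classic (unweighted) preranked GSEA with a gene-draw
  permutation null, one-sided hypergeometric overlap tests, and GO-style
  over-representation from GMT collections.
* **Signature survival validation** — a gene signature (significant genes
  split by direction) scores external median-centered profiles with the
  *t-score*: the pooled two-sample t contrasting a profile's values over
  signature-up versus signature-down genes. Scores are tested against
  overall survival by continuous Cox (Newton–Raphson partial likelihood,
  Breslow ties, optional histology stratification) and by tertile
  log-rank (plain and stratified).
* **Consensus subtyping** — pair-centered differential profiles, top
  variable genes, consensus Ward clustering (resampled, 1−Pearson
  distance) over k=2..10, consensus-CDF/delta-area diagnostics and a
  PAC-based automatic choice of k, per-subset marker genes, and subset
  survival comparison.
* **Synthetic cohort generator** — paired cohorts with planted
  differential genes, subset programs, somatic events on an artificial
  genome, and an independent validation cohort whose survival is tied to
  a latent signature score; every planted feature is recorded as ground
  truth for recovery testing.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (55 patients, 62 recurrent/progressive tumors, 2000 genes, seed 1):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_somatic_events.py
python analysis/03_paired_diffexp.py
python analysis/04_enrichment.py
python analysis/05_signature_survival.py
python analysis/06_subtype_clustering.py
```

Selected output (what it means in brackets):

```
41/44 patients have >=1 event gained at recurrence
mean events gained 2.77 vs lost 1.48 per patient (paired t, p=0.000283)
```
[later tumors carry significantly more new DNA events than they lose —
the planted excess gain rate is recovered]

```
2000 genes tested over 62 pairs (prior df d0=184.9, s0^2=2.041)
  p<0.001: 125 significant vs ~2 expected by chance
purity adjustment: 125/125 of the p<0.001 genes keep p<0.01 ...
```
[the planted differential genes far exceed multiple-testing chance, and
tumor purity cannot explain them away]

```
  planted_up         ES=+0.96 NES=+6.09 p=0.000999
  decoy_0            ES=+0.13 NES=+1.04 p=0.38
```
[preranked GSEA separates planted programs from random decoy sets]

```
continuous Cox: HR per SD = 2.52 (p=2.3e-22); stratified HR = 2.48
```
[the signature t-score recovers the simulated hazard ratio of 2 per SD in
an independent 300-tumor validation cohort, also after histology
stratification]

```
no unambiguous k; argmin PAC k=6 ... adjusted Rand index vs planted subsets: 0.692
```
[on the full default cohort — where patients with two later tumors share a
centering reference — consensus structure is honest but imperfect; under
the cleaner recovery conditions (one tumor per patient, see
`tests/test_acceptance.py`) the three planted subsets are recovered with
ARI 1.0 and k chosen 3]

The same pipeline is available as one command (`pairedprog run-all --seed 1
--out results/pipeline`) and stage by stage through the `pairedprog` CLI
(`simulate`, `call-events`, `diffexp`, `enrich`, `overlap`, `score`,
`cluster`).

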