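# Methods

## The paired design

Every expression contrast is recurrent-minus-initial within one patient.
If sample expression decomposes as histology baseline + patient effect +
tumor-specific change + noise, the within-patient difference cancels the
first two terms exactly, so the analysis needs no histology covariates and
tolerates strongly heterogeneous cohorts. A patient contributing several
later tumors contributes one pair per tumor against the same initial
sample; the mild within-patient correlation this induces (the shared
initial sample's noise appears in both difference columns with coefficient
−1, giving sibling columns a correlation of ½ in the pure-noise limit) is
accepted rather than modeled. This matters most for clustering, where
sibling profiles attract each other; see Limitations.

## Somatic event rules

An event is a (sample, gene, type) triple with type one of `snv_hotspot`,
`inactivating`, `amplification`, `deep_deletion`, `sv_altered_expression`.

* SNV/indel: oncogenes only through hotspot residues (the hotspot catalog
  is an annotation input, not recomputed); tumor suppressors through
  hotspots or inactivating classes (nonsense, nonstop, frameshift or
  in-frame indel); silent variants and genes of role `other` never call.
* CNA: thresholded calls in {−2..2}; ±2 on COSMIC-flagged genes call
  amplification / deep deletion; |call| ≤ 1 never calls.
* SV: for genes with a known SV–expression association sign, a breakpoint
  within 1,000,000 bp (unsigned, inclusive, strand-ignorant) of the
  annotated gene start calls an event iff the sample's expression deviates
  from the reference-cohort median by strictly more than 0.4 reference-SD
  in the associated direction. The reference cohort is an explicit
  parameter (here: all simulated samples); genes with zero reference SD
  are ineligible and logged.

Gains and losses are tabulated at the (gene, type) level per patient:
gained = present in ≥1 later tumor and absent initially; lost = present
initially and absent from *all* later tumors (the conservative reading for
multi-tumor patients). The gained-versus-lost comparison is a classical
paired t on per-patient counts; all-zero differences return p = 1, and
zero-variance nonzero differences return the smallest positive double with
a degeneracy flag rather than an unbounded statistic.

## Moderated paired t

Per gene, with n pairs and differences d: s²_g on df = n−1 degrees of
freedom; hierarchical model s²_g|σ²_g ~ σ²_g·χ²_df/df and 1/σ²_g ~
χ²_d0/(d0·s0²). Hyperparameters by moment matching on
e_g = log s²_g − ψ(df/2) + log(df/2): the excess of var(e) over ψ′(df/2)
identifies d0 through the trigamma inverse (solved by bracketed root
finding, which is monotone-safe); s0² = exp(ē + ψ(d0/2) − log(d0/2)).
When the excess is ≤ 0 there is no detectable between-gene variance
spread: d0 = ∞ and the prior variance is the pooled mean of s²_g (the
common-variance estimate; the log-scale back-transform would carry a
χ²-bias factor that contradicts the all-equal-variances limit). Posterior
variance s̃² = (d0·s0² + df·s²_g)/(d0+df); t = d̄/(s̃/√n) on d0+df df
(standard normal at d0 = ∞). d0 = 0 reproduces the ordinary paired t
exactly and is exposed as a fallback. Genes with s² = 0 are handled
through shrinkage (s̃² > 0 whenever s0² > 0). Two-sided p throughout; no
multiple-testing adjustment by default — significant-gene counts are
reported against the chance expectation n·α, with BH q-values as an extra
column for users.

Quantile normalization is sample-wise: every column is mapped onto the
across-sample mean of order statistics, ties receiving midrank-interpolated
values; it is idempotent. The detection filter (median > 0 across samples,
applied on the linear scale before log2(x+1)) is available as
`median_positive_filter`.

The purity adjustment regresses, per gene, expression on a tumor-status
indicator plus purity over stacked rows: initial tumors enter with zeros
for both expression and purity, later tumors with pair-centered expression
and pair-centered purity. The status coefficient's t equals the paired
one-sample t when purity deviations vanish (the residual df is 2n−2, as
the zero rows contribute no residual); a purity column collinear with
status is dropped and flagged.

## Enrichment statistics

The classic (unweighted) enrichment score walks the ranked list,
adding 1/n_hits at members and subtracting 1/(N−n_hits) elsewhere; ES is
the signed extremum of the running sum, evaluated after each position. It
depends only on rank order. The permutation null draws `n_perm` random
same-size gene sets from the ranked universe (gene-label permutation; the
only null available in preranked mode). NES divides ES by the mean |null
ES| of matching sign. The permutation p is the |ES| tail frequency with a
+1 pseudocount over all permutations: because the enrichment direction is
chosen by the data, a same-sign tail without conditioning is ~2×
anti-conservative, while the magnitude tail is calibrated (null sets reach
p < 0.05 at ~5%) and still gives exactly 1/(n_perm+1) for a perfect
prefix set. Sets with fewer than 3 usable members are skipped. Ties in
the ranking statistic are broken by input order.

Overlap significance is the upper-tail hypergeometric P(X ≥ k), identical
to the one-sided Fisher exact test on the 2×2 table; the universe is a
mandatory explicit argument and is never defaulted. GO-style
over-representation applies the same test per term, intersecting each term
with the universe first.

## Signature and survival

The signature is {p < α} split by direction of the paired effect (zero
effects excluded); the headline α is 0.001. External profiles are
median-centered per gene, then scored with the t-score: the pooled
two-sample t contrasting the profile's values on up-genes versus
down-genes, with a variance floor of 1e-8 so an exactly signature-shaped
profile yields a large finite score. Scoring uses the intersection of
signature genes with the profiled genes and logs the coverage; fewer than
two genes on either side yields a missing score. Tertiles partition scored
samples into thirds by rank (sizes differ by ≤1; remainders go to the
lower bins; ties broken by stable sample order).

Survival machinery is implemented directly so its contracts are exact:

* Kaplan–Meier product-limit curves (via lifelines), censoring at an event
  time handled after the events.
* Log-rank: observed−expected event counts and their hypergeometric
  covariance accumulated over event times, χ² on g−1 groups; with strata
  the moments are summed within strata first. Degenerate stratification
  (every stratum one group) raises; no events returns p = 1 with a
  warning.
* Cox: single-covariate Newton–Raphson on the partial likelihood, Breslow
  tie handling by default (Efron behind a flag — the two coincide without
  ties); with strata, risk sets form within stratum. The score test at
  β = 0 is reported and equals the log-rank χ² for a binary covariate
  without ties (verified to 1e-6 in tests; cross-checked against
  lifelines). A diverging β (monotone likelihood / perfect separation)
  raises with diagnostics rather than returning a spurious estimate.

The per-gene outcome scan runs the stratified Cox per signature gene,
records failures without aborting, and flags genes whose hazard direction
matches their signature direction.

## Consensus subtyping

Pair-centered profiles (same operation as the differential-expression
stage, re-exported) are reduced to the top-variable genes by SD (stable
tie order). The analysis's standard selection is the top 2000 of ~16.5k
genes (~12%); on smaller simulated matrices the same *fraction* is used
(240 of 2000), since an absolute count equal to the whole matrix would
disable selection entirely. Consensus clustering: 250 resamples by default
(100 in the recovery tests; the consensus estimates stabilize well below
that), subsampling 80% of samples without replacement, Ward linkage
(Ward.D2 semantics — scipy squares distances internally) on 1 − Pearson
correlation between columns, cut at each k in 2..10;
consensus(i,j) = co-cluster count / co-sample count (never co-sampled
pairs get 0 with a warning). Final labels per k come from Ward clustering
of 1 − consensus, not from any single resample.

Model selection: the per-k consensus CDF area and the delta-area curve
(total area at k_min; relative increase, floored at 0, above) are
computed and reported. The automatic k, however, uses the PAC statistic
(proportion of off-diagonal consensus entries in (0.1, 0.9)): the largest
k with PAC ≤ 0.05, i.e. the finest partition the resampling still
reproduces essentially without ambiguity, with argmin-PAC fallback. The
delta-area elbow was evaluated and rejected for the automatic rule: on
cleanly separated synthetic subsets the delta tail decays slowly (0.03–0.11
through k≈8), so any small fixed threshold over-estimates k, while PAC
identifies the planted k in 10/10 recovery runs. A forced k (as in a
headline analysis that fixes k after inspecting the diagnostics) always
overrides. Subset markers are per-subset unpaired equal-variance t
(subset versus rest) on the centered values, top 200 by descending t;
genes marking several subsets are flagged. Subset survival collapses
tumor-level labels to patients (first tumor's label; disagreements
flagged, not guessed) and applies the multi-group log-rank.

## Synthetic cohorts: what they emulate, and what not

Defaults (all configurable): 55 patients, ~15% with a second later tumor
(→ ~62 pairs), 2000 genes, 6 histologic types with N(0,1) per-gene
baselines, per-patient per-gene random effect N(0,1), planted shift ±1.0
log2 units in 30+30 genes of every later tumor, three 40-gene subset
programs at +2.0 assigned uniformly to later tumors, residual noise
N(0,1). Purity: initial U(0.4,0.9); later tumors shifted +0.05 with SD
0.15, so the paired purity difference is only marginally detectable at
cohort size and purity is not quasi-collinear with tumor status in the
adjustment regression — both properties of the real estimator this column
stands in for. Somatic tables cover a 44-patient subcohort on an
artificial genome (genes 3 Mb apart, so 1 Mb windows are unambiguous; a
planted breakpoint sits at exactly 1,000,000 bp and decoys at 1,000,001 bp
and at zero deviation, exercising both boundaries). Event rates are set so
patients gain ~3.15 and lose ~1.52 events on average; a gene carries at
most one copy-number state per patient. SV events are materialized by
pushing the sample's expression 2 reference-SD from the median in the
associated direction, so callers recover the planted events exactly.
Survival: exponential with baseline hazard 1/1500 per day; the validation
cohort (300 patients) draws a latent score z ~ N(0,1), loads the planted
up/down genes on ±z (closing the loop between signature derivation and
validation), and multiplies the hazard by HR^z with HR = 2 per SD;
censoring is an independent exponential tuned to a 40% censoring
fraction.

What passing recovery tests therefore shows: the estimators recover
effects of the planted form — additive log-scale shifts, label-shaped
programs, proportional hazards — at realistic sizes and noise. What they
do not show: robustness to heavy-tailed counts, batch effects, mutational
signature structure, copy-number segmentation artifacts, informative
censoring, or misannotated pairings, none of which the generator emulates.

## Numerical choices and degenerate inputs

Trigamma inverse by brentq on [1e-8, 1e8]; p-values floored at the
smallest positive double; BH via scipy. Paired-count and t-score
degeneracies return flagged sentinels (see above). Cox Newton stops at
|Δβ| < 1e-9 within 50 iterations, raising on non-convergence.
Consensus CDF areas use a 100-bin empirical CDF. All stages are
deterministic given their seeds; the pipeline derives stage seeds from
the run seed by fixed offsets.

Problem sizes in the tests and acceptance script (2000 genes, 40–60
patients, 300 validation tumors, 100–250 resamples, 200–1000
permutations) are the package's simulation defaults, chosen to match the
cohort scale the design targets while keeping full runs fast.

## Known limitations

* Within-patient correlation between sibling pairs is unmodeled; on the
  default cohort (with second tumors) consensus clustering sees sibling
  attraction and its automatic k is honest but unstable (PAC ≈ 0.15,
  ARI ≈ 0.7 against planted subsets), while one-tumor-per-patient designs
  recover subsets cleanly.
* The log-rank power for a 3× hazard subset among three subsets of ~20
  patients is ~70% at 40% censoring (100% with fully observed survival);
  recovery tests therefore isolate the detection property at censoring 0.
* The SV caller matches events at the gene level; breakpoint identity
  across tumors is not compared.
* The Cox implementation is single-covariate (plus strata) by design;
  multivariable adjustment is out of scope.
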