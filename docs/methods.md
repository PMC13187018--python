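# Methods

## Exact single-arm statistics

Responses are tabulated over the RECIST best-response categories; patients
with no assessment (NE) stay in the denominator but in neither the
objective-response (CR+PR) nor disease-control (CR+PR+SD) numerator, so
reported rates are intention-to-treat. The Clopper–Pearson interval is the
exact beta-quantile form: lower = `Beta(α/2; x, n−x+1)` (0 when x = 0),
upper = `Beta(1−α/2; x+1, n−x)` (1 when x = n). Percentages are rendered
with round-half-away-from-zero, the convention of clinical tables (Python's
builtin banker's rounding would round 65.45 to 65.4).

The A'Hern design is computed by scanning r = 0…n for the smallest r with
exact binomial tail `P(X ≥ r | n, p0) ≤ α` — no normal approximation. An
infeasible design (no r ≤ n controls α) is signalled by the sentinel
r = n + 1. Exact power is the same tail under p1. The threshold is computed
directly at the analysed n; for n = 73, p0 = 0.66, α = 0.05 this gives
r = 56 (tail 0.0324; 0.0565 at r = 55) with exact power 0.804 at p1 = 0.80,
so the printed design pair is self-consistent under exact computation.

## Survival

Kaplan–Meier estimation and the two-group log-rank (Mantel–Cox) statistic
are implemented directly so the curve object carries at-risk/event counts
per time and the test result carries per-group observed and expected
events; both are cross-checked against lifelines in the test suite
(exhaustively over all event/censor patterns on ≤ 6 subjects). Conventions,
fixed because source descriptions of such analyses rarely state them:

- ties of events and censorings at one time are resolved events-first
  (censored subjects at t remain in the risk set at t);
- the median is the smallest *event* time with S(t) ≤ 0.5 (boundary
  inclusive), `NOT_REACHED` (∞) if none;
- a log-rank comparison whose hypergeometric variance sums to zero (no
  events, or a single shared time) is degenerate: χ² = 0, p = 1, flagged;
- no continuity correction.

Median confidence intervals (Brookmeyer–Crowley) are not implemented: no
downstream decision in this pipeline consumes them.

## Quartile signatures

The profiled-MSS subcohort is ranked by observed PFS regardless of
censoring status, with ties broken by (event before censored, then patient
id) so the partition is deterministic. Q1 and Q4 take ⌊n/4⌋ patients each;
the middle splits into Q2/Q3 with the remainder patient in Q2 — for n = 49
this yields 12/13/12/12. Subcohorts under 8 patients are refused.

RES = genes altered (any class — SNV, indel, CNV, LOH are collapsed; no
allele-fraction weighting) in ≥ 1 Q1 patient and 0 Q4 patients; SENS is the
mirror. The sets are disjoint by construction. Carrier status is ≥ 1
alteration in ≥ 1 signature gene. Held-out evaluation removes
derivation-quartile patients from the **carrier arm only** (the non-carrier
arm is untouched): every Q4 patient is RES-negative by construction (a
Q4 carrier's gene cannot enter RES), so the negative arm always contains
the best-PFS quartile and even the held-out comparison remains optimistic
under the null — this structural circularity is demonstrated, not hidden,
by the test suite (null-median derivation p ≪ 0.5; held-out p distribution
closer to uniform; a-priori carrier groups calibrate at the nominal 5%).

TMB is dichotomised at 10.4 mutations/Mb, boundary inclusive (≥ cutoff is
high). Pathway stratification labels a patient MUT on ≥ 1 alteration in
≥ 1 pathway gene and reports the MUT/WT log-rank plus the 2×2
pathway-by-TMB-class Fisher exact test (two-sided; degenerate margins give
p = 1, flagged).

## Expression processing

Filtering removes all-zero genes and genes with fewer than 20 counts; the
threshold applies to the total across samples by default
(`total_across_samples`), with `max_in_any_sample` available — the rule is
strictly "< threshold", so exactly 20 counts is retained.

TMM factors follow the trimmed-mean-of-M-values recipe: reference = sample
whose upper-quartile count fraction is closest to the mean; per sample, the
gene-wise log2 ratio M (after library-size scaling) is trimmed 30% on M
and 5% on average log-abundance A, and the survivors are averaged with
inverse delta-method binomial variance weights; factors are rescaled to
geometric mean 1. Agreement with the Bioconductor reference implementation
is ~1e-6 on test fixtures. Normalized expression is
`log2(count·10⁶/(library·factor) + 1)`.

PCA operates on gene-wise mean-centred log expression with a fixed sign
convention (largest-magnitude loading positive) for run-to-run determinism.

Differential expression uses a pooled-variance (Student) two-sample t-test
per gene on normalized values — not Welch, matching the two-group default
of the GUI workflows these analyses typically come from — with fold change
taken on linear-scale (2^v) group means under the signed ±1/ratio
convention. Selection requires |FC| strictly above the threshold (default
2.5) and p ≤ the working threshold (default 0.0128, applied unadjusted).
Zero-variance genes with equal means get p = 1.

## Nearest-template prediction

A subtype template is a ±1 signed vector over marker genes. `one_vs_rest`
takes each class's own up/down rows; `pairwise_icms` (two classes) admits a
gene as a +1 marker of class A only if it is up in A and not up in B
(opposite or absent), excluding same-direction genes — the construction
used for intrinsic epithelial subtype pairs.

Similarity is, by default, the Pearson correlation between the sample's
expression over the template genes and the signed template. This makes the
score invariant to any affine rescaling of a sample's expression, which is
the standardization contract the classifier needs; a cosine option (scale-
but not shift-invariant) is provided. The permutation null draws random
gene subsets of template size from the measured gene universe
(`n_permutations` default 1000, minimum 100), p = fraction of draws
reaching the observed similarity with a 1/(n+1) floor to avoid zero p
before adjustment. BH runs across samples (the unclassified rule is per
sample); FDR ≥ 0.05 ⇒ UNCLASSIFIED. Per-sample permutation streams are
keyed by a stable hash of the sample id, so sample order is irrelevant and
results are reproducible from the seed. The exact permutation scheme of
external NTP implementations is not published; these choices are this
package's own, documented alternatives.

## Enrichment

One-sided hypergeometric tail P(overlap ≥ observed) per gene set, sets
intersected with the universe first; BH step-up across tested sets. The
default universe is the measured (post-filter) gene list, not the genome —
configurable, since enrichment p-values are only meaningful relative to a
stated universe.

## Synthetic cohort generator

The generator emulates the cohort structure this analysis assumes, not any
particular patient data. Defaults (one decision each, with units):

| parameter | default | rationale |
|---|---|---|
| n_patients / MSI count | 55 / 6 (deterministic rounding) | targeted-panel cohort size for a ~73-patient trial with ~80% profiling success |
| gene_universe | 336 genes | panel-scale alteration universe |
| background rate | 17.85/336 per gene-patient (mean) | ≈ 18 alterations per patient |
| per-gene rate spread | log-normal, log-sd 1.5 | panels show a long-tailed frequency spectrum (few recurrent drivers, many rare genes); uniform rates would make every patient a signature carrier and collapse the carrier-negative arm |
| planted genes | 5 resistance (HR 3) + 5 sensitivity (HR 1/3), marginal prevalence 0.15 | HR 3 concentrates carriers in the worst quartile at ≈ 0.3 prevalence |
| baseline hazard | ln2/10 events/month | median PFS ≈ 10 months |
| censoring | admin at 24 months + exponential dropout 0.01/month | ~2-year follow-up |
| TMB | log-normal, median 6.71 mut/Mb, log-sd 0.7 | straddles the 10.4 cut-off with a realistic range (~1–35) |
| expression | NB, dispersion 0.3, 500 genes, libraries 50–150k | FFPE-targeted-RNA scale, reduced for speed |
| subtype/DEG effects | ±2 log2 units on 40 markers/class and 50 planted DEGs | recoverable but not trivial effects |

PFS is exponential with per-patient hazard = baseline × MSI modifier (0.5)
× the product of carried planted-gene hazard ratios; exponential rather
than Weibull because every consumer uses only ranks, medians and log-rank
statistics. Draws flow from named sub-streams of a single seed (stage name
hashed into the seed sequence), so adding a stage never perturbs another
stage's draws and identical seeds give field-identical cohorts.

What the generator does **not** emulate: co-occurrence/mutual-exclusivity
structure between driver genes, copy-number segment geometry, tumor purity,
batch effects in expression, non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate correctness of the
*machinery* and recoverability of planted effects under a clean model —
not clinical validity on real cohorts.

## Problem sizes and determinism

Monte-Carlo checks use 200 cohort replicates (signature recovery, null
calibration), 500 replicates for log-rank type-I error, and 10×5 seeded
noise samples for NTP, with a 120-gene expression block in simulated
cohorts; the full suite runs in well under a minute on one core. The
pipeline is a pure function of (inputs, config, seed): tabular outputs are
rendered at fixed precision and re-runs are byte-identical.

## Known limitations

- Signature derivation is presence/absence only; no recurrence threshold
  (≥ 1 carrier suffices) and no multivariable adjustment.
- The held-out evaluation reduces but cannot remove derivation circularity
  (see above); external validation is the only full cure.
- NTP calls depend on the supplied marker tables; no marker lists ship with
  the package beyond synthetic test fixtures.
- Cox modelling, median CIs, two-stage designs, and network/GO-graph
  enrichment are out of scope.
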