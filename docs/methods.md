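# Methods

`neoresponse` implements the downstream statistics used to link paired
pre-/post-treatment tumor multi-omics to pathological response after
neoadjuvant immunotherapy in gastric cancer, together with a synthetic
cohort generator so that every stage runs and is tested without
controlled-access patient data. This note records the models, the
parameter choices, and the places where a genuinely open design decision
had to be made.

## Pathological response model

Response is graded from the percentage of residual viable tumor cells in
the resected tumor bed. The nested endpoints are CPR (0%), MPR (≤ 10%),
PPR+ (≤ 30%) and PPR (≤ 50%); the Becker TRG grades are TRG1a (0%),
TRG1b (< 10%), TRG2 (10–50%) and TRG3 (≥ 50%). The definitions are
asymmetric at exactly 10% residual tumor: "no more than 10%" makes such a
case MPR, while TRG1b's strict "< 10%" pushes it to TRG2. We follow the
letter of both definitions rather than forcing agreement; consequently
`count(TRG1a) + count(TRG1b) == count(MPR)` holds exactly unless a case
sits on the 10% boundary, and the test suite asserts exactly that
conditional identity. The TRG2 interval is taken half-open, [10, 50).

Cohort rates carry exact Clopper–Pearson intervals (beta-quantile form,
via `statsmodels`). The exact method is conservative: simulated coverage
at p = 0.3, n = 19 is above the nominal 95%, which a test verifies. One
printed reference interval for 8/19 differs from the exact beta-quantile
value in its lower bound (20.0 vs 20.25 → 20.3 at one decimal); the
package reports the exact value, which R's `binom.test` independently
confirms.

## Purity-corrected mutation dynamics

Observed VAF scales with tumor purity, so raw pre/post VAF comparisons
confound tumor kill with biopsy composition. The default correction is

    adj_vaf = min(1, vaf / purity)

the simplest monotone correction that is the identity in a pure sample. A
cancer-cell-fraction variant for a copy-neutral heterozygous diploid locus
(`2·vaf/purity`, `ccf=True`) is provided; every fate class below depends
only on the *sign* of the adjusted change, which is invariant to the
constant factor, so the choice does not affect fate calls.

Mutations are keyed by `chrom:pos:ref:alt` (1-based), never by gene, so
multiple mutations per gene stay distinct. Fates: `gain` (absent pre),
`lost` (absent post), otherwise `increase` / `decrease` / `stable` by the
sign of the adjusted-VAF change against a tie tolerance (default 0 —
sequencing noise makes exact ties measure-zero, but integer synthetic
counts can tie, so the tolerance is exposed). The lost fraction uses the
pre-treatment mutation count as its denominator,
`lost / (lost + increase + decrease + stable)`; it is reported as
undefined (an error, never a silent 0) when no pre-treatment mutation
survives the filters.

Call filters retain `vaf ≥ 0.02` (boundary inclusive, mirroring removal
of sub-2% calls), with optional depth and alt-read floors. Whether fates
are computed on filtered or unfiltered calls is configurable by simply
passing either table; the pipeline default is filtered.

TMB is nonsynonymous calls per megabase, TNB neoantigen-flagged calls per
megabase, over an exome footprint parameter defaulting to 35 Mb (a typical
whole-exome capture size; the footprint is never hard-coded).

The purity-balancing dilution is a desk-scale abstraction of blending
tumor reads with matched-normal reads: with mixing fraction
`m = 1 − target_purity / purity`, each call's alt count is redrawn
`Binomial(depth, vaf·(1−m))` with depth preserved, filters re-applied and
burden recomputed. `m = 0` is an exact identity (no resampling), the
deep-sequencing limit realizes `vaf·(1−m)`, and expected filtered TMB is
non-increasing in `m`; all three are asserted in tests. Selecting which
pairs to dilute (purity ratio > 1.5 by default) is left to the caller/CLI
flag.

The subclone-consistency check compares the sign of a mutation's
adjusted-VAF change with the sign of its cluster's cellular-prevalence
change, with absence coded as zero and zero-vs-zero consistent — so a
lost mutation in an eradicated subclone counts as consistent. Cluster
inference itself (Dirichlet-process clustering etc.) is out of scope;
cluster assignments are inputs.

Biomarker screens use the two-sided Fisher exact test on 2×2 tables of
mutation × response flags. No multiplicity correction is applied anywhere
in the package — the analyses are exploratory and every output carries an
explicit `p_adjusted: False` flag or report caveat instead.

## TCR repertoire statistics

Clonotypes are keyed by (CDR3 amino-acid sequence, V segment, J segment).
Normalization recomputes frequencies as `count/total`, drops zero-count
rows, and sorts by descending frequency with a lexicographic tie-break so
that "top-k" is deterministic.

The clone-expansion (CE) score is the summed pre→post frequency change of
the top-20 clonotypes. Two readings of "top 20" exist; the default
`pooled` mode ranks by the mean of pre and post frequency and sums the
change over that one shared set, because a score over a fixed set is
antisymmetric (swapping pre and post negates it) and bounded in [−1, 1] —
both properties are property-tested. The literal `per-sample` mode (sum
of post's own top-20 frequencies minus pre's) is provided for sensitivity
analysis. Frequencies, not raw counts, are used throughout.

Size classes partition frequencies as small ≤ 1e-4 < medium ≤ 1e-3 <
large ≤ 1e-2 < hyperexpanded ≤ 1. The conventional class bounds overlap
("large" is sometimes quoted up to 0.1 while "hyperexpanded" starts at
0.01); we resolve large = (0.001, 0.01] so the four classes are a true
partition.

Diversity: richness (distinct clonotypes), Shannon entropy in nats,
Pielou evenness `H / ln(richness)` (defined 0 for a single clone), and
D50 — the smallest number of top clonotypes whose cumulative frequency
reaches 0.5 — reported both as a count and as % of richness, since both
conventions are in circulation. V/J usage sums clonotype frequency per
segment; repertoire overlap counts shared keys.

## Expression signatures

A signature score is the unweighted mean of `log2(TPM + 1)` over a gene
set's genes — a transparent stand-in for weighted published scores, with
a `weights` hook for users who have the weights. The shipped sets
(cytolytic, IFN-γ response, T-cell exhaustion, CD8 effector) are short
curated marker lists, editable via YAML, and are defaults rather than an
authoritative panel. Group contrasts use the two-sided Wilcoxon rank-sum
test (unpaired) or signed-rank test (paired, exact null when feasible),
reporting the median difference and an unadjusted p.

## Spearman correlations

Correlations of lost fraction or CE score with % regression use Spearman
rank correlation with mid-ranks. For n ≤ 8 the two-sided p is computed
exactly by enumerating all n! rank permutations; larger n uses the
t-approximation. Constant input vectors raise instead of yielding NaN.

## Synthetic cohort generator

The generator is first-class, tested code. What it emulates, per layer:

* **Pathology** — % regression ~ 100·Beta(a, b), with defaults
  Beta(8, 2) for responders (mean 80%) and Beta(2, 5) for non-responders
  (mean ≈ 29%), consistent with a cohort whose median regression is ~40%
  with wide quartiles. `frac_responders` defaults to 0.4 (≈ the PPR+
  fraction of a small evaluable cohort).
* **Mutations** — each tumor has `n_subclones` (default 4) clusters: one
  truncal at prevalence 1 plus subclones at Uniform(0.2, 0.9), each with
  `muts_per_clone` (default 25) mutations. Under a copy-neutral
  heterozygous diploid model the true VAF is `prevalence × purity / 2`;
  alt reads are Binomial at Poisson depths (mean 200). Therapy eradicates
  each subclone independently with probability 0.6 (responders) vs 0.15
  (non-responders) — eradication is the generative mechanism for "lost"
  mutations, the only quantitative anchor available; surviving subclones
  get a mild log-normal prevalence jitter (σ = 0.3). Purity is
  Uniform(0.4, 0.8) pre and Uniform(0.2, 0.6) post, reflecting the purity
  drop expected after effective therapy. 75% of mutations are flagged
  nonsynonymous and 15% of those neoantigenic, so TNB ≤ TMB by
  construction.
* **TCR** — pre-treatment clonotype counts follow a Zipf law
  (exponent 1.0 over 3 000 clonotypes, ≈ 10⁶ reads), which occupies all
  four size classes. Post-treatment counts equal pre counts with the
  top-20 clones multiplied by an expansion factor, then renormalized:
  2.0 for responders, 0.9 for non-responders. The mild contraction
  (rather than exactly 1) reflects that dominant-clone frequencies drift
  down when other clones expand, and gives non-responders strictly
  negative CE scores — the qualitative pattern the score is meant to
  capture; a factor of exactly 1 would make their CE identically 0 and
  its sign undefined.
* **Expression** — values are generated in `log2(TPM+1)` space, Gaussian
  (σ = 0.5) around per-gene baselines; signature genes sit at baseline 5
  so the additive responder-post shift (default +1 log2) never clips at
  zero, making the planted effect exactly recoverable by the scorer.

Determinism: one config seed; each patient × stage gets an independent
substream via `SeedSequence([seed, crc32(patient), crc32(stage)])`, so any
subset of patients or omics layers reproduces byte-identically — the
`include=` argument of `generate_cohort` exploits this to generate single
layers cheaply, and a test pins the equality.

What the generator does **not** emulate: copy-number variation and
non-diploid loci, caller-specific artifacts, clonal phylogenies
(clusters are independent), shared public TCR clonotypes across patients,
batch effects or library-size variation in expression, and any coupling
between omics layers beyond the responder label. Passing tests therefore
show that the statistics recover planted structure under this idealized
model, not that they are robust to real-data artifacts.

## Problem sizes used in checks

Recovery checks run 100 generator seeds for the CE-score sign test
(default 19-patient cohorts) and 100 seeds of 100-patient cohorts for the
lost-fraction correlation; the acceptance script uses 25 seeds for each,
sizes chosen to make Monte-Carlo error small relative to the planted
effects while keeping a laptop run short. Dilution monotonicity averages
200 seeds per mixing fraction on a 300-mutation sample.

## Known limitations

* The purity correction has no copy-number awareness; in CNA-dense tumors
  adjusted VAFs are biased, though fate signs are less sensitive.
* The CE score depends on k (default 20) and on the top-set convention;
  both are exposed, and the two conventions disagree on asymmetric
  repertoires.
* Signature scoring is an unweighted mean; it will not reproduce weighted
  published scores numerically, only directionally.
* Eradication probabilities per response group are a two-point law; real
  subclone dynamics are continuous and history-dependent.
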