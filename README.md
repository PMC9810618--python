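# neoresponse

Analysis toolkit for paired pre-/post-treatment multi-omics in neoadjuvant
immunotherapy cohorts (built around the gastric-cancer setting), for
translational researchers who have tabular outputs of an upstream calling
pipeline — somatic mutation tables, tumor purity estimates, pathology
review percentages, TCR clonotype tables, a TPM matrix — and want the
downstream response statistics computed reproducibly:

* **Pathological response** — CPR / MPR / PPR+ / PPR and Becker TRG1a–3
  grades from % residual viable tumor, with exact Clopper–Pearson
  binomial confidence intervals on cohort rates.
* **Mutation dynamics** — purity-corrected VAF
  (`adj = min(1, vaf/purity)`), per-mutation fate classes
  (gain / lost / increase / decrease / stable), the lost-mutation
  fraction and its Spearman correlation with pathological regression,
  TMB/TNB per megabase, a read-dilution simulation that balances purity
  between paired samples before comparing burdens, subclone-consistency
  checks and Fisher-exact biomarker tables.
* **TCR repertoire** — clone-expansion score
  (CE = Σ top-20 (f_post − f_pre)), frequency size classes
  (small / medium / large / hyperexpanded), richness, Shannon entropy,
  Pielou evenness, D50, V/J usage and pairwise repertoire overlap.
* **Immune signatures** — mean log2(TPM+1) gene-set scores with Wilcoxon
  rank-sum / signed-rank group contrasts.
* **Synthetic cohorts** — a seeded generator producing paired mutation
  tables from subclone prevalences with binomial read sampling, Zipf TCR
  repertoires with responder-specific top-clone expansion, and expression
  matrices with planted signature shifts, so the full pipeline runs
  without access-restricted patient data.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Generate a synthetic 19-patient cohort and run the full pipeline:

```sh
neoresponse simulate --out cohort --seed 11
neoresponse report --in cohort --out results --seed 11
```

`results/report.md` then contains (actual output for seed 11):

```
endpoint  k  n  rate_pct  ci_low_pct  ci_high_pct  conf
     CPR  0 19    0.0000      0.0000      17.6467  0.95
     MPR  2 19   10.5263      1.3012      33.1377  0.95
    PPR+  7 19   36.8421     16.2886      61.6422  0.95
...
- Spearman rho(lost fraction, regression) = 0.5554 (p = 0.0136)
...
- positive CE scores: 8/19
- Spearman rho(CE score, regression) = 0.8563 (p = 2.89e-06)
```

Reading: 2 of the 19 synthetic patients reached major pathological
response (10.5%, exact 95% CI 1.3–33.1%); the fraction of pre-treatment
mutations eradicated by therapy correlates positively with pathological
regression (rho 0.56), and the clone-expansion score of the peripheral
TCR repertoire tracks regression strongly (rho 0.86) — the structure the
generator plants and the analysis is designed to recover. Per-stage
tables (`response_rates.tsv`, `fates.tsv`, `burden.tsv`, `ce_scores.tsv`,
`tcr_metrics.tsv`, `overlap_matrix.tsv`, `signature_scores.tsv`,
`signature_contrasts.tsv`) are written next to the report.

The same functionality is available as a library:

```python
from neoresponse import clopper_pearson_ci, classify_response

clopper_pearson_ci(3, 19)        # (3.38..., 39.57...) — 15.8%, CI 3.4–39.6%
classify_response(8.0).is_mpr    # True ("no more than 10% viable tumor")
```

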