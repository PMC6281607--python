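# rvburden

Gene-level rare-variant collapsing burden analysis for case–control exome
studies, with a full QC cascade, consensus damage classification, exact
carrier tests, and a consistency check against an aggregated external
reference population.

## The problem and the method

Rare coding variants of moderate-to-large effect are individually too rare
to test one by one in a small cohort. The collapsing (burden) strategy
aggregates them: within each gene, a subject is a **carrier** if it holds at
least one qualifying rare alternate allele, and the carrier proportions of
cases and controls are compared with a two-sided Fisher exact test on the
2×2 table

```
              carriers   non-carriers
    cases         a           b          (a + b = n_cases)
    controls      c           d          (c + d = n_controls)
```

Qualifying variants are rare (cohort minor allele frequency < 1%) and
predicted damaging. Damage is assigned by consensus: protein-truncating
variants (PTV: nonsense, frameshift, canonical splice-site with a
loss-of-function annotation) plus missense variants graded Mis3/Mis2/Mis1 by
how many of three in-silico predictors call them damaging. Tests run on four
**embedded classes** — PTV ⊂ PTV+Mis3 ⊂ PTV+Mis3+Mis2 ⊂ PTV+Mis3+Mis2+Mis1 —
so carrier counts are non-decreasing across classes. Significance is judged
against the exome-wide Bonferroni threshold 0.05/20,000 = 2.5×10⁻⁶, with
Benjamini–Hochberg FDR alongside.

Because large reference exome aggregations publish allele counts rather than
genotypes, the reference carrier proportion per gene × class is approximated
by **TAC/ANmax** (total aggregated allele count over the maximum number of
individuals with allele information). Two further Fisher tests — cases vs
reference and controls vs reference — yield a per-gene robustness verdict
(`reinforced`, `questionable`, `potential_false_positive`,
`not_analyzable`): a gene whose controls look depleted relative to the
reference may owe its signal to poor variant detection in the control
series, not to disease.

Upstream of the tests, a fixed QC cascade masks genotypes with depth ≤ 6 or
quality ≤ 20, drops samples with > 15% missingness or pairwise relatedness
π̂ > 0.15 (method-of-moments IBD), and excludes variants in low-complexity /
tandem-repeat masks, with > 5% missingness, failing an exact
Hardy–Weinberg test in controls (p < 10⁻⁶), with case/control differential
missingness (p < 10⁻⁶), or with skewed mean allele balance.

## Worked example

`examples/02_published_tables_reproduction.py` recomputes the headline
statistics of the motivating bipolar-disorder exome study (92 cases, 1051
controls) from its embedded carrier tables:

```
gene      class                cases ctrls     OR           95% CI         p
CCDC171   PTV+Mis3+Mis2+Mis1      11    31    4.5        (1.9-9.5)   2.7e-04
FAM19A3   PTV+Mis3+Mis2+Mis1       5     4   15.0       (3.2-76.8)   3.0e-04
BOC       PTV+Mis3+Mis2+Mis1      10    26    4.8       (2.0-10.7)   3.1e-04
ACPP      PTV+Mis3                 3     0    inf        (4.8-inf)   5.1e-04
...
```

Each row is a gene's carrier counts, the cross-product odds ratio with the
exact conditional 95% CI, and the two-sided Fisher exact p. No gene reaches
the exome-wide threshold of 2.5×10⁻⁶ — these are candidate risk genes, not
confirmed associations. The other examples simulate a cohort end to end
(`01_burden_scan_on_simulated_cohort.py`) and run the reference consistency
check with its robustness verdicts (`03_reference_consistency_check.py`).

The same analyses are available from the shell:

```
rvburden simulate --config sim.yaml --outdir cohort/
rvburden run-all --config pipeline.yaml
rvburden qc|classify|burden|refcompare ...   # single stages, file-to-file
```

## Library layout

| module | role |
| --- | --- |
| `rvburden.variant_io` | VCF/BED/TSV boundary, multi-allelic splitting, indel left-alignment |
| `rvburden.qc_filters` | genotype/variant/sample QC cascade with audit report |
| `rvburden.variant_classify` | PTV/Mis3/Mis2/Mis1/benign consensus classes, cohort MAF, embedded classes |
| `rvburden.burden_test` | Fisher exact kernel, odds ratios with exact conditional CIs, per-gene scan, Bonferroni/FDR |
| `rvburden.reference_compare` | TAC/ANmax aggregation, dual reference tests, robustness verdicts |
| `rvburden.synthetic_cohort` | cohort/reference generator with ground truth; embedded published-table fixtures |
| `rvburden.pipeline_cli` / `rvburden.cli` | end-to-end orchestration and the `rvburden` command |

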