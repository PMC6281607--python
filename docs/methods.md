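# Methods

## Model and procedure

The package implements a gene-level rare-variant collapsing burden analysis
for a case–control exome design, plus the surrounding machinery (QC,
classification, reference comparison) needed to run it end to end on
standard files.

For each gene g and embedded variant class k, the qualifying set is the
gene's variants that are (i) rare in the combined post-QC cohort (minor
allele frequency strictly below 1%, denominator = 2 × non-missing
genotypes, folded to the minor allele) and (ii) members of class k under
the nesting PTV ⊂ PTV+Mis3 ⊂ PTV+Mis3+Mis2 ⊂ PTV+Mis3+Mis2+Mis1. A sample
is a carrier if it has dosage ≥ 1 at ≥ 1 qualifying site; multiple
qualifying variants in one sample count once. Carrier counts against the
full phenotype-group sizes form the 2×2 table tested by the exact kernel.

### Exact test conventions

- **Two-sided Fisher p**: minimum-likelihood convention — the sum of
  hypergeometric probabilities of all tables (margins fixed) whose
  probability does not exceed the observed table's probability times
  1 + 1e-7. This is the convention of R's `fisher.test`, and it is what the
  motivating study's printed p values follow. The relative tolerance
  absorbs floating-point ties exactly as R does.
- **Odds ratio**: the cross-product (a·d)/(b·c) is the primary estimate
  (+∞ when controls have no carriers but cases do; NA when neither group
  has carriers). The conditional maximum-likelihood estimate (the
  noncentral hypergeometric MLE that `fisher.test` reports) is computed
  alongside in `or_cmle`; the two published ORs that the cross-product does
  not reproduce to printed rounding are reproduced by the CMLE.
- **95% CI**: inversion of the two one-sided exact conditional tests at
  2.5% each, solved by bisection on log ψ over the noncentral
  hypergeometric CDF/SF. Bounds at the support edges are 0 / ∞. These
  bounds agree with direct rational-arithmetic inversion to < 1e-4
  relative error; note R's printed upper bounds can differ by ~0.5% on
  extreme tables (e.g. 263.9 vs the exact 265.1) due to its internal
  approximation — the exact inversion is kept.
- **Hardy–Weinberg exact test**: conditional on observed allele counts,
  enumerating heterozygote counts of matching parity with weights
  2^het · n!/(n_AA! n_Aa! n_aa!); p sums configurations no more likely than
  the observed one (relative tie tolerance 1e-12). Computed in log-space
  via `gammaln` for numerical range.
- **FDR**: Benjamini–Hochberg step-up via statsmodels, applied across
  genes *within* each embedded class by default — the four classes are
  nested and strongly correlated, so pooling them in one FDR run would mix
  four copies of nearly the same test. Configurable.
- **Bonferroni**: threshold α / n_genes with n_genes defaulting to 20,000
  (the approximate number of protein-coding genes), giving 2.5e-6 at
  α = 0.05.

### Classification

PTV status follows the upstream loss-of-function annotation when present;
without it, nonsense / frameshift / canonical splice terms are accepted
unless flagged terminal-exon (unknown terminal-exon status is treated as
non-terminal with a warning — the aggressive reading, flagged because the
conservative LOF definition depends on gene position information this
package does not recompute). Missense variants are graded by the count of
"damaging" verdicts among the three predictors; missing verdicts are not
counted as damaging, so (damaging, missing, missing) is Mis1. The
alternative — excluding any variant with a missing verdict — is available
via `exclude_missing_predictors`. Non-missense, non-PTV coding terms are
benign; unknown terms are unclassified and never qualify. Variants
annotated to several genes count once per gene (gene-level tests are
marginal).

### QC cascade

Fixed order, so each statistic sees the cohort that survives the previous
step: genotype masking (retain DP > 6 and GQ > 20; failing either sets the
call missing; calls lacking the subfield are retained) → sample
missingness (> 15% dropped) → relatedness → region masks → variant
missingness (> 5%) → HWE in controls (p < 1e-6) → differential
missingness (Fisher, p < 1e-6) → mean allele balance (het mean outside
[25%, 75%] or hom mean < 90%; categories without usable AD impose no
constraint; zero-depth calls are skipped). Genotype masking must precede
missingness statistics; sample drops precede variant statistics so
frequencies reflect the final cohort. HWE is restricted to controls and
thresholded at 1e-6 (mirroring the differential-missingness threshold)
because testing in cases could delete true association signals; both
choices are configurable. An optional VQSLOD pass-through cut exists but is
off by default — tranche-style recalibration needs the upstream model and
is out of scope.

Relatedness uses the method-of-moments IBD estimator from identity-by-state
counts and within-cohort allele frequencies at sites with MAF ≥ 1%:
P(IBD=0) from opposite-homozygote counts, P(IBD=1) and P(IBD=2) by
successive moment matching, clamped to [0,1] and renormalized (the standard
small-sample correction), π̂ = P(IBD=1)/2 + P(IBD=2). Pairs with π̂ > 0.15
lose the member with higher missingness (tie → later sample-sheet order).
With fewer than 50 informative sites the step is skipped with a warning —
rare-variant-only cohorts carry no IBD information, and this also bounds
the O(n²) pair loop to cohorts that genuinely have common sites.

### Variant canonicalization

Multi-allelic records split into one bi-allelic record per alternate
allele; a sample's dosage for allele k is the count of k in its genotype,
so the split conserves per-sample alternate-allele totals, and genotypes
with any missing allele are fully missing (conservative, matching carrier
semantics). Indels are left-aligned against a reference window: shared
suffix trimmed, pure indels shifted left while sequence-equivalent, then
shared prefix trimmed, keeping ≥ 1 base per allele. The operation is
idempotent and verified in tests by applying both edits to the window and
comparing the resulting sequences.

### Reference comparison

Sitewise reference exports are filtered (reference MAF < 1%, missingness
< 20% where the export's maximal AN is known) and aggregated per gene ×
class with embedding: TAC = Σ allele counts, ANmax = max(AN)/2 rounded
down. TAC itself serves as the reference carrier count in the 2×2
(carriers, n − carriers; TAC, ANmax − TAC) — valid while double carriers
are rare, which the < 1% rarity filter enforces. The per-gene verdict
pools the control-side test over all four classes: control excess at
p < 1e-3 → `not_analyzable`; control depletion at p < 1e-3 →
`potential_false_positive`; depletion at p < 0.1 → `questionable`; else
`reinforced`. The two thresholds are not published; they are the package's
operating points, chosen so the rule reproduces every published verdict
given the printed control-vs-reference p values, and both are configurable.
Pooling across classes matters: one published gene (LGR5) is unremarkable
in its headline class and only shows depletion once Mis1 variants enter.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: a small
extreme-phenotype case series (default 92) against a larger control panel
(default 1051). Carrier status is drawn per gene × damage class — controls
with probability q, cases with the p solving odds(p) = OR·odds(q) — so the
input OR is exactly the odds ratio the collapsing estimator targets, making
parameter recovery well-defined. Carriers are heterozygous for one
qualifying variant drawn uniformly from the gene's variant list (at
MAF < 1% homozygotes and double carriers are negligible; both exist as
options). Depth is Poisson or negative-binomial, GQ a clipped integer
normal, het allele depths binomial at a configurable alternate fraction,
and genotypes go missing uniformly at random. One root seed feeds
per-component substreams; identical configurations are byte-identical on
disk.

What the generator does *not* emulate: linkage disequilibrium between
variants, coverage heterogeneity along genes, batch effects between case
and control series, population stratification, and sequencing artifacts
beyond the depth/quality/balance noise above. Tests passing on these
cohorts therefore validate the statistical machinery and plumbing, not
robustness to those real-data phenomena — which is precisely why the
reference-comparison stage (which targets detection-rate artifacts) is part
of the pipeline.

The truth table records realized carrier counts; they equal the pipeline's
recount from the emitted VCF provided planted variants stay under the 1%
MAF cut — configurations near the boundary can legitimately lose a variant
to the rarity rule, so the generator's intended operating regime is carrier
frequencies comfortably below 1% per variant.

A separate crafted cohort (`qc_violation_cohort`) plants exactly one
violation per QC rule in disjoint samples (1000 samples, 8 sites), sized so
each rule — and only that rule — fires: e.g. case-only missingness is kept
at 4% overall (below the 5% variant-missingness cut) while reaching
p < 1e-6 on the case/control contrast.

## Embedded published-table fixtures

The thirteen top-hit carrier tables of the motivating study are embedded as
data (`TABLE_TOP_HITS`, `TABLE_REFERENCE`), and `fixture_matrix()` builds a
minimal cohort reproducing them exactly: each gene receives variants of the
single damage class that places it in precisely its listed embedded class,
with carriers spread over enough sites that every site stays below 1% MAF,
and all calls at high quality so QC passes the cohort unchanged. Per-gene
ANmax values are not published; a single assumed value of 33,370
(consistent with the study's "around 33,300 subjects") reproduces every
printed reference odds ratio and p value and is used throughout. The
Mis1-inclusive LGR5 reference entry is not printed and is synthesized
(`LGR5_SYNTHETIC_M1_TAC`) to encode the qualitative depletion the study
reports; it is labelled synthetic in the source.

## Problem sizes used in the test suite

Desk-scale checks run the full pipeline on the 1143-sample fixture
(< 5 s). Oracle-equivalence suites sweep all 2×2 tables with ≤ 12–14
individuals exhaustively plus 1000 seeded random tables up to 60, and all
HWE configurations with ≤ 30 individuals plus 500 random up to 60.
Stochastic properties use 2000 null genes in the 92/1051 design for the
type-I-error bound and 500 single-gene replicates for OR recovery at a
planted OR of 15 — sizes chosen to keep the whole suite around half a
minute while leaving Monte-Carlo noise well inside the asserted margins.

## Known limitations

- No covariate adjustment, dosage weighting, or variance-component
  (SKAT-style) tests; the statistic is the plain carrier-collapsing Fisher
  test.
- Annotation is consumed, never computed: effect terms, LOF flags and
  predictor verdicts must come from upstream tools, and the ±2 bp
  splice-region extraction rule is enforced only through the controlled
  effect-term vocabulary.
- The TAC/ANmax approximation inherits its stated assumptions (rare double
  carriers, near-uniform coverage); no meta-analysis across cohort and
  reference is attempted.
- Sex checks, contamination scores, ancestry PCA and related sample-level
  screens are out of scope; the QC cascade starts at genotype quality.
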