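"""Reproduce the published top-hit statistics from their carrier counts.

The 13 top genes of the motivating bipolar-disorder exome study are
embedded as 2x2 carrier tables (92 cases / 1051 controls). This example
recomputes the odds ratio, exact conditional 95% CI and two-sided Fisher
exact p value for each, which match the published table to its printed
rounding.
"""

from rvburden import Table2x2, fisher_two_sided, odds_ratio
from rvburden.synthetic_cohort import TABLE_TOP_HITS, fixture_tables

print(f"{'gene':<9} {'class':<20} {'cases':>5} {'ctrls':>5} "
      f"{'OR':>6} {'95% CI':>16} {'p':>9}")
for gene, (a, b, c, d) in fixture_tables().items():
    cc = TABLE_TOP_HITS[gene][0]
    tab = Table2x2(a, b, c, d)
    point, lo, hi = odds_ratio(tab)
    p = fisher_two_sided(tab)
    ci = f"({lo:.1f}-{'inf' if hi == float('inf') else f'{hi:.1f}'})"
    or_s = "inf" if point == float("inf") else f"{point:.1f}"
    print(f"{gene:<9} {cc.value:<20} {a:>5} {c:>5} {or_s:>6} {ci:>16} {p:>9.1e}")

print()
print(
    "Carrier counts are the published inputs; every statistic above is\n"
    "recomputed. None of the p values crosses the exome-wide Bonferroni\n"
    "threshold of 0.05/20000 = 2.5e-6, matching the study's conclusion."
)
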