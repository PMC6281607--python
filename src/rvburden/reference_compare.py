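"""Consistency check against an aggregated external reference (ExAC-style).

Individual-level genotypes are not available for large reference exome
aggregations, so the carrier proportion in the reference population is
approximated per gene and variant class by TAC/ANmax — the total aggregated
alternate-allele count divided by the maximum number of individuals with
allele information on the gene. The approximation rests on the rarity of
double carriers and near-uniform coverage within the gene.

Two Fisher exact tests per gene x class then compare (i) case carriers and
(ii) control carriers against the reference proportion. A per-gene
robustness verdict summarizes the control-side test across all four
embedded classes:

- control excess vs reference at p < severe (1e-3)    -> not_analyzable
  (the reference lacks variants, the comparison is uninformative)
- control depletion at p < severe                     -> potential_false_positive
- control depletion at p < mild (0.1)                 -> questionable
- otherwise                                           -> reinforced
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .burden_test import Table2x2, fisher_two_sided, odds_ratio
from .variant_classify import CollapseClass, DamageClass, embedded_membership

__all__ = [
    "RefGeneCount",
    "RefComparison",
    "Robustness",
    "read_reference_table",
    "aggregate_reference",
    "carrier_proportion",
    "compare_to_reference",
    "classify_robustness",
    "compare_gene",
]


class Robustness(Enum):
    REINFORCED = "reinforced"
    QUESTIONABLE = "questionable"
    POTENTIAL_FALSE_POSITIVE = "potential_false_positive"
    NOT_ANALYZABLE = "not_analyzable"


@dataclass(frozen=True)
class RefGeneCount:
    """Aggregated reference counts for one gene x embedded class."""

    gene: str
    collapse_class: CollapseClass
    tac: int
    anmax: int

    def __post_init__(self) -> None:
        if self.tac < 0 or self.anmax <= 0:
            raise ValueError("tac must be >= 0 and anmax > 0")
        if self.tac > 2 * self.anmax:
            raise ValueError("tac exceeds 2 * anmax")


@dataclass
class RefComparison:
    """Dual-test comparison of one gene x class against the reference."""

    gene: str
    collapse_class: CollapseClass
    or_case: float
    p_case: float
    or_ctrl: float
    p_ctrl: float
    comparable: bool = True


_DAMAGE_OF = {
    "PTV": DamageClass.PTV,
    "Mis3": DamageClass.MIS3,
    "Mis2": DamageClass.MIS2,
    "Mis1": DamageClass.MIS1,
    "benign": DamageClass.BENIGN,
}
_CLASS_OF = {c.value: c for c in CollapseClass}


def aggregate_reference(
    reference_variants: pd.DataFrame,
    maf_max: float = 0.01,
    missing_max: float = 0.20,
    an_total: int | None = None,
) -> dict[tuple[str, CollapseClass], RefGeneCount]:
    """Aggregate a sitewise reference export into per-gene x class counts.

    ``reference_variants`` needs columns gene, damage_class (PTV/Mis3/Mis2/
    Mis1/benign), ac (alternate allele count) and an (allele number, i.e.
    2 x individuals with a call). Rows with reference MAF >= ``maf_max``
    or missingness >= ``missing_max`` are discarded (missingness needs
    ``an_total``, the maximal AN of the export; without it the missingness
    filter is skipped). TAC sums qualifying allele counts with class
    embedding; ANmax is the largest per-variant an/2, rounded down.
    """
    req = {"gene", "damage_class", "ac", "an"}
    missing = req - set(reference_variants.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    out: dict[tuple[str, CollapseClass], RefGeneCount] = {}
    acc: dict[tuple[str, CollapseClass], list[int]] = {}
    anmax: dict[tuple[str, CollapseClass], int] = {}
    for row in reference_variants.itertuples(index=False):
        ac, an = int(row.ac), int(row.an)
        if an <= 0:
            continue
        maf = min(ac / an, 1 - ac / an)
        if maf >= maf_max:
            continue
        if an_total is not None and (1 - an / an_total) >= missing_max:
            continue
        dc = _DAMAGE_OF.get(str(row.damage_class))
        if dc is None:
            warnings.warn(f"unknown damage class {row.damage_class!r}; skipped")
            continue
        for cc in embedded_membership(dc):
            key = (str(row.gene), cc)
            acc.setdefault(key, []).append(ac)
            anmax[key] = max(anmax.get(key, 0), an // 2)
    for key, acs in acc.items():
        out[key] = RefGeneCount(key[0], key[1], sum(acs), anmax[key])
    return out


def read_reference_table(path: str) -> dict[tuple[str, CollapseClass], RefGeneCount]:
    """Read a reference TSV, pre-aggregated or sitewise.

    Pre-aggregated form: ``gene<TAB>class<TAB>tac<TAB>anmax`` with class in
    {PTV, PTV+Mis3, PTV+Mis3+Mis2, PTV+Mis3+Mis2+Mis1}. Sitewise form:
    ``gene<TAB>damage_class<TAB>ac<TAB>an`` (see :func:`aggregate_reference`).
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"gene", "class", "tac", "anmax"} <= cols:
        out = {}
        for row in df.to_dict("records"):
            cc = _CLASS_OF.get(str(row["class"]))
            if cc is None:
                raise ValueError(f"unknown collapse class {row['class']!r}")
            out[(str(row["gene"]), cc)] = RefGeneCount(
                str(row["gene"]), cc, int(row["tac"]), int(row["anmax"])
            )
        return out
    if {"gene", "damage_class", "ac", "an"} <= cols:
        return aggregate_reference(df)
    raise ValueError(
        "reference TSV must have columns (gene, class, tac, anmax) "
        "or (gene, damage_class, ac, an)"
    )


def carrier_proportion(ref_count: RefGeneCount) -> float:
    """Approximate reference carrier proportion TAC/ANmax, capped at 1."""
    prop = ref_count.tac / ref_count.anmax
    if prop > 1:
        warnings.warn(
            f"{ref_count.gene}: TAC > ANmax; carrier proportion capped at 1"
        )
        return 1.0
    return prop


def compare_to_reference(
    carriers: int, n: int, ref_count: RefGeneCount | None
) -> tuple[float, float] | None:
    """Fisher exact comparison of cohort carriers against the reference.

    Builds the 2x2 (carriers, n - carriers; TAC, ANmax - TAC), treating TAC
    as the reference carrier count (double carriers assumed negligible).
    Returns (odds ratio, p) or None when no reference entry exists.
    """
    if ref_count is None:
        return None
    tab = Table2x2(
        carriers, n - carriers, ref_count.tac, ref_count.anmax - ref_count.tac
    )
    point, _, _ = odds_ratio(tab)
    return point, fisher_two_sided(tab)


def classify_robustness(
    comparisons: Sequence[RefComparison],
    severe_p: float = 1e-3,
    mild_p: float = 0.1,
) -> Robustness:
    """Gene-level robustness verdict pooling all embedded classes.

    Evaluated over every comparable class of the gene, in order of
    severity: control excess vs reference at p < ``severe_p`` makes the
    gene not analyzable; control depletion at p < ``severe_p`` a potential
    false positive; control depletion at p < ``mild_p`` questionable;
    otherwise the association is reinforced.
    """
    usable = [c for c in comparisons if c.comparable]
    if not usable:
        return Robustness.NOT_ANALYZABLE
    if any(c.or_ctrl > 1 and c.p_ctrl < severe_p for c in usable):
        return Robustness.NOT_ANALYZABLE
    if any(c.or_ctrl < 1 and c.p_ctrl < severe_p for c in usable):
        return Robustness.POTENTIAL_FALSE_POSITIVE
    if any(c.or_ctrl < 1 and c.p_ctrl < mild_p for c in usable):
        return Robustness.QUESTIONABLE
    return Robustness.REINFORCED


def compare_gene(
    gene: str,
    carrier_counts: Mapping[CollapseClass, tuple[int, int, int, int]],
    reference: Mapping[tuple[str, CollapseClass], RefGeneCount],
    severe_p: float = 1e-3,
    mild_p: float = 0.1,
) -> tuple[list[RefComparison], Robustness]:
    """Run both reference tests for every class of a gene and give a verdict.

    ``carrier_counts`` maps each class to (case_carriers, case_n,
    control_carriers, control_n) as produced by the burden collapse.
    """
    comps: list[RefComparison] = []
    for cc, (a, case_n, c, control_n) in carrier_counts.items():
        ref = reference.get((gene, cc))
        case_res = compare_to_reference(a, case_n, ref)
        ctrl_res = compare_to_reference(c, control_n, ref)
        if case_res is None or ctrl_res is None:
            comps.append(
                RefComparison(gene, cc, math.nan, math.nan, math.nan, math.nan, False)
            )
        else:
            comps.append(
                RefComparison(gene, cc, case_res[0], case_res[1], ctrl_res[0], ctrl_res[1])
            )
    verdict = classify_robustness(comps, severe_p, mild_p)
    return comps, verdict
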