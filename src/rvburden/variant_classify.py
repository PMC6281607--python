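"""Consensus damage classification and embedded collapsing classes.

Variants are classified as protein-truncating (PTV), or — for missense —
as Mis3/Mis2/Mis1/benign according to how many of the three in-silico
damage predictors call them damaging. After excluding benign variants the
burden tests operate on four strictly nested ("embedded") variant classes:

    PTV  ⊂  PTV+Mis3  ⊂  PTV+Mis3+Mis2  ⊂  PTV+Mis3+Mis2+Mis1

Rarity is decided on the combined case+control post-QC cohort: a variant
qualifies when its minor allele frequency is strictly below 1%, with the
denominator being twice the number of non-missing genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import CohortMatrix, VariantSite

__all__ = [
    "DamageClass",
    "CollapseClass",
    "ClassificationTable",
    "is_ptv",
    "classify_missense",
    "classify_variant",
    "cohort_maf",
    "embedded_membership",
    "classify_variants",
]

#: Effect terms the classifier understands. Anything else is UNCLASSIFIED.
KNOWN_EFFECT_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "splice_region_variant",
        "missense_variant",
        "synonymous_variant",
        "inframe_insertion",
        "inframe_deletion",
        "initiator_codon_variant",
    }
)

#: Effect terms eligible for the PTV fallback when no LOF flag is present.
PTV_FALLBACK_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)

RARE_MAF = 0.01


class DamageClass(Enum):
    PTV = "PTV"
    MIS3 = "Mis3"
    MIS2 = "Mis2"
    MIS1 = "Mis1"
    BENIGN = "benign"
    UNCLASSIFIED = "unclassified"


class CollapseClass(Enum):
    """Embedded collapsing classes, most to least restrictive."""

    C_PTV = "PTV"
    C_PTV_M3 = "PTV+Mis3"
    C_PTV_M3_M2 = "PTV+Mis3+Mis2"
    C_PTV_M3_M2_M1 = "PTV+Mis3+Mis2+Mis1"


def is_ptv(
    effect_term: str,
    lof_flag: bool | None = None,
    terminal_exon: bool | None = None,
) -> bool:
    """Decide protein-truncating status.

    The upstream loss-of-function flag, when present, is authoritative.
    Without it, nonsense / frameshift / canonical splice-site terms count
    as PTV unless the variant is annotated as falling in the terminal exon
    (a position where truncation often escapes nonsense-mediated decay);
    an unknown terminal-exon status is treated as non-terminal with a
    warning.
    """
    if lof_flag is not None:
        return bool(lof_flag)
    if effect_term not in PTV_FALLBACK_TERMS:
        return False
    if terminal_exon is None:
        warnings.warn(
            f"no LOF flag and unknown terminal-exon status for {effect_term}; "
            "assuming non-terminal (PTV)"
        )
        return True
    return not terminal_exon


def classify_missense(predictor_calls: Sequence[str]) -> DamageClass:
    """Mis3/Mis2/Mis1/benign from the count of damaging predictor verdicts.

    Missing verdicts are simply not counted as damaging (the conservative
    reading of a damaging-call count), so (damaging, missing, missing)
    yields Mis1.
    """
    n = sum(1 for c in predictor_calls if c == "damaging")
    return {3: DamageClass.MIS3, 2: DamageClass.MIS2, 1: DamageClass.MIS1}.get(
        n, DamageClass.BENIGN
    )


def classify_variant(
    site: VariantSite, exclude_missing_predictors: bool = False
) -> DamageClass:
    """Assign the damage class of one annotated variant site."""
    if is_ptv(site.effect_term, site.lof_flag, site.terminal_exon):
        return DamageClass.PTV
    if site.effect_term not in KNOWN_EFFECT_TERMS:
        warnings.warn(f"unknown effect term {site.effect_term!r} -> unclassified")
        return DamageClass.UNCLASSIFIED
    if site.effect_term == "missense_variant":
        if exclude_missing_predictors and "missing" in site.predictor_calls:
            return DamageClass.UNCLASSIFIED
        return classify_missense(site.predictor_calls)
    return DamageClass.BENIGN


def cohort_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency over non-missing dosages (folded)."""
    d = np.asarray(dosages)
    called = d >= 0
    n = int(called.sum())
    if n == 0:
        raise ValueError("all calls missing")
    alt = float(d[called].sum()) / (2 * n)
    return min(alt, 1.0 - alt)


_MEMBERSHIP: Mapping[DamageClass, tuple[CollapseClass, ...]] = {
    DamageClass.PTV: tuple(CollapseClass),
    DamageClass.MIS3: tuple(CollapseClass)[1:],
    DamageClass.MIS2: tuple(CollapseClass)[2:],
    DamageClass.MIS1: tuple(CollapseClass)[3:],
    DamageClass.BENIGN: (),
    DamageClass.UNCLASSIFIED: (),
}


def embedded_membership(damage_class: DamageClass) -> set[CollapseClass]:
    """Embedded collapsing classes a damage class belongs to (nested)."""
    return set(_MEMBERSHIP[damage_class])


@dataclass
class ClassificationTable:
    """Per-site classification results plus fast qualifying-set lookup."""

    table: pd.DataFrame  # site_id, gene, damage_class, maf, rare, classes
    _index: dict[tuple[str, CollapseClass], np.ndarray] = field(repr=False, default_factory=dict)

    def genes(self) -> list[str]:
        g = self.table.loc[self.table["rare"], "gene"]
        return sorted(set(g) - {""})

    def qualifying_site_indices(
        self, gene: str, collapse_class: CollapseClass
    ) -> np.ndarray:
        """Matrix column indices of rare variants of the gene in the class."""
        return self._index.get((gene, collapse_class), np.array([], dtype=int))

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["damage_class"] = [d.value for d in out["damage_class"]]
        out.to_csv(path, sep="\t", index=False)

    def per_subject_mean_qualifying(self, matrix: CohortMatrix) -> float:
        """Mean per-subject count of rare qualifying (non-benign) variants."""
        mask = (
            self.table["rare"]
            & self.table["damage_class"].isin(
                [DamageClass.PTV, DamageClass.MIS3, DamageClass.MIS2, DamageClass.MIS1]
            )
        ).to_numpy()
        if not mask.any():
            return 0.0
        dos = matrix.dosage[:, mask]
        return float((dos > 0).sum(axis=1).mean())


def classify_variants(
    matrix: CohortMatrix, exclude_missing_predictors: bool = False
) -> ClassificationTable:
    """Classify every site of a (post-QC) cohort matrix.

    Computes the cohort MAF on cases+controls combined, assigns damage
    classes and embedded-class membership, and builds the per-gene
    qualifying-variant index used by the burden scan. Multi-gene annotation
    (comma-separated gene field) enters the index once per overlapping gene.
    """
    rows = []
    index: dict[tuple[str, CollapseClass], list[int]] = {}
    for j, site in enumerate(matrix.sites):
        dos = matrix.dosage[:, j]
        called = dos >= 0
        if not called.any():
            warnings.warn(f"{site.site_id}: all calls missing; excluded")
            maf, rare = np.nan, False
        else:
            maf = cohort_maf(dos)
            rare = maf < RARE_MAF
        dc = classify_variant(site, exclude_missing_predictors)
        member = _MEMBERSHIP[dc]
        genes = [g for g in site.gene.split(",") if g] if site.gene else []
        if rare:
            for g in genes:
                for cc in member:
                    index.setdefault((g, cc), []).append(j)
        rows.append(
            {
                "site_id": site.site_id,
                "gene": site.gene,
                "damage_class": dc,
                "maf": maf,
                "rare": rare,
                "classes": ",".join(c.value for c in member),
            }
        )
    table = pd.DataFrame(
        rows, columns=["site_id", "gene", "damage_class", "maf", "rare", "classes"]
    )
    return ClassificationTable(
        table=table,
        _index={k: np.array(v, dtype=int) for k, v in index.items()},
    )
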