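"""Genotype-, variant-, and sample-level quality-control cascade.

The cascade runs in a fixed order so that each statistic is computed on the
cohort that survives the previous step:

1. genotype masking (DP > 6 and GQ > 20 retained, else set missing)
2. sample missingness (> 15% dropped)
3. relatedness (pi_hat > 0.15: the worse-quality member of each pair dropped)
4. genomic region masks (low-complexity / tandem-repeat BED exclusion)
5. variant missingness (> 5% excluded)
6. Hardy-Weinberg exact test in controls (p < 1e-6 excluded)
7. case/control differential missingness (Fisher exact, p < 1e-6 excluded)
8. mean allele balance (het mean outside [25%, 75%] or hom mean < 90%)

Every exclusion is recorded with its rule in a :class:`QCReport`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variant_io import MISSING, CohortMatrix, IntervalSet

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCError",
    "mask_genotypes",
    "variant_missingness",
    "sample_missingness",
    "hwe_exact_p",
    "differential_missingness_p",
    "allele_balance_filter",
    "relatedness_pi_hat",
    "apply_masks",
    "run_qc",
]


class QCError(RuntimeError):
    """Raised when QC removes every sample or every variant."""

    def __init__(self, message: str, report: "QCReport" | None = None) -> None:
        super().__init__(message)
        self.report = report


@dataclass
class QCThresholds:
    """Thresholds of the QC cascade (defaults follow the study design).

    ``dp_min``/``gq_min`` are the smallest retained values (retain DP > 6
    and GQ > 20). ``vqslod_min`` is an optional pass-through cut, off by
    default. HWE is tested in controls only by default.
    """

    dp_min: int = 7
    gq_min: int = 21
    variant_missing_max: float = 0.05
    diff_missing_p: float = 1e-6
    hwe_p: float = 1e-6
    hwe_controls_only: bool = True
    ab_het_low: float = 0.25
    ab_het_high: float = 0.75
    ab_hom_min: float = 0.90
    sample_missing_max: float = 0.15
    pi_hat_max: float = 0.15
    vqslod_min: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "variant_missing_max",
            "ab_het_low",
            "ab_het_high",
            "ab_hom_min",
            "sample_missing_max",
            "pi_hat_max",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dp_min < 1 or self.gq_min < 1:
            raise ValueError("dp_min and gq_min must be positive")


@dataclass
class QCReport:
    """Per-rule counts of masked genotypes / excluded variants / samples."""

    genotypes_masked: int = 0
    samples_dropped_missingness: list[str] = field(default_factory=list)
    samples_dropped_relatedness: list[str] = field(default_factory=list)
    variants_dropped: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def n_samples_dropped(self) -> int:
        return len(self.samples_dropped_missingness) + len(
            self.samples_dropped_relatedness
        )

    def n_variants_dropped(self) -> int:
        return sum(len(v) for v in self.variants_dropped.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": "genotype_mask", "unit": "genotypes", "count": self.genotypes_masked},
            {
                "rule": "sample_missingness",
                "unit": "samples",
                "count": len(self.samples_dropped_missingness),
            },
            {
                "rule": "relatedness",
                "unit": "samples",
                "count": len(self.samples_dropped_relatedness),
            },
        ]
        for rule, ids in self.variants_dropped.items():
            rows.append({"rule": rule, "unit": "variants", "count": len(ids)})
        return pd.DataFrame(rows)


def mask_genotypes(matrix: CohortMatrix, thresholds: QCThresholds | None = None) -> tuple[CohortMatrix, int]:
    """Set low-confidence genotype calls to missing (idempotent).

    A call fails when its DP or GQ falls below the retention thresholds;
    calls whose DP or GQ subfield is absent are retained (the rule applies
    only where the field was emitted).
    """
    t = thresholds or QCThresholds()
    out = matrix.copy()
    fail = np.zeros(out.dosage.shape, dtype=bool)
    fail |= (out.dp != MISSING) & (out.dp < t.dp_min)
    fail |= (out.gq != MISSING) & (out.gq < t.gq_min)
    fail &= out.dosage != MISSING
    out.dosage[fail] = MISSING
    return out, int(fail.sum())


def variant_missingness(matrix: CohortMatrix) -> np.ndarray:
    """Fraction of missing calls per site (denominator: all samples)."""
    return (matrix.dosage == MISSING).mean(axis=0)


def sample_missingness(matrix: CohortMatrix) -> np.ndarray:
    """Fraction of missing calls per sample over all retained sites."""
    if matrix.n_sites == 0:
        return np.zeros(matrix.n_samples)
    return (matrix.dosage == MISSING).mean(axis=1)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p value.

    Conditions on the observed allele counts and enumerates every
    heterozygote count of matching parity; each configuration is weighted
    by its conditional probability and the p value is the total probability
    of configurations no more likely than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no individuals")
    n_a = n_Aa + 2 * n_aa  # minor-or-not does not matter: test is symmetric
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    homa = (n_a - hets) // 2
    homA = n - hets - homa
    # log P(het | n, n_a) up to a shared constant
    logp = (
        hets * math.log(2)
        - gammaln(homA + 1)
        - gammaln(hets + 1)
        - gammaln(homa + 1)
    )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    obs = w[hets == n_Aa][0]
    return float(min(w[w <= obs * (1 + 1e-12)].sum(), 1.0))


def differential_missingness_p(
    case_missing: int, case_total: int, ctrl_missing: int, ctrl_total: int
) -> float:
    """Two-sided Fisher exact p for case/control missing-call-rate difference."""
    from .burden_test import Table2x2, fisher_two_sided

    if not (0 <= case_missing <= case_total and 0 <= ctrl_missing <= ctrl_total):
        raise ValueError("missing count outside [0, total]")
    return fisher_two_sided(
        Table2x2(
            case_missing,
            case_total - case_missing,
            ctrl_missing,
            ctrl_total - ctrl_missing,
        )
    )


def allele_balance_filter(
    dosage: np.ndarray,
    ad_ref: np.ndarray,
    ad_alt: np.ndarray,
    thresholds: QCThresholds | None = None,
) -> tuple[bool, float, float]:
    """Mean-allele-balance site filter.

    Returns ``(passes, het_mean, hom_mean)``. Heterozygous balance is the
    mean over het calls of ad_alt/(ad_ref+ad_alt); homozygous balance
    averages the supporting-allele fraction over hom-alt and hom-ref calls.
    The site fails when the het mean leaves [ab_het_low, ab_het_high] or
    the hom mean falls below ab_hom_min; a category with no usable calls
    imposes no constraint, and a site with no AD at all passes with a
    warning (the caller records it).
    """
    t = thresholds or QCThresholds()
    has_ad = (ad_ref != MISSING) & (ad_alt != MISSING)
    total = ad_ref + ad_alt
    usable = has_ad & (total > 0) & (dosage != MISSING)
    if not usable.any():
        return True, math.nan, math.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(usable, ad_alt / np.where(total > 0, total, 1), np.nan)
        ref_frac = np.where(usable, ad_ref / np.where(total > 0, total, 1), np.nan)
    het = usable & (dosage == 1)
    hom_alt = usable & (dosage == 2)
    hom_ref = usable & (dosage == 0)
    het_mean = float(alt_frac[het].mean()) if het.any() else math.nan
    hom_fracs = np.concatenate([alt_frac[hom_alt], ref_frac[hom_ref]])
    hom_mean = float(hom_fracs.mean()) if hom_fracs.size else math.nan
    ok = True
    if het.any() and not (t.ab_het_low <= het_mean <= t.ab_het_high):
        ok = False
    if hom_fracs.size and hom_mean < t.ab_hom_min:
        ok = False
    return ok, het_mean, hom_mean


def _ibs_counts(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = (g1 != MISSING) & (g2 != MISSING)
    return np.abs(g1 - g2), both


def relatedness_pi_hat(
    matrix: CohortMatrix,
    maf_min: float = 0.01,
    min_sites: int = 50,
) -> pd.DataFrame | None:
    """Method-of-moments IBD estimation from identity-by-state counts.

    Uses within-cohort sites with MAF >= ``maf_min``. For each pair,
    observed IBS-sharing counts are compared with their expectations under
    IBD states 0/1/2 given per-site allele frequencies; the moment
    estimates of P(IBD=0,1,2) are clamped to [0,1] and renormalized, and
    pi_hat = P(IBD=1)/2 + P(IBD=2). Returns a DataFrame (sample_i,
    sample_j, pi_hat, n_sites) or None (with a warning) when fewer than
    ``min_sites`` informative sites are available.
    """
    dos = matrix.dosage
    called = dos != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            called.sum(axis=0) > 0,
            np.where(dos == MISSING, 0, dos).sum(axis=0) / (2 * np.maximum(called.sum(axis=0), 1)),
            np.nan,
        )
    maf = np.minimum(freq, 1 - freq)
    keep = np.isfinite(maf) & (maf >= maf_min)
    if keep.sum() < min_sites:
        warnings.warn(
            f"only {int(keep.sum())} informative sites (< {min_sites}); "
            "relatedness step skipped"
        )
        return None
    dos = dos[:, keep]
    p = freq[keep]
    q = 1 - p
    # expected IBS-class probabilities per site given each IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = 1 - e1_ibs1

    rows = []
    n_samples = matrix.n_samples
    for i, j in combinations(range(n_samples), 2):
        gi, gj = dos[i], dos[j]
        both = (gi != MISSING) & (gj != MISSING)
        if both.sum() < min_sites:
            continue
        diff = np.abs(gi[both] - gj[both])
        n_ibs0 = float((diff == 2).sum())
        n_ibs1 = float((diff == 1).sum())
        n_ibs2 = float((diff == 0).sum())
        s0_0, s0_1, s0_2 = e0_ibs0[both].sum(), e0_ibs1[both].sum(), e0_ibs2[both].sum()
        s1_1, s1_2 = e1_ibs1[both].sum(), e1_ibs2[both].sum()
        n_tot = float(both.sum())
        P0 = n_ibs0 / s0_0 if s0_0 > 0 else 0.0
        P1 = (n_ibs1 - P0 * s0_1) / s1_1 if s1_1 > 0 else 0.0
        P2 = (n_ibs2 - P0 * s0_2 - P1 * s1_2) / n_tot
        Ps = np.clip([P0, P1, P2], 0, 1)
        total = Ps.sum()
        if total > 0:
            Ps = Ps / total
        pi_hat = Ps[1] / 2 + Ps[2]
        rows.append(
            {
                "sample_i": matrix.samples["sample_id"].iloc[i],
                "sample_j": matrix.samples["sample_id"].iloc[j],
                "pi_hat": float(pi_hat),
                "n_sites": int(n_tot),
            }
        )
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "pi_hat", "n_sites"])


def apply_masks(
    matrix: CohortMatrix, masks: Sequence[IntervalSet]
) -> tuple[CohortMatrix, list[str]]:
    """Drop sites whose position falls inside any exclusion mask."""
    dropped = [
        s.site_id
        for s in matrix.sites
        if any(m.contains_site(s) for m in masks)
    ]
    keep = np.array(
        [not any(m.contains_site(s) for m in masks) for s in matrix.sites],
        dtype=bool,
    )
    return matrix.subset_sites(keep), dropped


def run_qc(
    matrix: CohortMatrix,
    thresholds: QCThresholds | None = None,
    masks: Sequence[IntervalSet] = (),
) -> tuple[CohortMatrix, QCReport]:
    """Run the full QC cascade in its fixed order; see module docstring."""
    t = thresholds or QCThresholds()
    report = QCReport()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # optional VQSLOD pass-through cut
        if t.vqslod_min is not None:
            keep = np.array(
                [s.vqslod is None or s.vqslod >= t.vqslod_min for s in matrix.sites]
            )
            report.variants_dropped["vqslod"] = [
                s.site_id for s, k in zip(matrix.sites, keep) if not k
            ]
            matrix = matrix.subset_sites(keep)

        # 1. genotype masking
        matrix, n_masked = mask_genotypes(matrix, t)
        report.genotypes_masked = n_masked

        # 2. sample missingness
        smiss = sample_missingness(matrix)
        drop = smiss > t.sample_missing_max
        report.samples_dropped_missingness = list(
            matrix.samples["sample_id"][drop]
        )
        if drop.any():
            matrix = matrix.subset_samples(np.flatnonzero(~drop))
        if matrix.n_samples == 0:
            raise QCError("all samples removed by QC", report)

        # 3. relatedness
        pairs = relatedness_pi_hat(matrix)
        if pairs is not None and len(pairs):
            flagged = pairs[pairs["pi_hat"] > t.pi_hat_max]
            smiss = sample_missingness(matrix)
            miss_of = dict(zip(matrix.samples["sample_id"], smiss))
            order_of = {s: i for i, s in enumerate(matrix.samples["sample_id"])}
            to_drop: set[str] = set()
            for row in flagged.itertuples(index=False):
                si, sj = row.sample_i, row.sample_j
                if si in to_drop or sj in to_drop:
                    continue
                # worse quality = higher missingness; tie -> later sheet order
                if (miss_of[si], order_of[si]) >= (miss_of[sj], order_of[sj]):
                    to_drop.add(si)
                else:
                    to_drop.add(sj)
            report.samples_dropped_relatedness = sorted(to_drop)
            if to_drop:
                keep = ~matrix.samples["sample_id"].isin(to_drop).to_numpy()
                matrix = matrix.subset_samples(np.flatnonzero(keep))

        # 4. region masks
        if masks:
            matrix, dropped = apply_masks(matrix, masks)
            report.variants_dropped["region_mask"] = dropped

        # 5. variant missingness
        vmiss = variant_missingness(matrix)
        drop_v = vmiss > t.variant_missing_max
        report.variants_dropped["variant_missingness"] = [
            s.site_id for s, d in zip(matrix.sites, drop_v) if d
        ]
        matrix = matrix.subset_sites(~drop_v)

        # 6. HWE (controls only by default)
        group = ~matrix.case_mask if t.hwe_controls_only else np.ones(
            matrix.n_samples, dtype=bool
        )
        dos = matrix.dosage[group]
        hwe_drop = []
        for j in range(matrix.n_sites):
            d = dos[:, j]
            called = d != MISSING
            if not called.any():
                continue
            n_aa = int((d[called] == 2).sum())
            n_Aa = int((d[called] == 1).sum())
            n_AA = int((d[called] == 0).sum())
            if hwe_exact_p(n_AA, n_Aa, n_aa) < t.hwe_p:
                hwe_drop.append(j)
        report.variants_dropped["hwe"] = [matrix.sites[j].site_id for j in hwe_drop]
        if hwe_drop:
            keep = np.ones(matrix.n_sites, dtype=bool)
            keep[hwe_drop] = False
            matrix = matrix.subset_sites(keep)

        # 7. differential missingness
        case = matrix.case_mask
        n_case, n_ctrl = int(case.sum()), int((~case).sum())
        dm_drop = []
        if n_case and n_ctrl:
            miss = matrix.dosage == MISSING
            case_miss = miss[case].sum(axis=0)
            ctrl_miss = miss[~case].sum(axis=0)
            for j in range(matrix.n_sites):
                p = differential_missingness_p(
                    int(case_miss[j]), n_case, int(ctrl_miss[j]), n_ctrl
                )
                if p < t.diff_missing_p:
                    dm_drop.append(j)
        report.variants_dropped["differential_missingness"] = [
            matrix.sites[j].site_id for j in dm_drop
        ]
        if dm_drop:
            keep = np.ones(matrix.n_sites, dtype=bool)
            keep[dm_drop] = False
            matrix = matrix.subset_sites(keep)

        # 8. allele balance
        ab_drop = []
        for j in range(matrix.n_sites):
            ok, _, _ = allele_balance_filter(
                matrix.dosage[:, j], matrix.ad_ref[:, j], matrix.ad_alt[:, j], t
            )
            if not ok:
                ab_drop.append(j)
        report.variants_dropped["allele_balance"] = [
            matrix.sites[j].site_id for j in ab_drop
        ]
        if ab_drop:
            keep = np.ones(matrix.n_sites, dtype=bool)
            keep[ab_drop] = False
            matrix = matrix.subset_sites(keep)

        report.warnings = [str(w.message) for w in caught]

    if matrix.n_sites == 0:
        raise QCError("all variants removed by QC", report)
    return matrix, report
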