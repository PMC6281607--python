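"""QC cascade: genotype mask, missingness, HWE, allele balance, IBD."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rvburden import qc_filters as qc
from rvburden.qc_filters import QCThresholds
from rvburden.synthetic_cohort import (
    GeneSpec,
    GenotypeModel,
    SimulationConfig,
    qc_violation_cohort,
    simulate_matrix,
)
from rvburden.variant_classify import CollapseClass, classify_variants
from rvburden.variant_io import MISSING, CohortMatrix, IntervalSet, VariantSite

from conftest import hwe_oracle


def _matrix(dosage, dp=None, gq=None, ad_ref=None, ad_alt=None, labels=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sites = [
        VariantSite(chrom="1", pos=100 * (j + 1), ref="A", alt="G", gene=f"G{j}",
                    effect_term="missense_variant")
        for j in range(m)
    ]
    fill = lambda arr, v: np.full((n, m), v, np.int32) if arr is None else np.asarray(arr, np.int32)
    if ad_alt is None:
        ad_alt = np.where(dosage == 1, 25, np.where(dosage == 2, 50, 0))
    if ad_ref is None:
        ad_ref = np.maximum(fill(dp, 50) - np.asarray(ad_alt, np.int32), 0)
    labels = labels or ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return CohortMatrix(
        samples=pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "status": labels}),
        sites=sites,
        dosage=dosage,
        dp=fill(dp, 50),
        gq=fill(gq, 99),
        ad_ref=fill(ad_ref, 25),
        ad_alt=fill(ad_alt, 25),
    )


# ---------------------------------------------------------------------------
# genotype mask
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dp, gq, retained",
    [(7, 21, True), (6, 99, False), (99, 20, False), (7, 20, False), (6, 21, False)],
)
def test_genotype_mask_boundaries(dp, gq, retained):
    """Retention requires depth > 6 AND quality > 20; failing either masks."""
    m = _matrix([[1]], dp=[[dp]], gq=[[gq]])
    out, n_masked = qc.mask_genotypes(m)
    assert bool(out.dosage[0, 0] != MISSING) == retained
    assert n_masked == (0 if retained else 1)


def test_genotype_mask_idempotent():
    rng = np.random.default_rng(5)
    m = _matrix(
        rng.integers(0, 3, (20, 10)),
        dp=rng.integers(0, 60, (20, 10)),
        gq=rng.integers(0, 99, (20, 10)),
    )
    once, n1 = qc.mask_genotypes(m)
    twice, n2 = qc.mask_genotypes(once)
    assert np.array_equal(once.dosage, twice.dosage)
    assert n2 == 0


def test_genotype_mask_missing_subfields_retained():
    m = _matrix([[1]], dp=[[MISSING]], gq=[[MISSING]])
    out, _ = qc.mask_genotypes(m)
    assert out.dosage[0, 0] == 1


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_missing, excluded", [(0, False), (5, False), (6, True)])
def test_variant_missingness_strict_threshold(n_missing, excluded):
    dosage = np.zeros((100, 1), dtype=np.int8)
    dosage[:n_missing, 0] = MISSING
    frac = qc.variant_missingness(_matrix(dosage))[0]
    assert frac == pytest.approx(n_missing / 100)
    assert bool(frac > 0.05) == excluded


def test_sample_missingness():
    dosage = np.zeros((2, 100), dtype=np.int8)
    dosage[1, :16] = MISSING
    frac = qc.sample_missingness(_matrix(dosage))
    assert frac[0] == 0.0
    assert frac[1] == pytest.approx(0.16)


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def test_hwe_known_values():
    assert qc.hwe_exact_p(100, 0, 0) == 1.0
    # full enumeration over het in {0, 2, 4}: weights 6/70, 48/70, 16/70
    assert qc.hwe_exact_p(0, 4, 0) == pytest.approx(22 / 70)


def test_hwe_exhaustive_against_oracle():
    """All genotype configurations with <= 30 individuals match enumeration."""
    for n in range(1, 31):
        for n_aa in range(n + 1):
            for n_Aa in range(n - n_aa + 1):
                n_AA = n - n_aa - n_Aa
                assert qc.hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
                    hwe_oracle(n_AA, n_Aa, n_aa), rel=1e-9
                )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
)
def test_hwe_oracle_upto_60(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0 or n_AA + n_Aa + n_aa > 60:
        return
    assert qc.hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
        hwe_oracle(n_AA, n_Aa, n_aa), rel=1e-9
    )


def test_hwe_rejects_negative():
    with pytest.raises(ValueError):
        qc.hwe_exact_p(-1, 0, 1)


# ---------------------------------------------------------------------------
# differential missingness
# ---------------------------------------------------------------------------

def test_differential_missingness_degenerate():
    assert qc.differential_missingness_p(0, 92, 0, 1051) == 1.0
    # equal proportions
    assert qc.differential_missingness_p(10, 100, 100, 1000) == pytest.approx(1.0, abs=0.05)


def test_differential_missingness_matches_oracle():
    from conftest import fisher_oracle

    rng = np.random.default_rng(2)
    for _ in range(50):
        ct, tt = int(rng.integers(1, 25)), int(rng.integers(1, 25))
        cm, tm = int(rng.integers(0, ct + 1)), int(rng.integers(0, tt + 1))
        assert qc.differential_missingness_p(cm, ct, tm, tt) == pytest.approx(
            fisher_oracle(cm, ct - cm, tm, tt - tm), rel=1e-9
        )


# ---------------------------------------------------------------------------
# allele balance
# ---------------------------------------------------------------------------

def _ab(dosage, ad_ref, ad_alt):
    return qc.allele_balance_filter(
        np.array(dosage, np.int8), np.array(ad_ref, np.int32), np.array(ad_alt, np.int32)
    )


def test_allele_balance_het_pass():
    ok, het_mean, _ = _ab([1, 1], [25, 25], [25, 25])
    assert ok and het_mean == pytest.approx(0.5)


def test_allele_balance_het_fail_low():
    # alt fractions 0.1 and 0.3 -> mean 0.2 < 0.25
    ok, het_mean, _ = _ab([1, 1], [45, 35], [5, 15])
    assert not ok and het_mean == pytest.approx(0.2)


def test_allele_balance_hom_alt_pass():
    ok, _, hom_mean = _ab([2], [0], [20])
    assert ok and hom_mean == pytest.approx(1.0)


def test_allele_balance_hom_ref_fail():
    # hom-ref supported by only 80% ref reads -> hom mean 0.8 < 0.9
    ok, _, hom_mean = _ab([0, 0], [40, 40], [10, 10])
    assert not ok and hom_mean == pytest.approx(0.8)


def test_allele_balance_no_ad_passes():
    ok, het_mean, hom_mean = _ab([1], [MISSING], [MISSING])
    assert ok and math.isnan(het_mean)


def test_allele_balance_zero_depth_skipped():
    ok, het_mean, _ = _ab([1, 1], [0, 25], [0, 25])
    assert ok and het_mean == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def _population_matrix(rng, n_extra, n_sites=1000):
    """Background samples drawn from common allele frequencies."""
    freqs = rng.uniform(0.2, 0.5, n_sites)
    geno = rng.binomial(2, freqs, size=(n_extra, n_sites)).astype(np.int8)
    return freqs, geno


def test_pi_hat_duplicate_independent_parent_offspring():
    rng = np.random.default_rng(42)
    n_sites = 1000
    freqs = rng.uniform(0.2, 0.5, n_sites)
    background = rng.binomial(2, freqs, size=(20, n_sites)).astype(np.int8)
    dup = background[0].copy()  # duplicate of sample 0
    # parent-offspring: one allele transmitted, one drawn from population
    parent = background[1]
    transmitted = np.where(rng.random(n_sites) < parent / 2, 1, 0)
    child = (transmitted + rng.binomial(1, freqs)).astype(np.int8)
    dosage = np.vstack([background, dup, child])
    m = _matrix(dosage, labels=["control"] * dosage.shape[0])
    pairs = qc.relatedness_pi_hat(m)
    tab = {(r.sample_i, r.sample_j): r.pi_hat for r in pairs.itertuples(index=False)}
    n = dosage.shape[0]
    assert tab[("s0", f"s{n-2}")] == pytest.approx(1.0, abs=0.05)
    assert tab[("s1", f"s{n-1}")] == pytest.approx(0.5, abs=0.05)
    # unrelated pairs sit near zero
    unrelated = [tab[(f"s{i}", f"s{j}")] for i in range(2, 10) for j in range(i + 1, 10)]
    assert abs(float(np.mean(unrelated))) < 0.05


def test_pi_hat_skipped_with_few_informative_sites():
    dosage = np.zeros((4, 20), dtype=np.int8)  # all monomorphic
    with pytest.warns(UserWarning, match="informative"):
        assert qc.relatedness_pi_hat(_matrix(dosage)) is None


# ---------------------------------------------------------------------------
# masks and the full cascade
# ---------------------------------------------------------------------------

def test_apply_masks():
    m = _matrix(np.zeros((4, 3), dtype=np.int8))  # sites at pos 100, 200, 300
    mask = IntervalSet([("1", 150, 250)])  # covers pos 200 only
    out, dropped = qc.apply_masks(m, [mask])
    assert dropped == ["1:200:A:G"]
    assert out.n_sites == 2
    empty_out, empty_dropped = qc.apply_masks(m, [IntervalSet()])
    assert empty_dropped == [] and empty_out.n_sites == 3


def test_run_qc_clean_cohort_no_exclusions():
    rng = np.random.default_rng(1)
    m = _matrix(rng.binomial(1, 0.01, (50, 20)))
    out, report = qc.run_qc(m)
    assert report.genotypes_masked == 0
    assert report.n_variants_dropped() == 0
    assert report.n_samples_dropped() == 0
    assert out.n_sites == 20 and out.n_samples == 50


def test_run_qc_planted_violations_each_caught():
    """One planted violation per rule; each is caught by exactly its rule."""
    m, mask_ivs, expected = qc_violation_cohort()
    out, report = qc.run_qc(m, masks=[IntervalSet(mask_ivs)])
    assert report.genotypes_masked == 3
    assert report.samples_dropped_missingness == [expected["sample_missingness"]]
    for rule in (
        "region_mask",
        "variant_missingness",
        "hwe",
        "differential_missingness",
        "allele_balance",
    ):
        assert report.variants_dropped[rule] == [expected[rule]], rule
    # nothing else was removed
    assert out.n_sites == m.n_sites - 5
    assert out.n_samples == m.n_samples - 1


def test_run_qc_error_when_everything_removed():
    dosage = np.full((10, 2), MISSING, dtype=np.int8)
    with pytest.raises(qc.QCError):
        qc.run_qc(_matrix(dosage))


def test_run_qc_carrier_counts_monotone():
    """QC only removes: per-gene carrier counts never increase."""
    cfg = SimulationConfig(
        seed=9,
        genes=[GeneSpec(f"G{i}", {"Mis3": 2}, 0.02, 2.0) for i in range(5)],
        n_case=40,
        n_control=120,
        genotype=GenotypeModel(depth_mean=12.0, missing_rate=0.02),
    )
    m, _, _ = simulate_matrix(cfg)
    before = classify_variants(m)
    out, _ = qc.run_qc(m)
    after = classify_variants(out)
    from rvburden.burden_test import collapse_carriers

    for gene in before.genes():
        for cc in CollapseClass:
            a0, _, c0, _ = collapse_carriers(m, before, gene, cc)
            a1, _, c1, _ = collapse_carriers(out, after, gene, cc)
            assert a1 <= a0 and c1 <= c0
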