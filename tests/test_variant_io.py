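"""Format boundary: VCF/BED/TSV reading, canonicalization, round trips."""

import math
import warnings

import numpy as np
import pytest

from rvburden import variant_io as vio
from rvburden.variant_io import (
    CohortError,
    IntervalSet,
    VariantSite,
    normalize_variant,
    read_mask,
    split_multiallelic,
)
from rvburden.synthetic_cohort import (
    GeneSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_matrix,
    write_annotation_tsv,
    write_vcf,
)

from conftest import apply_edit


# ---------------------------------------------------------------------------
# VariantSite invariants
# ---------------------------------------------------------------------------

def test_site_rejects_bad_alleles():
    with pytest.raises(CohortError):
        VariantSite(chrom="1", pos=1, ref="A", alt="A")
    with pytest.raises(CohortError):
        VariantSite(chrom="1", pos=1, ref="A", alt="")
    with pytest.raises(CohortError):
        VariantSite(chrom="1", pos=1, ref="AN", alt="A")
    with pytest.raises(CohortError):
        VariantSite(chrom="1", pos=1, ref="A", alt="G", predictor_calls=("damaging",))


# ---------------------------------------------------------------------------
# multi-allelic splitting
# ---------------------------------------------------------------------------

def test_split_single_alt_identity():
    out = split_multiallelic("1", 100, "A", ["C"], [[0, 1], [1, 1], [-1, -1]])
    assert len(out) == 1
    (key, dos), = out
    assert key == ("1", 100, "A", "C")
    assert list(dos) == [1, 2, vio.MISSING]


def test_split_het_two_alts():
    """Sample C/G at ref A: dosage 1 for each split record."""
    out = split_multiallelic("1", 100, "A", ["C", "G"], [[1, 2]])
    assert [int(d[0]) for _, d in out] == [1, 1]


def test_split_hom_first_alt():
    out = split_multiallelic("1", 100, "A", ["C", "G"], [[1, 1]])
    assert [int(d[0]) for _, d in out] == [2, 0]


def test_split_conserves_alt_count():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n_alt = int(rng.integers(1, 4))
        gts = [list(rng.integers(0, n_alt + 1, 2)) for _ in range(10)]
        out = split_multiallelic("1", 1, "A", ["C", "G", "T"][:n_alt], gts)
        for i, gt in enumerate(gts):
            total = sum(int(d[i]) for _, d in out)
            assert total == sum(1 for a in gt if a > 0)


def test_split_malformed_genotype():
    with pytest.raises(CohortError):
        split_multiallelic("1", 1, "A", ["C"], [[0, 5]])


# ---------------------------------------------------------------------------
# normalization (left alignment) against the sequence-application oracle
# ---------------------------------------------------------------------------

def test_normalize_snv_identity():
    s = VariantSite(chrom="1", pos=100, ref="A", alt="C")
    assert normalize_variant(s, 95, "GGGGGACTTTG") is s


def test_normalize_left_aligns_deletion():
    # window ...A C T T T G... starting at 100: deletion CTT->CT at 101
    window = "ACTTTG"
    s = VariantSite(chrom="1", pos=101, ref="CTT", alt="CT")
    out = normalize_variant(s, 100, window)
    # leftmost equivalent single-T deletion anchors on the C at 101
    assert (out.pos, out.ref, out.alt) == (101, "CT", "C")
    # sequence equivalence via the oracle
    assert apply_edit(100, window, s.pos, s.ref, s.alt) == apply_edit(
        100, window, out.pos, out.ref, out.alt
    )


def test_normalize_mismatching_ref_rejected():
    s = VariantSite(chrom="1", pos=100, ref="T", alt="A")
    with pytest.raises(CohortError):
        normalize_variant(s, 100, "AAAA")


def test_normalize_random_indels_idempotent_and_equivalent():
    """Random indels: canonical form preserves the edited sequence and the
    operation is idempotent (checked against the application oracle)."""
    rng = np.random.default_rng(17)
    bases = "ACGT"
    for _ in range(300):
        window = "".join(rng.choice(list(bases), size=40))
        start = int(rng.integers(1, 1000))
        off = int(rng.integers(5, 30))
        length = int(rng.integers(1, 5))
        ref = window[off : off + length]
        if rng.random() < 0.5:  # deletion-like: alt is prefix of ref
            alt = ref[0] + "".join(rng.choice(list(bases), size=rng.integers(0, 2)))
        else:  # insertion-like
            alt = ref + "".join(rng.choice(list(bases), size=rng.integers(1, 4)))
        if alt == ref:
            continue
        s = VariantSite(chrom="1", pos=start + off, ref=ref, alt=alt)
        out = normalize_variant(s, start, window)
        assert apply_edit(start, window, s.pos, s.ref, s.alt) == apply_edit(
            start, window, out.pos, out.ref, out.alt
        )
        again = normalize_variant(out, start, window)
        assert (again.pos, again.ref, again.alt) == (out.pos, out.ref, out.alt)


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def test_mask_containment_and_merge(tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t10\t20\nchr1\t15\t30\n")
    mask = read_mask(str(bed))
    assert mask.intervals("chr1") == [(10, 30)]  # merged
    assert mask.contains("chr1", 11)  # 1-based 11 -> 0-based 10
    assert mask.contains("chr1", 30)  # 0-based 29 < 30
    assert not mask.contains("chr1", 31)  # half-open end
    assert not mask.contains("chr2", 11)


def test_mask_rejects_bad_lines(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t20\t10\n")
    with pytest.raises(CohortError):
        read_mask(str(bad))
    bad.write_text("chr1\tten\t20\n")
    with pytest.raises(CohortError):
        read_mask(str(bad))


# ---------------------------------------------------------------------------
# cohort reading
# ---------------------------------------------------------------------------

@pytest.fixture()
def small_cohort(tmp_path):
    cfg = SimulationConfig(
        seed=3,
        genes=[GeneSpec("GENE1", {"Mis3": 2}, 0.05, 3.0)],
        n_case=3,
        n_control=5,
    )
    paths = simulate_cohort(cfg, str(tmp_path / "cohort"))
    return cfg, paths


def test_read_cohort_round_trip(small_cohort):
    cfg, paths = small_cohort
    m = vio.read_cohort(paths["vcf"], paths["sample_sheet"], paths["annotation"])
    mem, _, _ = simulate_matrix(cfg)
    assert m.n_samples == 8
    pos = {sid: j for j, sid in enumerate(m.site_ids)}
    for j_mem, site in enumerate(mem.sites):
        j = pos[site.site_id]
        assert np.array_equal(m.dosage[:, j], mem.dosage[:, j_mem])
        assert np.array_equal(m.dp[:, j], mem.dp[:, j_mem])
        assert np.array_equal(m.ad_alt[:, j], mem.ad_alt[:, j_mem])
        got = m.sites[j]
        assert (got.gene, got.effect_term, got.predictor_calls) == (
            site.gene, site.effect_term, site.predictor_calls
        )


def test_read_cohort_sample_missing_from_sheet(small_cohort, tmp_path):
    _, paths = small_cohort
    sheet = tmp_path / "short.tsv"
    lines = open(paths["sample_sheet"]).read().splitlines()
    sheet.write_text("\n".join(lines[:-1]) + "\n")  # drop last sample
    missing_sample = lines[-1].split("\t")[0]
    with pytest.raises(CohortError, match=missing_sample):
        vio.read_cohort(paths["vcf"], str(sheet), paths["annotation"])


def test_read_cohort_bad_phenotype(small_cohort, tmp_path):
    _, paths = small_cohort
    sheet = tmp_path / "bad.tsv"
    content = open(paths["sample_sheet"]).read().replace("control", "unknown")
    sheet.write_text(content)
    with pytest.raises(CohortError, match="phenotype"):
        vio.read_cohort(paths["vcf"], str(sheet), paths["annotation"])


def test_read_cohort_unannotated_sites_flagged(small_cohort):
    _, paths = small_cohort
    with pytest.warns(UserWarning, match="lack annotation"):
        m = vio.read_cohort(paths["vcf"], paths["sample_sheet"], None)
    assert all(s.predictor_calls == ("missing",) * 3 for s in m.sites)


def test_study_scale_cohort_loads(top_hits_matrix, tmp_path):
    """A cohort at the study's size (92 cases / 1051 controls) loads with
    the right phenotype counts."""
    vcf = tmp_path / "c.vcf"
    sheet = tmp_path / "s.tsv"
    ann = tmp_path / "a.tsv"
    write_vcf(top_hits_matrix, str(vcf))
    top_hits_matrix.samples.to_csv(sheet, sep="\t", index=False)
    write_annotation_tsv(top_hits_matrix.sites, str(ann))
    m = vio.read_cohort(str(vcf), str(sheet), str(ann))
    counts = m.samples["status"].value_counts()
    assert counts["case"] == 92 and counts["control"] == 1051


# ---------------------------------------------------------------------------
# results TSV round trip
# ---------------------------------------------------------------------------

def test_write_results_empty(tmp_path):
    path = tmp_path / "r.tsv"
    vio.write_results([], str(path))
    assert path.read_text().strip() == "\t".join(vio.RESULT_COLUMNS)


def test_write_read_results_round_trip(tmp_path):
    from rvburden.burden_test import BurdenResult

    rng = np.random.default_rng(4)
    results = []
    for i in range(20):
        a, c = int(rng.integers(0, 10)), int(rng.integers(0, 40))
        p = float(rng.uniform(1e-6, 1))
        results.append(
            BurdenResult(
                gene=f"G{i}",
                collapse_class="C_PTV_M3",
                case_carriers=a,
                case_n=92,
                control_carriers=c,
                control_n=1051,
                or_point=math.inf if c == 0 else float(rng.uniform(0.1, 30)),
                or_cmle=math.nan,
                ci_low=float(rng.uniform(0, 1)),
                ci_high=math.inf,
                p=p,
                q=min(1.0, p * 2),
            )
        )
    path = tmp_path / "res.tsv"
    vio.write_results(results, str(path))
    df = vio.read_results(str(path))
    assert len(df) == 20
    for r, row in zip(results, df.itertuples(index=False)):
        assert row.gene == r.gene
        assert row.case_carriers == r.case_carriers
        assert row.or_point == pytest.approx(r.or_point)
        assert row.p == pytest.approx(r.p, rel=1e-12)
        assert row.ci_high == math.inf
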