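"""Reading, writing and canonicalization of variant-level data.

This module owns the boundary with the standard file formats the pipeline
touches: VCF (v4.x, FORMAT fields GT/DP/GQ/AD) for cohort genotypes, a TSV
sample sheet mapping sample ids to case/control status, an annotation sidecar
TSV (or VCF INFO subfields) carrying the functional annotation per variant,
BED masks of excluded genomic regions, and the TSV results report.

Coordinate conventions: VCF positions are 1-based inclusive and stay 1-based
internally; BED intervals are 0-based half-open and are converted only inside
:class:`IntervalSet`. All alleles are reference-strand.
"""

from __future__ import annotations

import csv
import io
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantSite",
    "CohortMatrix",
    "IntervalSet",
    "CohortError",
    "PREDICTOR_STATES",
    "read_sample_sheet",
    "read_annotation",
    "read_cohort",
    "split_multiallelic",
    "normalize_variant",
    "read_mask",
    "write_results",
    "read_results",
]

#: Allowed states for each of the three damage-predictor verdicts.
PREDICTOR_STATES = ("damaging", "benign", "missing")

MISSING = -1  # sentinel for missing integer genotype subfields

_DNA = frozenset("ACGT")


class CohortError(ValueError):
    """Raised for malformed cohort inputs (files, sheets, annotations)."""


@dataclass(frozen=True)
class VariantSite:
    """One bi-allelic variant site with its functional annotation.

    ``predictor_calls`` is the ordered triple of verdicts from the three
    in-silico missense damage predictors; each entry is one of ``damaging``,
    ``benign`` or ``missing``. ``lof_flag`` is the upstream loss-of-function
    annotation when present. ``vqslod`` is carried through untouched.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect_term: str = ""
    lof_flag: bool | None = None
    predictor_calls: tuple[str, str, str] = ("missing", "missing", "missing")
    vqslod: float | None = None
    terminal_exon: bool | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise CohortError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise CohortError(f"ref == alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _DNA.issuperset(allele):
                raise CohortError(
                    f"non-ACGT allele {allele!r} at {self.chrom}:{self.pos}"
                )
        if len(self.predictor_calls) != 3:
            raise CohortError("predictor_calls must have exactly 3 entries")
        for call in self.predictor_calls:
            if call not in PREDICTOR_STATES:
                raise CohortError(f"unknown predictor verdict {call!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CohortMatrix:
    """Samples x sites genotype matrix with per-call quality subfields.

    Integer arrays use -1 for missing; ``dosage`` is the alternate-allele
    count in {0, 1, 2} or -1. A call whose dosage is missing is absent for
    all downstream carrier logic.
    """

    samples: pd.DataFrame  # columns: sample_id, status in {case, control}
    sites: list[VariantSite]
    dosage: np.ndarray  # (n_samples, n_sites) int8
    dp: np.ndarray  # int32
    gq: np.ndarray  # int32
    ad_ref: np.ndarray  # int32
    ad_alt: np.ndarray  # int32

    def __post_init__(self) -> None:
        shape = (self.n_samples, self.n_sites)
        for name in ("dosage", "dp", "gq", "ad_ref", "ad_alt"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise CohortError(f"{name} has shape {arr.shape}, expected {shape}")
        if self.samples["sample_id"].duplicated().any():
            raise CohortError("duplicate sample ids")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise CohortError(f"duplicate site_id after canonicalization: {dup}")
        bad = set(self.samples["status"]) - {"case", "control"}
        if bad:
            raise CohortError(f"phenotype not in {{case, control}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()

    def subset_samples(self, keep: np.ndarray) -> "CohortMatrix":
        return CohortMatrix(
            samples=self.samples.iloc[keep].reset_index(drop=True),
            sites=self.sites,
            dosage=self.dosage[keep],
            dp=self.dp[keep],
            gq=self.gq[keep],
            ad_ref=self.ad_ref[keep],
            ad_alt=self.ad_alt[keep],
        )

    def subset_sites(self, keep: np.ndarray) -> "CohortMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CohortMatrix(
            samples=self.samples,
            sites=[self.sites[i] for i in keep],
            dosage=self.dosage[:, keep],
            dp=self.dp[:, keep],
            gq=self.gq[:, keep],
            ad_ref=self.ad_ref[:, keep],
            ad_alt=self.ad_alt[:, keep],
        )

    def copy(self) -> "CohortMatrix":
        return CohortMatrix(
            samples=self.samples.copy(),
            sites=list(self.sites),
            dosage=self.dosage.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            ad_ref=self.ad_ref.copy(),
            ad_alt=self.ad_alt.copy(),
        )


class IntervalSet:
    """Per-chromosome sorted, merged, half-open 0-based intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise CohortError(f"interval start >= end: {chrom}:{start}-{end}")
            raw.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in raw.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(zip(self._starts.get(chrom, []), self._ends.get(chrom, [])))

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True iff the 1-based position falls inside an interval."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        p = pos_1based - 1  # to 0-based
        i = bisect_right(starts, p) - 1
        return i >= 0 and p < self._ends[chrom][i]

    def contains_site(self, site: VariantSite) -> bool:
        return self.contains(site.chrom, site.pos)

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())


def read_mask(bed_path: str) -> IntervalSet:
    """Read a BED file of excluded regions into an :class:`IntervalSet`."""
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise CohortError(f"{bed_path}:{lineno}: unparsable BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise CohortError(f"{bed_path}:{lineno}: {exc}") from exc
            intervals.append((parts[0], start, end))
    return IntervalSet(intervals)


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read the ``sample_id<TAB>status`` sheet; status must be case/control."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "sample_id" not in cols or "status" not in cols:
        # headerless two-column form
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "status"], dtype=str)
    else:
        df.columns = cols
        df = df[["sample_id", "status"]]
    bad = set(df["status"]) - {"case", "control"}
    if bad:
        raise CohortError(f"phenotype not in {{case, control}}: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise CohortError("duplicate sample ids in sample sheet")
    return df.reset_index(drop=True)


def _parse_lof(value: str) -> bool | None:
    if value in ("", ".", "NA"):
        return None
    return value in ("1", "true", "True", "LOF", "HC")


def _parse_pred(value: str) -> str:
    v = value.strip()
    if v in ("D", "damaging", "deleterious"):
        return "damaging"
    if v in ("B", "T", "N", "benign", "tolerated", "neutral"):
        return "benign"
    return "missing"


def read_annotation(path: str) -> dict[str, dict]:
    """Read the sidecar annotation TSV keyed by site_id.

    Columns: site_id, gene, effect_term, lof_flag, pred1, pred2, pred3
    (lof_flag in {0,1,.}; predictors in {D,B,.}).
    """
    out: dict[str, dict] = {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"site_id", "gene", "effect_term", "lof_flag", "pred1", "pred2", "pred3"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"annotation sidecar missing columns: {sorted(missing)}")
    for row in df.itertuples(index=False):
        out[row.site_id] = {
            "gene": row.gene,
            "effect_term": row.effect_term,
            "lof_flag": _parse_lof(row.lof_flag),
            "predictor_calls": (
                _parse_pred(row.pred1),
                _parse_pred(row.pred2),
                _parse_pred(row.pred3),
            ),
        }
    return out


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    per_sample_gts: Sequence[Sequence[int]],
) -> list[tuple[tuple[str, int, str, str], np.ndarray]]:
    """Split a multi-allelic record into one bi-allelic record per alt.

    ``per_sample_gts`` holds allele indices per sample (0 = ref, k = k-th
    alt, negative = missing). For alt k the output dosage of a sample is the
    number of k alleles in its genotype; genotypes carrying only other alt
    alleles contribute dosage 0, and genotypes with any missing allele are
    fully missing. Total alternate-allele count per sample is conserved
    across the split records.
    """
    if not alts:
        raise CohortError(f"no alt alleles at {chrom}:{pos}")
    out = []
    n = len(per_sample_gts)
    for k, alt in enumerate(alts, start=1):
        dos = np.zeros(n, dtype=np.int8)
        for i, gt in enumerate(per_sample_gts):
            if len(gt) == 0 or any(a < 0 for a in gt):
                dos[i] = MISSING
            else:
                if any(a > len(alts) for a in gt):
                    raise CohortError(f"malformed genotype {gt} at {chrom}:{pos}")
                dos[i] = sum(1 for a in gt if a == k)
        out.append(((chrom, pos, ref, alt), dos))
    return out


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # shared suffix first, then shared prefix, keeping >= 1 base each
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    site: VariantSite, window_start: int, window_seq: str
) -> VariantSite:
    """Canonicalize a variant against a reference window (left-alignment).

    ``window_seq`` is the reference sequence starting at 1-based position
    ``window_start`` and must cover the site plus upstream context. Shared
    suffix then prefix are trimmed (keeping at least one base per allele)
    and indels are shifted left while the edit stays sequence-equivalent.
    The operation is idempotent.
    """
    window_seq = window_seq.upper()
    off = site.pos - window_start
    if off < 0 or off + len(site.ref) > len(window_seq):
        raise CohortError("reference window does not cover the site")
    if window_seq[off : off + len(site.ref)] != site.ref:
        raise CohortError(
            f"ref allele {site.ref} disagrees with reference window at {site.pos}"
        )
    pos, ref, alt = site.pos, site.ref, site.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (len(ref) == 1) != (len(alt) == 1) and ref[-1] == alt[-1]:
            # pure indel whose alleles end with the same base: shift left
            prev = pos - 1 - window_start
            if prev < 0:
                break
            base = window_seq[prev]
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break
    pos, ref, alt = _trim(pos, ref, alt)
    if (pos, ref, alt) == (site.pos, site.ref, site.alt):
        return site
    return replace(site, pos=pos, ref=ref, alt=alt)


def _int_or_missing(value) -> int:
    try:
        v = int(value)
    except (TypeError, ValueError):
        return MISSING
    return v if v >= 0 else MISSING


def read_cohort(
    vcf_path: str,
    sample_sheet_path: str,
    annotation_source: str | Mapping[str, dict] | None = None,
) -> CohortMatrix:
    """Load a cohort from VCF + sample sheet (+ annotation) into memory.

    Multi-allelic records are split into bi-allelic sites and trimmed.
    Functional annotation comes from VCF INFO subfields (GENE, EFFECT, LOF,
    PRED=p1|p2|p3, VQSLOD) and/or a sidecar TSV keyed by site_id; the
    sidecar wins on conflict with a warning. Sites lacking annotation are
    retained with all predictor verdicts missing.
    """
    from cyvcf2 import VCF

    sheet = read_sample_sheet(sample_sheet_path)
    if isinstance(annotation_source, str):
        annotation = read_annotation(annotation_source)
    else:
        annotation = dict(annotation_source or {})

    vcf = VCF(vcf_path)
    vcf_samples = list(vcf.samples)
    sheet_idx = {s: i for i, s in enumerate(sheet["sample_id"])}
    for s in vcf_samples:
        if s not in sheet_idx:
            raise CohortError(f"VCF sample {s!r} absent from sample sheet")
    # samples ordered as in the sheet, restricted to those present in the VCF
    present = [s for s in sheet["sample_id"] if s in set(vcf_samples)]
    samples = sheet[sheet["sample_id"].isin(present)].reset_index(drop=True)
    col_of = {s: j for j, s in enumerate(vcf_samples)}
    order = np.array([col_of[s] for s in samples["sample_id"]])
    n = len(samples)

    sites: list[VariantSite] = []
    dosage_cols, dp_cols, gq_cols, adr_cols, ada_cols = [], [], [], [], []
    unannotated: list[str] = []

    for rec in vcf:
        alts = rec.ALT
        if not alts:
            continue
        gts = [gt[:-1] for gt in rec.genotypes]  # drop phase flag

        def fmt_int(key):
            try:
                arr = rec.format(key)
            except KeyError:
                arr = None
            if arr is None:
                return np.full(n, MISSING, dtype=np.int32)
            arr = np.asarray(arr)
            if arr.ndim > 1:
                arr = arr[:, 0]
            out = arr.astype(np.int64)[order]
            out[out < 0] = MISSING
            return out.astype(np.int32)

        dp = fmt_int("DP")
        gq = fmt_int("GQ")
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None

        info = dict(rec.INFO)
        split = split_multiallelic(rec.CHROM, rec.POS, rec.REF, alts, gts)
        for k, ((chrom, pos, ref, alt), dos) in enumerate(split, start=1):
            pos_t, ref_t, alt_t = _trim(pos, ref, alt)
            site_kwargs = dict(chrom=chrom, pos=pos_t, ref=ref_t, alt=alt_t)
            # INFO-level annotation (applies to every split allele)
            gene = info.get("GENE", "")
            effect = info.get("EFFECT", "")
            lof = info.get("LOF")
            pred = info.get("PRED")
            vqslod = info.get("VQSLOD")
            calls = ("missing", "missing", "missing")
            if pred:
                parts = str(pred).split("|")
                if len(parts) == 3:
                    calls = tuple(_parse_pred(p) for p in parts)
            site = VariantSite(
                gene=str(gene) if gene else "",
                effect_term=str(effect) if effect else "",
                lof_flag=_parse_lof(str(lof)) if lof is not None else None,
                predictor_calls=calls,  # type: ignore[arg-type]
                vqslod=float(vqslod) if vqslod is not None else None,
                **site_kwargs,
            )
            ann = annotation.get(site.site_id)
            if ann is not None:
                if site.effect_term and site.effect_term != ann["effect_term"]:
                    warnings.warn(
                        f"annotation sidecar overrides INFO for {site.site_id}"
                    )
                site = replace(site, **ann)
            elif not site.effect_term:
                unannotated.append(site.site_id)
            sites.append(site)
            dosage_cols.append(dos[order])
            dp_cols.append(dp)
            gq_cols.append(gq)
            if ad is not None and ad.shape[1] > k:
                adr = ad[:, 0].astype(np.int64)[order]
                ada = ad[:, k].astype(np.int64)[order]
                adr[adr < 0] = MISSING
                ada[ada < 0] = MISSING
                adr_cols.append(adr.astype(np.int32))
                ada_cols.append(ada.astype(np.int32))
            else:
                adr_cols.append(np.full(n, MISSING, dtype=np.int32))
                ada_cols.append(np.full(n, MISSING, dtype=np.int32))

    if unannotated:
        warnings.warn(
            f"{len(unannotated)} sites lack annotation and keep missing "
            f"predictor verdicts (first: {unannotated[0]})"
        )

    def stack(cols, dtype):
        if not cols:
            return np.zeros((n, 0), dtype=dtype)
        return np.stack(cols, axis=1).astype(dtype)

    return CohortMatrix(
        samples=samples,
        sites=sites,
        dosage=stack(dosage_cols, np.int8),
        dp=stack(dp_cols, np.int32),
        gq=stack(gq_cols, np.int32),
        ad_ref=stack(adr_cols, np.int32),
        ad_alt=stack(ada_cols, np.int32),
    )


RESULT_COLUMNS = [
    "gene",
    "collapse_class",
    "case_carriers",
    "case_n",
    "control_carriers",
    "control_n",
    "or_point",
    "ci_low",
    "ci_high",
    "p",
    "q",
    "robustness",
]


def write_results(results: Iterable, path: str) -> None:
    """Write burden results as TSV in the fixed column order.

    Accepts BurdenResult-like objects or dicts; missing fields print as NA,
    infinite odds ratios as ``inf``. Round-trips via :func:`read_results`.
    """
    rows = []
    for r in results:
        d = r if isinstance(r, dict) else {c: getattr(r, c, None) for c in RESULT_COLUMNS}
        rows.append([d.get(c) for c in RESULT_COLUMNS])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for row in rows:
            w.writerow(["NA" if v is None else repr(v) if isinstance(v, float) else v for v in row])


def read_results(path: str) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, comment="#"
    )
    return df
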