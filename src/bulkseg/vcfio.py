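"""VCF ingestion, normalization to the internal variant table, and the
depth / allele-frequency / genotype-quality filters applied to bulk SNPs
before QTL scanning.

The variant table is a pandas DataFrame with one row per (site, alt
allele): ``chrom, pos, ref, alt, ad_ref, ad_alt, dp, gq, af, is_snp``.
Multiallelic sites are split into one row per alt; each alt's frequency is
ad_alt / (ad_ref + sum of all alt depths), a conservative apportionment
that can only be lower than the biallelic value.  DP is taken as reported
and may exceed ad_ref + ad_alt (uninformative reads).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

COLUMNS = ["chrom", "pos", "ref", "alt", "ad_ref", "ad_alt", "dp", "gq", "af", "is_snp"]
KEY = ["chrom", "pos", "alt"]


@dataclass
class FilterConfig:
    """Bulk-SNP filter bounds.  All bounds are inclusive of the stated
    endpoints: sites are excluded only strictly below min_depth / above
    max_depth, below min_af / above max_af, or below min_gq."""

    min_depth: int = 20
    max_depth: int = 360
    min_af: float = 0.10
    max_af: float = 0.90
    min_gq: int = 99

    def __post_init__(self) -> None:
        if not self.min_depth < self.max_depth:
            raise ValueError("min_depth must be < max_depth")
        if not (0 <= self.min_af < self.max_af <= 1):
            raise ValueError("need 0 <= min_af < max_af <= 1")


def read_vcf(path: str, sample: str | None = None) -> pd.DataFrame:
    """Read one sample of a VCF 4.x into the internal variant table.

    Multiallelic records are split per alt allele.  Missing FORMAT values
    are emitted as NaN and fail closed in :func:`filter_variants`.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        if sample is None:
            sample = list(vf.header.samples)[0]
        for rec in vf:
            fmt = rec.samples[sample]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            gq = fmt.get("GQ")
            alts = rec.alts or ()
            if ad is not None and any(a is None for a in ad):
                ad = None
            ad_ref = float(ad[0]) if ad is not None else np.nan
            total = float(sum(ad)) if ad is not None else np.nan
            for i, alt in enumerate(alts):
                ad_alt = float(ad[1 + i]) if ad is not None and len(ad) > 1 + i else np.nan
                af = ad_alt / total if ad is not None and total > 0 else np.nan
                rows.append(
                    (
                        rec.chrom,
                        rec.pos,
                        rec.ref,
                        alt,
                        ad_ref,
                        ad_alt,
                        float(dp) if dp is not None else np.nan,
                        float(gq) if gq is not None else np.nan,
                        af,
                        len(rec.ref) == 1 and len(alt) == 1,
                    )
                )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_vcf(table: pd.DataFrame, path: str, sample: str = "SAMPLE",
              contig_lengths: dict[str, int] | None = None) -> str:
    """Write a variant table back out as a single-sample VCF 4.2."""
    header = pysam.VariantHeader()
    if contig_lengths is None:
        contig_lengths = {
            c: int(table.loc[table["chrom"] == c, "pos"].max()) + 1000
            for c in pd.unique(table["chrom"])
        }
    for c, ln in contig_lengths.items():
        header.contigs.add(c, length=ln)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in table.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos) - 1, stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            s = rec.samples[sample]
            s["GT"] = (0, 1)
            if not (pd.isna(row.ad_ref) or pd.isna(row.ad_alt)):
                s["AD"] = (int(row.ad_ref), int(row.ad_alt))
            if not pd.isna(row.dp):
                s["DP"] = int(row.dp)
            if not pd.isna(row.gq):
                s["GQ"] = int(row.gq)
            out.write(rec)
    return str(path)


def filter_variants(
    records: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the bulk-SNP filters; returns (retained, per-rule rejection tally).

    Retained iff min_depth <= dp <= max_depth, min_af <= af <= max_af,
    gq >= min_gq and the record is a SNP.  Records missing dp/gq/af fail
    closed and are tallied as "missing-field".  A record failing several
    rules is tallied once under the first failing rule in the order
    missing-field, not-snp, depth, frequency, gq.
    """
    if cfg is None:
        cfg = FilterConfig()
    dp = records["dp"]
    af = records["af"]
    gq = records["gq"]
    missing = dp.isna() | af.isna() | gq.isna()
    not_snp = ~records["is_snp"].astype(bool)
    bad_depth = (dp < cfg.min_depth) | (dp > cfg.max_depth)
    bad_af = (af < cfg.min_af) | (af > cfg.max_af)
    bad_gq = gq < cfg.min_gq

    reason = np.full(len(records), "", dtype=object)
    for name, mask in [
        ("missing-field", missing),
        ("not-snp", not_snp),
        ("depth", bad_depth.fillna(False)),
        ("frequency", bad_af.fillna(False)),
        ("gq", bad_gq.fillna(False)),
    ]:
        reason[(reason == "") & mask.to_numpy()] = name
    retained = records[reason == ""].copy()
    tally = {
        name: int((reason == name).sum())
        for name in ["missing-field", "not-snp", "depth", "frequency", "gq"]
    }
    tally["retained"] = len(retained)
    tally["input"] = len(records)
    return retained, tally


def presence_calls(
    records: pd.DataFrame, min_alt_reads: int = 3, min_af: float = 0.02
) -> pd.DataFrame:
    """Emulate a caller's *unfiltered* call set: a site counts as present
    when the alt allele has minimal read support, far below the bulk
    filters.  Used for parental-presence lookups, where stray error reads
    must not register as presence."""
    keep = (records["ad_alt"] >= min_alt_reads) & (records["af"] >= min_af)
    return records[keep.fillna(False)]


def _check_sorted(df: pd.DataFrame, label: str) -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        bad = np.nonzero(np.diff(pos) < 0)[0]
        if bad.size:
            raise ValueError(
                f"{label} records not position-sorted: {chrom}:{pos[bad[0] + 1]} "
                f"follows {chrom}:{pos[bad[0]]}"
            )


def intersect_bulks(
    tol: pd.DataFrame,
    sen: pd.DataFrame,
    af_diff_threshold: float | None = None,
) -> pd.DataFrame:
    """Outer-join the two bulks' (filtered) variant tables on (chrom, pos, alt).

    Emits per-bulk AD/DP/af columns, presence flags, delta_snp
    (af_tol - af_sen, NaN where a bulk is absent) and ``is_difference``:
    by default a SNP present and passing in exactly one bulk; when
    ``af_diff_threshold`` is given, SNPs present in both with
    |delta_snp| > threshold also count (sensitivity-analysis mode).
    """
    _check_sorted(tol, "tolerant bulk")
    _check_sorted(sen, "sensitive bulk")
    cols = KEY + ["ref", "ad_ref", "ad_alt", "dp", "af"]
    joint = pd.merge(
        tol[cols], sen[cols], on=KEY + ["ref"], how="outer",
        suffixes=("_tol", "_sen"), sort=False,
    )
    joint["in_tol"] = joint["af_tol"].notna()
    joint["in_sen"] = joint["af_sen"].notna()
    joint["delta_snp"] = joint["af_tol"] - joint["af_sen"]
    exclusive = joint["in_tol"] ^ joint["in_sen"]
    if af_diff_threshold is not None:
        exclusive |= joint["delta_snp"].abs() > af_diff_threshold
    joint["is_difference"] = exclusive
    joint = joint.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    return joint
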