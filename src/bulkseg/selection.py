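"""Two-round candidate-SNP selection for panel design.

Round 1 takes bulk-exclusive (difference) SNPs in a curated literature
gene list restricted to the QTL intervals; the searched footprint of each
gene is its annotated extent extended strand-aware by 2000 bp at the 5'
end and 500 bp at the 3' end, and at most ``max_snps_per_gene`` SNPs are
kept per gene, prioritized by effect severity then position.  Round 2
widens to every annotated gene under a QTL but only admits missense and
nonsense SNPs, minus anything round 1 already took.  The union is the
panel design set; probe design needs 200 bp of flank either side of each
target SNP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
import pysam

KEY = ["chrom", "pos", "alt"]

#: closed effect vocabulary, most severe first
SEVERITY_ORDER = [
    "nonsense",
    "missense",
    "synonymous",
    "5'UTR",
    "3'UTR",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
    "other",
]
SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

_SNPEFF_MAP = {
    "missense_variant": "missense",
    "stop_gained": "nonsense",
    "stop_lost": "nonsense",
    "start_lost": "nonsense",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "intron_variant": "intron",
    "5_prime_utr_variant": "5'UTR",
    "5_prime_utr_premature_start_codon_gain_variant": "5'UTR",
    "3_prime_utr_variant": "3'UTR",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
}


def normalize_effect(term: str) -> str:
    t = term.strip()
    if t in SEVERITY_RANK:
        return t
    t = t.lower().replace("'", "_prime_").replace(" ", "_")
    low = term.strip().lower()
    if low in SEVERITY_RANK:
        return low if low in SEVERITY_RANK else "other"
    if low in ("5'utr", "5_prime_utr"):
        return "5'UTR"
    if low in ("3'utr", "3_prime_utr"):
        return "3'UTR"
    return _SNPEFF_MAP.get(t, _SNPEFF_MAP.get(low, "other"))


@dataclass
class SelectionConfig:
    upstream_bp: int = 2000  # 5' flank beyond the gene extent
    downstream_bp: int = 500  # 3' flank
    max_snps_per_gene: int = 3
    literature_genes: set[str] = field(default_factory=set)
    qtl_intervals: pd.DataFrame | None = None  # chrom/start_bp/end_bp, 1-based inclusive

    def __post_init__(self) -> None:
        if self.max_snps_per_gene < 1:
            raise ValueError("max_snps_per_gene must be >= 1")


def load_gene_models(gff_path: str) -> pd.DataFrame:
    """Gene features of a GFF3 as chrom / start / end (1-based inclusive)
    / strand / gene_id."""
    df = pr.read_gff3(str(gff_path)).df
    genes = df[df["Feature"] == "gene"]
    return pd.DataFrame(
        {
            "gene_id": genes["ID"].astype(str),
            "chrom": genes["Chromosome"].astype(str),
            "start": genes["Start"].astype(int) + 1,
            "end": genes["End"].astype(int),
            "strand": genes["Strand"].astype(str),
        }
    ).reset_index(drop=True)


def parse_effects(source: str, fmt: str | None = None) -> tuple[pd.DataFrame, dict]:
    """Effect annotations from a SnpEff-annotated VCF (ANN field) or a
    tab-separated table (chrom, pos, effect, gene_id).

    For each SNP-gene pair only the most severe effect is kept; unknown
    terms map to "other".  Returns (table, counters) where counters tally
    malformed ANN entries skipped and unknown terms encountered.
    """
    if fmt is None:
        fmt = "vcf" if str(source).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    counters = {"malformed": 0, "unknown_term": 0}
    rows = []
    if fmt == "vcf":
        with pysam.VariantFile(str(source)) as vf:
            for rec in vf:
                ann = rec.info.get("ANN")
                if ann is None:
                    continue
                if isinstance(ann, str):
                    ann = (ann,)
                for entry in ann:
                    parts = entry.split("|")
                    if len(parts) < 4 or not parts[1]:
                        counters["malformed"] += 1
                        continue
                    eff = normalize_effect(parts[1])
                    if eff == "other" and parts[1].strip().lower() not in _SNPEFF_MAP:
                        counters["unknown_term"] += 1
                    gene = parts[4] if len(parts) > 4 and parts[4] else parts[3]
                    rows.append((rec.chrom, rec.pos, eff, gene))
    else:
        table = pd.read_csv(
            str(source), sep="\t", comment="#",
            names=["chrom", "pos", "effect", "gene_id"], dtype={"pos": str},
        )
        if len(table) and table.iloc[0]["pos"] in ("pos", "position"):
            table = table.iloc[1:]
        for r in table.itertuples(index=False):
            try:
                pos = int(r.pos)
            except (TypeError, ValueError):
                counters["malformed"] += 1
                continue
            eff = normalize_effect(str(r.effect))
            rows.append((r.chrom, pos, eff, str(r.gene_id)))
    out = pd.DataFrame(rows, columns=["chrom", "pos", "effect", "gene_id"])
    if len(out):
        out["severity"] = out["effect"].map(SEVERITY_RANK)
        out = (
            out.sort_values(["chrom", "pos", "gene_id", "severity"], kind="mergesort")
            .drop_duplicates(["chrom", "pos", "gene_id"], keep="first")
            .drop(columns="severity")
            .reset_index(drop=True)
        )
    return out, counters


def _extended_extent(gene) -> tuple[int, int]:
    """Strand-aware search footprint: 5' flank of upstream_bp, 3' flank of
    downstream_bp beyond the annotated extent."""
    return gene.ext_start, gene.ext_end


def _genes_in_scope(genes: pd.DataFrame, cfg: SelectionConfig) -> pd.DataFrame:
    scoped = genes
    if cfg.qtl_intervals is not None:
        keep = np.zeros(len(scoped), dtype=bool)
        for iv in cfg.qtl_intervals.itertuples(index=False):
            keep |= (
                (scoped["chrom"] == iv.chrom)
                & (scoped["start"] <= iv.end_bp)
                & (scoped["end"] >= iv.start_bp)
            ).to_numpy()
        scoped = scoped[keep]
    return scoped.copy()


def _with_extents(genes: pd.DataFrame, cfg: SelectionConfig) -> pd.DataFrame:
    plus = genes["strand"] == "+"
    genes = genes.copy()
    genes["ext_start"] = np.where(
        plus, genes["start"] - cfg.upstream_bp, genes["start"] - cfg.downstream_bp
    )
    genes["ext_end"] = np.where(
        plus, genes["end"] + cfg.downstream_bp, genes["end"] + cfg.upstream_bp
    )
    return genes


def _snps_for_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, effects: pd.DataFrame
) -> pd.DataFrame:
    """Cross SNPs with extended gene footprints and attach effect classes.

    A SNP without an annotated effect for the gene is classed by position:
    upstream / downstream in the flank, otherwise "other".
    """
    out = []
    eff_idx = effects.set_index(["chrom", "pos", "gene_id"])["effect"] if len(effects) else None
    for gene in genes.itertuples(index=False):
        lo, hi = _extended_extent(gene)
        hit = snps[(snps["chrom"] == gene.chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)]
        for s in hit.itertuples(index=False):
            eff = None
            if eff_idx is not None:
                eff = eff_idx.get((s.chrom, s.pos, gene.gene_id))
            if eff is None:
                if s.pos < gene.start:
                    eff = "upstream" if gene.strand == "+" else "downstream"
                elif s.pos > gene.end:
                    eff = "downstream" if gene.strand == "+" else "upstream"
                else:
                    eff = "other"
            out.append((s.chrom, s.pos, s.alt, gene.gene_id, eff))
    return pd.DataFrame(out, columns=KEY + ["gene_id", "effect"])


def round1_select(
    difference_snps: pd.DataFrame,
    genes: pd.DataFrame,
    effects: pd.DataFrame,
    cfg: SelectionConfig,
) -> pd.DataFrame:
    """Round 1: bulk-exclusive SNPs in literature genes under the QTLs,
    capped per gene by severity-then-position priority."""
    if not cfg.literature_genes:
        warnings.warn("empty literature gene list: round 1 selects nothing", stacklevel=2)
        return pd.DataFrame(columns=KEY + ["gene_id", "effect", "round"])
    scoped = _genes_in_scope(genes, cfg)
    scoped = scoped[scoped["gene_id"].isin(cfg.literature_genes)]
    scoped = _with_extents(scoped, cfg)
    snps = difference_snps
    if "is_difference" in snps:
        snps = snps[snps["is_difference"]]
    cand = _snps_for_genes(snps, scoped, effects)
    if cand.empty:
        cand["round"] = pd.Series(dtype=int)
        return cand
    cand["severity"] = cand["effect"].map(SEVERITY_RANK).fillna(SEVERITY_RANK["other"])
    cand = cand.sort_values(["gene_id", "severity", "pos"], kind="mergesort")
    cand = cand.groupby("gene_id", group_keys=False).head(cfg.max_snps_per_gene)
    cand = cand.drop(columns="severity").reset_index(drop=True)
    cand["round"] = 1
    return cand


def round2_select(
    difference_snps: pd.DataFrame,
    effects: pd.DataFrame,
    genes_under_qtl: pd.DataFrame,
    round1_result: pd.DataFrame,
) -> pd.DataFrame:
    """Round 2: missense / nonsense bulk-exclusive SNPs in any gene under a
    QTL, excluding SNPs already selected in round 1."""
    snps = difference_snps
    if "is_difference" in snps:
        snps = snps[snps["is_difference"]]
    damaging = effects[effects["effect"].isin(["missense", "nonsense"])]
    damaging = damaging[damaging["gene_id"].isin(set(genes_under_qtl["gene_id"]))]
    merged = snps.merge(damaging, on=["chrom", "pos"], how="inner")
    cols = KEY + ["gene_id", "effect"]
    merged = merged[cols].drop_duplicates(KEY + ["gene_id"])
    if len(round1_result):
        taken = set(map(tuple, round1_result[KEY].itertuples(index=False)))
        mask = [tuple(k) not in taken for k in merged[KEY].itertuples(index=False)]
        merged = merged[mask]
    merged = merged.reset_index(drop=True)
    merged["round"] = 2
    return merged


def combine_rounds(round1: pd.DataFrame, round2: pd.DataFrame) -> pd.DataFrame:
    """Panel design set: round-1 union round-2, no duplicate SNP keys."""
    panel = pd.concat([round1, round2], ignore_index=True)
    panel = panel.drop_duplicates(KEY, keep="first").reset_index(drop=True)
    return panel


def panel_summary(panel: pd.DataFrame) -> dict:
    """SNP and gene tallies per round plus gene-level de-duplicated totals."""
    out = {"n_snps": len(panel), "n_genes": panel["gene_id"].nunique()}
    for r in (1, 2):
        sub = panel[panel["round"] == r]
        out[f"round{r}_snps"] = len(sub)
        out[f"round{r}_genes"] = sub["gene_id"].nunique()
    return out


def probe_flanks_bed(panel: pd.DataFrame, path: str, flank: int = 200) -> str:
    """BED (0-based half-open) of the +/- flank bp needed around each target
    SNP for allele-specific probe design."""
    with open(path, "w") as fh:
        for s in panel.itertuples(index=False):
            start = max(0, int(s.pos) - 1 - flank)
            fh.write(f"{s.chrom}\t{start}\t{int(s.pos) + flank}\t{s.chrom}:{s.pos}:{s.alt}\n")
    return str(path)


def design_yield_pct(n_designable: int, n_selected: int) -> float:
    """Share of selected SNPs for which probe design succeeded, in percent
    truncated to one decimal (410/1034 -> 39.6)."""
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    return math.floor(1000.0 * n_designable / n_selected) / 10.0
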