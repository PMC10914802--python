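"""Synthetic autotetraploid cross generator for bulked-segregant analysis.

Emulates a biparental cross between two tetraploid cultivars (parent A,
drought tolerant, and parent E, drought sensitive), tetrasomic inheritance
in the F1, a starch-yield phenotype in which planted QTL dosage shifts the
relative yield under stress, and pooled whole-genome sequencing of
phenotypic-extreme bulks at high coverage with overdispersed depth and
sequencing error.  Everything downstream of raw reads is produced: per-pool
VCFs with GT/AD/DP/GQ, a GFF3 gene annotation, a SnpEff-style effect table,
long-format phenotype tables and a panel genotype table.

Inheritance model: each parent carries four homologous copies per locus;
a gamete receives two of the four chosen uniformly (random bivalent
pairing).  The resulting gamete dosage for a parent of dosage d is
hypergeometric, P(k) = C(d,k)C(4-d,2-k)/C(4,2).  Double reduction (a gamete
receiving two sister copies of one homolog) is off by default but available.
Loci are unlinked by default; optional block linkage makes all loci within
a window share one gamete draw, creating correlated allele-frequency
signals around a QTL the way physical linkage does.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

PLOIDY = 4
GAMETE_PAIRS = list(itertools.combinations(range(PLOIDY), 2))  # 6 bivalent outcomes

EFFECT_CLASSES = (
    "missense",
    "nonsense",
    "synonymous",
    "intron",
    "5'UTR",
    "3'UTR",
    "intergenic",
)


@dataclass(frozen=True)
class QtlLocus:
    """A planted QTL: position, additive effect on RelSY per (dosage-2)/2,
    and which parent carries the tolerance-increasing allele."""

    chrom: int
    pos: int
    effect: float
    tolerant_parent: str = "A"  # {"A", "E"}

    def __post_init__(self) -> None:
        if self.tolerant_parent not in ("A", "E"):
            raise ValueError(f"tolerant_parent must be 'A' or 'E', got {self.tolerant_parent!r}")


@dataclass
class SimConfig:
    """Generative model parameters for the synthetic tetraploid cross.

    Defaults mirror the study design this generator emulates: 100 F1
    clones phenotyped in 3 experiments, bulks of 20, ~120x pooled
    coverage.  ``linkage_block_bp`` of None means unlinked loci.
    """

    n_chromosomes: int = 5
    chrom_length_bp: int = 5_000_000
    snp_density: float = 2e-4
    qtl_loci: list[QtlLocus] = field(default_factory=list)
    n_f1: int = 100
    bulk_size: int = 20
    coverage_mean: float = 120.0
    coverage_dispersion: float = 0.2
    seq_error_rate: float = 0.002
    n_experiments: int = 3
    base_relsy: float = 0.6
    residual_sd: float = 0.05
    control_yield_mean: float = 100.0
    control_yield_sd: float = 10.0
    linkage_block_bp: int | None = None
    double_reduction: float = 0.0
    qtl_dosage_tolerant: int = 3
    qtl_dosage_other: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not self.snp_density > 0:
            raise ValueError("snp_density must be positive")
        if not 0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate must be in [0, 0.5)")
        if not self.coverage_mean > 0:
            raise ValueError("coverage_mean must be positive")
        if self.coverage_dispersion < 0:
            raise ValueError("coverage_dispersion must be non-negative")
        if not 0 <= self.double_reduction <= 1:
            raise ValueError("double_reduction must be a probability")
        for q in self.qtl_loci:
            if not (1 <= q.pos <= self.chrom_length_bp):
                raise ValueError(f"QTL position {q.pos} outside [1, {self.chrom_length_bp}]")
            if not (1 <= q.chrom <= self.n_chromosomes):
                raise ValueError(f"QTL chromosome {q.chrom} out of range")

    def chrom_name(self, i: int) -> str:
        return f"chr{i:02d}"


@dataclass
class Parents:
    """Phased parental genomes over a shared locus set.

    ``hap_a``/``hap_e``: (4, n_loci) 0/1 arrays, one row per homolog.
    Dosage is the column sum.  ``qtl_index`` maps each planted QTL to its
    locus index.
    """

    chrom: np.ndarray  # str array, n_loci
    pos: np.ndarray  # int array, 1-based
    ref: np.ndarray  # single-base ref allele
    alt: np.ndarray  # single-base alt allele
    hap_a: np.ndarray
    hap_e: np.ndarray
    qtl_index: np.ndarray  # locus index of each cfg.qtl_loci entry
    cfg: SimConfig

    @property
    def n_loci(self) -> int:
        return self.pos.size

    @property
    def dosage_a(self) -> np.ndarray:
        return self.hap_a.sum(axis=0)

    @property
    def dosage_e(self) -> np.ndarray:
        return self.hap_e.sum(axis=0)


def _haplotypes_from_dosage(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place d alt alleles on d of the 4 homologs, uniformly at random."""
    n = dosage.size
    order = np.argsort(rng.random((PLOIDY, n)), axis=0)  # random permutation per locus
    return (order < dosage[None, :]).astype(np.int8)


_BASES = np.array(list("ACGT"))


def simulate_parents(cfg: SimConfig, rng: np.random.Generator | None = None) -> Parents:
    """Draw the shared locus set and both parental genomes.

    Loci are placed by a Poisson process at ``snp_density``; each parent's
    dosage at a non-QTL locus is uniform on {0..4}, so loci where both
    parents are reference (dosage 0) are retained — they model
    reference-vs-cultivar differences shared by both bulks.  Planted QTL
    loci are forced to dosage ``qtl_dosage_tolerant`` in the tolerant
    parent and ``qtl_dosage_other`` in the other.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for c in range(1, cfg.n_chromosomes + 1):
        n_loci = rng.poisson(cfg.snp_density * cfg.chrom_length_bp)
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1, size=n_loci))
        extra = [q.pos for q in cfg.qtl_loci if q.chrom == c]
        if extra:
            pos = np.unique(np.concatenate([pos, np.asarray(extra, dtype=np.int64)]))
        positions.append(pos.astype(np.int64))
        chroms.append(np.full(pos.size, cfg.chrom_name(c)))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    if pos.size == 0:
        raise ValueError("zero loci generated; raise snp_density or chrom_length_bp")

    dosage_a = rng.integers(0, PLOIDY + 1, size=pos.size)
    dosage_e = rng.integers(0, PLOIDY + 1, size=pos.size)

    qtl_index = np.empty(len(cfg.qtl_loci), dtype=np.int64)
    for i, q in enumerate(cfg.qtl_loci):
        (idx,) = np.nonzero((chrom == cfg.chrom_name(q.chrom)) & (pos == q.pos))
        qtl_index[i] = idx[0]
        if q.tolerant_parent == "A":
            dosage_a[idx[0]] = cfg.qtl_dosage_tolerant
            dosage_e[idx[0]] = cfg.qtl_dosage_other
        else:
            dosage_e[idx[0]] = cfg.qtl_dosage_tolerant
            dosage_a[idx[0]] = cfg.qtl_dosage_other

    ref_i = rng.integers(0, 4, size=pos.size)
    alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
    return Parents(
        chrom=chrom,
        pos=pos,
        ref=_BASES[ref_i],
        alt=_BASES[alt_i],
        hap_a=_haplotypes_from_dosage(dosage_a, rng),
        hap_e=_haplotypes_from_dosage(dosage_e, rng),
        qtl_index=qtl_index,
        cfg=cfg,
    )


def _block_ids(parents: Parents, linkage_block_bp: int | None) -> np.ndarray:
    """Gamete-draw block id per locus: one block per locus when unlinked,
    otherwise one per ``linkage_block_bp`` window per chromosome."""
    if linkage_block_bp is None:
        return np.arange(parents.n_loci)
    codes, _ = pd.factorize(parents.chrom)
    within = parents.pos // int(linkage_block_bp)
    _, ids = np.unique(np.stack([codes, within]), axis=1, return_inverse=True)
    return ids


def _sample_gametes(
    hap: np.ndarray,
    n_gametes: int,
    block: np.ndarray,
    double_reduction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamete alt-dosage matrix (n_gametes, n_loci) under bivalent pairing.

    One homolog-pair choice per block; with probability ``double_reduction``
    a block instead receives two copies of a single homolog.
    """
    pair_sums = np.stack([hap[i] + hap[j] for i, j in GAMETE_PAIRS])  # (6, n_loci)
    dr_sums = 2 * hap  # (4, n_loci)
    outcomes = np.concatenate([pair_sums, dr_sums])  # (10, n_loci)
    n_blocks = int(block.max()) + 1
    choice = rng.integers(0, len(GAMETE_PAIRS), size=(n_gametes, n_blocks))
    if double_reduction > 0:
        is_dr = rng.random((n_gametes, n_blocks)) < double_reduction
        dr_choice = len(GAMETE_PAIRS) + rng.integers(0, PLOIDY, size=(n_gametes, n_blocks))
        choice = np.where(is_dr, dr_choice, choice)
    per_locus = choice[:, block]  # (n_gametes, n_loci)
    locus_idx = np.arange(outcomes.shape[1])
    return outcomes[per_locus, locus_idx[None, :]]


def simulate_f1(
    parents: Parents,
    n_f1: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """F1 dosage matrix (n_f1, n_loci): gamete from A plus gamete from E.

    Linkage and double-reduction behaviour come from ``parents.cfg``.
    """
    if n_f1 < 1:
        raise ValueError("n_f1 must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = parents.cfg
    block = _block_ids(parents, cfg.linkage_block_bp)
    ga = _sample_gametes(parents.hap_a, n_f1, block, cfg.double_reduction, rng)
    ge = _sample_gametes(parents.hap_e, n_f1, block, cfg.double_reduction, rng)
    return (ga + ge).astype(np.int8)


def genotype_ids(n_f1: int) -> list[str]:
    return [f"F1_{i:03d}" for i in range(n_f1)]


def simulate_phenotypes(
    f1: np.ndarray,
    parents: Parents,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format starch-yield table for each genotype x experiment x treatment.

    Control yield is drawn per genotype x experiment; stress yield is
    control times a genotype-specific relative yield
    base_relsy + sum_q effect_q * (dosage_q - 2) / 2 + Normal(0, residual_sd),
    clipped at zero.  Row count is n_f1 * n_experiments * 2.
    """
    if f1.shape[0] == 0:
        raise ValueError("no F1 genotypes supplied")
    cfg = parents.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ids = genotype_ids(f1.shape[0])
    genetic = np.zeros(f1.shape[0])
    for q, idx in zip(cfg.qtl_loci, parents.qtl_index):
        genetic += q.effect * (f1[:, idx].astype(float) - 2.0) / 2.0

    rows = []
    for e in range(1, cfg.n_experiments + 1):
        exp_id = f"E{e}"
        control = rng.normal(cfg.control_yield_mean, cfg.control_yield_sd, size=len(ids))
        control = np.clip(control, 0.0, None)
        relsy = cfg.base_relsy + genetic + rng.normal(0.0, cfg.residual_sd, size=len(ids))
        stress = np.clip(control * relsy, 0.0, None)
        for g, c, s in zip(ids, control, stress):
            rows.append((g, exp_id, "control", c))
            rows.append((g, exp_id, "stress", s))
    return pd.DataFrame(rows, columns=["genotype", "experiment", "treatment", "starch_yield"])


# ---------------------------------------------------------------------------
# pooled sequencing


def pool_alt_frequency(dosages: np.ndarray) -> np.ndarray:
    """True pool alt-allele frequency: mean dosage / 4 (equimolar pooling)."""
    return dosages.mean(axis=0) / PLOIDY if dosages.ndim == 2 else dosages / PLOIDY


def simulate_pool_counts(
    freq: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(depth, alt read count) per locus for a pool with true alt frequency
    ``freq``: depth is negative-binomial with mean ``coverage_mean`` and
    variance m + dispersion*m^2 (Poisson at dispersion 0); alt reads are
    binomial with error-perturbed success probability f(1-e) + (1-f)e."""
    m = cfg.coverage_mean
    k = cfg.coverage_dispersion
    if k > 0:
        depth = rng.negative_binomial(1.0 / k, 1.0 / (1.0 + k * m), size=freq.size)
    else:
        depth = rng.poisson(m, size=freq.size)
    e = cfg.seq_error_rate
    p = freq * (1.0 - e) + (1.0 - freq) * e
    alt = rng.binomial(depth, p)
    return depth, alt


def _gq_from_depth(depth: np.ndarray) -> np.ndarray:
    """GQ proxy: 99 for confidently covered sites, scaled down at low depth."""
    return np.minimum(99, 7 * depth).astype(int)


def counts_to_table(parents: Parents, depth: np.ndarray, alt: np.ndarray) -> pd.DataFrame:
    """Variant table in the layout the vcfio reader produces."""
    informative = depth  # all reads informative in this generator
    ad_ref = informative - alt
    denom = np.maximum(informative, 1)
    return pd.DataFrame(
        {
            "chrom": parents.chrom,
            "pos": parents.pos,
            "ref": parents.ref,
            "alt": parents.alt,
            "ad_ref": ad_ref,
            "ad_alt": alt,
            "dp": depth,
            "gq": _gq_from_depth(depth),
            "af": alt / denom,
            "is_snp": True,
        }
    )


def simulate_bulk_counts(
    parents: Parents, member_dosages: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """In-memory pooled-sequencing table for a bulk of F1 dosage rows."""
    freq = pool_alt_frequency(member_dosages)
    depth, alt = simulate_pool_counts(freq, parents.cfg, rng)
    return counts_to_table(parents, depth, alt)


def _vcf_header(cfg: SimConfig, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in range(1, cfg.n_chromosomes + 1):
        header.contigs.add(cfg.chrom_name(c), length=cfg.chrom_length_bp)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample)
    return header


def write_pool_vcf(
    parents: Parents, table: pd.DataFrame, out_path: str, sample: str
) -> str:
    """Write a single-sample VCF 4.2 with GT/AD/DP/GQ for one pool."""
    cfg = parents.cfg
    header = _vcf_header(cfg, sample)
    try:
        out = pysam.VariantFile(str(out_path), "w", header=header)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot write VCF to {out_path}: {exc}") from exc
    with out:
        for row in table.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            dp = int(row.dp)
            ad_alt = int(row.ad_alt)
            ad_ref = int(row.ad_ref)
            if ad_alt == 0:
                gt = (0, 0)
            elif ad_ref == 0:
                gt = (1, 1)
            else:
                gt = (0, 1)
            rec.samples[sample]["GT"] = gt
            rec.samples[sample]["AD"] = (ad_ref, ad_alt)
            rec.samples[sample]["DP"] = dp
            rec.samples[sample]["GQ"] = int(row.gq)
            out.write(rec)
    return str(out_path)


def simulate_bulk_vcf(
    parents: Parents,
    member_dosages: np.ndarray,
    out_path: str,
    sample: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate pooled sequencing of a bulk and write it as a VCF.

    Returns the underlying count table (same content the VCF carries).
    """
    table = simulate_bulk_counts(parents, member_dosages, rng)
    write_pool_vcf(parents, table, out_path, sample)
    return table


def simulate_parent_vcf(
    parents: Parents, which: str, out_path: str, sample: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Sequence one parent as a pool of its own four homologs (f = dosage/4)."""
    dosage = parents.dosage_a if which == "A" else parents.dosage_e
    freq = pool_alt_frequency(dosage.astype(float))
    depth, alt = simulate_pool_counts(freq, parents.cfg, rng)
    table = counts_to_table(parents, depth, alt)
    write_pool_vcf(parents, table, out_path, sample)
    return table


# ---------------------------------------------------------------------------
# annotation

GENE_LENGTH = 3000
GENE_SPACING = 5000
UTR5_LEN = 300
UTR3_LEN = 200
EXON_LEN = 400
_CODING_WEIGHTS = {"missense": 0.5, "nonsense": 0.05, "synonymous": 0.45}


def _gene_models(cfg: SimConfig) -> pd.DataFrame:
    """Non-overlapping gene models tiled along every chromosome."""
    rows = []
    gid = 0
    for c in range(1, cfg.n_chromosomes + 1):
        start = 1000
        while start + GENE_LENGTH <= cfg.chrom_length_bp:
            gid += 1
            rows.append(
                (
                    f"gene{gid:05d}",
                    cfg.chrom_name(c),
                    start,
                    start + GENE_LENGTH - 1,
                    "+" if gid % 2 else "-",
                )
            )
            start += GENE_SPACING
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _classify_position(pos: int, gene: tuple, rng: np.random.Generator) -> str:
    """Effect class for a SNP inside a gene model, strand-aware."""
    _, _, start, end, strand = gene
    off5 = pos - start if strand == "+" else end - pos
    off3 = end - pos if strand == "+" else pos - start
    if off5 < UTR5_LEN:
        return "5'UTR"
    if off3 < UTR3_LEN:
        return "3'UTR"
    coding_off = off5 - UTR5_LEN
    if (coding_off // EXON_LEN) % 2 == 0:  # alternating exon/intron blocks
        classes = list(_CODING_WEIGHTS)
        return classes[rng.choice(len(classes), p=list(_CODING_WEIGHTS.values()))]
    return "intron"


def simulate_annotation(
    parents: Parents, gff_path: str, effects_path: str, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile gene models over the genome, write GFF3, and assign each locus a
    positionally consistent effect class (written as a 4-column TSV)."""
    cfg = parents.cfg
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    genes = _gene_models(cfg)

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in range(1, cfg.n_chromosomes + 1):
            fh.write(f"##sequence-region {cfg.chrom_name(c)} 1 {cfg.chrom_length_bp}\n")
        for g in genes.itertuples(index=False):
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.chrom}\tbulkseg\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tbulkseg\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )

    eff_rows = []
    for chrom_name, grp in genes.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        mask = parents.chrom == chrom_name
        loci_pos = parents.pos[mask]
        gi = np.searchsorted(starts, loci_pos, side="right") - 1
        for p, i in zip(loci_pos, gi):
            if i >= 0 and p <= grp.iloc[i]["end"]:
                g = tuple(grp.iloc[i])
                eff_rows.append((chrom_name, int(p), _classify_position(int(p), g, rng), g[0]))
            else:
                eff_rows.append((chrom_name, int(p), "intergenic", "."))
    effects = pd.DataFrame(eff_rows, columns=["chrom", "pos", "effect", "gene_id"])
    effects.to_csv(effects_path, sep="\t", index=False)
    return genes, effects


# ---------------------------------------------------------------------------
# association panel


def simulate_panel(
    snp_keys: Sequence[tuple[str, int, str]],
    causal_keys: Sequence[tuple[str, int, str]],
    n_varieties: int = 34,
    causal_shift: float = 0.4,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel genotypes plus a DRYM-style tolerance ranking.

    Each variety gets a latent tolerance score; at causal SNPs the
    alt-carrying probability is shifted by ``causal_shift`` between the
    tolerant and sensitive halves, other SNPs are independent of the score.
    Returns (long genotype table, ranking table sorted most-tolerant first).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    varieties = [f"V{i:02d}" for i in range(1, n_varieties + 1)]
    score = rng.normal(0.0, 0.1, size=n_varieties)
    order = np.argsort(-score)
    tolerant_half = set(np.asarray(varieties)[order[: n_varieties // 2]])
    causal = set(causal_keys)
    rows = []
    for key in snp_keys:
        base = rng.uniform(0.2, 0.8)
        for v in varieties:
            p = base
            if key in causal:
                p = np.clip(base + (causal_shift if v in tolerant_half else -causal_shift) / 2, 0.02, 0.98)
            state = "alt" if rng.random() < p else "ref"
            rows.append((v, key[0], key[1], key[2], state))
    panel = pd.DataFrame(rows, columns=["variety", "chrom", "pos", "alt", "allele_state"])
    ranking = pd.DataFrame(
        {"variety": np.asarray(varieties)[order], "drym": np.sort(score)[::-1]}
    )
    ranking["rank"] = np.arange(1, n_varieties + 1)
    return panel, ranking


def default_config(**overrides) -> SimConfig:
    """Study-shaped default scenario: one planted QTL of effect 0.2 whose
    tolerance allele comes from parent A, on a 5 x 5 Mbp genome."""
    cfg = SimConfig(qtl_loci=[QtlLocus(chrom=1, pos=2_500_000, effect=0.2, tolerant_parent="A")])
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
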