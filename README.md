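# bulkseg

Bulked-segregant QTL mapping (BSA-Seq) for autotetraploid crosses, built
around the drought-tolerance design used in starch potato breeding: two
tetraploid parents, an F1 clone population phenotyped for starch yield
under drought stress and control irrigation, pooled whole-genome
sequencing of the two phenotypic-extreme bulks, and a targeted SNP panel
for downstream association in a variety collection.

It is aimed at plant geneticists who want a tested, scriptable version of
this analysis chain that runs offline: every stage can be exercised on a
built-in generative model of the tetraploid cross, so pipelines can be
validated before (or without) touching real sequencing data.

## What it computes

**Phenotype.** Per genotype *G* and experiment *E*,

    RelSY_GE = SY_GE(stress) / SY_GE(control)
    DRYM_GE  = RelSY_GE − median_G(RelSY_GE)

where SY is tuber starch yield (mass × starch content). DRYM > 0 means
more drought tolerant than the experiment's median. Genotypes are ranked
by DRYM per experiment; mean ranks across experiments define the tolerant
and sensitive bulks (default 20 clones each), whose separation is tested
with Welch's *t*.

**QTL scan.** At each SNP the 2×2 table of (ref, alt) read depths in the
two bulks gives the likelihood-ratio statistic G = 2·Σ nᵢ ln(nᵢ/n̂ᵢ). G′ is
the tricube-weighted mean of G over a 1 Mbp window. A log-normal null is
fitted robustly (median/MAD of ln G′) on SNPs with |ΔSNP| < 0.1, giving
per-SNP p-values; Bonferroni-significant runs (p < 0.01) become QTL
intervals summarized by span, overlapping gene count and ceiling gene
density (genes/Mbp).

**Filters.** Bulk SNPs are kept for the scan when 20 ≤ DP ≤ 360,
0.10 ≤ AF ≤ 0.90 and GQ ≥ 99 (all bounds inclusive), SNPs only.

**Candidate selection.** Round 1: bulk-exclusive SNPs in curated
literature genes under the QTLs, searching the gene extent plus 2000 bp
5′ / 500 bp 3′ flanks, at most 3 SNPs per gene by severity-then-position.
Round 2: missense/nonsense bulk-exclusive SNPs in any gene under a QTL.

**Association.** The variety panel is split at the DRYM-ranking median
(17 vs 17 for 34 varieties); each panel SNP gets a two-sided Fisher exact
p on carriers × group (significant at p < 0.05) and a Kruskal–Wallis test
with effect size η² = (H − k + 1)/(n − k).

## Worked example

Run the whole chain on a simulated cross with one planted QTL
(effect 0.2 on RelSY at chr01:1,000,000):

```yaml
# demo.yaml
seed: 3
simulate:
  n_chromosomes: 3
  chrom_length_bp: 2000000
  snp_density: 0.0002
  linkage_block_bp: 500000
  coverage_mean: 80
  qtl_loci:
    - {chrom: 1, pos: 1000000, effect: 0.2, tolerant_parent: A}
```

```sh
$ bulkseg run --config demo.yaml --out demo_out --seed 3
{
  "simulate": "complete",
  "drym": "complete",
  "bulks": "complete",
  "filter": "complete",
  "scan": "complete",
  "attribute": "complete",
  "select": "complete",
  "assoc": "complete"
}
$ cat demo_out/qtl_table.tsv
qtl  chrom  start_bp  end_bp   area_bp  n_genes  gene_density  n_snps_total  n_snps_unique_to_a_bulk
1    chr01  921092    1535661  614569   123      201           114           23
```

The single called interval (chr01:921,092–1,535,661) covers the planted
locus: its span is `end − start` = 614,569 bp, it overlaps 123 simulated
gene models, and `gene_density` = ⌈123 / 0.614569⌉ = 201 genes/Mbp. The
`manifest.json` in the output directory records per-stage record counts
(e.g. input SNPs → filtered SNPs → difference SNPs → candidates) and the
Welch separation of the bulks' DRYM values. Each stage is also available
as its own subcommand (`bulkseg drym`, `bulkseg bulks`, `bulkseg filter`,
`bulkseg scan`, `bulkseg attribute`, `bulkseg windows`, `bulkseg assoc`)
and as plain library functions.

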