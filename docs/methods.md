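# Methods

## The analysis chain

bulkseg implements bulked-segregant analysis on pooled whole-genome
sequencing (BSA-Seq) for an autotetraploid biparental cross. The chain
is: phenotype indices (RelSY, DRYM) → rank-based bulk selection → bulk
VCF filtering → per-SNP G statistic with tricube-smoothed G′ and a
log-normal null → QTL interval calling and summarization → parental
attribution of bulk SNPs → two-round candidate-SNP selection → Fisher /
Kruskal–Wallis association in a variety panel. Each stage is a module
with a stable DataFrame-in / DataFrame-out surface; the pipeline module
wires them together behind one YAML config.

## Phenotype model

RelSY = SY(stress)/SY(control) per genotype × experiment; DRYM subtracts
the experiment median of RelSY. DRYM is therefore conserved (median zero
within each experiment) and invariant to rescaling all yields of an
experiment — both properties are asserted in tests. Bulk selection ranks
genotypes by DRYM within each experiment (average ranks on ties, matching
the default of standard ranking procedures), averages ranks over the
experiments a genotype appears in, and takes the two tails. Orientation
is re-checked against mean DRYM so the "tolerant" bulk is never a label
accident. Outlier flagging is a configurable Tukey rule (1.5·IQR on
per-experiment DRYM), off by default: the original analysis used an
external method that is not reproducible from its description, so the
package ships its own explicit rule instead.

## Sequencing filters

Bulk SNPs enter the scan when 20 ≤ DP ≤ 360, 0.10 ≤ AF ≤ 0.90, GQ ≥ 99,
SNPs only. The stated exclusions are strict ("below 20", "above 90%"),
so all endpoints are inclusive; boundary fixtures pin this down. AF is
computed from allele depths, AD_alt/(AD_ref + ΣAD_alt); for multiallelic
sites each alt is apportioned against the full site depth, a conservative
choice that cannot exceed the biallelic frequency. DP ≥ AD_ref + AD_alt
is *not* assumed (uninformative reads). Records missing DP/AF/GQ fail
closed and are tallied separately.

## G′ scan

G is the standard 2×2 likelihood-ratio statistic on bulk read counts;
zero cells contribute nothing and a zero margin gives G = 0. G′ averages
G with tricube weights w = (1 − (d/h)³)³ over neighbours within
h = windowSize/2 = 500 kbp of the focal SNP (windowSize = 1 Mbp spans the
whole window). The null is fitted on SNPs with |ΔSNP| < 0.1 — sites with
no allele-frequency contrast between bulks, hence unlikely to be linked
to a QTL — as a log-normal with μ = median(ln G′) and σ = 1.4826·MAD,
robust against contamination by true signal. P-values are upper-tail
survival probabilities; Benjamini–Hochberg q-values are attached, and
interval calling defaults to the Bonferroni rule p < α/n with α = 0.01.
Intervals span the outermost significant SNPs (reproducible from discrete
data, unlike threshold interpolation); runs closer than one window are
merged. Requiring at least 50 null-subset SNPs guards the fit; the error
message suggests raising the threshold.

Interval summaries use span = end − start (no +1) and gene density
⌈genes / (span/10⁶)⌉; both conventions are forced by checking all fifteen
published rows of the reference QTL table shipped in
`bulkseg/data/exa_qtl_regions.tsv` (the totals-row density is the plain
mean of the per-interval ceiling densities, one decimal). A gene counts
when any basepair overlaps the interval; the rule is exposed in config
because published gene counts depend on the annotation used.

## Parental attribution

A bulk SNP is A-only / E-only / both / neither according to presence in
the parents' *unfiltered* call sets — using filtered parent calls would
inflate "unique" SNPs whenever a real parental SNP narrowly fails a
filter. Presence still requires minimal read evidence (≥3 alt reads and
AF ≥ 0.02 in the pooled-parent model) so stray error reads do not
register; with default error rates this keeps attribution accuracy of
truly parent-exclusive SNPs above 99% at 80×. Rolling windows (1 Mbp,
step 0.5 Mbp) anchor at position 1 per chromosome, keep the final partial
window, and reduce exactly to disjoint tiling when step = size.

## Candidate selection

Round 1 searches literature genes under the QTLs within the annotated
gene extent extended strand-aware by 2000 bp (5′) and 500 bp (3′): fixed
flank sizes cannot be annotation UTRs, so they are interpreted as flanking
windows. The per-gene cap is 3 with priority nonsense > missense >
synonymous > UTR > intron > upstream/downstream, ties broken by position;
the severity ordering follows variant-annotation convention (coding
changes above modifier classes), since the original selection did not
state how it chose among surplus SNPs. Round 2 admits only missense and
nonsense difference SNPs in any gene under a QTL, minus round-1 SNP keys;
the combined panel is de-duplicated at the SNP level and reported with
both per-round and gene-level-deduplicated tallies. Probe design needs
±200 bp flanks, exported as BED. The design-yield helper truncates (not
rounds) percentages to one decimal, matching the convention of the
reported figures it reproduces.

## Association

The ranked panel splits at the median; with odd n the middle variety goes
to the sensitive group. Genotypes are dichotomized as presence/absence of
the alt allele per variety — the only dichotomy available from
presence-style targeted-genotyping spreadsheets; a dosage-class mode
feeds the Kruskal–Wallis path. Fisher p-values are two-sided exact
(scipy), verified in tests against an exhaustive hypergeometric
enumeration oracle for every table with n ≤ 30. No multiple-testing
correction is applied to the panel (raw p at 0.05, as in the original
design); BH q-values are emitted informationally. η² = (H − k + 1)/(n − k)
can be slightly negative under the null; it is reported as computed.

## Synthetic cross generator

The generator emulates the study conditions end to end:

- **Loci**: Poisson placement at `snp_density` (default 2×10⁻⁴/bp over
  5 × 5 Mbp chromosomes — a desk-scale genome, not the 840 Mbp potato
  genome); parental dosages uniform on {0..4}, so a fifth of loci are
  reference-vs-cultivar SNPs shared by both parents, mimicking the
  dominance of reference-genome differences in real tetraploid calls.
- **Inheritance**: each parent's four homologs are explicit haplotypes; a
  gamete takes two of four uniformly (random bivalent pairing), giving the
  hypergeometric gamete-dosage law C(d,k)C(4−d,2−k)/C(4,2). Double
  reduction is available (default 0). Loci are unlinked by default;
  block-linkage mode makes all loci in a window share one gamete draw,
  producing the correlated allele-frequency signal around a QTL that
  smoothing is meant to exploit.
- **QTLs**: a planted locus fixes the tolerant parent at dosage 3 and the
  other at 1, so offspring segregate 1..3 and the effect allele traces
  predominantly to the named parent. The phenotype is
  RelSY = 0.6 + Σ effect·(dosage−2)/2 + N(0, 0.05), times a normal control
  yield (100 ± 10), clipped at zero. Effect 0.2 with residual 0.05 gives
  bulk mean DRYM near ±0.1 and a decisive Welch separation, the regime the
  published bulks sit in.
- **Sequencing**: pool alt frequency is mean dosage/4 (equimolar pooling
  of clones — the DNA-pooling protocol is not specified in the original,
  equal contribution is assumed); depth is negative-binomial (mean 120×,
  dispersion 0.2; Poisson at dispersion 0) because real WGS is
  overdispersed; alt reads are binomial with error-perturbed success
  f(1−e)+(1−f)e, e = 0.002. GQ is 99 at confident depth and degrades
  linearly below ~15×, so the GQ filter is exercisable.
- **Annotation**: non-overlapping 3 kbp gene models every 5 kbp with
  strand-aware UTR/exon/intron zones; effect classes are drawn
  consistently with position (coding SNPs are missense/nonsense/synonymous
  at 0.50/0.05/0.45). An association panel generator produces
  presence/absence genotypes with a tunable carrier-probability shift at
  causal SNPs.

What the generator does **not** model: read-level artifacts (mapping
error, indel realignment, reference bias), linkage disequilibrium decay
within blocks (linkage is all-or-nothing per block), segregation
distortion, genotype-calling error structure beyond binomial sampling,
population structure in the panel, and realistic gene-density variation.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated sampling model, not robustness to alignment
or calling artifacts in real data.

## Problem sizes and numerical choices

The recovery experiment uses 5 chromosomes × 5 Mbp at 2×10⁻⁴ SNPs/bp
(~5,000 loci), 100 F1, bulks of 20, 80× coverage, 1 Mbp linkage blocks —
small enough to run a replicate in under a second while leaving ~4,000
SNPs after filtering, enough for a stable null fit. Ten seeded replicates
recover the planted QTL (called interval within one window of the locus)
and keep non-QTL chromosomes clean. Null calibration simulates 10⁴
log-normal G′ values with no signal and checks the fraction of p < 0.01.
Degenerate cases are pinned by convention: G = 0 at zero margins; Welch
t = 0, p = 1 for identical zero-variance groups; sd = 0 for single-SNP
windows; p = 1 for monomorphic panel SNPs. Ranking uses stable sorts
throughout so ties resolve deterministically.
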