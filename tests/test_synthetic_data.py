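"""Generator checks: locus placement, tetrasomic gamete law, phenotype
model, pooled sequencing and annotation consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkseg import synthetic_data as sd
from bulkseg import vcfio


def test_locus_count_tracks_density():
    cfg = sd.SimConfig(n_chromosomes=1, chrom_length_bp=1_000_000, snp_density=1e-3, seed=5)
    parents = sd.simulate_parents(cfg)
    # Poisson(1000): 5 sigma ~ 158
    assert abs(parents.n_loci - 1000) < 160


def test_zero_loci_is_an_error():
    cfg = sd.SimConfig(n_chromosomes=1, chrom_length_bp=100, snp_density=1e-9, seed=1)
    with pytest.raises(ValueError, match="zero loci"):
        sd.simulate_parents(cfg)


def test_full_determinism_under_fixed_seed(small_cfg):
    def run():
        rng = np.random.default_rng(small_cfg.seed)
        parents = sd.simulate_parents(small_cfg, rng)
        f1 = sd.simulate_f1(parents, small_cfg.n_f1, rng)
        pheno = sd.simulate_phenotypes(f1, parents, rng)
        counts = sd.simulate_bulk_counts(parents, f1[:20], rng)
        return parents, f1, pheno, counts

    p1, f1a, ph1, c1 = run()
    p2, f1b, ph2, c2 = run()
    assert np.array_equal(p1.pos, p2.pos)
    assert np.array_equal(p1.hap_a, p2.hap_a)
    assert np.array_equal(f1a, f1b)
    pd.testing.assert_frame_equal(ph1, ph2)
    pd.testing.assert_frame_equal(c1, c2)


def test_parent_dosage_prior_is_uniform():
    cfg = sd.SimConfig(n_chromosomes=1, chrom_length_bp=10_000_000, snp_density=1e-2, seed=7)
    parents = sd.simulate_parents(cfg)
    n = parents.n_loci
    assert n > 90_000
    counts = np.bincount(parents.dosage_a, minlength=5)
    # multinomial: sd per cell = sqrt(n p (1-p)), p = 1/5
    sdev = np.sqrt(n * 0.2 * 0.8)
    assert np.all(np.abs(counts - n / 5) < 3 * sdev)


@pytest.mark.parametrize(
    "dosage,expected_pmf",
    [
        (0, {0: 1.0}),
        (1, {0: 0.5, 1: 0.5}),
        (2, {0: 1 / 6, 1: 4 / 6, 2: 1 / 6}),
        (3, {1: 0.5, 2: 0.5}),
        (4, {2: 1.0}),
    ],
)
def test_gamete_dosage_follows_hypergeometric(dosage, expected_pmf):
    """Random bivalent pairing: gamete k alt alleles with pmf
    C(d,k) C(4-d,2-k) / C(4,2) — checked by chi-square GOF at n=1e5."""
    n = 100_000
    cfg = sd.SimConfig(n_chromosomes=1, chrom_length_bp=1000, snp_density=1e-3, seed=3)
    rng = np.random.default_rng(13)
    hap = sd._haplotypes_from_dosage(np.array([dosage]), rng)
    gam = sd._sample_gametes(hap, n, np.array([0]), 0.0, rng)[:, 0]
    # cross-check the stated pmf against scipy's hypergeometric law
    for k, p in expected_pmf.items():
        assert stats.hypergeom(4, dosage, 2).pmf(k) == pytest.approx(p)
    obs = np.bincount(gam, minlength=3)
    exp = np.array([expected_pmf.get(k, 0.0) for k in range(3)]) * n
    keep = exp > 0
    assert np.all(obs[~keep] == 0)
    if keep.sum() > 1:
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001


def test_phenotypes_degenerate_model_is_constant(small_cross):
    parents, f1 = small_cross
    cfg = sd.SimConfig(
        n_chromosomes=parents.cfg.n_chromosomes,
        chrom_length_bp=parents.cfg.chrom_length_bp,
        residual_sd=0.0,
        control_yield_sd=0.0,
        n_experiments=2,
    )
    p2 = sd.Parents(**{**parents.__dict__, "cfg": cfg, "qtl_index": np.empty(0, dtype=int)})
    pheno = sd.simulate_phenotypes(f1, p2)
    relsy = (
        pheno.pivot_table(index=["genotype", "experiment"], columns="treatment",
                          values="starch_yield")
        .eval("stress / control")
    )
    assert np.allclose(relsy, cfg.base_relsy)


def test_phenotype_qtl_effect_is_additive_in_dosage():
    """With one QTL of effect 0.2 and no noise, dosage-4 genotypes sit
    exactly 0.2 above dosage-2 genotypes in RelSY."""
    cfg = sd.SimConfig(
        n_chromosomes=1, chrom_length_bp=1000, snp_density=2e-3,
        qtl_loci=[sd.QtlLocus(1, 500, 0.2, "A")],
        residual_sd=0.0, control_yield_sd=0.0, n_experiments=1, seed=2,
    )
    parents = sd.simulate_parents(cfg)
    qi = parents.qtl_index[0]
    f1 = np.full((2, parents.n_loci), 2, dtype=np.int8)
    f1[0, qi] = 4
    f1[1, qi] = 2
    pheno = sd.simulate_phenotypes(f1, parents)
    wide = pheno.pivot_table(index="genotype", columns="treatment", values="starch_yield")
    relsy = wide["stress"] / wide["control"]
    assert relsy["F1_000"] - relsy["F1_001"] == pytest.approx(0.2)


def test_phenotype_row_count(small_cross):
    parents, f1 = small_cross
    pheno = sd.simulate_phenotypes(f1, parents)
    assert len(pheno) == f1.shape[0] * parents.cfg.n_experiments * 2


def test_pool_zero_frequency_zero_error_gives_zero_alt():
    cfg = sd.SimConfig(seq_error_rate=0.0, coverage_mean=50)
    rng = np.random.default_rng(0)
    depth, alt = sd.simulate_pool_counts(np.zeros(5000), cfg, rng)
    assert alt.sum() == 0


def test_pool_half_frequency_recovers_af_within_binomial_ci():
    cfg = sd.SimConfig(seq_error_rate=0.0, coverage_mean=200, coverage_dispersion=0.0)
    rng = np.random.default_rng(1)
    n = 20_000
    depth, alt = sd.simulate_pool_counts(np.full(n, 0.5), cfg, rng)
    af = alt / depth
    se = np.sqrt(0.25 / depth.mean() / n)
    assert abs(af.mean() - 0.5) < 4 * se


def test_bulk_vcf_round_trips_through_reader(small_cross, tmp_path):
    parents, f1 = small_cross
    rng = np.random.default_rng(9)
    path = tmp_path / "bulk.vcf"
    table = sd.simulate_bulk_vcf(parents, f1[:20], path, "HROEXATOL", rng)
    back = vcfio.read_vcf(path)
    assert len(back) == len(table)
    for col in ("chrom", "pos", "ref", "alt"):
        assert np.array_equal(back[col].to_numpy(), table[col].to_numpy())
    for col in ("ad_ref", "ad_alt", "dp", "gq"):
        assert np.array_equal(back[col].to_numpy().astype(int), table[col].to_numpy())


def test_annotation_effect_table_agrees_with_gff(small_cross, tmp_path):
    """Every locus's effect class must be positionally consistent with the
    gene models: checked by an independent interval lookup."""
    from intervaltree import IntervalTree

    parents, _ = small_cross
    genes, effects = sd.simulate_annotation(
        parents, tmp_path / "genes.gff3", tmp_path / "effects.tsv",
        np.random.default_rng(4),
    )
    trees = {}
    for g in genes.itertuples(index=False):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    genic = {"missense", "nonsense", "synonymous", "intron", "5'UTR", "3'UTR"}
    for row in effects.itertuples(index=False):
        hits = trees[row.chrom][row.pos]
        if row.effect == "intergenic":
            assert not hits and row.gene_id == "."
        else:
            assert row.effect in genic
            assert {h.data for h in hits} == {row.gene_id}
    # and the GFF written to disk round-trips to the same gene set
    from bulkseg.selection import load_gene_models

    loaded = load_gene_models(tmp_path / "genes.gff3")
    assert set(loaded["gene_id"]) == set(genes["gene_id"])
    assert np.array_equal(
        loaded.sort_values("gene_id")[["start", "end"]].to_numpy(),
        genes.sort_values("gene_id")[["start", "end"]].to_numpy(),
    )


def test_delta_snp_centred_at_zero_without_qtl():
    """Random bulks from a cross with no QTL: mean delta-SNP over ~1e4 loci
    within 3 standard errors of zero."""
    cfg = sd.SimConfig(
        n_chromosomes=2, chrom_length_bp=5_000_000, snp_density=1e-3,
        coverage_mean=80, seed=21,
    )
    rng = np.random.default_rng(cfg.seed)
    parents = sd.simulate_parents(cfg, rng)
    f1 = sd.simulate_f1(parents, 40, rng)
    tol = sd.simulate_bulk_counts(parents, f1[:20], rng)
    sen = sd.simulate_bulk_counts(parents, f1[20:], rng)
    delta = tol["af"] - sen["af"]
    se = delta.std(ddof=1) / np.sqrt(len(delta))
    assert abs(delta.mean()) < 3 * se


def test_planted_qtl_creates_selection_signal():
    """Selecting bulks by extreme phenotype shifts allele frequency at the
    QTL locus: |delta-SNP| there exceeds the genome-wide mean (one-sided
    t over 10 replicates, p < 0.01)."""
    from bulkseg import phenotype as ph

    excess = []
    for seed in range(10):
        cfg = sd.SimConfig(
            n_chromosomes=2, chrom_length_bp=2_000_000, snp_density=2e-4,
            qtl_loci=[sd.QtlLocus(1, 1_000_000, 0.2, "A")],
            coverage_mean=80, seed=100 + seed,
        )
        rng = np.random.default_rng(cfg.seed)
        parents = sd.simulate_parents(cfg, rng)
        f1 = sd.simulate_f1(parents, 100, rng)
        pheno = sd.simulate_phenotypes(f1, parents, rng)
        drym = ph.compute_drym(ph.compute_relsy(pheno))
        bulks = ph.select_bulks(drym, n_bulk=20)
        ids = sd.genotype_ids(100)
        idx = {g: i for i, g in enumerate(ids)}
        tol = sd.simulate_bulk_counts(parents, f1[[idx[g] for g in bulks.tolerant_ids]], rng)
        sen = sd.simulate_bulk_counts(parents, f1[[idx[g] for g in bulks.sensitive_ids]], rng)
        delta = np.abs(tol["af"].to_numpy() - sen["af"].to_numpy())
        qi = parents.qtl_index[0]
        excess.append(delta[qi] - delta.mean())
    t, p = stats.ttest_1samp(excess, 0.0, alternative="greater")
    assert p < 0.01
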