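"""Two-round candidate selection, effect parsing, and panel invariants."""

import numpy as np
import pandas as pd
import pytest

from bulkseg import selection
from conftest import write_text_vcf


@pytest.fixture
def plus_gene():
    return pd.DataFrame(
        {"gene_id": ["gA"], "chrom": ["chr01"], "start": [10_000], "end": [13_000],
         "strand": ["+"]}
    )


def _diff_snps(positions, chrom="chr01"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "alt": "T", "is_difference": True}
    )


def _cfg(genes, **kw):
    intervals = pd.DataFrame(
        {"chrom": ["chr01"], "start_bp": [1], "end_bp": [10_000_000]}
    )
    return selection.SelectionConfig(
        literature_genes=set(genes), qtl_intervals=intervals, **kw
    )


class TestRound1:
    def test_snp_within_5prime_window_included(self, plus_gene):
        snps = _diff_snps([8_500])  # 1500 bp 5' of a + strand gene
        out = selection.round1_select(snps, plus_gene, pd.DataFrame(), _cfg(["gA"]))
        assert len(out) == 1
        assert out.iloc[0]["effect"] == "upstream"

    def test_snp_beyond_3prime_window_excluded(self, plus_gene):
        snps = _diff_snps([13_601])  # 601 bp 3' of the gene end
        out = selection.round1_select(snps, plus_gene, pd.DataFrame(), _cfg(["gA"]))
        assert len(out) == 0

    def test_minus_strand_windows_are_mirrored(self, plus_gene):
        gene = plus_gene.assign(strand="-")
        # 5' flank of a - strand gene is beyond its end coordinate
        assert len(selection.round1_select(_diff_snps([14_500]), gene, pd.DataFrame(), _cfg(["gA"]))) == 1
        assert len(selection.round1_select(_diff_snps([8_500]), gene, pd.DataFrame(), _cfg(["gA"]))) == 0

    def test_cap_with_severity_then_position_priority(self, plus_gene):
        positions = [11_000, 11_100, 11_200, 11_300, 11_400]
        effects = pd.DataFrame(
            {
                "chrom": "chr01",
                "pos": positions,
                "effect": ["intron", "missense", "nonsense", "missense", "3'UTR"],
                "gene_id": "gA",
            }
        )
        out = selection.round1_select(
            _diff_snps(positions), plus_gene, effects, _cfg(["gA"], max_snps_per_gene=3)
        )
        assert len(out) == 3
        # nonsense first, then the two missense in position order
        assert list(out["pos"]) == [11_200, 11_100, 11_300]

    def test_empty_literature_list_warns_and_selects_nothing(self, plus_gene):
        with pytest.warns(UserWarning, match="literature"):
            out = selection.round1_select(
                _diff_snps([11_000]), plus_gene, pd.DataFrame(), _cfg([])
            )
        assert len(out) == 0

    def test_shrinking_utr_windows_never_adds_candidates(self, plus_gene):
        rng = np.random.default_rng(5)
        snps = _diff_snps(np.sort(rng.integers(7000, 16_000, 40)))
        prev = None
        for up, down in [(2000, 500), (1000, 250), (500, 100), (0, 0)]:
            out = selection.round1_select(
                snps, plus_gene, pd.DataFrame(),
                _cfg(["gA"], upstream_bp=up, downstream_bp=down, max_snps_per_gene=100),
            )
            keys = set(map(tuple, out[["chrom", "pos"]].to_numpy()))
            if prev is not None:
                assert keys <= prev
            prev = keys


class TestRound2:
    def test_toy_set_difference(self, plus_gene):
        """10 difference SNPs: 3 missense + 1 nonsense + 6 other; 2 of the
        damaging ones already taken in round 1 -> round 2 adds 2."""
        positions = list(range(11_000, 11_500, 50))
        effect_classes = ["missense", "missense", "missense", "nonsense"] + ["intron"] * 6
        effects = pd.DataFrame(
            {"chrom": "chr01", "pos": positions, "effect": effect_classes, "gene_id": "gA"}
        )
        round1 = pd.DataFrame(
            {"chrom": "chr01", "pos": positions[:2], "alt": "T", "gene_id": "gA",
             "effect": "missense", "round": 1}
        )
        out = selection.round2_select(_diff_snps(positions), effects, plus_gene, round1)
        assert len(out) == 2
        assert set(out["effect"]) <= {"missense", "nonsense"}

    def test_synonymous_excluded_and_non_literature_gene_included(self, plus_gene):
        effects = pd.DataFrame(
            {"chrom": "chr01", "pos": [11_000, 11_050], "effect": ["synonymous", "missense"],
             "gene_id": "gA"}
        )
        out = selection.round2_select(
            _diff_snps([11_000, 11_050]), effects, plus_gene, pd.DataFrame()
        )
        assert list(out["pos"]) == [11_050]


class TestCombined:
    def test_no_duplicate_keys_and_cap_respected(self, plus_gene):
        positions = list(range(10_500, 12_500, 100))
        effects = pd.DataFrame(
            {"chrom": "chr01", "pos": positions, "effect": "missense", "gene_id": "gA"}
        )
        cfg = _cfg(["gA"], max_snps_per_gene=3)
        snps = _diff_snps(positions)
        r1 = selection.round1_select(snps, plus_gene, effects, cfg)
        r2 = selection.round2_select(snps, effects, plus_gene, r1)
        panel = selection.combine_rounds(r1, r2)
        keys = panel[["chrom", "pos", "alt"]]
        assert not keys.duplicated().any()
        assert (r1.groupby("gene_id").size() <= 3).all()
        # r2 picks up the capped-out damaging SNPs
        assert len(panel) == len(positions)

    def test_selected_snps_inside_extended_extent_interval_tree(self, plus_gene):
        from intervaltree import IntervalTree

        rng = np.random.default_rng(9)
        snps = _diff_snps(np.sort(rng.integers(5_000, 20_000, 60)))
        cfg = _cfg(["gA"], max_snps_per_gene=100)
        out = selection.round1_select(snps, plus_gene, pd.DataFrame(), cfg)
        tree = IntervalTree()
        g = plus_gene.iloc[0]
        tree.addi(g["start"] - cfg.upstream_bp, g["end"] + cfg.downstream_bp + 1)
        assert len(out) > 0
        for pos in out["pos"]:
            assert tree[pos]


class TestParseEffects:
    ANN_ROWS = [
        "chr01\t100\t.\tA\tT\t.\t.\tANN=T|missense_variant|MODERATE|GeneX|GeneX|transcript|t1\tGT\t0/1",
        "chr01\t200\t.\tC\tG\t.\t.\tANN=G|synonymous_variant|LOW|GeneY|GeneY|transcript|t2,"
        "G|stop_gained|HIGH|GeneY|GeneY|transcript|t2\tGT\t0/1",
        "chr01\t300\t.\tG\tA\t.\t.\tANN=A|intron_variant|MODIFIER|GeneZ|GeneZ|transcript|t3\tGT\t0/1",
    ]

    def test_ann_parsing_and_severity_collapse(self, tmp_path):
        path = write_text_vcf(tmp_path / "ann.vcf", self.ANN_ROWS)
        table, counters = selection.parse_effects(str(path))
        by_pos = table.set_index("pos")
        assert by_pos.loc[100, "effect"] == "missense"
        assert by_pos.loc[100, "gene_id"] == "GeneX"
        assert by_pos.loc[200, "effect"] == "nonsense"  # most severe of two kept
        assert by_pos.loc[300, "effect"] == "intron"
        assert counters["malformed"] == 0

    def test_malformed_ann_skipped_with_count(self, tmp_path):
        rows = ["chr01\t100\t.\tA\tT\t.\t.\tANN=broken\tGT\t0/1"] + self.ANN_ROWS[2:]
        path = write_text_vcf(tmp_path / "bad.vcf", rows)
        table, counters = selection.parse_effects(str(path))
        assert counters["malformed"] == 1
        assert len(table) == 1

    def test_tsv_and_ann_paths_are_equivalent(self, tmp_path):
        vcf = write_text_vcf(tmp_path / "e.vcf", self.ANN_ROWS)
        from_vcf, _ = selection.parse_effects(str(vcf))
        tsv = tmp_path / "e.tsv"
        tsv.write_text(
            "chr01\t100\tmissense\tGeneX\n"
            "chr01\t200\tnonsense\tGeneY\n"
            "chr01\t300\tintron_variant\tGeneZ\n"
        )
        from_tsv, _ = selection.parse_effects(str(tsv), fmt="tsv")
        pd.testing.assert_frame_equal(
            from_vcf.sort_values("pos").reset_index(drop=True),
            from_tsv.sort_values("pos").reset_index(drop=True),
        )


def test_design_yield_percentage():
    assert selection.design_yield_pct(410, 1034) == 39.6
    assert selection.design_yield_pct(1, 3) == 33.3
    with pytest.raises(ValueError):
        selection.design_yield_pct(1, 0)
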