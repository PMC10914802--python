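import numpy as np
import pandas as pd
import pytest

from bulkseg import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully featured cross: 3 chromosomes, one planted QTL."""
    return sd.SimConfig(
        n_chromosomes=3,
        chrom_length_bp=2_000_000,
        snp_density=2e-4,
        qtl_loci=[sd.QtlLocus(1, 1_000_000, 0.2, "A")],
        n_f1=100,
        bulk_size=20,
        coverage_mean=80.0,
        linkage_block_bp=500_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cross(small_cfg):
    rng = np.random.default_rng(small_cfg.seed)
    parents = sd.simulate_parents(small_cfg, rng)
    f1 = sd.simulate_f1(parents, small_cfg.n_f1, rng)
    return parents, f1


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run shared by the integration-level tests."""
    out = tmp_path_factory.mktemp("demo_run")
    config = {
        "simulate": {
            "n_chromosomes": 3,
            "chrom_length_bp": 2_000_000,
            "snp_density": 2e-4,
            "linkage_block_bp": 500_000,
            "coverage_mean": 80,
            "qtl_loci": [{"chrom": 1, "pos": 1_000_000, "effect": 0.2, "tolerant_parent": "A"}],
        },
        "seed": 3,
    }
    manifest = pipeline.run_pipeline(config, out, seed=3)
    return out, manifest, config


def write_text_vcf(path, body_rows, sample="POOL", contigs=("chr01",), length=1_000_000):
    """Minimal plain-text VCF writer for hand-built fixtures."""
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c},length={length}>")
    lines += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    lines += body_rows
    path.write_text("\n".join(lines) + "\n")
    return path
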