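"""End-to-end orchestration: simulate -> drym -> bulks -> filter -> scan
-> attribute -> select -> assoc, driven by one YAML config, with a JSON
manifest recording per-stage outputs and record counts.

The simulate stage generates the cross, phenotypes, annotation and parent
pool VCFs; the bulks stage selects the phenotypic extremes and sequences
them as pooled VCFs.  Every downstream stage reads only files written by
earlier stages, so any stage can be re-run from cached upstream outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, attribution, phenotype, scan, selection, synthetic_data, vcfio

STAGES = ["simulate", "drym", "bulks", "filter", "scan", "attribute", "select", "assoc"]

_SCHEMA = {
    "simulate": {f.name for f in dataclasses.fields(synthetic_data.SimConfig)} | {"qtl_loci"},
    "phenotype": {"n_bulk", "outlier_rule"},
    "filter": {f.name for f in dataclasses.fields(vcfio.FilterConfig)},
    "scan": {f.name for f in dataclasses.fields(scan.ScanConfig)},
    "select": {"upstream_bp", "downstream_bp", "max_snps_per_gene", "literature_fraction"},
    "assoc": {"alpha", "n_varieties", "causal_shift"},
    "seed": None,
}


def validate_config(config: dict) -> None:
    problems = []
    for section, payload in config.items():
        if section not in _SCHEMA:
            problems.append(f"unknown section '{section}'")
            continue
        allowed = _SCHEMA[section]
        if allowed is None:
            continue
        for key in payload:
            if key not in allowed:
                problems.append(f"unknown key '{section}.{key}'")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))


def _param_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def build_sim_config(config: dict, seed: int) -> synthetic_data.SimConfig:
    section = dict(config.get("simulate", {}))
    qtl_raw = section.pop("qtl_loci", None)
    section.pop("seed", None)
    cfg = synthetic_data.SimConfig(seed=seed, **section)
    if qtl_raw is None:
        cfg.qtl_loci = synthetic_data.default_config().qtl_loci
    else:
        cfg.qtl_loci = [synthetic_data.QtlLocus(**q) for q in qtl_raw]
    cfg.validate()
    return cfg


class PipelineRun:
    """Mutable run state shared between stages (in-memory caches plus the
    on-disk files each stage writes)."""

    def __init__(self, config: dict, out_dir: Path, seed: int):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = seed
        self.sim_cfg = build_sim_config(config, seed)
        self.rng = np.random.default_rng(seed)
        self.cache: dict = {}

    def path(self, name: str) -> Path:
        return self.out / name


def _stage_simulate(run: PipelineRun) -> dict:
    cfg = run.sim_cfg
    parents = synthetic_data.simulate_parents(cfg, run.rng)
    f1 = synthetic_data.simulate_f1(parents, cfg.n_f1, run.rng)
    pheno = synthetic_data.simulate_phenotypes(f1, parents, run.rng)
    pheno.to_csv(run.path("phenotypes.tsv"), sep="\t", index=False)
    genes, effects = synthetic_data.simulate_annotation(
        parents, run.path("genes.gff3"), run.path("effects.tsv"), run.rng
    )
    pa = synthetic_data.simulate_parent_vcf(parents, "A", run.path("parentA.vcf"), "HROALB", run.rng)
    pe = synthetic_data.simulate_parent_vcf(parents, "E", run.path("parentE.vcf"), "HROEUR", run.rng)
    run.cache.update(parents=parents, f1=f1, pheno=pheno, genes=genes, effects=effects,
                     parent_a_table=pa, parent_e_table=pe)
    return {
        "n_loci": parents.n_loci,
        "n_f1": int(f1.shape[0]),
        "phenotype_rows": len(pheno),
        "n_genes": len(genes),
        "outputs": ["phenotypes.tsv", "genes.gff3", "effects.tsv", "parentA.vcf", "parentE.vcf"],
    }


def _stage_drym(run: PipelineRun) -> dict:
    pheno = run.cache.get("pheno")
    if pheno is None:
        pheno = pd.read_csv(run.path("phenotypes.tsv"), sep="\t")
    relsy = phenotype.compute_relsy(pheno)
    drym = phenotype.compute_drym(relsy)
    drym.to_csv(run.path("drym.tsv"), sep="\t", index=False)
    run.cache["drym"] = drym
    return {"rows": len(drym), "outputs": ["drym.tsv"]}


def _stage_bulks(run: PipelineRun) -> dict:
    cfg = run.sim_cfg
    pcfg = run.config.get("phenotype", {})
    bulks = phenotype.select_bulks(
        run.cache["drym"],
        n_bulk=pcfg.get("n_bulk", cfg.bulk_size),
        outlier_rule=pcfg.get("outlier_rule"),
    )
    pd.DataFrame(
        {
            "genotype": bulks.tolerant_ids + bulks.sensitive_ids,
            "bulk": ["tolerant"] * len(bulks.tolerant_ids)
            + ["sensitive"] * len(bulks.sensitive_ids),
        }
    ).to_csv(run.path("bulks.tsv"), sep="\t", index=False)
    ids = synthetic_data.genotype_ids(run.cache["f1"].shape[0])
    idx = {g: i for i, g in enumerate(ids)}
    f1 = run.cache["f1"]
    parents = run.cache["parents"]
    tol_rows = f1[[idx[g] for g in bulks.tolerant_ids]]
    sen_rows = f1[[idx[g] for g in bulks.sensitive_ids]]
    synthetic_data.simulate_bulk_vcf(parents, tol_rows, run.path("tolerant.vcf"), "HROEXATOL", run.rng)
    synthetic_data.simulate_bulk_vcf(parents, sen_rows, run.path("sensitive.vcf"), "HROEXASEN", run.rng)
    drym = run.cache["drym"]
    per_geno = drym.groupby("genotype")["drym"].mean()
    t, df, p = phenotype.bulk_separation_test(
        per_geno[bulks.tolerant_ids], per_geno[bulks.sensitive_ids]
    )
    run.cache["bulks"] = bulks
    return {
        "bulk_size": len(bulks.tolerant_ids),
        "welch_t": t,
        "welch_p": p,
        "outputs": ["bulks.tsv", "tolerant.vcf", "sensitive.vcf"],
    }


def _stage_filter(run: PipelineRun) -> dict:
    fcfg = vcfio.FilterConfig(**run.config.get("filter", {}))
    tol = vcfio.read_vcf(run.path("tolerant.vcf"))
    sen = vcfio.read_vcf(run.path("sensitive.vcf"))
    tol_f, tally_t = vcfio.filter_variants(tol, fcfg)
    sen_f, tally_s = vcfio.filter_variants(sen, fcfg)
    joint = vcfio.intersect_bulks(tol_f, sen_f)
    joint.to_csv(run.path("joint_bulks.tsv"), sep="\t", index=False)
    pd.DataFrame([{"bulk": "tolerant", **tally_t}, {"bulk": "sensitive", **tally_s}]).to_csv(
        run.path("filter_tally.tsv"), sep="\t", index=False
    )
    run.cache["joint"] = joint
    return {
        "input_snps": tally_t["input"] + tally_s["input"],
        "filtered_snps": tally_t["retained"] + tally_s["retained"],
        "difference_snps": int(joint["is_difference"].sum()),
        "outputs": ["joint_bulks.tsv", "filter_tally.tsv"],
    }


def _stage_scan(run: PipelineRun) -> dict:
    scfg = scan.ScanConfig(**run.config.get("scan", {}))
    joint = run.cache["joint"]
    records = scan.gprime_scan(joint, scfg)
    records.to_csv(run.path("gprime_scan.tsv"), sep="\t", index=False)
    intervals = scan.call_qtl_intervals(records, scfg)
    genes = run.cache["genes"]
    for iv in intervals:
        scan.summarize_qtl(iv, genes, joint)
    table = scan.intervals_to_frame(intervals)
    table.to_csv(run.path("qtl_table.tsv"), sep="\t", index=False)
    if intervals:
        scan.intervals_to_bed(intervals, run.path("qtl.bed"))
    run.cache["scan_records"] = records
    run.cache["intervals"] = intervals
    run.cache["qtl_table"] = table
    return {
        "scanned_snps": len(records),
        "n_qtl": len(intervals),
        "outputs": ["gprime_scan.tsv", "qtl_table.tsv"] + (["qtl.bed"] if intervals else []),
    }


def _stage_attribute(run: PipelineRun) -> dict:
    joint = run.cache["joint"]
    bulk_tol = joint[joint["in_tol"]].rename(columns={"af_tol": "af"})
    bulk_sen = joint[joint["in_sen"]].rename(columns={"af_sen": "af"})
    pa = vcfio.presence_calls(run.cache["parent_a_table"])  # unfiltered parent calls
    pe = vcfio.presence_calls(run.cache["parent_e_table"])
    intervals = run.cache["qtl_table"] if len(run.cache["qtl_table"]) else None
    _, venn_tol = attribution.classify_origin(bulk_tol, pa, pe, "tolerant", intervals)
    _, venn_sen = attribution.classify_origin(bulk_sen, pa, pe, "sensitive", intervals)
    venn = pd.concat([venn_tol, venn_sen], ignore_index=True)
    venn.to_csv(run.path("venn.tsv"), sep="\t", index=False)
    windows = pd.concat(
        [
            attribution.rolling_windows(bulk_tol.assign(bulk="tolerant")),
            attribution.rolling_windows(bulk_sen.assign(bulk="sensitive")),
        ],
        keys=["tolerant", "sensitive"],
        names=["bulk", None],
    ).reset_index(level=0)
    windows.to_csv(run.path("windows.tsv"), sep="\t", index=False)
    return {"venn_rows": len(venn), "window_rows": len(windows), "outputs": ["venn.tsv", "windows.tsv"]}


def _stage_select(run: PipelineRun) -> dict:
    sel = run.config.get("select", {})
    genes = run.cache["genes"]
    qtl_table = run.cache["qtl_table"]
    intervals = qtl_table[["chrom", "start_bp", "end_bp"]] if len(qtl_table) else pd.DataFrame(
        columns=["chrom", "start_bp", "end_bp"]
    )
    genes_under = selection._genes_in_scope(
        genes, selection.SelectionConfig(qtl_intervals=intervals)
    )
    frac = sel.get("literature_fraction", 0.2)
    lit = set(sorted(genes_under["gene_id"])[:: max(1, int(round(1 / frac)))]) if frac else set()
    cfg = selection.SelectionConfig(
        upstream_bp=sel.get("upstream_bp", 2000),
        downstream_bp=sel.get("downstream_bp", 500),
        max_snps_per_gene=sel.get("max_snps_per_gene", 3),
        literature_genes=lit,
        qtl_intervals=intervals,
    )
    effects, _ = selection.parse_effects(run.path("effects.tsv"), fmt="tsv")
    joint = run.cache["joint"]
    diff = joint[joint["is_difference"]]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        r1 = selection.round1_select(diff, genes, effects, cfg)
    r2 = selection.round2_select(diff, effects, genes_under, r1)
    panel = selection.combine_rounds(r1, r2)
    panel.to_csv(run.path("panel_design.tsv"), sep="\t", index=False)
    if len(panel):
        selection.probe_flanks_bed(panel, run.path("probes.bed"))
    run.cache["panel_design"] = panel
    summary = selection.panel_summary(panel) if len(panel) else {"n_snps": 0, "n_genes": 0}
    summary["outputs"] = ["panel_design.tsv"] + (["probes.bed"] if len(panel) else [])
    return summary


def _stage_assoc(run: PipelineRun) -> dict:
    acfg = run.config.get("assoc", {})
    panel_design = run.cache["panel_design"]
    if not len(panel_design):
        pd.DataFrame().to_csv(run.path("association.tsv"), sep="\t", index=False)
        return {"tested_snps": 0, "significant": 0, "outputs": ["association.tsv"]}
    keys = [tuple(k) for k in panel_design[["chrom", "pos", "alt"]].itertuples(index=False)]
    qtl_table = run.cache["qtl_table"]
    causal = []
    for iv in qtl_table.itertuples(index=False):
        causal += [k for k in keys if k[0] == iv.chrom and iv.start_bp <= k[1] <= iv.end_bp]
    genos, ranking = synthetic_data.simulate_panel(
        keys,
        causal[: max(1, len(causal) // 4)],
        n_varieties=acfg.get("n_varieties", 34),
        causal_shift=acfg.get("causal_shift", 0.4),
        seed=run.rng,
    )
    tolerant, sensitive = association.split_panel(ranking["variety"])
    fisher = association.fisher_association(genos, tolerant, sensitive, acfg.get("alpha", 0.05))
    kw = association.kw_association(
        genos, ranking.set_index("variety")["drym"], acfg.get("alpha", 0.05)
    )
    res = fisher.merge(kw, on=["chrom", "pos", "alt"], how="left", suffixes=("", "_kw"))
    res = res.merge(panel_design, on=["chrom", "pos", "alt"], how="left")
    res.to_csv(run.path("association.tsv"), sep="\t", index=False)
    return {
        "tested_snps": len(res),
        "significant": int(res["significant"].sum()) if len(res) else 0,
        "outputs": ["association.tsv"],
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "drym": _stage_drym,
    "bulks": _stage_bulks,
    "filter": _stage_filter,
    "scan": _stage_scan,
    "attribute": _stage_attribute,
    "select": _stage_select,
    "assoc": _stage_assoc,
}


def recovery_replicate(
    seed: int,
    effect: float = 0.2,
    n_f1: int = 100,
    bulk_size: int = 20,
    coverage: float = 80.0,
    n_chromosomes: int = 5,
    chrom_length_bp: int = 5_000_000,
    snp_density: float = 2e-4,
    linkage_block_bp: int = 1_000_000,
    qtl_chrom: int = 1,
    qtl_pos: int = 2_500_000,
) -> dict:
    """One planted-QTL recovery experiment, run fully in memory.

    Simulates the cross, selects bulks by DRYM rank, sequences the pools,
    filters, scans and calls QTLs.  Returns whether a called interval
    overlaps the planted locus (with one smoothing window of slack on
    either side) and whether chromosomes without a QTL stayed clean.
    """
    cfg = synthetic_data.SimConfig(
        n_chromosomes=n_chromosomes,
        chrom_length_bp=chrom_length_bp,
        snp_density=snp_density,
        qtl_loci=[synthetic_data.QtlLocus(qtl_chrom, qtl_pos, effect, "A")],
        n_f1=n_f1,
        bulk_size=bulk_size,
        coverage_mean=coverage,
        linkage_block_bp=linkage_block_bp,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    parents = synthetic_data.simulate_parents(cfg, rng)
    f1 = synthetic_data.simulate_f1(parents, cfg.n_f1, rng)
    pheno = synthetic_data.simulate_phenotypes(f1, parents, rng)
    drym = phenotype.compute_drym(phenotype.compute_relsy(pheno))
    bulks = phenotype.select_bulks(drym, n_bulk=cfg.bulk_size)
    ids = synthetic_data.genotype_ids(cfg.n_f1)
    idx = {g: i for i, g in enumerate(ids)}
    tol = synthetic_data.simulate_bulk_counts(parents, f1[[idx[g] for g in bulks.tolerant_ids]], rng)
    sen = synthetic_data.simulate_bulk_counts(parents, f1[[idx[g] for g in bulks.sensitive_ids]], rng)
    tol_f, _ = vcfio.filter_variants(tol)
    sen_f, _ = vcfio.filter_variants(sen)
    joint = vcfio.intersect_bulks(tol_f, sen_f)
    scfg = scan.ScanConfig()
    records = scan.gprime_scan(joint, scfg)
    intervals = scan.call_qtl_intervals(records, scfg)
    qtl_chrom_name = cfg.chrom_name(qtl_chrom)
    slack = scfg.window_size
    recovered = any(
        iv.chrom == qtl_chrom_name
        and iv.start_bp - slack <= qtl_pos <= iv.end_bp + slack
        for iv in intervals
    )
    off_target = [iv for iv in intervals if iv.chrom != qtl_chrom_name]
    return {
        "recovered": recovered,
        "null_chromosomes_clean": len(off_target) == 0,
        "n_intervals": len(intervals),
        "n_off_target": len(off_target),
        "n_snps_scanned": len(records),
    }


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Run all stages; returns (and writes) the manifest.

    A stage failure is recorded and every downstream stage is marked
    skipped rather than raising.
    """
    config = load_config(config)
    if seed is None:
        seed = int(config.get("seed", 0))
    run = PipelineRun(config, Path(out_dir), seed)
    manifest = {
        "seed": seed,
        "parameter_hash": _param_hash(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    failed = False
    for stage in STAGES:
        if failed:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            info = _STAGE_FUNCS[stage](run)
            info.update(status="complete", seconds=round(time.time() - t0, 3))
            info["outputs"] = [str(run.path(o)) for o in info.get("outputs", [])]
            manifest["stages"][stage] = info
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            manifest["stages"][stage] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
            failed = True
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(run.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
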