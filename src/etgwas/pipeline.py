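"""End-to-end pipeline: sampling -> pooling -> screening -> haplo-pheno.

``run_pipeline`` wires the stages together: bulk construction from the
phenotype distribution, pooled allele counting, MAF/depth filtering, the
bulk-trend GLM with genomic control, MTA calling, LD-window candidate-gene
scanning and haplotype-phenotype analysis, writing every artefact plus a
manifest into a run directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import Thresholds, call_mtas, run_association
from .bulking import FilterConfig, assign_bulks, filter_report, filter_snps, pool_alleles, write_bulk_csv
from .candidates import DEFAULT_BIN_SIZE, DEFAULT_HALF_WIDTH, DEFAULT_R2_MIN, overlap_mtas, scan_all_mtas
from .errors import EtgwasError, NoVariantError
from .haplotypes import (
    DuncanConfig,
    SuperiorRule,
    collapse_haplotypes,
    duncan_mrt,
    filter_haplotypes,
    haplotype_report,
    list_donors,
    select_superior,
)
from .io import read_gff_genes, read_phenotype, read_vcf, write_assoc_table
from .plots import render_manhattan, render_qq
from .types import GeneModel, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Defaults: 20% bulks, pooled MAF floor 0.05, depth floor = bulk size,
    binomial-logit model, thresholds 1e-4/1e-6, LD r^2 >= 0.4 in a 100-kb
    window, 100-kb overlap bins, Duncan alpha 0.05 with >= 2 carriers, and
    the one-panel-SD superiority margin.
    """

    vcf: str | Path | None = None
    pheno: str | Path | None = None
    gff: str | Path | None = None
    outdir: str | Path = "etgwas_run"
    trait: str = "SPY"
    fraction: float = 0.20
    seed: int = 17
    maf_min: float = 0.05
    depth_min: int | None = None
    model: str = "binomial_logit"
    thr_primary: float = 1e-4
    thr_secondary: float = 1e-6
    r2_min: float = DEFAULT_R2_MIN
    half_width: int = DEFAULT_HALF_WIDTH
    bin_size: int = DEFAULT_BIN_SIZE
    duncan_alpha: float = 0.05
    min_members: int = 2
    k_sd: float = 1.0
    superior_mode: str = "sd"
    match_random: bool = True


@dataclass
class RunResult:
    """In-memory handles to every stage output of one pipeline run."""

    outdir: Path
    bulks: object
    pooled: object
    retained: np.ndarray
    assoc: pd.DataFrame
    mtas: pd.DataFrame
    candidates: pd.DataFrame | None
    haplotypes: pd.DataFrame | None
    donors: pd.DataFrame | None
    manifest: dict


def run_pipeline(
    cfg: RunConfig,
    geno: GenotypeMatrix | None = None,
    pheno: PhenotypeTable | None = None,
    genes: list[GeneModel] | None = None,
    write_plots: bool = True,
) -> RunResult:
    """Execute the full pipeline, loading inputs from ``cfg`` paths unless
    in-memory objects are supplied.  Any stage error aborts with a
    stage-named message; outputs of completed stages are retained."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in dataclasses.asdict(cfg).items()},
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("load_inputs")
        if geno is None:
            if cfg.vcf is None:
                raise EtgwasError("no genotype input: supply cfg.vcf or an in-memory matrix")
            geno = read_vcf(cfg.vcf)
        if pheno is None:
            if cfg.pheno is None:
                raise EtgwasError("no phenotype input: supply cfg.pheno or an in-memory table")
            pheno = read_phenotype(cfg.pheno, cfg.trait)
        if genes is None and cfg.gff is not None:
            genes = read_gff_genes(cfg.gff)
        # restrict the panel to accessions present in both inputs
        common = [a for a in pheno.values.index if a in set(geno.accessions)]
        if len(common) < pheno.n:
            logger.warning("pipeline: %d phenotyped accessions lack genotypes", pheno.n - len(common))
            pheno = PhenotypeTable(pheno.trait_name, pheno.values[common])
        manifest["panel_n"] = pheno.n
        manifest["n_snps_input"] = geno.n_sites

        stage("sampling")
        bulks = assign_bulks(pheno, cfg.fraction, cfg.seed, match_random=cfg.match_random)
        write_bulk_csv(bulks, pheno, outdir / "bulks.csv")
        manifest["bulk_size"] = bulks.bulk_size

        stage("pooling")
        pooled = pool_alleles(geno, bulks)
        fcfg = FilterConfig(maf_min=cfg.maf_min, depth_min=cfg.depth_min)
        retained = filter_snps(pooled, fcfg)
        filter_report(pooled, fcfg).to_csv(outdir / "filter_report.csv", index=False)
        manifest["n_snps_retained"] = int(len(retained))

        stage("association")
        assoc = run_association(pooled, retained, n_panel=pheno.n, model=cfg.model)
        manifest["lambda_gc"] = assoc.attrs.get("lambda_gc")
        write_assoc_table(assoc, outdir / "association.csv")
        if write_plots:
            render_manhattan(assoc, outdir / "manhattan.png", thresholds=(cfg.thr_primary, cfg.thr_secondary))
            render_qq(assoc, outdir / "qq.png")
        mtas = call_mtas(assoc, Thresholds(cfg.thr_primary, cfg.thr_secondary))
        mtas.to_csv(outdir / "mtas.csv", index=False)
        manifest["n_mtas"] = int(len(mtas))
    except EtgwasError as exc:
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise EtgwasError(f"pipeline aborted in stage {manifest['stages'][-1]!r}: {exc}") from exc

    candidates_df = haplo_df = donors_df = None
    if genes is None:
        logger.warning("pipeline: no gene annotation; skipping candidate and haplo-pheno stages")
        manifest["skipped"] = ["candidate_scan", "haplo_pheno"]
    elif len(mtas) == 0:
        logger.warning("pipeline: no MTAs; skipping candidate and haplo-pheno stages")
        manifest["skipped"] = ["candidate_scan", "haplo_pheno"]
    else:
        stage("candidate_scan")
        candidates_df = scan_all_mtas(mtas, geno, genes, r2_min=cfg.r2_min, half_width=cfg.half_width)
        candidates_df.to_csv(outdir / "candidate_genes.csv", index=False)
        manifest["n_candidate_genes"] = int(candidates_df["gene_id"].nunique())

        stage("haplo_pheno")
        gene_by_id = {g.gene_id: g for g in genes}
        rule = SuperiorRule(
            panel_mean=pheno.mean, panel_sd=pheno.sd, k_sd=cfg.k_sd, mode=cfg.superior_mode
        )
        dcfg = DuncanConfig(alpha=cfg.duncan_alpha, min_members=cfg.min_members)
        reports, superior_by_gene = [], {}
        for gene_id in candidates_df["gene_id"].unique():
            gene = gene_by_id[gene_id]
            try:
                groups = collapse_haplotypes(geno, gene, pheno)
            except NoVariantError:
                continue
            groups = filter_haplotypes(groups, dcfg.min_members)
            if len(groups) >= 2:
                groups = duncan_mrt(groups, dcfg)
                sup = select_superior(groups, rule)
                if sup:
                    superior_by_gene[gene_id] = sup
            reports.append(haplotype_report(groups))
        haplo_df = pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
        haplo_df.to_csv(outdir / "haplotypes.csv", index=False)
        donors_df = list_donors(superior_by_gene, pheno)
        donors_df.to_csv(outdir / "donors.csv", index=False)
        manifest["n_superior_haplotypes"] = int(sum(len(v) for v in superior_by_gene.values()))
        manifest["n_donors"] = int(len(donors_df))

    _write_manifest(manifest, outdir)
    return RunResult(
        outdir=outdir,
        bulks=bulks,
        pooled=pooled,
        retained=retained,
        assoc=assoc,
        mtas=mtas,
        candidates=candidates_df,
        haplotypes=haplo_df,
        donors=donors_df,
        manifest=manifest,
    )


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def compare_runs(run_a: str | Path, run_b: str | Path, bin_size: int = DEFAULT_BIN_SIZE) -> dict:
    """Overlap the MTA lists of two run directories on fixed genome bins."""
    mtas_a = pd.read_csv(Path(run_a) / "mtas.csv")
    mtas_b = pd.read_csv(Path(run_b) / "mtas.csv")
    for df in (mtas_a, mtas_b):
        df["chrom"] = df["chrom"].astype(str)
    report = overlap_mtas(mtas_a, mtas_b, bin_size=bin_size)
    return report
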