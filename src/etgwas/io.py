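"""Readers and writers for the standard formats the pipeline touches.

VCF is read through :mod:`cyvcf2` and written as plain VCF 4.2 text (the
simulator's output); GFF3 gene models go through :mod:`gffutils`; phenotype
tables and result tables are delimited text via pandas.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigError, EmptyInputError, ParseError
from .types import MISSING, GeneModel, GenotypeMatrix, PhenotypeTable, VariantSite

logger = logging.getLogger(__name__)

#: Column order of the association output table.
ASSOC_COLUMNS = ["chrom", "pos", "snp_id", "beta", "se", "stat", "p_raw", "p_adj", "pve", "maf", "r2"]


def read_vcf(path: str | os.PathLike, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of alt-allele dosages.

    Dosage is the count of alternate alleles in the GT field; genotypes with
    any missing allele (``./.``, ``./1``) are recorded as :data:`MISSING`.
    Multiallelic records are dropped with a logged count when
    ``biallelic_only`` is set, otherwise they raise :class:`ParseError`.
    """
    path = os.fspath(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    accessions = list(vcf.samples)
    if not accessions:
        raise ParseError(f"VCF {path} has no sample columns")

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if biallelic_only:
                n_multi += 1
                continue
            raise ParseError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} with biallelic_only disabled"
            )
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        sites.append(VariantSite(rec.CHROM, rec.POS, snp_id, rec.REF, rec.ALT[0]))
        col = np.full(len(accessions), MISSING, dtype=np.int16)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if any(a < 0 for a in alleles):
                continue
            col[i] = sum(1 for a in alleles if a > 0)
        columns.append(col)
    if n_multi:
        logger.info("read_vcf: dropped %d multiallelic records", n_multi)
    if not sites:
        raise EmptyInputError(f"VCF {path} contains no biallelic sites")

    calls = np.column_stack(columns)
    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    return GenotypeMatrix([sites[i] for i in order], accessions, calls[:, order])


def write_vcf(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a genotype matrix as uncompressed VCF 4.2 (GT-only)."""
    path = os.fspath(path)
    chrom_seen: dict[str, int] = {}
    for s in geno.sites:
        chrom_seen[s.chrom] = max(chrom_seen.get(s.chrom, 0), s.pos)
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_seen.items():
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accessions)
            + "\n"
        )
        for j, s in enumerate(geno.sites):
            gts = "\t".join(gt_code[int(d)] for d in geno.calls[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotype(
    path: str | os.PathLike,
    trait_column: str,
    accession_column: str = "accession",
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype table (header row required).

    Rows whose trait value is empty or non-numeric are dropped with a logged
    count.  Duplicate accession ids raise :class:`ConfigError`.  The
    delimiter is sniffed from the extension unless given (.csv -> comma,
    otherwise tab/whitespace via pandas' python engine).
    """
    path = os.fspath(path)
    if sep is None:
        sep = "," if path.endswith(".csv") else r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python", dtype={0: str})
    if trait_column not in df.columns:
        raise ConfigError(f"trait column {trait_column!r} not in {list(df.columns)}")
    if accession_column not in df.columns:
        raise ConfigError(f"accession column {accession_column!r} not in {list(df.columns)}")
    vals = pd.to_numeric(df[trait_column], errors="coerce")
    bad = vals.isna()
    if bad.any():
        logger.warning("read_phenotype: dropped %d rows with missing/non-numeric trait", int(bad.sum()))
    df = df.loc[~bad]
    series = pd.Series(vals[~bad].to_numpy(), index=df[accession_column].astype(str).to_numpy())
    return PhenotypeTable(trait_name=trait_column, values=series)


def read_gff_genes(path: str | os.PathLike, feature_type: str = "gene") -> list[GeneModel]:
    """Extract gene models from a GFF3 file.

    Returns one :class:`GeneModel` per feature of ``feature_type``; the id is
    taken from the ``ID`` attribute (falling back to ``Name``/``gene_id``).
    An annotation with no gene features returns an empty list with a warning.
    """
    path = os.fspath(path)
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ParseError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        gid = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or f"{feat.seqid}:{feat.start}-{feat.end}"
        )
        desc = feat.attributes.get("description", [""])[0] if feat.attributes.get("description") else ""
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                description=desc,
            )
        )
    if not genes:
        logger.warning("read_gff_genes: no %r features found in %s", feature_type, path)
    return genes


def write_gff_genes(genes: list[GeneModel], path: str | os.PathLike, source: str = "etgwas") -> None:
    """Write gene models as a minimal GFF3 file."""
    with open(os.fspath(path), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.description:
                attrs += f";description={g.description}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_assoc_table(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the association result table as CSV in the canonical column order.

    An empty result set writes the header only and logs a warning.
    """
    if results is None or len(results) == 0:
        logger.warning("write_assoc_table: empty result set; writing header only")
        pd.DataFrame(columns=ASSOC_COLUMNS).to_csv(path, index=False)
        return
    cols = [c for c in ASSOC_COLUMNS if c in results.columns]
    extra = [c for c in results.columns if c not in cols]
    results[cols + extra].to_csv(path, index=False)


def pca_panel(geno: GenotypeMatrix, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the panel on mean-imputed, centred dosages.

    Returns ``(coordinates, explained_variance_fraction)`` where coordinates
    has shape (n_accessions, n_components).  Used to visualise population
    structure; three components by default.
    """
    X = geno.calls.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]
    X -= X.mean(axis=0)
    # economy SVD; eigenvalues of the covariance are s^2 / (n-1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    coords = U[:, :n_components] * s[:n_components]
    return coords, frac[:n_components]


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
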