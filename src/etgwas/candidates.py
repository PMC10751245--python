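"""LD-window candidate-gene scanning and 100-kb-bin MTA overlap.

Around each marker-trait association (MTA) a 100-kb window centred on the
peak SNP is scanned: window SNPs in high linkage with the peak (r^2 >= 0.4
by default) are intersected with the gene annotation, and the genes
harbouring them become candidate genes.  Separately, MTA sets from
different runs are compared by cutting each chromosome into fixed 100-kb
bins; MTAs sharing a bin are counted as overlapping (consistent) MTAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .types import MISSING, GeneModel, GenotypeMatrix, VariantSite

logger = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.4
DEFAULT_HALF_WIDTH = 50_000
DEFAULT_BIN_SIZE = 100_000


@dataclass
class LdLink:
    """A window SNP and its squared dosage correlation with the peak SNP."""

    snp: VariantSite
    r2: float
    defined: bool = True  # False when r^2 was undefined (monomorphic pairs)


@dataclass
class CandidateGene:
    """A gene harbouring SNPs linked to an MTA peak."""

    gene: GeneModel
    linked_snps: list[LdLink]
    max_r2: float
    source_mta: VariantSite


def ld_r2(geno: GenotypeMatrix, a: int, b: int) -> float:
    """Squared Pearson correlation of dosages at two site indices.

    Composite (unphased) LD over pairwise-complete accessions.  If either
    site is monomorphic over the complete pairs the correlation is
    undefined and reported as 0; fewer than two complete pairs raises
    :class:`InsufficientDataError`.
    """
    va = geno.calls[:, a].astype(float)
    vb = geno.calls[:, b].astype(float)
    ok = (va != MISSING) & (vb != MISSING)
    if ok.sum() < 2:
        raise InsufficientDataError(
            f"ld_r2: only {int(ok.sum())} pairwise-complete accessions for sites {a},{b}"
        )
    va, vb = va[ok], vb[ok]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return 0.0
    r = np.corrcoef(va, vb)[0, 1]
    return float(r * r)


def candidate_genes(
    mta: VariantSite,
    geno: GenotypeMatrix,
    genes: list[GeneModel],
    r2_min: float = DEFAULT_R2_MIN,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> list[CandidateGene]:
    """Candidate genes for one MTA.

    SNPs within ``half_width`` bp of the peak with ``r^2 >= r2_min`` against
    it are intersected with gene intervals; genes are deduplicated per MTA
    and the gene harbouring the peak SNP itself is always included.
    LD is computed against the full panel's genotypes, not bulk members.
    """
    window_start = max(1, mta.pos - half_width)
    window_end = mta.pos + half_width
    peak_idx_arr = [
        i for i, s in enumerate(geno.sites) if s.chrom == mta.chrom and s.pos == mta.pos
    ]
    if not peak_idx_arr:
        raise InsufficientDataError(f"peak SNP {mta.chrom}:{mta.pos} not in genotype matrix")
    peak_idx = peak_idx_arr[0]

    links: list[LdLink] = []
    for i in geno.site_indices_in(mta.chrom, window_start, window_end):
        site = geno.sites[int(i)]
        try:
            r2 = ld_r2(geno, peak_idx, int(i))
        except InsufficientDataError:
            continue
        if r2 >= r2_min or int(i) == peak_idx:
            links.append(LdLink(snp=site, r2=r2))

    out: list[CandidateGene] = []
    for gene in genes:
        in_gene = [l for l in links if gene.contains(l.snp.chrom, l.snp.pos)]
        harbours_peak = gene.contains(mta.chrom, mta.pos)
        if in_gene or harbours_peak:
            out.append(
                CandidateGene(
                    gene=gene,
                    linked_snps=in_gene,
                    max_r2=max((l.r2 for l in in_gene), default=1.0 if harbours_peak else 0.0),
                    source_mta=mta,
                )
            )
    return out


def scan_all_mtas(
    mtas: pd.DataFrame,
    geno: GenotypeMatrix,
    genes: list[GeneModel],
    r2_min: float = DEFAULT_R2_MIN,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """Run :func:`candidate_genes` for every MTA row; tabular output."""
    rows = []
    site_by_key = {(s.chrom, s.pos): s for s in geno.sites}
    for _, m in mtas.iterrows():
        site = site_by_key.get((m["chrom"], int(m["pos"])))
        if site is None:
            logger.warning("scan_all_mtas: MTA %s:%s not in genotypes; skipped", m["chrom"], m["pos"])
            continue
        for cand in candidate_genes(site, geno, genes, r2_min=r2_min, half_width=half_width):
            rows.append(
                {
                    "mta_chrom": site.chrom,
                    "mta_pos": site.pos,
                    "gene_id": cand.gene.gene_id,
                    "gene_start": cand.gene.start,
                    "gene_end": cand.gene.end,
                    "n_linked_snps": len(cand.linked_snps),
                    "max_r2": cand.max_r2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mta_chrom", "mta_pos", "gene_id", "gene_start", "gene_end", "n_linked_snps", "max_r2"],
    )


def bin_index(pos: int, bin_size: int = DEFAULT_BIN_SIZE) -> int:
    """Fixed-origin half-open bin of a 1-based position.

    Bins are [1..bin_size], [bin_size+1..2*bin_size], ... so the index is
    floor((pos - 1) / bin_size).
    """
    return (int(pos) - 1) // int(bin_size)


def overlap_mtas(
    set_a: pd.DataFrame, set_b: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE
) -> dict:
    """Pair MTAs from two sets that fall in the same 100-kb genome bin.

    Returns the overlapping pairs plus per-set counts of MTAs having at
    least one partner (the "consistent MTAs" of a cross-run comparison).
    """
    pairs = []
    a_hit: set[int] = set()
    b_hit: set[int] = set()
    b_bins: dict[tuple[str, int], list[int]] = {}
    for j, row in set_b.reset_index(drop=True).iterrows():
        b_bins.setdefault((row["chrom"], bin_index(row["pos"], bin_size)), []).append(j)
    a_reset = set_a.reset_index(drop=True)
    b_reset = set_b.reset_index(drop=True)
    for i, row in a_reset.iterrows():
        key = (row["chrom"], bin_index(row["pos"], bin_size))
        for j in b_bins.get(key, []):
            pairs.append(
                {
                    "chrom": row["chrom"],
                    "bin": key[1],
                    "pos_a": int(row["pos"]),
                    "pos_b": int(b_reset.loc[j, "pos"]),
                }
            )
            a_hit.add(i)
            b_hit.add(j)
    frac_a = len(a_hit) / len(a_reset) if len(a_reset) else 0.0
    frac_b = len(b_hit) / len(b_reset) if len(b_reset) else 0.0
    return {
        "pairs": pd.DataFrame(pairs, columns=["chrom", "bin", "pos_a", "pos_b"]),
        "n_a": len(a_reset),
        "n_b": len(b_reset),
        "n_a_overlapping": len(a_hit),
        "n_b_overlapping": len(b_hit),
        "frac_a": frac_a,
        "frac_b": frac_b,
    }
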