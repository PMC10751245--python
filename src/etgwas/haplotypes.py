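"""Haplotype-phenotype analysis: collapse, Duncan grouping, superior haplotypes.

For a candidate gene, every accession's calls over the gene's variant sites
are converted to a symbol string — R (homozygous reference), H
(heterozygous), A (homozygous alternate) — and identical strings are
collapsed into haplotype groups.  Accessions with any missing call in the
region are excluded rather than imputed, protecting haplotype identity in a
selfing-crop panel.  Groups carried by at least two accessions are compared
with Duncan's multiple range test on accession-level trait values, and a
haplotype is called superior when its mean phenotype clears the panel mean
by a configured margin (default one panel standard deviation) while holding
the top Duncan letter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .errors import ConfigError, NoVariantError
from .types import MISSING, GeneModel, GenotypeMatrix, PhenotypeTable, VariantSite

logger = logging.getLogger(__name__)

_SYMBOL = {0: "R", 1: "H", 2: "A"}


@dataclass
class HaplotypeSequence:
    """Collapsed gene-region genotype string over {R, H, A}."""

    gene_id: str
    symbols: str
    positions: list[VariantSite]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.positions):
            raise ConfigError("haplotype symbols and positions differ in length")


@dataclass
class HaplotypeGroup:
    """One haplotype, its carriers and their phenotype statistics."""

    haplotype: HaplotypeSequence
    members: list[str]
    values: np.ndarray
    letters: str = ""
    superior: bool = False

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mean_pheno(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd_pheno(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0


@dataclass
class DuncanConfig:
    """Duncan's multiple range test settings."""

    alpha: float = 0.05
    min_members: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_members < 2:
            raise ConfigError("min_members must be >= 2")


@dataclass
class SuperiorRule:
    """Threshold rule for superior haplotypes.

    ``mode='sd'`` (default): mean > panel_mean + k_sd * panel_sd.
    ``mode='absolute'``: mean > panel_mean + offset (trait units).
    """

    panel_mean: float
    panel_sd: float
    k_sd: float = 1.0
    offset: float = 1.0
    mode: str = "sd"
    require_top_letter: bool = True

    def threshold(self) -> float:
        if self.mode == "sd":
            return self.panel_mean + self.k_sd * self.panel_sd
        if self.mode == "absolute":
            return self.panel_mean + self.offset
        raise ConfigError(f"unknown superior-rule mode {self.mode!r}")


def collapse_haplotypes(
    geno: GenotypeMatrix, gene: GeneModel, pheno: PhenotypeTable
) -> list[HaplotypeGroup]:
    """Collapse gene-region variants into haplotype groups.

    Every accession fully called over the gene's variant sites lands in
    exactly one group; singletons are retained at this stage.  Accessions
    without a phenotype record are excluded (their trait value is needed
    downstream).
    """
    idx = geno.site_indices_in(gene.chrom, gene.start, gene.end)
    if len(idx) == 0:
        raise NoVariantError(f"gene {gene.gene_id} contains no variant sites")
    sites = [geno.sites[int(i)] for i in idx]
    sub = geno.calls[:, idx]
    groups: dict[str, list[str]] = {}
    for row, acc in enumerate(geno.accessions):
        if acc not in pheno.values.index:
            continue
        dosages = sub[row]
        if np.any(dosages == MISSING):
            continue
        key = "".join(_SYMBOL[int(d)] for d in dosages)
        groups.setdefault(key, []).append(acc)
    out = [
        HaplotypeGroup(
            haplotype=HaplotypeSequence(gene.gene_id, key, sites),
            members=members,
            values=pheno.values[members].to_numpy(dtype=float),
        )
        for key, members in groups.items()
    ]
    out.sort(key=lambda g: (-g.n, g.haplotype.symbols))
    return out


def filter_haplotypes(
    groups: list[HaplotypeGroup], min_members: int = 2
) -> list[HaplotypeGroup]:
    """Drop haplotype groups carried by fewer than ``min_members`` accessions."""
    kept = [g for g in groups if g.n >= min_members]
    dropped = len(groups) - len(kept)
    if dropped:
        logger.info("filter_haplotypes: dropped %d groups below %d members", dropped, min_members)
    return kept


@lru_cache(maxsize=4096)
def _q_crit(p: int, df: float, alpha: float) -> float:
    """Studentized-range quantile at Duncan's protection level.

    alpha_p = 1 - (1 - alpha)^(p - 1); returns q*(p, df, alpha_p).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(studentized_range.ppf(1.0 - alpha_p, p, df))


def _sort_groups(groups: list[HaplotypeGroup]) -> list[HaplotypeGroup]:
    # means descending; ties broken by size (larger first) then string order
    return sorted(groups, key=lambda g: (-g.mean_pheno, -g.n, g.haplotype.symbols))


def duncan_critical_range(
    span: int, df: float, mse: float, sizes: list[int], alpha: float
) -> float:
    """Duncan critical range R_p for a stretch of ``span`` consecutive means.

    R_p = q*(p, df, alpha_p) * sqrt(MSE / n_h) with n_h the harmonic mean of
    the group sizes in the stretch.
    """
    n_h = span / sum(1.0 / s for s in sizes)
    return _q_crit(span, df, alpha) * math.sqrt(mse / n_h)


def duncan_mrt(groups: list[HaplotypeGroup], cfg: DuncanConfig | None = None) -> list[HaplotypeGroup]:
    """Duncan's multiple range test with letter display.

    Accession-level trait values are the observations.  The pooled one-way
    ANOVA error mean square supplies the scale; means sorted descending are
    tested stepwise: a stretch of p consecutive means whose range does not
    exceed the critical range R_p is declared homogeneous, and inner pairs
    of a homogeneous stretch are not separated.  Groups sharing no letter
    differ significantly.  Returns the groups (sorted by descending mean)
    with ``letters`` filled in.
    """
    cfg = cfg or DuncanConfig()
    if len(groups) < 2:
        raise ConfigError("duncan_mrt needs >= 2 groups")
    if any(g.n < 2 for g in groups):
        raise ConfigError("duncan_mrt: every group needs >= 2 members")
    g_sorted = _sort_groups(groups)
    k = len(g_sorted)
    n_total = sum(g.n for g in g_sorted)
    df_err = n_total - k
    sse = sum(((g.values - g.mean_pheno) ** 2).sum() for g in g_sorted)
    mse = sse / df_err
    means = [g.mean_pheno for g in g_sorted]
    sizes = [g.n for g in g_sorted]

    # direct homogeneity of stretch [i..j]: range <= R_p for its span
    def stretch_homog(i: int, j: int) -> bool:
        if i == j:
            return True
        if mse == 0.0:
            return means[i] == means[j]
        span = j - i + 1
        return (means[i] - means[j]) <= duncan_critical_range(
            span, df_err, mse, sizes[i : j + 1], cfg.alpha
        )

    homog = [[stretch_homog(i, j) if j >= i else False for j in range(k)] for i in range(k)]
    # maximal homogeneous stretches get one letter each
    stretches = []
    for i in range(k):
        for j in range(i, k):
            if homog[i][j] and not any(a <= i and j <= b and (a, b) != (i, j) and homog[a][b]
                                       for a in range(i + 1) for b in range(j, k)):
                stretches.append((i, j))
    stretches.sort()
    letters = [""] * k
    for s_idx, (i, j) in enumerate(stretches):
        letter = _letter(s_idx)
        for g in range(i, j + 1):
            letters[g] += letter
    for g, let in zip(g_sorted, letters):
        g.letters = let
    return g_sorted


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def select_superior(groups: list[HaplotypeGroup], rule: SuperiorRule) -> list[HaplotypeGroup]:
    """Superior haplotypes: above the panel threshold, strictly, and (by
    default) carrying the top Duncan letter."""
    thr = rule.threshold()
    top_letter = None
    if rule.require_top_letter:
        lettered = [g for g in groups if g.letters]
        if lettered:
            top = max(lettered, key=lambda g: g.mean_pheno)
            top_letter = top.letters[0]
    out = []
    for g in groups:
        ok = g.mean_pheno > thr
        if ok and rule.require_top_letter and top_letter is not None:
            ok = top_letter in g.letters
        g.superior = bool(ok)
        if g.superior:
            out.append(g)
    return out


def list_donors(
    superior_by_gene: dict[str, list[HaplotypeGroup]], pheno: PhenotypeTable
) -> pd.DataFrame:
    """Donor accessions carrying one or more superior haplotypes.

    One row per accession with the genes/haplotypes it carries, sorted by
    number of superior haplotypes carried then by trait value (both
    descending).
    """
    carriers: dict[str, dict] = {}
    for gene_id, groups in superior_by_gene.items():
        for g in groups:
            for acc in g.members:
                rec = carriers.setdefault(
                    acc, {"accession": acc, "genes": [], "haplotypes": [], "n_superior_haps": 0}
                )
                rec["genes"].append(gene_id)
                rec["haplotypes"].append(g.haplotype.symbols)
                rec["n_superior_haps"] += 1
    rows = []
    for acc, rec in carriers.items():
        rec["trait_value"] = float(pheno.values.get(acc, np.nan))
        rec["genes"] = ";".join(rec["genes"])
        rec["haplotypes"] = ";".join(rec["haplotypes"])
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["accession", "genes", "haplotypes", "n_superior_haps", "trait_value"])
    if len(df):
        df = df.sort_values(["n_superior_haps", "trait_value"], ascending=False).reset_index(drop=True)
    return df


def haplotype_report(groups: list[HaplotypeGroup]) -> pd.DataFrame:
    """Tabular haplotype report for one gene."""
    return pd.DataFrame(
        [
            {
                "gene_id": g.haplotype.gene_id,
                "haplotype": g.haplotype.symbols,
                "n": g.n,
                "mean": g.mean_pheno,
                "sd": g.sd_pheno,
                "letters": g.letters,
                "superior": g.superior,
            }
            for g in groups
        ]
    )
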