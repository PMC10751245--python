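"""Bulk construction, pooled allele counting and SNP filtering.

The sampling step of extreme-trait GWAS: from a phenotyped diversity panel,
take the ``fraction`` of accessions with the lowest trait values as the low
bulk, the same number with the highest values as the high bulk, and an
equal-sized random draw from the whole panel as the control ("random") bulk.
Allele counts are then pooled per bulk and SNPs are filtered on pooled minor
allele frequency and total depth — deliberately *not* on missingness, so
that rare variants carried by few accessions survive into the association.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, IdMismatchError
from .types import MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

#: Fixed bulk order: the ordinal covariate of the association GLM is the
#: index into this tuple (low=0, random=1, high=2).
BULK_ORDER = ("low", "random", "high")

#: Capped number of redraws when matching the random bulk to panel moments.
MATCH_RANDOM_MAX_ATTEMPTS = 200


def round_half_up(x: float) -> int:
    """Round to the nearest integer with .5 rounding away from zero upward.

    Used for bulk sizing: 0.20 x 378 -> 76 and 0.20 x 389 -> 78 (flooring
    would give 75 and 77).
    """
    return int(math.floor(x + 0.5))


@dataclass
class BulkAssignment:
    """The three accession sets defining a bulk design."""

    fraction: float
    bulk_size: int
    low: list[str]
    high: list[str]
    random: list[str]
    seed: int
    panel_n: int

    def __post_init__(self) -> None:
        if not (len(self.low) == len(self.high) == len(self.random) == self.bulk_size):
            raise ConfigError("all three bulks must have exactly bulk_size members")
        if set(self.low) & set(self.high):
            raise ConfigError("low and high bulks overlap")

    def members(self, bulk: str) -> list[str]:
        return {"low": self.low, "random": self.random, "high": self.high}[bulk]

    def to_frame(self, pheno: PhenotypeTable | None = None) -> pd.DataFrame:
        rows = []
        for bulk in BULK_ORDER:
            for acc in self.members(bulk):
                rows.append(
                    {
                        "accession": acc,
                        "bulk": bulk,
                        "trait_value": float(pheno.values[acc]) if pheno is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class FilterConfig:
    """SNP retention rules applied to pooled counts.

    ``maf_min`` is the pooled minor-allele-frequency floor (default 0.05);
    ``depth_min`` is the minimum total allele-copy depth across the three
    bulks, defaulting to the bulk size when left as None.
    """

    maf_min: float = 0.05
    depth_min: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise ConfigError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if self.depth_min is not None and self.depth_min < 0:
            raise ConfigError("depth_min must be >= 0")


@dataclass
class PooledCounts:
    """Per SNP x per bulk allele counts and derived frequencies.

    Arrays have shape ``(n_snps, 3)`` with columns ordered as
    :data:`BULK_ORDER`.  ``ref_count + alt_count = 2 * n_called`` holds for
    every cell because each called diploid genotype contributes two allele
    copies.
    """

    snp_ids: list[str]
    chroms: np.ndarray
    positions: np.ndarray
    alt_count: np.ndarray
    n_called: np.ndarray
    bulk_size: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def ref_count(self) -> np.ndarray:
        return 2 * self.n_called - self.alt_count

    @property
    def depth(self) -> np.ndarray:
        """Allele copies per SNP per bulk (= 2 * n_called)."""
        return 2 * self.n_called

    @property
    def total_depth(self) -> np.ndarray:
        """Allele copies summed over the three bulks; at most 6 * bulk_size."""
        return self.depth.sum(axis=1)

    @property
    def alt_af(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.depth > 0, self.alt_count / self.depth, np.nan)

    @property
    def ref_af(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return 1.0 - self.alt_af

    def pooled_alt_fraction(self) -> np.ndarray:
        """Combined alt-allele fraction over all three bulks."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_depth > 0, self.alt_count.sum(axis=1) / self.total_depth, np.nan
            )

    def maf(self) -> np.ndarray:
        """Pooled minor allele frequency min(p, 1-p)."""
        p = self.pooled_alt_fraction()
        return np.minimum(p, 1.0 - p)


def assign_bulks(
    pheno: PhenotypeTable,
    fraction: float,
    seed: int,
    match_random: bool = True,
) -> BulkAssignment:
    """Construct low/high/random bulks from the phenotype distribution.

    The low bulk holds the ``k = round_half_up(fraction * panel_n)`` smallest
    trait values and the high bulk the ``k`` largest, with boundary ties
    broken by accession-id lexical order for reproducibility.  The random
    (control) bulk is a seeded uniform draw without replacement from the
    *entire* panel; with ``match_random`` it is redrawn (capped attempts)
    until its mean and median are within 0.25 panel standard deviations of
    the panel's, keeping the best attempt otherwise.
    """
    panel_n = pheno.n
    if panel_n < 10:
        raise ConfigError(f"panel too small for bulking: {panel_n} < 10")
    if not (0 < fraction <= 0.5):
        raise ConfigError(f"fraction must be in (0, 0.5], got {fraction}")
    k = round_half_up(fraction * panel_n)
    if k < 2:
        raise ConfigError(f"bulk size {k} too small (fraction {fraction} of {panel_n})")
    if 2 * k > panel_n:
        raise ConfigError(f"low and high bulks of size {k} would overlap in a panel of {panel_n}")

    order = sorted(pheno.values.index, key=lambda a: (pheno.values[a], a))
    low = order[:k]
    high = sorted(order[-k:], key=lambda a: (-pheno.values[a], a))

    rng = np.random.default_rng(seed)
    ids = np.array(pheno.values.index, dtype=object)
    panel_mean, panel_median, panel_sd = pheno.mean, pheno.median, pheno.sd
    tol = 0.25 * panel_sd

    best: np.ndarray | None = None
    best_score = np.inf
    attempts = MATCH_RANDOM_MAX_ATTEMPTS if match_random else 1
    for _ in range(attempts):
        draw = rng.choice(ids, size=k, replace=False)
        vals = pheno.values[draw].to_numpy()
        dev_mean = abs(float(np.mean(vals)) - panel_mean)
        dev_median = abs(float(np.median(vals)) - panel_median)
        score = max(dev_mean, dev_median)
        if score < best_score:
            best_score, best = score, draw
        if not match_random or (dev_mean <= tol and dev_median <= tol):
            best = draw
            break
    else:
        logger.warning(
            "assign_bulks: random bulk moment-matching not met after %d attempts "
            "(best deviation %.3g, tolerance %.3g); keeping best attempt",
            attempts,
            best_score,
            tol,
        )
    assert best is not None
    return BulkAssignment(
        fraction=fraction,
        bulk_size=k,
        low=list(low),
        high=list(high),
        random=[str(a) for a in best],
        seed=seed,
        panel_n=panel_n,
    )


def pool_alleles(geno: GenotypeMatrix, bulks: BulkAssignment) -> PooledCounts:
    """Pool per-bulk allele counts for every SNP.

    ``alt_count`` is the sum of alt dosages over the non-missing members of
    each bulk; missing calls contribute nothing to either allele.
    """
    alt = np.zeros((geno.n_sites, 3), dtype=np.int64)
    called = np.zeros((geno.n_sites, 3), dtype=np.int64)
    for b, bulk in enumerate(BULK_ORDER):
        rows = geno.accession_rows(bulks.members(bulk))
        sub = geno.calls[rows]  # (k, n_sites)
        ok = sub != MISSING
        alt[:, b] = np.where(ok, sub, 0).sum(axis=0)
        called[:, b] = ok.sum(axis=0)
    return PooledCounts(
        snp_ids=[s.snp_id for s in geno.sites],
        chroms=geno.chroms(),
        positions=geno.positions(),
        alt_count=alt,
        n_called=called,
        bulk_size=bulks.bulk_size,
    )


def filter_snps(pooled: PooledCounts, cfg: FilterConfig | None = None) -> np.ndarray:
    """Indices of SNPs retained by the MAF and depth rules.

    MAF is computed from the three bulks' combined allele counts; a SNP is
    retained iff ``maf >= maf_min`` and ``total_depth >= depth_min``.  No
    missingness filter is applied, by design.
    """
    cfg = cfg or FilterConfig()
    depth_min = cfg.depth_min if cfg.depth_min is not None else pooled.bulk_size
    maf = pooled.maf()
    with np.errstate(invalid="ignore"):
        keep = (maf >= cfg.maf_min) & (pooled.total_depth >= depth_min)
    keep &= ~np.isnan(maf)
    idx = np.flatnonzero(keep)
    logger.info(
        "filter_snps: retained %d / %d SNPs (maf_min=%.3g, depth_min=%d)",
        len(idx),
        pooled.n_snps,
        cfg.maf_min,
        depth_min,
    )
    if len(idx) == 0:
        logger.warning("filter_snps: no SNPs retained")
    return idx


def filter_report(pooled: PooledCounts, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-SNP filter report: maf, total depth and retained flag."""
    cfg = cfg or FilterConfig()
    retained = np.zeros(pooled.n_snps, dtype=bool)
    retained[filter_snps(pooled, cfg)] = True
    return pd.DataFrame(
        {
            "snp_id": pooled.snp_ids,
            "maf": pooled.maf(),
            "total_depth": pooled.total_depth,
            "retained": retained,
        }
    )


def write_bulk_csv(bulks: BulkAssignment, pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    bulks.to_frame(pheno).to_csv(path, index=False)
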