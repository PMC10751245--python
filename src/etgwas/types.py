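"""Core in-memory containers: variant sites, genotype matrices, phenotypes, genes.

Conventions owned here and used by every other module:

* Physical coordinates are 1-based and inclusive, as in VCF and GFF3.
* Genotype calls are alternate-allele dosages in {0, 1, 2}; a missing call
  (including half-missing genotypes such as ``./1``) is stored as ``MISSING``.
* The heterozygote dosage is 1 regardless of phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: chromosome, 1-based position, id and alleles."""

    chrom: str
    pos: int
    snp_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ConfigError(f"site {self.snp_id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ConfigError(f"site {self.snp_id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs with alt-allele dosage calls.

    ``calls`` has shape ``(len(accessions), len(sites))`` with entries in
    {0, 1, 2, MISSING}.  Sites must be sorted by (chrom, pos) and accession
    ids must be unique.
    """

    sites: list[VariantSite]
    accessions: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.accessions), len(self.sites)):
            raise ConfigError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.sites)} sites"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ConfigError("duplicate accession ids in genotype matrix")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise ConfigError("sites must be sorted by (chrom, pos)")
        self._acc_index = {a: i for i, a in enumerate(self.accessions)}

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def accession_rows(self, ids: list[str]) -> np.ndarray:
        """Row indices for the given accession ids (raises on unknown ids)."""
        missing = [a for a in ids if a not in self._acc_index]
        if missing:
            from .errors import IdMismatchError

            raise IdMismatchError(f"accessions absent from genotypes: {missing}")
        return np.array([self._acc_index[a] for a in ids], dtype=np.intp)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def site_indices_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites with ``chrom`` and ``start <= pos <= end``."""
        return np.array(
            [i for i, s in enumerate(self.sites) if s.chrom == chrom and start <= s.pos <= end],
            dtype=np.intp,
        )


@dataclass
class PhenotypeTable:
    """One trait value per accession (pre-averaged across replicates)."""

    trait_name: str
    values: pd.Series  # index: accession id, values: float

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ConfigError(f"duplicate accession ids in phenotype table: {dups}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ConfigError("phenotype values must be finite")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))

    @property
    def median(self) -> float:
        return float(self.values.median())


@dataclass(frozen=True)
class GeneModel:
    """A gene feature from a GFF3 annotation (1-based inclusive interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end
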