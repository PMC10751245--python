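"""Synthetic structured panels with planted causal and rare variants.

Genotypes follow the Balding-Nichols model: each SNP draws an ancestral
allele frequency, each of the (default three) subpopulations perturbs it
with a Beta distribution governed by the divergence parameter F_ST, and
diploid dosages are binomial draws from the subpopulation frequency.  This
emulates a diversity panel whose PCA separates into distinct clusters, the
setting the pooled-bulk association is designed for.  Local LD is induced
by copy-with-mutation tiling around causal sites so the candidate-gene scan
has signal; causal SNPs can be forced to a target (possibly rare) allele
frequency by rejection sampling.  Phenotypes are additive in the causal
dosages plus optional subpopulation offsets and Gaussian noise scaled to a
target narrow-sense heritability.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, EtgwasError
from .io import write_gff_genes, write_vcf
from .types import MISSING, GeneModel, GenotypeMatrix, PhenotypeTable, VariantSite

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class CausalSpec:
    """A planted causal SNP: column index, additive effect, target frequency.

    ``effect`` is in trait units per alternate allele copy.  When
    ``target_freq`` is set, the SNP's dosages are drawn iid Binomial(2, f)
    and rejected until the realised frequency is within ``freq_tol`` of the
    target (rare variants need this to exist at all in a finite panel).
    """

    index: int
    effect: float
    target_freq: float | None = None
    rare: bool = False
    freq_tol: float = 0.02


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults describe the standard fixture: a 300-accession, 5,000-SNP
    panel with three subpopulation clusters (F_ST 0.1), a yield-like trait
    with heritability 0.4, one common causal SNP (frequency 0.3) and one
    rare strong-effect causal SNP (frequency 0.03).
    """

    n_accessions: int = 300
    n_snps: int = 5000
    n_subpops: int = 3
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: list[CausalSpec] = field(default_factory=list)
    h2: float = 0.4
    subpop_shift: tuple[float, ...] | None = None
    missing_rate: float = 0.0
    baseline: float = 3.5  # panel-level trait mean, in trait units (e.g. grams)
    noise_sd: float = 1.0  # residual sd when no genetic variance is present
    chrom: str = "1"
    spacing: int = 2000  # bp between adjacent SNPs
    ld_block_half: int = 8  # SNPs tiled on each side of a causal site
    ld_copy_prob: float = 0.9
    skew_transform: bool = False  # exponential transform for right-skewed traits
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ConfigError("h2 must be in [0, 1)")
        if self.fst < 0 or self.fst > 0.3:
            raise ConfigError("fst must be in [0, 0.3]")
        for c in self.causal:
            if not (0 <= c.index < self.n_snps):
                raise ConfigError(f"causal index {c.index} out of range")
        if self.subpop_shift is not None and len(self.subpop_shift) != self.n_subpops:
            raise ConfigError("subpop_shift length must equal n_subpops")


@dataclass
class SimTruth:
    """Ground truth written alongside simulated panels for oracle tests."""

    causal: list[dict]
    labels: np.ndarray  # per-accession subpopulation index
    realized_freqs: np.ndarray  # per-SNP alt allele frequency (pre-missingness)
    realized_h2: float
    genetic_values: np.ndarray
    complete_calls: np.ndarray  # dosages before missingness masking

    def to_json(self) -> dict:
        return {
            "causal": self.causal,
            "labels": self.labels.tolist(),
            "realized_h2": self.realized_h2,
        }


def _force_frequency(rng: np.random.Generator, n: int, spec: CausalSpec) -> np.ndarray:
    """Draw an iid Binomial(2, f) column with realised frequency near target."""
    assert spec.target_freq is not None
    for _ in range(200):
        col = rng.binomial(2, spec.target_freq, size=n)
        freq = col.sum() / (2 * n)
        if abs(freq - spec.target_freq) <= spec.freq_tol and 0 < col.sum() < 2 * n and (col > 0).sum() >= 2:
            return col
    raise EtgwasError(
        f"could not realise target frequency {spec.target_freq} at tolerance "
        f"{spec.freq_tol} in a panel of {n} (infeasible target?)"
    )


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a structured genotype panel under Balding-Nichols."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_accessions, cfg.n_snps
    labels = rng.integers(0, cfg.n_subpops, size=n)

    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    if cfg.fst > 0:
        F = cfg.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    calls = rng.binomial(2, p_sub[labels, :]).astype(np.int16)

    # planted causal columns, optionally frequency-forced
    for spec in cfg.causal:
        if spec.target_freq is not None:
            calls[:, spec.index] = _force_frequency(rng, n, spec)

    # LD tiling: neighbours copy the causal column per accession with high
    # probability, yielding r^2 ~ copy_prob^2 against the causal SNP
    for spec in cfg.causal:
        causal_col = calls[:, spec.index].copy()
        for off in range(-cfg.ld_block_half, cfg.ld_block_half + 1):
            j = spec.index + off
            if off == 0 or not (0 <= j < m):
                continue
            mask = rng.random(n) < cfg.ld_copy_prob
            calls[mask, j] = causal_col[mask]

    complete = calls.copy()
    realized = complete.sum(axis=0) / (2 * n)

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, MISSING, calls).astype(np.int16)

    accessions = [f"ACC{i:04d}" for i in range(n)]
    ref = _BASES[rng.integers(0, 4, size=m)]
    alt_shift = rng.integers(1, 4, size=m)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    sites = [
        VariantSite(
            chrom=cfg.chrom,
            pos=1 + cfg.spacing * i,
            snp_id=f"snp{i:05d}",
            ref_allele=str(ref[i]),
            alt_allele=str(alt[i]),
        )
        for i in range(m)
    ]
    geno = GenotypeMatrix(sites=sites, accessions=accessions, calls=calls)
    truth = SimTruth(
        causal=[
            {
                "index": c.index,
                "pos": sites[c.index].pos,
                "chrom": cfg.chrom,
                "effect": c.effect,
                "target_freq": c.target_freq,
                "rare": c.rare,
                "realized_freq": float(realized[c.index]),
            }
            for c in cfg.causal
        ],
        labels=labels,
        realized_freqs=realized,
        realized_h2=float("nan"),
        genetic_values=np.zeros(n),
        complete_calls=complete,
    )
    return geno, truth


def simulate_phenotype(
    geno: GenotypeMatrix, truth: SimTruth, cfg: SimConfig
) -> PhenotypeTable:
    """Additive phenotype with subpopulation offsets and h2-scaled noise.

    The residual variance is chosen so that the causal genetic variance over
    total variance (excluding structure offsets) matches ``h2`` on the
    realised sample: sigma^2 = var(g) * (1 - h2) / h2.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = geno.n_accessions
    g = np.zeros(n)
    for c in truth.causal:
        g += c["effect"] * truth.complete_calls[:, c["index"]].astype(float)
    var_g = float(np.var(g))
    if var_g > 0 and cfg.h2 > 0:
        sigma = float(np.sqrt(var_g * (1 - cfg.h2) / cfg.h2))
    else:
        if var_g > 0 and cfg.h2 <= 0:
            warnings.warn("h2=0 with nonzero causal effects; using noise_sd for residual scale")
        sigma = cfg.noise_sd
    shifts = np.zeros(n)
    if cfg.subpop_shift is not None:
        shifts = np.asarray(cfg.subpop_shift, dtype=float)[truth.labels]
    eps = rng.normal(0.0, sigma, size=n)
    y = cfg.baseline + g - g.mean() + shifts + eps
    if cfg.skew_transform:
        centred = (y - y.mean()) / max(np.std(y), 1e-12)
        y = np.exp(centred / 1.5) * max(np.std(y), 1e-12) + y.mean() - 1.0
    truth.genetic_values = g
    truth.realized_h2 = var_g / float(np.var(y)) if np.var(y) > 0 else 0.0
    return PhenotypeTable(trait_name="SPY", values=pd.Series(y, index=geno.accessions))


def standard_fixture_config(seed: int = 0) -> SimConfig:
    """The standard test panel: n=300, 5,000 SNPs, one common and one rare
    causal SNP, three clusters with modest phenotype offsets."""
    return SimConfig(
        n_accessions=300,
        n_snps=5000,
        n_subpops=3,
        fst=0.1,
        causal=[
            CausalSpec(index=1500, effect=1.0, target_freq=0.30),
            CausalSpec(index=3500, effect=3.0, target_freq=0.03, rare=True),
        ],
        h2=0.4,
        subpop_shift=(-0.3, 0.0, 0.3),
        seed=seed,
    )


def standard_fixture(seed: int = 0) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    cfg = standard_fixture_config(seed)
    geno, truth = simulate_genotypes(cfg)
    pheno = simulate_phenotype(geno, truth, cfg)
    return geno, pheno, truth


def toy_gff_over_causals(cfg: SimConfig, truth: SimTruth, half_width: int = 2000) -> list[GeneModel]:
    """Toy gene models, one interval over each causal SNP."""
    genes = []
    for i, c in enumerate(truth.causal):
        genes.append(
            GeneModel(
                gene_id=f"gene_causal_{i}",
                chrom=c["chrom"],
                start=max(1, c["pos"] - half_width),
                end=c["pos"] + half_width,
                strand="+",
                description=f"synthetic gene over causal SNP index {c['index']}",
            )
        )
    return genes


def emit_fixtures(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    truth: SimTruth,
    outdir: str | Path,
    cfg: SimConfig | None = None,
) -> dict[str, Path]:
    """Write the simulated panel in the pipeline's native file formats.

    Produces an uncompressed VCF, a phenotype CSV, a toy GFF3 with one gene
    over each causal SNP, and a truth JSON for oracle tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "pheno": outdir / "phenotype.csv",
        "gff": outdir / "genes.gff3",
        "truth": outdir / "truth.json",
    }
    write_vcf(geno, paths["vcf"])
    pd.DataFrame({"accession": pheno.values.index, pheno.trait_name: pheno.values.to_numpy()}).to_csv(
        paths["pheno"], index=False
    )
    if cfg is None:
        cfg = SimConfig(n_accessions=geno.n_accessions, n_snps=geno.n_sites)
    write_gff_genes(toy_gff_over_causals(cfg, truth), paths["gff"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return paths
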