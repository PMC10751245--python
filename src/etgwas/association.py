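"""The screening core: per-SNP GLM over ordered bulks, genomic control, PVE.

Each retained SNP is tested for a monotone allele-frequency trend across the
low, random and high bulks, coded as an ordinal covariate x = 0, 1, 2 with
the random (control) bulk at the midpoint.  The default model is a binomial
GLM on pooled allele counts,

    alt_count_b ~ Binomial(depth_b, pi_b),   logit(pi_b) = alpha + beta * x_b,

fitted by Newton scoring (iteratively reweighted least squares), with a
1-df Wald chi-square test on beta.  A weighted-least-squares fit of the
per-bulk alt frequencies (weights = allele-copy depth) is available as an
alternative model.  Study-wide inflation from population stratification is
absorbed by Devlin-Roeder genomic control on the Wald statistics, and each
SNP's phenotypic variance explained is computed from (beta, se, MAF, N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

from .bulking import PooledCounts
from .errors import ConfigError, DegenerateSnpError, EtgwasError

logger = logging.getLogger(__name__)

#: Ordinal bulk codes: low=0, random=1, high=2.
BULK_CODES = np.array([0.0, 1.0, 2.0])

#: Median of the 1-df chi-square distribution, the null expectation used by
#: genomic control.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_MAX_ITER = 60
_TOL = 1e-10
_MAX_STEP = 8.0  # Newton step damping; guards quasi-separated SNPs


@dataclass
class Thresholds:
    """Genome-wide significance cutoffs (primary 1e-4, stringent 1e-6)."""

    primary: float = 1e-4
    secondary: float = 1e-6

    def __post_init__(self) -> None:
        if self.secondary > self.primary:
            raise ConfigError("secondary threshold must be <= primary")


@dataclass
class GlmFit:
    """Per-SNP fit: slope, standard error, Wald statistic and p-value."""

    beta: float
    se: float
    stat: float
    p_raw: float
    converged: bool
    n_iter: int
    separated: bool = False
    r2: float = float("nan")  # McFadden pseudo-R^2 (binomial model only)


def _binomial_loglik(alt: np.ndarray, depth: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Full binomial log-likelihood rows, including the binomial coefficient."""
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return (
        gammaln(depth + 1)
        - gammaln(alt + 1)
        - gammaln(depth - alt + 1)
        + alt * np.log(mu)
        + (depth - alt) * np.log(1 - mu)
    ).sum(axis=-1)


def _fit_binomial_many(alt: np.ndarray, depth: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised Newton-scoring fit of the two-parameter logistic trend.

    ``alt`` and ``depth`` have shape (m, 3).  Bulks with zero depth carry
    zero weight and drop out naturally.  Returns arrays of beta, se, stat,
    p_raw, convergence flags, iteration counts, separation flags and
    McFadden pseudo-R^2.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    m = alt.shape[0]
    x = BULK_CODES

    tot_alt = alt.sum(axis=1)
    tot_depth = depth.sum(axis=1)
    degenerate = (tot_alt <= 0) | (tot_alt >= tot_depth) | ((depth > 0).sum(axis=1) < 2)

    p0 = np.clip(np.where(tot_depth > 0, tot_alt / np.maximum(tot_depth, 1), 0.5), 1e-6, 1 - 1e-6)
    a = np.log(p0 / (1 - p0))
    b = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    n_iter = np.zeros(m, dtype=np.int32)
    S0 = S1 = S2 = np.ones(m)

    for it in range(_MAX_ITER):
        eta = a[:, None] + b[:, None] * x
        mu = expit(eta)
        w = depth * mu * (1 - mu)
        S0 = w.sum(axis=1)
        S1 = (w * x).sum(axis=1)
        S2 = (w * x * x).sum(axis=1)
        r = alt - depth * mu
        g0 = r.sum(axis=1)
        g1 = (r * x).sum(axis=1)
        det = S0 * S2 - S1 * S1
        ok = (det > 1e-12) & ~degenerate & ~converged
        da = np.zeros(m)
        db = np.zeros(m)
        da[ok] = (S2[ok] * g0[ok] - S1[ok] * g1[ok]) / det[ok]
        db[ok] = (S0[ok] * g1[ok] - S1[ok] * g0[ok]) / det[ok]
        step = np.maximum(np.abs(da), np.abs(db))
        shrink = np.where(step > _MAX_STEP, _MAX_STEP / np.maximum(step, 1e-300), 1.0)
        a += da * shrink
        b += db * shrink
        newly = ok & (step < _TOL)
        n_iter[ok] += 1
        converged |= newly
        if (converged | degenerate).all():
            break

    # final information matrix at the solution
    eta = a[:, None] + b[:, None] * x
    mu = expit(eta)
    w = depth * mu * (1 - mu)
    S0 = w.sum(axis=1)
    S1 = (w * x).sum(axis=1)
    S2 = (w * x * x).sum(axis=1)
    det = S0 * S2 - S1 * S1
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.where(det > 0, S0 / np.maximum(det, 1e-300), np.nan))
        stat = (b / se) ** 2
    p_raw = stats.chi2.sf(stat, 1)
    separated = ~converged & ~degenerate

    # McFadden pseudo-R^2 against the intercept-only model
    eta0 = np.log(p0 / (1 - p0))[:, None] * np.ones_like(x)
    ll = _binomial_loglik(alt, depth, eta)
    ll0 = _binomial_loglik(alt, depth, eta0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ll0 < 0, 1.0 - ll / ll0, 0.0)

    return {
        "beta": b,
        "se": se,
        "stat": stat,
        "p_raw": p_raw,
        "converged": converged,
        "n_iter": n_iter,
        "separated": separated,
        "degenerate": degenerate,
        "r2": r2,
    }


def _fit_wls_many(alt: np.ndarray, depth: np.ndarray) -> dict[str, np.ndarray]:
    """Weighted least squares of per-bulk alt frequency on the bulk code.

    Weights are the per-bulk allele-copy depths; with three bulks and two
    parameters one residual degree of freedom remains, so the error variance
    is estimated from the single residual and the Wald statistic uses the
    1-df chi-square reference, mirroring the binomial route.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    m = alt.shape[0]
    x = BULK_CODES
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    w = depth.copy()
    w[~np.isfinite(y)] = 0.0
    y = np.nan_to_num(y)

    S0 = w.sum(axis=1)
    S1 = (w * x).sum(axis=1)
    S2 = (w * x * x).sum(axis=1)
    Sy = (w * y).sum(axis=1)
    Sxy = (w * x * y).sum(axis=1)
    det = S0 * S2 - S1 * S1
    tot_alt = alt.sum(axis=1)
    tot_depth = depth.sum(axis=1)
    degenerate = (tot_alt <= 0) | (tot_alt >= tot_depth) | ((depth > 0).sum(axis=1) < 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (S0 * Sxy - S1 * Sy) / det
        a = (Sy - S1 * b) / S0
        resid = y - (a[:, None] + b[:, None] * x)
        rss = (w * resid**2).sum(axis=1)
        dof = (w > 0).sum(axis=1) - 2  # 1 with all three bulks present
        sigma2 = np.where(dof > 0, rss / np.maximum(dof, 1), np.nan)
        se = np.sqrt(sigma2 * S0 / det)
        stat = (b / se) ** 2
    p_raw = stats.chi2.sf(stat, 1)
    return {
        "beta": b,
        "se": se,
        "stat": stat,
        "p_raw": p_raw,
        "converged": np.ones(m, dtype=bool),
        "n_iter": np.ones(m, dtype=np.int32),
        "separated": np.zeros(m, dtype=bool),
        "degenerate": degenerate,
        "r2": np.full(m, np.nan),
    }


def fit_snp_glm(
    alt_counts: np.ndarray, depths: np.ndarray, model: str = "binomial_logit"
) -> GlmFit:
    """Fit the bulk-trend GLM for one SNP.

    ``alt_counts`` and ``depths`` are length-3 arrays in (low, random, high)
    order; ``depths`` are allele copies (2 x called genotypes).  Raises
    :class:`DegenerateSnpError` for SNPs monomorphic after pooling.
    """
    if model not in ("binomial_logit", "wls_freq"):
        raise ConfigError(f"unknown model {model!r}")
    alt = np.asarray(alt_counts, dtype=float).reshape(1, 3)
    depth = np.asarray(depths, dtype=float).reshape(1, 3)
    fitter = _fit_binomial_many if model == "binomial_logit" else _fit_wls_many
    res = fitter(alt, depth)
    if res["degenerate"][0]:
        raise DegenerateSnpError("SNP is monomorphic (or <2 informative bulks) after pooling")
    return GlmFit(
        beta=float(res["beta"][0]),
        se=float(res["se"][0]),
        stat=float(res["stat"][0]),
        p_raw=float(res["p_raw"][0]),
        converged=bool(res["converged"][0]),
        n_iter=int(res["n_iter"][0]),
        separated=bool(res["separated"][0]),
        r2=float(res["r2"][0]),
    )


def genomic_control(stats_vec: np.ndarray) -> tuple[float, np.ndarray]:
    """Devlin-Roeder genomic control on 1-df Wald chi-square statistics.

    lambda = median(chi^2) / 0.4549, clamped at 1 so p-values are never made
    more significant; adjusted p-values come from chi^2 / lambda on 1 df.
    """
    stats_vec = np.asarray(stats_vec, dtype=float)
    if stats_vec.size == 0:
        raise EtgwasError("genomic_control: empty statistic vector")
    if stats_vec.size < 100:
        logger.warning(
            "genomic_control: only %d statistics; lambda estimate is unstable", stats_vec.size
        )
    lam = float(np.nanmedian(stats_vec) / CHI2_1DF_MEDIAN)
    lam = max(lam, 1.0)
    p_adj = stats.chi2.sf(stats_vec / lam, 1)
    return lam, p_adj


def compute_pve(beta, se, maf, n_panel):
    """Phenotypic variance explained by a SNP.

    The pipeline's PVE formula

        PVE = 2 beta^2 MAF (1 - MAF)
              / [2 beta^2 MAF (1 - MAF) + 2 se(beta)^2 N MAF (1 - MAF)]

    simplifies algebraically to ``beta^2 / (beta^2 + N se^2)`` because the
    ``2 MAF (1 - MAF)`` factor cancels; both forms are computed and checked
    against each other.  ``n_panel`` is the number of phenotyped accessions
    in the diversity panel.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    maf = np.asarray(maf, dtype=float)
    if np.any(se <= 0):
        raise ConfigError("compute_pve: se must be > 0")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ConfigError("compute_pve: maf must be in (0, 0.5]")
    if n_panel < 1:
        raise ConfigError("compute_pve: N must be >= 1")
    g = 2.0 * maf * (1.0 - maf)
    printed = (g * beta**2) / (g * beta**2 + 2.0 * se**2 * n_panel * maf * (1.0 - maf))
    simplified = beta**2 / (beta**2 + n_panel * se**2)
    if not np.allclose(printed, simplified, rtol=1e-12, atol=1e-15):
        raise EtgwasError("compute_pve: formula forms disagree")  # pragma: no cover
    return simplified if simplified.ndim else float(simplified)


def run_association(
    pooled: PooledCounts,
    retained: np.ndarray,
    n_panel: int,
    model: str = "binomial_logit",
) -> pd.DataFrame:
    """Fit every retained SNP, apply genomic control and compute PVE.

    Returns a DataFrame (one row per retained, non-degenerate SNP) with
    columns chrom, pos, snp_id, beta, se, stat, p_raw, p_adj, pve, maf, r2
    plus fit diagnostics; the genomic-control inflation factor is stored in
    ``df.attrs['lambda_gc']``.
    """
    if model not in ("binomial_logit", "wls_freq"):
        raise ConfigError(f"unknown model {model!r}")
    retained = np.asarray(retained, dtype=np.intp)
    alt = pooled.alt_count[retained]
    depth = pooled.depth[retained]
    fitter = _fit_binomial_many if model == "binomial_logit" else _fit_wls_many
    res = fitter(alt, depth)
    ok = ~res["degenerate"] & np.isfinite(res["se"]) & (res["se"] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("run_association: skipped %d degenerate SNPs", n_bad)
    idx = retained[ok]
    maf = pooled.maf()[idx]
    lam, p_adj = genomic_control(res["stat"][ok])
    pve = compute_pve(res["beta"][ok], res["se"][ok], np.clip(maf, 1e-9, 0.5), n_panel)
    df = pd.DataFrame(
        {
            "chrom": pooled.chroms[idx],
            "pos": pooled.positions[idx],
            "snp_id": np.asarray(pooled.snp_ids, dtype=object)[idx],
            "beta": res["beta"][ok],
            "se": res["se"][ok],
            "stat": res["stat"][ok],
            "p_raw": res["p_raw"][ok],
            "p_adj": p_adj,
            "pve": pve,
            "maf": maf,
            "r2": res["r2"][ok],
            "converged": res["converged"][ok],
            "separated": res["separated"][ok],
        }
    )
    df.attrs["lambda_gc"] = lam
    df.attrs["n_panel"] = n_panel
    logger.info("run_association: %d SNPs fitted, lambda_gc=%.4f", len(df), lam)
    return df


def call_mtas(results: pd.DataFrame, thr: Thresholds | None = None) -> pd.DataFrame:
    """Marker-trait associations: SNPs with adjusted p <= primary threshold.

    Each MTA is tagged with whether it also clears the stringent secondary
    cutoff; the list is sorted by (chrom, pos).
    """
    thr = thr or Thresholds()
    if results is None or len(results) == 0:
        return pd.DataFrame(columns=list(results.columns) + ["secondary"] if results is not None else [])
    mtas = results[results["p_adj"] <= thr.primary].copy()
    mtas["secondary"] = mtas["p_adj"] <= thr.secondary
    return mtas.sort_values(["chrom", "pos"]).reset_index(drop=True)
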