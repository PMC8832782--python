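"""SNP heritability and genome-wide genetic correlation via LD score regression.

The polygenic model behind both fits: for SNP j with LD score l_j,

    E[chi2_j]        = 1 + N h2 l_j / M                      (univariate)
    E[z1_j z2_j]     = sqrt(N1 N2) rho_g l_j / M + Ns r / sqrt(N1 N2)

where h2 is the SNP heritability, rho_g the genetic covariance, M the
number of SNPs, N the sample sizes, Ns the number of overlapping samples
and r the phenotypic correlation among them.  Both quantities are the
slope of a weighted two-pass regression on l_j; standard errors come from
a delete-a-block jackknife over contiguous SNP blocks.

The genetic correlation is r_g = rho_g / sqrt(h2_1 h2_2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SumStatsError, align_alleles

MIN_SNPS = 200


@dataclass
class OverlapSpec:
    """Sample overlap between two GWAS cohorts.

    n_s
        Number of overlapping samples (default 0: non-overlapping cohorts).
    r_pheno
        Phenotypic correlation within the overlapping samples.
    """

    n_s: float = 0.0
    r_pheno: float = 0.0

    def __post_init__(self) -> None:
        if self.n_s < 0:
            raise ValueError("n_s must be >= 0")
        if abs(self.r_pheno) > 1:
            raise ValueError("|r_pheno| must be <= 1")

    def intercept(self, n1: float, n2: float) -> float:
        """The cross-trait regression intercept N_s r / sqrt(N1 N2)."""
        return self.n_s * self.r_pheno / np.sqrt(n1 * n2)


@dataclass
class H2Estimate:
    h2: float
    se: float
    intercept: float
    intercept_se: float
    m: int
    n: float
    n_blocks: int


@dataclass
class RgEstimate:
    h2_1: float
    h2_2: float
    gencov: float
    rg: float | None
    rg_se: float | None
    p: float | None
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    m: int
    n1: float
    n2: float
    n_blocks: int
    gencov_se: float | None = None
    out_of_bounds: bool = False
    pseudovalues: np.ndarray | None = field(default=None, repr=False)


def _wls(x, y, w, fixed_intercept=None):
    """Weighted least squares of y on [1, x] (or on x with fixed intercept).

    Returns (intercept, slope)."""
    if fixed_intercept is not None:
        yy = y - fixed_intercept
        slope = np.sum(w * x * yy) / np.sum(w * x * x)
        return fixed_intercept, slope
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    intercept = (sy * sxx - sx * sxy) / det
    return intercept, slope


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    """Boundaries of n_blocks contiguous, near-equal SNP blocks."""
    return np.linspace(0, m, n_blocks + 1).astype(int)


class _JackknifeWLS:
    """Delete-a-block weighted regression with O(1) per-block updates.

    Accumulates the 2x2 normal equations per block so each delete-one
    refit is a rank-correction, not a re-scan.
    """

    def __init__(self, x, y, w, bounds, fixed_intercept=None):
        self.fixed = fixed_intercept
        n_blocks = len(bounds) - 1
        stats = np.zeros((n_blocks, 5))
        yy = y if fixed_intercept is None else y - fixed_intercept
        for b in range(n_blocks):
            s = slice(bounds[b], bounds[b + 1])
            xb, yb, wb = x[s], yy[s], w[s]
            stats[b] = [
                np.sum(wb), np.sum(wb * xb), np.sum(wb * yb),
                np.sum(wb * xb * xb), np.sum(wb * xb * yb),
            ]
        self.block_stats = stats
        self.totals = stats.sum(axis=0)

    def _solve(self, t):
        sw, sx, sy, sxx, sxy = t
        if self.fixed is not None:
            return self.fixed, sxy / sxx
        det = sw * sxx - sx * sx
        return (sy * sxx - sx * sxy) / det, (sw * sxy - sx * sy) / det

    def full(self):
        return self._solve(self.totals)

    def delete_block(self, b):
        return self._solve(self.totals - self.block_stats[b])


def _jackknife_se(theta_full, theta_del):
    """SE of an estimator from delete-one-block pseudovalues."""
    theta_del = np.asarray(theta_del, dtype=float)
    g = len(theta_del)
    pseudo = g * theta_full - (g - 1) * theta_del
    return float(np.std(pseudo, ddof=1) / np.sqrt(g)), pseudo


def _merge_ld(stats: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    if "L2" not in ld.columns:
        raise SumStatsError("LD score table must have columns SNP, L2")
    m = stats.merge(ld[["SNP", "L2"]], on="SNP", how="inner")
    return m.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)


def _h2_design(df: pd.DataFrame, m_total: int):
    """Design for chi2 ~ intercept + x with x = N l / M (slope = h2)."""
    ell = df["L2"].to_numpy(dtype=float)
    n = df["N"].to_numpy(dtype=float)
    x = n * ell / m_total
    chi2 = df["Z"].to_numpy(dtype=float) ** 2
    return x, chi2, ell, n


def _h2_weights(x, chi2, ell):
    """Two-pass heteroskedasticity weights 1/[max(l,1) * E[chi2]^2]."""
    a0, s0 = _wls(x, chi2, np.ones_like(x))
    pred = np.maximum(a0 + s0 * x, 0.05)
    return 1.0 / (np.maximum(ell, 1.0) * pred**2), (a0, s0)


def fit_h2(
    stats: pd.DataFrame,
    ld: pd.DataFrame,
    n_blocks: int = 200,
    m_total: int | None = None,
) -> H2Estimate:
    """Estimate SNP heritability by LD score regression.

    ``m_total`` is the number of SNPs M in the polygenic model (defaults to
    the number of regression SNPs).  The intercept is free; under a clean
    null it estimates 1.
    """
    df = _merge_ld(stats, ld)
    if len(df) < MIN_SNPS:
        raise SumStatsError(f"fit_h2: only {len(df)} SNPs after LD merge (< {MIN_SNPS})")
    if len(df) < n_blocks:
        raise SumStatsError(
            f"fit_h2: {len(df)} SNPs is fewer than n_blocks={n_blocks}"
        )
    m_total = m_total or len(df)
    x, chi2, ell, n = _h2_design(df, m_total)
    w, _ = _h2_weights(x, chi2, ell)

    bounds = _block_bounds(len(df), n_blocks)
    jk = _JackknifeWLS(x, chi2, w, bounds)
    icpt, slope = jk.full()
    dels = np.array([jk.delete_block(b) for b in range(n_blocks)])
    se_slope, _ = _jackknife_se(slope, dels[:, 1])
    se_icpt, _ = _jackknife_se(icpt, dels[:, 0])
    nbar = float(np.mean(n))
    return H2Estimate(
        h2=float(slope), se=se_slope, intercept=float(icpt),
        intercept_se=se_icpt, m=m_total, n=nbar, n_blocks=n_blocks,
    )


def fit_rg(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    ld: pd.DataFrame,
    overlap: OverlapSpec | None = None,
    n_blocks: int = 200,
    m_total: int | None = None,
    constrain_intercept: bool = False,
) -> RgEstimate:
    """Estimate genetic covariance and correlation between two traits.

    The two tables are allele-aligned on their shared SNPs, merged with the
    LD scores, and the product z1*z2 is regressed on sqrt(N1 N2) l / M with
    two-pass weights.  The cross-trait intercept absorbs sample overlap; it
    is free by default and constrained to ``overlap.intercept`` when
    ``constrain_intercept`` is set.  The jackknife is taken over the full
    (h2_1, h2_2, gencov) triple so the SE of r_g reflects all three fits.
    """
    merged = align_alleles(stats1, stats2)
    df = _merge_ld(merged, ld)
    if len(df) < MIN_SNPS:
        raise SumStatsError(f"fit_rg: only {len(df)} shared SNPs (< {MIN_SNPS})")
    if len(df) < n_blocks:
        raise SumStatsError(f"fit_rg: {len(df)} SNPs is fewer than n_blocks={n_blocks}")
    m_total = m_total or len(df)

    ell = df["L2"].to_numpy(dtype=float)
    z1 = df["Z"].to_numpy(dtype=float)
    z2 = df["Z_2"].to_numpy(dtype=float)
    n1 = df["N"].to_numpy(dtype=float)
    n2 = df["N_2"].to_numpy(dtype=float)
    n1bar, n2bar = float(np.mean(n1)), float(np.mean(n2))

    x1 = n1 * ell / m_total
    x2 = n2 * ell / m_total
    x12 = np.sqrt(n1 * n2) * ell / m_total
    y12 = z1 * z2

    # first (unweighted) pass supplies the expected-value predictions used
    # in the second-pass weights; using predictions keeps the self-pairing
    # case exactly proportional to the univariate weights, so rg(self) == 1.
    a1, s1 = _wls(x1, z1**2, np.ones_like(x1))
    a2, s2 = _wls(x2, z2**2, np.ones_like(x2))
    fixed = overlap.intercept(n1bar, n2bar) if (constrain_intercept and overlap) else None
    a12, s12 = _wls(x12, y12, np.ones_like(x12), fixed_intercept=fixed)

    pred1 = np.maximum(a1 + s1 * x1, 0.05)
    pred2 = np.maximum(a2 + s2 * x2, 0.05)
    pred12 = a12 + s12 * x12
    lmax = np.maximum(ell, 1.0)
    w1 = 1.0 / (lmax * pred1**2)
    w2 = 1.0 / (lmax * pred2**2)
    w12 = 1.0 / (lmax * (pred1 * pred2 + pred12**2))

    bounds = _block_bounds(len(df), n_blocks)
    jk1 = _JackknifeWLS(x1, z1**2, w1, bounds)
    jk2 = _JackknifeWLS(x2, z2**2, w2, bounds)
    jk12 = _JackknifeWLS(x12, y12, w12, bounds, fixed_intercept=fixed)
    i1, h2_1 = jk1.full()
    i2, h2_2 = jk2.full()
    i12, gencov = jk12.full()

    dels = np.empty((n_blocks, 3))
    for b in range(n_blocks):
        dels[b, 0] = jk1.delete_block(b)[1]
        dels[b, 1] = jk2.delete_block(b)[1]
        dels[b, 2] = jk12.delete_block(b)[1]
    gencov_se, _ = _jackknife_se(gencov, dels[:, 2])

    if h2_1 <= 0 or h2_2 <= 0:
        warnings.warn(
            "fit_rg: non-positive heritability for at least one trait; "
            "rg undefined, reporting genetic covariance only"
        )
        return RgEstimate(
            h2_1=float(h2_1), h2_2=float(h2_2), gencov=float(gencov),
            rg=None, rg_se=None, p=None, intercept_1=float(i1),
            intercept_2=float(i2), intercept_cross=float(i12),
            m=m_total, n1=n1bar, n2=n2bar, n_blocks=n_blocks,
            gencov_se=gencov_se,
        )

    rg = float(gencov / np.sqrt(h2_1 * h2_2))
    ok = (dels[:, 0] > 0) & (dels[:, 1] > 0)
    rg_del = np.where(
        ok, dels[:, 2] / np.sqrt(np.abs(dels[:, 0] * dels[:, 1])), rg
    )
    rg_se, pseudo = _jackknife_se(rg, rg_del)
    p = float(2.0 * sps.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else np.nan
    oob = abs(rg) > 1
    if oob:
        warnings.warn(f"fit_rg: |rg| = {abs(rg):.3f} > 1 (not truncated)")
    return RgEstimate(
        h2_1=float(h2_1), h2_2=float(h2_2), gencov=float(gencov), rg=rg,
        rg_se=rg_se, p=p, intercept_1=float(i1), intercept_2=float(i2),
        intercept_cross=float(i12), m=m_total, n1=n1bar, n2=n2bar,
        n_blocks=n_blocks, gencov_se=gencov_se, out_of_bounds=bool(oob),
        pseudovalues=pseudo,
    )


#: Bonferroni threshold for the four obesity-trait x outcome screen
RG_SCREEN_ALPHA = 0.05 / 4
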