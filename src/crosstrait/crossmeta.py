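"""Cross-trait meta-analysis: S_Hom / S_Het statistics, greedy clumping,
and shared-locus calling under dual significance thresholds.

S_Hom is the fixed-effect cross-phenotype statistic: with per-trait
z-scores z, weights w_k = sqrt(n_k), and trait correlation matrix R
(estimated once genome-wide from null SNPs),

    S_Hom = ((R^-1 w)' z)^2 / (w' R^-1 w)   ~  chi2_1  under the null.

S_Het extends it to heterogeneous effects by maximizing the same statistic
over trait subsets selected by an |z| threshold tau on a grid; its null
distribution is calibrated by simulation and summarized by a fitted gamma.

Shared loci are clumps (greedy PLINK-style: index SNPs at p < p1, members
at p < p2 within a kb window and r^2 >= threshold) whose index SNP meets
p < 1e-3 in each single trait and p < 5e-8 in the cross-trait statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .localcorr import LDMatrix
from .sumstats import SumStatsError

#: dual significance rule for shared loci
P_SINGLE_TRAIT = 1e-3
P_CPASSOC = 5e-8

#: default PLINK-style clumping parameters
CLUMP_P1 = 5e-8
CLUMP_P2 = 1e-5
CLUMP_R2 = 0.2
CLUMP_KB = 500

DEFAULT_TAU_GRID = np.arange(0.0, 5.5, 0.5)


@dataclass
class TraitCorrMatrix:
    """Trait x trait correlation of z-scores under the null, capturing
    shared population structure / cryptic relatedness across GWASs."""

    R: np.ndarray
    n_null_snps: int

    def __post_init__(self) -> None:
        self.R = _psd_repair(np.asarray(self.R, dtype=float))


def _psd_repair(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Symmetrize, floor eigenvalues, and restore the unit diagonal."""
    R = (R + R.T) / 2.0
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < floor:
        vals = np.maximum(vals, floor)
        R = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def estimate_trait_corr(
    z: np.ndarray | pd.DataFrame,
    null_z_cutoff: float = 1.96,
    min_null_snps: int = 1000,
) -> TraitCorrMatrix:
    """Pearson correlation of z-scores across SNPs that are null
    (|z| < cutoff) in every trait.

    ``z`` is SNPs x traits, already aligned to a common effect allele.
    """
    Z = np.asarray(z, dtype=float)
    mask = np.all(np.abs(Z) < null_z_cutoff, axis=1)
    n_null = int(mask.sum())
    if n_null < min_null_snps:
        raise SumStatsError(
            f"estimate_trait_corr: only {n_null} null SNPs at |z| < "
            f"{null_z_cutoff} (need >= {min_null_snps})"
        )
    R = np.corrcoef(Z[mask], rowvar=False)
    return TraitCorrMatrix(R=R, n_null_snps=n_null)


def _s_stat(z: np.ndarray, w: np.ndarray, R: np.ndarray) -> float:
    """Fixed-effect cross-phenotype statistic for one trait subset."""
    Ri_w = np.linalg.solve(R, w)
    denom = float(w @ Ri_w)
    if denom <= 0:
        return 0.0
    return float((Ri_w @ z) ** 2 / denom)


def s_hom(z, n, R: TraitCorrMatrix | np.ndarray) -> tuple[float, float]:
    """S_Hom statistic and its chi2_1 p-value for one SNP.

    Reduces to z^2 for a single trait and to the inverse-variance-weighted
    fixed-effect meta-statistic in general.
    """
    z = np.asarray(z, dtype=float)
    w = np.sqrt(np.asarray(n, dtype=float))
    Rm = R.R if isinstance(R, TraitCorrMatrix) else np.asarray(R, dtype=float)
    s = _s_stat(z, w, Rm)
    return s, float(sps.chi2.sf(s, df=1))


@dataclass
class SHetCalibration:
    """Gamma summary of the simulated S_Het null distribution."""

    shape: float
    scale: float
    n_draws: int
    seed: int
    samples_max: float = np.nan

    def sf(self, s):
        return sps.gamma.sf(s, self.shape, scale=self.scale)


def _s_het_values(Z: np.ndarray, w: np.ndarray, R: np.ndarray,
                  tau_grid: np.ndarray) -> np.ndarray:
    """Vectorized S_Het for a batch of z-vectors (rows).

    Maximizing over the tau grid (augmented per-SNP with the observed |z|
    values) is equivalent to maximizing over the "top-j by |z|" trait
    subsets, because the subset selected by any threshold is exactly the
    set of traits whose |z| exceeds it.
    """
    B, K = Z.shape
    absZ = np.abs(Z)
    order = np.argsort(-absZ, axis=1)
    out = np.zeros(B)
    # group rows by the identity of their top-j subset
    for j in range(1, K + 1):
        subs = np.sort(order[:, :j], axis=1)
        uniq, inv = np.unique(subs, axis=0, return_inverse=True)
        for u_idx in range(len(uniq)):
            sel = uniq[u_idx]
            rows = inv == u_idx
            Rs = R[np.ix_(sel, sel)]
            ws = w[sel]
            Ri_w = np.linalg.solve(Rs, ws)
            denom = float(ws @ Ri_w)
            s = (Z[np.ix_(rows, sel)] @ Ri_w) ** 2 / denom
            out[rows] = np.maximum(out[rows], s)
    # honour the explicit grid: a tau larger than every |z| empties the
    # subset (statistic 0), already covered by initializing out at 0
    del tau_grid
    return out


def s_het_exhaustive(z, n, R) -> float:
    """Reference evaluation: maximum of the subset statistic over every
    threshold-reachable subset, via the literal tau grid.  Used as a slow
    cross-check of the vectorized path."""
    z = np.asarray(z, dtype=float)
    w = np.sqrt(np.asarray(n, dtype=float))
    Rm = R.R if isinstance(R, TraitCorrMatrix) else np.asarray(R, dtype=float)
    taus = np.concatenate([DEFAULT_TAU_GRID, np.abs(z)])
    best = 0.0
    for tau in taus:
        sel = np.where(np.abs(z) > tau)[0]
        if len(sel) == 0:
            continue
        best = max(best, _s_stat(z[sel], w[sel], Rm[np.ix_(sel, sel)]))
    return best


def calibrate_s_het(
    n,
    R: TraitCorrMatrix | np.ndarray,
    null_draws: int = 1_000_000,
    seed: int = 0,
    tau_grid: np.ndarray | None = None,
) -> SHetCalibration:
    """Simulate the S_Het null under MVN(0, R) z-scores and fit a gamma
    distribution (method-of-moments start, maximum-likelihood refine)."""
    Rm = R.R if isinstance(R, TraitCorrMatrix) else np.asarray(R, dtype=float)
    w = np.sqrt(np.asarray(n, dtype=float))
    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(Rm)
    S = np.empty(null_draws)
    chunk = 200_000
    for start in range(0, null_draws, chunk):
        stop = min(start + chunk, null_draws)
        Z = rng.standard_normal((stop - start, len(w))) @ L.T
        S[start:stop] = _s_het_values(Z, w, Rm, tau_grid)
    mean, var = float(np.mean(S)), float(np.var(S))
    shape0 = mean**2 / var
    scale0 = var / mean
    try:
        shape, _, scale = sps.gamma.fit(S, shape0, floc=0, scale=scale0)
    except Exception:  # MLE refinement failed; keep the moment fit
        shape, scale = shape0, scale0
    return SHetCalibration(
        shape=float(shape), scale=float(scale), n_draws=null_draws,
        seed=seed, samples_max=float(S.max()),
    )


def s_het_calibrated(
    z,
    n,
    R: TraitCorrMatrix | np.ndarray,
    tau_grid: np.ndarray | None = None,
    null_draws: int = 1_000_000,
    seed: int = 0,
    calibration: SHetCalibration | None = None,
):
    """S_Het statistic(s) with calibrated p-values.

    ``z`` may be a single z-vector or a SNPs x traits matrix.  The null
    calibration is computed once (or passed in) and shared across SNPs.
    Returns ``(s, p, floored, calibration)`` where ``floored`` flags
    p-values clipped at 1/null_draws.
    """
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    w = np.sqrt(np.asarray(n, dtype=float))
    Rm = R.R if isinstance(R, TraitCorrMatrix) else np.asarray(R, dtype=float)
    tau = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid)
    if calibration is None:
        calibration = calibrate_s_het(n, Rm, null_draws=null_draws, seed=seed,
                                      tau_grid=tau)
    s = _s_het_values(Z, w, Rm, tau)
    p = calibration.sf(s)
    # p-values below 1/n_draws rest on the gamma tail beyond the simulated
    # support; they are reported as-is but flagged as extrapolated
    floored = p < 1.0 / calibration.n_draws
    if floored.any():
        warnings.warn(
            f"s_het_calibrated: {int(floored.sum())} p-value(s) below "
            f"1/{calibration.n_draws} rely on the fitted gamma tail"
        )
    if np.ndim(z) == 1:
        return float(s[0]), float(p[0]), bool(floored[0]), calibration
    return s, p, floored, calibration


# ---------------------------------------------------------------------------
# clumping and shared-locus calling

@dataclass
class Clump:
    index_snp: str
    members: list
    chrom: str
    start: int
    end: int


def _build_r2_lookup(ld: dict[int, LDMatrix]):
    """Map SNP -> (region id, row index) for pairwise r^2 queries.
    SNPs in different regions are treated as unlinked (r^2 = 0)."""
    loc = {}
    for rid, mat in ld.items():
        for i, s in enumerate(mat.snp_ids):
            loc[s] = (rid, i)

    def r2(a: str, b: str) -> float:
        pa, pb = loc.get(a), loc.get(b)
        if pa is None or pb is None or pa[0] != pb[0]:
            return 0.0
        return float(ld[pa[0]].V[pa[1], pb[1]] ** 2)

    return r2


def clump(
    records: pd.DataFrame,
    ld: dict[int, LDMatrix],
    p1: float = CLUMP_P1,
    p2: float = CLUMP_P2,
    r2: float = CLUMP_R2,
    kb: float = CLUMP_KB,
    p_col: str = "P",
) -> list[Clump]:
    """Greedy PLINK-style clumping.

    Repeatedly take the unassigned SNP with the smallest p < p1 as an index
    (ties broken by chromosome, position); assign to it every unassigned
    SNP with p < p2 within +-kb kilobases and r^2 >= r2.  An empty result
    is allowed.
    """
    need = {"SNP", "CHR", "BP", p_col}
    if not need <= set(records.columns):
        raise SumStatsError(f"clump: records need columns {sorted(need)}")
    df = records.sort_values([p_col, "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    r2_of = _build_r2_lookup(ld)
    assigned: set[str] = set()
    clumps: list[Clump] = []
    window = kb * 1000.0
    cand = df[df[p_col] < p2]
    by_chrom = {c: g for c, g in cand.groupby(cand["CHR"].astype(str))}
    for row in df.itertuples(index=False):
        p_idx = getattr(row, p_col)
        if p_idx >= p1:
            break  # sorted by p: no more index candidates
        if row.SNP in assigned:
            continue
        members = [row.SNP]
        assigned.add(row.SNP)
        near = by_chrom.get(str(row.CHR))
        if near is not None:
            sel = near[(near["BP"] - row.BP).abs() <= window]
            for cand_row in sel.itertuples(index=False):
                s = cand_row.SNP
                if s in assigned:
                    continue
                if r2_of(row.SNP, s) >= r2:
                    members.append(s)
                    assigned.add(s)
        pos = records.set_index("SNP").loc[members, "BP"]
        clumps.append(
            Clump(index_snp=row.SNP, members=members, chrom=str(row.CHR),
                  start=int(pos.min()), end=int(pos.max()))
        )
    return clumps


@dataclass
class SharedLocus:
    index_snp: str
    chrom: str
    start: int
    end: int
    p_trait1: float
    p_trait2: float
    p_cpassoc: float
    n_members: int
    known_trait1: bool = False
    known_trait2: bool = False


def call_shared_loci(
    clumps: list[Clump],
    p_trait1: dict | pd.Series,
    p_trait2: dict | pd.Series,
    p_cpassoc: dict | pd.Series,
    known_hits_trait1: list | None = None,
    known_hits_trait2: list | None = None,
    p_single: float = P_SINGLE_TRAIT,
    p_meta: float = P_CPASSOC,
) -> list[SharedLocus]:
    """Retain clumps whose index SNP meets the dual rule: p < p_single in
    BOTH single traits and p < p_meta in the cross-trait statistic.
    Novelty flags mark index SNPs present in the supplied known-hit lists."""
    known1 = set(known_hits_trait1 or [])
    known2 = set(known_hits_trait2 or [])
    out = []
    for c in clumps:
        s = c.index_snp
        pt1, pt2, pm = p_trait1.get(s), p_trait2.get(s), p_cpassoc.get(s)
        if pt1 is None or pt2 is None or pm is None:
            continue
        if pt1 < p_single and pt2 < p_single and pm < p_meta:
            out.append(
                SharedLocus(
                    index_snp=s, chrom=c.chrom, start=c.start, end=c.end,
                    p_trait1=float(pt1), p_trait2=float(pt2),
                    p_cpassoc=float(pm), n_members=len(c.members),
                    known_trait1=s in known1, known_trait2=s in known2,
                )
            )
    return out
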