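"""Synthetic GWAS summary statistics and MR instrument tables with known
generative truth.

``simulate_pair`` draws a pair of traits under the polygenic LD score
model: per-SNP true effects (beta1_j, beta2_j) are bivariate normal with
variances h2/M and correlation r_g; LD is block-diagonal AR(1); observed
z-scores are

    z_t = sqrt(N_t) V beta_t + eps_t,   eps_t ~ MVN(0, V),

with cross-trait noise correlation Ns r / sqrt(N1 N2) when the cohorts
overlap.  By construction E[z1_j z2_j] = sqrt(N1 N2) rho_g l_j / M +
Ns r / sqrt(N1 N2), the regression model the genome-wide fit assumes.

``simulate_mr`` draws two-sample MR instrument tables: instrument strengths
gamma_j ~ N(0, var_gamma), optional balanced or directional pleiotropy
alpha_j, observed beta_exp = gamma_j + noise and beta_out = theta gamma_j
+ alpha_j + noise, with truthful SEs.

All draws flow from one seeded generator per call; the same seed gives
byte-identical outputs.  Truth records serialize alongside the tables so
downstream checks read truth from data, not from test constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .ldsc import OverlapSpec
from .localcorr import LDMatrix, Region, compute_ld_scores, save_ld_matrices, save_regions
from .sumstats import CANONICAL_COLUMNS, log10p_from_z, write_sumstats


@dataclass
class SimPairConfig:
    m_snps: int = 20_000
    n1: float = 100_000
    n2: float = 100_000
    h2_1: float = 0.25
    h2_2: float = 0.25
    rg: float = 0.0
    n_regions: int = 50
    block_size: int = 50
    ar1_rho: float = 0.9
    overlap: OverlapSpec = field(default_factory=OverlapSpec)
    #: list of (region index, effect multiplier) for planted shared loci.
    #: mode "causal": each entry plants one shared causal variant (mid-SNP
    #: of the region's strongest-LD block) with effect size
    #: sqrt(mult * h2 / M) on both traits — a locus the meta-analysis and
    #: fine-mapping stages should find.  mode "diffuse": the whole region's
    #: per-SNP effect variance is multiplied by mult with cross-trait
    #: correlation 0.9 — concentrated local genetic covariance.
    shared_locus_spec: list = field(default_factory=list)
    shared_locus_mode: str = "causal"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rg) > 1:
            raise ValueError("|rg| must be <= 1")
        if self.shared_locus_mode not in ("causal", "diffuse"):
            raise ValueError("shared_locus_mode must be 'causal' or 'diffuse'")
        if not (0 <= self.h2_1 < 1 and 0 <= self.h2_2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if self.m_snps % self.n_regions:
            raise ValueError("m_snps must divide evenly into n_regions")
        if (self.m_snps // self.n_regions) % self.block_size:
            raise ValueError("region size must divide evenly into LD blocks")
        c = self.overlap.intercept(self.n1, self.n2)
        if abs(c) > 1:
            raise ValueError("overlap intercept exceeds 1: covariance not PSD")


@dataclass
class SimPairResult:
    stats1: pd.DataFrame
    stats2: pd.DataFrame
    ld: dict
    regions: list
    ldscores: pd.DataFrame
    truth: dict


#: scenario bank mirroring the study's trait pairs (genetic correlation
#: and GWAS sample sizes); used for parameter-recovery runs at desk scale
PAIR_PRESETS = {
    "null": dict(rg=0.0, n1=100_000, n2=100_000),
    "adult_bmi_pcos": dict(rg=0.47, n1=434_794, n2=113_238),
    "childhood_bmi_pcos": dict(rg=0.31, n1=39_620, n2=113_238),
    "whr_pcos": dict(rg=0.32, n1=381_152, n2=113_238),
    "whr_adj_bmi_pcos": dict(rg=0.09, n1=379_501, n2=113_238),
}


def pair_config(preset: str, **overrides) -> SimPairConfig:
    if preset not in PAIR_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(PAIR_PRESETS)}")
    kwargs = dict(PAIR_PRESETS[preset])
    kwargs.update(overrides)
    return SimPairConfig(**kwargs)


def _ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_pair(cfg: SimPairConfig) -> SimPairResult:
    """Generate a pair of summary-statistics tables plus LD reference."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.m_snps
    region_size = m // cfg.n_regions
    # cycle block LD decay over a deterministic ladder up to ar1_rho, so LD
    # scores span a wide range (as in real data) and the regression
    # intercept is anchored rather than extrapolated
    levels = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * cfg.ar1_rho
    V_levels = [_ar1_matrix(cfg.block_size, r) for r in levels]
    L_levels = [np.linalg.cholesky(V) for V in V_levels]

    # per-SNP polygenic effect-size scales and cross-trait correlation
    sd1 = np.full(m, np.sqrt(cfg.h2_1 / m))
    sd2 = np.full(m, np.sqrt(cfg.h2_2 / m))
    corr = np.full(m, float(cfg.rg))
    if cfg.shared_locus_mode == "diffuse":
        for region_idx, mult in cfg.shared_locus_spec:
            sl = slice(region_idx * region_size, (region_idx + 1) * region_size)
            sd1[sl] *= np.sqrt(mult)
            sd2[sl] *= np.sqrt(mult)
            corr[sl] = 0.9

    x = rng.standard_normal(m)
    y = rng.standard_normal(m)
    beta1 = sd1 * x
    beta2 = sd2 * (corr * x + np.sqrt(1.0 - corr**2) * y)

    # planted shared causal variants: deterministic effects, fully shared
    blocks_per_region = region_size // cfg.block_size
    planted: list[tuple[int, int]] = []  # (region, snp index)
    cov_extra = np.zeros(m)
    var_extra1 = np.zeros(m)
    var_extra2 = np.zeros(m)
    spec = cfg.shared_locus_spec if cfg.shared_locus_mode == "causal" else []
    for region_idx, mult in spec:
        base_block = region_idx * blocks_per_region
        # prefer the block on the strongest rung of the LD-decay ladder
        offsets = [(base_block + i) % 5 for i in range(blocks_per_region)]
        best = int(np.argmax(offsets))
        j = (base_block + best) * cfg.block_size + cfg.block_size // 2
        b1, b2 = np.sqrt(mult * cfg.h2_1 / m), np.sqrt(mult * cfg.h2_2 / m)
        beta1[j] += b1
        beta2[j] += b2
        cov_extra[j] += b1 * b2
        var_extra1[j] += b1**2
        var_extra2[j] += b2**2
        planted.append((region_idx, j))

    c = cfg.overlap.intercept(cfg.n1, cfg.n2)
    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    e1_raw = u
    e2_raw = c * u + np.sqrt(1.0 - c**2) * v

    n_blocks = m // cfg.block_size
    z1 = np.empty(m)
    z2 = np.empty(m)
    for b in range(n_blocks):
        sl = slice(b * cfg.block_size, (b + 1) * cfg.block_size)
        V_b, L_b = V_levels[b % len(levels)], L_levels[b % len(levels)]
        z1[sl] = np.sqrt(cfg.n1) * V_b @ beta1[sl] + L_b @ e1_raw[sl]
        z2[sl] = np.sqrt(cfg.n2) * V_b @ beta2[sl] + L_b @ e2_raw[sl]

    spacing = 1000
    snps = np.array([f"snp{j:06d}" for j in range(m)])
    bp = (np.arange(m) * spacing + 1).astype(int)
    eaf = rng.uniform(0.05, 0.95, size=m)

    stats1 = _make_table(snps, bp, z1, cfg.n1, eaf, "trait1")
    stats2 = _make_table(snps, bp, z2, cfg.n2, eaf, "trait2")

    regions = []
    ld = {}
    reps = region_size // cfg.block_size
    for r in range(cfg.n_regions):
        sl = slice(r * region_size, (r + 1) * region_size)
        first_block = r * reps
        V_region = block_diag(
            *[V_levels[(first_block + i) % len(levels)] for i in range(reps)]
        )
        regions.append(
            Region(chrom="1", start=int(bp[sl][0]),
                   end=int(bp[sl][-1] + spacing), snp_ids=list(snps[sl]))
        )
        ld[r] = LDMatrix(snp_ids=list(snps[sl]), V=V_region)

    ldscores = compute_ld_scores(ld)
    per_snp_cov = sd1 * sd2 * corr + cov_extra
    per_snp_v1 = sd1**2 + var_extra1
    per_snp_v2 = sd2**2 + var_extra2
    gencov = float(np.sum(per_snp_cov))
    h2_1_eff = float(np.sum(per_snp_v1))
    h2_2_eff = float(np.sum(per_snp_v2))
    truth = {
        "m_snps": m, "n1": cfg.n1, "n2": cfg.n2,
        "h2_1": h2_1_eff, "h2_2": h2_2_eff,
        "gencov": gencov,
        "rg": gencov / np.sqrt(h2_1_eff * h2_2_eff) if h2_1_eff * h2_2_eff > 0 else 0.0,
        "cross_intercept": c, "seed": cfg.seed,
        "region_h2_1": [float(np.sum(per_snp_v1[r * region_size:(r + 1) * region_size]))
                        for r in range(cfg.n_regions)],
        "region_gencov": [
            float(np.sum(per_snp_cov[r * region_size:(r + 1) * region_size]))
            for r in range(cfg.n_regions)
        ],
        "shared_regions": [int(r) for r, _ in cfg.shared_locus_spec],
        "planted_snps": [str(f"snp{j:06d}") for _, j in planted],
    }
    return SimPairResult(stats1=stats1, stats2=stats2, ld=ld, regions=regions,
                         ldscores=ldscores, truth=truth)


def _make_table(snps, bp, z, n, eaf, label) -> pd.DataFrame:
    se = 1.0 / np.sqrt(n)
    df = pd.DataFrame(
        {
            "SNP": snps, "CHR": "1", "BP": bp, "A1": "A", "A2": "G",
            "BETA": z * se, "SE": se, "Z": z,
            "P": np.power(10.0, log10p_from_z(z)), "N": float(n),
            "EAF": eaf, "INFO": 1.0,
        }
    )
    df["LOG10P"] = log10p_from_z(z)
    df = df[CANONICAL_COLUMNS + ["LOG10P"]]
    df.attrs["trait_label"] = label
    return df


# ---------------------------------------------------------------------------
# two-sample MR instrument tables

@dataclass
class SimMRConfig:
    n_iv: int = 100
    var_gamma: float = 0.01
    theta_true: float = 0.0
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    se_exp: float = 0.005
    se_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iv < 2:
            raise ValueError("n_iv must be >= 2")
        if min(self.var_gamma, self.se_exp, self.se_out) <= 0:
            raise ValueError("variance parameters must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none|balanced|directional")


def simulate_mr(cfg: SimMRConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a harmonized MR instrument table with known causal effect."""
    rng = np.random.default_rng(cfg.seed)
    # instrument strengths are coded on the exposure-increasing allele
    # (half-normal), the convention under which directional pleiotropy
    # has a well-defined sign
    gamma = np.abs(rng.normal(0.0, np.sqrt(cfg.var_gamma), size=cfg.n_iv))
    if cfg.pleiotropy == "none":
        alpha = np.zeros(cfg.n_iv)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=cfg.n_iv)
    else:
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=cfg.n_iv)
    beta_exp = gamma + rng.normal(0.0, cfg.se_exp, size=cfg.n_iv)
    beta_out = cfg.theta_true * gamma + alpha + rng.normal(0.0, cfg.se_out, size=cfg.n_iv)
    ds = pd.DataFrame(
        {
            "SNP": [f"iv{j:04d}" for j in range(cfg.n_iv)],
            "beta_exp": beta_exp, "se_exp": cfg.se_exp,
            "beta_out": beta_out, "se_out": cfg.se_out,
            "eaf": rng.uniform(0.05, 0.95, size=cfg.n_iv),
            "palindromic": False, "pleiotropic": False,
        }
    )
    ds.attrs["exposure_label"] = "exposure"
    ds.attrs["outcome_label"] = "outcome"
    truth = {
        "theta": cfg.theta_true, "pleiotropy": cfg.pleiotropy,
        "pleiotropy_mean": cfg.pleiotropy_mean, "seed": cfg.seed,
        "n_iv": cfg.n_iv,
    }
    return ds, truth


def mr_tables_from_dataset(ds: pd.DataFrame, n_exp: float = 200_000,
                           n_out: float = 100_000):
    """Express an MR dataset as two canonical sumstats-shaped IV tables,
    the on-disk interchange format."""
    m = len(ds)

    def table(beta, se, n):
        z = np.asarray(beta) / np.asarray(se)
        df = pd.DataFrame(
            {
                "SNP": ds["SNP"], "CHR": "1",
                "BP": (np.arange(m) + 1) * 10_000, "A1": "A", "A2": "G",
                "BETA": beta, "SE": se, "Z": z,
                "P": np.power(10.0, log10p_from_z(z)), "N": float(n),
                "EAF": ds["eaf"], "INFO": 1.0,
            }
        )
        df["LOG10P"] = log10p_from_z(z)
        return df[CANONICAL_COLUMNS + ["LOG10P"]]

    return (
        table(ds["beta_exp"].to_numpy(), ds["se_exp"].to_numpy(), n_exp),
        table(ds["beta_out"].to_numpy(), ds["se_out"].to_numpy(), n_out),
    )


# ---------------------------------------------------------------------------
# on-disk bundles (the same formats the analysis commands read)

def write_pair_dataset(result: SimPairResult, outdir) -> dict:
    """Write a simulated pair to TSV/BED/matrix files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stats1": outdir / "stats1.tsv",
        "stats2": outdir / "stats2.tsv",
        "ldscores": outdir / "ldscores.tsv",
        "regions": outdir / "regions.bed",
        "ld_dir": outdir / "ld",
        "truth": outdir / "truth.json",
    }
    write_sumstats(result.stats1, paths["stats1"])
    write_sumstats(result.stats2, paths["stats2"])
    result.ldscores.to_csv(paths["ldscores"], sep="\t", index=False)
    save_regions(result.regions, paths["regions"])
    save_ld_matrices(result.ld, paths["ld_dir"])
    paths["truth"].write_text(json.dumps(result.truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}


def write_mr_dataset(ds: pd.DataFrame, truth: dict, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp, out = mr_tables_from_dataset(ds)
    paths = {
        "exposure_ivs": outdir / "exposure_ivs.tsv",
        "outcome_stats": outdir / "outcome_stats.tsv",
        "truth": outdir / "mr_truth.json",
    }
    exp.to_csv(paths["exposure_ivs"], sep="\t", index=False)
    out.to_csv(paths["outcome_stats"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
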