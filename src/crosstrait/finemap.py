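"""Flat-prior approximate-Bayes-factor fine-mapping and credible sets.

For each shared locus we take the variants within a window around the
index SNP, compute Wakefield's approximate Bayes factor for each variant
from its (beta, se),

    log ABF = 0.5 log( se^2 / (se^2 + W) ) + z^2 W / (2 (se^2 + W)),

normalize under a flat prior across the locus to posterior inclusion
probabilities PIP_j = ABF_j / sum_i ABF_i, and report the smallest
descending-PIP prefix whose cumulative sum reaches the credible level
(99% by default).  This is the standard summary-statistics realization of
single-causal flat-prior fine-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SumStatsError

#: prior variance W of the causal effect; 0.04 = (0.2)^2 on the
#: log-odds / per-SD scale
DEFAULT_PRIOR_W = 0.04


@dataclass
class FinemapConfig:
    window_bp: int = 500_000
    prior_w: float = DEFAULT_PRIOR_W
    level: float = 0.99

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise SumStatsError("credible level must lie in (0, 1)")
        if self.prior_w <= 0:
            raise SumStatsError("prior_w must be positive")


@dataclass
class CredibleSet:
    index_snp: str
    members: pd.DataFrame = field(repr=False)  # SNP, BP, BETA, SE, LOGABF, PIP
    cumulative_pip: float = 0.0
    level: float = 0.99

    @property
    def size(self) -> int:
        return len(self.members)


def wakefield_abf(beta, se, prior_w: float = DEFAULT_PRIOR_W) -> np.ndarray:
    """Log approximate Bayes factor for association, computed in log space.

    Records with se <= 0 return NaN (excluded by callers).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = se**2
        z2 = (beta / se) ** 2
        labf = 0.5 * np.log(v / (v + prior_w)) + z2 * prior_w / (2 * (v + prior_w))
        labf = np.where(se > 0, labf, np.nan)
    return labf


def pips_from_logabf(logabf: np.ndarray) -> np.ndarray:
    """Normalize log Bayes factors to PIPs (softmax; shift-invariant)."""
    labf = np.asarray(logabf, dtype=float)
    shifted = labf - np.nanmax(labf)
    bf = np.exp(shifted)
    return bf / np.nansum(bf)


def credible_set(
    pips: pd.Series | np.ndarray,
    level: float = 0.99,
    positions=None,
    snp_ids=None,
) -> np.ndarray:
    """Indices of the smallest descending-PIP prefix summing to >= level.

    Ties in PIP are broken by position then SNP id so the set is
    deterministic.
    """
    if not (0 < level < 1):
        raise SumStatsError("credible level must lie in (0, 1)")
    p = np.asarray(pips, dtype=float)
    n = len(p)
    pos = np.asarray(positions) if positions is not None else np.arange(n)
    ids = np.asarray(snp_ids).astype(str) if snp_ids is not None else np.arange(n).astype(str)
    order = np.lexsort((ids, pos, -p))
    cum = np.cumsum(p[order])
    cut = int(np.searchsorted(cum, level) + 1)
    return order[: min(cut, n)]


def finemap_locus(
    index_snp: str,
    stats: pd.DataFrame,
    cfg: FinemapConfig | None = None,
) -> CredibleSet:
    """Fine-map one locus: window selection, ABFs, PIPs, credible set.

    The window is all SNPs on the index chromosome with
    |pos - index_pos| <= window_bp (boundary inclusive).
    """
    cfg = cfg or FinemapConfig()
    hit = stats[stats["SNP"] == index_snp]
    if len(hit) == 0:
        raise SumStatsError(f"finemap_locus: index SNP {index_snp} not in stats")
    chrom = hit["CHR"].iloc[0]
    pos0 = hit["BP"].iloc[0]
    win = stats[
        (stats["CHR"] == chrom)
        & ((stats["BP"] - pos0).abs() <= cfg.window_bp)
        & (stats["SE"] > 0)
    ].copy()
    if len(win) == 0:
        win = hit.copy()
    win["LOGABF"] = wakefield_abf(win["BETA"].to_numpy(), win["SE"].to_numpy(),
                                  cfg.prior_w)
    win = win[np.isfinite(win["LOGABF"])].reset_index(drop=True)
    win["PIP"] = pips_from_logabf(win["LOGABF"].to_numpy())
    idx = credible_set(
        win["PIP"].to_numpy(), cfg.level,
        positions=win["BP"].to_numpy(), snp_ids=win["SNP"].to_numpy(),
    )
    members = win.iloc[idx][["SNP", "CHR", "BP", "BETA", "SE", "LOGABF", "PIP"]]
    members = members.reset_index(drop=True)
    win["IN_SET"] = win.index.isin(idx)
    cs = CredibleSet(
        index_snp=index_snp, members=members,
        cumulative_pip=float(members["PIP"].sum()), level=cfg.level,
    )
    cs.window = win  # full per-SNP table for reporting
    return cs
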