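"""GWAS summary-statistics I/O, quality control, and allele harmonization.

All downstream analyses consume one canonical table shape: a pandas
DataFrame with columns

    SNP CHR BP A1 A2 BETA SE Z P N EAF INFO LOG10P

where A1 is the effect allele, BETA is the per-allele effect on the trait
scale (log-odds for binary traits), Z = BETA/SE, and N is the per-SNP
effective sample size.  P-values are additionally carried in log10 space
(``LOG10P``) so that magnitudes such as 1e-49 survive round-trips even when
the linear-scale column underflows.  Coordinates are 1-based GRCh37 and are
never lifted over.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("crosstrait")

#: canonical column order for on-disk TSVs
CANONICAL_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "P", "N", "EAF", "INFO",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

LOG10 = np.log(10.0)


class SumStatsError(ValueError):
    """Raised when a summary-statistics table violates its contract."""


@dataclass
class QcConfig:
    """Per-record QC thresholds.

    Defaults mirror common GWAS post-imputation filters: imputation
    quality (INFO) > 0.30, minor allele frequency > 0.0001, call rate
    > 0.95 (applied only when a per-SNP missing-rate column is present).
    """

    min_info: float = 0.30
    min_maf: float = 0.0001
    max_missing_rate: float = 0.05
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_info <= 1):
            raise ValueError("min_info must lie in [0, 1]")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if not (0 <= self.max_missing_rate <= 1):
            raise ValueError("max_missing_rate must lie in [0, 1]")


@dataclass
class QcReport:
    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def log10p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided log10 p-value from a signed z-score, safe for |z| > 38."""
    z = np.asarray(z, dtype=float)
    return (np.log(2.0) + sps.norm.logsf(np.abs(z))) / LOG10


def _valid_allele(a) -> bool:
    if not isinstance(a, str) or len(a) == 0:
        return False
    return all(ch in "ACGT" for ch in a)


def read_sumstats(
    path,
    column_map: dict | None = None,
    n_default: float | None = None,
    trait_label: str = "",
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical shape.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text file with a header row.
    column_map
        Mapping from source header names to canonical names
        (e.g. ``{"A1": "A1", "b": "BETA", "MarkerName": "SNP"}``).  An
        ``OR`` source column is converted to log-odds on read.
    n_default
        Sample size used for records lacking a per-SNP N.
    trait_label
        Stored in ``df.attrs["trait_label"]``.

    Raises
    ------
    SumStatsError
        If neither (BETA, SE) nor Z can be recovered, or no SNP identity.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    df.columns = [c.upper() for c in df.columns]

    if "OR" in df.columns and "BETA" not in df.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["BETA"] = np.log(pd.to_numeric(df["OR"], errors="coerce"))

    has_beta_se = "BETA" in df.columns and "SE" in df.columns
    has_z = "Z" in df.columns
    if not has_beta_se and not has_z:
        missing = [c for c in ("BETA", "SE") if c not in df.columns]
        raise SumStatsError(
            f"no usable effect columns: need (BETA, SE) or Z; missing {missing + ['Z']}"
        )
    if "SNP" not in df.columns and not {"CHR", "BP"} <= set(df.columns):
        raise SumStatsError("need SNP or (CHR, BP) to identify records")

    for col in ("BETA", "SE", "Z", "P", "N", "EAF", "INFO", "BP"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    n_in = len(df)
    if "SNP" not in df.columns:
        df["SNP"] = df["CHR"].astype(str) + ":" + df["BP"].astype(int).astype(str)

    # uppercase alleles, drop unknown characters
    for col in ("A1", "A2"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.upper()
    if {"A1", "A2"} <= set(df.columns):
        ok = df["A1"].map(_valid_allele) & df["A2"].map(_valid_allele)
        n_bad = int((~ok).sum())
        if n_bad:
            warnings.warn(f"dropped {n_bad} records with unknown allele characters")
        df = df[ok].copy()

    if has_beta_se:
        bad = ~(df["SE"] > 0)
        if bad.any():
            warnings.warn(f"dropped {int(bad.sum())} records with non-positive SE")
            df = df[~bad].copy()
        if "Z" not in df.columns:
            df["Z"] = df["BETA"] / df["SE"]
        else:
            df["Z"] = df["Z"].fillna(df["BETA"] / df["SE"])
    # drop records that still lack a z-score (unparseable effect)
    n_parse_fail = int(df["Z"].isna().sum())
    if n_parse_fail:
        logger.info("read_sumstats: %d records failed to parse", n_parse_fail)
        df = df[df["Z"].notna()].copy()

    df["LOG10P"] = log10p_from_z(df["Z"].to_numpy())
    if "P" not in df.columns:
        df["P"] = np.power(10.0, df["LOG10P"])
    else:
        recompute = df["P"].isna()
        if recompute.any():
            df.loc[recompute, "P"] = np.power(10.0, df.loc[recompute, "LOG10P"])

    if "N" not in df.columns:
        if n_default is None:
            warnings.warn("no N column and no n_default supplied; N left missing")
            df["N"] = np.nan
        else:
            df["N"] = float(n_default)
    elif n_default is not None:
        df["N"] = df["N"].fillna(float(n_default))

    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    df = df[CANONICAL_COLUMNS + ["LOG10P"]].reset_index(drop=True)
    df.attrs["trait_label"] = trait_label
    df.attrs["n_parse_failures"] = n_parse_fail + (n_in - len(df) - n_parse_fail)
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write the canonical TSV (fixed column order, no LOG10P)."""
    df.loc[:, CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def qc_filter(df: pd.DataFrame, cfg: QcConfig | None = None) -> tuple[pd.DataFrame, QcReport]:
    """Apply per-record QC filters; return the surviving table and a report.

    Removal rules (counted separately, applied in order): imputation INFO
    below ``min_info``; minor allele frequency below ``min_maf``; missing
    rate above ``max_missing_rate`` (only if a MISSING_RATE column exists);
    duplicate SNP ids (keeping the record with the larger N, then the
    smaller p — a deterministic tie-break).  The survivors are sorted by
    (CHR, BP).
    """
    cfg = cfg or QcConfig()
    report = QcReport(n_input=len(df))
    out = df.copy()

    if "INFO" in out.columns:
        drop = out["INFO"].notna() & (out["INFO"] < cfg.min_info)
        report.removed["info"] = int(drop.sum())
        out = out[~drop]
    if "EAF" in out.columns:
        maf = np.minimum(out["EAF"], 1.0 - out["EAF"])
        drop = maf.notna() & (maf < cfg.min_maf)
        report.removed["maf"] = int(drop.sum())
        out = out[~drop]
    if "MISSING_RATE" in out.columns:
        drop = out["MISSING_RATE"].notna() & (out["MISSING_RATE"] > cfg.max_missing_rate)
        report.removed["missing_rate"] = int(drop.sum())
        out = out[~drop]

    if cfg.drop_duplicates:
        before = len(out)
        out = out.sort_values(
            ["SNP", "N", "P"], ascending=[True, False, True], kind="mergesort"
        ).drop_duplicates("SNP", keep="first")
        report.removed["duplicate"] = before - len(out)

    out = out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    report.n_output = len(out)
    if report.n_output == 0:
        warnings.warn("qc_filter: no records survived QC")
    out.attrs = dict(df.attrs)
    return out, report


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or G/C)."""
    if not isinstance(effect_allele, str) or not isinstance(other_allele, str):
        return False
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(ch, "N") for ch in allele)


def align_alleles(
    left: pd.DataFrame, right: pd.DataFrame, drop_palindromic: bool = False
) -> pd.DataFrame:
    """Merge two QC'd tables on SNP id, expressing right-hand effects on the
    left-hand effect allele.

    Per shared SNP: matching alleles keep their sign; swapped alleles negate
    the right-hand BETA/Z and complement its EAF; strand-complement pairs
    are resolved by complementing then matching; irreconcilable pairs are
    dropped and counted in ``attrs["n_mismatch"]``.  Palindromic (A/T, G/C)
    SNPs are flagged in the ``PALINDROMIC`` column and optionally excluded.

    Returns a merged frame with left-hand columns unsuffixed and right-hand
    statistics suffixed ``_2``.
    """
    m = left.merge(right, on="SNP", suffixes=("", "_2"), how="inner")
    if len(m) == 0:
        raise SumStatsError("align_alleles: zero overlapping SNPs")

    a1, a2 = m["A1"], m["A2"]
    b1, b2 = m["A1_2"], m["A2_2"]
    same = (b1 == a1) & (b2 == a2)
    swap = (b1 == a2) & (b2 == a1)
    cb1, cb2 = b1.map(_complement), b2.map(_complement)
    comp = ~same & ~swap & (cb1 == a1) & (cb2 == a2)
    comp_swap = ~same & ~swap & (cb1 == a2) & (cb2 == a1)

    keep = same | swap | comp | comp_swap
    flip = (swap | comp_swap).to_numpy()
    n_mismatch = int((~keep).sum())
    m = m[keep].copy()
    flip = flip[keep.to_numpy()]

    for col in ("BETA_2", "Z_2"):
        if col in m.columns:
            m.loc[flip, col] = -m.loc[flip, col]
    if "EAF_2" in m.columns:
        m.loc[flip, "EAF_2"] = 1.0 - m.loc[flip, "EAF_2"]
    m["A1_2"] = m["A1"]
    m["A2_2"] = m["A2"]

    m["PALINDROMIC"] = [
        is_palindromic(x, y) for x, y in zip(m["A1"], m["A2"])
    ]
    if drop_palindromic:
        m = m[~m["PALINDROMIC"]].copy()

    m = m.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    m.attrs["n_mismatch"] = n_mismatch
    m.attrs["trait_label_1"] = left.attrs.get("trait_label", "")
    m.attrs["trait_label_2"] = right.attrs.get("trait_label", "")
    return m


def extract_side(merged: pd.DataFrame, side: int) -> pd.DataFrame:
    """Pull one trait's canonical table back out of an aligned merge."""
    suffix = "" if side == 1 else "_2"
    cols = {}
    for col in CANONICAL_COLUMNS:
        source = col if col in ("SNP",) else (
            col + suffix if (col + suffix) in merged.columns else col
        )
        cols[col] = merged[source] if source in merged.columns else np.nan
    out = pd.DataFrame(cols)
    out["LOG10P"] = log10p_from_z(out["Z"].to_numpy())
    out.attrs["trait_label"] = merged.attrs.get(f"trait_label_{side}", "")
    return out
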