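"""Bidirectional two-sample Mendelian randomization with sensitivity
analyses and an analytic power calculation.

Estimators operate on a harmonized instrument table (one row per IV, all
effects expressed on the exposure effect allele):

- IVW: inverse-variance-weighted ratio average, the primary estimator;
  multiplicative random effects by default (SE inflated by
  max(1, sqrt(Q/(n-1)))).
- MR-Egger: weighted regression beta_out = alpha + theta beta_exp with the
  intercept alpha testing directional pleiotropy.
- Weighted median: robust to up to 50% invalid instruments by weight.
- Leave-one-out IVW, and a mixture-model clustering of per-IV ratio
  estimates (substantive clusters + a point-null + a broad junk component,
  fitted by EM with BIC model selection).

Binary-outcome effects are log-odds throughout; exposures are per-SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SumStatsError, align_alleles, is_palindromic

#: instrument-selection p thresholds: stringent for the forward (exposure)
#: direction, genome-wide for the reverse direction
IV_P_FORWARD = 5e-9
IV_P_REVERSE = 5e-8

#: palindromic SNPs with effect-allele frequency in this band (or missing)
#: cannot be oriented by frequency and are dropped from primary analyses
AMBIGUOUS_EAF_BAND = (0.42, 0.58)

Z95 = 1.959963984540054


@dataclass
class MREstimate:
    method: str
    theta: float
    se: float
    n_iv: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    or_: float = field(init=False)
    or_ci_low: float = field(init=False)
    or_ci_high: float = field(init=False)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None

    def __post_init__(self) -> None:
        self.ci_low = self.theta - Z95 * self.se
        self.ci_high = self.theta + Z95 * self.se
        self.or_ = float(np.exp(self.theta))
        self.or_ci_low = float(np.exp(self.ci_low))
        self.or_ci_high = float(np.exp(self.ci_high))


def harmonize_mr(
    exposure_ivs: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    drop_palindromic: bool = False,
    pleiotropy_list: list | None = None,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> pd.DataFrame:
    """Align exposure instruments with outcome statistics into an MR table.

    Palindromic IVs are removed outright when ``drop_palindromic`` is set
    (the sensitivity analysis); otherwise the ambiguous-frequency rule
    applies: drop if EAF is missing or inside the ambiguity band, else
    orient by frequency (flip the outcome effect when the frequencies
    disagree across datasets).  IVs named in ``pleiotropy_list`` and IVs
    absent from the outcome table are dropped and counted.
    """
    n_in = len(exposure_ivs)
    merged = align_alleles(exposure_ivs, outcome_stats)
    n_missing = n_in - len(merged) - merged.attrs.get("n_mismatch", 0)

    ds = pd.DataFrame(
        {
            "SNP": merged["SNP"],
            "beta_exp": merged["BETA"],
            "se_exp": merged["SE"],
            "beta_out": merged["BETA_2"],
            "se_out": merged["SE_2"],
            "eaf": merged["EAF"],
            "eaf_out": merged.get("EAF_2"),
            "palindromic": merged["PALINDROMIC"],
        }
    )
    n_palin_dropped = 0
    if drop_palindromic:
        n_palin_dropped = int(ds["palindromic"].sum())
        ds = ds[~ds["palindromic"]]
    else:
        pal = ds["palindromic"].to_numpy()
        eaf = ds["eaf"].to_numpy(dtype=float)
        lo, hi = AMBIGUOUS_EAF_BAND
        ambiguous = pal & (~np.isfinite(eaf) | ((eaf >= lo) & (eaf <= hi)))
        n_palin_dropped = int(ambiguous.sum())
        # orientable palindromic IVs: flip the outcome effect when the two
        # datasets disagree on which allele is the minor one
        if "eaf_out" in ds and ds["eaf_out"].notna().any():
            eo = ds["eaf_out"].to_numpy(dtype=float)
            flip = pal & ~ambiguous & np.isfinite(eo) & ((eaf - 0.5) * (eo - 0.5) < 0)
            ds.loc[flip, "beta_out"] = -ds.loc[flip, "beta_out"]
        ds = ds[~ambiguous]

    pleio = set(pleiotropy_list or [])
    ds["pleiotropic"] = ds["SNP"].isin(pleio)
    n_pleio = int(ds["pleiotropic"].sum())
    ds = ds[~ds["pleiotropic"]].reset_index(drop=True)

    if len(ds) < 2:
        raise SumStatsError(
            f"harmonize_mr: only {len(ds)} IVs survive harmonization (need >= 2)"
        )
    ds.attrs.update(
        exposure_label=exposure_label, outcome_label=outcome_label,
        n_input=n_in, n_missing_in_outcome=int(max(n_missing, 0)),
        n_palindromic_dropped=n_palin_dropped, n_pleiotropic_dropped=n_pleio,
    )
    return ds


def _check_ivs(data: pd.DataFrame, minimum: int, method: str) -> None:
    if len(data) < minimum:
        raise SumStatsError(f"{method}: needs >= {minimum} IVs, got {len(data)}")


def ivw(data: pd.DataFrame, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    theta = sum(bx by / se_y^2) / sum(bx^2 / se_y^2); the multiplicative
    random-effects model (default) inflates the fixed-effect SE by
    max(1, sqrt(Q/(n-1))).
    """
    _check_ivs(data, 2, "ivw")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    if np.allclose(bx, 0):
        raise SumStatsError("ivw: all exposure effects are zero")
    w = bx**2 / sy**2
    theta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    ratios = by / bx
    q = float(np.sum(w * (ratios - theta) ** 2))
    se = se_fixed
    if model == "random":
        se = se_fixed * max(1.0, np.sqrt(q / max(len(bx) - 1, 1)))
    elif model != "fixed":
        raise ValueError("model must be 'fixed' or 'random'")
    return MREstimate(method=f"ivw_{model}", theta=theta, se=se,
                      n_iv=len(bx), q_stat=q)


def egger(data: pd.DataFrame) -> MREstimate:
    """MR-Egger regression with a directional-pleiotropy intercept test.

    All instruments are oriented so beta_exp >= 0 before the weighted
    regression beta_out = alpha + theta beta_exp (weights 1/se_out^2);
    inference uses the t reference with n-2 degrees of freedom.
    """
    _check_ivs(data, 3, "egger")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) < 1e-12:
        raise SumStatsError("egger: no spread in exposure effects (collinear)")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    beta = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ beta
    dof = len(bx) - 2
    s2 = float(np.sum(w * resid**2) / dof)
    cov = s2 * np.linalg.inv(xtx)
    alpha, theta = float(beta[0]), float(beta[1])
    se_a, se_t = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_a = float(2 * sps.t.sf(abs(alpha / se_a), dof))
    return MREstimate(
        method="egger", theta=theta, se=se_t, n_iv=len(bx),
        intercept=alpha, intercept_se=se_a, intercept_p=p_a,
    )


def weighted_median(
    data: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: the 50th weighted percentile of the
    per-IV ratio estimates, consistent when instruments carrying half the
    weight are valid.  SE by seeded parametric bootstrap.
    """
    _check_ivs(data, 3, "weighted_median")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sx = data["se_exp"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    theta = _weighted_median_point(bx, by, sx, sy)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        boots[b] = _weighted_median_point(bxb, byb, sx, sy)
    return MREstimate(
        method="weighted_median", theta=float(theta),
        se=float(np.std(boots, ddof=1)), n_iv=len(bx),
    )


def _weighted_median_point(bx, by, sx, sy) -> float:
    ratios = by / bx
    # delta-method variance of the ratio
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    w = 1.0 / var
    order = np.argsort(ratios)
    r, w = ratios[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, r))


def leave_one_out(data: pd.DataFrame, model: str = "random") -> pd.DataFrame:
    """IVW with each instrument omitted in turn.

    Returns one row per omitted IV with the re-estimated theta/se and a
    flag for omissions that move the estimate by more than one pooled SE.
    """
    _check_ivs(data, 3, "leave_one_out")
    full = ivw(data, model=model)
    rows = []
    for i in range(len(data)):
        sub = data.drop(data.index[i])
        est = ivw(sub, model=model)
        rows.append(
            {
                "omitted": data["SNP"].iloc[i], "theta": est.theta,
                "se": est.se, "shift": est.theta - full.theta,
            }
        )
    out = pd.DataFrame(rows)
    out["outlier_flag"] = out["shift"].abs() > full.se
    out.attrs["theta_full"] = full.theta
    out.attrs["se_full"] = full.se
    return out


# ---------------------------------------------------------------------------
# mixture-model clustering of ratio estimates

@dataclass
class MRClusterResult:
    assignments: pd.DataFrame  # SNP, cluster, posterior
    cluster_means: dict
    n_clusters: int
    bic: float
    converged: bool


def clustered_mr(
    data: pd.DataFrame,
    max_k: int = 3,
    seed: int = 0,
    assign_threshold: float = 0.8,
    junk_sd: float = 10.0,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> MRClusterResult:
    """Cluster instruments by their ratio estimates.

    Finite mixture over per-IV ratios theta_j with known SEs: up to
    ``max_k`` Gaussian substantive clusters (common unknown means), a
    point-null at zero, and a broad junk component.  Fitted by seeded EM;
    the number of substantive clusters is selected by BIC.  IVs are
    assigned to their maximum-posterior component when that posterior
    reaches ``assign_threshold``, else labelled "unassigned".
    """
    _check_ivs(data, 5, "clustered_mr")
    bx = data["beta_exp"].to_numpy(dtype=float)
    by = data["beta_out"].to_numpy(dtype=float)
    sx = data["se_exp"].to_numpy(dtype=float)
    sy = data["se_out"].to_numpy(dtype=float)
    theta_j = by / bx
    se_j = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)

    best = None
    rng = np.random.default_rng(seed)
    for k in range(0, max_k + 1):
        fit = _em_mixture(theta_j, se_j, k, rng, junk_sd, max_iter, n_restarts)
        if best is None or fit["bic"] < best["bic"]:
            best = fit

    labels = ["null", "junk"] + [f"cluster_{i+1}" for i in range(best["k"])]
    post = best["post"]
    top = np.argmax(post, axis=1)
    top_p = post[np.arange(len(theta_j)), top]
    cluster = np.array(labels, dtype=object)[top]
    cluster[top_p < assign_threshold] = "unassigned"
    assignments = pd.DataFrame(
        {
            "SNP": data["SNP"].to_numpy(), "ratio": theta_j, "ratio_se": se_j,
            "cluster": cluster, "posterior": top_p,
        }
    )
    means = {f"cluster_{i+1}": float(m) for i, m in enumerate(best["means"])}
    means["null"] = 0.0
    return MRClusterResult(
        assignments=assignments, cluster_means=means, n_clusters=best["k"],
        bic=float(best["bic"]), converged=bool(best["converged"]),
    )


def _em_mixture(theta, se, k, rng, junk_sd, max_iter, n_restarts):
    """EM for the (null + junk + k substantive clusters) mixture."""
    n = len(theta)
    n_comp = 2 + k
    best = None
    for _ in range(max(1, n_restarts if k > 0 else 1)):
        means = (
            rng.choice(theta, size=k, replace=False) if k > 0 else np.empty(0)
        )
        pi = np.full(n_comp, 1.0 / n_comp)
        prev_ll = -np.inf
        converged = False
        for _it in range(max_iter):
            dens = np.empty((n, n_comp))
            dens[:, 0] = sps.norm.pdf(theta, 0.0, se)           # point-null
            dens[:, 1] = sps.norm.pdf(theta, 0.0, np.sqrt(se**2 + junk_sd**2))
            for c in range(k):
                dens[:, 2 + c] = sps.norm.pdf(theta, means[c], se)
            num = dens * pi
            tot = num.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1e-300
            post = num / tot
            ll = float(np.sum(np.log(tot)))
            pi = post.mean(axis=0)
            for c in range(k):
                w = post[:, 2 + c] / se**2
                if w.sum() > 0:
                    means[c] = float(np.sum(w * theta) / np.sum(w))
            if abs(ll - prev_ll) < 1e-8:
                converged = True
                break
            prev_ll = ll
        n_par = (n_comp - 1) + k  # mixing proportions + cluster means
        bic = -2 * ll + n_par * np.log(n)
        cand = {"k": k, "means": means, "post": post, "bic": bic,
                "converged": converged, "ll": ll}
        if best is None or cand["ll"] > best["ll"]:
            best = cand
    if not best["converged"]:
        warnings.warn(f"clustered_mr: EM did not converge for k={k}")
    return best


# ---------------------------------------------------------------------------
# analytic power

def mr_power_binary(
    n_outcome: float,
    case_fraction: float,
    r2_exposure: float,
    or_detect: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power of a two-sample MR with a binary outcome.

    Normal approximation for a case-control outcome with case fraction K
    and instruments explaining R^2 of the exposure variance: the detectable
    effect on the risk-difference scale is b = K (OR/(1 + K(OR-1)) - 1),
    its variance (K(1-K) - b^2) / (N R^2), and the two-sided power at level
    alpha is Phi(|b|/se - z_{1-alpha/2}) + Phi(-|b|/se - z_{1-alpha/2}).
    With a null OR this reduces to alpha.
    """
    if r2_exposure <= 0:
        raise ValueError("r2_exposure must be positive")
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must lie in (0, 1)")
    if n_outcome <= 0 or or_detect <= 0 or not (0 < alpha < 1):
        raise ValueError("invalid power-calculation argument")
    k = case_fraction
    b = k * (or_detect / (1.0 + k * (or_detect - 1.0)) - 1.0)
    var = (k * (1.0 - k) - b**2) / (n_outcome * r2_exposure)
    ncp = abs(b) / np.sqrt(var)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(ncp - z) + sps.norm.cdf(-ncp - z))


# ---------------------------------------------------------------------------
# bidirectional driver

def run_estimators(
    data: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """IVW (random + fixed), Egger, and weighted median on one dataset."""
    out = [ivw(data, model="random"), ivw(data, model="fixed")]
    if len(data) >= 3:
        try:
            out.append(egger(data))
        except SumStatsError as exc:
            warnings.warn(str(exc))
        out.append(weighted_median(data, n_boot=n_boot, seed=seed))
    return out


def bidirectional(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    exposure_ivs: pd.DataFrame,
    outcome_ivs: pd.DataFrame,
    drop_palindromic: bool = False,
    pleiotropy_list: list | None = None,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Run the full estimator suite in both causal directions.

    Forward: exposure instruments against the outcome GWAS (binary
    outcome; estimates are log-odds, reported with OR scale).  Reverse:
    outcome instruments against the exposure GWAS (continuous; beta
    scale).  Swapping the two trait roles swaps the bundles exactly.
    """
    fwd_data = harmonize_mr(
        exposure_ivs, outcome_stats, drop_palindromic=drop_palindromic,
        pleiotropy_list=pleiotropy_list,
    )
    rev_data = harmonize_mr(
        outcome_ivs, exposure_stats, drop_palindromic=drop_palindromic,
        pleiotropy_list=pleiotropy_list,
    )
    return {
        "forward": {"data": fwd_data,
                    "estimates": run_estimators(fwd_data, n_boot=n_boot, seed=seed)},
        "reverse": {"data": rev_data,
                    "estimates": run_estimators(rev_data, n_boot=n_boot, seed=seed)},
    }


def estimates_to_frame(estimates: list[MREstimate], direction: str = "") -> pd.DataFrame:
    """Long-format table of estimates, forest-plot ready."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "direction": direction, "method": e.method, "theta": e.theta,
                "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "or": e.or_, "or_ci_low": e.or_ci_low, "or_ci_high": e.or_ci_high,
                "n_iv": e.n_iv, "intercept": e.intercept,
                "intercept_p": e.intercept_p,
            }
        )
    return pd.DataFrame(rows)
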