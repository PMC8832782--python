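"""Config-driven orchestration of the cross-trait workflow.

Stages run in dependency order: genome-wide genetic correlation ->
local correlation -> cross-trait meta-analysis -> clumping/shared loci ->
fine-mapping -> bidirectional MR.  Each stage writes its own TSV/JSON
under ``out_dir/<stage>/`` plus a manifest recording parameters, seed,
and input checksums; a re-run with unchanged inputs is skipped via the
checksum match.  A consolidated ``report.tsv``/``report.json`` collects
each stage's headline numbers directly from the stage outputs.  The run
log is JSON lines (stage, level, message); nothing in the outputs depends
on wall-clock time, so the same config and seed reproduce the report
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import crossmeta, finemap, ldsc, localcorr, mr, sumstats
from .sumstats import SumStatsError

STAGES = ["rg", "local", "cpassoc", "clump", "finemap", "mr"]

#: stage -> input-file keys it requires
STAGE_INPUTS = {
    "rg": ["stats1", "stats2", "ldscores"],
    "local": ["stats1", "stats2", "regions", "ld_dir"],
    "cpassoc": ["stats1", "stats2"],
    "clump": ["stats1", "stats2", "ld_dir"],
    "finemap": ["stats1", "stats2", "ld_dir"],
    "mr": ["exposure_ivs", "outcome_stats"],
}

STAGE_DEPS = {
    "clump": ["cpassoc"],
    "finemap": ["clump"],
}

_ALLOWED_PARAMS = {
    "rg": {"n_blocks", "m_total", "constrain_intercept"},
    "local": {"var_explained", "k_cap", "alpha"},
    "cpassoc": {"null_z_cutoff", "min_null_snps", "null_draws"},
    "clump": {"p1", "p2", "r2", "kb", "p_single", "p_meta"},
    "finemap": {"window_bp", "prior_w", "level", "stats"},
    "mr": {"drop_palindromic", "n_boot"},
}


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    inputs: dict
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            out_dir=raw["out_dir"], inputs=raw.get("inputs", {}),
            params=raw.get("params", {}), seed=int(raw.get("seed", 0)),
        )

    def validate(self, stages: list[str]) -> None:
        for stage in stages:
            for key in STAGE_INPUTS[stage]:
                path = self.inputs.get(key)
                if path is None:
                    raise PipelineError(f"stage {stage!r} needs input {key!r}")
                if not Path(path).exists():
                    raise PipelineError(
                        f"stage {stage!r}: input {key!r} not found at {path}"
                    )
        for stage, block in self.params.items():
            if stage not in _ALLOWED_PARAMS:
                raise PipelineError(f"unknown parameter block {stage!r}")
            bad = set(block) - _ALLOWED_PARAMS[stage]
            if bad:
                raise PipelineError(f"unknown parameters in {stage!r}: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _input_digest(cfg: PipelineConfig, stage: str) -> str:
    parts = [f"seed={cfg.seed}", f"params={json.dumps(cfg.params.get(stage, {}), sort_keys=True)}"]
    for key in STAGE_INPUTS[stage]:
        p = Path(cfg.inputs[key])
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    parts.append(f"{key}:{f.name}:{_sha256(f)}")
        else:
            parts.append(f"{key}:{_sha256(p)}")
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


class _Logger:
    def __init__(self, path: Path):
        self.fh = open(path, "a")

    def log(self, stage: str, level: str, message: str, **counters):
        rec = {"stage": stage, "level": level, "message": message}
        rec.update(counters)
        self.fh.write(json.dumps(rec, sort_keys=True) + "\n")
        self.fh.flush()

    def close(self):
        self.fh.close()


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; returns the consolidated report dict.

    A failed stage halts its dependents; independent stages still run.
    The per-stage status is in the returned report under ``status``.
    """
    stages = [s for s in STAGES if s in (stages or STAGES)]
    for s in stages:
        for dep in STAGE_DEPS.get(s, []):
            if dep not in stages:
                out = Path(cfg.out_dir) / dep / "manifest.json"
                if not out.exists():
                    raise PipelineError(f"stage {s!r} requires {dep!r} output")
    cfg.validate(stages)

    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    logger = _Logger(out_root / "pipeline.log.jsonl")
    status: dict[str, str] = {}
    report: dict[str, dict] = {}
    ctx: dict = {}

    runners = {
        "rg": _stage_rg, "local": _stage_local, "cpassoc": _stage_cpassoc,
        "clump": _stage_clump, "finemap": _stage_finemap, "mr": _stage_mr,
    }
    for stage in stages:
        sdir = out_root / stage
        sdir.mkdir(exist_ok=True)
        if any(status.get(d) in ("failed", "halted") for d in STAGE_DEPS.get(stage, [])):
            status[stage] = "halted"
            logger.log(stage, "error", "halted: dependency failed")
            continue
        digest = _input_digest(cfg, stage)
        manifest_path = sdir / "manifest.json"
        if manifest_path.exists():
            old = json.loads(manifest_path.read_text())
            if old.get("digest") == digest and (sdir / "summary.json").exists():
                status[stage] = "skipped"
                report[stage] = json.loads((sdir / "summary.json").read_text())
                logger.log(stage, "info", "skipped: inputs unchanged")
                continue
        try:
            summary = runners[stage](cfg, sdir, ctx)
        except Exception as exc:  # deliberate: independent stages continue
            status[stage] = "failed"
            logger.log(stage, "error", f"failed: {exc}")
            continue
        status[stage] = "ok"
        report[stage] = summary
        (sdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest_path.write_text(json.dumps(
            {"digest": digest, "seed": cfg.seed,
             "params": cfg.params.get(stage, {}),
             "inputs": {k: str(cfg.inputs[k]) for k in STAGE_INPUTS[stage]}},
            indent=2, sort_keys=True))
        logger.log(stage, "info", "completed")
    logger.close()

    # the on-disk report carries only scientific outputs, never run status,
    # so reruns with unchanged inputs reproduce it byte for byte
    (out_root / "report.json").write_text(
        json.dumps({"stages": report}, indent=2, sort_keys=True))
    full = {"status": status, "stages": report}
    rows = []
    for stage, summary in report.items():
        for key, val in summary.items():
            if isinstance(val, (int, float, str)):
                rows.append({"stage": stage, "metric": key, "value": val})
    pd.DataFrame(rows).to_csv(out_root / "report.tsv", sep="\t", index=False)
    if any(v == "failed" for v in status.values()):
        raise PipelineError(f"stage failures: {status}")
    return full


# ---------------------------------------------------------------------------
# stage runners

_cache: dict = {}


def _load_pair(cfg):
    key = ("pair", cfg.inputs["stats1"], cfg.inputs["stats2"])
    if key not in _cache:
        s1 = sumstats.read_sumstats(cfg.inputs["stats1"], trait_label="trait1")
        s2 = sumstats.read_sumstats(cfg.inputs["stats2"], trait_label="trait2")
        _cache[key] = (s1, s2)
    return _cache[key]


def _stage_rg(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    s1, s2 = _load_pair(cfg)
    ld = pd.read_csv(cfg.inputs["ldscores"], sep="\t")
    p = cfg.params.get("rg", {})
    est = ldsc.fit_rg(s1, s2, ld, n_blocks=p.get("n_blocks", 200),
                      m_total=p.get("m_total"))
    out = {k: v for k, v in dataclasses.asdict(est).items()
           if not isinstance(v, (list, type(None))) or v is None}
    out.pop("pseudovalues", None)
    pd.DataFrame([out]).to_csv(sdir / "rg.tsv", sep="\t", index=False)
    return {"rg": est.rg, "rg_se": est.rg_se, "p": est.p,
            "h2_1": est.h2_1, "h2_2": est.h2_2, "gencov": est.gencov}


def _stage_local(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    s1, s2 = _load_pair(cfg)
    regions = localcorr.load_regions(cfg.inputs["regions"])
    ld = localcorr.load_ld_matrices(cfg.inputs["ld_dir"])
    p = cfg.params.get("local", {})
    est = localcorr.local_estimates(
        s1, s2, ld, regions, var_explained=p.get("var_explained", 0.99),
        k_cap=p.get("k_cap", 50), alpha=p.get("alpha", 0.05),
    )
    est.to_csv(sdir / "local.tsv", sep="\t", index=False)
    sig = est[est["sig_bonferroni"]]
    return {
        "n_regions_tested": int(est.attrs["n_regions_tested"]),
        "n_significant": int(len(sig)),
        "top_region": (f"{sig.iloc[0]['chrom']}:{sig.iloc[0]['start']}-"
                       f"{sig.iloc[0]['end']}") if len(sig) else "",
        "sum_rho_local": float(est["rho_local"].sum(skipna=True)),
    }


def _stage_cpassoc(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    s1, s2 = _load_pair(cfg)
    merged = sumstats.align_alleles(s1, s2)
    p = cfg.params.get("cpassoc", {})
    Z = merged[["Z", "Z_2"]].to_numpy()
    n = [float(merged["N"].mean()), float(merged["N_2"].mean())]
    R = crossmeta.estimate_trait_corr(
        Z, null_z_cutoff=p.get("null_z_cutoff", 1.96),
        min_null_snps=p.get("min_null_snps", 1000),
    )
    w = np.sqrt(np.asarray(n))
    Ri_w = np.linalg.solve(R.R, w)
    denom = float(w @ Ri_w)
    s_hom = (Z @ Ri_w) ** 2 / denom
    p_hom = sps.chi2.sf(s_hom, df=1)
    s_het, p_het, floored, calib = crossmeta.s_het_calibrated(
        Z, n, R, null_draws=p.get("null_draws", 1_000_000), seed=cfg.seed,
    )
    out = merged[["SNP", "CHR", "BP", "A1", "A2", "P", "P_2"]].copy()
    out["Z_1"] = merged["Z"]
    out["Z_2"] = merged["Z_2"]
    out["S_HOM"] = s_hom
    out["P_HOM"] = p_hom
    out["S_HET"] = s_het
    out["P_HET"] = p_het
    out.to_csv(sdir / "cpassoc.tsv", sep="\t", index=False)
    meta = {"n_null_snps": R.n_null_snps,
            "r_offdiag": float(R.R[0, 1]),
            "calibration_shape": calib.shape, "calibration_scale": calib.scale,
            "calibration_seed": calib.seed, "n_snps": int(len(out)),
            "min_p_het": float(np.min(p_het))}
    ctx["cpassoc"] = out
    return meta


def _stage_clump(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    table = ctx.get("cpassoc")
    if table is None:
        table = pd.read_csv(Path(cfg.out_dir) / "cpassoc" / "cpassoc.tsv", sep="\t")
    ld = _ld_matrices(cfg)
    p = cfg.params.get("clump", {})
    clumps = crossmeta.clump(
        table.rename(columns={"P_HET": "P_META"}), ld,
        p1=p.get("p1", crossmeta.CLUMP_P1), p2=p.get("p2", crossmeta.CLUMP_P2),
        r2=p.get("r2", crossmeta.CLUMP_R2), kb=p.get("kb", crossmeta.CLUMP_KB),
        p_col="P_META",
    )
    loci = crossmeta.call_shared_loci(
        clumps,
        dict(zip(table["SNP"], table["P"])),
        dict(zip(table["SNP"], table["P_2"])),
        dict(zip(table["SNP"], table["P_HET"])),
        p_single=p.get("p_single", crossmeta.P_SINGLE_TRAIT),
        p_meta=p.get("p_meta", crossmeta.P_CPASSOC),
    )
    pd.DataFrame([c.__dict__ for c in clumps]).to_csv(
        sdir / "clumps.tsv", sep="\t", index=False)
    pd.DataFrame([s.__dict__ for s in loci]).to_csv(
        sdir / "shared_loci.tsv", sep="\t", index=False)
    ctx["shared_loci"] = loci
    return {"n_clumps": len(clumps), "n_shared_loci": len(loci)}


def _ld_matrices(cfg):
    key = ("ld", cfg.inputs["ld_dir"])
    if key not in _cache:
        _cache[key] = localcorr.load_ld_matrices(cfg.inputs["ld_dir"])
    return _cache[key]


def _stage_finemap(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    loci = ctx.get("shared_loci")
    if loci is None:
        df = pd.read_csv(Path(cfg.out_dir) / "clump" / "shared_loci.tsv", sep="\t")
        loci = [crossmeta.SharedLocus(**row) for row in df.to_dict("records")]
    p = cfg.params.get("finemap", {})
    which = p.get("stats", "trait2")
    s1, s2 = _load_pair(cfg)
    stats = s1 if which == "trait1" else s2
    fmcfg = finemap.FinemapConfig(
        window_bp=p.get("window_bp", 500_000),
        prior_w=p.get("prior_w", finemap.DEFAULT_PRIOR_W),
        level=p.get("level", 0.99),
    )
    sizes = []
    for locus in loci:
        cs = finemap.finemap_locus(locus.index_snp, stats, fmcfg)
        cs.window.to_csv(sdir / f"locus_{locus.index_snp}.tsv", sep="\t", index=False)
        sizes.append({"index_snp": locus.index_snp, "set_size": cs.size,
                      "cumulative_pip": cs.cumulative_pip})
    pd.DataFrame(sizes).to_csv(sdir / "credible_sets.tsv", sep="\t", index=False)
    return {"n_loci": len(sizes),
            "total_credible_snps": int(sum(s["set_size"] for s in sizes))}


def _stage_mr(cfg: PipelineConfig, sdir: Path, ctx: dict) -> dict:
    p = cfg.params.get("mr", {})
    exp_ivs = sumstats.read_sumstats(cfg.inputs["exposure_ivs"], trait_label="exposure")
    out_stats = sumstats.read_sumstats(cfg.inputs["outcome_stats"], trait_label="outcome")
    data = mr.harmonize_mr(
        exp_ivs, out_stats, drop_palindromic=p.get("drop_palindromic", False)
    )
    estimates = mr.run_estimators(data, n_boot=p.get("n_boot", 1000), seed=cfg.seed)
    frames = [mr.estimates_to_frame(estimates, direction="forward")]
    if cfg.inputs.get("outcome_ivs") and cfg.inputs.get("exposure_stats"):
        rev = mr.harmonize_mr(
            sumstats.read_sumstats(cfg.inputs["outcome_ivs"], trait_label="outcome"),
            sumstats.read_sumstats(cfg.inputs["exposure_stats"], trait_label="exposure"),
            drop_palindromic=p.get("drop_palindromic", False),
        )
        frames.append(mr.estimates_to_frame(
            mr.run_estimators(rev, n_boot=p.get("n_boot", 1000), seed=cfg.seed),
            direction="reverse"))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(sdir / "estimates.tsv", sep="\t", index=False)
    primary = table[table["method"] == "ivw_random"].iloc[0]
    return {"ivw_theta": float(primary["theta"]), "ivw_or": float(primary["or"]),
            "ivw_ci_low": float(primary["ci_low"]),
            "ivw_ci_high": float(primary["ci_high"]),
            "n_iv": int(primary["n_iv"])}
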