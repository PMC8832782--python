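# crosstrait

Genome-wide cross-trait analysis of GWAS summary statistics, built for the
kind of question posed by obesity-related traits (adult/childhood BMI,
waist-to-hip ratio) and polycystic ovary syndrome (PCOS): do two traits
share genetic architecture, where in the genome, and is the relationship
causal?

The package takes per-SNP association tables (effect size, SE, p, N) from
two GWASs and runs the standard cross-trait workflow end to end:

1. **Genome-wide genetic correlation** by bivariate LD score regression:
   `E[β_j γ_j] = √(N₁N₂) r_g / M · l_j + N_s r / √(N₁N₂)`, where `l_j` is
   SNP j's LD score, `M` the SNP count, `N_s` the overlapping samples and
   `r` their phenotypic correlation. Standard errors come from a
   delete-a-block jackknife.
2. **Local genetic correlation** over predefined LD regions, via truncated
   eigendecomposition of the regional LD matrix:
   `ĥ²_local = (z'V⁺z − k)/(N − k)` and the analogous cross-trait
   covariance, with Bonferroni flags per region.
3. **Cross-trait meta-analysis** (S_Hom, the fixed-effect statistic, and
   S_Het, its heterogeneity-robust maximization over |z|-thresholded trait
   subsets with a simulated, gamma-summarized null), followed by greedy
   PLINK-style clumping (`p1 5e-8, p2 1e-5, r2 0.2, kb 500`) and
   shared-locus calling under the dual rule `P_single < 1e-3` in both
   traits and `P_meta < 5e-8`.
4. **Fine-mapping** of each shared locus with Wakefield approximate Bayes
   factors under a flat prior, normalized to posterior inclusion
   probabilities and reported as 99% credible sets.
5. **Bidirectional two-sample Mendelian randomization**: IVW (fixed and
   multiplicative-random-effects), MR-Egger with its pleiotropy intercept
   test, weighted median, leave-one-out, mixture-model clustering of
   per-instrument ratio estimates, and an analytic power calculation for
   binary outcomes.

A first-class synthetic-data module (`crosstrait.simulate`) generates
paired summary statistics under exactly the polygenic model the estimators
assume — planted heritability, genetic correlation, LD block structure,
sample overlap, shared causal loci — plus MR instrument tables with known
causal effects and pleiotropy, so every stage is testable against
generative truth without any external downloads.

## Worked example

```python
import numpy as np
import crosstrait as ct

# a scenario mirroring the adult-BMI/PCOS pair: rg = 0.47,
# N1 = 434,794, N2 = 113,238, at desk scale (20,000 SNPs, 50 LD regions)
cfg = ct.pair_config("adult_bmi_pcos", m_snps=20_000, n_regions=50, seed=2)
res = ct.simulate_pair(cfg)
est = ct.fit_rg(res.stats1, res.stats2, res.ldscores, n_blocks=200)
print(f"rg = {est.rg:.3f} (SE {est.rg_se:.3f}), p = {est.p:.2e}")

# forward MR with 278 instruments and a planted OR of 2.92
ds, truth = ct.simulate_mr(ct.SimMRConfig(
    n_iv=278, var_gamma=0.001, se_exp=0.0016, se_out=0.0104,
    theta_true=np.log(2.92), seed=0))
ivw = ct.ivw(ds)
print(f"IVW OR = {ivw.or_:.2f} "
      f"(95% CI {ivw.or_ci_low:.2f}-{ivw.or_ci_high:.2f}), n_iv = {ivw.n_iv}")

# analytic MR power: binary outcome, N=113,238, 9% cases, R2=4%, OR=1.15
print(f"power = {ct.mr_power_binary(113_238, 0.09, 0.04, 1.15, 0.05):.3f}")
```

prints

```
rg = 0.438 (SE 0.034), p = 2.19e-38
IVW OR = 2.85 (95% CI 2.74-2.96), n_iv = 278
power = 0.814
```

The genetic-correlation estimate recovers the planted 0.47 within two
jackknife SEs; the IVW odds ratio recovers the planted 2.92 within its CI;
the power value says a study with that outcome sample size and instrument
strength detects a 15% odds-ratio effect with ~80% probability.

## Command line

Each stage is also a subcommand of the `crosstrait` console script:

```bash
crosstrait simulate pair --preset adult_bmi_pcos --seed 7 --out data/
crosstrait rg --sumstats1 data/stats1.tsv --sumstats2 data/stats2.tsv \
              --ldscores data/ldscores.tsv --n-blocks 200
crosstrait run --config config.yaml            # full pipeline, YAML-driven
```

`crosstrait run` executes rg → local → cpassoc → clump → finemap → mr with
per-stage manifests (parameters, seed, input checksums), skips stages whose
inputs are unchanged, and consolidates headline numbers into
`report.tsv`/`report.json`. The same config and seed reproduce the report
byte for byte.

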