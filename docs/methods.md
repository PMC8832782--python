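# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want to
know about.

## Summary-statistics model and harmonization

All analyses consume one canonical table (SNP, CHR, BP, A1, A2, BETA, SE,
Z, P, N, EAF, INFO), 1-based GRCh37 coordinates, effect sizes on the trait
scale (log-odds for binary traits). P-values are carried in log10 space
alongside the linear column so magnitudes like 1e-49 survive; the linear
column may underflow for |z| ≳ 38 but the log column never does.

Harmonization expresses the right-hand table's effects on the left-hand
effect allele: matching alleles keep sign, swapped alleles negate beta/z
and complement the frequency, strand flips are resolved by complementing
and re-matching, and irreconcilable pairs are dropped with a count.
Palindromic (A/T, G/C) variants are flagged at merge, not dropped:
correlation-type analyses keep them, while MR removes them in the
dedicated sensitivity run and otherwise applies the conventional
conservative frequency rule — drop if the effect-allele frequency is
missing or in [0.42, 0.58], else orient by frequency. Duplicate SNP ids
keep the record with the larger N, then the smaller p (a deterministic
tie-break). Multi-allelic sites are not resolved; irreconcilable allele
pairs are simply dropped and counted.

QC defaults mirror common post-imputation GWAS filters: INFO > 0.30,
MAF > 0.0001, call-rate filter applied only when a per-SNP missing-rate
column exists. An empty post-QC table warns rather than fails, so a
pipeline can surface the problem with context.

## Genome-wide genetic correlation (LD score regression)

The polygenic model: chi² regresses on N·l/M with slope h²; the product
z₁z₂ regresses on √(N₁N₂)·l/M with slope equal to the genetic covariance
ρ_g, and intercept N_s·r/√(N₁N₂) absorbing sample overlap. The genetic
correlation is r_g = ρ_g/√(h²₁h²₂).

- **Weights.** Two-pass heteroskedasticity weights: an unweighted first
  pass supplies fitted means; the second pass weights by
  1/[max(l,1)·Ê[chi²]²] (univariate) and
  1/[max(l,1)·(Ê₁Ê₂ + Ê[z₁z₂]²)] (bivariate). Using *fitted means* rather
  than plugged-in parameter estimates keeps the self-pairing case exactly
  proportional between the univariate and bivariate fits, so a trait
  paired with itself returns r_g = 1 to machine precision — a property the
  tests assert. Fitted means are floored at 0.05 to keep weights finite.
- **Standard errors.** Delete-a-block jackknife over contiguous SNP blocks
  (default 200, a genome-wide convention). The jackknife is taken over the
  full (h²₁, h²₂, ρ_g) triple so the SE of r_g reflects all three fits.
- **Intercepts** are free by default (unknown overlap); the cross-trait
  intercept can be constrained to N_s·r/√(N₁N₂) via `OverlapSpec`. Under a
  clean null the univariate intercept estimates 1.
- **No clamping**: |r_g| > 1 is reported with a warning flag rather than
  truncated, so miscalibration is visible rather than hidden.
- Non-positive estimated heritability makes r_g undefined; the genetic
  covariance is still returned, with a warning.
- The four-pair screen threshold is Bonferroni 0.05/4.

## Local genetic correlation

The genome is partitioned by a BED-like file of non-overlapping regions
(the classic partition has 1703 regions of ~1.5 Mb; the file is an input,
never hard-coded). Within a region with reference LD matrix V and
truncated pseudoinverse V⁺ of rank k:

    h²_local = (z'V⁺z − k) / (N − k)
    ρ_local  = z₁'V⁺z₂/√(N₁N₂) − k·N_s·r/(N₁N₂)
    r_g,local = ρ_local / √(h²₁,local · h²₂,local)   (only if both h² > 0)

- **Truncation rank**: smallest k explaining ≥99% of the trace, capped at
  50 — a deterministic rule suited to rank-deficient reference panels.
  With the package's full-rank simulated LD the cap deflates region sums
  (only the top-k eigendirections of signal are counted), so
  sum-consistency checks raise the cap; the default stays conservative
  for real reference panels.
- **Standard errors** come from a jackknife over the k eigencomponents of
  the truncated eigenbasis. These components are exactly independent under
  the model, unlike SNP subsets, whose deletion would change V⁺ and the
  rank rule itself. For k < 3 an analytic product-moment variance
  (homogeneous per-component moments) is the fallback.
- Regions with fewer than k+2 usable SNPs are skipped and flagged.
  Bonferroni significance uses 0.05/(regions actually tested); both the
  total and tested counts are reported.
- A warning is emitted when either GWAS has N < 50,000, below which local
  estimates of this type are known to be unstable.
- Sample overlap defaults to zero (appropriate for non-overlapping
  cohorts) and is overridable.

## Cross-trait meta-analysis

S_Hom is the fixed-effect cross-phenotype statistic with weights √n_k and
a trait-correlation matrix R estimated once genome-wide from SNPs null in
every trait (|z| < 1.96; Pearson correlation; eigenvalue-floored to
positive semi-definite). It reduces exactly to z² for one trait and is
chi²₁ under the null.

S_Het maximizes the same statistic over trait subsets selected by an |z|
threshold τ on the grid {0, 0.5, …, 5} plus the observed |z| values. The
implementation exploits that every threshold-selected subset is a "top-j
by |z|" subset, which makes the scan vectorizable; a literal grid
evaluation is kept as a cross-check oracle in the tests. The null is
calibrated per run by simulating multivariate-normal z under R (default
10⁶ draws, seeded, recorded in output metadata) and fitting a gamma
distribution to the full sample (method-of-moments start,
maximum-likelihood refinement). P-values come from the gamma tail;
values below 1/draws are flagged as extrapolated beyond the simulated
support rather than clipped — clipping would make genome-wide
significance unreachable and defeat the point of a parametric tail.
Calibration was verified to hold the 5% level within [0.04, 0.06] across
trait correlations 0 to 0.6.

Clumping is the greedy PLINK rule (index = smallest p below p1, absorb
p < p2 within ±kb at r² ≥ threshold; ties broken by chromosome then
position; defaults 5e-8 / 1e-5 / 0.2 / 500 kb), with r² taken from the
per-region LD matrices and zero between regions. Shared loci are clumps
whose index SNP meets p < 1e-3 in both single traits and p < 5e-8 in the
cross-trait statistic; novelty is annotated against user-supplied
known-hit lists (no catalog download). One caveat discovered in testing:
the intuitive monotonicity "loosening r²/kb never shrinks any clump" holds
for the first clump but not globally — looser settings can let an earlier
clump absorb a SNP that a later clump would otherwise have claimed.

## Fine-mapping

Flat-prior single-causal fine-mapping via Wakefield's approximate Bayes
factor, `log ABF = ½·log(se²/(se²+W)) + z²W/(2(se²+W))`, computed in log
space; PIP_j = ABF_j normalized over the ±500 kb window (boundary
inclusive) around the index SNP; the 99% credible set is the smallest
descending-PIP prefix reaching the level, with ties broken by position
then SNP id. The prior effect variance W defaults to 0.04 (0.2² on the
log-odds / per-SD scale) and is configurable. This is the standard
summary-data realization of flat-prior credible sets; no multi-causal
search or conditional analysis is attempted, matching the single-signal
scheme. Per-SNP ABF fine-mapping is only calibrated when the locus signal
is strong; coverage claims are made for index-SNP-strength signals
(z ≈ 8–12, the regime of genome-wide-significant loci), where the
simulated 99% sets cover the planted causal variant in ≥97% of runs.
Which trait's statistics are fine-mapped at a locus is an explicit choice
(`--stats` / config key), not guessed.

## Mendelian randomization

Estimators on the harmonized instrument table:

- **IVW**: θ̂ = Σ(β_Xβ_Y/se_Y²)/Σ(β_X²/se_Y²). The primary model is
  multiplicative random effects — SE inflated by max(1, √(Q/(n−1))) —
  robust to heterogeneity across hundreds of instruments; the
  fixed-effect variant is exposed and its SE never exceeds the
  random-effects SE.
- **MR-Egger**: weighted regression β_Y = α + θβ_X (weights 1/se_Y²) after
  orienting all β_X ≥ 0; the intercept α tests directional pleiotropy with
  a t reference on n−2 degrees of freedom. Fails loudly below 3
  instruments or with no spread in β_X.
- **Weighted median**: inverse-variance (delta-method) weighted 50th
  percentile of the per-instrument ratios, with a seeded parametric
  bootstrap SE (default 1000 draws). Its robustness to invalid
  instruments comes partly from the weights themselves: grossly deviant
  ratios carry large delta-method variances and lose weight.
- **Leave-one-out** IVW flags instruments whose omission moves the
  estimate by more than one pooled SE. With heavily skewed instrument
  weights a single strong instrument can legitimately trip this flag.
- **Clustered MR**: a finite mixture over ratio estimates with known SEs —
  up to max_k Gaussian substantive clusters plus a point-null and a broad
  junk component (SD 10) — fitted by seeded EM with restarts, model
  selection by BIC, and an 0.8 posterior threshold for assignment.
- **Power**: the binary-outcome approximation with detectable
  risk-difference effect b = K(OR/(1+K(OR−1)) − 1) and variance
  (K(1−K) − b²)/(N·R²); two-sided, so a null OR returns exactly α. At the
  reference design point (N = 113,238, K = 0.09, R² = 0.04, OR = 1.15)
  this gives 0.814 ≈ 80%.

Instrument-selection thresholds default to 5e-9 in the forward direction
and genome-wide 5e-8 in reverse. Pleiotropy exclusion consumes a
user-supplied SNP list. Binary-outcome effects are log-odds throughout;
exposures are per-SD.

## The synthetic-data generator

`simulate_pair` draws per-SNP true effects from a bivariate normal with
variances h²/M and correlation r_g, block-diagonal AR(1) LD, and observed
z = √N·Vβ + ε with ε ~ MVN(0, V); cross-trait noise correlation
N_s·r/√(N₁N₂) implements sample overlap. The regression identity
E[z₁z₂] = √(N₁N₂)ρ_g l/M + N_s r/√(N₁N₂) then holds by construction.
Design choices:

- Block size 50 with AR(1) decay cycled over a deterministic ladder
  {0, ¼, ½, ¾, 1}·0.9. Real LD scores span a wide range; a single decay
  would make all LD scores nearly equal and leave the regression intercept
  an unanchored extrapolation.
- Planted shared loci come in two modes: `causal` (one deterministic
  shared variant per listed region, placed mid-block in the region's
  strongest-LD block — what locus-calling and fine-mapping should find)
  and `diffuse` (region-wide effect-variance inflation at correlation
  0.9 — concentrated local genetic covariance for the local-correlation
  stage).
- Instrument strengths in `simulate_mr` are half-normal, i.e. coded on the
  exposure-increasing allele — the convention under which directional
  pleiotropy has a well-defined sign; with symmetric coding the Egger
  intercept would be zero by construction regardless of planted
  pleiotropy.
- The preset bank pins the scenario parameters used in recovery tests:
  r_g ∈ {0, 0.47, 0.31, 0.32, 0.09} with the corresponding GWAS sample
  sizes (434,794 / 39,620 / 381,152 / 379,501 against 113,238). SNP
  heritability defaults to 0.25 per trait, a typical anthropometric-trait
  value; the papers' per-trait h² is not pinned by the workflow itself.
- Everything flows from one seeded generator per call; the same seed gives
  byte-identical outputs, and truth records serialize next to the data.

What the generator does **not** emulate: minor-allele-frequency-dependent
architecture, population stratification and relatedness (beyond the
overlap intercept), imputation error, long-range LD between regions, and
binary-trait liability-scale subtleties (the binary outcome is treated on
the observed log-odds scale throughout). Passing tests therefore
demonstrate correctness of the estimators under their own model
assumptions at desk scale, not robustness to those real-data
complications. Desk-scale problem sizes (20,000 SNPs, 50 regions for
genome-wide fits; 500-SNP single loci for fine-mapping; ≤1000 replicates
for coverage) were chosen so the full suite runs in well under an hour on
one CPU while leaving Monte-Carlo error small relative to the tested
tolerances.

## Pipeline

Stages run in dependency order with per-stage manifests (seed, parameters,
SHA-256 of inputs); a stage whose digest matches its manifest is skipped
and its outputs reused. The consolidated report carries only scientific
outputs — run status lives in the JSON-lines log — so reruns and fresh
runs with the same config and seed are byte-identical. Stage failure halts
dependents but not independent stages; the process exits non-zero with
per-stage status. Multiple-testing defaults are wired per stage (0.05/4
genome-wide screen, 0.05/regions-tested locally, the dual 5e-8 + 1e-3 rule
for shared loci), each overridable in the YAML config.

## Known limitations

- LD score regression weights are approximate; small biases (a few percent
  of h²) remain at desk-scale M with very large N, within the jackknife
  uncertainty the tests use.
- The local estimator's default truncation cap trades bias for stability;
  sums of local quantities across regions under-count when the cap binds.
- The S_Het gamma tail is an extrapolation for extreme statistics; such
  p-values are flagged.
- Per-SNP ABF fine-mapping under strong LD is anti-conservative for weak
  signals; credible-set coverage claims hold in the strong-signal regime
  only.
- Weighted-median robustness degrades when invalid instruments are
  numerous *and* their ratios are only mildly shifted (they then retain
  weight); the estimator is consistent only while valid instruments carry
  a weight majority.
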