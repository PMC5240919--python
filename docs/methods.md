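# Methods

## Model and assumptions

`metapower` computes the statistical power and polygenic-score (PGS)
accuracy of a fixed-effects meta-analysis of GWAS results from `C`
genetically heterogeneous studies, plus a hold-out prediction sample.

The genetic architecture is an independent-block abstraction: `S` effective
SNPs, each tagging one haplotype block, `M ≤ S` of them causal. LD within
and between blocks is not modeled; imperfect tagging of causal variants is
assumed to be absorbed into downwardly biased SNP-heritability inputs, which
is how GREML-style estimates behave. All `M` causal SNPs share the same
theoretical R² (`h²_c / M` in study `c`) — the "equal-R²" assumption.

Cross-study heterogeneity follows a random-effects model: the vector of
standardized causal effects across studies and hold-out sample is mean-zero
jointly Gaussian with correlation matrix given by the CGR structure (the
bordered `(C+1)×(C+1)` matrix must be PSD; tolerance `−1e−8` on the smallest
eigenvalue, reported in the error message when violated). Under the null an
effect is exactly zero, so heterogeneity shows up as excess variance of the
meta-analysis Z statistic rather than a mean shift.

Key consequences built into the closed forms:

* Z-score meta-analysis weights are `√(N_c/N_T)`, effect-size weights
  `N_c/N_T`. With standardized phenotypes and genotypes the per-study
  sampling variance of both the Z statistic and the estimated standardized
  effect is `∝ 1/N_c`, so these are the inverse-variance weights.
* Power is the marginal Gaussian tail `β = 2Φ(−t/σ)` with
  `t = Φ⁻¹(1−α/2)`: because the effects are Gaussian, the marginal of
  `Z_meta` is exactly normal and no integration over the effect distribution
  is needed. `α` counts two-sided false positives (`E[#FP] = α(S−M)`).
* The hold-out R² treats the phenotype as standardized; its denominator
  `S/N_T + (genetic term)/N_T²` is the variance of the all-SNP score, the
  `S/N_T` part being pure estimation noise. Hence prediction accuracy decays
  with the effective number of SNPs, and its ceiling is `ρ_ch² h²_h`.

## Parameters

| parameter | meaning | units/range | default |
|---|---|---|---|
| `N_c` | per-study sample size | individuals, ≥ 1, fractional allowed | — |
| `h²_c`, `h²_h` | SNP heritability per study / hold-out | [0, 1] | — |
| `ρ_cd`, `ρ_ch` | CGR among studies / to hold-out | [−1, 1], PSD overall | — |
| `S` | effective number of independent SNPs | count (literature: ~6e4–5e6) | — |
| `M` | causal subset size | 1 ≤ M ≤ S | — |
| `α` | genome-wide significance level | (0, 1) | 5e−8 |

Equal designs split `N_T` into `C` fractional parts `N_T/C` without
rounding: rounding to integers shifts expected hit counts of the published
benchmark designs at the second decimal. The simulator, which instantiates
individuals, requires integer sizes.

## Numerical choices

* Tail probabilities run through `scipy.special.log_ndtr`, so powers down to
  ~1e−300 are representable; `(1−β)^M` and `(1−α)^(S−M)` accumulate via
  `log1p`/`expm1`, surviving `M = 10⁶` with `β = 1e−300`.
* `power_per_causal_snp(1.0, α)` returns `α` to floating precision.
* Attenuation guards the benchmark: if the CGR=1 expected value is below
  1e−300 the ratio is reported as NaN with an explicit `*_defined = False`
  flag rather than silently. (Expected hits can only be that small when
  `M = S` and `α` is itself astronomically small, since `β ≥ α`.)
* Correlated effect draws use an eigendecomposition factor rather than a
  Cholesky, so exactly singular targets (all correlations one) give exactly
  identical effect vectors.
* Single-study designs carry a trivial 1×1 among-study matrix; the hold-out
  correlation and `h²_h` are still required for PGS output.

## The simulator

Each replicate generates the full multi-study world from scratch:

1. **Allele frequencies** — fixed, or Uniform(0.05, 0.5) per SNP; optionally
   redrawn independently per study (and hold-out) to model studies that
   disagree about which variants are common.
2. **Effects** — jointly Gaussian across the `C+1` samples at `M` causal
   loci with the target CGR. The per-SNP standardized-effect variance is
   `∝ [2f(1−f)]^(s+1)`, renormalized to sum to `h²`; `s = −1` reproduces the
   equal-R² assumption, `s = 0` (equal raw-effect variance) violates it. A
   strict equal-R² variant (fixed magnitude `√(h²/M)`, random signs coupled
   through a Gaussian copula with latent correlation `sin(πρ/2)`) is
   available for sensitivity analysis.
3. **Genotypes/phenotypes** — allele counts 0/1/2 from two Bernoulli(f)
   draws, standardized by within-sample moments (GWAS practice; population
   moments available as an oracle switch); phenotype = genetic component
   plus Gaussian noise of variance `1 − h²`, then standardized. Monomorphic
   SNPs are flagged and excluded from that study's GWAS; meta-analysis
   weights renormalize over the contributing studies, and SNPs excluded
   everywhere are recorded missing.
4. **GWAS + meta-analysis** — per-SNP coefficient is the sample correlation;
   `Z = √N_c × coefficient` (the large-sample form matching the theory);
   meta Z and meta effect use `√(N_c/N_T)` and `N_c/N_T` weights.
5. **Hold-out PGS** — all-SNP score with meta effects as weights; empirical
   R² is the squared Pearson correlation with the hold-out phenotype.

Genotype matrices are held in float32: the per-SNP statistics are sample
correlations of O(1) quantities, where single precision contributes ~1e−6
error, orders of magnitude below Monte-Carlo noise at any feasible
replicate count.

**Causal-overlap scenarios** model CGR arising from partially shared causal
loci: one common set of `q·M` loci shared by all samples (effects correlated
`ρ_e` across samples there) plus disjoint per-sample private sets of
`(1−q)·M` loci with independent effects. Every pair's genome-wide effect
correlation is then `q·ρ_e`, and the closed forms are evaluated at that
implied CGR. Empirical "power per associated SNP" in these scenarios is the
number of true positives over the union of causal loci divided by `M` (the
per-study causal count): the closed form predicts `β·M` true positives,
while the union itself has `(2−q)M` members whose average rejection rate is
a different (and systematically smaller) estimand. MAF-effect coupling is
not combined with overlap scenarios; they use equal-R² effects.

**Randomness discipline.** One master seed per scenario; the scenario label
is hashed into the seed sequence, and replicate/study substreams are spawned
from it, so adding scenarios to a grid never perturbs existing ones and
identical (label, seed) pairs are bit-identical.

### Validation grids and what they show

The default baseline grid crosses `S ∈ {1000, 2000}` (with `M = S/10`),
`C ∈ {2, 5}`, `h² ∈ {0.2, 0.5}`, `ρ ∈ {0.3, 0.7, 1.0}` at 2,000 individuals
per study and per hold-out sample, 60 replicates per cell, with both
violations switched on (`s = 0`, per-study frequencies). The overlap grid
crosses `h² ∈ {0.2, 0.5}`, `q ∈ {0.5, 0.8}`, `ρ_e ∈ {0.6, 1.0}` at `C = 2`.
Cell sizes are chosen so the full run takes minutes on one CPU; at this
scale the per-cell Monte-Carlo standard error is ≤ 0.7 percentage points
for power and ≤ 0.2 for R², well below the reported aggregate RMSEs.

Validation uses a relaxed `α = 5e−4` (with the matching threshold on both
the theory and simulation side): at genome-wide `α` these sample sizes give
essentially zero power, and the closed form is a statement about the Z
variance that holds at any `α`.

These grids exercise the random-effects machinery, the violations above,
and the overlap mechanism — not LD, case-control ascertainment, imputation
error, within-study stratification, or binary traits. Agreement here shows
the closed forms are robust to the modeled violations at desk scale; it
does not certify behavior on real genotype data.

## Reproduction catalog

`metapower.run_all()` (CLI: `metapower reproduce`) recomputes every
cataloged published value: the predicted hits/R²/attenuation table for ten
large-scale GWAS designs (height, BMI, years of education, self-rated
health re-expressed as equal-size designs with `S = 250k`, `M = 20k`) and
the in-text figure values. All R² and R²-attenuation cells and all figure
values reproduce at printed precision. The expected-hits cells do not all:
the well-powered designs agree to within the sensitivity of the three-digit
printed `h²`/CGR inputs (≤ 0.02% relative for rows with > 100 hits, ≤ 1%
overall) but not to the printed 0.005 absolute, and the printed hit counts
of the weakest designs are mutually inconsistent with any equal-design
parameterization of their printed inputs — e.g. a printed 0.00 that lies
below the `α(S−M) = 0.0115` false-positive floor of the count formula, next
to same-trait rows that match the formula closely. The catalog reports both
values with notes; nothing is hidden or adjusted.

## Known limitations

* Independent-block abstraction only; no LD-aware effective-SNP estimation.
* Quantitative traits only; no liability-scale conversion for binary traits.
* No estimation of `h²` or CGR from data — these are inputs, taken e.g.
  from GREML; the framework inherits their sampling error silently.
* The fixed-effects meta-analysis is the object of study, not a
  recommendation; heterogeneity-aware meta-analysis methods are out of
  scope.
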