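# Methods

This note documents the statistical model behind `mrkit`, the defaults it
ships with and why, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reproducing results.

## Two-sample MR model and assumptions

The package estimates the causal effect θ of an exposure on an outcome
from per-SNP summary statistics drawn from two non-overlapping GWAS
samples. For instrument *j*: γ̂ⱼ ~ N(γⱼ, σₓⱼ²) on the exposure and
Γ̂ⱼ ~ N(θγⱼ + αⱼ, σᵧⱼ²) on the outcome, where αⱼ is a direct (pleiotropic)
effect, zero for a valid instrument. All inference is built on three
assumptions: the SNP is associated with the exposure (relevance), is not
confounded with the outcome (exchangeability), and affects the outcome only
through the exposure (exclusion; αⱼ = 0). The estimators differ in how much
of the third assumption they need:

* **Wald ratio / IVW** require all instruments valid; the fixed-effects
  inverse-variance weighting matches a setting where each SNP estimates the
  same θ and heterogeneity is sampling noise.
* **Correlated IVW** additionally models LD between instruments via the
  outcome covariance Ω = Dᵧ ρ Dᵧ (Dᵧ = diag σᵧ): correlated instruments
  carry overlapping information, and ignoring ρ understates the SE.
* **Maximum likelihood** maximizes the joint normal likelihood over
  (γ₁…γₖ, θ), so exposure-side measurement error enters the estimate
  rather than only the delta-method SE. With an LD matrix supplied, the
  outcome residual uses Ω; without one, Ω is diagonal.
* **MR-Egger** frees the intercept: under InSIDE (instrument strength
  independent of direct effects) its slope is consistent for θ even with
  directional pleiotropy, and the intercept estimates the average direct
  effect. Its price is regression dilution when exposure effects are
  measured with error, quantified by I²GX = max(0, (Q_GX − (k−1))/Q_GX);
  values near 1 mean negligible dilution.
* **Weighted median / weighted mode** are consistent when, respectively,
  valid instruments carry ≥ 50% of the inverse-variance weight, or the
  largest homogeneous cluster of instruments is valid. Both conditions are
  asymptotic in instrument precision — see the benchmark section.

## Defaults and parameters that matter

| parameter | default | rationale |
|---|---|---|
| delta-method order | first | the common convention; second order (adds σₓ²σᵧ²/γ̂⁴) available via `wald_se_delta(..., order=2)` |
| IVW weights | full delta SE | ratio-of-coefficients framing; `weighting="simple"` (σᵧ/|γ̂|) reproduces WLS-through-origin and is used for heterogeneity Q (below) |
| CI multiplier | 1.96 | normal approximation for 95% CIs used throughout |
| palindrome policy | `drop`, eaf tolerance 0.08 | A/T and C/G SNPs are strand-ambiguous; frequency inference is only trusted when both studies sit > 0.08 from 0.5 |
| orientation | γ̂ⱼ ≥ 0 | exposure-increasing allele convention; presentation only — all estimators are orientation-invariant (tested) |
| Ω regularization | ridge 1e-8·tr(Ω)/k once if min eig < 1e-10·max | LD matrices from finite reference panels are near-singular |
| ML convergence | max-gradient ≤ 1e-8 in standardized units | likelihood is smooth and near-quadratic; BFGS plus analytic-Hessian Newton polish |
| bootstrap B | 1,000, explicit seed | median/mode SEs; doubling B moves SEs < 5% on reference fixtures (tested) |
| mode bandwidth | φ = 1 × modified Silverman, 0.9·min(sd, IQR/1.349)·k^(−1/5) | standard kernel-mode choice; ties break to the smallest estimate |
| weak-instrument flag | F ≤ 10 | conventional first-stage threshold |
| power α | 0.05 two-sided | standard |

Design choices made where the design was genuinely open:

* **Egger covariance.** Coefficient SEs use the known-variance
  (fixed-effect) covariance (XᵀWX)⁻¹ with W = 1/σᵧ², consistent with the
  fixed-effects IVW model; much published software scales by the residual
  variance instead (a multiplicative random-effects flavor). Point
  estimates are identical; SEs differ when heterogeneity is present.
* **Heterogeneity Q weights.** Cochran's Q uses wⱼ = (γ̂ⱼ/σᵧⱼ)², not the
  full delta-method weight: the exposure-error term Γ̂ⱼ²σₓⱼ²/γ̂ⱼ⁴ is
  correlated with the squared residual, which demonstrably makes Q
  conservative (type-I error ≈ 0.036 instead of 0.05 at per-SNP F ≈ 260),
  whereas with the standard weights Q is exactly χ²(k−1) conditional on the
  exposure draws under the null.
* **F statistic form.** `f_statistic` defaults to the single-regressor
  expression R²(n−2)/(1−R²); the multi-instrument form
  R²(n−1−k)/(k(1−R²)) is available via `form="multi"`.
* **LD sign alignment.** When harmonization flips a SNP's orientation
  allele, its row and column of ρ are negated — the mathematically
  consistent convention if the LD matrix is supplied in the exposure file's
  allele orientation.
* **Likelihood for correlated instruments.** Both the independence
  approximation and the Ω-weighted likelihood are implemented; the pipeline
  uses the Ω-weighted fit as the sensitivity analysis for LD-correlated
  panels.

## The synthetic-data generator

`simulate_two_sample` emulates two-sample summary statistics with known
truth. Per-SNP SEs follow the standard large-sample approximations for an
additively coded variant with minor-allele frequency *p* and a standardized
trait: σₓ = 1/√(2p(1−p)·n_exp), and for a binary outcome on the log-odds
scale σᵧ = 1/√(2p(1−p)·n_out·K(1−K)) with case fraction K (the K(1−K)
factor is dropped for continuous outcomes). Pleiotropy regimes: `balanced`
(mean-zero αⱼ), `directional` (nonzero mean), optionally confined to a
random subset (`pleiotropy_fraction`) and optionally correlated with γⱼ
(`inside_violated`, correlation 0.7). Optional LD blocks correlate the
sampling errors of *both* the exposure and the outcome estimates within a
block — LD affects estimation error in each GWAS sample, not only the
outcome — and the same matrix is exported for the correlated estimators.
With `r2_target` set, drawn γⱼ are rescaled so Σ2p(1−p)γⱼ² hits the target
exactly.

The bundled four study arms mimic a published antioxidant/AD design: two
single-SNP vitamin exposures (R² ≈ 0.009 at n = 3,512 and R² ≈ 0.005 at
n = 9,302, the latter on the log scale), a four-variant carotenoid locus
with within-block ρ = 0.3 (R² ≈ 0.061, n = 2,344, log scale), and a 30-SNP
independent urate panel (R² ≈ 0.07, n = 110,347), all against a
case-control outcome of n = 54,162 with 31.4% cases.

What the generator does **not** emulate: realistic genome-wide LD,
allele-frequency/effect-size coupling from selection, sample overlap
between the two GWAS, population stratification, or winner's-curse
selection of instruments. Passing calibration tests on these fixtures
therefore demonstrates the estimators' statistical correctness under the
stated model, not robustness to those real-data complications.

## Monte-Carlo benchmark designs

The calibration benchmarks in `mrkit.benchmarks` fix their study
conditions:

* **Null IVW calibration and Q type-I error** use the urate-like arm at
  θ = 0 (500 and 2,000 replicates respectively).
* **Egger intercept recovery** uses directional pleiotropy
  αⱼ ~ N(0.02, 0.005²) on all 30 instruments with InSIDE held and a very
  large exposure GWAS (n_exp = 5×10⁶, so I²GX ≈ 1): this isolates the
  InSIDE-consistency property from regression dilution, which is diagnosed
  separately through I²GX.
* **Weighted-median robustness** puts directional pleiotropy of about eight
  ratio-SEs on 40% of 30 instruments (holding ≈ 39% of the weight) with
  precise instruments from two large continuous-trait GWAS
  (n = 2×10⁶ each). The median's validity condition is asymptotic: its
  finite-sample bias is a quantile shift of order the per-ratio SE
  (≈ 0.967 × SE at 40% invalid weight), so instrument precision — not the
  number of replicates — controls how close it gets to the truth. Under
  these conditions the expected bias is ≈ 0.01 at θ = 0.5.

Replicate counts (500/2,000) were chosen so Monte-Carlo SEs are a few
permille, keeping the whole benchmark suite under half a minute on one CPU.

## Degenerate inputs and numerical notes

Wald ratios are undefined at γ̂ = 0 and raise a named error. Estimators
requiring k ≥ 2 (Q, I²GX) or k ≥ 3 (Egger, median, mode) raise for smaller
panels; the pipeline converts this into a logged "skipped" notice for
single-SNP exposures and into per-method error rows in subset reruns.
Near-symmetric LD matrices (asymmetry < 1e-8) are symmetrized, larger
asymmetries rejected; a duplicated instrument (ρ → 1) is handled by the
ridge and contributes no extra information. The ML optimizer works in
standardized exposure deviations (γ = γ̂ + σₓa), which keeps the Hessian
well-conditioned even as σₓ → 0; the SE comes from the θ-entry of the
inverse observed information, which is invariant under that linear
reparameterization. All report tables are written with a fixed float
format, so repeated runs with the same configuration and seed are
byte-identical.

## Known limitations

Fixed-effects IVW only (no multiplicative/additive random-effects
overdispersion), no multivariable MR, no MR-PRESSO/Radial MR/Steiger
filtering, no proxy-SNP lookup or LD computation from genotypes, and the
binary-outcome power formula is the standard normal approximation for a
standardized exposure (continuous-outcome power is out of scope). Bootstrap
SEs for median/mode assume the per-SNP ratio SEs are correct; with very
weak instruments the normal resampling model understates ratio tail risk.
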