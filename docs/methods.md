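# Methods

## Model

`rhodoscreen` treats color tuning as a sparse linear regression problem on
pocket physicochemistry. For K training pairs (**x**⁽ᵏ⁾, λmax⁽ᵏ⁾):

- Likelihood: λmax⁽ᵏ⁾ ~ N(μ + **β**ᵀ**x**⁽ᵏ⁾, σ²), wavelengths in nm.
- Prior on coefficients: conditional Laplace,
  π(**β**|σ²) = ∏ⱼ (γ/2√σ²) exp(−γ|βⱼ|/√σ²). The maximum of the
  conditional posterior of **β** given (σ, γ) is exactly the LASSO solution
  with ℓ₁ penalty 2γσ, so the Bayesian model inherits LASSO's automatic
  variable selection while adding calibrated uncertainty.
- Hyper-priors: γ² ~ Gamma(r, δ) (shape/rate), σ² ~ InvGamma(a, b); μ flat.

Inference is Gibbs sampling on the scale-mixture representation
βⱼ|σ²,τⱼ² ~ N(0, σ²τⱼ²), τⱼ² ~ Exp(γ²/2), with the standard full
conditionals: multivariate normal for **β** (covariance σ²(XᵀX + D_τ⁻¹)⁻¹,
solved by Cholesky with escalating diagonal jitter on failure), normal for
μ, inverse-gamma for σ², inverse-Gaussian for each 1/τⱼ² (drawn with the
Wald sampler; means clamped to 10¹² when |βⱼ| underflows, τⱼ² floored at
10⁻¹²), and gamma for γ². The update order per sweep is fixed —
**β**, μ, σ², τ², γ² — and one seeded generator drives the whole chain, so
a (seed, config, data) triple reproduces draws bit-for-bit.

The Laplace prior keeps the **β** conditional covariance positive definite
even when coefficients outnumber sequences (432 > K), which is the regime
the screening problem lives in.

## Acquisition criterion

For a candidate **x** with subfamily base wavelength λ_base, the red-shift
gain is max(f(**x**) − λ_base, 0) and the screening score is its posterior
mean, estimated from the T retained draws by the truncated-mean average.
Because max(·, 0) is convex, the estimator exactly satisfies the Jensen
bound 𝔼[gain] ≥ max(pred_mean − λ_base, 0) on every draw set; it is
non-increasing in λ_base and invariant to shifting draws and base by the
same constant. Candidates with equal predictive means below λ_base rank by
predictive spread — the exploration side of the trade-off. Alongside the
point score the package reports the fraction of draws above λ_base and the
Monte-Carlo standard error (sample SD of truncated values / √T), which
makes "is this ranking difference real or MC noise" answerable.

Selection takes candidates with 𝔼[gain] strictly greater than the
threshold (default 10 nm), sorted descending with ties broken by id for
reproducibility. An optional subfamily whitelist restricts selection (e.g.
to ion-pump subfamilies) without hiding other candidates from the ranking,
and candidates whose pocket string coincides with a training sequence are
flagged so already-characterized genes can be excluded.

## Defaults and parameters

| parameter | default | notes |
|---|---|---|
| pocket positions | 24 BR-numbered residues | bundled `pocket_positions.tsv`; includes 93, 186, 215, the classic color-switch sites. A stand-in list of well-known retinal-contact residues — replace with study-specific columns via `--pocket` |
| feature scales | 18 | bundled `feature_table.tsv`: standard literature scales (Kyte–Doolittle and three other hydrophobicities, volume, bulkiness, two polarities, pI, net charge, MW, ASA, flexibility, three secondary-structure propensities, refractivity, polarizability). Replaceable the same way |
| T retained draws | 10,000 | burn-in 1,000, thinning 1 |
| r, δ (γ² prior) | 1, 0.1 | weakly informative; prior mean γ² = 10 |
| a, b (σ² prior) | 0.01, 0.01 | near-improper |
| selection threshold | 10 nm | strict inequality |
| base wavelengths | 7 subfamilies | BacHR 537, XeR 565, ClR 530, PR 520, NaR 525, DTG 535, CyanDTEDTD 545 nm |
| gap policy | `error` | alternatives: `zero`, `training_mean` (coordinate-mean imputation); in pipeline mode offending records are dropped with a warning |

Features are z-scored per coordinate on the training set (population SD;
zero-variance coordinates pass through centered with scale 1) and the same
transform is applied to candidates — a single global shrinkage γ is only
meaningful on a common scale. The fitted posterior carries the
standardizer's hash and prediction refuses candidates transformed with a
different one. Pocket files declare their convention in the header:
`column0` / `column1` for raw alignment columns, `br_position` for 1-based
residue numbers mapped through an ungapped reference sequence.

Reported gain means are rounded to one decimal nm with round-half-even.
PCA projections fix component signs by making each component's
largest-magnitude loading positive.

## Synthetic data generator

`simulate_dataset` emulates the statistical structure the model assumes:
each pocket column draws residues from a private 6-letter alphabet with
Dirichlet-weighted frequencies (non-degenerate, position-specific
composition), filler columns are uniform noise the model never reads, and
λmax = intercept + Σ_support (±coefficient_scale)·z + N(0, noise_sd²) on the
standardized encoding. Defaults — 300 training sequences, 24×18 features,
10 nonzero coefficients of ±10 nm, 5 nm noise, 540 nm intercept — mirror
the scale of a realistic training compendium and of published per-residue
color-tuning effect sizes.

What it does **not** emulate: phylogenetic correlation between sequences,
alignment errors and real gap structure, subfamily-specific feature
composition, and any nonlinear or epistatic color tuning. Passing recovery
tests therefore show the inference machinery is correct under the model's
own assumptions, not that real rhodopsin data satisfy them. One consequence
visible in the recovery numbers: the 18 scales of one pocket position are
functions of a single categorical residue, so within-position features are
strongly collinear and individual coefficients are only partially
identifiable — support-coefficient correlations around 0.9 are the expected
ceiling, not a sampler deficiency.

## Numerical and design choices

- Exact binomial test: two-sided p sums all outcome probabilities no larger
  than the observed one (with a 10⁻⁹ relative slack against floating-point
  ties); at p₀ = 0.5 this equals twice the smaller tail capped at 1.
  Two-sided is the default because it is the stricter claim; a one-sided
  upper-tail variant is provided. Unchanged outcomes (observed = base)
  count as failures and are not dropped from n.
- Posterior-mode check: the retained draw maximizing the conditional
  log-density −[RSS + 2γ̂σ̂Σ|β|]/(2σ̂²) (γ̂, σ̂ posterior means of √γ², √σ²)
  is compared coordinate-wise against an independent coordinate-descent
  LASSO fit at α = γ̂σ̂/K; on a 1-feature problem that solution is the
  analytic soft-threshold, used as a hand oracle in the tests.
- Problem sizes in the test suite and acceptance script are scaled to keep
  runs short while preserving the regime of interest (more coefficients
  than sequences for the main recovery run at K = 300, p = 432,
  T = 2,000 + 500 burn-in; toy 1- and 20-feature problems for the mode
  check); the package itself defaults to T = 10,000.

## Known limitations

- The bundled pocket list and feature table are documented stand-ins, not
  a published study's exact supplementary configuration; absolute λmax
  predictions on real data depend on substituting the real ones.
- The linear model cannot express epistasis between pocket residues or
  structural effects beyond the chosen columns; observed gains smaller than
  expected gains (selection optimism) are inherent to acquisition-driven
  screening and are not corrected for.
- One screening round only: no sequential re-training loop, and no
  acquisition functions other than the expected truncated gain.
- Gibbs draws are serially correlated; the reported MC standard errors
  treat draws as independent and thus understate uncertainty for short,
  poorly mixed chains. Increase T or thinning when in doubt.
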