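# Methods

## Model 1: the expected leverage slope under a no-leverage null

Protein intake `U` and non-protein intake `V` (kJ/day) are modelled as
bivariate normal with means `μ_U, μ_V`, SDs `σ_U, σ_V` and correlation
`ρ_UV`. Total energy `Z = U + V` is then normal with
`σ_Z² = σ_U² + σ_V² + 2σ_UV`, and protein–total covariance
`σ_UZ = σ_U² + σ_UV`. The protein share `W = U/Z` is a ratio of two
correlated normals; its exact density is evaluated in the confluent-
hypergeometric form

```
f_W(w) ∝ exp(−c) / (σ_Z²w² − 2σ_UZ w + σ_U²) · M(1, 1/2, θ(w))
```

with `θ(w)` a ratio of quadratics in `w`. `M(1, 1/2, z)` is computed on the
log scale through the identity `M(1, 1/2, z) = 1 + √(πz) e^z erf(√z)`, so
arbitrarily sharp share distributions (large `z`) never overflow; the
general `kummer_M(θ, γ, ζ)` entry point applies the Kummer transformation
`M(θ,γ,ζ) = e^ζ M(γ−θ,γ,−ζ)` for `ζ > 50` and raises on genuine overflow
rather than returning infinity.

The expected slope of the leverage regression is

```
E(L) = σ_XY / σ_X²,   σ_XY = log(1 + σ_WZ/(μ_W μ_Z)),   σ_WZ = μ_U − μ_W μ_Z,
```

where `μ_W` is the mean of `W` and `σ_X²` the variance of `X = log W`,
both obtained by adaptive quadrature (absolute and relative tolerance
1e−8) of the exact density. `σ_XY` is the standard first-order Taylor
approximation for the covariance of logs; it is the only approximation in
the chain, and simulation shows it is near-exact where `E(L) < 0` and a
slight underestimate where `E(L) > 0`.

### Support truncation and feasibility conditioning

The ratio of normals has full real support. Densities here carry explicit
bounds enclosing at least `1 − 1e−9` of mass, found by stepping outward
from `μ_U/μ_Z` in units of the delta-method SD of `W` until a 4σ band
contributes less than a quarter of the tail allowance; every density is
then checked to integrate to 1 within `1e−5`.

When an intake coefficient of variation approaches 0.5 the normal model
places visible mass (up to a few percent) on negative intakes, i.e. on
`W ∉ (0, 1)`. Two conventions are used, deliberately:

- `σ_WZ = E[U] − E[W]E[Z]` is an identity in **unconditional** moments, so
  `μ_W` is integrated over the full ratio density. This is what makes the
  second-order sign rule `sign(σ_WZ) = sign(ID_U − ID_V)` (at `ρ_UV = 0`)
  hold at every grid point.
- The log moments `μ_X, σ_X²` require `W ∈ (0, 1)`, so the density is
  truncated to `(10⁻⁶, 1 − 10⁻⁶)` and renormalized — the analytical
  analogue of excluding negative draws from a simulated cohort, which is
  exactly what the simulators do.

Both conventions coincide (to the 1e−9 tail allowance) in the well-posed
regime `CV < 0.5`, where a warning marks departures.

## Model 2: the dispersion fingerprint of true leverage

Here leverage is assumed: `W ~ Beta(κ, τ)` (parameterizable by mean and SD
through exact moment inversion) and log energy `Y = α + L·X + ε` with
`X = log W` and `ε ~ N(0, σ_ε²)`. Defaults anchor the deterministic kernel
at the recommended adult intake: `α = log(8700/μ_W^L)` (so energy is
8700 kJ when the share equals its mean) and `σ_ε² = log(8700)·0.02 ≈ 0.181`.

- `X`-moments: quadrature of the log-beta density; the digamma/trigamma
  closed forms `ψ(κ) − ψ(κ+τ)`, `ψ₁(κ) − ψ₁(κ+τ)` are kept as an
  independent check (agreement 1e−8). The beta support is cut at 1e−15
  tail mass per side — far below the generic 1e−9 convention — because
  the `x²` weight of the variance integrand amplifies the truncated tail.
- `f_Y` is the convolution of the scaled log-beta density with the normal
  residual kernel. It is integrated over the **residual** (Gauss–Legendre,
  240 nodes on ±8σ_ε): a rule with nodes on the `X` side aliases once
  `σ_ε` falls below the node spacing, and the degenerate limits (`L = 0`,
  or `σ_ε² → 0`) are exercised by the tests. `L = 0` is a separate branch
  (`Y` exactly normal). The moments of `Y` use the exact linear-transform
  identities `μ_Y = α + Lμ_X`, `σ_Y² = L²σ_X² + σ_ε²`, which the
  density-side quadrature reproduces to 1e−6.
- Natural-scale energy moments integrate `e^y f_Y(y)` on the log scale.
- Intake moments: `log U = X + Y` with exact covariance `σ_XY = Lσ_X²`;
  `(μ_U, σ_U²)` by the lognormal back-transform; `μ_V = μ_Z − μ_U`
  exactly; `σ_V²` via `log V = S + Y`, `S = log(1−W)` (a log-beta with
  swapped shapes) and the Taylor covariance
  `σ_SY = log(1 + (μ_Z μ_W − μ_U)/((1−μ_W)μ_Z))`.

The lognormal back-transform assumes log-scale normality that log-beta
variables only approximate; against 100 000-draw simulations the intake
moments sit within a few percent (tests assert 10%) on the default grid,
with the model IDR slightly above the simulated IDR in the low-share,
weak-leverage corner — the same bias direction the analytical/simulation
comparison is expected to show. Index of dispersion is `σ²/μ` per
nutrient; `IDR = ID_U/ID_V` falls monotonically as leverage strengthens
over the whole default grid.

## Simulators

All generators take an explicit integer seed (numpy `default_rng`),
record generator name, parameters, seed, requested and excluded counts in
table provenance, and are bit-reproducible.

- **Bivariate normal**: draws with any component ≤ 0 are excluded and
  counted (log intake is undefined for them); exclusions above 0.1% of
  the request trigger a warning.
- **Bivariate lognormal**: Gaussian copula. By default the *natural-scale*
  means, SDs and correlation match the requested parameters, using
  `s² = log(1 + CV²)` per marginal and the exact inverse of the lognormal
  correlation mapping
  `ρ_log = log(1 + ρ·√(expm1(s_U²)·expm1(s_V²)))/(s_U s_V)`; requested
  correlations outside the attainable lognormal range raise with the
  bounds. A `match="log"` alternative applies the parameters on the log
  scale directly (the exponential-of-normal convention); which convention
  a study intends is often ambiguous, so both are exposed.
- **Leverage-generative**: `W ~ Beta`, `Y = α + L log W + ε`, `Z = e^Y`,
  `U = ZW`, `V = Z(1−W)`; positive by construction.

What the generators deliberately do not emulate: repeated-measures survey
designs, misreporting and measurement error (beyond what a user can add
as covariate columns), heavy-tailed or multimodal intake distributions.
Passing tests therefore show the estimators recover the generating
process under these idealized regimes, not that any real survey is free
of confounding — the covariate-adjustment test shows confounders can be
removed only when they are measured.

## Estimation

`fit_leverage` is OLS (statsmodels) of `log E` on `log p` with optional
covariate columns; natural logarithms throughout, so `P = exp(α)` is in
kJ (the slope is base-invariant, the intercept is not). Non-positive
intakes are rejected listing the offending rows — how zero intakes in
real survey data should be treated is a substantive decision the package
refuses to make silently. Rank-deficient designs are rejected naming the
most collinear columns. `fit_power_law` fits `E = P·p^L` by nonlinear
least squares (scipy `curve_fit`) initialized from the log-log fit.
Dispersion statistics use unbiased (n−1) variances — IDR is scale-
sensitive at small n, so the convention matters and is fixed here. A
Spearman correlation is provided as the non-parametric signal check; no
non-parametric leverage *coefficient* is defined. A sklearn-compatible
`ProteinLeverageRegressor` wraps the same fits for pipeline use.

## Problem sizes and defaults

Default validation sizes: 20 000 subjects per grid point for the Model-1
null (60-point share × IDR × correlation grid, `ID_V = 125`), 100 000 per
point for the Model-2 grid (`μ_W ∈ {0.15, 0.2, 0.3}`, `σ_W ∈ {0.03, 0.05,
0.07}`, `L ∈ {−1, −0.7, −0.4, −0.1}`). Grid resolutions are the package's
defaults for routine runs; `--dense` on the CLI restores fine grids.
Degenerate shares are clipped to `[0.01, 0.99]`, and grid points where the
Taylor log argument is non-positive are flagged in output rather than
dropped.

## Known limitations

- `E(L)` is a population expectation; no standard error accompanies it.
- The Taylor covariance underestimates positive `E(L)`; conclusions about
  *negative* slopes (the protein-leverage direction) are the reliable ones.
- Model-2 back-transforms are approximations; exact natural-scale protein
  moments could be obtained by beta-function ratios but the approximate
  chain is kept as the primary path with simulation as its error envelope.
- Only two-component (protein vs non-protein) compositions are handled;
  no amino-acid-level or n-nutrient extensions.
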