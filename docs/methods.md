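# Methods

## Descriptors

An ion's surface is a weighted point set: COSMO-style segments carry
(area Å², screening charge density σ in e/Å²), ESP surfaces carry
(area Å², electrostatic potential in kcal/mol). A descriptor is the total
area falling in one bin of a fixed grid:

| grid | range | bin width | bins | label |
|------|-------|-----------|------|-------|
| σ (cation and anion) | [−0.03, 0.03) e/Å² | 0.001 | 60 | left edge, 3 decimals |
| ESP, cation | [0, 150) kcal/mol | 0.5 | 300 | midpoint, 2 decimals |
| ESP, anion | [−150, 0) kcal/mol | 0.5 | 300 | midpoint, 2 decimals |

Bins are half-open [left, right); a value exactly on the top edge of the grid
joins the last bin (the usual histogram convention — the choice only matters
for the single value σ = 0.03 or ESP = ±150). Conventional ESP names label a
bin by its midpoint (`S_EP-C88.75` ⇔ [88.5, 89.0)). Conventional σ names such
as `S_σ-C0.013` end in three decimals, which midpoints of a 0.001-wide grid
anchored at −0.03 cannot produce (they end in …5); we therefore label σ bins
by their **left edge** (`S_σ-C0.013` ⇔ [0.013, 0.014)) and state that choice
here rather than hiding it. Bin assignment snaps values within 10⁻⁹ bin
widths of their right edge upward, so decimal values that sit exactly on an
edge mathematically (0.013) are never mis-binned by their binary float
representation.

Out-of-grid area is never dropped silently: each profile carries a spill area
and count, and binned + spill always equals the input total area (the
conservation invariant, tested to 1e-9 relative). A surface entirely outside
its grid is degenerate and raises by default (configurable to a warning).

The σ axis partitions chemically at ±0.0082 e/Å²: σ < −0.0082 is
hydrogen-bond-donor surface, σ > 0.0082 hydrogen-bond-acceptor surface, and
the closed band between them non-polar. Profiles are per-ion raw areas; no
mole-fraction weighting is applied, so two ILs sharing a cation share that
cation's 360 feature values exactly.

File dialect: two-column (area, value) text, whitespace- or comma-delimited,
`#` comments; `area_col`/`value_col` map wider quantum-chemistry tables onto
the two needed columns. Units are fixed (Å², kcal/mol, e/Å²) and conversion
is the caller's responsibility.

## Stepwise multiple linear regression

`fit_ols` solves least squares on [1 | X] via `lstsq` and reports per-term
t statistics (coefficient / standard error from σ̂²·(XᵀX)⁻¹) and p-values
(two-sided Student t with n−p−1 df). Rank deficiency is detected by pivoted
QR and the error names the dependent columns. Coefficients are for
**unstandardized** descriptors; the package never rescales features
implicitly.

Selection alternates a forward move (admit the candidate with the smallest
p-value if below `p_enter`; ties broken by column order) and a backward move
(drop the included term with the largest p-value if above `p_remove`) until
neither applies or `max_terms` is reached. Zero-variance candidates are
excluded up front with a log entry. The trace records R², adjusted R² and
the regression standard error after every move; along forward-only prefixes
R² is non-decreasing (nested models).

Defaults are the classic `p_enter = 0.05`, `p_remove = 0.10`. These control
the *per-test* false-entry rate: with ~100 candidate descriptors the chance
that at least one pure-noise candidate clears 0.05 at some scan approaches 1,
so an exact-support recovery experiment must Bonferroni-correct the entry
threshold. The recovery experiments here use `p_enter = 1e-4 ≈ 0.05 / (105
candidates × ~6 scans)` and `p_remove = 1e-3`; with that correction, 5
informative descriptors (coefficients of the published magnitudes, noise SD
5 % of signal SD, n = 200) are recovered exactly, with zero decoys, in
≳95 % of replicates. This is a property of stepwise testing itself, not of
this implementation.

`published_model()` returns the reported 11-term model (intercept 2.712;
eight cation ESP terms, three cation σ terms; t values attached) from a
packaged JSON asset. All eleven descriptors are cation features, consistent
with the cation dominating AChE toxicity.

## Extreme learning machine

A single hidden layer of `n_hidden` sine neurons: H = sin(Z ωᵀ + b) on
standardized features Z (means/SDs stored in the model, so prediction is
self-contained; zero-variance features get scale 1). ω and b are drawn
uniform[−1, 1] from numpy's PCG64 generator under an explicit seed — one
block of shape (n_hidden, n_features + 1), so a k-neuron model is exactly
the first k rows of a larger model from the same seed. Neuron sweeps
therefore use *nested* random bases, which makes training R² non-decreasing
in the count and keeps any swept count bit-identical to a direct fit at that
count.

The output layer is the minimum-norm least-squares solution of H β ≈ y via
SVD pseudoinverse (`rcond = 1e-10`; an optional ridge term solves the
regularized normal equations instead). The residual is orthogonal to the
column space of H, and with n_hidden = n_samples the network interpolates
noiseless data (training RMSE ≤ 1e-6 in the tests).

**Output bias.** A constant column is appended to H by default. Activity
targets have a large mean relative to their spread, and a bias-free random
sine basis represents a constant poorly at moderate neuron counts: in a
bias-free fit of the default synthetic study, training R² was deeply
negative until the basis was near-square. The strictly bias-free layer is
available via `include_output_bias=False`.

`sweep_neurons` scores every count on train and test (R² and AARD%);
`best_n` minimizes test AARD% by default — the quantity whose U-shaped curve
locates the generalization optimum. Test-set model selection is a known
hazard; the criterion is a parameter so a validation split can be used
instead. `auto_sweep` runs a coarse grid (5…100 step 5 by default, capped at
the training-set size) and refines ±4 around the coarse optimum.

## Validation statistics

All statistics are computed exactly as defined in the module docstring
(R² = 1 − SSE/SST about the experimental mean; AARD%; RMSE; per-sample
ARD%; through-origin slopes k = Σyᵉyᶜ/Σ(yᶜ)², k′ = Σyᵉyᶜ/Σ(yᵉ)²). For the
through-origin correlations R₀² and R₀′² two modes exist because the
commonly reprinted closed forms scale a variable by its own slope (their
numerator Σ(yᶜ − k·yᶜ)² collapses to (1−k)²Σ(yᶜ)², which cannot be the
intended quantity): the default `standard` mode computes the
Golbraikh–Tropsha regressions-through-origin properly (residuals of
ŷᶜ = k′·yᵉ about the variance of yᶜ, and the converse), while `as_printed`
evaluates the reprinted forms literally for comparison with sources that use
them. The external-validation verdict requires all four criteria: R² > 0.7;
(R²−R₀²)/R² < 0.1 with 0.85 < k < 1.15; the primed converse; and
|R₀² − R₀′²| < 0.3.

Samples with |yᵉ| < 1e-12 would divide by zero in relative deviations and
are excluded from AARD%/ARD% with a logged count (they still count in R²
and RMSE). The ARD% report uses the four conventional half-open ranges
[0,1), [1,5), [5,10), [10,∞) %, with percentages rounded to two decimals
(sum 100 ± 0.05). The train/test split is a seeded uniform random partition
with train size ⌈fraction·n⌉ (160 → 128/32 at 0.8); no stratification.
Total-set metrics are computed on the union of train and test predictions,
not averaged. Adjusted R² is undefined when a set has ≤ p + 1 points (a
32-sample test set scored against a 45-neuron ELM); the report carries NaN
there rather than a misleading number.

## Synthetic data

The generators define the study conditions for everything the tests
establish:

* **Surfaces**: segment areas Dirichlet-partition a 300 Å² total (a
  realistic single-ion surface area) across 500 segments; σ comes from a
  three-Gaussian mixture (means ∓0.012/0/+0.012, SD 0.004, weights
  0.2/0.6/0.2) emulating donor/non-polar/acceptor mass of a mid-polarity
  ion. ESP points are uniform over the role's range. Truth records
  (per-region and per-bin area) are computed by independent scans, not by
  the histogram code under test.
* **QSAR tables**: the default mirrors the reference study's shape — 160
  samples, 11 informative descriptors named and weighted as the published
  model (intercept 2.712), 709 decoys covering the rest of the 720-name
  grid, half-normal features (bin areas are non-negative) of unit scale and
  Gaussian noise of SD 0.1 on logEC₅₀ (the order of the published training
  RMSE). `relative_noise=True` interprets the noise SD as a fraction of the
  noiseless-signal SD, which is how the recovery experiments pin the 5 %
  noise condition.

What synthetic data does **not** emulate: correlations between neighbouring
bins of real profiles, shared-ion block structure across ILs, and any
nonlinearity in the descriptor→activity map. Consequences: passing tests
demonstrate correctness of the algorithms, not predictive performance on
real ILs; and because the generated truth is exactly linear, the MLR
outperforms the ELM on these benchmarks by construction — the reverse of
what curved real-world activity surfaces can show. Reproducing published
whole-dataset statistics would require the original quantum-chemistry
surface files, which are not distributable here.

## Numerical choices and limitations

* One RNG family everywhere (numpy PCG64 via `default_rng(seed)`); all
  generators, splits and ELM fits are bit-reproducible under their seed.
* Histogram edges come from `linspace`; assignment snaps 1e-9-bin-width
  float noise at right edges (see above); conservation is tested at 1e-9
  relative.
* Stepwise p-value ties are broken by column order, making selection
  deterministic.
* The acceptance script scales its experiments to desk size (100 recovery
  replicates at n = 200, 100 surfaces, 1000 oracle sets) — the sizes are
  stated in its output alongside each value.
* Known limitations: stepwise inference is greedy and its p-values are
  nominal, not selection-adjusted; ELM quality on small linear problems is
  seed-sensitive; the `as_printed` R₀² mode is provided for comparison only
  and deliberately not used in any verdict.
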