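# iltox

Surface-histogram QSAR models for ionic-liquid (IL) toxicity toward the
acetylcholinesterase enzyme (AChE).

Ionic liquids — salts of a discrete organic cation and an anion that are
liquid near ambient temperature — are candidate green solvents whose toxicity
is poorly characterized across the ~10⁸ possible cation/anion combinations.
`iltox` implements a descriptor-based route to predicting their toxicity
endpoint logEC₅₀(AChE) (log₁₀ of the µM concentration inhibiting half the
enzyme activity) from quantum-chemistry *surface* outputs, without requiring
the quantum chemistry itself:

* **Descriptors.** Each ion's COSMO surface (segments of area *a* in Å² and
  screening charge density σ in e/Å²) is histogrammed on the σ grid
  [−0.03, 0.03) with 0.001-wide bins, and its electrostatic-potential surface
  (patch area vs ESP in kcal/mol) on 0.5-wide bins over [0, 150) for cations
  and [−150, 0) for anions. Each bin's total area is one named descriptor:
  `S_EP-C88.75` is the cation area with ESP in [88.5, 89.0) kcal/mol,
  `S_σ-C0.013` the cation area with σ in [0.013, 0.014) e/Å². An IL's feature
  vector concatenates cation/anion ESP and σ profiles (720 features).
* **Linear model (MLR).** Stepwise (forward + backward) descriptor selection
  followed by ordinary least squares:
  logEC₅₀ = P₀ + Σᵢ Cᵢ·S_EP-h + Σⱼ Cⱼ·S_σ-k.
  The reported 11-descriptor model (8 cation ESP terms, 3 cation σ terms,
  P₀ = 2.712) ships as `published_model()`.
* **Nonlinear model (ELM).** A single-hidden-layer extreme learning machine:
  random fixed input weights and biases, sine activation, and an exactly
  solved least-squares output layer, plus a neuron-count sweep that locates
  the generalization optimum.
* **Validation.** The full statistic suite — R², adjusted R², AARD%, RMSE,
  per-sample ARD% and its 0–1/1–5/5–10/≥10 % distribution report — and the
  Golbraikh–Tropsha external-validation criteria (R² > 0.7; through-origin
  slopes k, k′ ∈ (0.85, 1.15) with (R²−R₀²)/R² < 0.1 and the converse;
  |R₀² − R₀′²| < 0.3), plus the seeded 80/20 train/test split
  (160 samples → 128/32).
* **Synthetic data.** Seeded generators for surfaces, ESP point sets and
  descriptor tables with known linear ground truth, so the whole pipeline is
  testable end to end without Gaussian/Multiwfn/COSMO-RS runs.

## Worked example

`examples/` contains one narrative script per capability. For instance
`python examples/02_published_model.py` prints:

```
intercept P0 = 2.712
11 terms; most influential (|t|):
  S_σ-C0.013     coef +0.537 t +18.957
  S_EP-C36.25    coef +0.361 t +10.565
  S_EP-C82.75    coef -0.213 t -10.501
prediction on zero row: 2.712
with 1 A^2 in S_σ-C0.013: 3.249
```

An all-zero descriptor row evaluates to the intercept; adding one Å² of
cation surface in the σ bin [0.013, 0.014) — hydrogen-bond-acceptor surface —
raises the predicted logEC₅₀ by its coefficient 0.537, i.e. lowers the
predicted toxicity. `examples/03_stepwise_vs_elm.py` runs the full synthetic
study (160 ILs, 80/20 split) and prints the MLR-vs-ELM comparison table;
on this generator's *linear* ground truth the stepwise MLR recovers all 11
true descriptors (test R² ≈ 0.95) and outperforms the ELM, as expected when
no curvature is present.

A thin CLI mirrors the workflow (`iltox synth|featurize|train-mlr|train-elm|
sweep|predict|evaluate|run`); see `iltox --help`.

## Scope

The package consumes surface files (two-column area/value text, with column
mapping for wider COSMO-style tables); it does not perform geometry
optimization, compute ESP grids or COSMO charge densities. Reproducing the
published 160-IL headline statistics would require the original
quantum-chemistry outputs for 57 cations and 21 anions, which are not part
of this package.
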