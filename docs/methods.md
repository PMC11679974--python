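# Methods

## Scope and model

`monofilm` analyses Langmuir monolayers formed at the air–water
interface by the constant-area (saturation) method.  Three physical
models are chained:

1. **Saturation-point geometry.**  A π(n) trace (surface pressure vs
   amount of lipid spread at fixed trough area) rises steeply while the
   film compresses and flattens once the interface saturates.  The
   saturation point is defined as the intersection of two ordinary
   least-squares lines: one through the contiguous window of maximal
   slope (default width 5 points, ties broken toward larger n), one
   through the plateau points (π ≥ π_max − 0.5 mN/m, at least three;
   the final three points if fewer qualify).  The construction requires
   the steepest window slope to exceed five times the final-window
   slope, otherwise no plateau is declared; near-parallel lines
   (< 1° apart) are rejected as degenerate.  The mean area per lipid is
   A_sat = trough area / (N_A · n_sat), counting **all** molecules
   including sterols.

2. **Helmholtz parallel-plate capacitor.**  ΔV = 12π·μ⊥/A (+ ΔV0), with
   ΔV in mV, μ⊥ in millidebye, A in Å².  The 12π prefactor is exact in
   this mixed unit system.  The offset variant uses ΔV0 = 100 mV by
   default, the typical area-independent intercept of ΔV-vs-1/A plots
   for zwitterionic phospholipids; it is configurable everywhere it
   appears.  Because at the saturation pressure and at 30 mN/m the film
   is in the same phase, μ⊥ obtained at saturation is reused to
   extrapolate the dipole potential to 30 mN/m (the conventional
   bilayer-equivalent lateral pressure).

3. **Gouy–Chapman diffuse layer.**  For charged films the measured
   potential is ψ_measured = ψ_dipole + ψ0.  ψ0 solves the Grahame
   equation σ² = 2000·ε0·εr·R·T·Σ Cᵢ(exp(−zᵢFψ0/RT) − 1) (Cᵢ in mol/L),
   implemented as bracketed Brent root finding on ψ ∈ [−500, 500] mV
   (widened once to ±1000 mV), residual below 1e−10 C/m².  For a single
   1:1 electrolyte the solver agrees with the closed-form
   ψ0 = (2RT/F)·asinh(σ/√(8000·ε0εr·RT·C)) to better than 1e−6 mV
   (asserted in the tests against an independent bisection oracle).
   The surface charge density is σ = (Σ xᵢzᵢ)·e/A with POPS treated as
   fully ionized (z = −1); partial ionization of PS at high charge
   density is a recognized possibility that this package deliberately
   does not model.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| ΔV0 | 100 | mV | typical intercept for zwitterionic lipids; configurable |
| εr | 78.5 | — | water at 25 °C; no temperature dependence modelled |
| subphase | 150 mM NaCl, 298.15 K | — | dominant electrolyte of the standard buffer |
| plateau tolerance | 0.5 | mN/m | robust to small drift near saturation |
| steep window | 5 | points | narrow enough to sit inside the rise, wide enough to average noise |
| polynomial degree | 3 | — | lowest degree that tracks the compressed branch |
| fit cutoff | 100 | Å² | liquid expanded/condensed regime |

An optional extended-buffer preset adds an approximate speciation of
HEPES (10 mM, pKa₂ ≈ 7.5 → ≈ 44 % anionic at pH 7.4, one-site
Henderson–Hasselbalch) and EDTA (1 mM, carried as HEDTA³⁻),
Na⁺-balanced.  At physiological charge densities it shifts |ψ0| by only
a few mV, which is why the plain 1:1 salt is the default; the preset
exists to bound that approximation, not to be a speciation engine.

Rounding for report tables is to the nearest integer (mV, mD) with
halves away from zero; values are snapped to 9 decimals first so exact
halves perturbed by float arithmetic (e.g. 370.5 computed as a
product/quotient chain) still tie-break upward.  All rounding happens
at reporting/serialization; internal values keep full precision.

## The packaged study dataset

`monofilm.study` carries the measured inputs of an eleven-system
monolayer campaign (pure POPC/POPE/POPS/SpM and their binary, ternary
and quaternary mixtures with cholesterol) — areas per lipid at 30 mN/m
and at saturation, saturation pressures where determined, and dipole
potentials at saturation.  For charged films the stored potential is the
dipole potential (already corrected for ψ0); `study_records`
back-computes ψ_measured = ψd + ψ0 with the Grahame solver so the
forward pipeline, not a table lookup, produces every derived number.

Two caveats of the source data are preserved rather than repaired:

* **SpM:Chol 6:4** has no saturation-area determination; its dipole
  moments (379/286 mD) and 30 mN/m potentials (357/370 mV) are ingested
  as reported.  The reported pair is not exactly Helmholtz-consistent
  with its 39.0 Å² area at 30 mN/m (12π·379/39 ≈ 366 mV ≠ 357 mV).
  The cross-system ψd30*–ψd_sat correlations (R² = 0.54 plain, 0.65
  with offset) use these reported values; the sensitivity of R² to the
  choice is < 0.02.
* The **transbilayer potential at saturation** of the plasma-membrane
  model (inner PC:Chol:PE:PS 4:3:2:1 vs outer SpM:Chol 6:4) is reported
  two ways: Δψd = 66 mV and Δ(ψd + ψ0) = 32 mV.  Which convention a
  given experiment probes depends on where the potential reference
  sits, so `bilayer_summary` emits both and asserts neither.  At
  30 mN/m the difference is +26 mV (plain capacitor).

## Synthetic data generator

Raw trough traces are not publicly deposited, so `monofilm.synthetic`
generates them with recorded ground truth:

* π(n) traces use a hard plateau, π = min(poly(A(n)), π_sat), putting
  the knee exactly at the true saturation amount — matching the
  two-line extraction geometry and making truth well defined.  The
  truth polynomial approximates π = α + β/A, the form under which a
  constant-area trace rises linearly in n (as observed traces do); a
  degree-5 fit keeps the approximation error below ~0.02 mN/m so the
  knee is sharp and the extraction unbiased (noiseless recovery error
  < 0.1 %).  `degree=3` is available when a truth matching the default
  analysis polynomial is wanted.
* Potential readings compose the Helmholtz term, optional ΔV0, the
  Grahame ψ0 for charged compositions, and Gaussian noise.
* Noise is Gaussian and homoscedastic: 0.3 mN/m on pressure and 5 mV on
  potentials by default, matching the scatter of the study's
  measurements.  All randomness flows through explicit seeds
  (`numpy.random.default_rng`); no global state.

What the generator does **not** emulate: compression–expansion
hysteresis, 2D phase-transition kinks, slow equilibration drift,
heteroscedastic noise near collapse, or ionization shifts with charge
density.  Passing recovery tests therefore demonstrates the estimators'
correctness and noise behaviour under the stated model, not robustness
to every artefact of real traces.

Recovery performance under the default conditions (40-point traces,
noise 0.3 mN/m): median |Â_sat − A_sat|/A_sat ≈ 1.9 % over 200 seeds,
95th percentile ≈ 4.4 %; dipole-moment estimates from noisy potential
readings are unbiased (mean of 500 replicates well within one standard
deviation of truth).  These problem sizes (200 seeds, 500 replicates)
are the package's standard quick-validation settings.

## Numerical choices

* Grahame solver: Brent's method, xtol 1e−12 mV, with a second pass at
  tighter tolerance if the residual exceeds 1e−10 C/m²; σ = 0 returns
  ψ0 = 0 exactly; the bracket is widened once to ±1000 mV and failure
  beyond that raises (physiological double layers are far inside).
* `area_at_pressure` inverts the fitted polynomial by computing all
  real roots, keeping those inside the fitted range on a branch with
  dπ/dA < 0, and returning the largest such area (high-order fits can
  wiggle; the largest decreasing-branch root is the physical
  compression solution).
* Composition fractions must sum to 1 within 1e−9 at construction;
  ratio notation ("7:3") is normalized at the I/O boundary only.
* Electroneutrality of the subphase is validated to 1e−9 M, with an
  explicit `Subphase.balanced` constructor that adds a monovalent
  counter-ion.

## Limitations

No Stern layer or ion-specific binding; no pKa/speciation engine; no
temperature-dependent permittivity; no monolayer hysteresis or kink
analysis; the additivity analysis makes no claim about mixing
thermodynamics beyond the sign and size of the deviation from linear
combination.
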