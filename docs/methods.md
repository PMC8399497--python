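# Methods

## The system and the model

The sensor pairs fluorescent carbon dots (CDs, the energy donor) with
riboflavin (RF, the energy acceptor and analyte). When RF binds to the
nanoparticle surface, Förster resonance energy transfer (FRET) quenches the
donor emission band (around 441–456 nm) and sensitizes the acceptor emission
(around 521 nm). The ratio I₅₂₁/I₄₄₁ is the sensor readout: it grows linearly
with RF concentration and self-corrects for source and concentration
fluctuations.

The photophysics is the standard point-dipole FRET model, extended to a
nanoparticle donor carrying `n` proximal acceptors:

- Overlap integral, with the donor emission area-normalized so J does not
  depend on arbitrary intensity units:
  `J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ / ∫ F_D(λ) dλ` (M⁻¹ cm⁻¹ nm⁴; ×1e-28 for
  M⁻¹ cm³).
- Förster distance: `R0⁶ [cm⁶] = 8.79e-25 κ² η⁻⁴ φ J [M⁻¹ cm³]`, with
  κ² = 2/3 (isotropic orientational averaging), η = 1.336 (aqueous buffer)
  and φ the donor quantum yield. The implementation cross-checks this
  against the equivalent Å-scale form `R0[Å] = 0.211 (κ² η⁻⁴ φ J[nm⁴-units])^{1/6}`;
  the two printed constants agree to about 0.4%, and a discrepancy beyond 1%
  is logged as a unit error.
- Efficiency: `E = n R0⁶ / (n R0⁶ + r⁶)` from geometry, or
  `E = 1 − F_DA / F_D` from integrated donor fluorescence with and without
  acceptor.

### Note on the area normalization

The overlap-integral expression is often printed without the donor
normalization. Unnormalized, J would scale with the arbitrary units of the
recorded intensity and the 8.79e-25 constant would not be dimensionally
closed, so this package uses the area-normalized form throughout; the
dual-unit cross-check above validates the convention.

### Consistency flag instead of reconciliation

The `FretParams` bundle carries an `is_consistent()` check of whether
(E, R0, r, n) jointly satisfy the multi-acceptor relation. Published
parameter triples for systems like this one are not always mutually
consistent (e.g. E = 91% with R0 = 3.3 nm implies r ≈ 2.24 nm at n = 1, not
1.8 nm); the package reports the flag rather than silently adjusting any of
the four quantities.

## Titration analysis: why an extrapolation is needed

Binding follows a 1:1 Langmuir isotherm on the donor surface sites,
θ = K·c/(1 + K·c), the simplest isotherm consistent with a single
association constant. At finite acceptor concentration only the bound
fraction θ of donors is quenched, so the measured per-point quench is
θ(c)·E, not E. Writing F = F0·(1 − θE) gives exactly the Lehrer
("modified Stern–Volmer") linearization

    F0 / (F0 − F) = 1/f_a + 1/(f_a · K · [Q]),

whose intercept is 1/E (the accessible fraction f_a equals the asymptotic
efficiency at full occupancy) and whose intercept/slope ratio is K. The
titration analysis therefore: (1) unmixes each composite spectrum into
donor and acceptor components by non-negative least squares against the
measured single-species references, (2) integrates the donor component over
the 390–500 nm donor band (bounds configurable; the donor peak sits at
441–456 nm), and (3) fits the Lehrer line to obtain E and K in one step.
On noise-free synthetic data this chain recovers the planted efficiency and
binding constant to machine precision.

Reference-based NNLS was chosen over free-form peak fitting for the
"deconvolution" step because donor-only and acceptor-only references exist
in every experiment of this kind and NNLS is deterministic; near-collinear
references (cosine similarity > 0.999) are rejected as unidentifiable.

## Quantification layer

- Ratiometric signal: 11 nm window means centred on 521 and 441 nm, not
  single pixels, for robustness to grid alignment (windows configurable).
- Calibration: ordinary least squares of ratio on concentration;
  `DL = 3·sd(blanks)/slope` with the sample (n−1) standard deviation of
  n = 10 blank replicates, the standard analytical convention. The linear
  range is reported descriptively as the fitted span (no breakpoint
  detection).
- Standard addition: least-squares line of ratio on added concentration;
  the sample concentration is |x-intercept| = intercept/slope. Per-level
  recovery uses the spiked increment, 100·(found − base)/added with
  found = ratio/slope; the RSD is taken over the per-level base estimates
  (found_total − addition) within one series, a replicate-precision proxy
  chosen because per-sample replicate tables are not available.
- Interference score: percent change of the probe ratio upon adding a
  coexisting species.

## Photophysics and biology utilities

- Relative quantum yield by the gradient method,
  φ_x = φ_st·(Grad_x/Grad_st)·(η_x²/η_st²), against quinine sulfate
  (φ_st = 0.54). Gradients are slopes of integrated fluorescence against
  absorbance, with a warning above A = 0.1 (inner-filter risk). The quinine
  reference is variously quoted at 0.1 M or 0.5 M H₂SO₄; the concentration
  is metadata and does not enter the computation.
- Photostability: retention = 100·last/first plus an OLS drift slope in
  %/hour (descriptive only).
- Viability: 100·A_treated/A_control from crystal-violet absorbance, well
  means taken before the ratio (plate wells are unpaired). Reactivity bands
  default to ≥90 none, [70, 90) mild, [30, 70) moderate, <30 severe —
  lower-inclusive, total, and overridable, consistent with the qualitative
  five-point scale (70–90% mild, ~55–65% moderate, ~17% severe).

## The synthetic-data generator

No instrument data are deposited for this system, so every analysis runs on
synthetic data with planted ground truth. The generator emulates:

- Gaussian donor emission bands at 420/440/456 nm (σ = 25 nm) for
  320/340/360 nm excitation, amplitude linear in donor concentration;
  Gaussian RF absorption at 445 nm (σ = 20 nm, peak ε = 1.25e4 M⁻¹cm⁻¹)
  and RF emission at 521 nm (σ = 30 nm). Grid: 350–650 nm at 1 nm (the
  instrument step is not documented; 1 nm is a typical spectrofluorimeter
  export).
- Titrations per the cuvette protocol: 10 successive 20 µL additions of a
  1000 µM acceptor stock into 3 mL, dilution included (endpoint ≈ 62.5 µM).
  Composite spectra follow the Langmuir/FRET forward model above, with the
  sensitized acceptor amplitude tied to the donor peak (transfer gain
  default 1, configurable) and direct acceptor excitation default 0 (its
  direct emission is negligible under donor excitation; a nonzero option
  exists for robustness checks). Noise is multiplicative Gaussian clipped
  at zero — fluorescence shot/source noise scales with signal — at 1% of
  signal by default.
- Calibration sets with planted slope 0.12 ratio/µM and blank σ = 0.001
  over 0–11 µM, so the planted detection limit 3σ/S is exactly 0.025 µM.
- Spiked series with base 2 µM and additions 1–7 µM (totals stay inside
  the 0–11 µM linear range) at 0.3% multiplicative ratio noise, which keeps
  the within-series RSD far below the 4% quality bound.
- Viability plates with lognormal well-to-well variation (cv 8%, 6 wells),
  parameterized so the well mean equals the target fraction.

All randomness flows from one integer seed through a local
`numpy.random.Generator`; identical (config, seed) gives bit-identical
output, and presets are frozen dataclasses.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: inner-filter effects, instrument response
functions, photobleaching during acquisition, non-Gaussian band shapes,
matrix effects of real beverages, and any photon-level statistics. The
recovery results show that the estimators are correct and stable under the
stated noise model, not that the physical system behaves this way.

## Problem sizes and numerical choices

Monte-Carlo summaries use 100 seeds (efficiency under noise), 200 seeds
(binding constant, detection limit) and 500 seeds (standard addition) —
enough for stable medians and tail fractions while keeping the whole
analysis suite at a few seconds on one core. Integration is trapezoidal
everywhere (dense grids; robust to irregular spacing); resampling is
linear interpolation with extrapolation forbidden; duplicate wavelengths
on input collapse to their mean; efficiency values slightly above the
physical range (F_DA up to 2% above F_D) are treated as noise and clipped
with a warning, beyond that as unit errors.

## Known limitations

- The Lehrer extrapolation assumes the 1:1 Langmuir isotherm; cooperative
  or multi-site binding would bias both E and K.
- NNLS unmixing assumes the references span the composite; an unmodeled
  background component inflates the donor coefficient.
- The detection-limit estimator inherits the small-sample bias of the
  blank standard deviation (median ≈ 5% low at n = 10); this is the
  standard 3σ/S convention, not corrected.
- No weighted regression: calibration and standard-addition fits assume
  homoscedastic noise over the working range.
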