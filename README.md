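# cdfret

Analysis toolkit for a carbon-dot / riboflavin FRET sensing platform:
spectral overlap and Förster-distance calculation, transfer-efficiency
estimation under a multi-acceptor model, binding-constant fitting by the
modified Stern–Volmer analysis, ratiometric calibration with a 3σ detection
limit, standard-addition quantification, relative quantum yield and
cell-viability scoring.

It is written for analytical chemists and photophysicists working with
nanoparticle-donor FRET sensors who need the whole chain — from raw
two-column spectra to a quantified analyte concentration — as tested,
scriptable building blocks. Because no instrument data are publicly
available for this system, the package ships a synthetic-data generator
that emulates the study conditions with planted ground truth, so every
estimator is validated as a recovery problem.

## The model

Donor (carbon dots, emission 420–456 nm depending on excitation) and
acceptor (riboflavin, absorption peak 445 nm, emission 521 nm) couple by
Förster transfer. With `n` acceptors per nanoparticle donor at distance `r`:

    E = n R0^6 / (n R0^6 + r^6)
    R0^6 [cm^6] = 8.79e-25 · κ² · η⁻⁴ · φ · J [M⁻¹ cm³]
    J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ / ∫ F_D(λ) dλ

Experimentally `E = 1 − F_DA/F_D` from integrated donor fluorescence.
Because binding follows θ = K·c/(1 + K·c), the per-point quench is θ(c)·E;
the Lehrer linearization `F0/(F0−F) = 1/f_a + 1/(f_a·K·[Q])` recovers both
the association constant `K` and the asymptotic efficiency (`f_a`) in one
linear fit. The sensor readout is the ratio I₅₂₁/I₄₄₁, calibrated linearly
against concentration with `DL = 3·sd(blanks)/slope`, and real samples are
quantified by standard addition. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
import numpy as np
from cdfret import fret, synthetic as syn

# donor emission at the three candidate excitations + acceptor absorption
cfg = syn.get_preset("low_donor")
acceptor = syn.make_acceptor_absorptivity(cfg)
candidates = {x: syn.make_donor_emission(cfg, x) for x in (320., 340., 360.)}
best = fret.select_excitation(candidates, acceptor)

j = fret.overlap_integral(candidates[best], acceptor)
r0 = fret.forster_distance(j.j_cm3, phi=0.54)
print(best, j.j_nm4, r0)

# quench titration -> unmix -> integrate -> Lehrer extrapolation
series = syn.simulate_titration(syn.get_preset("low_donor", noise_sigma=0.0))
analysis = fret.analyze_titration(series)
print(analysis.efficiency, analysis.binding.K)
```

prints

```
360.0 302137973318867.56 3.797914141292787
0.910000000000001 26999.99999999992
```

i.e. 360 nm excitation maximizes the overlap (J ≈ 3.0×10¹⁴ M⁻¹cm⁻¹nm⁴,
R0 ≈ 3.8 nm at φ = 0.54), and on noise-free synthetic data the full
analysis chain returns the planted transfer efficiency (91%) and binding
constant (2.7×10⁴ M⁻¹) to machine precision.

## Analysis scripts

The numbered drivers under `analysis/` run the complete study and write
their tables to `results/`:

| script | what it does |
| --- | --- |
| `01_spectral_overlap.py` | overlap integrals per excitation, excitation selection |
| `02_fret_efficiency.py` | efficiency recovery at two donor concentrations, FRET parameters, distance-regime check |
| `03_binding_constant.py` | modified Stern–Volmer binding fit, noise robustness |
| `04_calibration_dl.py` | ratiometric calibration and 3σ detection limit |
| `05_standard_addition.py` | spiked-sample quantification, recoveries, RSD |
| `06_qy_viability.py` | relative quantum yield; viability plates and reactivity classes |

A `cdfret` command-line tool wraps the same library for one-off use
(`cdfret simulate`, `overlap`, `r0`, `efficiency`, `titration-analyze`,
`binding-fit`, `calibrate`, `quantify`, `std-add`, `qy`, `viability`); every
seeded command is bit-reproducible and writes a run manifest next to its
report.

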