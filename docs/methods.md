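# Methods

## Assay model

The chromogenic anti-Xa AT assay is modeled in three layers.

**Inhibition and color kinetics.** Factor Xa (initial amount `fxa0_uM`)
is neutralized by AT in a 1:1 complex. The default *instantaneous* mode
fixes the residual enzyme at t = 0,

    E_res = max(0, fxa0 − inhibition_capacity · activity_fraction),

where `inhibition_capacity_uM` is the enzyme neutralized per unit
activity; an optional *second-order* mode co-integrates
dE/dt = −k_inhib·E·I for kinetics exploration (not used by default —
with Xa in excess and a fast association, the stoichiometric limit is
the standard assumption). Residual enzyme releases pNA from a single
substrate pool at the Michaelis–Menten rate
d[pNA]/dt = kcat·E_res·[S]/(Km+[S]), integrated with LSODA at
rtol 1e−10; the product series is clamped monotone and ≤ [S]₀.

**Optics.** A(t) = ε₄₀₅·[pNA](t)·l_total + static + drift·t/60, with
l_total = 2 × chamber gap (double pass off the reflective electrode).
The decadic convention is used throughout (absorbance standard).
`static` models icteric/hemolyzed baselines, which cancel exactly out of
ΔA; `drift` models lipemic scattering, which does not — this is the
designed failure mode for chylous samples.

**Photon counting.** Expected transmitted counts per 1000 ms bin are
`source_mean(T) · 10^(−A(t))`, where source_mean(T) applies the linear
temperature model around a 25 °C reference. Lamp flicker multiplies the
expectation by Gaussian(1, cv); shot noise replaces it by a Poisson
draw; Gaussian dark counts are added. The dark distribution is Gaussian,
not Poisson: the characterized SD (559 counts at mean 384 461) is far
sub-Poissonian, so a Poisson dark model would contradict the instrument.
With shot noise off, counts are kept as floats so the noiseless path is
exact to solver precision.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| wavelength / bandwidth | 405 / 10 | nm | pNA absorption line of the bandpass-filtered LED |
| chamber gap (`path_length_mm`) | 0.3 | mm | not a measured quantity; typical DMF plate spacing, configurable. Only ΔA-level results are gap-independent |
| ε₄₀₅ (pNA) | 9.9×10³ | M⁻¹cm⁻¹ | standard literature value for p-nitroaniline |
| substrate₀ / Km / kcat | 2000 µM / 100 µM / 100 s⁻¹ | | generic chromogenic-substrate scale; [S]₀ ≫ Km keeps the 60 s window near zero-order |
| `fxa0`, `inhibition_capacity` | derived | µM | solved from the measured plasma calibration line so the simulator's ΔA/min spans ≈0.038 (0% activity) to ≈0.012 (100%), with 0–120% inside the linear range (E_res > 0 up to ≈146%) |
| source mean / CV | 24 429 585.36 / 0.103% | counts/bin, % | empty-chip characterization; the CV is dominated by lamp flicker (shot noise alone would be 0.02%) |
| dark mean / SD | 384 460.71 / 559.22 | counts/bin | dark-current characterization over 30 bins |
| temperature slope / intercept | 7704.504 / 2.358×10⁷ | counts/°C, counts | linear source–temperature law, validated 18–38 °C; a <1% effect, so correction is exposed but **off** by default |
| saturation voltage | 2.45 (strict >) | V | PMT clips above this; 2.45 V itself is usable, operating point 2.44 V |
| rate window | 0–60 | s | assay convention; endpoints taken from nearest bins, ties to the earlier bin, no interpolation (≤0.5 s timing error) |
| R² bound / CV bound / source-CV bound | 0.985 / 10% / 0.5% | | linearity, repeatability (pharmacopoeial) and source-stability acceptance |

## Study conditions emulated by the generator

Calibration experiments are emulated as 8 replicates at activity
fractions {0.25, 0.5, 0.75, 1.0}, rates drawn from the plasma line
(0.0382 − 0.02616·a) or whole-blood line (0.01363 − 0.00916·a) with
Gaussian noise SD 5×10⁻⁴ AU/min. Instrument characterizations are
emulated at their acquisition cadence: 30 one-second bins for dark
current, and 30 bins per held temperature at {18, 23, 28, 33, 38} °C
with 5000-count read noise for the temperature law (the counter streams
1000 ms bins while a condition is held, so a block of bins per condition
is the natural sampling).

**Whole blood.** Hemoglobin-rich red cells add a static 405 nm baseline
(default 1.5 AU undiluted, scaled 1/dilution) and a matrix effect on the
apparent rate, modeled as a multiplier (1 + 2/dilution) normalized to 1
at the standard dilution of 10 — so ΔA/min decreases and flattens
(convexly) over dilutions {1, 2, 5, 10, 20}, and the whole-blood
calibration line holds exactly at the 1:9 on-chip dilution. The true
hemoglobin→absorbance mapping in this geometry is unknown; both numbers
are free parameters chosen to reproduce the qualitative trend. Activity
is always read against a calibration built under the same preparation,
so no dilution back-correction is applied.

**What the generator does not capture:** pipetting/droplet-volume
variability, reagent lot effects, PMT dead time, spectral width of the
bandpass, evaporation, and real biological matrix heterogeneity — so
passing recovery tests demonstrates correctness of the *analysis chain*,
not clinical performance of a physical device.

## Numerical and design choices

- ΔA uses log base 10 throughout; the count-ratio form makes it
  independent of reflectance, detector area and photon energy (verified
  to 1e−12 by cancellation tests).
- Dark subtraction uses the scalar dark mean per bin (dark CV ≈ 0.15%,
  a time-resolved model adds nothing); it must precede the log-ratio.
  Negative corrected counts are kept with a warning rather than clamped
  (clamping biases ΔA upward at low signal); rate computation rejects
  nonpositive endpoint counts outright.
- Calibration is fit by OLS of rate on activity with activity as a
  *fraction* (with percent units the plasma line would go negative above
  146% and the printed line would be unusable); inverse prediction is
  algebraic inversion (classical calibration). Pearson r and R² come
  from the same fit and satisfy r² = R² exactly.
- Relative difference uses the reference instrument as denominator,
  displayed half-up to one decimal; full precision is always retained in
  JSON.
- The two-sample KS p-value is asymptotic; exact small-sample p is out
  of scope at the n ≈ 20–30 sizes this assay compares.
- Sample SD uses the n−1 denominator everywhere.
- Seeds: every stochastic entry point takes an explicit seed or
  Generator; the CLI default seed is 20250630.

## Problem sizes

Test-suite simulations are desk-scale by design: ≤ 400-bin traces,
200-replicate recovery ensembles, 90 s reactions at 1 s steps. The
acceptance script runs 32-point calibration fits, a 150-point
temperature fit and a 30-bin dark characterization — a few seconds in
total.

## Known limitations

- The chamber gap is configurable but unknown; absolute absorbances and
  α values are therefore arbitrary up to that scale — only ΔA-level
  quantities are meaningful, which is also all the assay uses.
- Saturation is a voltage-threshold flag; PMT nonlinearity near
  saturation is not modeled.
- The interferent model is additive in absorbance; true lipemic
  scattering is wavelength- and geometry-dependent.
- The second-order inhibition mode is provided for exploration and has
  no measured rate constant behind it.
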