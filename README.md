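# atassay

Photon-count photometry and activity quantification for chromogenic
anti-Xa **antithrombin (AT)** assays on digital-microfluidic (DMF)
point-of-care chips — together with a **virtual instrument** that
forward-simulates the whole device so every analysis stage can be
developed and tested without hardware.

## The problem and who this is for

AT is the main plasma inhibitor of coagulation proteases; its activity
(reported as % of a normal calibrator, reference range 80–120%) guides
heparin therapy and thrombosis risk assessment. The chromogenic anti-Xa
assay adds factor Xa in excess: AT neutralizes Xa in a 1:1 complex, and
the *residual* enzyme cleaves a chromogenic substrate, releasing yellow
p-nitroaniline (pNA, absorbing at 405 nm). The color-formation rate is
therefore **inversely** related to AT activity.

On a DMF chip the droplet sits over a reflective electrode, so detection
uses a double-pass reflection–transmission geometry read by a
photon-counting PMT in 1000 ms bins. This package is for engineers and
laboratorians building or validating such a device: it implements the
signal chain from raw photon counts to reported activity, the QC rules
around it, and the clinical method-validation statistics.

## The model

Double-pass Beer–Lambert optics with electrode reflectance *r* and total
path *l* (twice the chamber gap):

```
I_out = I_in · e^(−αl) · r                # reflection–transmission
A(t)  = −log10( I(t) / I0 )               # decadic absorbance
ΔA    = log10( N(t0) / N(t1) )            # photon-count form; r, h, f, A cancel
```

The assay observable is ΔA/min over the window t0 = 0 s, t1 = 60 s, after
subtracting the PMT dark current (≈384 461 ± 559 counts/bin) and
rejecting traces acquired above the 2.45 V saturation voltage. Activity
is quantified by classical calibration: fit
`rate = intercept + slope·activity` (slope < 0) on calibrator levels
{25, 50, 75, 100}%, accept if R² ≥ 0.985, and invert algebraically.
Repeatability is accepted at CV ≤ 10%; agreement with a reference
instrument is summarized by per-sample relative differences and a
two-sample Kolmogorov–Smirnov test.

The virtual instrument chains Michaelis–Menten kinetics of the residual
enzyme (instantaneous stoichiometric inhibition by default), the optics
above, and the photon-counting noise model (Poisson shot noise, Gaussian
lamp flicker, Gaussian dark counts, linear temperature dependence of the
source). See `docs/methods.md` for parameters and assumptions.

## Worked example

Simulate an 80%-activity plasma sample, process it, and quantify it
against a calibration line:

```bash
$ atassay simulate --activity 80 --seed 11 --out run.csv
$ atassay process run.csv --out rec.json
INFO atassay: subtracting dark mean 384460.71 counts/bin
$ cat pairs.csv             # calibrator levels on the measured plasma line
activity_fraction,rate_per_min
0.25,0.03166
0.50,0.02512
0.75,0.01858
1.00,0.01204
$ atassay calibrate pairs.csv --out cal.json
INFO atassay: calibration plasma: rate = 0.03820 -0.02616*activity, R^2=1.0000 (bound 0.985) -> pass
$ atassay quantify --calibration cal.json --records rec.json
INFO atassay: sample '': dA/min 0.01758 -> activity 78.8%
```

The simulated sample's true ΔA/min was 0.01727 (written to
`run.csv.truth.json`); with full instrument noise the pipeline measured
0.01758, which inverts to **78.8%** against the calibration — within the
assay's repeatability of the 80% ground truth. The same stages are
available as library functions (`simulate_run`, `subtract_dark`,
`compute_rate`, `fit_calibration`, `invert_calibration`, ...), and
`atassay qc` / `atassay compare` cover saturation & source-stability
checks and reference-method comparison.

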