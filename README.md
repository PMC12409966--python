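# ledspec

A software digital twin of a six-channel LED absorbance spectrophotometer,
together with the analysis used to characterise such an instrument:
Beer–Lambert calibration, a two-component stray-light model for the
deviation a broadband LED source produces, and initial-rate enzyme kinetics
across the six cuvette positions.

It is aimed at people who build, teach with, or write client software for
LED-based photometers: the virtual instrument reproduces the observable
behaviour of the real device — frequency-output light sensor, per-channel
blank zeroing, three-button front panel, two-line display, and the
newline-framed serial command protocol — so acquisition and analysis code
can be developed and tested without hardware.

## The models

**Absorbance from frequencies.** The light-to-frequency sensor outputs a
square wave with frequency *f* proportional to transmitted intensity
(linear up to 500 kHz). After recording a reference frequency *f*ᵣ on a
blank, the firmware reports the decadic absorbance

&nbsp;&nbsp;&nbsp;&nbsp;*A* = log₁₀(*f*ᵣ / *f*)

**Band-integrated forward model.** For an LED with emission spectrum
*S*(λ) and an analyte with extinction spectrum ε(λ), the apparent
absorbance of a sample at concentration *C* and path length *l* is

&nbsp;&nbsp;&nbsp;&nbsp;*A*app(*C*) = log₁₀ [ ∫*S*(λ) dλ / ∫*S*(λ)·10^(−*C l* ε(λ)) dλ ]

This is exactly Beer–Lambert (*A* = *C l* ε) when ε is flat over the band,
and curves downward otherwise.

**Two-component reduction.** Splitting the source light into an absorbable
fraction (1 − *f*ₙₐ) and an unabsorbable fraction *f*ₙₐ gives the
two-parameter model

&nbsp;&nbsp;&nbsp;&nbsp;*A*app = −log₁₀[ (1 − *f*ₙₐ)·10^(−*C l* ε) + *f*ₙₐ ]

which plateaus at −log₁₀ *f*ₙₐ. `TwoComponentRegression` fits (ε, *f*ₙₐ)
by nonlinear least squares; `BeerLambertRegression` fits the
origin-constrained line. Both are scikit-learn-compatible estimators.

**Kinetics.** Six absorbance time courses (one enzyme concentration per
cuvette) are baselined to their first time point, fitted with a straight
line, converted to concentration rates via *v* = slope/(ε·*l*)
(default ε = 8.88×10³ M⁻¹cm⁻¹, the mean of the six per-channel
calibrations), and regressed against enzyme concentration.

## Worked example

Generate a synthetic p-nitroaniline dilution series (12 log-spaced
concentrations over 0.0065–0.19 mM) for a virtual channel with ε = 9.43×10³
M⁻¹cm⁻¹ and 0.97 % unabsorbable light, then fit both models:

```sh
$ ledspec generate --scenario dilution --seed 7 --epsilon 9430 --f-na 0.0097 --out demo
$ ledspec fit demo/dilution_series.csv
{
  "beer_lambert":  { "estimates": { "epsilon": 8734.4, ... }, "r_squared": 0.9964, ... },
  "two_component": { "estimates": { "epsilon": 9427.1, "f_na": 0.00965 },
                     "standard_errors": { "epsilon": 5.5, "f_na": 6.5e-05 },
                     "r_squared": 0.9999983, ... }
}
```

(output abridged; both fits report estimates, standard errors and R²).
The Beer–Lambert fit *underestimates* the generating ε (8734 vs 9430):
the unabsorbable light bends the curve downward and the straight line
splits the difference. The two-component fit recovers both generating
parameters within their standard errors — the same contrast seen between a
monochromator instrument and an LED instrument on real dilution series.

The virtual instrument speaks the serial protocol directly:

```sh
$ ledspec simulate --scenario rainbow --script "check,cuvset 2,readabs,readi"
> check
imhere
> cuvset 2
ready
> readabs
-0.001
ready
> readi
200436
ready
```

The `-0.001` is read noise on a freshly zeroed blank (sd 10⁻³ absorbance);
`readi` shows the raw sensor frequency in Hz.

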