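# Methods

## Scope and architecture

`ledspec` models a six-channel LED absorbance photometer at the level of its
observable behaviour, not its electronics: one LED + cuvette +
light-to-frequency sensor per position, one active position at a time, and
the firmware rules for zeroing, button handling, display formatting and the
serial command protocol. On top of the instrument sit the analysis layers a
user of such an instrument needs: dilution-series model fits and
initial-rate kinetics.

## Optical model

The forward model treats an LED as a Gaussian emission band S(λ) sampled on
a wavelength grid (default 350–750 nm at 1 nm; the grid is a modelling
choice, finer than any LED bandwidth handled here). Transmission through a
sample is band-integrated decadic attenuation,

    I(C) = ∫ S(λ) · 10^(−C·l·ε(λ)) dλ,

evaluated with the trapezoid rule on the stored grid; at 1 nm spacing this
agrees with a 0.01 nm brute-force quadrature to better than 4 significant
digits (tested). Apparent absorbance is log10(I(0)/I(C)). All logarithms
are decadic throughout — the convention under which ε = 1×10⁴ M⁻¹cm⁻¹
gives A = 1 at 0.1 mM and 1 cm. Intensities are relative; only ratios enter
any absorbance, so no absolute radiometric calibration exists anywhere in
the package.

Two structural facts about this model drive the analysis design:

* **Bracketing** — A_app always lies between C·l·min ε and C·l·max ε over
  the band (a mixture of exponentials cannot escape its extremes).
* **Concavity** — A_app(C) is concave, so a straight Beer–Lambert fit to
  broadband data is biased low, and increasingly so at high absorbance.

The two-component reduction, A_app = −log10((1−f_na)·10^(−C·l·ε) + f_na),
compresses all band-structure effects into a single "unabsorbable fraction"
f_na ∈ [0, 1). We make no attempt to attribute f_na to true stray light
versus finite source bandwidth; the forward model generates the effect via
ε(λ) variation and the reduction absorbs it as one number.

The p-nitroaniline extinction *spectrum* used by the wavelength-resolved
generator is a synthetic stand-in: a single Gaussian band (default peak
380 nm, FWHM 60 nm) scaled so ε(405 nm) = 1×10⁴ M⁻¹cm⁻¹ exactly — only
that single-wavelength value is an established constant; the band shape
exists to exercise the model, not to reproduce the compound's true
spectrum.

## Instrument emulation

* **Electrical model.** LED current is (V_supply − V_forward)/R_drop with
  V_supply = 5 V and a default forward drop of 1.7 V (typical for 5 mm
  visible LEDs; per-channel override available). 330 Ω therefore gives
  10 mA; the bright violet LED uses 660 Ω (5 mA) so its blank reading stays
  inside the sensor's linear range.
* **Sensor.** Frequency = responsivity × band-integrated intensity, counted
  over a 1 s gate and hence rounded to integer Hz. The 500 kHz linearity
  ceiling is reported as a *flag*, never a clamp: over-range readings stay
  visible so the user knows to fit a larger dropping resistor. Responsivity
  is configured directly per channel (the defaults put a blank at
  ~200 kHz); datasheet luminous intensities never enter the quantitative
  path because absorbance is a frequency ratio.
* **Noise.** Multiplicative Gaussian on frequency with relative sd
  ln(10)×noise_sd_abs, chosen so repeated absorbance reads have
  sd ≈ noise_sd_abs (default 10⁻³, i.e. fluctuation in the third decimal
  place, the stability of the assembled hardware). The 1 Hz quantisation
  adds negligibly at 200 kHz. No thermal warm-up drift is modelled. All
  draws come from one per-instrument `numpy` generator seeded at
  construction, so identical seeds give bit-identical sessions.
* **Zeroing.** A zero stores the current (single-gate) frequency as f_r;
  power-on zeroes all six positions. Whether the real firmware averages
  several gates during zeroing is unknown; single-reading zeroing is the
  implemented choice and only affects the (already modelled) read noise.
* **Protocol choices.** `check` answers `imhere` *instead of* `ready` (the
  firmware documents it as the exception to the ready contract). Responses
  are newline-terminated, symmetric with command framing, since the real
  response terminator is undocumented. Both `beepon` and the firmware
  listing's spelling `beeepon` are accepted. Numeric payloads use the
  display formats: absorbance to 3 decimals, frequency as integer Hz.
  Cuvette numbering is 1-based everywhere.

## Fitting

* **Beer–Lambert** is linear least squares through the origin with l fixed
  (the law has no intercept and the instrument is zeroed on a blank); an
  intercept flag exists for diagnostics but defaults off.
* **Two-component** uses `scipy.optimize.curve_fit` with f_na bounded to
  [0, 1). Initialisation is deterministic: ε₀ from the origin-constrained
  slope of the three lowest concentrations (near-linear regime), f₀ =
  10^(−max A) clipped to [10⁻⁴, 0.5] (the plateau bounds f_na from above).
  The fit agrees with a brute-force 400×400 grid search to within one grid
  cell on random instances (tested).
* Standard errors are Jacobian-based covariances at the optimum; no
  bootstrap. R² is computed against the mean model for both fits, which
  makes the two models comparable but means the origin-constrained value is
  not the "uncentered" R² some packages print for through-origin
  regression. At the modelled noise level this distinction is far below the
  >0.99 values these fits produce.
* **Linearity ceiling** (`linearity_bound`): the relative deviation
  (C·l·ε − A_app)/(C·l·ε) of the two-component curve from the Beer–Lambert
  line increases monotonically in concentration, so the largest absorbance
  meeting a given tolerance is found by root bracketing (`brentq`) and
  cross-checked against a dense grid scan in the tests. For f_na ≈ 0.01 and
  a 5 % tolerance the ceiling lands near A ≈ 1 — the usual "keep A below
  about 1" working rule, made quantitative.

## Kinetics

Product accumulation is modelled as exactly linear in time (zero-order over
the 5 min window), valid while ≤ 4 % of substrate is consumed; the
generator warns, naming the channels, when a configuration breaks that
bound. Per-channel lines are ordinary least squares; slopes convert to
concentration rates via v = m/(ε·l) with default
ε = 8.88×10³ M⁻¹cm⁻¹, the mean of the six per-channel calibration values
(8.71, 8.93, 8.87, 8.71, 9.11, 8.94 ×10³). For traces whose total variance
is below 10× the read-noise variance (a no-enzyme control), R² is reported
as not-applicable rather than a misleading near-zero number. The
rate-versus-enzyme regression keeps its intercept so the
passes-through-origin expectation of the initial-rate regime can be tested
(|intercept| < 3 SE).

## Synthetic-data generator

The generator defines the study conditions and embeds the generating
parameters in each dataset's metadata, making parameter-recovery tests
unambiguous.

* **Dilution series**: 12 concentrations, log-spaced over 6.5×10⁻⁶ to
  1.9×10⁻⁴ M (log spacing covers both the linear and the curved regime;
  the real experiment's exact design is not published, so n = 12 is a
  choice), absorbances from the two-component model plus Gaussian noise of
  sd 10⁻³ A.
* **Kinetics runs**: 0–5 min sampled every 0.5 min (11 points), enzyme
  series 0–50 nM in 10 nM steps with a no-enzyme control, catalytic
  proportionality 200 min⁻¹ (top channel: 10 µM product/min), substrate
  1.5 mM (worst-case consumption 3.3 %, inside the 4 % guard). The enzyme
  levels are a realistic choice for tens-of-nanomolar protease assays, not
  published values.
* **Instruments**: "rainbow" carries the six-colour LED set
  (405/470/505/560/591/630 nm with FWHM 15/25/32/27/16/16 nm); "six-405nm"
  carries six nominally identical 405 nm LEDs with ±10 % seeded FWHM
  jitter, standing in for the LED-to-LED spectral variation that makes the
  six channels calibrate differently.

What the generator does **not** emulate: real p-nitroaniline
photochemistry, temperature effects, substrate-depletion curvature,
cuvette-to-cuvette optical variation, warm-up drift, or ambient-light
leakage. Passing recovery tests therefore demonstrate correctness of the
estimation pipeline under the stated noise model, not robustness to those
real-world effects.

## Numerical choices and degenerate inputs

Trapezoid integration on the stored grid everywhere (no adaptive
quadrature); linear interpolation when extinction and source grids differ,
with an error if they do not overlap. Gaussian spectrum fits start from
argmax/half-max-crossing estimates and refuse spectra whose maximum sits on
a grid edge. Fits refuse: all-zero concentrations, a single distinct
concentration, < 3 points for two-parameter models, < 3 time points for
rate fits, all-equal enzyme concentrations, and dark channels (frequency 0)
for zeroing or reading. Generated emission bands require the grid to span
peak ± 3×FWHM so no band is silently truncated.

## Problem sizes

The Monte-Carlo checks in the test suite use 200 replicates (spectrum
refits, dilution-series recoveries, kinetics runs) and 400×400 grids for
the fit oracle; the whole suite runs in a few seconds on one CPU.

## Known limitations

* f_na is a phenomenological catch-all; the package cannot separate stray
  light from bandwidth effects.
* The instrument model has no time base beyond "one reading per call";
  acquisition intervals exist only in the kinetics data model.
* Saturation above 500 kHz flags but does not distort readings; the real
  sensor's soft compression near the ceiling is not modelled.
* Michaelis–Menten saturation kinetics are out of scope: rates are assumed
  proportional to enzyme concentration, the regime the instrument is
  characterised in.
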