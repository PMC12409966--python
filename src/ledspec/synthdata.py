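"""Seeded generators for dilution series, kinetics runs and virtual instruments.

Every generator is a pure function of its arguments: a fixed seed gives
byte-identical output, and the generating (ground-truth) parameters are
embedded in the returned object's metadata so that parameter-recovery tests
are unambiguous.

The default designs emulate the instrument's characterisation experiments:

* dilution series — 12 log-spaced p-nitroaniline concentrations over
  0.0065-0.19 mM, absorbances from the two-component model plus Gaussian
  noise (sd 1e-3 absorbance, the instrument's read noise);
* kinetics runs — six channels read every 0.5 min for 5 min (11 points),
  product accumulating linearly at a rate proportional to the per-channel
  enzyme concentration, with a <= 4 % substrate-consumption guard;
* instruments — either the six-colour LED set ("rainbow": 405-630 nm) or six
  nominally identical 405 nm LEDs with seeded FWHM jitter ("six-405nm"),
  emulating LED-to-LED spectral variation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fitters import ConcentrationSeries
from .instrument import (
    ChannelState,
    InstrumentState,
    LedChannelConfig,
    SensorModel,
)
from .kinetics import CONSUMPTION_LIMIT, DEFAULT_EPSILON, KineticsRun
from .optics import two_component_absorbance
from .spectra import GaussianPeak, gaussian_emission

__all__ = [
    "RAINBOW_LEDS",
    "make_dilution_series",
    "make_kinetics_run",
    "make_default_instrument",
]

#: (peak_nm, fwhm_nm) of the six-colour LED set, violet through red.
RAINBOW_LEDS = ((405.0, 15.0), (470.0, 25.0), (505.0, 32.0), (560.0, 27.0), (591.0, 16.0), (630.0, 16.0))

#: Default dilution-series design: 12 log-spaced points over 0.0065-0.19 mM.
DILUTION_C_MIN = 6.5e-6
DILUTION_C_MAX = 1.9e-4
DILUTION_N = 12

#: Default six-channel enzyme series (mol/L), a no-enzyme control plus five
#: equally spaced levels in the tens-of-nanomolar range typical of trypsin
#: nitroanilide assays.
DEFAULT_ENZYME_CONCS = (0.0, 1.0e-8, 2.0e-8, 3.0e-8, 4.0e-8, 5.0e-8)

#: Default catalytic proportionality (min^-1): rate = k * [E].  200/min puts
#: the top channel at 10 uM product/min.
DEFAULT_RATE_PER_ENZYME = 200.0

#: Default substrate concentration (mol/L): 1.5 mM keeps the worst-case
#: default channel at ~3.3 % consumption over 5 min, inside the 4 % guard.
DEFAULT_SUBSTRATE_M = 1.5e-3


def make_dilution_series(
    epsilon: float = 1.0e4,
    f_na: float = 0.0,
    n: int = DILUTION_N,
    c_min: float = DILUTION_C_MIN,
    c_max: float = DILUTION_C_MAX,
    noise_sd: float = 1.0e-3,
    seed: int = 0,
    path_length: float = 1.0,
) -> ConcentrationSeries:
    """Synthetic dilution series from the two-component absorbance model.

    Concentrations are log-spaced over [c_min, c_max]; absorbances are the
    exact model values plus additive Gaussian noise of standard deviation
    ``noise_sd`` (absorbance units).  The generating parameters are recorded
    in ``metadata``.
    """
    if n < 3:
        raise ValueError("need n >= 3 points")
    if not 0 < c_min < c_max:
        raise ValueError("require 0 < c_min < c_max")
    rng = np.random.default_rng(seed)
    conc = np.logspace(np.log10(c_min), np.log10(c_max), n)
    a = two_component_absorbance(conc * path_length * epsilon, f_na)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=n)
    return ConcentrationSeries(
        conc,
        a,
        path_length=path_length,
        metadata={
            "true_epsilon": epsilon,
            "true_f_na": f_na,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def make_kinetics_run(
    enzyme_concs=DEFAULT_ENZYME_CONCS,
    rate_per_enzyme: float = DEFAULT_RATE_PER_ENZYME,
    duration: float = 5.0,
    dt: float = 0.5,
    epsilon: float = DEFAULT_EPSILON,
    noise_sd: float = 1.0e-3,
    seed: int = 0,
    substrate_M: float = DEFAULT_SUBSTRATE_M,
    path_length: float = 1.0,
) -> KineticsRun:
    """Synthetic six-channel kinetics run.

    Absorbance in channel i grows linearly, ``A_i(t) = eps * l * v_i * t``
    with ``v_i = rate_per_enzyme * [E]_i``, plus Gaussian read noise.  The
    default design (0-5 min sampled every 0.5 min) gives 11 time points.  If
    any channel would consume more than 4 % of the substrate over the run, a
    warning lists the offending channels (the linear model is then suspect),
    but the run is still generated.
    """
    e = np.asarray(enzyme_concs, dtype=float)
    if e.shape != (6,):
        raise ValueError("need exactly six enzyme concentrations")
    times = np.arange(0.0, duration + dt / 2, dt)
    if times.size < 3:
        raise ValueError("duration/dt must yield at least 3 time points")
    rates = rate_per_enzyme * e  # mol/(L min) per channel
    consumed = rates * duration / substrate_M
    if np.any(consumed > CONSUMPTION_LIMIT):
        bad = [int(i) + 1 for i in np.flatnonzero(consumed > CONSUMPTION_LIMIT)]
        warnings.warn(
            f"channels {bad} consume more than {CONSUMPTION_LIMIT:.0%} of the "
            "substrate over the run; the linear initial-rate model may not hold"
        )
    rng = np.random.default_rng(seed)
    clean = epsilon * path_length * np.outer(times, rates)
    noisy = clean + (rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0)
    return KineticsRun(
        times=times,
        absorbances=noisy,
        enzyme_concentrations=e,
        epsilon_used=epsilon,
        path_length=path_length,
        noise_sd_abs=noise_sd,
        metadata={
            "true_rates": rates,
            "rate_per_enzyme": rate_per_enzyme,
            "substrate_M": substrate_M,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def _channel(position: int, peak: GaussianPeak, resistor: float, noise_sd_abs: float) -> ChannelState:
    # responsivity chosen so a blank reads ~200 kHz: comfortably inside the
    # sensor's 500 kHz linear range with headroom for bright channels
    blank_intensity = gaussian_emission(peak).integral()
    sensor = SensorModel(responsivity=200_000.0 / blank_intensity, noise_sd_abs=noise_sd_abs)
    config = LedChannelConfig(emission=peak, dropping_resistor=resistor)
    return ChannelState(position=position, config=config, sensor=sensor)


def make_default_instrument(
    scenario: str = "rainbow",
    seed: int = 0,
    noise_sd_abs: float = 1.0e-3,
    power_on: bool = True,
) -> InstrumentState:
    """A fully configured virtual instrument for a named scenario.

    ``"rainbow"``
        The six-colour LED set (405/470/505/560/591/630 nm with their
        measured FWHMs); the bright 405 nm LED gets the 660 ohm dropping
        resistor, the others 330 ohm.
    ``"six-405nm"``
        Six nominally identical 405 nm LEDs, FWHM jittered +/-10 % (seeded)
        to emulate LED-to-LED spectral variation.

    The instrument is powered on (all positions zeroed on blanks) unless
    ``power_on=False``.
    """
    rng = np.random.default_rng(seed)
    if scenario == "rainbow":
        channels = [
            _channel(
                i + 1,
                GaussianPeak(peak, fwhm),
                660.0 if peak == 405.0 else 330.0,
                noise_sd_abs,
            )
            for i, (peak, fwhm) in enumerate(RAINBOW_LEDS)
        ]
    elif scenario == "six-405nm":
        base_fwhm = 15.0
        jitter = rng.uniform(0.9, 1.1, size=6)
        channels = [
            _channel(i + 1, GaussianPeak(405.0, base_fwhm * jitter[i]), 660.0, noise_sd_abs)
            for i in range(6)
        ]
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: 'rainbow', 'six-405nm'"
        )
    inst = InstrumentState(channels, rng_seed=seed)
    if power_on:
        inst.power_on()
    return inst
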