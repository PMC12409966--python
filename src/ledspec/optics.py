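"""Physical forward model of light transmission and apparent absorbance.

A broadband source (an LED) shining through an absorbing solution is not
attenuated uniformly: the decadic transmittance ``10^(-C*l*eps(lambda))``
varies across the emission band whenever the extinction coefficient
``eps(lambda)`` does.  The band-integrated apparent absorbance

    A_app(C) = log10( I(0) / I(C) ),   I(C) = integral S(lam) 10^(-C l eps(lam)) dlam

then curves downward versus concentration, falling below the Beer-Lambert
line ``A = C*l*eps``.  A useful two-parameter reduction of this effect splits
the source light into an absorbable fraction ``1 - f_na`` obeying
Beer-Lambert and an unabsorbable fraction ``f_na`` passing straight through:

    A_app = -log10( (1 - f_na) * 10^(-C*l*eps) + f_na )

which is exact Beer-Lambert at ``f_na = 0`` and plateaus at ``-log10(f_na)``
for large ``C*l*eps``.  Both the wavelength-resolved model and the
two-component reduction live here; fitting the reduction to data is done in
:mod:`ledspec.fitters`.

All logarithms are decadic, the convention in which an extinction
coefficient of 1e4 M^-1 cm^-1 gives A = 1 at 0.1 mM over a 1 cm path.
Intensities are relative (arbitrary units); only ratios enter absorbances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .spectra import GaussianPeak, Spectrum, default_grid

__all__ = [
    "Sample",
    "TwoComponentParams",
    "LightBudget",
    "transmitted_intensity",
    "apparent_absorbance",
    "two_component_absorbance",
    "two_component_budget",
    "pnitroaniline_extinction",
]

#: Molar extinction coefficient of p-nitroaniline at 405 nm (M^-1 cm^-1).
PNA_EPSILON_405 = 1.0e4


@dataclass(frozen=True)
class Sample:
    """An absorbing solution in a cuvette.

    Parameters
    ----------
    concentration : mol/L
    path_length : cm (cuvette light path; 1 cm for standard cuvettes)
    extinction : float or Spectrum
        Molar extinction coefficient: a scalar at the working wavelength, or
        a wavelength-resolved extinction spectrum (M^-1 cm^-1).
    """

    concentration: float
    extinction: Union[float, Spectrum]
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.path_length > 0:
            raise ValueError("path_length must be positive")
        if isinstance(self.extinction, Spectrum):
            if self.extinction.kind != "extinction":
                raise ValueError("extinction Spectrum must have kind='extinction'")
        elif self.extinction < 0:
            raise ValueError("extinction must be >= 0")


@dataclass(frozen=True)
class TwoComponentParams:
    """Parameters of the two-component (unabsorbable-fraction) model."""

    epsilon: float  # apparent extinction coefficient, M^-1 cm^-1
    f_na: float  # unabsorbable fraction of source light, in [0, 1)

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 <= self.f_na < 1.0:
            raise ValueError("f_na must lie in [0, 1)")


@dataclass(frozen=True)
class LightBudget:
    """Incident and transmitted intensities under the two-component split."""

    incident: float  # I0
    transmitted: float  # I = Ia + Ina
    transmitted_absorbable: float  # Ia
    nonabsorbable: float  # Ina = I0 * f_na

    def __post_init__(self) -> None:
        if not 0 <= self.transmitted <= self.incident:
            raise ValueError("transmitted intensity must lie in [0, incident]")
        if not np.isclose(
            self.transmitted_absorbable + self.nonabsorbable, self.transmitted
        ):
            raise ValueError("Ia + Ina must equal the transmitted intensity")


def _band_extinction(source: Spectrum, sample: Sample) -> np.ndarray:
    if isinstance(sample.extinction, Spectrum):
        return sample.extinction.interpolate(source.wavelengths)
    return np.full_like(source.wavelengths, float(sample.extinction))


def transmitted_intensity(source: Spectrum, sample: Sample) -> float:
    """Band-integrated intensity transmitted through the sample.

    Evaluates ``integral S(lam) * 10^(-C*l*eps(lam)) dlam`` by the trapezoid
    rule on the source grid; a scalar extinction makes the integral factorise
    into ``(integral S) * 10^(-C*l*eps)``.  Equals ``integral S`` at C = 0.
    """
    if source.kind != "emission":
        raise ValueError("source must be an emission Spectrum")
    eps = _band_extinction(source, sample)
    trans = source.values * np.power(
        10.0, -sample.concentration * sample.path_length * eps
    )
    return float(np.trapezoid(trans, source.wavelengths))


def apparent_absorbance(source: Spectrum, sample: Sample) -> float:
    """Apparent (band-integrated) decadic absorbance of the sample.

    ``log10(I(0) / I(C))`` with I the band-integrated transmitted intensity.
    Equals ``C*l*eps`` exactly when the extinction is flat over the band.
    """
    blank = Sample(0.0, sample.extinction, sample.path_length)
    i0 = transmitted_intensity(source, blank)
    i = transmitted_intensity(source, sample)
    if i <= 0.0:
        raise ValueError("transmitted intensity underflowed to 0; absorbance out of range")
    return float(np.log10(i0 / i))


def two_component_absorbance(cle, f_na: float):
    """Apparent absorbance of the two-component model.

    Parameters
    ----------
    cle : float or array
        The dimensionless Beer-Lambert product ``C * l * eps``.
    f_na : float
        Unabsorbable fraction in [0, 1).

    Returns ``-log10((1 - f_na) * 10^(-cle) + f_na)``: the Beer-Lambert line
    for ``f_na = 0``, plateauing at ``-log10(f_na)`` otherwise.
    """
    if not 0.0 <= f_na < 1.0:
        raise ValueError("f_na must lie in [0, 1)")
    cle = np.asarray(cle, dtype=float)
    if np.any(cle < 0):
        raise ValueError("cle must be >= 0")
    a = -np.log10((1.0 - f_na) * np.power(10.0, -cle) + f_na)
    return float(a) if a.ndim == 0 else a


def two_component_budget(
    incident: float, cle: float, params: TwoComponentParams | float
) -> LightBudget:
    """Split an incident intensity into the two-component light budget."""
    f_na = params.f_na if isinstance(params, TwoComponentParams) else float(params)
    ina = incident * f_na
    ia = incident * (1.0 - f_na) * 10.0 ** (-cle)
    return LightBudget(
        incident=incident,
        transmitted=ia + ina,
        transmitted_absorbable=ia,
        nonabsorbable=ina,
    )


def pnitroaniline_extinction(
    peak_nm: float = 380.0,
    fwhm_nm: float = 60.0,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Synthetic p-nitroaniline extinction spectrum (Gaussian band stand-in).

    Only the single-wavelength value eps(405 nm) = 1e4 M^-1 cm^-1 is an
    established constant; the band shape here is a synthetic single-Gaussian
    stand-in (default peak 380 nm, FWHM 60 nm) scaled so that
    eps(405 nm) = 1e4 exactly.  It exists to drive the wavelength-resolved
    forward model, not to reproduce the true absorption spectrum.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    sigma = GaussianPeak(peak_nm, fwhm_nm).sigma_nm
    # evaluated directly (no full-band span requirement: the UV tail of the
    # band falls outside the instrument's visible grid by design)
    values = np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)
    at_405 = float(np.interp(405.0, wl, values))
    if at_405 <= 0:
        raise ValueError("band has no support at 405 nm; cannot anchor epsilon")
    return Spectrum(wl, values * (PNA_EPSILON_405 / at_405), kind="extinction")
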