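"""Emission and extinction spectra on a wavelength grid.

A :class:`Spectrum` is a sampled, non-negative function of wavelength: either
a relative LED emission intensity or a molar extinction coefficient
(M^-1 cm^-1).  LED emission bands are well described by a single Gaussian;
:func:`gaussian_emission` generates one and :func:`fit_gaussian` recovers the
peak position, full width at half maximum (FWHM) and amplitude from sampled
data by nonlinear least squares, the standard way LED bandwidths are
characterised from spectrometer traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FWHM_PER_SIGMA",
    "Spectrum",
    "GaussianPeak",
    "default_grid",
    "gaussian_emission",
    "fit_gaussian",
    "normalize",
]

#: FWHM / sigma ratio for a Gaussian line shape: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default grid bounds (nm) and spacing: covers the visible operating range
#: of the instrument with margin, at a spacing finer than any LED bandwidth.
GRID_MIN_NM = 350.0
GRID_MAX_NM = 750.0
GRID_STEP_NM = 1.0


def default_grid() -> np.ndarray:
    """Default wavelength grid: 350-750 nm at 1 nm spacing."""
    n = int(round((GRID_MAX_NM - GRID_MIN_NM) / GRID_STEP_NM)) + 1
    return np.linspace(GRID_MIN_NM, GRID_MAX_NM, n)


@dataclass(frozen=True)
class Spectrum:
    """A sampled non-negative function of wavelength.

    Parameters
    ----------
    wavelengths : array, nm
        Strictly increasing grid, length >= 2.
    values : array
        Non-negative finite values on the grid: relative intensity for
        ``kind="emission"``, molar extinction (M^-1 cm^-1) for
        ``kind="extinction"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: Literal["emission", "extinction"] = "emission"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 grid points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("spectrum values must be finite and non-negative")
        if self.kind not in ("emission", "extinction"):
            raise ValueError(f"unknown spectrum kind: {self.kind!r}")

    def integral(self) -> float:
        """Integral over the stored grid (trapezoid rule)."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def interpolate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation of the values onto another grid.

        Raises if the target grid does not overlap the stored grid at all.
        """
        wl = np.asarray(wavelengths, dtype=float)
        if wl.max() < self.wavelengths[0] or wl.min() > self.wavelengths[-1]:
            raise ValueError(
                "requested grid "
                f"[{wl.min():g}, {wl.max():g}] nm does not overlap spectrum grid "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        return np.interp(wl, self.wavelengths, self.values)

    def to_csv(self, path) -> None:
        """Write as two-column CSV ``wavelength_nm,value``."""
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: Literal["emission", "extinction"] = "emission") -> "Spectrum":
        """Read a two-column CSV ``wavelength_nm,value`` (header required)."""
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"spectrum CSV is missing columns: {sorted(missing)}")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), kind=kind)


@dataclass(frozen=True)
class GaussianPeak:
    """Gaussian emission band: peak wavelength, FWHM and amplitude.

    ``fwhm_nm = sigma_nm * 2*sqrt(2 ln 2)`` where ``sigma_nm`` is the Gaussian
    standard deviation.
    """

    peak_nm: float
    fwhm_nm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError("fwhm_nm must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / FWHM_PER_SIGMA


def _gauss(wl: np.ndarray, peak: float, sigma: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


def gaussian_emission(peak: GaussianPeak, grid: np.ndarray | None = None) -> Spectrum:
    """Gaussian emission spectrum sampled on ``grid``.

    The result is normalised so its maximum grid value equals
    ``peak.amplitude`` (the maximum falls on the grid point nearest
    ``peak.peak_nm``).  The grid must span ``peak_nm +/- 3*fwhm_nm`` so that
    the band is fully contained.
    """
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    lo, hi = peak.peak_nm - 3 * peak.fwhm_nm, peak.peak_nm + 3 * peak.fwhm_nm
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"grid [{wl[0]:g}, {wl[-1]:g}] nm too narrow: need at least "
            f"[{lo:g}, {hi:g}] nm ({peak.peak_nm:g} +/- 3x{peak.fwhm_nm:g})"
        )
    vals = _gauss(wl, peak.peak_nm, peak.sigma_nm, 1.0)
    vals = vals * (peak.amplitude / vals.max())
    return Spectrum(wl, vals, kind="emission")


def _initial_gaussian_guess(spec: Spectrum) -> tuple[float, float, float]:
    """Deterministic start: peak at argmax, FWHM from half-max crossings."""
    wl, vals = spec.wavelengths, spec.values
    i = int(np.argmax(vals))
    amp = float(vals[i])
    half = amp / 2.0
    above = vals >= half
    idx = np.flatnonzero(above)
    # linear-interpolated half-max crossings on each side
    lo_i, hi_i = idx[0], idx[-1]
    if lo_i > 0:
        f = (half - vals[lo_i - 1]) / (vals[lo_i] - vals[lo_i - 1])
        left = wl[lo_i - 1] + f * (wl[lo_i] - wl[lo_i - 1])
    else:
        left = wl[0]
    if hi_i < wl.size - 1:
        f = (half - vals[hi_i + 1]) / (vals[hi_i] - vals[hi_i + 1])
        right = wl[hi_i + 1] - f * (wl[hi_i + 1] - wl[hi_i])
    else:
        right = wl[-1]
    fwhm = max(right - left, np.mean(np.diff(wl)))
    return float(wl[i]), fwhm, amp


def fit_gaussian(spec: Spectrum) -> tuple[GaussianPeak, GaussianPeak]:
    """Least-squares Gaussian fit of an emission spectrum.

    Returns
    -------
    (estimate, stderr) : tuple of GaussianPeak
        Point estimates and the corresponding standard errors (from the
        Jacobian-based covariance at the optimum), both packaged as
        :class:`GaussianPeak` for symmetric access to ``peak_nm``,
        ``fwhm_nm`` and ``amplitude``.

    Raises
    ------
    ValueError
        If the spectrum maximum sits on the grid edge (the band is not fully
        captured) or the fit does not converge.
    """
    wl, vals = spec.wavelengths, spec.values
    i_max = int(np.argmax(vals))
    if i_max == 0 or i_max == wl.size - 1:
        raise ValueError("spectrum maximum lies on the grid edge; cannot fit a peak")
    peak0, fwhm0, amp0 = _initial_gaussian_guess(spec)
    try:
        popt, pcov = curve_fit(
            _gauss,
            wl,
            vals,
            p0=[peak0, fwhm0 / FWHM_PER_SIGMA, amp0],
            maxfev=10000,
        )
    except RuntimeError as exc:  # scipy reports the iteration count in the message
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    est = GaussianPeak(
        peak_nm=float(popt[0]),
        fwhm_nm=float(abs(popt[1]) * FWHM_PER_SIGMA),
        amplitude=float(popt[2]),
    )
    # stderr amplitude/fwhm can be 0 on noiseless data; GaussianPeak requires
    # positives, so floor at a tiny value.
    tiny = 1e-12
    err = GaussianPeak(
        peak_nm=float(perr[0]),
        fwhm_nm=float(max(perr[1] * FWHM_PER_SIGMA, tiny)),
        amplitude=float(max(perr[2], tiny)),
    )
    return est, err


def normalize(spec: Spectrum) -> Spectrum:
    """Scale a spectrum to a maximum value of 1 (shape preserved)."""
    m = spec.values.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return Spectrum(spec.wavelengths, spec.values / m, kind=spec.kind)
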