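"""Concentration-absorbance model fits.

Two regression models for an absorbance-versus-concentration dilution
series:

* :class:`BeerLambertRegression` — the Beer-Lambert law ``A = C * l * eps``
  with the path length ``l`` fixed (1 cm by default) and no intercept, so the
  only free parameter is the extinction coefficient ``eps``.
* :class:`TwoComponentRegression` — the unabsorbable-fraction model
  ``A = -log10((1 - f_na) * 10^(-C*l*eps) + f_na)``, which reduces to
  Beer-Lambert at ``f_na = 0`` and captures the downward curvature a
  broadband LED source produces.

Both are scikit-learn compatible estimators (``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with trailing underscores)
so they compose with sklearn model selection; :func:`fit_beer_lambert` and
:func:`fit_two_component` are the corresponding one-call wrappers returning
a :class:`FitResult` report.

Standard errors come from the Jacobian-based covariance at the least-squares
optimum.  R^2 is always computed against the mean model, including for the
origin-constrained Beer-Lambert fit (this makes R^2 comparable across the
two models but means the origin-constrained value is not the regression-
through-origin R^2 some software reports).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .optics import TwoComponentParams, two_component_absorbance

__all__ = [
    "ConcentrationSeries",
    "FitResult",
    "BeerLambertRegression",
    "TwoComponentRegression",
    "fit_beer_lambert",
    "fit_two_component",
    "linearity_bound",
    "NO_CEILING",
]

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ConcentrationSeries:
    """A dilution series: concentrations (mol/L) and measured absorbances."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    path_length: float = 1.0  # cm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "absorbances", a)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("concentrations and absorbances must be 1-D of equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if not self.path_length > 0:
            raise ValueError("path_length must be positive")
        if np.unique(c).size < 2:
            raise ValueError("need at least 2 distinct concentrations")

    def __len__(self) -> int:
        return self.concentrations.size

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"concentration_M": self.concentrations, "absorbance": self.absorbances}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, path_length: float = 1.0) -> "ConcentrationSeries":
        df = pd.read_csv(path)
        missing = {"concentration_M", "absorbance"} - set(df.columns)
        if missing:
            raise ValueError(f"series CSV is missing columns: {sorted(missing)}")
        return cls(
            df["concentration_M"].to_numpy(),
            df["absorbance"].to_numpy(),
            path_length=path_length,
        )


@dataclass(frozen=True)
class FitResult:
    """Point estimates, standard errors and R^2 of one model fit."""

    model: str
    estimates: dict
    standard_errors: dict
    r_squared: float
    n: int
    path_length_cm: Optional[float]

    def __post_init__(self) -> None:
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        if any(v < 0 for v in self.standard_errors.values()):
            raise ValueError("standard errors must be >= 0")

    def to_json(self) -> str:
        d = asdict(self)
        d["schema_version"] = REPORT_SCHEMA_VERSION
        return json.dumps(d, indent=2)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


def _as_concentration_vector(X) -> np.ndarray:
    """Accept a 1-D vector or an (n, 1) design matrix of concentrations."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("expected a single concentration feature")
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("concentrations must be 1-D or a single-column matrix")
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("concentrations must be finite and >= 0")
    return X


class BeerLambertRegression(RegressorMixin, BaseEstimator):
    """Least-squares Beer-Lambert fit ``A = C * l * eps`` (+ optional intercept).

    Parameters
    ----------
    path_length : float, cm
        Fixed cuvette path length; never fitted.
    fit_intercept : bool
        The law has no intercept and the instrument is zeroed on a blank, so
        the default is an origin-constrained fit; an intercept can be enabled
        for diagnostic use.

    Attributes
    ----------
    epsilon_ : float
        Fitted extinction coefficient, M^-1 cm^-1.
    epsilon_stderr_ : float
    intercept_, intercept_stderr_ : float
        0.0 when ``fit_intercept`` is off.
    r_squared_ : float
    """

    def __init__(self, path_length: float = 1.0, fit_intercept: bool = False) -> None:
        self.path_length = path_length
        self.fit_intercept = fit_intercept

    def fit(self, X, y) -> "BeerLambertRegression":
        c = _as_concentration_vector(X)
        a = np.asarray(y, dtype=float)
        if c.size != a.size or c.size < 2:
            raise ValueError("need >= 2 (concentration, absorbance) pairs")
        x = c * self.path_length
        if np.all(x == 0):
            raise ValueError("all concentrations are zero; epsilon is unidentifiable")
        if self.fit_intercept:
            design = np.column_stack([x, np.ones_like(x)])
        else:
            design = x[:, None]
        coef, _, _, _ = np.linalg.lstsq(design, a, rcond=None)
        resid = a - design @ coef
        dof = max(c.size - design.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        self.epsilon_ = float(coef[0])
        self.epsilon_stderr_ = float(np.sqrt(cov[0, 0]))
        self.intercept_ = float(coef[1]) if self.fit_intercept else 0.0
        self.intercept_stderr_ = float(np.sqrt(cov[1, 1])) if self.fit_intercept else 0.0
        self.r_squared_ = _r_squared(a, design @ coef)
        self.n_ = int(c.size)
        return self

    def predict(self, X) -> np.ndarray:
        c = _as_concentration_vector(X)
        return c * self.path_length * self.epsilon_ + self.intercept_

    def result(self) -> FitResult:
        return FitResult(
            model="beer_lambert",
            estimates={"epsilon": self.epsilon_, "intercept": self.intercept_},
            standard_errors={
                "epsilon": self.epsilon_stderr_,
                "intercept": self.intercept_stderr_,
            },
            r_squared=self.r_squared_,
            n=self.n_,
            path_length_cm=self.path_length,
        )


class TwoComponentRegression(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the unabsorbable-fraction model.

    Fits ``A = -log10((1 - f_na) * 10^(-C*l*eps) + f_na)`` with ``f_na``
    constrained to [0, 1).  Initialisation is deterministic: ``eps`` from an
    origin-constrained slope of the three lowest concentrations (that region
    is nearly Beer-Lambert) and ``f_na`` from the high-absorbance plateau,
    ``10^(-max A)`` clipped to [1e-4, 0.5].

    Attributes
    ----------
    epsilon_, f_na_ : float
    epsilon_stderr_, f_na_stderr_ : float
    r_squared_ : float
    covariance_ : (2, 2) array
    """

    def __init__(self, path_length: float = 1.0) -> None:
        self.path_length = path_length

    @staticmethod
    def _model(cl: np.ndarray, epsilon: float, f_na: float) -> np.ndarray:
        return two_component_absorbance(cl * epsilon, f_na)

    def fit(self, X, y) -> "TwoComponentRegression":
        c = _as_concentration_vector(X)
        a = np.asarray(y, dtype=float)
        if c.size != a.size:
            raise ValueError("concentrations and absorbances must have equal length")
        if np.unique(c).size < 2:
            raise ValueError("degenerate series: a single concentration cannot constrain the model")
        if c.size < 3:
            raise ValueError("need >= 3 points for the two-parameter fit")
        if a.max() - a.min() <= 0:
            raise ValueError("absorbances show no spread; model is unidentifiable")
        cl = c * self.path_length
        order = np.argsort(cl)
        low = order[: 3]
        eps0 = float(np.sum(cl[low] * a[low]) / np.sum(cl[low] ** 2)) if np.any(cl[low] > 0) else 1.0
        if not np.isfinite(eps0) or eps0 <= 0:
            eps0 = a.max() / cl.max()
        f0 = float(np.clip(10.0 ** (-a.max()), 1e-4, 0.5))
        try:
            popt, pcov = curve_fit(
                self._model,
                cl,
                a,
                p0=[eps0, f0],
                bounds=([0.0, 0.0], [np.inf, 1.0 - 1e-12]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise ValueError(f"two-component fit did not converge: {exc}") from exc
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        self.epsilon_ = float(popt[0])
        self.f_na_ = float(popt[1])
        self.epsilon_stderr_ = float(perr[0])
        self.f_na_stderr_ = float(perr[1])
        self.covariance_ = pcov
        self.r_squared_ = _r_squared(a, self._model(cl, *popt))
        self.n_ = int(c.size)
        return self

    def predict(self, X) -> np.ndarray:
        c = _as_concentration_vector(X)
        return self._model(c * self.path_length, self.epsilon_, self.f_na_)

    def result(self) -> FitResult:
        return FitResult(
            model="two_component",
            estimates={"epsilon": self.epsilon_, "f_na": self.f_na_},
            standard_errors={"epsilon": self.epsilon_stderr_, "f_na": self.f_na_stderr_},
            r_squared=self.r_squared_,
            n=self.n_,
            path_length_cm=self.path_length,
        )


def fit_beer_lambert(series: ConcentrationSeries, fit_intercept: bool = False) -> FitResult:
    """Beer-Lambert fit of a dilution series (path length fixed, no intercept
    by default)."""
    est = BeerLambertRegression(path_length=series.path_length, fit_intercept=fit_intercept)
    est.fit(series.concentrations, series.absorbances)
    return est.result()


def fit_two_component(series: ConcentrationSeries) -> FitResult:
    """Two-component (unabsorbable-fraction) fit of a dilution series."""
    est = TwoComponentRegression(path_length=series.path_length)
    est.fit(series.concentrations, series.absorbances)
    return est.result()


#: Sentinel returned by :func:`linearity_bound` when f_na = 0 (no ceiling).
NO_CEILING = math.inf


def linearity_bound(params: TwoComponentParams, tolerance: float) -> float:
    """Largest apparent absorbance at which the two-component curve stays
    within a relative deviation ``tolerance`` of the Beer-Lambert line.

    The relative deviation ``(cle - A_app) / cle`` increases monotonically
    with ``cle`` for fixed ``f_na > 0``, so the crossing is found by scalar
    root bracketing; the returned ceiling is ``A_app`` at the crossing.
    Returns :data:`NO_CEILING` (inf) when ``f_na = 0`` and 0.0 (with a
    warning) when the tolerance is unreachable at any positive absorbance.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    f_na = params.f_na
    if f_na == 0.0:
        return NO_CEILING

    def rel_dev(cle: float) -> float:
        return (cle - two_component_absorbance(cle, f_na)) / cle

    lo, hi = 1e-9, 1.0
    if rel_dev(lo) >= tolerance:
        warnings.warn("tolerance unreachable at any positive absorbance; ceiling is 0")
        return 0.0
    while rel_dev(hi) < tolerance:
        hi *= 2.0
        if hi > 1e6:  # tolerance never violated (tiny f_na): effectively unbounded
            return NO_CEILING
    cle_star = brentq(lambda x: rel_dev(x) - tolerance, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(two_component_absorbance(cle_star, f_na))
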