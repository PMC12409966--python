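"""Initial-rate enzyme kinetics from multi-channel absorbance time courses.

A chromogenic substrate (a nitroanilide) releases p-nitroaniline on
hydrolysis, so the reaction progress appears as a linear rise in absorbance
while only a small fraction (<= 4 %) of the substrate is consumed.  The
pipeline mirrors the standard analysis:

1. subtract the first-time-point absorbance from every channel (baselining),
2. fit a straight line ``A = m t + b`` per channel,
3. convert the slope to a concentration rate ``v = m / (eps * l)``,
4. regress the rates against the per-channel enzyme concentration; in the
   initial-rate regime the line passes close to the origin.

The default extinction coefficient for the rate conversion, 8.88e3
M^-1 cm^-1, is the mean of the six per-LED Beer-Lambert calibration values
in :data:`LED_CALIBRATION_EPSILONS`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .fitters import FitResult

__all__ = [
    "LED_CALIBRATION_EPSILONS",
    "DEFAULT_EPSILON",
    "KineticsRun",
    "RateResult",
    "baseline_subtract",
    "fit_rates",
    "rate_vs_enzyme",
    "max_substrate_consumption",
]

#: Per-LED apparent extinction coefficients (M^-1 cm^-1) of p-nitroaniline at
#: 405 nm, from Beer-Lambert calibration of the six instrument channels.
LED_CALIBRATION_EPSILONS = (8.71e3, 8.93e3, 8.87e3, 8.71e3, 9.11e3, 8.94e3)

#: Default extinction coefficient for slope-to-rate conversion: the mean of
#: the six channel calibrations, rounded to three significant figures.
DEFAULT_EPSILON = 8.88e3

#: Largest tolerated fractional substrate consumption for the linear
#: (zero-order) initial-rate approximation to hold.
CONSUMPTION_LIMIT = 0.04

N_POSITIONS = 6


@dataclass(frozen=True)
class KineticsRun:
    """Six absorbance time series on a shared time grid.

    Parameters
    ----------
    times : array, min
        Strictly increasing, starting at 0.
    absorbances : (n_times, 6) array
        One column per cuvette position (1-based positions map to columns
        0-5).
    enzyme_concentrations : length-6 array, mol/L
        Per-position enzyme concentration labels.
    epsilon_used : M^-1 cm^-1, for slope-to-rate conversion.
    noise_sd_abs : absorbance noise level of the instrument, used only to
        decide when an R^2 value would be meaningless (flat traces).
    """

    times: np.ndarray
    absorbances: np.ndarray
    enzyme_concentrations: np.ndarray
    epsilon_used: float = DEFAULT_EPSILON
    path_length: float = 1.0
    noise_sd_abs: float = 1.0e-3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        e = np.asarray(self.enzyme_concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        object.__setattr__(self, "enzyme_concentrations", e)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.diff(t) > 0) or t[0] != 0.0:
            raise ValueError("times must be strictly increasing and start at 0")
        if a.shape != (t.size, N_POSITIONS):
            raise ValueError(f"absorbances must have shape (n_times, {N_POSITIONS})")
        if e.shape != (N_POSITIONS,):
            raise ValueError(f"need exactly {N_POSITIONS} enzyme concentration labels")
        if not self.epsilon_used > 0 or not self.path_length > 0:
            raise ValueError("epsilon_used and path_length must be positive")

    def to_csv(self, path, sidecar_json=None) -> None:
        """Write ``time_min,pos1..pos6`` CSV plus a sidecar JSON of labels."""
        cols = {"time_min": self.times}
        for i in range(N_POSITIONS):
            cols[f"pos{i + 1}"] = self.absorbances[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar_json is not None:
            with open(sidecar_json, "w") as fh:
                json.dump(
                    {
                        "enzyme_concentrations_M": list(self.enzyme_concentrations),
                        "epsilon_M_cm": self.epsilon_used,
                        "path_length_cm": self.path_length,
                        "noise_sd_abs": self.noise_sd_abs,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def from_csv(cls, path, sidecar_json) -> "KineticsRun":
        df = pd.read_csv(path)
        expected = ["time_min"] + [f"pos{i + 1}" for i in range(N_POSITIONS)]
        missing = set(expected) - set(df.columns)
        if missing:
            raise ValueError(f"kinetics CSV is missing columns: {sorted(missing)}")
        with open(sidecar_json) as fh:
            side = json.load(fh)
        return cls(
            times=df["time_min"].to_numpy(),
            absorbances=df[expected[1:]].to_numpy(),
            enzyme_concentrations=np.asarray(side["enzyme_concentrations_M"], dtype=float),
            epsilon_used=float(side.get("epsilon_M_cm", DEFAULT_EPSILON)),
            path_length=float(side.get("path_length_cm", 1.0)),
            noise_sd_abs=float(side.get("noise_sd_abs", 1.0e-3)),
        )


@dataclass(frozen=True)
class RateResult:
    """Straight-line fit of one channel's time course.

    ``rate = slope / (epsilon * path_length)`` converts the absorbance slope
    (A/min) into a concentration rate (mol L^-1 min^-1).  ``r_squared`` is
    None for traces whose total variance is within noise (no meaningful
    trend, e.g. a no-enzyme control).
    """

    position: int
    slope: float  # absorbance / min
    intercept: float  # absorbance
    slope_stderr: float
    rate: float  # mol / (L min)
    rate_stderr: float
    r_squared: float | None


def baseline_subtract(run: KineticsRun) -> KineticsRun:
    """Subtract each channel's first-time-point value so every trace starts
    at exactly 0; time differences and slopes are unchanged."""
    if run.absorbances.size == 0:
        raise ValueError("empty series")
    return replace(run, absorbances=run.absorbances - run.absorbances[0, :])


def fit_rates(run: KineticsRun) -> list[RateResult]:
    """Ordinary least-squares line per channel; slopes converted to
    concentration rates via the run's extinction coefficient."""
    if run.times.size < 3:
        raise ValueError("need >= 3 time points for a rate fit")
    scale = run.epsilon_used * run.path_length
    out = []
    for i in range(N_POSITIONS):
        y = run.absorbances[:, i]
        res = stats.linregress(run.times, y)
        # an R^2 for a flat trace is noise-on-noise; report not-applicable
        if np.var(y) < 10.0 * run.noise_sd_abs**2:
            r2 = None
        else:
            r2 = float(res.rvalue**2)
        out.append(
            RateResult(
                position=i + 1,
                slope=float(res.slope),
                intercept=float(res.intercept),
                slope_stderr=float(res.stderr),
                rate=float(res.slope / scale),
                rate_stderr=float(res.stderr / scale),
                r_squared=r2,
            )
        )
    return out


def rate_vs_enzyme(
    rates: list[RateResult], enzyme_concentrations: np.ndarray
) -> FitResult:
    """Least-squares line of concentration rate against enzyme concentration.

    The intercept is reported (with its standard error) so the
    passes-through-the-origin expectation of the initial-rate regime can be
    checked.
    """
    e = np.asarray(enzyme_concentrations, dtype=float)
    v = np.asarray([r.rate for r in rates], dtype=float)
    if e.size != v.size:
        raise ValueError("one enzyme concentration per rate is required")
    if np.unique(e).size < 2:
        raise ValueError("all enzyme concentrations are equal; slope is unidentifiable")
    if e.size < 3:
        raise ValueError("need >= 3 channels for the rate-vs-enzyme regression")
    res = stats.linregress(e, v)
    return FitResult(
        model="rate_vs_enzyme",
        estimates={"slope": float(res.slope), "intercept": float(res.intercept)},
        standard_errors={
            "slope": float(res.stderr),
            "intercept": float(res.intercept_stderr),
        },
        r_squared=float(res.rvalue**2),
        n=int(e.size),
        path_length_cm=None,
    )


def max_substrate_consumption(
    rates_M_per_min: np.ndarray, duration_min: float, substrate_M: float
) -> np.ndarray:
    """Fraction of substrate consumed per channel over the run."""
    if not substrate_M > 0:
        raise ValueError("substrate concentration must be positive")
    return np.asarray(rates_M_per_min, dtype=float) * duration_min / substrate_M
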