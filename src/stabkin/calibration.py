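"""Detector-response calibration: OLS line fitting, back-calculation, LOD/LOQ.

The detector response of an HPLC-UV assay is modelled as a straight line
``area = slope * concentration + intercept`` fitted by ordinary (unweighted)
least squares over the calibration range.  :class:`CalibrationModel` is the
statsmodels-style entry point: build it from paired concentration/area data
(or a calibration table), call :meth:`~CalibrationModel.fit`, and use the
returned :class:`CalibrationResults` to back-calculate unknowns and derive
detection limits.

The limit of detection (LOD) is defined through a signal-to-noise ratio of 3:
the lowest concentration whose noise-free predicted *net* signal
``slope * conc`` reaches three times the baseline noise standard deviation.
The limit of quantification (LOQ) is the lowest calibration level whose
replicate precision (CV%) stays below a threshold (1.5% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDesignError,
    InvalidInputError,
    SingularFitError,
)

__all__ = [
    "LinearFit",
    "CalibrationModel",
    "CalibrationResults",
    "DetectionLimits",
    "ols_fit",
    "fit_calibration",
    "back_calculate",
    "lod_loq",
]


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line ``y = slope * x + intercept``.

    ``sd_slope`` and ``sd_intercept`` are the classical standard errors from
    the residual variance with ``n - 2`` degrees of freedom; they are NaN for
    a two-point (saturated) fit.  ``r_squared`` is the squared Pearson
    correlation of x and y.
    """

    slope: float
    intercept: float
    r_squared: float
    sd_slope: float
    sd_intercept: float
    n: int

    def predict(self, x):
        """Predicted response at ``x`` (scalar or array)."""
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, y):
        """Solve the line for x given a response ``y``."""
        if self.slope == 0:
            raise SingularFitError("cannot invert a zero-slope line")
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope


def ols_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Unweighted ordinary least squares of ``y`` on ``x``.

    Parameters
    ----------
    x, y : sequences of equal length (>= 2)
        Predictor and response.  ``x`` must not be constant.

    Returns
    -------
    LinearFit

    Raises
    ------
    InsufficientDesignError
        Fewer than two points or unequal lengths.
    SingularFitError
        Zero variance in ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InsufficientDesignError("x and y must be 1-D sequences of equal length")
    if x.size < 2:
        raise InsufficientDesignError(f"need at least 2 points, got {x.size}")
    if np.ptp(x) == 0:
        raise SingularFitError("x has zero variance; the fit is singular")

    res = stats.linregress(x, y)
    n = int(x.size)
    if n == 2:
        sd_slope = sd_intercept = float("nan")
    else:
        sd_slope = float(res.stderr)
        sd_intercept = float(res.intercept_stderr)
    # linregress reports r = 1 exactly for an exact line; square for r².
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        sd_slope=sd_slope,
        sd_intercept=sd_intercept,
        n=n,
    )


@dataclass(frozen=True)
class DetectionLimits:
    """LOD/LOQ pair in concentration units.

    ``loq`` is NaN and ``loq_defined`` False when no calibration level meets
    the CV% criterion — a flagged result, not an error.
    """

    lod: float
    loq: float
    loq_defined: bool
    cv_threshold_pct: float


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted detector-response line plus its dispersion statistics."""

    slope: float
    intercept: float
    r_squared: float
    sd_slope: float
    sd_intercept: float
    rsd_slope_pct: float
    n_points: int
    n_levels: int
    model: "CalibrationModel" = field(repr=False, compare=False, default=None)

    @property
    def linear_fit(self) -> LinearFit:
        return LinearFit(
            self.slope, self.intercept, self.r_squared,
            self.sd_slope, self.sd_intercept, self.n_points,
        )

    def predict(self, conc):
        """Predicted peak area at a concentration."""
        return self.linear_fit.predict(conc)

    def back_calculate(self, area):
        """Concentration read off the calibration line: ``(area - intercept) / slope``."""
        return self.linear_fit.invert(area)

    def detection_limits(
        self,
        noise_sd: float,
        cv_by_level: Mapping[float, float],
        cv_threshold_pct: float = 1.5,
    ) -> DetectionLimits:
        """LOD from S/N = 3 against ``noise_sd``; LOQ from per-level CV%."""
        return lod_loq(self, noise_sd, cv_by_level, cv_threshold_pct)

    def summary(self) -> str:
        sign = "-" if self.intercept < 0 else "+"
        lines = [
            "Calibration (ordinary least squares)",
            f"  Regression equation        y = {self.slope:.2f}x {sign} {abs(self.intercept):.2f}",
            f"  SD of slope                {self.sd_slope:.2f}",
            f"  RSD of slope (%)           {self.rsd_slope_pct:.2f}",
            f"  SD of intercept            {self.sd_intercept:.2f}",
            f"  Correlation coefficient r2 {self.r_squared:.4f}",
            f"  Points / levels            {self.n_points} / {self.n_levels}",
        ]
        return "\n".join(lines)


class CalibrationModel:
    """Straight-line detector-response model for an external-standard assay.

    Parameters
    ----------
    conc : sequence of float
        Nominal concentrations (e.g. µg/mL), one per injection.
    area : sequence of float
        Measured peak areas.

    Examples
    --------
    >>> m = CalibrationModel([1, 2, 5, 10, 15, 20],
    ...                      [31.1, 70.59, 189.06, 386.51, 583.96, 781.41])
    >>> r = m.fit()
    >>> round(r.slope, 2), round(r.intercept, 2)
    (39.49, -8.39)
    >>> round(float(r.back_calculate(386.51)), 6)
    10.0
    """

    def __init__(self, conc: Sequence[float], area: Sequence[float]):
        conc = np.asarray(conc, dtype=float)
        area = np.asarray(area, dtype=float)
        if conc.size != area.size:
            raise InsufficientDesignError("conc and area must have equal length")
        if np.any(conc <= 0):
            raise InvalidInputError("concentrations must be positive")
        levels = np.unique(conc)
        if levels.size < 3:
            raise InsufficientDesignError(
                f"need at least 3 distinct concentration levels, got {levels.size}"
            )
        self.conc = conc
        self.area = area
        self.n_levels = int(levels.size)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, conc_col: str = "conc_ugml", area_col: str = "area"
    ) -> "CalibrationModel":
        """Build from a calibration table with concentration and area columns."""
        return cls(table[conc_col].to_numpy(), table[area_col].to_numpy())

    def fit(self) -> CalibrationResults:
        lf = ols_fit(self.conc, self.area)
        rsd = 100.0 * lf.sd_slope / abs(lf.slope) if lf.slope != 0 else math.inf
        return CalibrationResults(
            slope=lf.slope,
            intercept=lf.intercept,
            r_squared=lf.r_squared,
            sd_slope=lf.sd_slope,
            sd_intercept=lf.sd_intercept,
            rsd_slope_pct=rsd,
            n_points=lf.n,
            n_levels=self.n_levels,
            model=self,
        )


def fit_calibration(
    table: pd.DataFrame, conc_col: str = "conc_ugml", area_col: str = "area"
) -> CalibrationResults:
    """Fit the calibration line from a (day, replicate, conc, area) table."""
    return CalibrationModel.from_dataframe(table, conc_col, area_col).fit()


def back_calculate(fit: CalibrationResults | LinearFit, area):
    """Concentration corresponding to a measured area: ``(area - intercept) / slope``."""
    if isinstance(fit, CalibrationResults):
        return fit.back_calculate(area)
    return fit.invert(area)


def lod_loq(
    fit: CalibrationResults | LinearFit,
    noise_sd: float,
    cv_by_level: Mapping[float, float],
    cv_threshold_pct: float = 1.5,
) -> DetectionLimits:
    """Detection and quantification limits of the calibrated assay.

    LOD is the smallest concentration whose noise-free predicted net signal
    ``slope * conc`` reaches ``3 * noise_sd`` (signal-to-noise of 3), i.e.
    ``3 * noise_sd / slope``.  LOQ is the lowest calibration level whose
    replicate CV% does not exceed ``cv_threshold_pct``; when no level
    qualifies the LOQ is flagged undefined rather than raising.
    """
    if noise_sd <= 0:
        raise InvalidInputError("noise_sd must be positive")
    if not cv_by_level:
        raise InvalidInputError("cv_by_level must be non-empty")
    slope = fit.slope
    if slope <= 0:
        raise SingularFitError("LOD requires a positive calibration slope")
    lod = 3.0 * noise_sd / slope
    feasible = sorted(c for c, cv in cv_by_level.items() if cv <= cv_threshold_pct)
    if feasible:
        return DetectionLimits(lod, float(feasible[0]), True, cv_threshold_pct)
    return DetectionLimits(lod, float("nan"), False, cv_threshold_pct)
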