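"""Degradation kinetics: percent-remaining time courses and rate-law fitting.

A forced-degradation experiment tracks the intact-drug peak area over time
under a stress condition (e.g. 2 M HCl at 90 °C).  Expressing the areas as a
percentage of the time-zero response gives a :class:`TimeCourse` with
``C0 = 100`` by construction.  Under pseudo-first-order kinetics — the
co-reactant (acid, peroxide) in large excess — the remaining percentage decays
exponentially and its base-10 logarithm is linear in time:

    log10(Ct) = log10(C0) - k * t / ln(10)

so an ordinary least-squares fit of ``log10(Ct)`` against ``t`` gives the
apparent rate constant ``k = -slope * ln(10)`` (the classical "2.303" factor)
and the half-life ``t1/2 = ln(2) / k``.  Zero-order (``Ct`` linear in ``t``)
and second-order (``1/Ct`` linear in ``t``) laws are supported for order
screening; :func:`select_order` fits all three and picks the most linear,
with a parsimony tie-break.

:class:`KineticModel` is the statsmodels-style front end:
``KineticModel(tc, order="first").fit()`` returns a :class:`KineticResults`
with slope, intercept, r², k, t1/2 and a rendered equation string.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import LinearFit, ols_fit
from .exceptions import InsufficientDesignError, InvalidInputError

__all__ = [
    "ORDERS",
    "TimeCourse",
    "KineticModel",
    "KineticResults",
    "percent_remaining",
    "linearize",
    "fit_kinetics",
    "rate_constant_from_slope",
    "half_life",
    "select_order",
]

logger = logging.getLogger(__name__)

ORDERS = ("zero", "first", "second")

#: ln(10): conversion between the base-10 slope and the natural-log rate
#: constant; traditionally rounded to 2.303 in the pharmaceutical literature.
LN10 = math.log(10.0)

# Points below this percent remaining are excluded from log/reciprocal
# linearizations, where they would dominate the fit through transform
# amplification of relative noise.
DEFAULT_MIN_PERCENT = 1.0


def _check_order(order: str) -> str:
    if order not in ORDERS:
        raise InvalidInputError(f"order must be one of {ORDERS}, got {order!r}")
    return order


@dataclass(frozen=True)
class TimeCourse:
    """One stress condition's percent-remaining series.

    Attributes
    ----------
    condition : str
        Stress medium label, e.g. ``"2 M HCl"`` or ``"0.5% H2O2"``.
    temperature_c : float
        Incubation temperature in °C.
    times_h : ndarray
        Sampling times in hours, non-negative and strictly increasing.
    percent_remaining : ndarray
        Remaining drug as a percent of the time-zero response (C0 = 100).
    n_clamped : int
        Number of simulated points clamped at the 0.1% floor (see the
        synthetic-data generator); 0 for measured data.
    """

    condition: str
    temperature_c: float
    times_h: np.ndarray
    percent_remaining: np.ndarray
    n_clamped: int = 0

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.percent_remaining, dtype=float)
        if t.size != c.size:
            raise InvalidInputError("times and percent series must have equal length")
        if t.size == 0:
            raise InvalidInputError("time course must be non-empty")
        if np.any(t < 0):
            raise InvalidInputError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "percent_remaining", c)

    def __len__(self) -> int:
        return int(self.times_h.size)

    def rescaled(self, factor: float) -> "TimeCourse":
        """Same series with all percent values multiplied by ``factor``."""
        return replace(self, percent_remaining=self.percent_remaining * factor)


def percent_remaining(
    areas: Sequence[tuple[float, float]],
    reference_area: float,
    condition: str = "",
    temperature_c: float = float("nan"),
) -> TimeCourse:
    """Convert (time, peak area) pairs into a percent-remaining time course.

    ``Ct = 100 * area(t) / reference_area`` where the reference is the
    time-zero response, so ``C0 = 100`` by construction.  Non-positive areas
    are excluded with a logged warning rather than propagated into the
    log-linear fit.

    Raises
    ------
    InvalidInputError
        Non-positive reference area, or a first time point that is not 0.
    """
    if reference_area <= 0:
        raise InvalidInputError("reference area must be positive")
    pairs = [(float(t), float(a)) for t, a in areas]
    if not pairs:
        raise InvalidInputError("empty area series")
    if pairs[0][0] != 0:
        raise InvalidInputError("first time point must be 0 (the reference injection)")
    kept_t, kept_c, dropped = [], [], 0
    for t, a in pairs:
        if a <= 0:
            dropped += 1
            continue
        kept_t.append(t)
        kept_c.append(100.0 * a / reference_area)
    if dropped:
        logger.warning("percent_remaining: excluded %d non-positive area(s)", dropped)
    return TimeCourse(condition, temperature_c, np.array(kept_t), np.array(kept_c))


def linearize(
    tc: TimeCourse, order: str, min_percent: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Transform a time course to the straight-line scale of a rate law.

    zero -> ``y = Ct``; first -> ``y = log10(Ct)``; second -> ``y = 1/Ct``.
    For first/second order, points with ``Ct <= 0`` (transform undefined) or
    ``Ct < min_percent`` are excluded with a logged warning.
    """
    _check_order(order)
    t = tc.times_h
    c = tc.percent_remaining
    if order == "zero":
        return t, c.copy()
    usable = c > max(0.0, min_percent)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "linearize(%s): excluded %d point(s) at or below %.3g%% remaining",
            order, n_dropped, max(0.0, min_percent),
        )
    t, c = t[usable], c[usable]
    if order == "first":
        return t, np.log10(c)
    return t, 1.0 / c


def rate_constant_from_slope(slope: float, order: str) -> float:
    """Apparent rate constant (per hour) from the linearized-plot slope.

    first: ``k = -slope * ln(10)`` (slope of log10 Ct vs t);
    zero: ``k = -slope``; second: ``k = slope``.
    """
    _check_order(order)
    if order == "first":
        return -slope * LN10
    if order == "zero":
        return -slope
    return slope


def half_life(k: float, order: str, c0: float = 100.0) -> float:
    """Half-life in hours; NaN (undefined) when ``k <= 0``.

    first: ``ln(2)/k``; zero: ``c0/(2k)``; second: ``1/(k c0)``.
    """
    _check_order(order)
    if k <= 0 or not np.isfinite(k):
        return float("nan")
    if order == "first":
        return math.log(2.0) / k
    if order == "zero":
        return c0 / (2.0 * k)
    return 1.0 / (k * c0)


@dataclass(frozen=True)
class KineticResults:
    """Fitted rate law for one time course.

    ``slope``/``intercept``/``r_squared`` describe the linearized plot;
    ``k`` and ``t_half`` are on the natural (per-hour) scale.  A series whose
    fitted slope does not indicate decay is flagged ``degrading=False`` with
    ``k <= 0`` and an undefined (NaN) half-life.  Values are stored at full
    precision; rounding happens only in the rendering helpers.
    """

    order: str
    slope: float
    intercept: float
    r_squared: float
    sd_slope: float
    k: float
    t_half: float
    n_points: int
    n_excluded: int
    degrading: bool
    condition: str = ""
    temperature_c: float = float("nan")
    c0: float = 100.0
    model: "KineticModel" = field(repr=False, compare=False, default=None)

    def equation(self, decimals: int = 3) -> str:
        """Linearized-plot equation rendered as ``y = -0.027x + 1.917``."""
        sign = "-" if self.intercept < 0 else "+"
        return (
            f"y = {self.slope:.{decimals}f}x {sign} {abs(self.intercept):.{decimals}f}"
        )

    def t_half_display(self, unit: str = "h") -> float:
        """Half-life in the requested display unit ('h' or 'min')."""
        if unit == "h":
            return self.t_half
        if unit == "min":
            return self.t_half * 60.0
        raise InvalidInputError(f"unknown half-life unit {unit!r}")

    def summary(self, half_life_unit: str = "h") -> str:
        th = self.t_half_display(half_life_unit)
        th_txt = f"{th:.1f} {half_life_unit}" if np.isfinite(th) else "undefined"
        head = f"{self.condition} @ {self.temperature_c:g} °C" if self.condition else "Kinetic fit"
        lines = [
            head,
            f"  order       {self.order}",
            f"  equation    {self.equation()}",
            f"  r^2         {self.r_squared:.3f}",
            f"  k (1/h)     {self.k:.3f}",
            f"  t1/2        {th_txt}",
            f"  n (used/excluded)  {self.n_points}/{self.n_excluded}",
        ]
        if not self.degrading:
            lines.append("  flag        non-degrading series (k <= 0)")
        return "\n".join(lines)


class KineticModel:
    """Rate-law model for one percent-remaining time course.

    Parameters
    ----------
    timecourse : TimeCourse
    order : {"zero", "first", "second"}
        Rate law to linearize under (default pseudo-first-order).
    min_percent : float
        Exclusion floor for log/reciprocal transforms, in percent remaining
        (default 1.0; ignored for zero order).

    Examples
    --------
    >>> import numpy as np
    >>> t = np.array([0., 12., 24., 48., 72.])
    >>> tc = TimeCourse("2 M HCl", 90.0, t, 100.0 * np.exp(-0.0622 * t))
    >>> r = KineticModel(tc, order="first").fit()
    >>> round(r.k, 4), round(r.t_half, 1)
    (0.0622, 11.1)
    """

    def __init__(
        self,
        timecourse: TimeCourse,
        order: str = "first",
        min_percent: float = DEFAULT_MIN_PERCENT,
    ):
        self.timecourse = timecourse
        self.order = _check_order(order)
        self.min_percent = min_percent

    def fit(self) -> KineticResults:
        floor = self.min_percent if self.order in ("first", "second") else 0.0
        t, y = linearize(self.timecourse, self.order, min_percent=floor)
        n_excluded = len(self.timecourse) - t.size
        if t.size < 3:
            raise InsufficientDesignError(
                f"need >= 3 usable points for a kinetic fit, got {t.size}"
            )
        lf: LinearFit = ols_fit(t, y)
        k = rate_constant_from_slope(lf.slope, self.order)
        degrading = k > 0
        return KineticResults(
            order=self.order,
            slope=lf.slope,
            intercept=lf.intercept,
            r_squared=lf.r_squared,
            sd_slope=lf.sd_slope,
            k=k,
            t_half=half_life(k, self.order) if degrading else float("nan"),
            n_points=int(t.size),
            n_excluded=int(n_excluded),
            degrading=degrading,
            condition=self.timecourse.condition,
            temperature_c=self.timecourse.temperature_c,
            model=self,
        )


def fit_kinetics(tc: TimeCourse, order: str = "first") -> KineticResults:
    """Fit one rate law to a time course (see :class:`KineticModel`)."""
    return KineticModel(tc, order=order).fit()


def select_order(
    tc: TimeCourse, tie_delta: float = 0.005
) -> tuple[str | None, dict[str, KineticResults]]:
    """Screen zero/first/second-order laws by linearity of the transformed plot.

    Fits all three orders and returns the one with the highest r², together
    with the per-order fits.  When the top candidates are within ``tie_delta``
    of the best r², the lowest order among them wins (parsimony).  Returns
    ``(None, fits)`` when every fit is degenerate or non-degrading.
    """
    if len(tc) < 4:
        raise InsufficientDesignError("order screening needs >= 4 points")
    fits: dict[str, KineticResults] = {}
    for order in ORDERS:
        try:
            fits[order] = fit_kinetics(tc, order)
        except (InsufficientDesignError,) as exc:
            logger.warning("select_order: %s-order fit failed (%s)", order, exc)
    candidates = {o: f for o, f in fits.items() if f.degrading and np.isfinite(f.r_squared)}
    if not candidates:
        return None, fits
    best_r2 = max(f.r_squared for f in candidates.values())
    for order in ORDERS:  # lowest order first
        f = candidates.get(order)
        if f is not None and best_r2 - f.r_squared < tie_delta:
            return order, fits
    return None, fits
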