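"""Arrhenius analysis: activation energy from per-temperature rate constants.

The Arrhenius law ``k = A * exp(-Ea / (R T))`` makes ``ln k`` linear in the
reciprocal absolute temperature, with slope ``-Ea / R``.  Given apparent rate
constants measured at two or more temperatures, :class:`ArrheniusModel` fits
that line by unweighted OLS and :class:`ArrheniusResults` reports the
activation energy ``Ea = -slope * R`` (J/mol), the log pre-exponential factor
``lnA`` (intercept), and extrapolated rate constants and half-lives at other
temperatures.

Conventions: temperatures enter in °C and are converted with
``T_K = T_C + 273.15``; ``R = 8.314 J/(mol K)``; rate constants are per hour,
so ``A`` is per hour as well (expressing k per minute shifts lnA by ln 60 but
leaves Ea unchanged).  The OLS slope standard error propagates to a standard
error on Ea — an extension beyond the classical graphical treatment, labelled
as such in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import ols_fit
from .exceptions import InvalidInputError
from .kinetics import KineticResults

__all__ = ["R_GAS", "ArrheniusModel", "ArrheniusResults",
           "arrhenius_fit", "predict_k", "predict_half_life"]

logger = logging.getLogger(__name__)

#: Molar gas constant, J/(mol K).
R_GAS = 8.314

_ABS_ZERO_C = -273.15


def _to_kelvin(temp_c) -> np.ndarray:
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= _ABS_ZERO_C):
        raise InvalidInputError("temperature must be above absolute zero")
    return t + 273.15


@dataclass(frozen=True)
class ArrheniusResults:
    """Fitted Arrhenius line ``ln k = lnA - Ea / (R T)``.

    ``slope_K`` is the slope of ln k vs 1/T (Kelvin); ``Ea`` is in J/mol
    (``ea_kj`` converts); ``se_Ea`` is NaN for a two-point fit.
    """

    slope_K: float
    lnA: float
    Ea: float
    r_squared: float
    n_temperatures: int
    se_Ea: float
    temperatures_c: np.ndarray = field(repr=False, default=None)
    k_per_h: np.ndarray = field(repr=False, default=None)
    model: "ArrheniusModel" = field(repr=False, compare=False, default=None)

    @property
    def ea_kj(self) -> float:
        """Activation energy in kJ/mol."""
        return self.Ea / 1000.0

    @property
    def A(self) -> float:
        """Pre-exponential factor, per hour."""
        return math.exp(self.lnA)

    def predict_k(self, temperature_c) -> float | np.ndarray:
        """Rate constant (per hour) extrapolated to a temperature in °C."""
        t_k = _to_kelvin(temperature_c)
        out = np.exp(self.lnA - self.Ea / (R_GAS * t_k))
        return float(out) if np.isscalar(temperature_c) else out

    def predict_half_life(self, temperature_c) -> float | np.ndarray:
        """First-order half-life (hours) at a temperature in °C."""
        return math.log(2.0) / self.predict_k(temperature_c)

    def residuals(self) -> np.ndarray:
        """Residuals of ln k about the fitted line, per input temperature."""
        t_k = _to_kelvin(self.temperatures_c)
        return np.log(self.k_per_h) - (self.lnA + self.slope_K / t_k)

    def summary(self) -> str:
        se_txt = f"{self.se_Ea / 1000.0:.1f}" if np.isfinite(self.se_Ea) else "n/a"
        return "\n".join(
            [
                f"Arrhenius fit (n = {self.n_temperatures} temperatures)",
                f"  slope (K)        {self.slope_K:.1f}",
                f"  Ea (kJ/mol)      {self.ea_kj:.1f}",
                f"  SE of Ea (kJ/mol, OLS extension)  {se_txt}",
                f"  ln A (A in 1/h)  {self.lnA:.2f}",
                f"  r^2              {self.r_squared:.4f}",
            ]
        )


class ArrheniusModel:
    """Arrhenius regression of rate constants on reciprocal temperature.

    Parameters
    ----------
    temperatures_c : sequence of float
        Temperatures in °C (>= 2 distinct values).  Duplicate temperatures
        are collapsed to the mean of their ln k with a logged warning.
    k_per_h : sequence of float
        Apparent rate constants at those temperatures, per hour, all > 0.

    Examples
    --------
    >>> m = ArrheniusModel([70, 80, 85, 90], [0.005, 0.014, 0.030, 0.062])
    >>> r = m.fit()
    >>> round(r.ea_kj, 1)
    129.6
    """

    def __init__(self, temperatures_c: Sequence[float], k_per_h: Sequence[float]):
        t = np.asarray(temperatures_c, dtype=float)
        k = np.asarray(k_per_h, dtype=float)
        if t.size != k.size:
            raise InvalidInputError("temperatures and rate constants must align")
        if np.any(k <= 0):
            raise InvalidInputError("all rate constants must be positive")
        _to_kelvin(t)  # range check
        if np.unique(t).size != t.size:
            logger.warning("duplicate temperatures collapsed to mean ln k")
            uniq = np.unique(t)
            lnk = np.array([np.mean(np.log(k[t == u])) for u in uniq])
            t, k = uniq, np.exp(lnk)
        if t.size < 2:
            raise InvalidInputError("need >= 2 distinct temperatures")
        order = np.argsort(t)
        self.temperatures_c = t[order]
        self.k_per_h = k[order]

    @classmethod
    def from_fits(cls, fits: Mapping[float, KineticResults]) -> "ArrheniusModel":
        """Build from per-temperature kinetic fits (temperature °C -> results)."""
        temps = sorted(fits)
        return cls(temps, [fits[t].k for t in temps])

    def fit(self) -> ArrheniusResults:
        inv_t = 1.0 / _to_kelvin(self.temperatures_c)
        lf = ols_fit(inv_t, np.log(self.k_per_h))
        ea = -lf.slope * R_GAS
        se_ea = lf.sd_slope * R_GAS if np.isfinite(lf.sd_slope) else float("nan")
        return ArrheniusResults(
            slope_K=lf.slope,
            lnA=lf.intercept,
            Ea=ea,
            r_squared=lf.r_squared,
            n_temperatures=int(self.temperatures_c.size),
            se_Ea=se_ea,
            temperatures_c=self.temperatures_c,
            k_per_h=self.k_per_h,
            model=self,
        )


def arrhenius_fit(
    points: Mapping[float, float] | Sequence[tuple[float, float]]
) -> ArrheniusResults:
    """Fit the Arrhenius line from (temperature °C, k per hour) pairs."""
    if isinstance(points, Mapping):
        pairs = sorted(points.items())
    else:
        pairs = list(points)
    temps = [p[0] for p in pairs]
    ks = [p[1] for p in pairs]
    return ArrheniusModel(temps, ks).fit()


def predict_k(fit: ArrheniusResults, temperature_c: float) -> float:
    """Extrapolated rate constant at a temperature (see :class:`ArrheniusResults`)."""
    return fit.predict_k(temperature_c)


def predict_half_life(fit: ArrheniusResults, temperature_c: float) -> float:
    """Extrapolated first-order half-life, hours."""
    return fit.predict_half_life(temperature_c)
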