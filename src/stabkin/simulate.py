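"""Synthetic HPLC data with known ground truth.

No public instrument data exist for this assay, so every downstream stage is
exercised against simulated tables whose true parameters are known exactly:

* calibration tables from a linear detector response with multiplicative
  Gaussian noise (CV-type dispersion, matching how replicate precision is
  reported for such assays);
* percent-remaining degradation time courses from zero-, first- or
  second-order decay, with the rate either given directly or derived from an
  Arrhenius parameterisation (Ea, lnA, temperature);
* stress panels — one time course per incubation temperature — with a
  documented seed-splitting rule (per-temperature offset = panel index) so
  panels are reproducible element-wise;
* summary peak descriptors (widths at half and 5% height) from a Gaussian or
  exponentially-skewed peak shape, for system-suitability checks.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; a fixed seed yields bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrhenius import R_GAS, _to_kelvin
from .exceptions import InvalidInputError
from .kinetics import ORDERS, TimeCourse
from .validation import PeakDescriptor, _FWHM_FACTOR, _W5_FACTOR

__all__ = [
    "ResponseTruth",
    "KineticTruth",
    "PeakShape",
    "simulate_calibration",
    "simulate_timecourse",
    "simulate_stress_panel",
    "simulate_peak",
]

# Simulated percent-remaining floor: values below this are clamped (and
# counted) rather than emitted as ~0 or negative, keeping log transforms sane.
CLAMP_FLOOR_PCT = 0.1


@dataclass(frozen=True)
class ResponseTruth:
    """True detector-response line for simulation.

    Defaults mirror the validated assay's calibration line
    (slope 39.49 area/(µg/mL), intercept -8.39 area units) with 1%
    multiplicative noise.
    """

    slope: float = 39.49
    intercept: float = -8.39
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise InvalidInputError("slope must be positive")
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be non-negative")


@dataclass(frozen=True)
class KineticTruth:
    """True decay law for one simulated series.

    Exactly one of ``k`` (per hour) or the Arrhenius triple
    ``(Ea [J/mol], lnA [ln of 1/h], temperature_c)`` must supply the rate.
    ``c0`` is the initial percent (100 by default).
    """

    model: str = "first"
    k: float | None = None
    c0: float = 100.0
    Ea: float | None = None
    lnA: float | None = None
    temperature_c: float | None = None

    def __post_init__(self):
        if self.model not in ORDERS:
            raise InvalidInputError(f"model must be one of {ORDERS}")
        if self.c0 <= 0:
            raise InvalidInputError("c0 must be positive")
        arrhenius_given = (
            self.Ea is not None or self.lnA is not None or self.temperature_c is not None
        )
        if self.k is not None:
            if arrhenius_given:
                raise InvalidInputError("give either k or (Ea, lnA, temperature_c), not both")
            if self.k < 0:
                raise InvalidInputError("k must be non-negative")
        else:
            if None in (self.Ea, self.lnA, self.temperature_c):
                raise InvalidInputError("Arrhenius form needs Ea, lnA and temperature_c")

    @property
    def rate(self) -> float:
        """The per-hour rate constant, resolving the Arrhenius form if used."""
        if self.k is not None:
            return self.k
        t_k = float(_to_kelvin(self.temperature_c))
        return math.exp(self.lnA - self.Ea / (R_GAS * t_k))


@dataclass(frozen=True)
class PeakShape:
    """Chromatographic peak shape: apex position, width, and asymmetry.

    ``asymmetry`` is the ratio of the trailing to the leading Gaussian
    half-width (1 = symmetric; > 1 = tailing).
    """

    retention_time: float = 5.0
    sigma: float = 0.0845
    asymmetry: float = 1.0
    height: float = 1.0

    def __post_init__(self):
        if self.retention_time <= 0 or self.sigma <= 0 or self.asymmetry <= 0:
            raise InvalidInputError("retention_time, sigma and asymmetry must be positive")


def simulate_calibration(
    truth: ResponseTruth,
    levels: Sequence[float],
    replicates: int = 1,
    days: int = 1,
) -> pd.DataFrame:
    """Simulate a calibration table: one row per (day, replicate, level).

    ``area = (slope * conc + intercept) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_cv)``.  Reproducible for a fixed ``truth.seed``.

    Returns a DataFrame with columns ``day, replicate, conc_ugml, area``.
    """
    levels = [float(c) for c in levels]
    if not levels:
        raise InvalidInputError("levels must be non-empty")
    if any(c <= 0 for c in levels):
        raise InvalidInputError("all concentration levels must be positive")
    if replicates < 1 or days < 1:
        raise InvalidInputError("replicates and days must be >= 1")

    rng = np.random.default_rng(truth.seed)
    rows = []
    for day in range(1, days + 1):
        for rep in range(1, replicates + 1):
            for conc in levels:
                clean = truth.slope * conc + truth.intercept
                eps = rng.normal(0.0, truth.noise_cv) if truth.noise_cv > 0 else 0.0
                rows.append(
                    {"day": day, "replicate": rep, "conc_ugml": conc,
                     "area": clean * (1.0 + eps)}
                )
    return pd.DataFrame(rows)


def _clean_decay(truth: KineticTruth, t: np.ndarray) -> np.ndarray:
    k = truth.rate
    if truth.model == "first":
        return truth.c0 * np.exp(-k * t)
    if truth.model == "zero":
        return np.maximum(truth.c0 - k * t, 0.0)
    return 1.0 / (1.0 / truth.c0 + k * t)


def simulate_timecourse(
    truth: KineticTruth,
    times: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    condition: str = "simulated",
    temperature_c: float | None = None,
) -> TimeCourse:
    """Simulate one percent-remaining time course under a known decay law.

    Multiplicative Gaussian noise of relative SD ``noise_cv`` is applied to
    the clean decay; values falling below 0.1% remaining are clamped to the
    floor and counted in ``TimeCourse.n_clamped``.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise InvalidInputError("times must be non-empty")
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be non-negative")

    c = _clean_decay(truth, t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        c = c * (1.0 + rng.normal(0.0, noise_cv, size=c.size))
    low = c < CLAMP_FLOOR_PCT
    n_clamped = int(low.sum())
    c = np.where(low, CLAMP_FLOOR_PCT, c)

    temp = temperature_c
    if temp is None:
        temp = truth.temperature_c if truth.temperature_c is not None else float("nan")
    return TimeCourse(condition, float(temp), t, c, n_clamped=n_clamped)


def simulate_stress_panel(
    truths: Mapping[float, KineticTruth],
    times: Mapping[float, Sequence[float]] | Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    condition: str = "simulated",
) -> list[TimeCourse]:
    """Simulate one time course per incubation temperature.

    ``truths`` maps temperature (°C) to the decay law at that temperature;
    ``times`` is either a shared grid or a per-temperature mapping.  The
    per-temperature stream is seeded with ``seed + index`` (temperatures in
    ascending order), so the panel is reproducible element-wise and adding a
    temperature does not reshuffle the others.
    """
    temps = sorted(truths)
    if len(temps) < 2:
        raise InvalidInputError("a stress panel needs >= 2 temperatures")
    out = []
    for i, temp in enumerate(temps):
        grid = times[temp] if isinstance(times, Mapping) else times
        out.append(
            simulate_timecourse(
                truths[temp], grid, noise_cv=noise_cv, seed=seed + i,
                condition=condition, temperature_c=temp,
            )
        )
    return out


def simulate_peak(shape: PeakShape) -> PeakDescriptor:
    """Summary descriptor of a (possibly skewed) Gaussian peak.

    The leading half-width uses sigma and the trailing half-width
    ``asymmetry * sigma``, so for a symmetric shape
    ``width_at_half_height = 2 sqrt(2 ln 2) sigma`` and
    ``width_at_5pct = 2 sqrt(2 ln 20) sigma`` with the leading half exactly
    half of the 5% width (tailing factor 1).
    """
    s_lead = shape.sigma
    s_trail = shape.sigma * shape.asymmetry
    half_sum = (s_lead + s_trail) / 2.0
    return PeakDescriptor(
        retention_time=shape.retention_time,
        width_at_half_height=_FWHM_FACTOR * half_sum,
        width_at_5pct_height=_W5_FACTOR * half_sum,
        leading_half_width_at_5pct=(_W5_FACTOR / 2.0) * s_lead,
        area=shape.height * math.sqrt(math.pi / 2.0) * (s_lead + s_trail),
    )
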