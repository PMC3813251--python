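"""Method-validation statistics: precision/accuracy, recovery, stability, suitability.

These are the ICH-style figures of merit reported for a validated assay:
per-level precision (CV%) and accuracy (Error%) from replicate back-calculated
concentrations, relative recovery from spiked samples, stock-solution
stability, and USP system-suitability metrics (theoretical plates, tailing
factor, injection repeatability) derived from summary peak descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientReplicatesError, InvalidInputError

__all__ = [
    "PeakDescriptor",
    "SuitabilityLimits",
    "SuitabilityReport",
    "precision_accuracy",
    "relative_recovery",
    "solution_stability",
    "system_suitability",
]

# Gaussian width factors: FWHM = 2*sqrt(2 ln 2)*sigma, width at 5% height =
# 2*sqrt(2 ln 20)*sigma.
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))
_W5_FACTOR = 2.0 * np.sqrt(2.0 * np.log(20.0))


@dataclass(frozen=True)
class PeakDescriptor:
    """Summary description of one chromatographic peak.

    Widths are in the same time unit as the retention time (minutes by
    convention).  ``leading_half_width_at_5pct`` is the distance from the
    leading edge at 5% height to the peak apex (the "f" of the USP tailing
    factor).  ``area`` feeds injection-repeatability RSDs.
    """

    retention_time: float
    width_at_half_height: float
    width_at_5pct_height: float
    leading_half_width_at_5pct: float
    area: float = 1.0


@dataclass(frozen=True)
class SuitabilityLimits:
    """Pass/fail limits for system suitability (USP-style defaults)."""

    min_plate_count: float = 1500.0
    max_tailing_factor: float = 1.5
    max_rsd_pct: float = 1.0


@dataclass(frozen=True)
class SuitabilityReport:
    """System-suitability metrics with per-criterion pass flags."""

    rsd_retention_pct: float
    rsd_area_pct: float
    plate_count: float
    tailing_factor: float
    n_injections: int
    limits: SuitabilityLimits
    pass_flags: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.pass_flags.values())

    def summary(self) -> str:
        check = {True: "pass", False: "FAIL"}
        return "\n".join(
            [
                f"System suitability (n = {self.n_injections})",
                f"  Theoretical plates   {self.plate_count:.0f}"
                f"  (N > {self.limits.min_plate_count:.0f}: {check[self.pass_flags['plate_count']]})",
                f"  Tailing factor       {self.tailing_factor:.2f}"
                f"  (T < {self.limits.max_tailing_factor}: {check[self.pass_flags['tailing_factor']]})",
                f"  RSD retention (%)    {self.rsd_retention_pct:.2f}"
                f"  (RSD < {self.limits.max_rsd_pct}%: {check[self.pass_flags['rsd_retention']]})",
                f"  RSD peak area (%)    {self.rsd_area_pct:.2f}"
                f"  (RSD < {self.limits.max_rsd_pct}%: {check[self.pass_flags['rsd_area']]})",
            ]
        )


def precision_accuracy(groups: Mapping[float, Sequence[float]]) -> pd.DataFrame:
    """Per-level precision and accuracy from replicate measured concentrations.

    Parameters
    ----------
    groups : mapping
        Nominal concentration -> replicate back-calculated concentrations
        (at least two per group).

    Returns
    -------
    pandas.DataFrame
        Columns ``nominal, mean_measured, sd, cv_pct, error_pct``, one row per
        nominal level in ascending order.  SD uses the n-1 denominator,
        CV% = 100*sd/mean, Error% = 100*(mean - nominal)/nominal.
    """
    rows = []
    for nominal in sorted(groups):
        values = np.asarray(groups[nominal], dtype=float)
        if values.size < 2:
            raise InsufficientReplicatesError(
                f"group {nominal}: need >= 2 replicates, got {values.size}"
            )
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        rows.append(
            {
                "nominal": float(nominal),
                "mean_measured": mean,
                "sd": sd,
                "cv_pct": 100.0 * sd / mean,
                "error_pct": 100.0 * (mean - nominal) / nominal,
                "n": int(values.size),
            }
        )
    return pd.DataFrame(rows)


def relative_recovery(spiked_response: float, reference_response: float) -> float:
    """Percent recovery of a spiked sample relative to a matched standard."""
    if reference_response <= 0:
        raise InvalidInputError("reference response must be positive")
    return 100.0 * spiked_response / reference_response


def solution_stability(initial_response: float, stored_response: float) -> float:
    """Percent of the stock response remaining after storage."""
    if initial_response <= 0:
        raise InvalidInputError("initial response must be positive")
    return 100.0 * stored_response / initial_response


def _plate_count(d: PeakDescriptor, method: str) -> float:
    if method == "half_height":
        return 5.54 * (d.retention_time / d.width_at_half_height) ** 2
    if method == "tangent":
        # Tangent (4-sigma baseline) variant, assuming a Gaussian profile so
        # the base width can be recovered from the half-height width.
        sigma = d.width_at_half_height / _FWHM_FACTOR
        return 16.0 * (d.retention_time / (4.0 * sigma)) ** 2
    raise InvalidInputError(f"unknown plate-count method {method!r}")


def system_suitability(
    descriptors: Sequence[PeakDescriptor],
    limits: SuitabilityLimits | None = None,
    plate_method: str = "half_height",
) -> SuitabilityReport:
    """System-suitability report from replicate injection peak descriptors.

    Plate count uses the half-height formula ``N = 5.54 (tR / W_half)^2``
    (``plate_method="tangent"`` switches to the 4-sigma tangent variant);
    tailing factor is ``W_5% / (2 f)`` with ``f`` the leading half-width at
    5% height.  Both are averaged over injections; RSDs are the CV% of
    retention times and of peak areas.
    """
    if limits is None:
        limits = SuitabilityLimits()
    if len(descriptors) < 2:
        raise InvalidInputError("need >= 2 injections for RSD metrics")
    for d in descriptors:
        if min(d.width_at_half_height, d.width_at_5pct_height, d.leading_half_width_at_5pct) <= 0:
            raise InvalidInputError("peak widths must be positive")
        if d.retention_time <= 0:
            raise InvalidInputError("retention time must be positive")

    tr = np.array([d.retention_time for d in descriptors])
    areas = np.array([d.area for d in descriptors])
    plates = np.array([_plate_count(d, plate_method) for d in descriptors])
    tails = np.array(
        [d.width_at_5pct_height / (2.0 * d.leading_half_width_at_5pct) for d in descriptors]
    )

    rsd_tr = 100.0 * tr.std(ddof=1) / tr.mean()
    rsd_area = 100.0 * areas.std(ddof=1) / areas.mean()
    plate_count = float(plates.mean())
    tailing = float(tails.mean())

    flags = {
        "plate_count": plate_count > limits.min_plate_count,
        "tailing_factor": tailing < limits.max_tailing_factor,
        "rsd_retention": rsd_tr < limits.max_rsd_pct,
        "rsd_area": rsd_area < limits.max_rsd_pct,
    }
    return SuitabilityReport(
        rsd_retention_pct=float(rsd_tr),
        rsd_area_pct=float(rsd_area),
        plate_count=plate_count,
        tailing_factor=tailing,
        n_injections=len(descriptors),
        limits=limits,
        pass_flags=flags,
    )
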