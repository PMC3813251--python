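"""End-to-end pipeline: simulate (or load) → calibrate/validate → kinetics → Arrhenius.

A :class:`RunConfig` (built from a YAML file or a plain dict) describes one
reproducible run: the calibration design and detector truth, one or more
stress panels (per-temperature rate-constant truths or an input CSV), the
system-suitability design, and the pass/fail thresholds.  :func:`run_pipeline`
executes the stages in order, logging each one, and returns a
:class:`ReportBundle` whose tables mirror the standard reporting layout
(calibration statistics; precision/accuracy; suitability; per-temperature
kinetic table with columns Temperature / Equation / r² / k / t½; Arrhenius
report).  :func:`write_report` renders the bundle to CSV/JSON on disk; the
JSON summary has stable key order and full-precision values, while display
rounding (k to 3 decimals, t½ to 1, r² to 3) appears only in rendered tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .arrhenius import ArrheniusModel, ArrheniusResults
from .calibration import CalibrationResults, DetectionLimits, fit_calibration
from .exceptions import ConfigError, StabkinError
from .kinetics import KineticResults, TimeCourse, fit_kinetics
from .simulate import (
    KineticTruth,
    PeakShape,
    ResponseTruth,
    simulate_calibration,
    simulate_peak,
    simulate_stress_panel,
)
from .validation import (
    PeakDescriptor,
    SuitabilityLimits,
    SuitabilityReport,
    precision_accuracy,
    system_suitability,
)

__all__ = ["RunConfig", "PanelConfig", "ReportBundle", "run_pipeline",
           "write_report", "render_kinetics_table", "default_times"]

logger = logging.getLogger(__name__)


def default_times(k_per_h: float, n_points: int = 8) -> list[float]:
    """Sampling grid spanning two half-lives of a first-order decay."""
    horizon = 2.0 * math.log(2.0) / k_per_h
    return list(np.linspace(0.0, horizon, n_points))


@dataclass
class PanelConfig:
    """One stress panel: condition label, per-temperature truths or input CSV."""

    name: str
    condition: str
    half_life_unit: str = "h"
    noise_cv: float = 0.0
    truths: dict[float, float] = field(default_factory=dict)  # temp -> k (1/h)
    times: dict[float, list[float]] | list[float] | None = None
    input: str | None = None


@dataclass
class CalibrationConfig:
    levels: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 15.0, 20.0])
    replicates: int = 1
    days: int = 6
    slope: float = 39.49
    intercept: float = -8.39
    noise_cv: float = 0.01
    noise_sd: float = 2.633          # baseline noise (area units) for LOD
    loq_cv_threshold_pct: float = 1.5
    accuracy_levels: list[float] = field(default_factory=lambda: [1.0, 5.0, 20.0])
    accuracy_replicates: int = 3
    accuracy_days: int = 3
    input: str | None = None


@dataclass
class SuitabilityConfig:
    retention_time: float = 5.0
    sigma: float = 0.0845
    asymmetry: float = 1.0
    n_injections: int = 6
    retention_jitter_cv: float = 0.002
    area_jitter_cv: float = 0.005


@dataclass
class RunConfig:
    """Validated run configuration (see the README for the YAML schema)."""

    seed: int = 0
    output_dir: str = "stabkin_out"
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    panels: list[PanelConfig] = field(default_factory=list)
    suitability: SuitabilityConfig = field(default_factory=SuitabilityConfig)
    limits: SuitabilityLimits = field(default_factory=SuitabilityLimits)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        bad: list[str] = []
        if not isinstance(raw, Mapping):
            raise ConfigError("configuration must be a mapping")
        known = {"seed", "output_dir", "calibration", "panels", "suitability", "limits"}
        bad.extend(f"unknown key {k!r}" for k in raw if k not in known)

        if "panels" not in raw or not raw["panels"]:
            bad.append("panels: required section is missing or empty")
            panels = []
        else:
            panels = []
            for name, p in dict(raw["panels"]).items():
                p = dict(p)
                truths = {float(t): float(k) for t, k in dict(p.get("truths", {})).items()}
                if p.get("input") is None:
                    if len(truths) < 2:
                        bad.append(f"panels.{name}.truths: need >= 2 temperatures")
                    if any(k <= 0 for k in truths.values()):
                        bad.append(f"panels.{name}.truths: rate constants must be > 0")
                elif not Path(p["input"]).exists():
                    bad.append(f"panels.{name}.input: path {p['input']!r} does not exist")
                unit = p.get("half_life_unit", "h")
                if unit not in ("h", "min"):
                    bad.append(f"panels.{name}.half_life_unit: must be 'h' or 'min'")
                times = p.get("times")
                if isinstance(times, Mapping):
                    times = {float(t): [float(x) for x in v] for t, v in times.items()}
                elif times is not None:
                    times = [float(x) for x in times]
                panels.append(
                    PanelConfig(
                        name=str(name),
                        condition=str(p.get("condition", name)),
                        half_life_unit=unit,
                        noise_cv=float(p.get("noise_cv", 0.0)),
                        truths=truths,
                        times=times,
                        input=p.get("input"),
                    )
                )

        cal_raw = dict(raw.get("calibration", {}))
        cal = CalibrationConfig(**{k: v for k, v in cal_raw.items()
                                   if k in CalibrationConfig.__dataclass_fields__})
        bad.extend(f"calibration: unknown key {k!r}" for k in cal_raw
                   if k not in CalibrationConfig.__dataclass_fields__)
        if cal.input is not None and not Path(cal.input).exists():
            bad.append(f"calibration.input: path {cal.input!r} does not exist")
        if cal.loq_cv_threshold_pct <= 0 or cal.noise_sd <= 0:
            bad.append("calibration: thresholds must be positive")

        suit_raw = dict(raw.get("suitability", {}))
        suit = SuitabilityConfig(**{k: v for k, v in suit_raw.items()
                                    if k in SuitabilityConfig.__dataclass_fields__})
        bad.extend(f"suitability: unknown key {k!r}" for k in suit_raw
                   if k not in SuitabilityConfig.__dataclass_fields__)

        lim_raw = dict(raw.get("limits", {}))
        lim = SuitabilityLimits(**{k: v for k, v in lim_raw.items()
                                   if k in SuitabilityLimits.__dataclass_fields__})
        bad.extend(f"limits: unknown key {k!r}" for k in lim_raw
                   if k not in SuitabilityLimits.__dataclass_fields__)
        if min(lim.min_plate_count, lim.max_tailing_factor, lim.max_rsd_pct) <= 0:
            bad.append("limits: thresholds must be positive")

        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "stabkin_out")),
            calibration=cal,
            panels=panels,
            suitability=suit,
            limits=lim,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})


@dataclass
class PanelReport:
    config: PanelConfig
    timecourses: list[TimeCourse]
    fits: dict[float, KineticResults]
    arrhenius: ArrheniusResults


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, pre-rendering."""

    config: RunConfig
    calibration_table: pd.DataFrame
    calibration: CalibrationResults
    detection: DetectionLimits
    within_day: pd.DataFrame
    between_day: pd.DataFrame
    suitability: SuitabilityReport
    panels: dict[str, PanelReport]

    def summary_dict(self) -> dict:
        """Machine-readable summary (full precision, stable key order)."""
        out: dict[str, Any] = {
            "calibration": {
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept,
                "r_squared": self.calibration.r_squared,
                "sd_slope": self.calibration.sd_slope,
                "rsd_slope_pct": self.calibration.rsd_slope_pct,
                "sd_intercept": self.calibration.sd_intercept,
                "n_points": self.calibration.n_points,
                "lod_ugml": self.detection.lod,
                "loq_ugml": self.detection.loq if self.detection.loq_defined else None,
            },
            "suitability": {
                "plate_count": self.suitability.plate_count,
                "tailing_factor": self.suitability.tailing_factor,
                "rsd_retention_pct": self.suitability.rsd_retention_pct,
                "rsd_area_pct": self.suitability.rsd_area_pct,
                "all_pass": self.suitability.all_pass,
            },
            "precision_accuracy": {
                "within_day": self.within_day.to_dict(orient="records"),
                "between_day": self.between_day.to_dict(orient="records"),
            },
            "panels": {},
            "seed": self.config.seed,
        }
        for name, panel in sorted(self.panels.items()):
            out["panels"][name] = {
                "condition": panel.config.condition,
                "half_life_unit": panel.config.half_life_unit,
                "fits": {
                    f"{temp:g}": {
                        "slope": f.slope,
                        "intercept": f.intercept,
                        "r_squared": f.r_squared,
                        "k_per_h": f.k,
                        "t_half_h": f.t_half,
                    }
                    for temp, f in sorted(panel.fits.items())
                },
                "arrhenius": {
                    "slope_K": panel.arrhenius.slope_K,
                    "Ea_J_per_mol": panel.arrhenius.Ea,
                    "Ea_kJ_per_mol": panel.arrhenius.ea_kj,
                    "lnA": panel.arrhenius.lnA,
                    "r_squared": panel.arrhenius.r_squared,
                },
            }
        return out


def render_kinetics_table(
    fits: Mapping[float, KineticResults], half_life_unit: str = "h"
) -> pd.DataFrame:
    """Per-temperature kinetic table with the standard display rounding."""
    rows = []
    for temp in sorted(fits):
        f = fits[temp]
        th = f.t_half_display(half_life_unit)
        rows.append(
            {
                "Temperature_C": temp,
                "Equation": f.equation(),
                "r2": round(f.r_squared, 3),
                "k_per_h": round(f.k, 3),
                f"t_half_{half_life_unit}": round(th, 1) if np.isfinite(th) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _run_calibration_stage(cfg: RunConfig):
    cal = cfg.calibration
    truth = ResponseTruth(cal.slope, cal.intercept, cal.noise_cv, seed=cfg.seed)
    if cal.input is not None:
        table = skio.read_calibration_csv(cal.input)
        logger.info("calibration: loaded %d rows from %s", len(table), cal.input)
    else:
        table = simulate_calibration(truth, cal.levels, cal.replicates, cal.days)
        logger.info("calibration: simulated %d rows (%d levels x %d days x %d reps)",
                    len(table), len(cal.levels), cal.days, cal.replicates)
    fit = fit_calibration(table)
    logger.info("calibration: slope %.4f intercept %.4f r2 %.5f",
                fit.slope, fit.intercept, fit.r_squared)

    # Replicate accuracy study: fresh simulated injections back-calculated
    # through the fitted line, within-day (day 1) and pooled between-day.
    acc_truth = ResponseTruth(cal.slope, cal.intercept, cal.noise_cv, seed=cfg.seed + 1)
    acc = simulate_calibration(acc_truth, cal.accuracy_levels,
                               cal.accuracy_replicates, cal.accuracy_days)
    acc["measured"] = fit.back_calculate(acc["area"].to_numpy())
    day1 = acc[acc["day"] == 1]
    within = precision_accuracy(
        {lv: day1.loc[day1["conc_ugml"] == lv, "measured"].to_numpy()
         for lv in cal.accuracy_levels})
    between = precision_accuracy(
        {lv: acc.loc[acc["conc_ugml"] == lv, "measured"].to_numpy()
         for lv in cal.accuracy_levels})

    cv_by_level = {
        row["nominal"]: row["cv_pct"] for _, row in between.iterrows()
    }
    detection = fit.detection_limits(cal.noise_sd, cv_by_level, cal.loq_cv_threshold_pct)
    return table, fit, detection, within, between


def _run_suitability_stage(cfg: RunConfig) -> SuitabilityReport:
    s = cfg.suitability
    rng = np.random.default_rng(cfg.seed + 2)
    descriptors = []
    for _ in range(s.n_injections):
        tr = s.retention_time * (1.0 + rng.normal(0.0, s.retention_jitter_cv))
        base = simulate_peak(PeakShape(tr, s.sigma, s.asymmetry))
        descriptors.append(
            PeakDescriptor(
                retention_time=base.retention_time,
                width_at_half_height=base.width_at_half_height,
                width_at_5pct_height=base.width_at_5pct_height,
                leading_half_width_at_5pct=base.leading_half_width_at_5pct,
                area=base.area * (1.0 + rng.normal(0.0, s.area_jitter_cv)),
            )
        )
    report = system_suitability(descriptors, cfg.limits)
    logger.info("suitability: N=%.0f T=%.2f (pass=%s)",
                report.plate_count, report.tailing_factor, report.all_pass)
    return report


def _run_panel_stage(cfg: RunConfig, idx: int, pcfg: PanelConfig) -> PanelReport:
    if pcfg.input is not None:
        tcs = skio.read_timecourse_csv(pcfg.input)
        logger.info("panel %s: loaded %d time courses from %s",
                    pcfg.name, len(tcs), pcfg.input)
    else:
        truths = {t: KineticTruth(model="first", k=k) for t, k in pcfg.truths.items()}
        times = pcfg.times
        if times is None:
            times = {t: default_times(k) for t, k in pcfg.truths.items()}
        tcs = simulate_stress_panel(
            truths, times, noise_cv=pcfg.noise_cv,
            seed=cfg.seed + 100 * (idx + 1), condition=pcfg.condition,
        )
        logger.info("panel %s: simulated %d time courses", pcfg.name, len(tcs))
    fits = {tc.temperature_c: fit_kinetics(tc, order="first") for tc in tcs}
    for temp in sorted(fits):
        logger.debug("panel %s @ %g C: %s", pcfg.name, temp, fits[temp].summary())
    arr = ArrheniusModel.from_fits(fits).fit()
    logger.info("panel %s: Ea = %.1f kJ/mol (r2 %.4f)", pcfg.name, arr.ea_kj, arr.r_squared)
    return PanelReport(pcfg, tcs, fits, arr)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every stage; deterministic for a fixed ``config.seed``.

    Raises :class:`ConfigError` for malformed configuration and halts with
    the failing stage named for any downstream error.
    """
    stage = "calibration"
    try:
        table, fit, detection, within, between = _run_calibration_stage(config)
        stage = "suitability"
        suitability = _run_suitability_stage(config)
        panels = {}
        for idx, pcfg in enumerate(config.panels):
            stage = f"panel:{pcfg.name}"
            panels[pcfg.name] = _run_panel_stage(config, idx, pcfg)
    except StabkinError as exc:
        raise StabkinError(f"pipeline halted at stage {stage!r}: {exc}") from exc
    return ReportBundle(
        config=config,
        calibration_table=table,
        calibration=fit,
        detection=detection,
        within_day=within,
        between_day=between,
        suitability=suitability,
        panels=panels,
    )


def write_report(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    """Render the bundle to disk; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["calibration_table"] = out / "calibration_table.csv"
    skio.write_calibration_csv(bundle.calibration_table, paths["calibration_table"])

    pa = pd.concat(
        [bundle.within_day.assign(scope="within_day"),
         bundle.between_day.assign(scope="between_day")],
        ignore_index=True,
    )
    paths["precision_accuracy"] = out / "precision_accuracy.csv"
    pa.to_csv(paths["precision_accuracy"], index=False)

    for name, panel in sorted(bundle.panels.items()):
        tc_path = out / f"panel_{name}_timecourses.csv"
        skio.write_timecourse_csv(panel.timecourses, tc_path)
        paths[f"panel_{name}_timecourses"] = tc_path
        kt_path = out / f"panel_{name}_kinetics.csv"
        render_kinetics_table(panel.fits, panel.config.half_life_unit).to_csv(
            kt_path, index=False)
        paths[f"panel_{name}_kinetics"] = kt_path

    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(bundle.summary_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
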