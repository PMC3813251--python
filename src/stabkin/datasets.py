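"""Published reference values for the cetirizine dihydrochloride stress study.

These constants transcribe the published forced-degradation results for
cetirizine dihydrochloride (validated HPLC-UV assay; 2 M HCl and 0.5% H2O2
stress panels) and serve as inputs for reconstructions, cross-checks and the
worked examples: per-temperature linearized-plot slopes and intercepts, the
rounded apparent rate constants and half-lives as printed, the calibration
line, and the reported activation energies.

Note that the printed rate constants and half-lives are rounded to 3 and 1
decimals respectively; quantities recomputed from them (e.g. activation
energies) therefore differ slightly from the values the original unrounded
data gave.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PanelRow",
    "ReferencePanel",
    "ACID_PANEL",
    "PEROXIDE_PANEL",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "CALIBRATION_LEVELS_UGML",
    "CALIBRATION_R2",
]


@dataclass(frozen=True)
class PanelRow:
    """One temperature's published kinetic fit (first-order, log10 scale)."""

    temperature_c: float
    slope: float          # of log10(percent remaining) vs time (1/h)
    intercept: float      # log10 scale; 2.000 corresponds to 100%
    r_squared: float
    k_per_h: float        # printed apparent rate constant, 3 decimals
    t_half_display: float  # printed half-life, 1 decimal, in `half_life_unit`


@dataclass(frozen=True)
class ReferencePanel:
    """A published stress panel: condition, rows, and reported Ea."""

    condition: str
    half_life_unit: str   # display unit of t_half_display ("h" or "min")
    ea_reported_kj: float
    rows: tuple[PanelRow, ...]

    @property
    def temperatures_c(self) -> list[float]:
        return [r.temperature_c for r in self.rows]

    @property
    def k_by_temperature(self) -> dict[float, float]:
        return {r.temperature_c: r.k_per_h for r in self.rows}

    @property
    def slope_by_temperature(self) -> dict[float, float]:
        return {r.temperature_c: r.slope for r in self.rows}


#: Acid-mediated degradation (2 M HCl, 70-90 °C); half-lives printed in hours.
ACID_PANEL = ReferencePanel(
    condition="2 M HCl",
    half_life_unit="h",
    ea_reported_kj=121.8,
    rows=(
        PanelRow(70.0, -0.002, 2.003, 0.999, 0.005, 138.6),
        PanelRow(80.0, -0.006, 1.998, 0.992, 0.014, 49.5),
        PanelRow(85.0, -0.013, 2.000, 0.994, 0.030, 23.1),
        PanelRow(90.0, -0.027, 1.917, 0.991, 0.062, 11.2),
    ),
)

#: Oxidative degradation (0.5% H2O2, 50-80 °C); half-lives printed in minutes.
PEROXIDE_PANEL = ReferencePanel(
    condition="0.5% H2O2",
    half_life_unit="min",
    ea_reported_kj=36.3,
    rows=(
        PanelRow(50.0, -0.127, 1.997, 0.994, 0.293, 141.9),
        PanelRow(60.0, -0.193, 1.966, 0.994, 0.444, 93.6),
        PanelRow(70.0, -0.301, 2.037, 0.996, 0.693, 60.0),
        PanelRow(80.0, -0.409, 1.965, 0.999, 0.942, 44.1),
    ),
)

#: Published calibration line (peak area vs µg/mL) and its design.
CALIBRATION_SLOPE = 39.49
CALIBRATION_INTERCEPT = -8.39
CALIBRATION_LEVELS_UGML = (1.0, 2.0, 5.0, 10.0, 15.0, 20.0)
CALIBRATION_R2 = 0.9994
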