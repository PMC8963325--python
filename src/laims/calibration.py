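"""Matrix-matched external calibration with 3σ/10σ detection limits.

Calibration standards are gelatin blocks spiked with known zinc solutions:
spiking ``m`` grams of gelatin with ``v`` mL of a ``c`` µg/mL solution (spike
density taken as 1 g/mL for aqueous standards) yields a nominal concentration
``c·v / (m + v)`` µg/g — the standard recipe of 100 mg gelatin + 900 µL of
1…500 µg/mL solutions gives the 0.9…450 µg/g range.

Each standard is ablated as several lines; line means are averaged and fitted
against nominal concentration by ordinary least squares.  The limit of
detection (quantification) is 3 (10) times the standard deviation of the
blank's line means divided by the slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .raw_io import CONCENTRATION, INTENSITY, ElementMap, LineScanSet


@dataclass
class StandardLevel:
    """One calibration level: recipe, nominal value, and measured summary."""

    nominal_conc_ugg: float
    line_means_cps: np.ndarray
    mean_intensity_cps: float
    rsd_pct: float
    solution_conc_ug_ml: float | None = None
    spike_volume_ml: float | None = None
    gelatin_mass_g: float | None = None


@dataclass
class CalibrationModel:
    """Linear intensity-vs-concentration model with detection limits."""

    slope_cps_per_ugg: float
    intercept_cps: float
    r_squared: float
    sigma_blank_cps: float
    lod_ugg: float
    loq_ugg: float
    levels: list[StandardLevel] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slope_cps_per_ugg": self.slope_cps_per_ugg,
            "intercept_cps": self.intercept_cps,
            "r_squared": self.r_squared,
            "sigma_blank_cps": self.sigma_blank_cps,
            "lod_ugg": self.lod_ugg,
            "loq_ugg": self.loq_ugg,
            "levels": [
                {"nominal_conc_ugg": lv.nominal_conc_ugg,
                 "mean_intensity_cps": lv.mean_intensity_cps,
                 "rsd_pct": lv.rsd_pct,
                 "n_lines": int(len(lv.line_means_cps))}
                for lv in self.levels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(slope_cps_per_ugg=float(d["slope_cps_per_ugg"]),
                   intercept_cps=float(d["intercept_cps"]),
                   r_squared=float(d["r_squared"]),
                   sigma_blank_cps=float(d["sigma_blank_cps"]),
                   lod_ugg=float(d["lod_ugg"]), loq_ugg=float(d["loq_ugg"]))


def standard_concentration(gelatin_mass_g: float, spike_volume_ml: float,
                           solution_conc_ug_ml: float) -> float:
    """Nominal concentration (µg/g) of a spiked gelatin standard.

    Mass of the aqueous spike = volume × 1 g/mL, so
    conc = c·v / (m + v).
    """
    if gelatin_mass_g <= 0 or spike_volume_ml <= 0:
        raise ValueError("gelatin mass and spike volume must be positive")
    if solution_conc_ug_ml < 0:
        raise ValueError("solution concentration must be non-negative")
    return solution_conc_ug_ml * spike_volume_ml / (gelatin_mass_g + spike_volume_ml)


def summarize_standard(ls: LineScanSet, channel: str
                       ) -> tuple[float, float, np.ndarray]:
    """Per-line means, their grand mean, and the between-line RSD (%).

    RSD uses the sample standard deviation (n−1) of the line means; at least
    two lines are required.
    """
    if ls.n_lines < 2:
        raise ValueError("need at least 2 lines to estimate a between-line RSD")
    if channel not in ls.channel_names:
        raise ValueError(f"channel {channel!r} not present")
    line_means = np.array([float(np.mean(line[channel].intensities_cps))
                           for line in ls.lines])
    mean_intensity = float(np.mean(line_means))
    if mean_intensity == 0:
        raise ValueError("mean intensity is zero; RSD undefined")
    rsd = 100.0 * float(np.std(line_means, ddof=1)) / mean_intensity
    return mean_intensity, rsd, line_means


def make_level(ls: LineScanSet, channel: str, nominal_conc_ugg: float,
               **recipe) -> StandardLevel:
    mean, rsd, line_means = summarize_standard(ls, channel)
    return StandardLevel(nominal_conc_ugg=float(nominal_conc_ugg),
                         line_means_cps=line_means, mean_intensity_cps=mean,
                         rsd_pct=rsd, **recipe)


def fit_calibration(levels: list[StandardLevel]) -> CalibrationModel:
    """Ordinary least squares of mean intensity on nominal concentration.

    Requires >= 3 levels including a blank with distinct concentrations;
    the blank's line-mean scatter provides σ for the 3σ/10σ limits.
    """
    if len(levels) < 3:
        raise ValueError("need at least 3 calibration levels")
    concs = np.array([lv.nominal_conc_ugg for lv in levels])
    if len(set(concs.tolist())) < 2:
        raise ValueError("calibration levels have no concentration spread")
    blanks = [lv for lv in levels if lv.nominal_conc_ugg == 0]
    if not blanks:
        raise ValueError("no blank level: LOD/LOQ undefined")
    intens = np.array([lv.mean_intensity_cps for lv in levels])
    fit = stats.linregress(concs, intens)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope ({slope:.4g})")
    sigma_blank = float(np.std(blanks[0].line_means_cps, ddof=1))
    return CalibrationModel(
        slope_cps_per_ugg=slope,
        intercept_cps=intercept,
        r_squared=float(fit.rvalue) ** 2,
        sigma_blank_cps=sigma_blank,
        lod_ugg=3.0 * sigma_blank / slope,
        loq_ugg=10.0 * sigma_blank / slope,
        levels=sorted(levels, key=lambda lv: lv.nominal_conc_ugg),
    )


def quantify_map(emap: ElementMap, cal: CalibrationModel) -> ElementMap:
    """Back-calculate concentrations: (intensity − intercept)/slope, floored
    at 0 (concentrations are physical)."""
    if emap.value_kind != INTENSITY:
        raise ValueError("quantify_map expects an intensity-kind map")
    if cal.slope_cps_per_ugg <= 0:
        raise ValueError("calibration slope must be positive")
    conc = (emap.grid - cal.intercept_cps) / cal.slope_cps_per_ugg
    return emap.with_grid(np.maximum(conc, 0.0), value_kind=CONCENTRATION)
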