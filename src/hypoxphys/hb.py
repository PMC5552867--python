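"""Hemoglobin-O2 equilibrium curve analysis.

Absorbance plateaus measured at a series of %O2 gas steps are normalized
to fractional saturation between the fully deoxygenated (0% O2) and fully
oxygenated (100% O2) endpoints, linearized on a Hill plot
log10(S/(1-S)) vs log10(PO2), and fitted by OLS.  The fitted line gives
the Hill coefficient n_H (slope) and P50 = 10^(-intercept/slope).  Bohr
coefficients phi = d log10(P50) / d pH are estimated by OLS across
hemolysates run at several pH values, with pairwise two-point values also
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gas import WaterConditions, water_vapor_pressure_mmhg

__all__ = [
    "OECurve",
    "HillFit",
    "BohrResult",
    "percent_o2_to_po2",
    "saturation_from_absorbance",
    "fit_hill",
    "bohr_coefficient",
    "read_plate_csv",
]


def percent_o2_to_po2(
    gas_percent: float,
    conditions: WaterConditions,
    humidified: bool = True,
) -> float:
    """PO2 (mmHg) of a gas mixture containing ``gas_percent`` % O2.

    Tonometry gas equilibrated with an aqueous sample is water-saturated,
    so by default the saturated vapor pressure at the assay temperature is
    subtracted from barometric pressure; ``humidified=False`` gives the
    dry-gas value.
    """
    if not 0.0 <= gas_percent <= 100.0:
        raise ValueError(f"gas percent must lie in [0, 100], got {gas_percent}")
    p = conditions.barometric_pressure
    if humidified:
        p = p - water_vapor_pressure_mmhg(conditions.temperature)
    return gas_percent / 100.0 * p


@dataclass
class OECurve:
    """One hemolysate's O2 equilibrium data at a known pH and temperature."""

    gas_percent_o2: np.ndarray
    po2: np.ndarray
    absorbance: np.ndarray
    ph: float
    temperature: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.gas_percent_o2 = np.asarray(self.gas_percent_o2, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if not len(self.gas_percent_o2) == len(self.po2) == len(self.absorbance):
            raise ValueError("curve columns must have equal length")
        if 0.0 not in self.gas_percent_o2 or 100.0 not in self.gas_percent_o2:
            raise ValueError("curve must include 0% (deoxy) and 100% (oxy) endpoints")
        order = np.argsort(self.gas_percent_o2)
        if not np.all(np.diff(self.po2[order]) > 0):
            raise ValueError("po2 must increase strictly with gas_percent_o2")


@dataclass
class HillFit:
    """OLS fit of the Hill plot; slope is the Hill coefficient n_H."""

    slope: float
    intercept: float
    p50: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    p50_interpolated: float | None = None  # direct S=0.5 crossing diagnostic


@dataclass
class BohrResult:
    """Bohr coefficient phi = d log10 P50 / d pH."""

    phi: float
    ph_values: list[float]
    p50_values: list[float]
    fit_method: str
    pairwise: dict[tuple[float, float], float] = field(default_factory=dict)


def saturation_from_absorbance(curve: OECurve) -> np.ndarray:
    """Fractional saturation S = (A - A_0%) / (A_100% - A_0%) per step.

    Values may fall slightly outside [0, 1] under noise; they are
    returned as-is (the Hill fit excludes non-finite logit points).
    """
    a0 = float(curve.absorbance[curve.gas_percent_o2 == 0.0][0])
    a100 = float(curve.absorbance[curve.gas_percent_o2 == 100.0][0])
    if a100 == a0:
        raise ValueError("coincident deoxy/oxy endpoints: no dynamic range")
    return (curve.absorbance - a0) / (a100 - a0)


def fit_hill(
    saturation: np.ndarray,
    po2: np.ndarray,
    window: tuple[float, float] = (0.2, 0.8),
) -> HillFit:
    """Fit log10(S/(1-S)) = n_H * log10(PO2) + intercept over a window.

    Only points with saturation strictly inside ``window`` (default
    (0.2, 0.8), exclusive) enter the regression; S of exactly 0 or 1 has
    no logit and is always excluded.  P50 = 10^(-intercept/slope).  A
    direct linear interpolation of the S = 0.5 crossing is attached as a
    diagnostic.
    """
    s = np.asarray(saturation, dtype=float)
    p = np.asarray(po2, dtype=float)
    lo, hi = window
    m = (s > lo) & (s < hi) & (p > 0)
    if int(m.sum()) < 3:
        raise ValueError(
            f"need >= 3 points with saturation in ({lo}, {hi}); got {int(m.sum())}"
        )
    x = np.log10(p[m])
    y = np.log10(s[m] / (1.0 - s[m]))
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - ybar))) / sxx
    intercept = ybar - slope * xbar
    sst = float(np.sum((y - ybar) ** 2))
    sse = float(np.sum((y - (intercept + slope * x)) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    p50 = 10.0 ** (-intercept / slope)

    # Diagnostic: direct interpolation of the S = 0.5 crossing in PO2.
    p50_interp = None
    order = np.argsort(p)
    ss, pp = s[order], p[order]
    for i in range(len(ss) - 1):
        if (ss[i] - 0.5) * (ss[i + 1] - 0.5) <= 0 and ss[i] != ss[i + 1]:
            p50_interp = float(
                pp[i] + (0.5 - ss[i]) * (pp[i + 1] - pp[i]) / (ss[i + 1] - ss[i])
            )
            break
    return HillFit(
        slope=slope,
        intercept=intercept,
        p50=p50,
        r_squared=r2,
        n_points=int(m.sum()),
        window=window,
        p50_interpolated=p50_interp,
    )


def fit_curve(curve: OECurve, window: tuple[float, float] = (0.2, 0.8)) -> HillFit:
    """Convenience: normalize a curve to saturation and fit the Hill plot."""
    return fit_hill(saturation_from_absorbance(curve), curve.po2, window=window)


def bohr_coefficient(fits: list[tuple[float, HillFit | float]]) -> BohrResult:
    """Bohr coefficient from (pH, P50) pairs.

    phi is the OLS slope of log10(P50) on pH over all pairs; with exactly
    two pH values this equals delta log10 P50 / delta pH.  All pairwise
    two-point coefficients are also reported.
    """
    if len(fits) < 2:
        raise ValueError("Bohr coefficient needs >= 2 (pH, P50) pairs")
    ph = np.array([p for p, _ in fits], dtype=float)
    if len(np.unique(ph)) < 2:
        raise ValueError("Bohr coefficient needs >= 2 distinct pH values")
    p50 = np.array(
        [f.p50 if isinstance(f, HillFit) else float(f) for _, f in fits], dtype=float
    )
    y = np.log10(p50)
    phbar = ph.mean()
    phi = float(np.sum((ph - phbar) * (y - y.mean())) / np.sum((ph - phbar) ** 2))
    pairwise: dict[tuple[float, float], float] = {}
    for i in range(len(ph)):
        for j in range(i + 1, len(ph)):
            if ph[i] != ph[j]:
                pairwise[(float(min(ph[i], ph[j])), float(max(ph[i], ph[j])))] = float(
                    (y[j] - y[i]) / (ph[j] - ph[i])
                )
    return BohrResult(
        phi=phi,
        ph_values=[float(v) for v in ph],
        p50_values=[float(v) for v in p50],
        fit_method="ols" if len(ph) > 2 else "two-point",
        pairwise=pairwise,
    )


def read_plate_csv(path, conditions: WaterConditions, humidified: bool = True) -> list[OECurve]:
    """Read a plate CSV (sample_id, ph, gas_percent_o2, absorbance).

    One OECurve is built per (sample_id, ph) group; PO2 per step is
    derived from the gas %O2 under the given water conditions.
    """
    df = pd.read_csv(path)
    curves = []
    for (sid, ph), g in df.groupby(["sample_id", "ph"], sort=True):
        g = g.sort_values("gas_percent_o2")
        po2 = np.array(
            [percent_o2_to_po2(x, conditions, humidified) for x in g["gas_percent_o2"]]
        )
        curves.append(
            OECurve(
                gas_percent_o2=g["gas_percent_o2"].to_numpy(),
                po2=po2,
                absorbance=g["absorbance"].to_numpy(),
                ph=float(ph),
                temperature=conditions.temperature,
                sample_id=str(sid),
            )
        )
    return curves
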