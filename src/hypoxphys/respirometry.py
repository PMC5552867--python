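"""Intermittent-flow respirometry analysis: cycle slopes, MO2, SMR, Pcrit.

The chain is: fit an OLS line to the PO2 decline in the last part of each
closed cycle, convert the slope to a mass-specific oxygen uptake

    MO2 = -dPO2/dt * alpha_O2 * (V_chamber - M_f) / M_f   [umol kg-1 min-1]

subtract background (microbial) respiration assuming it ramps linearly in
time between pre- and post-trial measurements, take the mean of the lowest
10% of retained MO2 records as the standard metabolic rate (SMR), and
locate the critical oxygen tension (Pcrit) of a continuous closed run as
the PO2 where binned MO2 first drops below SMR for good, interpolating
linearly between the bracketing bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gas import WaterConditions, o2_solubility

__all__ = [
    "O2Trace",
    "ChamberSetup",
    "CycleRegression",
    "MO2Series",
    "SMREstimate",
    "PcritEstimate",
    "fit_cycle_slopes",
    "mo2_from_slope",
    "background_correct",
    "estimate_smr",
    "estimate_pcrit",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass
class O2Trace:
    """A time-stamped chamber-PO2 record with phase labels.

    ``time_min`` must be strictly increasing; ``phase`` holds "flush" or
    "closed" per sample and ``cycle`` the measurement-cycle index.
    """

    time_min: np.ndarray
    po2: np.ndarray
    phase: np.ndarray
    cycle: np.ndarray
    clipped_at_zero: bool = False

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        self.cycle = np.asarray(self.cycle, dtype=int)
        n = len(self.time_min)
        if not (len(self.po2) == len(self.phase) == len(self.cycle) == n):
            raise ValueError("trace columns must have equal length")
        if n > 1 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time must be strictly increasing")
        bad = set(np.unique(self.phase)) - {"flush", "closed"}
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "po2_mmHg": self.po2,
                "phase": self.phase,
                "cycle": self.cycle,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "O2Trace":
        return cls(
            time_min=df["time_min"].to_numpy(),
            po2=df["po2_mmHg"].to_numpy(),
            phase=df["phase"].to_numpy(),
            cycle=df["cycle"].to_numpy(),
        )

    def closed_cycles(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        """Return (cycle_index, time, po2) for every closed phase."""
        out = []
        mask_closed = self.phase == "closed"
        for idx in np.unique(self.cycle[mask_closed]):
            m = mask_closed & (self.cycle == idx)
            out.append((int(idx), self.time_min[m], self.po2[m]))
        return out


def read_trace_csv(path) -> O2Trace:
    """Read a trace CSV with columns time_min, po2_mmHg, phase, cycle."""
    return O2Trace.from_frame(pd.read_csv(path))


def write_trace_csv(trace: O2Trace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ChamberSetup:
    """Respirometer geometry: chamber volume (L), fish mass (kg), water."""

    v_chamber: float
    m_f: float
    conditions: WaterConditions

    def __post_init__(self) -> None:
        # A fish of mass m_f kg displaces ~m_f L; effective volume must be positive.
        if not self.v_chamber > self.m_f > 0:
            raise ValueError(
                f"require v_chamber > m_f > 0, got V={self.v_chamber}, M_f={self.m_f}"
            )

    @property
    def effective_volume(self) -> float:
        return self.v_chamber - self.m_f


@dataclass
class CycleRegression:
    """OLS fit of the PO2 decline over one closed-cycle window."""

    cycle_index: int
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    window: tuple[float, float]
    mean_po2: float
    retained: bool
    flag: str = ""


@dataclass
class MO2Series:
    """Per-cycle oxygen-uptake records (umol kg-1 min-1)."""

    time: np.ndarray
    mo2: np.ndarray
    mean_po2: np.ndarray
    retained: np.ndarray
    background_corrected: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mo2 = np.asarray(self.mo2, dtype=float)
        self.mean_po2 = np.asarray(self.mean_po2, dtype=float)
        self.retained = np.asarray(self.retained, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time,
                "mo2_umol_kg_min": self.mo2,
                "mean_po2_mmHg": self.mean_po2,
                "retained": self.retained,
                "background_corrected": self.background_corrected,
            }
        )


@dataclass
class SMREstimate:
    """Standard metabolic rate: mean of the lowest-quantile MO2 records."""

    value: float
    quantile_fraction: float
    n_used: int
    n_total: int
    units: str = "umol/kg/min"


@dataclass
class PcritEstimate:
    """Critical oxygen tension from the binned SMR-crossing rule."""

    value: float
    method: str
    bin_minutes: float
    censored: bool
    first_bin_below: float | None
    diagnostics: pd.DataFrame | None = None


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 of y on t.  R^2 is nan for zero-variance y."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0.0:
        return slope, intercept, math.nan
    sse = float(np.sum((y - (intercept + slope * t)) ** 2))
    return slope, intercept, 1.0 - sse / sst


def fit_cycle_slopes(
    trace: O2Trace,
    window_min: float = 2.0,
    r2_threshold: float = 0.95,
) -> list[CycleRegression]:
    """Fit an OLS line to the last ``window_min`` minutes of each closed cycle.

    Cycles with fewer than 3 samples in the window are flagged and not
    fitted; cycles whose R^2 falls below ``r2_threshold`` (or is undefined
    because PO2 was constant) are fitted but marked not retained.
    """
    cycles = trace.closed_cycles()
    if not cycles:
        raise ValueError("trace contains no closed cycles")
    out: list[CycleRegression] = []
    for idx, t, y in cycles:
        t_end = t[-1]
        m = t >= t_end - window_min
        tw, yw = t[m], y[m]
        if len(tw) < 3:
            out.append(
                CycleRegression(
                    cycle_index=idx,
                    slope=math.nan,
                    intercept=math.nan,
                    r_squared=math.nan,
                    n_points=len(tw),
                    window=(float(tw[0]) if len(tw) else math.nan, float(t_end)),
                    mean_po2=float(yw.mean()) if len(yw) else math.nan,
                    retained=False,
                    flag="too_few_points",
                )
            )
            continue
        slope, intercept, r2 = _ols_line(tw, yw)
        if math.isnan(r2):
            retained, flag = False, "degenerate_constant_po2"
        elif r2 < r2_threshold:
            retained, flag = False, "low_r2"
        else:
            retained, flag = True, ""
        out.append(
            CycleRegression(
                cycle_index=idx,
                slope=slope,
                intercept=intercept,
                r_squared=r2,
                n_points=len(tw),
                window=(float(tw[0]), float(t_end)),
                mean_po2=float(yw.mean()),
                retained=retained,
                flag=flag,
            )
        )
    return out


def mo2_from_slope(reg: CycleRegression, setup: ChamberSetup) -> float:
    """Mass-specific oxygen uptake (umol kg-1 min-1) from a cycle slope.

    MO2 = -slope * alpha * (V_chamber - M_f) / M_f, with alpha the O2
    solubility (umol L-1 mmHg-1) at the chamber water conditions.
    """
    alpha = o2_solubility(setup.conditions)
    return -reg.slope * alpha * setup.effective_volume / setup.m_f


def mo2_series_from_trace(
    trace: O2Trace,
    setup: ChamberSetup,
    window_min: float = 2.0,
    r2_threshold: float = 0.95,
) -> MO2Series:
    """Full per-cycle MO2 series for a flush/closed trace."""
    regs = fit_cycle_slopes(trace, window_min=window_min, r2_threshold=r2_threshold)
    regs_ok = [r for r in regs if r.n_points >= 3]
    time = np.array([0.5 * (r.window[0] + r.window[1]) for r in regs_ok])
    mo2 = np.array([mo2_from_slope(r, setup) for r in regs_ok])
    return MO2Series(
        time=time,
        mo2=mo2,
        mean_po2=np.array([r.mean_po2 for r in regs_ok]),
        retained=np.array([r.retained for r in regs_ok]),
    )


def background_correct(
    series: MO2Series,
    pre_rate: float,
    post_rate: float,
    t_start: float,
    t_end: float,
) -> MO2Series:
    """Subtract a linear-in-time background respiration ramp from a series.

    ``pre_rate`` and ``post_rate`` are background rates in the same units
    as the series values (umol kg-1 min-1 equivalents, i.e. chamber-level
    background divided by fish mass), measured at ``t_start`` and
    ``t_end``.  Records whose corrected MO2 goes negative are flagged and
    marked not retained, never silently dropped.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    flags = list(series.flags)
    if post_rate < pre_rate:
        flags.append("declining_background")
    frac = (series.time - t_start) / (t_end - t_start)
    bg = pre_rate + frac * (post_rate - pre_rate)
    corrected = series.mo2 - bg
    retained = series.retained.copy()
    neg = corrected < 0
    if np.any(neg & retained):
        flags.append(f"negative_after_correction:{int(np.sum(neg & retained))}")
    retained = retained & ~neg
    return MO2Series(
        time=series.time.copy(),
        mo2=corrected,
        mean_po2=series.mean_po2.copy(),
        retained=retained,
        background_corrected=True,
        flags=flags,
    )


def estimate_smr(series: MO2Series, quantile_fraction: float = 0.10) -> SMREstimate:
    """SMR as the mean of the lowest ``quantile_fraction`` of retained MO2.

    The count is ceil(fraction * n) so at least one record is always used.
    Requires at least 10 retained records.
    """
    if not 0 < quantile_fraction <= 1:
        raise ValueError("quantile_fraction must lie in (0, 1]")
    vals = np.sort(series.mo2[series.retained])
    n = len(vals)
    if n < 10:
        raise ValueError(
            f"SMR requires >= 10 retained MO2 records, got {n}"
        )
    k = math.ceil(quantile_fraction * n)
    return SMREstimate(
        value=float(vals[:k].mean()),
        quantile_fraction=quantile_fraction,
        n_used=k,
        n_total=n,
    )


def _bin_closed_run(
    closed_run: O2Trace, setup: ChamberSetup, bin_minutes: float
) -> pd.DataFrame:
    """Per-bin MO2 and mean PO2 over consecutive, non-overlapping bins."""
    m = closed_run.phase == "closed"
    t = closed_run.time_min[m]
    y = closed_run.po2[m]
    if len(t) < 3:
        raise ValueError("closed run has too few samples")
    alpha = o2_solubility(setup.conditions)
    t0 = t[0]
    n_bins = int(math.floor((t[-1] - t0) / bin_minutes))
    rows = []
    for i in range(n_bins):
        lo, hi = t0 + i * bin_minutes, t0 + (i + 1) * bin_minutes
        sel = (t >= lo) & (t < hi) if i < n_bins - 1 else (t >= lo) & (t <= hi)
        if int(sel.sum()) < 3:
            continue
        slope, _, r2 = _ols_line(t[sel], y[sel])
        mo2 = -slope * alpha * setup.effective_volume / setup.m_f
        rows.append(
            {"bin": i, "t_mid": 0.5 * (lo + hi), "mean_po2": float(y[sel].mean()),
             "mo2": mo2, "r_squared": r2, "n_points": int(sel.sum())}
        )
    return pd.DataFrame(rows)


def estimate_pcrit(
    closed_run: O2Trace,
    smr: SMREstimate | float,
    setup: ChamberSetup,
    bin_minutes: float = 2.0,
) -> PcritEstimate:
    """Pcrit of a continuous closed run by the SMR-crossing rule.

    The run is partitioned into consecutive ``bin_minutes`` bins; each bin
    yields an MO2 (slope of PO2 decline scaled by chamber geometry and O2
    solubility) plotted against its mean PO2.  Pcrit is the PO2 where MO2
    crosses below SMR for good (the crossing belonging to the terminal
    run of below-SMR bins, which is robust to isolated noisy bins).  The
    crossing PO2 is interpolated on the conforming limb: an OLS line
    through the terminal below-SMR bins (the bin straddling the
    breakpoint is dropped when at least three below bins exist) is
    extrapolated up to MO2 = SMR.  Above the breakpoint an oxyregulator's
    MO2 sits flat at SMR, so a two-point interpolation between the
    bracketing bins is degenerate there; it is used only as a fallback
    when a single below-SMR bin exists.  The mean PO2 of the first
    below-SMR bin is also reported as a conservative variant
    (``first_bin_below``).  If MO2 never drops below SMR the estimate is
    censored at the minimum observed PO2.
    """
    smr_value = smr.value if isinstance(smr, SMREstimate) else float(smr)
    bins = _bin_closed_run(closed_run, setup, bin_minutes)
    if bins.empty:
        raise ValueError("no usable bins in closed run")
    raw_min = float(closed_run.po2[closed_run.phase == "closed"].min())
    mo2 = bins["mo2"].to_numpy()
    po2 = bins["mean_po2"].to_numpy()
    # relative tolerance so an oxyregulator plateau sitting exactly at SMR
    # is not split by floating-point jitter
    below = mo2 < smr_value * (1.0 - 1e-9)
    if not below.any():
        return PcritEstimate(
            value=raw_min,
            method="censored-at-minimum",
            bin_minutes=bin_minutes,
            censored=True,
            first_bin_below=None,
            diagnostics=bins,
        )
    if below.all():
        # Conforming from the very start: crossing not observed above the run.
        return PcritEstimate(
            value=float(po2.max()),
            method="censored-at-maximum",
            bin_minutes=bin_minutes,
            censored=True,
            first_bin_below=float(po2[0]),
            diagnostics=bins,
        )
    # Crossing at the start of the terminal run of below-SMR bins: robust to
    # isolated noisy bins dipping below SMR earlier in the run.
    j = int(np.max(np.nonzero(~below)[0]))
    if j + 1 >= len(mo2):
        return PcritEstimate(
            value=raw_min,
            method="censored-at-minimum",
            bin_minutes=bin_minutes,
            censored=True,
            first_bin_below=None,
            diagnostics=bins,
        )
    m0, p0 = mo2[j], po2[j]
    below_idx = np.arange(j + 1, len(mo2))
    p1 = po2[below_idx[0]]
    if len(below_idx) >= 2:
        idx = below_idx[1:] if len(below_idx) >= 3 else below_idx
        pb, mb = po2[idx], mo2[idx]
        pbar, mbar = pb.mean(), mb.mean()
        sxx = float(np.sum((pb - pbar) ** 2))
        if sxx > 0:
            slope = float(np.sum((pb - pbar) * (mb - mbar))) / sxx
        else:
            slope = 0.0
        if slope > 0:
            value = pbar + (smr_value - mbar) / slope
        else:  # conformer limb should rise with PO2; fall back to two-point
            value = _two_point_crossing(p0, m0, p1, mo2[j + 1], smr_value)
    else:
        value = _two_point_crossing(p0, m0, p1, mo2[j + 1], smr_value)
    value = float(np.clip(value, po2.min(), p0))
    return PcritEstimate(
        value=value,
        method="first-crossing-interpolated",
        bin_minutes=bin_minutes,
        censored=False,
        first_bin_below=float(p1),
        diagnostics=bins,
    )


def _two_point_crossing(p0, m0, p1, m1, smr_value) -> float:
    if m1 == m0:
        return float(p1)
    return float(p0 + (smr_value - m0) * (p1 - p0) / (m1 - m0))
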