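"""Synthetic data generation with known ground truth.

Every analysis stage in this package can be validated by parameter
recovery: a generator here produces data under a known fish / hemoglobin
/ assay model, and the corresponding estimator must recover the model
parameters.  Generators cover:

* intermittent-flow respirometry PO2 traces driven by a
  regulator/conformer fish model (constant oxygen uptake above a true
  critical tension, uptake proportional to PO2 below it) plus a linearly
  ramping chamber-background respiration and Poisson activity bursts;
* single continuous closed-circuit declines for Pcrit trials;
* plate-spectrophotometer O2 equilibrium curves under a Hill saturation
  model with a pH-dependent P50 (Bohr model);
* qPCR ct tables generated from true relative transcript abundances
  under stated per-primer amplification efficiencies;
* gill morphometry measurement sets consistent with a true mass-specific
  surface area.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gas import WaterConditions, o2_solubility
from .gill import GillMorphometry
from .hb import OECurve, percent_o2_to_po2
from .qpcr import CtTable
from .respirometry import O2Trace

__all__ = [
    "FishModel",
    "TraceSimConfig",
    "TraceTruth",
    "simulate_trace",
    "simulate_closed_pcrit_run",
    "simulate_oec_plate",
    "simulate_ct_table",
    "simulate_morphometry",
    "OEC_GAS_STEPS",
]

#: %O2 steps of the equilibrium assay gas series.
OEC_GAS_STEPS = (0.0, 0.05, 0.1, 0.15, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0,
                 5.0, 8.0, 12.0, 21.0, 100.0)


@dataclass(frozen=True)
class FishModel:
    """Ground-truth fish: an oxyregulator above pcrit, conformer below.

    ``smr_true`` is the quiescent mass-specific uptake (umol kg-1 min-1);
    below ``pcrit_true`` uptake declines linearly through the origin,
    MO2 = smr_true * PO2 / pcrit_true.  Activity bursts are a Poisson
    process (``activity_rate`` events per hour) of multiplicative
    excursions to smr_true * (1 + activity_magnitude); magnitudes are
    non-negative so the lowest-decile SMR estimator targets smr_true.
    """

    smr_true: float  # umol kg-1 min-1
    pcrit_true: float  # mmHg
    mass: float  # kg
    activity_rate: float = 0.0  # events per hour
    activity_magnitude: float = 0.0  # multiple of SMR, >= 0

    def __post_init__(self) -> None:
        if self.smr_true <= 0:
            raise ValueError("smr_true must be > 0")
        if self.pcrit_true <= 0:
            raise ValueError("pcrit_true must be > 0")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.activity_rate < 0 or self.activity_magnitude < 0:
            raise ValueError("activity parameters must be >= 0")


@dataclass(frozen=True)
class TraceSimConfig:
    """Respirometry simulation settings.

    Measurement cycles are ``flush_min`` of re-oxygenation followed by
    ``closed_min`` sealed (defaults 3 + 3 min).  ``background_rate_start``
    and ``background_rate_end`` are chamber-level background respiration
    (umol min-1) at the start and end of the record, interpolated
    linearly in between.  The closed-phase PO2 is integrated by Euler
    steps of ``dt_s`` seconds (default 1 s); Gaussian noise of sd
    ``noise_sd`` is added to the sampled (not the state) PO2.
    """

    chamber_volume: float  # L
    flush_min: float = 3.0
    closed_min: float = 3.0
    duration_h: float = 20.0
    ambient_po2: float = 155.0  # mmHg
    background_rate_start: float = 0.0  # umol min-1, chamber level
    background_rate_end: float = 0.0
    noise_sd: float = 0.0  # mmHg
    seed: int = 0
    dt_s: float = 1.0
    flush_tau_min: float = 0.3
    conditions: WaterConditions = field(
        default_factory=lambda: WaterConditions(temperature=24.0, salinity=35.0)
    )

    def __post_init__(self) -> None:
        if min(self.flush_min, self.closed_min, self.duration_h, self.dt_s) <= 0:
            raise ValueError("durations and step size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ambient_po2 <= 0:
            raise ValueError("ambient_po2 must be > 0")
        if self.chamber_volume <= 0:
            raise ValueError("chamber_volume must be > 0")


@dataclass
class TraceTruth:
    """Ground-truth bookkeeping emitted alongside a simulated trace."""

    burst_intervals: list[tuple[float, float]]
    o2_removed_umol: list[float]  # per closed phase, from the PO2 state change
    consumption_integral_umol: list[float]  # per closed phase, sum of rates * dt
    clipped: bool = False


def _burst_schedule(
    rng: np.random.Generator, duration_min: float, rate_per_h: float,
    mean_duration_min: float = 1.0,
) -> list[tuple[float, float]]:
    if rate_per_h <= 0:
        return []
    n = rng.poisson(rate_per_h * duration_min / 60.0)
    starts = np.sort(rng.uniform(0.0, duration_min, size=n))
    durations = rng.exponential(mean_duration_min, size=n)
    return [(float(s), float(s + d)) for s, d in zip(starts, durations)]


def _in_burst(t: float, intervals: list[tuple[float, float]]) -> bool:
    return any(s <= t < e for s, e in intervals)


def _fish_mo2(fish: FishModel, po2: float, bursting: bool) -> float:
    """Instantaneous mass-specific uptake (umol kg-1 min-1)."""
    if po2 >= fish.pcrit_true:
        base = fish.smr_true
        if bursting:
            base *= 1.0 + fish.activity_magnitude
        return base
    # Conformer: linear through the origin; bursts suppressed (the fish is
    # oxygen-limited below its critical tension).
    return fish.smr_true * po2 / fish.pcrit_true


def _integrate_closed(
    fish: FishModel,
    cfg: TraceSimConfig,
    po2_start: float,
    t_start_min: float,
    duration_min: float,
    bursts: list[tuple[float, float]],
    bg_rate_at,
    alpha: float,
    stop_po2: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, bool]:
    """Euler-integrate a sealed phase; returns (t, po2, removed, consumed, clipped).

    ``removed`` is the O2 inferred from the PO2 state change,
    ``consumed`` the time-integral of fish + background consumption; the
    two agree to floating point by construction of the update, which is
    what makes the oxygen bookkeeping testable against the recorded
    trace.
    """
    dt_min = cfg.dt_s / 60.0
    eff_vol = cfg.chamber_volume - fish.mass
    if eff_vol <= 0:
        raise ValueError("chamber volume must exceed fish mass (L vs kg)")
    n_steps = int(round(duration_min / dt_min))
    times = [t_start_min]
    states = [po2_start]
    po2 = po2_start
    consumed = 0.0
    clipped = False
    for i in range(n_steps):
        t = t_start_min + i * dt_min
        bursting = _in_burst(t, bursts)
        rate = _fish_mo2(fish, po2, bursting) * fish.mass + bg_rate_at(t)  # umol/min
        dpo2 = -rate * dt_min / (alpha * eff_vol)
        if po2 + dpo2 < 0.0:
            # consumption limited by remaining O2 in this step
            consumed += po2 * alpha * eff_vol
            po2 = 0.0
            clipped = True
        else:
            po2 += dpo2
            consumed += rate * dt_min
        times.append(t_start_min + (i + 1) * dt_min)
        states.append(po2)
        if stop_po2 is not None and po2 <= stop_po2:
            break
    removed = (po2_start - po2) * alpha * eff_vol
    return np.asarray(times), np.asarray(states), removed, consumed, clipped


def simulate_trace(
    fish: FishModel, cfg: TraceSimConfig, return_truth: bool = False
):
    """Simulate an intermittent-flow respirometry trace.

    Alternates flush (exponential relaxation of PO2 toward ambient, time
    constant ``flush_tau_min``) and sealed phases for ``duration_h``
    hours.  Sealed-phase PO2 obeys

        dPO2/dt = -(MO2(t, PO2) * M_f + background(t)) / (alpha * (V - M_f))

    with the regulator/conformer uptake of the fish model.  Gaussian
    sampling noise is added to the recorded PO2.  With
    ``return_truth=True`` also returns a :class:`TraceTruth` with the
    burst schedule and per-closed-phase oxygen bookkeeping.
    """
    rng = np.random.default_rng(cfg.seed)
    alpha = o2_solubility(cfg.conditions)
    duration_min = cfg.duration_h * 60.0
    bursts = _burst_schedule(rng, duration_min, fish.activity_rate)
    t_total = cfg.background_rate_end - cfg.background_rate_start

    def bg_rate_at(t: float) -> float:
        frac = t / duration_min
        return cfg.background_rate_start + frac * t_total

    dt_min = cfg.dt_s / 60.0
    cycle_min = cfg.flush_min + cfg.closed_min
    n_cycles = int(math.floor(duration_min / cycle_min))
    t_arrays, p_arrays, phases, cycles = [], [], [], []
    truth = TraceTruth(burst_intervals=bursts, o2_removed_umol=[],
                       consumption_integral_umol=[])
    po2 = cfg.ambient_po2
    t = 0.0
    for c in range(n_cycles):
        # flush: first-order relaxation toward ambient; samples at
        # (t, t + flush_min], the last one being the sealing moment
        n_f = int(round(cfg.flush_min / dt_min))
        tf = t + (np.arange(n_f) + 1) * dt_min
        pf = cfg.ambient_po2 + (po2 - cfg.ambient_po2) * np.exp(
            -(tf - t) / cfg.flush_tau_min
        )
        t_arrays.append(tf)
        p_arrays.append(pf)
        phases.append(np.full(n_f, "flush", dtype=object))
        cycles.append(np.full(n_f, c, dtype=int))
        t = t + cfg.flush_min
        po2 = cfg.ambient_po2 + (po2 - cfg.ambient_po2) * math.exp(
            -cfg.flush_min / cfg.flush_tau_min
        )
        # closed
        tc, pc, removed, consumed, clipped = _integrate_closed(
            fish, cfg, po2, t, cfg.closed_min, bursts, bg_rate_at, alpha
        )
        truth.o2_removed_umol.append(removed)
        truth.consumption_integral_umol.append(consumed)
        truth.clipped = truth.clipped or clipped
        # tc[0] coincides with the sealing sample already recorded as flush
        t_arrays.append(tc[1:])
        p_arrays.append(pc[1:])
        phases.append(np.full(len(tc) - 1, "closed", dtype=object))
        cycles.append(np.full(len(tc) - 1, c, dtype=int))
        t = tc[-1]
        po2 = pc[-1]
    time = np.concatenate(t_arrays)
    po2_rec = np.concatenate(p_arrays)
    if cfg.noise_sd > 0:
        po2_rec = po2_rec + rng.normal(0.0, cfg.noise_sd, size=len(po2_rec))
        po2_rec = np.clip(po2_rec, 0.0, None)
    trace = O2Trace(
        time_min=time,
        po2=po2_rec,
        phase=np.concatenate(phases),
        cycle=np.concatenate(cycles),
        clipped_at_zero=truth.clipped,
    )
    return (trace, truth) if return_truth else trace


def simulate_closed_pcrit_run(
    fish: FishModel,
    cfg: TraceSimConfig,
    stop_po2: float,
    return_truth: bool = False,
):
    """Simulate one uninterrupted closed-circuit decline past ``stop_po2``.

    The chamber starts at ambient PO2 and stays sealed until PO2 drops to
    ``stop_po2`` (which must be below ambient), under the same
    regulator/conformer fish model as :func:`simulate_trace`.
    """
    if stop_po2 >= cfg.ambient_po2:
        raise ValueError("stop_po2 must be below ambient PO2")
    if stop_po2 < 0:
        raise ValueError("stop_po2 must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    alpha = o2_solubility(cfg.conditions)
    max_min = cfg.duration_h * 60.0
    bursts = _burst_schedule(rng, max_min, fish.activity_rate)
    t_total = cfg.background_rate_end - cfg.background_rate_start

    def bg_rate_at(t: float) -> float:
        return cfg.background_rate_start + (t / max_min) * t_total

    tc, pc, removed, consumed, clipped = _integrate_closed(
        fish, cfg, cfg.ambient_po2, 0.0, max_min, bursts, bg_rate_at, alpha,
        stop_po2=stop_po2,
    )
    if pc[-1] > stop_po2:
        raise ValueError(
            "closed run did not reach stop_po2 within duration_h; extend duration"
        )
    po2_rec = pc.copy()
    if cfg.noise_sd > 0:
        po2_rec = np.clip(po2_rec + rng.normal(0.0, cfg.noise_sd, len(po2_rec)), 0.0, None)
    trace = O2Trace(
        time_min=tc,
        po2=po2_rec,
        phase=np.full(len(tc), "closed", dtype=object),
        cycle=np.zeros(len(tc), dtype=int),
        clipped_at_zero=clipped,
    )
    truth = TraceTruth(
        burst_intervals=bursts,
        o2_removed_umol=[removed],
        consumption_integral_umol=[consumed],
        clipped=clipped,
    )
    return (trace, truth) if return_truth else trace


def simulate_oec_plate(
    p50_at_ph74: float,
    hill_n: float,
    bohr_phi: float,
    ph_levels=(7.0, 7.4, 7.8),
    o2_steps_percent=OEC_GAS_STEPS,
    a_deoxy: float = 0.40,
    a_oxy: float = 0.90,
    noise_sd: float = 0.0,
    seed: int = 0,
    conditions: WaterConditions | None = None,
    sample_id: str = "hemolysate",
) -> list[OECurve]:
    """Simulate O2 equilibrium curves for one hemolysate across pH levels.

    P50 at each pH follows the Bohr model
    log10 P50(pH) = log10 p50_at_ph74 + bohr_phi * (pH - 7.4); saturation
    is the Hill function S = PO2^n / (P50^n + PO2^n); absorbance is
    a_deoxy + (a_oxy - a_deoxy) * S plus Gaussian noise.
    """
    if hill_n <= 0:
        raise ValueError("hill_n must be > 0")
    if a_oxy == a_deoxy:
        raise ValueError("oxy and deoxy absorbances must differ")
    if p50_at_ph74 <= 0:
        raise ValueError("p50_at_ph74 must be > 0")
    if conditions is None:
        conditions = WaterConditions(temperature=22.0, salinity=0.0)
    rng = np.random.default_rng(seed)
    steps = np.asarray(o2_steps_percent, dtype=float)
    po2 = np.array([percent_o2_to_po2(x, conditions, humidified=True) for x in steps])
    curves = []
    for ph in ph_levels:
        p50 = p50_at_ph74 * 10.0 ** (bohr_phi * (ph - 7.4))
        with np.errstate(divide="ignore"):
            s = np.where(po2 > 0, po2**hill_n / (p50**hill_n + po2**hill_n), 0.0)
        # the 0% and 100% steps are the assay's deoxy/oxy reference
        # plateaus: force exact endpoints so normalization is anchored
        s[steps == 0.0] = 0.0
        s[steps == 100.0] = 1.0
        absorbance = a_deoxy + (a_oxy - a_deoxy) * s
        if noise_sd > 0:
            absorbance = absorbance + rng.normal(0.0, noise_sd, size=len(absorbance))
        curves.append(
            OECurve(
                gas_percent_o2=steps,
                po2=po2,
                absorbance=absorbance,
                ph=float(ph),
                temperature=conditions.temperature,
                sample_id=f"{sample_id}_pH{ph:g}",
            )
        )
    return curves


#: ct anchoring constant: each gene's zero-abundance intercept c_g satisfies
#: E_g^c_g = _CT_ANCHOR_K, so anchored abundance ratios invert exactly.
_CT_ANCHOR_K = 2.0**30


def simulate_ct_table(
    abundances: dict[str, float],
    efficiencies: dict[str, float],
    ref_gene: str,
    n_samples: int = 7,
    treatment_fold_changes: dict[str, float] | None = None,
    ct_noise_sd: float = 0.0,
    loading_sd: float = 0.0,
    seed: int = 0,
) -> CtTable:
    """Simulate a ct table from true relative transcript abundances.

    ct for gene g in sample s is ``c_g - log_{E_g}(a_g * fold * load_s)``
    with c_g chosen so that E_g^{c_g} is a shared constant (then the
    anchored-abundance estimator inverts the table exactly) and ``load_s``
    a per-sample lognormal loading offset shared by every gene of the
    sample (absorbed by the reference gene under ddct analysis).  With
    ``treatment_fold_changes`` given, a hypoxia group is generated where
    each listed gene's abundance is multiplied by its fold change; the
    reference gene must keep fold 1.
    """
    if ref_gene not in abundances:
        raise ValueError("reference gene must appear in abundances")
    for g, a in abundances.items():
        if a <= 0:
            raise ValueError(f"abundance of {g!r} must be > 0")
        e = efficiencies.get(g)
        if e is None:
            raise ValueError(f"no efficiency for gene {g!r}")
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency of {g!r} must lie in (1, 2], got {e}")
    folds = treatment_fold_changes or {}
    if folds.get(ref_gene, 1.0) != 1.0:
        raise ValueError("reference gene must have fold change 1")
    rng = np.random.default_rng(seed)
    treatments = ["normoxia"] + (["hypoxia"] if treatment_fold_changes is not None else [])
    rows = []
    for trt in treatments:
        for i in range(n_samples):
            sid = f"{trt[:3]}_{i + 1:02d}"
            load = math.exp(rng.normal(0.0, loading_sd)) if loading_sd > 0 else 1.0
            for gene, a in abundances.items():
                e = efficiencies[gene]
                fold = folds.get(gene, 1.0) if trt == "hypoxia" else 1.0
                c_g = math.log(_CT_ANCHOR_K) / math.log(e)
                ct = c_g - math.log(a * fold * load) / math.log(e)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {"sample_id": sid, "treatment": trt, "gene": gene,
                     "ct": ct, "efficiency": e}
                )
    return CtTable(data=pd.DataFrame(rows), ref_gene=ref_gene)


def simulate_morphometry(
    true_area_per_mass: float,
    mass: float,
    n_filaments: int = 60,
    spacing_cv: float = 0.0,
    seed: int = 0,
    mean_length_mm: float = 10.0,
    mean_spacing_mm: float = 0.1,
    n_spacing: int = 24,
    n_lamellae: int = 20,
    diffusion_um: float = 1.2,
    n_images: int = 15,
    n_diffusion_per_image: int = 10,
) -> GillMorphometry:
    """Simulate a gill morphometry measurement set for one fish.

    Measurements are drawn so the Hughes product L * f * B equals
    ``true_area_per_mass * mass`` exactly at ``spacing_cv = 0`` and in
    expectation otherwise (multiplicative noise with unit mean is applied
    to lengths, spacings and lamellar areas).  Filament lengths are
    sampled at every tenth position, as in a first-gill-arch count.
    """
    if min(true_area_per_mass, mass, mean_length_mm, mean_spacing_mm) <= 0:
        raise ValueError("all morphometry parameters must be positive")
    if spacing_cv < 0:
        raise ValueError("spacing_cv must be >= 0")
    rng = np.random.default_rng(seed)
    a_total = true_area_per_mass * mass
    l_true = n_filaments * mean_length_mm
    f_true = 2.0 / mean_spacing_mm
    b_true = a_total / (l_true * f_true)

    def draw(mean: float, n: int) -> np.ndarray:
        if spacing_cv == 0:
            return np.full(n, mean)
        out = rng.normal(mean, spacing_cv * mean, size=n)
        return np.clip(out, mean * 0.1, None)  # keep strictly positive

    positions = np.arange(1, n_filaments + 1, 10)
    return GillMorphometry(
        n_filaments=n_filaments,
        sampled_positions=positions.astype(float),
        sampled_lengths=draw(mean_length_mm, len(positions)),
        lamellar_spacing=draw(mean_spacing_mm, n_spacing),
        lamellar_bilateral_areas=draw(b_true, n_lamellae),
        diffusion_by_image={
            i: draw(diffusion_um, n_diffusion_per_image) for i in range(n_images)
        },
        body_mass=mass,
    )
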