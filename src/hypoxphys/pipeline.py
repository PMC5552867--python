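"""Desk-scale orchestration of a full hypoxia-acclimation study.

``run_study`` simulates a two-treatment (normoxia / hypoxia, 7 fish
each) acclimation experiment with known ground truth, runs every
analysis stage of the package on the simulated data, and returns the
study-shaped result tables: per-fish pre/post Pcrit with paired
one-tailed t-tests, an SMR table, a P50 x pH x treatment table with a
two-way ANOVA and Bohr coefficients, hemoglobin-subunit expression fold
changes and relative abundances, and gill morphometrics.  Everything is
deterministic under the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import gill, hb, qpcr, respirometry as resp, stats, synth
from .gas import WaterConditions, mo2_unit_convert

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "analyze_fish_respirometry",
    "pcrit_recovery_protocol",
]

# Default hemoglobin-subunit abundance model (alpha subunits relative to
# the dominant Hbalpha-3.1, plus the ef1a reference): second-most isoform
# at 0.12, minor isoforms low; hypoxia up-regulates Hba-2 and Hba-3.2.
_DEFAULT_ABUNDANCES = {
    "ef1a": 1.0,
    "Hba-3.1": 1.0,
    "Hba-3.2": 0.12,
    "Hba-2": 0.02,
    "Hba-6.1": 0.01,
    "Hba-short": 0.005,
}
_DEFAULT_EFFICIENCIES = {
    "ef1a": 1.93,
    "Hba-3.1": 1.90,
    "Hba-3.2": 1.86,
    "Hba-2": 1.80,
    "Hba-6.1": 1.77,
    "Hba-short": 1.96,
}
_DEFAULT_FOLDS = {"Hba-3.2": 8.0, "Hba-2": 4.0, "Hba-3.1": 1.2}


@dataclass
class StudyConfig:
    """Ground-truth parameters and stage settings of a simulated study."""

    n_per_group: int = 7
    seed: int = 0
    # respirometry ground truth (group means; per-fish spread via CVs)
    smr_true_mg_kg_h: dict = field(
        default_factory=lambda: {"normoxia": 151.0, "hypoxia": 167.0}
    )
    pcrit_pre_mmhg: dict = field(
        default_factory=lambda: {"normoxia": 36.2, "hypoxia": 36.2}
    )
    pcrit_post_mmhg: dict = field(
        default_factory=lambda: {"normoxia": 36.2, "hypoxia": 28.1}
    )
    fish_mass_kg: float = 0.091
    between_fish_cv: float = 0.08
    chamber_volume_l: float = 2.5
    smr_trace_hours: float = 6.0
    trace_noise_sd: float = 0.2
    activity_rate_per_h: float = 12.0
    activity_magnitude: float = 1.0
    stop_po2_mmhg: float = 12.7  # 8% air saturation
    water: WaterConditions = field(
        default_factory=lambda: WaterConditions(temperature=24.0, salinity=35.0)
    )
    # hemoglobin-O2 equilibria ground truth
    p50_at_ph74: dict = field(
        default_factory=lambda: {"normoxia": 20.0, "hypoxia": 17.0}
    )
    hill_n: float = 1.8
    bohr_phi: float = -0.45
    ph_levels: tuple = (7.0, 7.4, 7.8)
    oec_noise_sd: float = 0.004  # absorbance units (~1% of dynamic range)
    n_oec_fish: int = 5
    # the 15-step gas ladder is sparse mid-range; a (0.2, 0.8) window can
    # leave < 3 points at the acid pH, so the study pipeline widens it
    hill_window: tuple = (0.1, 0.9)
    assay_conditions: WaterConditions = field(
        default_factory=lambda: WaterConditions(temperature=22.0, salinity=0.0)
    )
    # qPCR ground truth
    abundances: dict = field(default_factory=lambda: dict(_DEFAULT_ABUNDANCES))
    efficiencies: dict = field(default_factory=lambda: dict(_DEFAULT_EFFICIENCIES))
    fold_changes: dict = field(default_factory=lambda: dict(_DEFAULT_FOLDS))
    ref_gene: str = "ef1a"
    anchor_gene: str = "Hba-3.1"
    ct_noise_sd: float = 0.2
    loading_sd: float = 0.1
    # gill morphometry ground truth
    gill_area_mm2_g: dict = field(
        default_factory=lambda: {"normoxia": 348.9, "hypoxia": 369.9}
    )
    gill_cv: float = 0.1
    body_mass_g: float = 91.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["water"] = dataclasses.asdict(self.water)
        d["assay_conditions"] = dataclasses.asdict(self.assay_conditions)
        d["ph_levels"] = list(self.ph_levels)
        d["hill_window"] = list(self.hill_window)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text)
        d["water"] = WaterConditions(**d["water"])
        d["assay_conditions"] = WaterConditions(**d["assay_conditions"])
        d["ph_levels"] = tuple(d["ph_levels"])
        d["hill_window"] = tuple(d["hill_window"])
        return cls(**d)


@dataclass
class StudyReport:
    """All stage outputs of one simulated-and-analyzed study."""

    pcrit_table: pd.DataFrame
    smr_table: pd.DataFrame
    pcrit_tests: dict
    smr_tests: dict
    p50_table: pd.DataFrame
    p50_anova: pd.DataFrame
    bohr_table: pd.DataFrame
    expression_folds: pd.DataFrame
    relative_abundance: pd.DataFrame
    morphometry_table: pd.DataFrame
    morphometry_tests: dict
    seed: int = 0
    errors: list = field(default_factory=list)

    def to_payload(self) -> dict:
        """JSON-serializable report payload (deterministic ordering)."""

        def df(d: pd.DataFrame):
            return json.loads(d.to_json(orient="records", double_precision=10))

        def test(t: stats.TestResult):
            return {
                "test": t.test, "statistic": round(t.statistic, 10),
                "df": t.df, "p_value": round(t.p_value, 10), "tail": t.tail,
                "flags": t.flags,
            }

        return {
            "seed": self.seed,
            "pcrit": df(self.pcrit_table),
            "smr": df(self.smr_table),
            "pcrit_tests": {k: test(v) for k, v in self.pcrit_tests.items()},
            "smr_tests": {k: test(v) for k, v in self.smr_tests.items()},
            "p50": df(self.p50_table),
            "p50_anova": df(self.p50_anova),
            "bohr": df(self.bohr_table),
            "expression_folds": df(self.expression_folds),
            "relative_abundance": df(self.relative_abundance),
            "morphometry": df(self.morphometry_table),
            "morphometry_tests": {k: test(v) for k, v in self.morphometry_tests.items()},
            "errors": self.errors,
        }


def analyze_fish_respirometry(
    fish: synth.FishModel,
    cfg: StudyConfig,
    seed: int,
    noise_sd: float | None = None,
) -> tuple[float, float]:
    """Simulate one fish's SMR trace and Pcrit run and analyze both.

    Returns (smr_estimate, pcrit_estimate) in (umol kg-1 min-1, mmHg);
    the Pcrit run uses the SMR measured immediately prior for the same
    individual.
    """
    noise = cfg.trace_noise_sd if noise_sd is None else noise_sd
    setup = resp.ChamberSetup(
        v_chamber=cfg.chamber_volume_l, m_f=fish.mass, conditions=cfg.water
    )
    trace_cfg = synth.TraceSimConfig(
        chamber_volume=cfg.chamber_volume_l,
        duration_h=cfg.smr_trace_hours,
        noise_sd=noise,
        seed=seed,
        conditions=cfg.water,
    )
    trace = synth.simulate_trace(fish, trace_cfg)
    series = resp.mo2_series_from_trace(trace, setup)
    smr = resp.estimate_smr(series)
    run_cfg = synth.TraceSimConfig(
        chamber_volume=cfg.chamber_volume_l,
        duration_h=4.0,
        noise_sd=noise,
        seed=seed + 1,
        conditions=cfg.water,
    )
    quiet = synth.FishModel(
        smr_true=fish.smr_true, pcrit_true=fish.pcrit_true, mass=fish.mass
    )
    run = synth.simulate_closed_pcrit_run(quiet, run_cfg, stop_po2=cfg.stop_po2_mmhg)
    pcrit = resp.estimate_pcrit(run, smr, setup)
    return smr.value, pcrit.value


def pcrit_recovery_protocol(
    breakpoint_mean_mmhg: float,
    smr_mg_kg_h: float,
    n_fish: int = 7,
    seed: int = 0,
    sem_mmhg: float = 0.0,
    config: StudyConfig | None = None,
) -> np.ndarray:
    """Zero-noise Pcrit parameter-recovery protocol for one group.

    Simulates ``n_fish`` noise-free fish whose true breakpoints are
    seeded-normal spread with the given between-fish SEM but centered
    exactly on ``breakpoint_mean_mmhg``, runs the full SMR-then-Pcrit
    measurement chain per individual (quiescent rate ``smr_mg_kg_h``),
    and returns the per-fish Pcrit estimates (mmHg).
    """
    cfg = config or StudyConfig(smr_trace_hours=2.0)
    rng = np.random.default_rng(seed)
    if sem_mmhg > 0 and n_fish > 1:
        x = rng.normal(0.0, sem_mmhg * math.sqrt(n_fish), size=n_fish)
        breakpoints = np.clip(breakpoint_mean_mmhg + (x - x.mean()),
                              breakpoint_mean_mmhg * 0.3, None)
    else:
        breakpoints = np.full(n_fish, breakpoint_mean_mmhg)
    smr_umol = mo2_unit_convert(smr_mg_kg_h, "mgO2/kg/h", "umol/kg/min")
    out = []
    for i, bp in enumerate(breakpoints):
        fish = synth.FishModel(
            smr_true=smr_umol, pcrit_true=float(bp), mass=cfg.fish_mass_kg
        )
        _, pcrit_hat = analyze_fish_respirometry(
            fish, cfg, seed=seed + 1000 + i, noise_sd=0.0
        )
        out.append(pcrit_hat)
    return np.asarray(out)


def _centered_spread(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """n values with sample mean exactly ``mean`` and spread ~ cv * mean."""
    if cv == 0 or n == 1:
        return np.full(n, mean)
    x = rng.normal(0.0, cv * mean, size=n)
    x = x - x.mean()
    return np.clip(mean + x, mean * 0.2, None)


def run_study(config: StudyConfig) -> StudyReport:
    """Simulate a full two-treatment study and run every analysis stage."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s) for s in ss.generate_state(64) % (2**31)]
    errors: list = []

    # --- respirometry: SMR and pre/post Pcrit per fish -------------------
    pcrit_rows, smr_rows = [], []
    k = 0
    for trt in ("normoxia", "hypoxia"):
        rng = np.random.default_rng(seeds[0] + (0 if trt == "normoxia" else 1))
        smr_means = _centered_spread(
            rng, mo2_unit_convert(config.smr_true_mg_kg_h[trt], "mgO2/kg/h", "umol/kg/min"),
            config.between_fish_cv, config.n_per_group,
        )
        pre = _centered_spread(rng, config.pcrit_pre_mmhg[trt],
                               config.between_fish_cv, config.n_per_group)
        post = pre * (config.pcrit_post_mmhg[trt] / config.pcrit_pre_mmhg[trt])
        for i in range(config.n_per_group):
            fish_id = f"{trt[:3]}_{i + 1:02d}"
            try:
                for phase, pc_true in (("pre", pre[i]), ("post", post[i])):
                    fish = synth.FishModel(
                        smr_true=smr_means[i], pcrit_true=pc_true,
                        mass=config.fish_mass_kg,
                        activity_rate=config.activity_rate_per_h,
                        activity_magnitude=config.activity_magnitude,
                    )
                    smr_hat, pcrit_hat = analyze_fish_respirometry(
                        fish, config, seeds[1] + 10 * k + (0 if phase == "pre" else 5)
                    )
                    pcrit_rows.append(
                        {"fish": fish_id, "treatment": trt, "phase": phase,
                         "pcrit_true": pc_true, "pcrit_mmHg": pcrit_hat}
                    )
                    smr_rows.append(
                        {"fish": fish_id, "treatment": trt, "phase": phase,
                         "smr_true": smr_means[i],
                         "smr_umol_kg_min": smr_hat,
                         "smr_mg_kg_h": mo2_unit_convert(smr_hat, "umol/kg/min", "mgO2/kg/h")}
                    )
            except Exception as exc:  # partial report on stage failure
                errors.append({"stage": "respirometry", "fish": fish_id, "error": str(exc)})
            k += 1
    pcrit_table = pd.DataFrame(pcrit_rows)
    smr_table = pd.DataFrame(smr_rows)

    pcrit_tests, smr_tests = {}, {}
    for trt in ("normoxia", "hypoxia"):
        sub = pcrit_table[pcrit_table["treatment"] == trt]
        pre_v = sub[sub["phase"] == "pre"].sort_values("fish")["pcrit_mmHg"].to_numpy()
        post_v = sub[sub["phase"] == "post"].sort_values("fish")["pcrit_mmHg"].to_numpy()
        if len(pre_v) >= 2 and len(pre_v) == len(post_v):
            # a-priori direction: acclimation should lower Pcrit
            pcrit_tests[trt] = stats.t_test(
                {"pre": pre_v, "post": post_v}, paired=True, tail="one",
                alternative="greater",
            )
        sub = smr_table[smr_table["treatment"] == trt]
        pre_s = sub[sub["phase"] == "pre"].sort_values("fish")["smr_mg_kg_h"].to_numpy()
        post_s = sub[sub["phase"] == "post"].sort_values("fish")["smr_mg_kg_h"].to_numpy()
        if len(pre_s) >= 2 and len(pre_s) == len(post_s):
            smr_tests[trt] = stats.t_test(
                {"pre": pre_s, "post": post_s}, paired=True, tail="two"
            )

    # --- hemoglobin-O2 equilibria ---------------------------------------
    p50_rows, bohr_rows = [], []
    for t_idx, trt in enumerate(("normoxia", "hypoxia")):
        rng = np.random.default_rng(seeds[2] + t_idx)
        p50s = _centered_spread(rng, config.p50_at_ph74[trt],
                                config.between_fish_cv, config.n_oec_fish)
        for i in range(config.n_oec_fish):
            sid = f"{trt[:3]}_{i + 1:02d}"
            try:
                curves = synth.simulate_oec_plate(
                    p50_at_ph74=p50s[i], hill_n=config.hill_n,
                    bohr_phi=config.bohr_phi, ph_levels=config.ph_levels,
                    noise_sd=config.oec_noise_sd,
                    seed=seeds[3] + 100 * t_idx + i,
                    conditions=config.assay_conditions, sample_id=sid,
                )
                fits = []
                for c in curves:
                    f = hb.fit_curve(c, window=tuple(config.hill_window))
                    fits.append((c.ph, f))
                    p50_rows.append(
                        {"sample_id": sid, "treatment": trt, "ph": c.ph,
                         "p50_mmHg": f.p50, "hill_n": f.slope, "r_squared": f.r_squared}
                    )
                bohr = hb.bohr_coefficient(fits)
                bohr_rows.append(
                    {"sample_id": sid, "treatment": trt, "phi": bohr.phi,
                     **{f"phi_{lo:g}_{hi:g}": v for (lo, hi), v in bohr.pairwise.items()}}
                )
            except Exception as exc:
                errors.append({"stage": "hb_equilibria", "sample": sid, "error": str(exc)})
    p50_table = pd.DataFrame(p50_rows)
    bohr_table = pd.DataFrame(bohr_rows)
    try:
        p50_anova = stats.two_way_anova(p50_table, "p50_mmHg", "treatment", "ph")
    except Exception as exc:
        p50_anova = pd.DataFrame()
        errors.append({"stage": "p50_anova", "error": str(exc)})

    # --- qPCR expression --------------------------------------------------
    table = synth.simulate_ct_table(
        abundances=config.abundances, efficiencies=config.efficiencies,
        ref_gene=config.ref_gene, n_samples=config.n_per_group,
        treatment_fold_changes=config.fold_changes,
        ct_noise_sd=config.ct_noise_sd, loading_sd=config.loading_sd,
        seed=seeds[4],
    )
    fold_rows = []
    for gene in table.genes():
        if gene == config.ref_gene:
            continue
        res = qpcr.ddct_fold_change(table, gene, "normoxia", "hypoxia")
        hyp = res.summary[res.summary["treatment"] == "hypoxia"].iloc[0]
        per = res.per_sample
        logf = np.log2(per.groupby("treatment")["fold_change"].apply(list).to_dict()["hypoxia"])
        ctrl_log = np.log2(per[per["treatment"] == "normoxia"]["fold_change"].to_numpy())
        t = stats.t_test({"hypoxia": logf, "normoxia": ctrl_log}, tail="two")
        fold_rows.append(
            {"gene": gene, "fold_change_mean": hyp["mean"], "fold_change_sem": hyp["sem"],
             "n": int(hyp["n"]), "true_fold": config.fold_changes.get(gene, 1.0),
             "p_value": t.p_value}
        )
    expression_folds = pd.DataFrame(fold_rows)
    abundance = qpcr.relative_abundance(table, config.anchor_gene).summary

    # --- gill morphometrics ----------------------------------------------
    morph_rows = []
    area_by_trt, diff_by_trt = {}, {}
    for t_idx, trt in enumerate(("normoxia", "hypoxia")):
        rng = np.random.default_rng(seeds[5] + t_idx)
        truths = _centered_spread(rng, config.gill_area_mm2_g[trt],
                                  config.between_fish_cv, config.n_per_group)
        areas, diffs = [], []
        for i in range(config.n_per_group):
            morph = synth.simulate_morphometry(
                true_area_per_mass=truths[i], mass=config.body_mass_g,
                spacing_cv=config.gill_cv, seed=seeds[6] + 100 * t_idx + i,
            )
            res = gill.gill_area(morph)
            areas.append(res.mass_specific_area)
            diffs.append(res.diffusion_distance_um)
            morph_rows.append(
                {"fish": f"{trt[:3]}_{i + 1:02d}", "treatment": trt,
                 "mass_specific_area_mm2_g": res.mass_specific_area,
                 "total_area_mm2": res.total_area,
                 "diffusion_um": res.diffusion_distance_um}
            )
        area_by_trt[trt] = np.array(areas)
        diff_by_trt[trt] = np.array(diffs)
    morphometry_table = pd.DataFrame(morph_rows)
    morphometry_tests = {
        "gill_area": stats.t_test(area_by_trt, tail="two"),
        "diffusion_distance": stats.t_test(diff_by_trt, tail="two"),
    }

    return StudyReport(
        pcrit_table=pcrit_table,
        smr_table=smr_table,
        pcrit_tests=pcrit_tests,
        smr_tests=smr_tests,
        p50_table=p50_table,
        p50_anova=p50_anova,
        bohr_table=bohr_table,
        expression_folds=expression_folds,
        relative_abundance=abundance,
        morphometry_table=morphometry_table,
        morphometry_tests=morphometry_tests,
        seed=config.seed,
        errors=errors,
    )
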