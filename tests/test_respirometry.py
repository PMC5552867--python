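import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypoxphys import respirometry as resp
from hypoxphys import synth
from hypoxphys.gas import o2_solubility


def _toy_trace(slope=-1.0, n_cycles=1, noise=None, rng=None):
    """Hand-built 3+3 min flush/closed trace sampled at 0.1 min."""
    t_blocks, p_blocks, ph_blocks, cy_blocks = [], [], [], []
    t0 = 0.0
    for c in range(n_cycles):
        tf = t0 + np.arange(1, 31) * 0.1
        t_blocks.append(tf)
        p_blocks.append(np.full(30, 150.0))
        ph_blocks.append(np.full(30, "flush", dtype=object))
        cy_blocks.append(np.full(30, c))
        tc = tf[-1] + np.arange(1, 31) * 0.1
        pc = 150.0 + slope * (tc - tf[-1])
        if noise is not None:
            pc = pc + rng.normal(0, noise, size=30)
        t_blocks.append(tc)
        p_blocks.append(pc)
        ph_blocks.append(np.full(30, "closed", dtype=object))
        cy_blocks.append(np.full(30, c))
        t0 = tc[-1]
    return resp.O2Trace(
        time_min=np.concatenate(t_blocks),
        po2=np.concatenate(p_blocks),
        phase=np.concatenate(ph_blocks),
        cycle=np.concatenate(cy_blocks),
    )


class TestFitCycleSlopes:
    def test_exact_line_recovered(self):
        regs = resp.fit_cycle_slopes(_toy_trace(slope=-1.0))
        assert regs[0].slope == pytest.approx(-1.0, abs=1e-12)
        assert regs[0].r_squared == pytest.approx(1.0, abs=1e-12)
        assert regs[0].retained

    def test_constant_po2_flagged_degenerate(self):
        regs = resp.fit_cycle_slopes(_toy_trace(slope=0.0))
        assert regs[0].slope == pytest.approx(0.0, abs=1e-12)
        assert not regs[0].retained
        assert regs[0].flag == "degenerate_constant_po2"

    def test_noisy_cycle_matches_polyfit_oracle(self, rng):
        trace = _toy_trace(slope=-0.8, noise=0.3, rng=rng)
        reg = resp.fit_cycle_slopes(trace)[0]
        m = (trace.phase == "closed") & (trace.time_min >= trace.time_min[-1] - 2.0)
        expected = np.polyfit(trace.time_min[m], trace.po2[m], 1)
        assert reg.slope == pytest.approx(expected[0], abs=1e-10)
        assert reg.intercept == pytest.approx(expected[1], abs=1e-10)

    def test_window_uses_last_two_minutes(self):
        regs = resp.fit_cycle_slopes(_toy_trace(slope=-1.0), window_min=2.0)
        lo, hi = regs[0].window
        assert hi - lo <= 2.0 + 1e-9
        assert regs[0].n_points == 21


class TestMo2FromSlope:
    def test_arithmetic(self, chamber, seawater_24):
        alpha = o2_solubility(seawater_24)
        reg = resp.CycleRegression(0, -1.0, 150.0, 1.0, 30, (1.0, 3.0), 100.0, True)
        expected = 1.0 * alpha * (2.5 - 0.091) / 0.091
        assert resp.mo2_from_slope(reg, chamber) == pytest.approx(expected, rel=1e-12)

    def test_zero_slope_zero_uptake(self, chamber):
        reg = resp.CycleRegression(0, 0.0, 150.0, math.nan, 30, (1.0, 3.0), 150.0, False)
        assert resp.mo2_from_slope(reg, chamber) == 0.0

    @given(s=st.floats(-5, 0), scale=st.floats(0.1, 10))
    def test_linear_in_slope(self, s, scale, chamber):
        r1 = resp.CycleRegression(0, s, 0, 1, 30, (0, 2), 100, True)
        r2 = resp.CycleRegression(0, s * scale, 0, 1, 30, (0, 2), 100, True)
        m1, m2 = resp.mo2_from_slope(r1, chamber), resp.mo2_from_slope(r2, chamber)
        assert m2 == pytest.approx(m1 * scale, rel=1e-12, abs=1e-12)

    def test_vanishing_effective_volume(self, seawater_24):
        setup = resp.ChamberSetup(0.0911, 0.091, seawater_24)
        reg = resp.CycleRegression(0, -1.0, 0, 1, 30, (0, 2), 100, True)
        assert resp.mo2_from_slope(reg, setup) == pytest.approx(
            o2_solubility(seawater_24) * 1e-4 / 0.091, rel=1e-9
        )

    def test_invalid_geometry_rejected(self, seawater_24):
        with pytest.raises(ValueError):
            resp.ChamberSetup(0.05, 0.091, seawater_24)


def _series(values, times=None):
    n = len(values)
    return resp.MO2Series(
        time=np.arange(n, dtype=float) if times is None else np.asarray(times),
        mo2=np.asarray(values, dtype=float),
        mean_po2=np.full(n, 100.0),
        retained=np.ones(n, dtype=bool),
    )


class TestBackgroundCorrect:
    def test_zero_rates_no_change(self):
        s = _series(np.linspace(5, 6, 12))
        out = resp.background_correct(s, 0.0, 0.0, 0.0, 11.0)
        assert np.allclose(out.mo2, s.mo2)
        assert out.background_corrected

    def test_midpoint_subtracts_one(self):
        s = _series([10.0] * 11)
        out = resp.background_correct(s, 0.0, 2.0, 0.0, 10.0)
        assert out.mo2[5] == pytest.approx(9.0)
        assert out.mo2[0] == pytest.approx(10.0)
        assert out.mo2[10] == pytest.approx(8.0)

    def test_negative_after_correction_flagged(self):
        s = _series([1.0, 1.0] + [5.0] * 10)
        out = resp.background_correct(s, 3.0, 3.0, 0.0, 11.0)
        assert not out.retained[0] and not out.retained[1]
        assert any("negative_after_correction" in f for f in out.flags)

    def test_background_ramp_recovery(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(smr_true=smr_umol, pcrit_true=36.2, mass=0.091)
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=2.0, noise_sd=0.0, seed=4,
            background_rate_start=0.5, background_rate_end=1.5,
            conditions=seawater_24,
        )
        trace = synth.simulate_trace(fish, cfg)
        series = resp.mo2_series_from_trace(trace, chamber)
        smr_raw = resp.estimate_smr(series).value
        corrected = resp.background_correct(
            series, 0.5 / 0.091, 1.5 / 0.091, 0.0, 120.0
        )
        smr_corr = resp.estimate_smr(corrected).value
        assert smr_corr == pytest.approx(smr_umol, rel=1e-3)
        # uncorrected is biased high by roughly the mean background
        assert smr_raw - smr_umol > 0.5 * (1.0 / 0.091)


class TestEstimateSmr:
    def test_lowest_decile_of_twenty(self):
        est = resp.estimate_smr(_series(np.arange(1.0, 21.0)))
        assert est.value == pytest.approx(1.5)
        assert est.n_used == 2

    def test_constant_series(self):
        assert resp.estimate_smr(_series([3.3] * 15)).value == pytest.approx(3.3)

    def test_permutation_invariant(self, rng):
        vals = rng.uniform(2, 9, size=40)
        a = resp.estimate_smr(_series(vals)).value
        b = resp.estimate_smr(_series(rng.permutation(vals))).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_monotone_in_record_values(self, rng):
        vals = rng.uniform(2, 9, size=40)
        lower = resp.estimate_smr(_series(vals)).value
        higher = resp.estimate_smr(_series(vals + 0.5)).value
        assert higher >= lower

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            resp.estimate_smr(_series([1.0] * 9))

    def test_r2_filter_removes_exactly_the_corrupted_cycle(self, rng, chamber):
        trace = _toy_trace(slope=-1.0, n_cycles=12)
        # corrupt cycle 5's regression window with alternating jitter
        m = (trace.cycle == 5) & (trace.phase == "closed")
        trace.po2[m] += np.where(np.arange(m.sum()) % 2 == 0, 3.0, -3.0)
        regs = resp.fit_cycle_slopes(trace)
        dropped = [r.cycle_index for r in regs if not r.retained]
        assert dropped == [5]


class TestEstimatePcrit:
    def test_zero_noise_recovery_within_one_bin(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(smr_true=smr_umol, pcrit_true=30.0, mass=0.091)
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=4.0, noise_sd=0.0, seed=0,
            conditions=seawater_24,
        )
        run = synth.simulate_closed_pcrit_run(fish, cfg, stop_po2=12.7)
        est = resp.estimate_pcrit(run, smr_umol, chamber)
        alpha = o2_solubility(seawater_24)
        bin_width = 2.0 * smr_umol * 0.091 / (alpha * (2.5 - 0.091))
        assert abs(est.value - 30.0) < bin_width
        assert not est.censored
        assert abs(est.first_bin_below - 30.0) < bin_width

    def test_regulator_never_conforming_is_censored(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(smr_true=smr_umol, pcrit_true=5.0, mass=0.091)
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=4.0, noise_sd=0.0, seed=0,
            conditions=seawater_24,
        )
        run = synth.simulate_closed_pcrit_run(fish, cfg, stop_po2=12.7)
        est = resp.estimate_pcrit(run, smr_umol, chamber)
        assert est.censored
        assert est.value == pytest.approx(run.po2.min(), abs=1.0)

    def test_pure_conformer_crossing_equals_pstar(self, chamber, seawater_24):
        # conformer from the start (pcrit above ambient); with SMR set to
        # the conformer line at P*, the crossing is exactly P*
        fish = synth.FishModel(smr_true=80.0, pcrit_true=500.0, mass=0.091)
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=20.0, noise_sd=0.0, seed=0,
            conditions=seawater_24,
        )
        run = synth.simulate_closed_pcrit_run(fish, cfg, stop_po2=20.0)
        p_star = 60.0
        smr_at_pstar = 80.0 * p_star / 500.0
        est = resp.estimate_pcrit(run, smr_at_pstar, chamber)
        assert est.value == pytest.approx(p_star, abs=0.5)

    def test_noise_robustness_median_error(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(smr_true=smr_umol, pcrit_true=36.2, mass=0.091)
        errs = []
        for s in range(100):
            cfg = synth.TraceSimConfig(
                chamber_volume=2.5, duration_h=4.0, noise_sd=0.5, seed=500 + s,
                conditions=seawater_24,
            )
            run = synth.simulate_closed_pcrit_run(fish, cfg, stop_po2=12.7)
            errs.append(resp.estimate_pcrit(run, smr_umol, chamber).value - 36.2)
        assert np.median(np.abs(errs)) <= 3.0


class TestFullChain:
    def test_zero_noise_recovers_smr_and_pcrit(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(smr_true=smr_umol, pcrit_true=36.2, mass=0.091)
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=2.0, noise_sd=0.0, seed=1,
            conditions=seawater_24,
        )
        trace = synth.simulate_trace(fish, cfg)
        series = resp.mo2_series_from_trace(trace, chamber)
        smr = resp.estimate_smr(series)
        assert smr.value == pytest.approx(smr_umol, rel=1e-6)
        run_cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=4.0, noise_sd=0.0, seed=2,
            conditions=seawater_24,
        )
        run = synth.simulate_closed_pcrit_run(fish, run_cfg, stop_po2=12.7)
        est = resp.estimate_pcrit(run, smr, chamber)
        alpha = o2_solubility(seawater_24)
        bin_width = 2.0 * smr_umol * 0.091 / (alpha * (2.5 - 0.091))
        assert abs(est.value - 36.2) < bin_width

    def test_smr_recovery_with_activity_bursts(self, smr_umol, chamber, seawater_24):
        fish = synth.FishModel(
            smr_true=smr_umol, pcrit_true=36.2, mass=0.091,
            activity_rate=12.0, activity_magnitude=1.0,
        )
        cfg = synth.TraceSimConfig(
            chamber_volume=2.5, duration_h=20.0, noise_sd=0.2, seed=7,
            conditions=seawater_24,
        )
        trace = synth.simulate_trace(fish, cfg)
        series = resp.mo2_series_from_trace(trace, chamber)
        smr = resp.estimate_smr(series)
        assert smr.value == pytest.approx(smr_umol, rel=0.05)


def test_trace_csv_round_trip(tmp_path, regulator_fish, quiet_trace_cfg):
    trace = synth.simulate_trace(regulator_fish, quiet_trace_cfg)
    path = tmp_path / "trace.csv"
    resp.write_trace_csv(trace, path)
    back = resp.read_trace_csv(path)
    assert np.allclose(back.po2, trace.po2)
    assert np.array_equal(back.phase, trace.phase)
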