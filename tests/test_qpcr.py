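import numpy as np
import pandas as pd
import pytest

from hypoxphys import qpcr, synth


def _table(rows, ref="ef1a"):
    return qpcr.CtTable(data=pd.DataFrame(rows), ref_gene=ref)


class TestEfficiencyFromStandardCurve:
    def test_perfect_doubling(self):
        x = np.array([0.0, -1.0, -2.0, -3.0])
        ct = 20.0 - 3.321928 * x
        e, pct = qpcr.efficiency_from_standard_curve(x, ct)
        assert e == pytest.approx(2.0, abs=1e-5)
        assert pct == pytest.approx(100.0, abs=1e-3)

    def test_slope_minus_3_9(self):
        # E = 10^(1/3.9) = 1.805, i.e. 80.5% efficiency
        x = np.array([0.0, -1.0, -2.0, -3.0])
        ct = 18.0 - 3.9 * x
        e, pct = qpcr.efficiency_from_standard_curve(x, ct)
        assert e == pytest.approx(1.805, abs=5e-4)
        assert pct == pytest.approx(80.5, abs=0.05)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            qpcr.efficiency_from_standard_curve([0, -1, -2], [20, 19, 18])

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            qpcr.efficiency_from_standard_curve([0, 0], [20, 20])
        with pytest.raises(ValueError):
            qpcr.efficiency_from_standard_curve([0, 0, 0], [20, 20, 21])


class TestDdctFoldChange:
    def test_identical_cts_give_fold_one(self):
        rows = []
        for trt in ("normoxia", "hypoxia"):
            for i in range(3):
                sid = f"{trt}{i}"
                rows.append({"sample_id": sid, "treatment": trt, "gene": "ef1a",
                             "ct": 18.0, "efficiency": 1.9})
                rows.append({"sample_id": sid, "treatment": trt, "gene": "hb",
                             "ct": 24.0, "efficiency": 1.8})
        res = qpcr.ddct_fold_change(_table(rows), "hb", "normoxia", "hypoxia")
        assert np.allclose(res.per_sample["fold_change"], 1.0)

    def test_one_cycle_drop_at_e2_doubles(self):
        rows = []
        for trt, ct_hb in (("normoxia", 24.0), ("hypoxia", 23.0)):
            for i in range(3):
                sid = f"{trt}{i}"
                rows.append({"sample_id": sid, "treatment": trt, "gene": "ef1a",
                             "ct": 18.0, "efficiency": 2.0})
                rows.append({"sample_id": sid, "treatment": trt, "gene": "hb",
                             "ct": ct_hb, "efficiency": 2.0})
        res = qpcr.ddct_fold_change(_table(rows), "hb", "normoxia", "hypoxia")
        hyp = res.summary[res.summary["treatment"] == "hypoxia"]["mean"].iloc[0]
        assert hyp == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("method", ["pfaffl", "target_only", "classic"])
    def test_generator_round_trip_fold_3_7(self, method):
        # loading offsets only cancel exactly under the Pfaffl ratio or
        # with equal efficiencies, so keep loading at zero here
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "hb": 0.2}, {"ef1a": 1.93, "hb": 1.86},
            ref_gene="ef1a", n_samples=5,
            treatment_fold_changes={"hb": 3.7}, ct_noise_sd=0.0, seed=2,
        )
        res = qpcr.ddct_fold_change(t, "hb", "normoxia", "hypoxia", method=method)
        hyp = res.summary[res.summary["treatment"] == "hypoxia"]["mean"].iloc[0]
        if method == "classic":
            assert hyp != pytest.approx(3.7, rel=1e-3)  # wrong E biases fold
        else:
            assert hyp == pytest.approx(3.7, rel=1e-9)

    def test_pfaffl_invariant_to_loading_offsets(self):
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "hb": 0.2}, {"ef1a": 1.93, "hb": 1.86},
            ref_gene="ef1a", n_samples=5,
            treatment_fold_changes={"hb": 3.7}, ct_noise_sd=0.0,
            loading_sd=0.5, seed=3,
        )
        res = qpcr.ddct_fold_change(t, "hb", "normoxia", "hypoxia")
        assert np.allclose(
            res.per_sample[res.per_sample["treatment"] == "hypoxia"]["fold_change"],
            3.7,
        )

    def test_reference_gene_against_itself_is_one(self):
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "hb": 0.2}, {"ef1a": 1.93, "hb": 1.86},
            ref_gene="ef1a", n_samples=4,
            treatment_fold_changes={"hb": 2.0}, ct_noise_sd=0.1, seed=4,
        )
        res = qpcr.ddct_fold_change(t, "ef1a", "normoxia", "hypoxia")
        hyp = res.summary[res.summary["treatment"] == "hypoxia"]["mean"].iloc[0]
        assert hyp == pytest.approx(1.0, abs=1e-9)

    def test_undetected_sample_excluded_with_log(self):
        rows = []
        for trt in ("normoxia", "hypoxia"):
            for i in range(3):
                sid = f"{trt}{i}"
                rows.append({"sample_id": sid, "treatment": trt, "gene": "ef1a",
                             "ct": 18.0, "efficiency": 1.9})
                ct = np.nan if sid == "hypoxia1" else 24.0
                rows.append({"sample_id": sid, "treatment": trt, "gene": "hb",
                             "ct": ct, "efficiency": 1.8})
        res = qpcr.ddct_fold_change(_table(rows), "hb", "normoxia", "hypoxia")
        assert res.excluded_samples == ["hypoxia1"]
        assert len(res.per_sample) == 5


class TestRelativeAbundance:
    def test_anchor_is_one_in_every_sample(self):
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "a31": 1.0, "a32": 0.12},
            {"ef1a": 1.93, "a31": 1.90, "a32": 1.86},
            ref_gene="ef1a", n_samples=7, ct_noise_sd=0.3, seed=5,
        )
        res = qpcr.relative_abundance(t, "a31")
        anchor = res.per_sample[res.per_sample["gene"] == "a31"]
        assert np.allclose(anchor["relative_abundance"], 1.0)

    def test_six_cycles_at_e2_is_64_fold(self):
        rows = [
            {"sample_id": "s1", "treatment": "normoxia", "gene": "hi",
             "ct": 20.0, "efficiency": 2.0},
            {"sample_id": "s1", "treatment": "normoxia", "gene": "lo",
             "ct": 26.0, "efficiency": 2.0},
        ]
        res = qpcr.relative_abundance(_table(rows, ref="hi"), "hi")
        lo = res.per_sample[res.per_sample["gene"] == "lo"]["relative_abundance"]
        assert lo.iloc[0] == pytest.approx(1.0 / 64.0, rel=1e-12)

    def test_true_abundance_recovered_exactly(self):
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "a31": 1.0, "a32": 0.12},
            {"ef1a": 1.93, "a31": 1.90, "a32": 1.86},
            ref_gene="ef1a", n_samples=7, ct_noise_sd=0.0, seed=6,
        )
        res = qpcr.relative_abundance(t, "a31")
        got = res.summary[
            (res.summary["gene"] == "a32") & (res.summary["treatment"] == "normoxia")
        ]["mean"].iloc[0]
        assert got == pytest.approx(0.12, rel=1e-12)

    def test_fold_ratio_consistency_with_equal_efficiencies(self):
        # with all E equal, the ratio of two genes' ddct fold changes
        # equals the ratio of their anchored-abundance changes
        t = synth.simulate_ct_table(
            {"ef1a": 1.0, "g1": 0.5, "g2": 0.1},
            {"ef1a": 1.9, "g1": 1.9, "g2": 1.9},
            ref_gene="ef1a", n_samples=4,
            treatment_fold_changes={"g1": 5.0, "g2": 2.0},
            ct_noise_sd=0.0, seed=7,
        )
        f1 = qpcr.ddct_fold_change(t, "g1", "normoxia", "hypoxia").summary
        f2 = qpcr.ddct_fold_change(t, "g2", "normoxia", "hypoxia").summary
        fold_ratio = (
            f1[f1["treatment"] == "hypoxia"]["mean"].iloc[0]
            / f2[f2["treatment"] == "hypoxia"]["mean"].iloc[0]
        )
        ab = qpcr.relative_abundance(t, "g1").summary
        a_n = ab[(ab["gene"] == "g2") & (ab["treatment"] == "normoxia")]["mean"].iloc[0]
        a_h = ab[(ab["gene"] == "g2") & (ab["treatment"] == "hypoxia")]["mean"].iloc[0]
        assert fold_ratio == pytest.approx(a_n / a_h, rel=1e-9)

    def test_detection_power_under_noise(self):
        # 4-fold up-regulation, ct noise 0.2, n = 7: the fold CI should
        # exclude 1 in at least 90% of replicates
        from scipy import stats as sps

        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            t = synth.simulate_ct_table(
                {"ef1a": 1.0, "hb": 0.2}, {"ef1a": 1.93, "hb": 1.86},
                ref_gene="ef1a", n_samples=7,
                treatment_fold_changes={"hb": 4.0}, ct_noise_sd=0.2, seed=seed,
            )
            res = qpcr.ddct_fold_change(t, "hb", "normoxia", "hypoxia")
            logf = np.log2(
                res.per_sample[res.per_sample["treatment"] == "hypoxia"]["fold_change"]
            )
            lo, hi = sps.t.interval(0.95, len(logf) - 1, loc=logf.mean(),
                                    scale=logf.sem())
            if lo > 0 or hi < 0:
                hits += 1
        assert hits / n_rep >= 0.90


class TestCtTableValidation:
    def test_missing_reference_rejected(self):
        rows = [{"sample_id": "s1", "treatment": "n", "gene": "hb",
                 "ct": 20.0, "efficiency": 1.9}]
        with pytest.raises(ValueError):
            _table(rows)

    def test_efficiency_bounds_enforced(self):
        rows = [{"sample_id": "s1", "treatment": "n", "gene": "ef1a",
                 "ct": 20.0, "efficiency": 2.3}]
        with pytest.raises(ValueError):
            _table(rows)

    def test_undetected_listed_not_imputed(self):
        rows = [
            {"sample_id": "s1", "treatment": "n", "gene": "ef1a",
             "ct": 18.0, "efficiency": 1.9},
            {"sample_id": "s1", "treatment": "n", "gene": "hba5",
             "ct": np.nan, "efficiency": 1.8},
        ]
        t = _table(rows)
        assert list(t.undetected()["gene"]) == ["hba5"]


def test_ct_csv_round_trip(tmp_path):
    t = synth.simulate_ct_table(
        {"ef1a": 1.0, "hb": 0.2}, {"ef1a": 1.93, "hb": 1.86},
        ref_gene="ef1a", n_samples=3, ct_noise_sd=0.1, seed=8,
    )
    path = tmp_path / "ct.csv"
    t.data.to_csv(path, index=False)
    back = qpcr.read_ct_csv(path, ref_gene="ef1a")
    assert np.allclose(back.data["ct"], t.data["ct"])
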