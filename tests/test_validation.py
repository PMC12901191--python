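"""Calibration fitting, ICH gates, LOD/LOQ, recovery, matrix effect."""

import itertools
import math

import numpy as np
import pytest

from licoquant.simulate import SimConfig, generate_injection_table
from licoquant.validation import (
    CalibrationFit,
    QCBatch,
    calibration_acceptance,
    fit_calibration,
    homogenate_to_tissue,
    lod_loq,
    matrix_effect,
    precision_accuracy,
    quantify,
    recovery,
    tissue_to_homogenate,
)

LEVELS = (0.5, 0.75, 1.5, 5.0, 10.0, 20.0)


def _fit_from_line(slope, intercept, assay_id=""):
    pts = [(c, slope * c + intercept) for c in LEVELS]
    return fit_calibration(pts, assay_id=assay_id)


class TestFitCalibration:
    def test_recovers_printed_line_to_six_sig_figs(self, noiseless_config):
        design = [{"role": "calibrator", "nominal": c} for c in LEVELS]
        t = generate_injection_table(design, noiseless_config, seed=0)
        fit = fit_calibration(t[["nominal", "area_ratio"]])
        assert fit.slope == pytest.approx(8.5133, rel=1e-7)
        assert fit.intercept == pytest.approx(1.7962, rel=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_simple_line(self):
        fit = _fit_from_line(2.0, 0.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_unbiased(self):
        cfg = SimConfig(cv_intra=0.05, cv_inter_day=0.0)
        design = [{"role": "solvent", "nominal": c} for c in LEVELS]
        slopes = []
        for seed in range(200):
            t = generate_injection_table(design, cfg, seed=seed)
            slopes.append(fit_calibration(t[["nominal", "area_ratio"]]).slope)
        assert np.mean(slopes) == pytest.approx(cfg.slope_true, rel=0.01)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(c, 2 * c) for c in (1, 2, 3, 4, 5)])

    def test_weighted_fit_on_exact_line_matches(self):
        pts = [(c, 8.5133 * c + 1.7962) for c in LEVELS]
        fit = fit_calibration(pts, weighting="1/x2")
        assert fit.slope == pytest.approx(8.5133, rel=1e-9)
        assert fit.intercept == pytest.approx(1.7962, rel=1e-9)


class TestCalibrationGate:
    def test_all_small_deviations_pass(self):
        assert calibration_acceptance(_fit_from_line(2.0, 0.0)).passed

    def test_counting_rule_oracle(self):
        """Gate decision equals brute-force rule application over
        enumerated deviation patterns."""
        for pattern in itertools.product([0.0, 18.0], repeat=6):
            pts = [
                (c, 2.0 * (c * (1 + d / 100))) for c, d in zip(LEVELS, pattern)
            ]
            fit = CalibrationFit(
                slope=2.0, intercept=0.0, r_squared=1.0,
                calibrators=fit_calibration(pts).calibrators,
            )
            gate = calibration_acceptance(fit)
            devs = fit.calibrators["pct_dev"].abs()
            expect = (
                (devs <= 15).mean() >= 0.75
                and bool(devs[np.isclose(fit.calibrators["nominal"], 0.5)]
                         .le(20).all())
            )
            assert gate.passed == expect

    def test_lloq_rule(self):
        pts = [(0.5, 2.0 * 0.5 * 1.25)] + [(c, 2.0 * c) for c in LEVELS[1:]]
        fit = fit_calibration(pts)
        # refit absorbs some deviation; apply the gate to raw back-calcs
        fit = CalibrationFit(2.0, 0.0, 1.0, fit.calibrators)
        import pandas as pd
        back = fit.calibrators["area_ratio"] / 2.0
        fit.calibrators["back_calc"] = back
        fit.calibrators["pct_dev"] = 100 * (back - fit.calibrators["nominal"]) / fit.calibrators["nominal"]
        assert not calibration_acceptance(fit).passed


class TestLodLoq:
    def test_printed_pair_couples_at_10_over_3_3(self):
        sigma = 0.14 * 8.5133 / 3.3
        rng = np.random.default_rng(0)
        # nine assays whose intercept SD is exactly sigma, mean slope 8.5133
        intercepts = np.array([1.8 + sigma * z for z in
                               (rng.standard_normal(9))])
        intercepts = (intercepts - intercepts.mean()) / intercepts.std(ddof=1)
        intercepts = 1.7962 + sigma * intercepts
        fits = [_fit_from_line(8.5133, b, assay_id=str(i))
                for i, b in enumerate(intercepts)]
        summary = lod_loq(fits)
        assert round(summary.lod, 2) == 0.14
        assert round(summary.loq, 2) == 0.42
        assert summary.loq / summary.lod == pytest.approx(10 / 3.3, rel=1e-12)

    def test_identical_intercepts_give_zero_limits(self):
        fits = [_fit_from_line(8.5133, 1.7962) for _ in range(3)]
        s = lod_loq(fits)
        assert s.lod == 0.0 and s.loq == 0.0

    def test_too_few_assays_rejected(self):
        with pytest.raises(ValueError):
            lod_loq([_fit_from_line(2, 0)] * 2)

    def test_monte_carlo_lod_near_analytic(self):
        """Mean LOD over meta-replicates tracks the analytic intercept SD."""
        cfg = SimConfig(cv_intra=0.04, cv_inter_day=0.0)
        design = [{"role": "calibrator", "nominal": c} for c in LEVELS]
        x = np.array(LEVELS)
        mu = ((cfg.slope_true * x + cfg.intercept_true)
              * cfg.recovery_true * cfg.matrix_factor_true)
        xbar = x.mean()
        sxx = ((x - xbar) ** 2).sum()
        w = 1 / len(x) - xbar * (x - xbar) / sxx
        sd_b0 = math.sqrt((w**2 * (cfg.cv_intra * mu) ** 2).sum())
        slope_eff = cfg.slope_true * cfg.recovery_true * cfg.matrix_factor_true
        analytic_lod = 3.3 * sd_b0 / slope_eff
        lods = []
        for meta in range(100):
            fits = [
                fit_calibration(
                    generate_injection_table(design, cfg, seed=meta * 9 + k)
                    [["nominal", "area_ratio"]]
                )
                for k in range(9)
            ]
            lods.append(lod_loq(fits).lod)
        assert np.mean(lods) == pytest.approx(analytic_lod, rel=0.30)


class TestPrecisionAccuracy:
    def test_printed_mqc_accuracy(self):
        batch = QCBatch("MQC", 7.5, {1: (7.15, 7.15, 7.15)})
        row = precision_accuracy([batch]).iloc[0]
        assert row["accuracy_pct"] == pytest.approx(95.3333, abs=1e-3)
        # printed 95.34 comes from the unrounded grand mean
        assert abs(row["accuracy_pct"] - 95.34) < 0.01

    def test_identical_replicates(self):
        batch = QCBatch("HQC", 15.0, {1: (16.0, 16.0), 2: (16.0, 16.0)})
        row = precision_accuracy([batch]).iloc[0]
        assert row["intra_day_cv_pct"] == 0.0
        assert row["inter_day_cv_pct"] == 0.0
        assert row["accuracy_pct"] == pytest.approx(100 * 16.0 / 15.0)

    def test_monte_carlo_intra_day_cv(self):
        """Mean intra-day CV estimate lands in [2.5, 5.5]% at truth 4%."""
        cfg = SimConfig(cv_intra=0.04)
        fit_design = [{"role": "calibrator", "nominal": c} for c in LEVELS]
        qc_design = [
            {"role": "QC", "nominal": 7.5, "day": d} for d in (1, 2, 3)
            for _ in range(3)
        ]
        estimates = []
        for seed in range(100):
            t = generate_injection_table(qc_design + fit_design, cfg, seed=seed)
            fit = fit_calibration(
                t[t["role"] == "calibrator"][["nominal", "area_ratio"]],
                weighting="1/x2",
            )
            qc = t[t["role"] == "QC"]
            by_day = {
                int(day): tuple(quantify(r, fit).conc for r in sub["area_ratio"])
                for day, sub in qc.groupby("day")
            }
            row = precision_accuracy(
                [QCBatch("MQC", 7.5, by_day)]
            ).iloc[0]
            estimates.append(row["intra_day_cv_pct"])
        assert 2.5 <= np.mean(estimates) <= 5.5

    def test_single_replicate_day_excluded_from_intra(self):
        batch = QCBatch("LQC", 0.5, {1: (0.51,), 2: (0.49, 0.50, 0.52)})
        row = precision_accuracy([batch]).iloc[0]
        assert not math.isnan(row["intra_day_cv_pct"])  # day 2 still counted
        assert row["grand_mean"] == pytest.approx(np.mean([0.51, 0.49, 0.50, 0.52]))


class TestRecoveryAndMatrix:
    def test_printed_lqc_recovery(self):
        res = recovery([0.678, 0.678, 0.678], [1.0, 1.0, 1.0], level=0.5)
        assert res.recovery_pct == pytest.approx(67.80)

    def test_equal_sides_give_100(self):
        res = recovery([1.1, 0.9, 1.0], [1.1, 0.9, 1.0], level=7.5)
        assert res.recovery_pct == pytest.approx(100.0)

    def test_monte_carlo_recovery_of_truth(self):
        cfg = SimConfig(recovery_true=0.70)
        design = (
            [{"role": "pre-spike", "nominal": 7.5}] * 3
            + [{"role": "post-spike", "nominal": 7.5}] * 3
        )
        ests = []
        for seed in range(100):
            t = generate_injection_table(design, cfg, seed=seed)
            res = recovery(
                t[t["role"] == "pre-spike"]["area_ratio"].tolist(),
                t[t["role"] == "post-spike"]["area_ratio"].tolist(),
                level=7.5,
            )
            ests.append(res.recovery_pct)
        assert abs(np.mean(ests) - 70.0) <= 3.0

    def test_matrix_effect_definition(self):
        res = matrix_effect([80] * 3, [100] * 3, [90] * 3, [100] * 3)
        assert res.mf_analyte == pytest.approx(0.8)
        assert res.mf_is == pytest.approx(0.9)
        assert res.is_normalized_mf == pytest.approx(0.8 / 0.9)
        assert "suppression" in res.gate.detail

    def test_no_matrix_effect(self):
        res = matrix_effect([100] * 3, [100] * 3, [50] * 3, [50] * 3)
        assert res.is_normalized_mf == pytest.approx(1.0)
        assert res.gate.passed

    def test_monte_carlo_gate_behavior_at_truth(self, default_config):
        """IS-normalized MF gate decides correctly >=95% of the time when
        the true normalized factor is 0.88."""
        design = (
            [{"role": "post-spike", "nominal": 7.5}] * 3
            + [{"role": "solvent", "nominal": 7.5}] * 3
        )
        correct = 0
        for seed in range(100):
            t = generate_injection_table(design, default_config, seed=seed)
            post = t[t["role"] == "post-spike"]
            solv = t[t["role"] == "solvent"]
            res = matrix_effect(
                post["area_quant"].tolist(), solv["area_quant"].tolist(),
                post["area_is"].tolist(), solv["area_is"].tolist(),
            )
            correct += res.gate.passed  # truth 0.88 lies inside [0.8, 1.2]
        assert correct >= 95

    def test_scale_invariance(self):
        a = matrix_effect([80, 82, 78], [100, 99, 101], [90, 91, 89], [100] * 3)
        k = 7.3
        b = matrix_effect(
            [k * v for v in (80, 82, 78)], [k * v for v in (100, 99, 101)],
            [k * v for v in (90, 91, 89)], [k * 100] * 3,
        )
        assert b.is_normalized_mf == pytest.approx(a.is_normalized_mf)
        assert b.cv_pct == pytest.approx(a.cv_pct)


class TestQuantify:
    def fit(self):
        return _fit_from_line(8.5133, 1.7962)

    def test_inverse_of_line(self):
        q = quantify(8.5133 * 5 + 1.7962, self.fit())
        assert q.conc == pytest.approx(5.0, abs=1e-9)
        assert q.flag is None

    def test_below_intercept_is_blq(self):
        q = quantify(1.0, self.fit(), loq=0.42)
        assert q.flag == "BLQ"

    def test_above_range_is_alq(self):
        q = quantify(8.5133 * 25 + 1.7962, self.fit())
        assert q.flag == "ALQ"

    def test_monte_carlo_unbiased(self):
        cfg = SimConfig(cv_intra=0.04, cv_inter_day=0.0)
        design = (
            [{"role": "calibrator", "nominal": c} for c in LEVELS]
            + [{"role": "unknown", "nominal": 7.5}] * 200
        )
        t = generate_injection_table(design, cfg, seed=11)
        fit = fit_calibration(
            t[t["role"] == "calibrator"][["nominal", "area_ratio"]]
        )
        concs = [
            quantify(r, fit).conc
            for r in t[t["role"] == "unknown"]["area_ratio"]
        ]
        assert np.mean(concs) == pytest.approx(7.5, rel=0.02)


class TestUnitBridge:
    def test_homogenate_to_tissue(self):
        assert homogenate_to_tissue(14.37) == pytest.approx(0.1437)
        assert homogenate_to_tissue(0.0) == 0.0

    def test_round_trip(self):
        assert tissue_to_homogenate(homogenate_to_tissue(7.31)) == pytest.approx(7.31)
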