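"""Dashboard tabs, trend regression, and label-gated performance metrics."""

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from driftwatch.datamodel import DailySnapshot, MonitorConfig
from driftwatch.monitors import (
    UndefinedMetricError,
    covariate_monitor,
    historical_monitor,
    last_window,
    missingness_monitor,
    outcome_performance,
    probability_monitor,
    run_all_monitors,
    trend_check,
    volume_monitor,
)
from driftwatch.synthetic import ShiftInjection, make_reference, simulate_stream

from conftest import small_generator


class TestProbabilityMonitor:
    def test_null_window_no_finding(self, reference, null_stream, monitor_cfg):
        report = probability_monitor(null_stream, reference, monitor_cfg)
        assert report.findings == []
        assert len(report.payload["daily_summary"]) == len(
            last_window(null_stream, monitor_cfg.window_days)
        )

    def test_score_inflation_emits_finding(self, reference, monitor_cfg, small_cfg):
        stream = simulate_stream(
            small_cfg,
            (ShiftInjection("probabilities", "mean_shift", onset_day=1, magnitude=0.15),),
        )
        report = probability_monitor(stream, reference, monitor_cfg)
        assert len(report.findings) == 1
        assert report.findings[0].kind == "probability_shift"

    def test_all_zero_probabilities_use_log_floor(self, reference, monitor_cfg):
        frame = reference.frame.iloc[:50].reset_index(drop=True)
        stream = [
            DailySnapshot(dt.date(2024, 1, 1) + dt.timedelta(days=d), frame, np.zeros(50))
            for d in range(3)
        ]
        report = probability_monitor(stream, reference, monitor_cfg)
        daily = report.payload["daily_summary"]
        assert np.allclose(daily["log10_mean"], np.log10(monitor_cfg.log_floor))

    def test_empty_window_reports_volume_outage(self, reference, monitor_cfg):
        report = probability_monitor([], reference, monitor_cfg)
        assert len(report.findings) == 1
        assert report.findings[0].kind == "volume_anomaly"


class TestCovariateMonitor:
    def test_rows_ordered_by_importance(self, reference, null_stream, monitor_cfg):
        report = covariate_monitor(null_stream, reference, monitor_cfg)
        table = report.payload["table"]
        assert list(table["importance_rank"]) == sorted(table["importance_rank"])
        assert table.iloc[0]["importance_rank"] == 1
        assert len(table) == len(reference.catalogue)

    def test_injected_feature_has_largest_standardized_difference(self):
        hits = 0
        for seed in range(10):
            cfg = small_generator(seed=seed, n_days=14, calls_per_day=100)
            ref = make_reference(cfg)
            stream = simulate_stream(
                cfg, (ShiftInjection("lab_03", "mean_shift", onset_day=1, magnitude=1.0),)
            )
            report = covariate_monitor(stream, ref, MonitorConfig(seed=seed))
            table = report.payload["table"]
            top = table.loc[table["standardized_difference"].abs().idxmax(), "feature"]
            hits += top == "lab_03"
        assert hits >= 9

    def test_degenerate_feature_kept_with_flag(self, monitor_cfg, small_cfg):
        ref = make_reference(small_cfg)
        stream = simulate_stream(
            small_cfg, (ShiftInjection("lab_02", "code_change", onset_day=1),)
        )
        report = covariate_monitor(stream, ref, monitor_cfg)
        row = report.payload["table"].set_index("feature").loc["lab_02"]
        assert bool(row["degenerate"])
        assert all(f.feature != "lab_02" for f in report.findings)

    def test_findings_match_significant_rows(self, reference, null_stream, monitor_cfg):
        report = covariate_monitor(null_stream, reference, monitor_cfg)
        table = report.payload["table"]
        n_sig = int(
            ((table["p_value"] < monitor_cfg.alpha) & ~table["degenerate"]).sum()
        )
        assert len(report.findings) == n_sig

    def test_window_discipline_truncation_equivalence(self, reference, null_stream, monitor_cfg):
        """Only the trailing window is read: feeding just those snapshots
        reproduces the report."""
        window = last_window(null_stream, monitor_cfg.window_days)
        full = covariate_monitor(null_stream, reference, monitor_cfg)
        trunc = covariate_monitor(window, reference, monitor_cfg)
        pd.testing.assert_frame_equal(full.payload["table"], trunc.payload["table"])
        p_full = probability_monitor(null_stream, reference, monitor_cfg)
        p_trunc = probability_monitor(window, reference, monitor_cfg)
        assert p_full.payload["comparison"] == p_trunc.payload["comparison"]


class TestHistoricalMonitors:
    def test_grid_ordering_findings_and_payload_complete(self, reference, null_stream, monitor_cfg):
        for monitor in (historical_monitor, missingness_monitor):
            report = monitor(null_stream, reference, monitor_cfg)
            grid = report.payload["grid"]
            assert list(grid["importance_rank"]) == sorted(grid["importance_rank"])
            assert set(grid["feature"]) == {f.name for f in reference.catalogue}
            assert set(report.payload["charts"]) == {f.name for f in reference.catalogue}
            n_red = int((grid["level_flag"] == "red").sum() + (grid["scale_flag"] == "red").sum())
            assert len(report.findings) == n_red

    def test_missingness_collapse_marks_blocking(self):
        cfg = small_generator(seed=4, n_days=40, calls_per_day=80)
        ref = make_reference(cfg)
        stream = simulate_stream(cfg, (ShiftInjection("lab_01", "code_change", onset_day=20),))
        report = missingness_monitor(stream, ref, MonitorConfig(n_permutations=400, seed=1))
        blocked = [f for f in report.findings if f.blocking]
        assert blocked and all(f.feature == "lab_01" for f in blocked)

    def test_reports_are_pure_functions(self, reference, null_stream, monitor_cfg):
        r1 = historical_monitor(null_stream, reference, monitor_cfg)
        r2 = historical_monitor(null_stream, reference, monitor_cfg)
        pd.testing.assert_frame_equal(r1.payload["grid"], r2.payload["grid"])
        assert [dataclasses.asdict(f) for f in r1.findings] == [
            dataclasses.asdict(f) for f in r2.findings
        ]


class TestVolumeMonitor:
    def _stream(self, counts, start=dt.date(2024, 3, 1), gaps=()):
        out = []
        for i, c in enumerate(counts):
            day = start + dt.timedelta(days=i)
            if day in gaps:
                continue
            frame = pd.DataFrame({"a": np.ones(c)})
            out.append(DailySnapshot(day, frame, np.full(c, 0.1)))
        return out

    def test_poisson_counts_no_anomaly(self, rng, monitor_cfg):
        stream = self._stream(rng.poisson(200, size=14))
        report = volume_monitor(stream, monitor_cfg)
        assert report.findings == []

    def test_zero_call_day_exactly_one_finding(self, rng, monitor_cfg):
        counts = list(rng.poisson(200, size=13)) + [0]
        stream = self._stream(counts)
        report = volume_monitor(stream, monitor_cfg)
        assert len(report.findings) == 1
        assert report.findings[0].detail == "zero model calls"

    def test_absent_date_reported(self, rng, monitor_cfg):
        gap = dt.date(2024, 3, 1) + dt.timedelta(days=7)
        stream = self._stream(rng.poisson(200, size=14), gaps=(gap,))
        report = volume_monitor(stream, monitor_cfg)
        assert [f.date for f in report.findings] == [gap.isoformat()]
        assert report.findings[0].detail == "no snapshot for this date"

    def test_burst_outside_mad_band_flagged(self, rng, monitor_cfg):
        counts = list(rng.poisson(200, size=13)) + [500]
        report = volume_monitor(self._stream(counts), monitor_cfg)
        assert len(report.findings) == 1
        assert report.findings[0].detail.startswith("count outside")


class TestTrendCheck:
    def _stream_from_daily_means(self, means, n=40, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i, m in enumerate(means):
            frame = pd.DataFrame({"a": np.ones(n)})
            p = np.clip(np.full(n, m) + rng.normal(0, 1e-6, n), 0, 1)
            out.append(DailySnapshot(dt.date(2024, 1, 1) + dt.timedelta(days=i), frame, p))
        return out

    def test_constant_means_slope_zero(self):
        stream = self._stream_from_daily_means([0.07] * 40)
        res = trend_check(stream, min_days=30)
        assert res.slope == pytest.approx(0.0, abs=1e-6)

    def test_slope_matches_closed_form_oracle(self, rng):
        """OLS slope equals sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)."""
        means = 0.06 + 0.0004 * np.arange(60) + rng.normal(0, 0.005, 60)
        means = np.clip(means, 0, 1)
        stream = self._stream_from_daily_means(means, n=5, seed=1)
        res = trend_check(stream, min_days=30)
        x = np.arange(60.0)
        y = np.array([s.probabilities.mean() for s in stream])
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert res.slope == pytest.approx(oracle, abs=1e-10)
        assert res.ci_low < oracle < res.ci_high

    def test_insufficient_days(self):
        stream = self._stream_from_daily_means([0.07] * 10)
        res = trend_check(stream, min_days=30)
        assert res.status == "insufficient_data"
        assert np.isnan(res.slope)


class TestOutcomePerformance:
    def test_perfect_probabilities_auroc_one(self):
        y = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        res = outcome_performance(y, y)
        assert res.auroc == 1.0
        assert res.auprc == 1.0

    def test_auroc_matches_pairwise_concordance_oracle(self, rng):
        """AUROC equals the O(n^2) count of concordant case/control pairs
        with half credit for ties."""
        for _ in range(10):
            p = np.round(rng.random(50), 2)  # rounding forces ties
            y = (rng.random(50) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            pos, neg = p[y == 1], p[y == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            oracle = (gt + 0.5 * eq) / (len(pos) * len(neg))
            assert outcome_performance(p, y).auroc == pytest.approx(oracle, abs=1e-10)

    def test_independent_probabilities_auroc_near_half(self, rng):
        p = rng.random(2000)
        y = (rng.random(2000) < 0.3).astype(float)
        res = outcome_performance(p, y)
        assert res.auroc == pytest.approx(0.5, abs=0.05)
        assert res.prevalence == pytest.approx(0.3, abs=0.05)

    def test_calibrated_model_recovers_identity(self, rng):
        p = rng.beta(1, 8, 5000)
        y = (rng.random(5000) < p).astype(float)
        res = outcome_performance(p, y)
        assert res.calibration_slope == pytest.approx(1.0, abs=0.15)
        assert res.calibration_intercept == pytest.approx(0.0, abs=0.25)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            outcome_performance(np.array([0.1, 0.9]), np.array([1.0, 1.0]))


def test_run_all_monitors_covers_all_tabs(reference, null_stream, monitor_cfg):
    reports = run_all_monitors(null_stream, reference, monitor_cfg)
    assert list(reports) == [
        "probabilities", "features", "historical_covariates",
        "historical_missingness", "volume",
    ]
    for tab, report in reports.items():
        assert report.tab == tab
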