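"""The five dashboard tabs as pure report-producing stages.

Each monitor is a pure function of (stream, reference, config): it returns a
:class:`TabReport` whose payload holds the tab's tables and series and whose
findings list carries exactly one :class:`~driftwatch.triage.Finding` per red
or anomalous payload entry. Nothing here mutates state or touches the file
system; the CLI layer serializes reports.

Tabs
----
probabilities
    Daily predicted-probability distributions (raw and log10 with a floor,
    since scores cluster near 0) plus a pooled window-vs-training comparison.
probabilities are the label-free stand-in for performance: with no outcome
    feed, a shift in the score distribution is the earliest visible symptom
    of performance loss.
features
    One comparison row per feature over the look-back window, joined with the
    model's importance rank so drift can be triaged by influence.
historical_covariates / historical_missingness
    Full-history level/scale rank charts per feature (green/red grid).
volume
    Daily call counts with a robust median +/- k*MAD anomaly band; zero-call
    and absent days are always anomalous.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .datamodel import (
    DailySnapshot,
    FeatureSpec,
    MonitorConfig,
    TrainingReference,
)
from .phase1_charts import (
    ChartResult,
    chart_feature_history,
    chart_missingness_history,
)
from .shift_stats import (
    ComparisonStats,
    WindowDriftTest,
    compare_window,
    daily_standardized_differences,
    pooled_window_values,
)
from .triage import Finding

TABS = (
    "probabilities",
    "features",
    "historical_covariates",
    "historical_missingness",
    "volume",
)


@dataclass
class TabReport:
    """One dashboard tab: a payload of tables/series plus its findings."""

    tab: str
    window: tuple[_dt.date, _dt.date] | None
    payload: dict
    findings: list[Finding] = field(default_factory=list)


def last_window(stream: Sequence[DailySnapshot], window_days: int) -> list[DailySnapshot]:
    """The snapshots falling in the trailing ``window_days`` calendar days."""
    if not stream:
        return []
    end = stream[-1].date
    start = end - _dt.timedelta(days=window_days - 1)
    return [s for s in stream if s.date >= start]


def _window_range(window: Sequence[DailySnapshot]):
    return (window[0].date, window[-1].date) if window else None


# ---------------------------------------------------------------------------
# Probabilities tab
# ---------------------------------------------------------------------------

def probability_monitor(
    stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> TabReport:
    """Daily score distributions plus pooled window-vs-training comparison."""
    window = last_window(stream, config.window_days)
    if not window:
        finding = Finding(
            source="probabilities",
            kind="volume_anomaly",
            detail="empty monitoring window: no model calls observed",
        )
        return TabReport(
            tab="probabilities", window=None, payload={"daily_summary": pd.DataFrame()},
            findings=[finding],
        )

    floor = config.log_floor
    rows = []
    for snap in window:
        p = snap.probabilities
        logp = np.log10(np.maximum(p, floor)) if len(p) else np.array([])
        rows.append(
            {
                "date": snap.date,
                "n": len(p),
                "mean": _safe(np.mean, p),
                "median": _safe(np.median, p),
                "q25": _safe(lambda x: np.quantile(x, 0.25), p),
                "q75": _safe(lambda x: np.quantile(x, 0.75), p),
                "log10_mean": _safe(np.mean, logp),
                "log10_median": _safe(np.median, logp),
            }
        )
    daily = pd.DataFrame(rows)

    pooled = np.concatenate([s.probabilities for s in window])
    test = WindowDriftTest(kind="continuous", alpha=config.alpha).fit(reference.probabilities)
    comparison = test.compare(pooled, feature_name="predicted_probability")

    findings = []
    if (not comparison.degenerate) and comparison.p_value < config.alpha:
        findings.append(
            Finding(
                source="probabilities",
                kind="probability_shift",
                magnitude=comparison.standardized_difference,
                detail=(
                    f"window score distribution shifted from training "
                    f"(KS p={comparison.p_value:.3g})"
                ),
            )
        )
    return TabReport(
        tab="probabilities",
        window=_window_range(window),
        payload={"daily_summary": daily, "comparison": comparison, "log_floor": floor},
        findings=findings,
    )


def _safe(fn, x):
    return float(fn(x)) if len(x) else float("nan")


# ---------------------------------------------------------------------------
# Features tab
# ---------------------------------------------------------------------------

def covariate_monitor(
    stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> TabReport:
    """Window-vs-training comparison for every catalogue feature.

    Rows are ordered by importance rank (rank 1 first); the interactive-table
    idiom of sorting by any column is preserved by shipping the full table.
    Degenerate features (no usable window data) stay in the table with an
    explicit flag.
    """
    if not reference.catalogue:
        raise ValueError("covariate_monitor requires a nonempty catalogue")
    window = last_window(stream, config.window_days)
    if not window:
        raise ValueError("covariate_monitor requires a nonempty window")
    rows, series, findings = [], {}, []
    for feature in sorted(reference.catalogue, key=lambda f: f.importance_rank):
        cs = compare_window(feature, window, reference, alpha=config.alpha)
        rows.append(cs.to_row())
        series[feature.name] = daily_standardized_differences(feature, window, reference)
        if (not cs.degenerate) and cs.p_value < config.alpha:
            # rows significant at per-feature alpha are expected in every
            # in-control fortnight (~alpha * n_features of them); they are
            # table material for the analyst, and escalate only when they
            # would survive a Bonferroni correction across the table
            findings.append(
                Finding(
                    source="features",
                    kind="covariate_shift",
                    feature=feature.name,
                    magnitude=cs.standardized_difference,
                    importance_rank=feature.importance_rank,
                    escalate=bool(cs.p_value < config.alpha / len(reference.catalogue)),
                    detail=f"{cs.test_name} p={cs.p_value:.3g} over the window",
                )
            )
    table = pd.DataFrame(rows)
    return TabReport(
        tab="features",
        window=_window_range(window),
        payload={"table": table, "daily_standardized_differences": series},
        findings=findings,
    )


# ---------------------------------------------------------------------------
# Historical chart tabs
# ---------------------------------------------------------------------------

def _chart_tab(
    tab: str,
    kind: str,
    charts_fn,
    full_stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> TabReport:
    charts: dict[str, tuple[ChartResult, ChartResult]] = {}
    rows, findings = [], []
    for feature in sorted(reference.catalogue, key=lambda f: f.importance_rank):
        lvl, scl = charts_fn(feature, full_stream, reference, config)
        charts[feature.name] = (lvl, scl)
        rows.append(
            {
                "feature": feature.name,
                "importance_rank": feature.importance_rank,
                "level_p": lvl.p_value,
                "level_flag": lvl.flag,
                "level_status": lvl.status,
                "scale_p": scl.p_value,
                "scale_flag": scl.flag,
                "scale_status": scl.status,
            }
        )
        n_charts = 2 * len(reference.catalogue)
        for chart in (lvl, scl):
            if chart.flag == "red":
                # each chart controls its own across-day FAP; across the
                # feature grid ~fap * n_charts red cells are expected under
                # control, so only grid-wise (Bonferroni) significant charts
                # escalate the protocol stage
                findings.append(
                    Finding(
                        source=tab,
                        kind=kind,
                        feature=feature.name,
                        magnitude=chart.p_value,
                        importance_rank=feature.importance_rank,
                        blocking=_wholly_absent(feature, full_stream, config)
                        if kind == "missingness_shift" and chart.chart_kind == "level"
                        else False,
                        escalate=bool(chart.p_value < config.alpha / n_charts),
                        detail=f"{chart.chart_kind} chart red (p={chart.p_value:.3g})",
                    )
                )
    return TabReport(
        tab=tab,
        window=(full_stream[0].date, full_stream[-1].date) if full_stream else None,
        payload={"grid": pd.DataFrame(rows), "charts": charts},
        findings=findings,
    )


def _wholly_absent(feature: FeatureSpec, stream, config: MonitorConfig) -> bool:
    """True when the feature is completely missing over the trailing window."""
    window = last_window(stream, config.window_days)
    if not window:
        return False
    return all(len(s.feature_values(feature.name)) == 0 for s in window)


def historical_monitor(
    full_stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> TabReport:
    """Full-history level/scale charts per feature, ordered by importance."""
    return _chart_tab(
        "historical_covariates", "covariate_shift", chart_feature_history,
        full_stream, reference, config,
    )


def missingness_monitor(
    full_stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> TabReport:
    """Full-history missingness charts per feature.

    A red level chart for a feature that is wholly absent from the trailing
    window is marked blocking: a covariate completely missing from the
    model's input makes the scores untrustworthy.
    """
    return _chart_tab(
        "historical_missingness", "missingness_shift", chart_missingness_history,
        full_stream, reference, config,
    )


# ---------------------------------------------------------------------------
# Volume tab
# ---------------------------------------------------------------------------

def volume_monitor(stream: Sequence[DailySnapshot], config: MonitorConfig) -> TabReport:
    """Daily call-count series with a robust anomaly band.

    A day is anomalous when its count is zero, when the date is absent from
    the stream altogether (a silent outage), or when the count falls outside
    median +/- k*MAD of the trailing window's counts. The MAD band is robust
    to the bursty counts typical of hospital census streams.
    """
    window = last_window(stream, config.window_days)
    findings: list[Finding] = []
    if not window:
        return TabReport(
            tab="volume", window=None, payload={"table": pd.DataFrame()}, findings=[]
        )
    counts = {s.date: s.call_count for s in window}
    observed = np.array(list(counts.values()), dtype=float)
    median = float(np.median(observed))
    mad = float(np.median(np.abs(observed - median)))
    lo = median - config.volume_mad_multiplier * mad
    hi = median + config.volume_mad_multiplier * mad

    start, end = window[0].date, window[-1].date
    rows = []
    day = start
    while day <= end:
        present = day in counts
        count = counts.get(day, 0)
        if not present:
            reason = "absent"
        elif count == 0:
            reason = "zero_calls"
        elif not (lo <= count <= hi):
            reason = "outside_band"
        else:
            reason = ""
        rows.append(
            {"date": day, "call_count": count if present else None,
             "anomalous": bool(reason), "reason": reason}
        )
        if reason:
            findings.append(
                Finding(
                    source="volume",
                    kind="volume_anomaly",
                    date=day.isoformat(),
                    magnitude=float(count),
                    detail={
                        "absent": "no snapshot for this date",
                        "zero_calls": "zero model calls",
                        "outside_band": f"count outside median +/- "
                        f"{config.volume_mad_multiplier}*MAD [{lo:.1f}, {hi:.1f}]",
                    }[reason],
                )
            )
        day += _dt.timedelta(days=1)
    table = pd.DataFrame(rows)
    table["band_low"], table["band_high"] = lo, hi
    return TabReport(
        tab="volume", window=(start, end), payload={"table": table}, findings=findings
    )


# ---------------------------------------------------------------------------
# Trend regression and label-gated performance
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    """OLS of daily mean predicted probability on days since deployment."""

    slope: float
    intercept: float
    p_value: float
    stderr: float
    ci_low: float
    ci_high: float
    n_days: int
    status: str = "ok"


def trend_check(
    stream: Sequence[DailySnapshot], min_days: int = 30, center: str = "mean"
) -> TrendResult:
    """Long-run linear trend in the daily central predicted probability.

    Fits ordinary least squares of the per-day mean (or median, via
    ``center``) probability on integer days since the first observed day and
    reports the two-sided slope test with a 95% CI. Catches slow score
    inflation or deflation that a two-week window cannot see.
    """
    days = [s for s in stream if s.call_count > 0]
    if len(days) < min_days:
        return TrendResult(*(float("nan"),) * 6, n_days=len(days), status="insufficient_data")
    t0 = days[0].date
    x = np.array([(s.date - t0).days for s in days], dtype=float)
    agg = np.mean if center == "mean" else np.median
    y = np.array([agg(s.probabilities) for s in days], dtype=float)
    res = _st.linregress(x, y)
    tcrit = _st.t.ppf(0.975, len(x) - 2)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n_days=len(x),
    )


class UndefinedMetricError(ValueError):
    """Outcome metrics are undefined (e.g. only one outcome class present)."""


@dataclass
class OutcomePerformance:
    auroc: float
    auprc: float
    calibration_intercept: float
    calibration_slope: float
    prevalence: float
    n: int


def outcome_performance(probabilities, labels) -> OutcomePerformance:
    """Label-gated performance metrics, for deployments with an outcome feed.

    AUROC by the rank formula (tied scores get half credit), AUPRC by step
    integration, and calibration by logistic recalibration of logit(p): a
    well-calibrated model has intercept 0 and slope 1. Outcome prevalence is
    reported alongside as the prior-probability-shift tracker.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score
    import statsmodels.api as sm

    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if len(p) != len(y):
        raise ValueError("probabilities and labels must have equal length")
    classes = np.unique(y)
    if len(classes) < 2 or not np.isin(classes, (0.0, 1.0)).all():
        raise UndefinedMetricError("labels must contain both classes coded 0/1")
    auroc = float(roc_auc_score(y, p))
    auprc = float(average_precision_score(y, p))
    eps = 1e-10
    logit = np.log(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps)))
    try:
        fit = sm.Logit(y, sm.add_constant(logit)).fit(disp=0, maxiter=200)
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    except Exception:  # perfect separation and kin
        intercept, slope = float("nan"), float("nan")
    return OutcomePerformance(
        auroc=auroc,
        auprc=auprc,
        calibration_intercept=intercept,
        calibration_slope=slope,
        prevalence=float(y.mean()),
        n=len(y),
    )


def run_all_monitors(
    stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> dict[str, TabReport]:
    """All five tabs in dashboard order."""
    return {
        "probabilities": probability_monitor(stream, reference, config),
        "features": covariate_monitor(stream, reference, config),
        "historical_covariates": historical_monitor(stream, reference, config),
        "historical_missingness": missingness_monitor(stream, reference, config),
        "volume": volume_monitor(stream, config),
    }
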