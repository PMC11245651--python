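"""Static report rendering and run-directory serialization.

The dashboard is rendered as a single self-contained HTML file (plots
embedded as base64 PNG) plus schema-stable CSV/JSON artifacts, so a live
web dashboard can be layered on the same outputs later. Everything written
here is a pure function of the monitor outputs: rerunning on identical
inputs reproduces the CSV/JSON artifacts byte for byte (the manifest's
wall-clock timestamp, written elsewhere, is the one volatile field).
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .monitors import TabReport, TrendResult
from .triage import Finding, RetrainingAdvice, TriageState, findings_to_json, triage_to_json

_STAGE_HEX = {"blue": "#2d6cdf", "green": "#2e9e44", "yellow": "#d9a400", "red": "#cc2929"}


def _fig_to_base64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _img(fig) -> str:
    return f'<img src="data:image/png;base64,{_fig_to_base64(fig)}"/>'


def _probability_plots(report: TabReport) -> str:
    daily = report.payload.get("daily_summary")
    if daily is None or daily.empty:
        return "<p>No probability data in window.</p>"
    html = []
    for cols, title in (
        (("mean", "median", "q25", "q75"), "daily predicted probabilities"),
        (("log10_mean", "log10_median"), "daily predicted probabilities (log10, floored)"),
    ):
        fig, ax = plt.subplots(figsize=(7, 2.6))
        x = [str(d) for d in daily["date"]]
        for col in cols:
            if col in daily:
                ax.plot(x, daily[col], marker="o", ms=3, label=col)
        ax.set_title(title, fontsize=9)
        ax.tick_params(axis="x", labelrotation=90, labelsize=6)
        ax.legend(fontsize=6)
        html.append(_img(fig))
    return "".join(html)


def _volume_plot(report: TabReport) -> str:
    table = report.payload.get("table")
    if table is None or table.empty:
        return "<p>No volume data.</p>"
    fig, ax = plt.subplots(figsize=(7, 2.6))
    x = [str(d) for d in table["date"]]
    counts = table["call_count"].fillna(0)
    colors = ["#cc2929" if a else "#4a7ebb" for a in table["anomalous"]]
    ax.bar(x, counts, color=colors)
    ax.axhline(float(table["band_low"].iloc[0]), ls="--", lw=0.8, color="gray")
    ax.axhline(float(table["band_high"].iloc[0]), ls="--", lw=0.8, color="gray")
    ax.set_title("daily model calls (red = anomalous)", fontsize=9)
    ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    return _img(fig)


def _grid_html(report: TabReport) -> str:
    grid = report.payload.get("grid")
    if grid is None or grid.empty:
        return "<p>No charts.</p>"

    def paint(flag):
        color = {"red": "#f5b5b5", "green": "#bfe6c3"}.get(flag, "#eeeeee")
        return f"background-color: {color}"

    rows = []
    for _, r in grid.iterrows():
        rows.append(
            f"<tr><td>{r['feature']}</td><td>{r['importance_rank']}</td>"
            f"<td style='{paint(r['level_flag'])}'>{r['level_flag']} (p={r['level_p']:.3g})</td>"
            f"<td style='{paint(r['scale_flag'])}'>{r['scale_flag']} (p={r['scale_p']:.3g})</td></tr>"
        )
    return (
        "<table><tr><th>feature</th><th>rank</th><th>level</th><th>scale</th></tr>"
        + "".join(rows)
        + "</table>"
    )


def render_report(
    reports: Mapping[str, TabReport],
    triage_state: TriageState,
    out_path: str | Path,
    trend: TrendResult | None = None,
    embed_plots: bool = True,
    timestamp: str = "",
) -> Path:
    """Render the full monitoring report as one self-contained HTML file."""
    sections = []
    for tab, report in reports.items():
        body = ""
        if tab == "probabilities":
            comparison = report.payload.get("comparison")
            if comparison is not None:
                body += pd.DataFrame([comparison.to_row()]).to_html(index=False, border=0)
            if embed_plots:
                body += _probability_plots(report)
        elif tab == "features":
            table = report.payload.get("table")
            if table is not None and not table.empty:
                body += table.to_html(index=False, border=0, float_format="%.4g")
        elif tab in ("historical_covariates", "historical_missingness"):
            body += _grid_html(report)
        elif tab == "volume":
            if embed_plots:
                body += _volume_plot(report)
            table = report.payload.get("table")
            if table is not None and not table.empty:
                body += table.to_html(index=False, border=0, float_format="%.4g")
        n_findings = len(report.findings)
        sections.append(
            f"<section><h2>{tab}</h2><p>{n_findings} finding(s).</p>{body}</section>"
        )
    trend_html = ""
    if trend is not None:
        trend_html = (
            f"<p>Long-run trend of daily mean probability: slope "
            f"{trend.slope:.3g}/day (95% CI [{trend.ci_low:.3g}, {trend.ci_high:.3g}], "
            f"p={trend.p_value:.3g}, {trend.n_days} days, status={trend.status}).</p>"
        )
    color = _STAGE_HEX[triage_state.color]
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>driftwatch monitoring report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; font-size: 11px; }}
td, th {{ padding: 2px 8px; border-bottom: 1px solid #ddd; text-align: right; }}
section {{ margin-bottom: 2em; }}
.banner {{ color: white; background: {color}; padding: 0.8em 1em; font-weight: bold; }}
</style></head><body>
<div class="banner" data-stage="{triage_state.stage}" data-color="{triage_state.color}">
Stage {triage_state.stage} ({triage_state.color}): {triage_state.message}
— recommended action: {triage_state.action}</div>
{trend_html}
{''.join(sections)}
<footer><small>generated by driftwatch{(' at ' + timestamp) if timestamp else ''}</small></footer>
</body></html>
"""
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path


# ---------------------------------------------------------------------------
# Run-directory serialization
# ---------------------------------------------------------------------------

def write_run_directory(
    reports: Mapping[str, TabReport],
    triage_state: TriageState,
    trend: TrendResult,
    advice: RetrainingAdvice,
    out_dir: str | Path,
    embed_plots: bool = True,
    timestamp: str = "",
) -> list[str]:
    """Serialize all monitor outputs under ``out_dir``; returns artifact paths."""
    out_dir = Path(out_dir)
    tabs_dir = out_dir / "tabs"
    tabs_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = tabs_dir / name
        df.to_csv(path, index=False)
        artifacts.append(str(path.relative_to(out_dir)))

    prob = reports["probabilities"]
    if not prob.payload["daily_summary"].empty:
        _write_csv(prob.payload["daily_summary"], "probabilities_daily.csv")
    comparison = prob.payload.get("comparison")
    if comparison is not None:
        path = tabs_dir / "probabilities_comparison.json"
        path.write_text(json.dumps(comparison.to_row(), indent=2, sort_keys=True) + "\n")
        artifacts.append(str(path.relative_to(out_dir)))

    feat = reports["features"]
    _write_csv(feat.payload["table"], "features.csv")
    series = feat.payload["daily_standardized_differences"]
    long = pd.concat(
        [s.rename("standardized_difference").rename_axis("date").reset_index().assign(feature=name)
         for name, s in series.items()],
        ignore_index=True,
    )[["feature", "date", "standardized_difference"]]
    _write_csv(long, "features_daily_stddiff.csv")

    for tab in ("historical_covariates", "historical_missingness"):
        rep = reports[tab]
        _write_csv(rep.payload["grid"], f"{tab}.csv")
        stats_rows = []
        for feature, (lvl, scl) in rep.payload["charts"].items():
            for chart in (lvl, scl):
                for day, z in chart.group_stats.items():
                    stats_rows.append(
                        {"feature": feature, "chart": chart.chart_kind, "date": day, "statistic": z}
                    )
        if stats_rows:
            _write_csv(pd.DataFrame(stats_rows), f"{tab}_stats.csv")

    vol = reports["volume"]
    if not vol.payload["table"].empty:
        _write_csv(vol.payload["table"], "volume.csv")

    all_findings: list[Finding] = [f for rep in reports.values() for f in rep.findings]
    findings_to_json(all_findings, out_dir / "findings.json")
    artifacts.append("findings.json")
    triage_to_json(triage_state, out_dir / "triage.json")
    artifacts.append("triage.json")
    (out_dir / "trend.json").write_text(json.dumps(asdict(trend), indent=2, sort_keys=True) + "\n")
    artifacts.append("trend.json")
    (out_dir / "advice.json").write_text(json.dumps(asdict(advice), indent=2, sort_keys=True) + "\n")
    artifacts.append("advice.json")

    render_report(
        reports, triage_state, out_dir / "report.html",
        trend=trend, embed_plots=embed_plots, timestamp=timestamp,
    )
    artifacts.append("report.html")
    return artifacts
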