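"""Error taxonomy, staged communication protocol, and retraining advice.

Monitoring output only matters if it turns into action. This module encodes
the policy layer of the platform:

* a four-way error taxonomy — technical infrastructure, explained shift,
  unexplained shift, performance loss — applied to each monitor finding;
* a four-stage communication protocol (1 blue: normal operation, 2 green:
  minor interface change, 3 yellow: possible performance degradation, use
  with discretion, 4 red: significant error, suspend use) with rendered
  status messages;
* retraining advice: fix upstream errors first, ignore drift confined to
  low-importance features, retrain on sustained performance loss.

The drift-magnitude thresholds behind escalation are inherently a team
judgment call; all of them (alpha, sustained days, importance cutoff,
staleness) live in :class:`~driftwatch.datamodel.MonitorConfig` so a team can
make its consensus declarative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

from .datamodel import FeatureSpec, MonitorConfig, ValidationError

FINDING_KINDS = (
    "probability_shift",
    "covariate_shift",
    "missingness_shift",
    "volume_anomaly",
    "stale_scores",
    "pipeline_error",
    "ui_change",
)

CATEGORIES = (
    "technical_infrastructure",
    "explained_shift",
    "unexplained_shift",
    "performance_loss",
)

STAGE_COLORS = {1: "blue", 2: "green", 3: "yellow", 4: "red"}
STAGE_ACTIONS = {1: "none", 2: "notify", 3: "use_with_discretion", 4: "suspend_use"}


@dataclass
class Finding:
    """One anomaly surfaced by a monitor (or entered by an operator).

    ``magnitude`` carries whatever effect measure the source monitor uses — a
    standardized difference for window tests, a chart p-value for the
    historical charts. ``blocking`` marks findings that make the model's
    output unusable (a covariate wholly absent from the input, an unresolved
    pipeline failure) and forces stage 4. ``escalate`` separates findings
    strong enough to change the protocol stage from informational ones: with
    dozens of features tested at per-feature level alpha, an in-control
    stream always shows a few significant rows, so monitors mark a shift
    finding escalating only when it survives a family-wise (Bonferroni)
    threshold within its tab. ``days_active`` tracks persistence for the
    retraining rule.
    """

    source: str
    kind: str
    feature: str | None = None
    magnitude: float = float("nan")
    importance_rank: int | None = None
    root_cause: str | None = None
    blocking: bool = False
    escalate: bool = True
    days_active: int = 1
    date: str | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FINDING_KINDS:
            raise ValidationError(f"unknown finding kind {self.kind!r}")
        if self.root_cause is not None and not self.root_cause.strip():
            raise ValidationError("root_cause, when present, must be nonempty")


@dataclass
class TriageState:
    """Current protocol stage with its color, rendered message, and action."""

    stage: int
    color: str
    message: str
    action: str


def classify_finding(f: Finding) -> str:
    """Assign the four-way error category to a finding.

    Infrastructure failures (pipeline errors, call-volume anomalies, stale
    scores, interface changes) are operational, not statistical. A shift in
    the predicted probabilities is the label-free proxy for performance loss.
    Covariate and missingness shifts split on whether a root cause has been
    identified.
    """
    if f.kind in ("pipeline_error", "volume_anomaly", "stale_scores", "ui_change"):
        return "technical_infrastructure"
    if f.kind == "probability_shift":
        return "performance_loss"
    # covariate_shift / missingness_shift
    return "explained_shift" if f.root_cause else "unexplained_shift"


@dataclass
class SystemStatus:
    """Operational facts the monitors cannot infer from the data stream."""

    scores_age_days: int = 0  # 0 = scores are current
    pipeline_ok: bool = True


def _finding_stage(f: Finding) -> int:
    if f.blocking or f.kind == "pipeline_error":
        return 4
    category = classify_finding(f)
    if f.kind == "stale_scores":
        return 3
    if category in ("performance_loss", "unexplained_shift") and f.escalate:
        return 3
    if f.kind == "ui_change":
        return 2
    return 1


def triage_stage(
    findings: Sequence[Finding],
    status: SystemStatus | None = None,
    config: MonitorConfig | None = None,
) -> TriageState:
    """Map active findings plus system status to the protocol stage.

    The stage is the maximum over per-finding stages, so adding a finding can
    never lower it: blocking findings and pipeline failures force stage 4
    (suspend use); stale scores, and escalating performance-loss or
    unexplained-shift findings, force stage 3 (use with discretion);
    interface changes force stage 2; otherwise stage 1 (normal operation).
    Explained shifts, and informational (non-escalating) shift findings, do
    not by themselves move the protocol beyond normal operation.
    """
    status = status or SystemStatus()
    stage = 1
    for f in findings:
        stage = max(stage, _finding_stage(f))
    if not status.pipeline_ok:
        stage = 4
    elif status.scores_age_days >= 1:
        stage = max(stage, 3)
    message = render_stage_message(stage, findings, status)
    return TriageState(
        stage=stage,
        color=STAGE_COLORS[stage],
        message=message,
        action=STAGE_ACTIONS[stage],
    )


def _load_template(stage: int) -> str:
    ref = resources.files("driftwatch") / "templates" / f"stage{stage}.txt"
    return ref.read_text()


def render_stage_message(stage: int, findings: Sequence[Finding], status: SystemStatus) -> str:
    """Render the stage banner from the plain-text template for that stage."""
    details = "; ".join(
        f"{f.kind}" + (f" ({f.feature})" if f.feature else "") for f in findings
    ) or "none"
    return _load_template(stage).format(
        n_findings=len(findings),
        details=details,
        scores_age_days=status.scores_age_days,
    ).strip()


@dataclass
class RetrainingAdvice:
    retrain: bool
    rationale: str


def retraining_advice(
    findings: Sequence[Finding],
    catalogue: Sequence[FeatureSpec],
    config: MonitorConfig,
) -> RetrainingAdvice:
    """Decide whether the model should be retrained given active findings.

    Rules, in order: never retrain while open infrastructure errors exist —
    fix upstream first, since a pipeline fix usually dissolves the apparent
    shift; retrain when performance loss has persisted for at least
    ``config.sustained_days``; do not retrain when the only shifts sit on
    features below the importance cutoff (nuisance drift); otherwise keep
    monitoring.
    """
    infra = [f for f in findings if classify_finding(f) == "technical_infrastructure"]
    if infra:
        return RetrainingAdvice(
            retrain=False,
            rationale=(
                "open technical-infrastructure findings present "
                f"({len(infra)}); identify and fix upstream errors before "
                "considering retraining"
            ),
        )
    sustained = [
        f
        for f in findings
        if classify_finding(f) == "performance_loss"
        and f.days_active >= config.sustained_days
    ]
    if sustained:
        return RetrainingAdvice(
            retrain=True,
            rationale=(
                "significant performance loss has persisted for "
                f">= {config.sustained_days} days; retrain"
            ),
        )
    shifts = [
        f
        for f in findings
        if classify_finding(f) in ("explained_shift", "unexplained_shift")
    ]
    if shifts and all(
        f.importance_rank is not None and f.importance_rank > config.importance_cutoff
        for f in shifts
    ):
        return RetrainingAdvice(
            retrain=False,
            rationale=(
                "all shifted covariates rank below the importance cutoff "
                f"(> {config.importance_cutoff}); treat as nuisance drift"
            ),
        )
    return RetrainingAdvice(
        retrain=False,
        rationale="no sustained performance loss; continue monitoring",
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def findings_to_json(findings: Sequence[Finding], path: str | Path) -> Path:
    path = Path(path)
    payload = [asdict(f) | {"category": classify_finding(f)} for f in findings]
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def triage_to_json(state: TriageState, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(state), indent=2, sort_keys=True) + "\n")
    return path
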