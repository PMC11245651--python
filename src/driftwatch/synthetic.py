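"""Synthetic clinical prediction streams with injectable failure modes.

The generator emulates the statistical shape of a deployed inpatient risk
model's data feed, scaled to desk size: a few dozen skewed continuous
features (log-normal / gamma — many clinical labs are heavily right-skewed)
and binary presence flags, per-call missingness, a Poisson daily call volume,
and predicted probabilities from a toy logistic risk model whose intercept is
chosen so scores cluster near 0 (most inpatients are not high-risk).

Shifts are injected, not emergent: each :class:`ShiftInjection` replays one
documented production failure mode — gradual mean or scale drift, a
missingness ramp from an upstream coding change, a lab-code change that
silently empties a feature, a zero-call outage day, prevalence shift in a
binary flag, score inflation, and concept shift (the probability-feature
relationship changes while every marginal stays put).

Seed discipline: one master seed; every (day, feature) pair gets its own
counter-derived substream, so an injection on one feature leaves every other
feature's drawn values *exactly* equal to the null stream — injection
locality is testable as equality, not approximation.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DailySnapshot,
    FeatureSpec,
    TrainingReference,
    ValidationError,
)

INJECTION_KINDS = (
    "mean_shift",
    "scale_shift",
    "missingness_ramp",
    "prevalence_shift",
    "code_change",
    "outage",
    "concept_shift",
)

# substream namespaces for counter-based seeding
_NS_REFERENCE = 2
_NS_STREAM = 1
_NS_VOLUME = 3


@dataclass(frozen=True)
class ShiftInjection:
    """One injected failure mode.

    ``magnitude`` is kind-specific: SD units for ``mean_shift`` (on features)
    or absolute probability for ``mean_shift`` on ``"probabilities"``; an SD
    multiplier for ``scale_shift``; a target missingness proportion for
    ``missingness_ramp``; an additive prevalence change for
    ``prevalence_shift``; a relative coefficient perturbation for
    ``concept_shift``. ``ramp_days`` spreads the onset linearly (0 = step).
    """

    target: str
    kind: str
    onset_day: int
    magnitude: float = 1.0
    ramp_days: int = 0

    def __post_init__(self) -> None:
        if self.kind not in INJECTION_KINDS:
            raise ValidationError(f"unknown injection kind {self.kind!r}")
        if not math.isfinite(self.magnitude):
            raise ValidationError("injection magnitude must be finite")
        if self.onset_day < 1:
            raise ValidationError("onset_day is 1-based and must be >= 1")

    def fraction(self, day: int) -> float:
        """Ramp fraction in [0, 1] applied on 1-based stream day ``day``."""
        if day < self.onset_day:
            return 0.0
        if self.ramp_days <= 1:
            return 1.0
        return min(1.0, (day - self.onset_day + 1) / self.ramp_days)


@dataclass(frozen=True)
class FeatureModel:
    """Generative law for one feature: family, parameters, missingness."""

    name: str
    kind: str  # continuous | binary
    family: str  # lognormal | gamma | bernoulli
    params: tuple[float, ...]
    missing_rate: float
    importance_rank: int
    aliases: tuple[str, ...] = ()

    @property
    def mean(self) -> float:
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        return self.params[0]

    @property
    def sd(self) -> float:
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.sqrt((math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2))
        if self.family == "gamma":
            shape, scale = self.params
            return math.sqrt(shape) * scale
        p = self.params[0]
        return math.sqrt(p * (1 - p))

    def draw(self, rng: np.random.Generator, n: int, prevalence_delta: float = 0.0) -> np.ndarray:
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mean=mu, sigma=sigma, size=n)
        if self.family == "gamma":
            shape, scale = self.params
            return rng.gamma(shape=shape, scale=scale, size=n)
        p = min(max(self.params[0] + prevalence_delta, 0.0), 1.0)
        return (rng.random(n) < p).astype(float)

    def spec(self) -> FeatureSpec:
        return FeatureSpec(
            name=self.name,
            kind=self.kind,
            importance_rank=self.importance_rank,
            aliases=self.aliases,
        )


@dataclass
class GeneratorConfig:
    """Study conditions for the simulator (a ~400x scale-down of a large
    deployment's 126 features and ~80,000 daily calls).

    Defaults: 20 features (12 skewed continuous, 8 binary), 1000 training
    records, Poisson(200) calls/day, 60 days. The risk model is logistic on
    the first 3 continuous and first 2 binary features (standardized), with
    intercept -3.5 so the mean predicted probability stays below 0.1.
    """

    n_features_continuous: int = 12
    n_features_binary: int = 8
    n_reference: int = 1000
    calls_per_day: float = 200.0
    n_days: int = 60
    start_date: _dt.date = _dt.date(2024, 1, 1)
    seed: int = 0
    continuous_sigmas: tuple[float, ...] | None = None
    binary_prevalences: tuple[float, ...] | None = None
    missing_rate: float = 0.05
    risk_coefficients: tuple[float, ...] = (0.9, -0.6, 0.45, 0.8, 0.55)
    risk_intercept: float = -3.5
    n_risk_continuous: int = 3
    n_risk_binary: int = 2
    feature_names: dict[str, str] = field(default_factory=dict)
    feature_aliases: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_features_continuous", "n_features_binary", "n_reference", "n_days"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.calls_per_day <= 0:
            raise ValidationError("calls_per_day must be positive")
        if not (0.0 < self.missing_rate < 1.0):
            raise ValidationError("missing_rate must lie in (0, 1)")
        if self.n_risk_continuous + self.n_risk_binary != len(self.risk_coefficients):
            raise ValidationError(
                "risk_coefficients length must equal n_risk_continuous + n_risk_binary"
            )
        if self.n_risk_continuous > self.n_features_continuous:
            raise ValidationError("n_risk_continuous exceeds n_features_continuous")
        if self.n_risk_binary > self.n_features_binary:
            raise ValidationError("n_risk_binary exceeds n_features_binary")


def build_feature_models(config: GeneratorConfig) -> list[FeatureModel]:
    """Materialize the per-feature generative laws from a config.

    Continuous features alternate log-normal and gamma families with a skew
    profile cycling from mild to heavy (sigma up to 1.3 / shape down to 1);
    binary prevalences spread over [0.05, 0.5]. Importance ranks follow the
    risk model: features in the linear predictor are ranked by absolute
    coefficient, then the remaining features in catalogue order.
    """
    nc, nb = config.n_features_continuous, config.n_features_binary
    sigmas = config.continuous_sigmas or tuple(
        (0.3, 0.6, 1.0, 1.3)[i % 4] for i in range(nc)
    )
    prevalences = config.binary_prevalences or tuple(np.linspace(0.05, 0.5, nb))

    names_c = [config.feature_names.get(f"lab_{i+1:02d}", f"lab_{i+1:02d}") for i in range(nc)]
    names_b = [config.feature_names.get(f"flag_{i+1:02d}", f"flag_{i+1:02d}") for i in range(nb)]

    # importance: risk features by |coefficient|, then the rest
    risk_names = names_c[: config.n_risk_continuous] + names_b[: config.n_risk_binary]
    order = np.argsort([-abs(c) for c in config.risk_coefficients], kind="stable")
    ranked = [risk_names[i] for i in order]
    ranked += [n for n in names_c + names_b if n not in ranked]
    rank_of = {name: i + 1 for i, name in enumerate(ranked)}

    models = []
    for i, name in enumerate(names_c):
        family = "lognormal" if i % 2 == 0 else "gamma"
        if family == "lognormal":
            params = (0.0, float(sigmas[i]))
        else:
            # match the cycling skew profile: small shape = heavy skew
            shape = {0.3: 8.0, 0.6: 4.0, 1.0: 2.0, 1.3: 1.0}.get(float(sigmas[i]), 2.0)
            params = (shape, 1.0)
        models.append(
            FeatureModel(
                name=name,
                kind="continuous",
                family=family,
                params=params,
                missing_rate=config.missing_rate,
                importance_rank=rank_of[name],
                aliases=config.feature_aliases.get(name, ()),
            )
        )
    for i, name in enumerate(names_b):
        models.append(
            FeatureModel(
                name=name,
                kind="binary",
                family="bernoulli",
                params=(float(prevalences[i]),),
                missing_rate=config.missing_rate,
                importance_rank=rank_of[name],
                aliases=config.feature_aliases.get(name, ()),
            )
        )
    return models


def _risk_features(config: GeneratorConfig, models: Sequence[FeatureModel]) -> list[FeatureModel]:
    cont = [m for m in models if m.kind == "continuous"]
    binr = [m for m in models if m.kind == "binary"]
    return cont[: config.n_risk_continuous] + binr[: config.n_risk_binary]


def compute_probabilities(
    frame: pd.DataFrame,
    config: GeneratorConfig,
    models: Sequence[FeatureModel],
    coefficients: Sequence[float] | None = None,
) -> np.ndarray:
    """Toy logistic risk model: sigmoid(intercept + sum coef_j * z_j).

    Features are standardized by their generative mean/SD; missing values
    enter as 0 (mean imputation), so missingness shifts propagate into the
    score distribution exactly as an imputing production model would show.
    """
    coefs = np.asarray(
        coefficients if coefficients is not None else config.risk_coefficients, dtype=float
    )
    eta = np.full(len(frame), config.risk_intercept, dtype=float)
    for coef, fm in zip(coefs, _risk_features(config, models)):
        x = frame[fm.name].to_numpy(dtype=float)
        z = (x - fm.mean) / fm.sd
        z[np.isnan(z)] = 0.0
        eta += coef * z
    return 1.0 / (1.0 + np.exp(-eta))


def _feature_rng(config: GeneratorConfig, namespace: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, namespace, *counters])
    )


def make_reference(config: GeneratorConfig) -> TrainingReference:
    """Draw the frozen training reference from the generative model."""
    models = build_feature_models(config)
    n = config.n_reference
    data = {}
    for i, fm in enumerate(models):
        rng = _feature_rng(config, _NS_REFERENCE, i)
        values = fm.draw(rng, n)
        missing = rng.random(n) < fm.missing_rate
        values = values.astype(float)
        values[missing] = np.nan
        data[fm.name] = values
    frame = pd.DataFrame(data)
    probs = compute_probabilities(frame, config, models)
    return TrainingReference(
        catalogue=[fm.spec() for fm in models],
        frame=frame,
        probabilities=probs,
        label=f"synthetic reference (seed={config.seed})",
    )


def validate_injections(config: GeneratorConfig, injections: Sequence[ShiftInjection]) -> None:
    models = {m.name: m for m in build_feature_models(config)}
    for inj in injections:
        if inj.onset_day > config.n_days:
            raise ValidationError(
                f"injection onset_day {inj.onset_day} beyond stream length {config.n_days}"
            )
        if inj.kind == "outage":
            if inj.target != "volume":
                raise ValidationError("outage injections must target 'volume'")
            continue
        if inj.kind == "concept_shift":
            if inj.target != "probabilities":
                raise ValidationError("concept_shift injections must target 'probabilities'")
            continue
        if inj.target == "probabilities":
            if inj.kind != "mean_shift":
                raise ValidationError(
                    "probability injections support mean_shift (score inflation) only"
                )
            continue
        fm = models.get(inj.target)
        if fm is None:
            raise ValidationError(f"injection targets unknown feature {inj.target!r}")
        if inj.kind == "prevalence_shift" and fm.kind != "binary":
            raise ValidationError("prevalence_shift applies to binary features")
        if inj.kind in ("mean_shift", "scale_shift") and fm.kind != "continuous":
            raise ValidationError(f"{inj.kind} applies to continuous features")


def simulate_stream(
    config: GeneratorConfig, injections: Sequence[ShiftInjection] = ()
) -> list[DailySnapshot]:
    """Simulate ``config.n_days`` daily snapshots with injections applied.

    Per day: call count ~ Poisson(calls_per_day) (0 on outage days); each
    feature drawn from its own (day, feature) substream; injections modify
    only their target from onset onward; probabilities are recomputed per
    call from the (possibly injected) feature values, then probability-level
    injections apply. Calls are i.i.d. across days — no repeat-patient model.
    """
    validate_injections(config, injections)
    models = build_feature_models(config)
    per_feature = {
        m.name: [inj for inj in injections if inj.target == m.name] for m in models
    }
    outages = [i for i in injections if i.kind == "outage"]
    concept = [i for i in injections if i.kind == "concept_shift"]
    prob_shifts = [
        i for i in injections if i.target == "probabilities" and i.kind == "mean_shift"
    ]

    snapshots = []
    for day in range(1, config.n_days + 1):
        date = config.start_date + _dt.timedelta(days=day - 1)
        rng_day = _feature_rng(config, _NS_VOLUME, day)
        n_calls = int(rng_day.poisson(config.calls_per_day))
        if any(
            inj.onset_day <= day < inj.onset_day + max(1, inj.ramp_days) for inj in outages
        ):
            n_calls = 0
        data = {}
        for i, fm in enumerate(models):
            rng = _feature_rng(config, _NS_STREAM, day, i)
            prevalence_delta = 0.0
            for inj in per_feature[fm.name]:
                if inj.kind == "prevalence_shift":
                    prevalence_delta += inj.magnitude * inj.fraction(day)
            values = fm.draw(rng, n_calls, prevalence_delta=prevalence_delta)
            missing_rate = fm.missing_rate
            for inj in per_feature[fm.name]:
                frac = inj.fraction(day)
                if frac == 0.0:
                    continue
                if inj.kind == "mean_shift":
                    values = values + inj.magnitude * fm.sd * frac
                elif inj.kind == "scale_shift":
                    factor = 1.0 + (inj.magnitude - 1.0) * frac
                    values = fm.mean + (values - fm.mean) * factor
                elif inj.kind == "missingness_ramp":
                    missing_rate = fm.missing_rate + (inj.magnitude - fm.missing_rate) * frac
                elif inj.kind == "code_change":
                    missing_rate = 1.0
            missing = rng.random(n_calls) < missing_rate
            values = np.asarray(values, dtype=float)
            values[missing] = np.nan
            data[fm.name] = values
        frame = pd.DataFrame(data, index=range(n_calls), dtype=float)

        coefs = np.asarray(config.risk_coefficients, dtype=float)
        for inj in concept:
            coefs = coefs * (1.0 + inj.magnitude * inj.fraction(day))
        probs = compute_probabilities(frame, config, models, coefficients=coefs)
        for inj in prob_shifts:
            probs = np.clip(probs + inj.magnitude * inj.fraction(day), 0.0, 1.0)
        snapshots.append(DailySnapshot(date=date, frame=frame, probabilities=probs))
    return snapshots


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    name: str
    config: GeneratorConfig
    injections: tuple[ShiftInjection, ...]
    description: str


def scenario_library(seed: int = 0) -> dict[str, Scenario]:
    """Named replicas of documented production failure modes.

    Every scenario shares the default study conditions; only the injections
    differ. ``troponin_code_change`` renames the most influential lab feature
    to "troponin" (with its legacy source codes as aliases) and empties it
    from day 30 on, reproducing the classic silent lab-code migration.
    """
    base = lambda **kw: GeneratorConfig(seed=seed, **kw)  # noqa: E731
    troponin_cfg = base(
        feature_names={"lab_01": "troponin"},
        feature_aliases={"troponin": ("TROPONIN_T_LEGACY", "TROP_NEW_CODE")},
    )
    scenarios = [
        Scenario("null", base(), (), "in-control stream; every monitor should stay quiet"),
        Scenario(
            "troponin_code_change",
            troponin_cfg,
            (ShiftInjection("troponin", "code_change", onset_day=30),),
            "an unmapped lab-code migration silently empties the top lab feature",
        ),
        Scenario(
            "mean_drift",
            base(),
            (ShiftInjection("lab_01", "mean_shift", onset_day=30, magnitude=1.0, ramp_days=14),),
            "gradual +1 SD location drift in the top lab feature",
        ),
        Scenario(
            "variance_burst",
            base(),
            (ShiftInjection("lab_01", "scale_shift", onset_day=30, magnitude=3.0),),
            "dispersion triples with the median unchanged",
        ),
        Scenario(
            "missingness_ramp",
            base(),
            (ShiftInjection("lab_02", "missingness_ramp", onset_day=30, magnitude=0.6, ramp_days=20),),
            "missingness ramps from baseline to 60%",
        ),
        Scenario(
            "outage_day",
            base(),
            (ShiftInjection("volume", "outage", onset_day=55),),
            "a zero-call day from a pipeline outage inside the monitored fortnight",
        ),
        Scenario(
            "score_inflation",
            base(),
            (ShiftInjection("probabilities", "mean_shift", onset_day=1, magnitude=0.06, ramp_days=60),),
            "slow linear score inflation (slope = magnitude / ramp_days per day)",
        ),
        Scenario(
            "concept_shift",
            base(),
            (ShiftInjection("probabilities", "concept_shift", onset_day=30, magnitude=1.5),),
            "risk-model coefficients change; marginals stay put, scores move",
        ),
    ]
    return {s.name: s for s in scenarios}
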