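"""Distribution-free Phase-I level and scale control charts.

Each feature's full post-deployment history is judged retrospectively against
the training baseline: was this feature in control over the whole period? The
chart is a permutation-calibrated max-type rank chart:

* pool the reference sample with every daily group and assign midranks;
* **level** statistic per day = studentized mean of that day's ranks: the
  group's rank mean, centered at the pooled mean and scaled by its own
  within-group rank variance (shrunk toward the pooled variance, with a
  finite-population correction). Studentizing by the within-group variance
  keeps the level chart quiet when only the dispersion of a day changes — a
  pooled-variance standardization over-flags under scale inhomogeneity;
* **scale** statistic = the same machinery applied to Mood-type scale
  scores, the squared deviation of each midrank from the central rank
  ``(R_i - (N+1)/2)^2``: a day with inflated (or collapsed) dispersion
  sends its values to the rank extremes (or center), moving its mean score.
  Because the scores are a function of the midranks alone, the scale chart
  is exactly invariant under location shifts;
* the chart statistic is the maximum absolute daily statistic, and its
  p-value comes from permuting the pooled values across groups (the same
  studentized statistic is recomputed per permutation, so the p-value is
  exact under exchangeability for any statistic), which controls the
  family-wise false-alarm probability (FAP) across days.

Ranks make the chart distribution-free — essential here because many clinical
lab features are highly skewed and heavily tied — and permutation calibration
gives finite-sample validity without any normality assumption. The reference
block takes part in the pooled ranking but is never itself a flaggable group:
the baseline is the yardstick, not a suspect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .datamodel import DailySnapshot, FeatureSpec, MonitorConfig, TrainingReference

MIN_REFERENCE = 20
MIN_GROUP = 2

# pseudo-observations shrinking a group's rank variance toward the pooled
# variance; keeps the studentized statistic finite for zero-variance groups
# (a day of identical values) without materially changing large groups
VARIANCE_SHRINKAGE = 5.0

# status values carried on ChartResult
STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_data"
STATUS_NO_VARIATION = "no_variation"


@dataclass
class ChartResult:
    """Outcome of one level or scale chart over a feature's history."""

    chart_kind: str  # "level" or "scale"
    group_stats: pd.Series  # per-day standardized rank statistic
    max_stat: float
    control_limit: float
    p_value: float
    flag: str  # "green" or "red"
    n_permutations: int
    seed: int
    status: str = STATUS_OK
    group_sizes: tuple[int, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    def to_json_dict(self) -> dict:
        return {
            "chart_kind": self.chart_kind,
            "max_stat": self.max_stat,
            "control_limit": self.control_limit,
            "p_value": self.p_value,
            "flag": self.flag,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "status": self.status,
        }


def derive_seed(base: int, *parts) -> int:
    """Stable sub-seed from a base seed and string/int tags (always < 2**31)."""
    entropy = [int(base) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(p).encode()) for p in parts]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


class RankControlChart(BaseEstimator):
    """Permutation-calibrated max-type rank chart (sklearn-style estimator).

    ``fit`` binds the reference sample; ``evaluate`` charts a grouped history
    against it and returns a full :class:`ChartResult`; ``predict`` returns
    just the green/red flag.

    Parameters
    ----------
    statistic : {"level", "scale"}
        Level charts track location via studentized midrank means; scale
        charts track dispersion via Mood-type squared centered midranks.
    alpha : float
        A history is flagged red when the permutation p-value of the maximum
        daily statistic falls below alpha.
    fap : float
        Family-wise false-alarm probability used for the displayed control
        limit (the (1 - fap) permutation quantile of the null maximum).
    n_permutations : int
        Permutation draws; the p-value uses the add-one estimator
        (b + 1) / (B + 1), which is valid in finite samples.
    random_state : int
        Seed for the permutation stream; identical inputs and seed give a
        bit-identical result.
    """

    def __init__(
        self,
        statistic: str = "level",
        alpha: float = 0.05,
        fap: float = 0.05,
        n_permutations: int = 2000,
        random_state: int = 0,
    ):
        self.statistic = statistic
        self.alpha = alpha
        self.fap = fap
        self.n_permutations = n_permutations
        self.random_state = random_state

    # -- estimator surface ---------------------------------------------------

    def fit(self, X, y=None) -> "RankControlChart":
        if self.statistic not in ("level", "scale"):
            raise ValueError(f"statistic must be 'level' or 'scale', got {self.statistic!r}")
        X = np.asarray(X, dtype=float).ravel()
        X = X[~np.isnan(X)]
        if len(X) < MIN_REFERENCE:
            raise ValueError(
                f"reference sample needs >= {MIN_REFERENCE} non-missing values, has {len(X)}"
            )
        self.reference_ = X
        self.n_reference_ = len(X)
        return self

    def evaluate(self, groups: Sequence[tuple]) -> ChartResult:
        """Chart a grouped history: ``groups`` is a sequence of (date, values).

        Groups with fewer than two non-missing values are excluded (their
        statistic cannot be standardized); if fewer than two usable groups
        remain the chart is skipped with an explicit insufficient-data result
        rather than a silent green.
        """
        ref = self.reference_
        dates, samples = [], []
        for day, values in groups:
            v = np.asarray(values, dtype=float).ravel()
            v = v[~np.isnan(v)]
            if len(v) >= MIN_GROUP:
                dates.append(day)
                samples.append(v)
        if len(samples) < 2:
            return self._non_ok(STATUS_INSUFFICIENT, dates)

        sizes = np.array([len(s) for s in samples])
        pooled = np.concatenate([ref, *samples])
        scores = self._scores(pooled)
        pop_var = scores.var(ddof=0)
        if pop_var == 0.0:
            # every pooled value identical (e.g. zero missingness everywhere)
            return self._non_ok(STATUS_NO_VARIATION, dates, sizes)

        offsets = np.concatenate(([0, len(ref)], len(ref) + np.cumsum(sizes)[:-1]))
        z = self._group_stats(scores[None, :], offsets, sizes, scores.mean(), pop_var)[0]
        max_stat = float(np.max(np.abs(z)))

        null = self._null_max(scores, offsets, sizes, scores.mean(), pop_var)
        b = int(np.sum(null >= max_stat - 1e-12))
        p_value = (b + 1) / (self.n_permutations + 1)
        control_limit = float(np.quantile(null, 1.0 - self.fap))
        flag = "red" if p_value < self.alpha else "green"
        return ChartResult(
            chart_kind=self.statistic,
            group_stats=pd.Series(z, index=pd.Index(dates, name="date")),
            max_stat=max_stat,
            control_limit=control_limit,
            p_value=float(p_value),
            flag=flag,
            n_permutations=self.n_permutations,
            seed=int(self.random_state),
            status=STATUS_OK,
            group_sizes=tuple(int(n) for n in sizes),
        )

    def predict(self, groups: Sequence[tuple]) -> str:
        return self.evaluate(groups).flag

    # -- internals -----------------------------------------------------------

    def _scores(self, pooled: np.ndarray) -> np.ndarray:
        ranks = rankdata(pooled, method="average")
        if self.statistic == "level":
            return ranks
        # Mood scale scores: rank functions only, so location shifts (and any
        # strictly increasing transform) leave the chart bit-identical
        return (ranks - (len(ranks) + 1) / 2.0) ** 2

    @staticmethod
    def _group_stats(rows, offsets, sizes, pop_mean, pop_var) -> np.ndarray:
        """Studentized group rank means for each row of ``rows`` (B, N).

        Per group: z = (mean - pooled mean) / sqrt(v_shrunk / n * (1 - n/N)),
        where v_shrunk pulls the within-group sample variance toward the
        pooled variance with VARIANCE_SHRINKAGE pseudo-observations.
        """
        n_total = rows.shape[1]
        group_offsets = offsets[1:]  # skip the reference block at offset 0
        s1 = np.add.reduceat(rows, group_offsets, axis=1)
        s2 = np.add.reduceat(rows * rows, group_offsets, axis=1)
        means = s1 / sizes
        var = (s2 - sizes * means**2) / np.maximum(sizes - 1, 1)
        var_shrunk = (sizes * var + VARIANCE_SHRINKAGE * pop_var) / (sizes + VARIANCE_SHRINKAGE)
        se = np.sqrt(var_shrunk / sizes * (n_total - sizes) / n_total)
        return (means - pop_mean) / se

    def _null_max(self, scores, offsets, sizes, pop_mean, pop_var) -> np.ndarray:
        """Null distribution of the max-|z| under permutation across groups.

        The pooled score vector is fixed; permuting pooled *values* across
        groups is equivalent to permuting the score vector and re-slicing it
        into the reference block plus the day groups. Vectorized in chunks.
        """
        rng = np.random.default_rng(self.random_state)
        n_total = len(scores)
        n_perm = self.n_permutations
        chunk = max(1, min(n_perm, int(8_000_000 / max(n_total, 1))))
        out = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perm = rng.permuted(np.broadcast_to(scores, (b, n_total)), axis=1)
            z = self._group_stats(perm, offsets, sizes, pop_mean, pop_var)
            out[done : done + b] = np.max(np.abs(z), axis=1)
            done += b
        return out

    def _non_ok(self, status: str, dates, sizes=None) -> ChartResult:
        return ChartResult(
            chart_kind=self.statistic,
            group_stats=pd.Series(dtype=float, index=pd.Index([], name="date")),
            max_stat=float("nan"),
            control_limit=float("nan"),
            p_value=float("nan") if status == STATUS_INSUFFICIENT else 1.0,
            flag="green",
            n_permutations=self.n_permutations,
            seed=int(self.random_state),
            status=status,
            group_sizes=tuple(int(n) for n in sizes) if sizes is not None else (),
        )


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def level_chart(reference_sample, grouped_stream, config: MonitorConfig, seed: int | None = None) -> ChartResult:
    """Level (location) chart of a grouped history against a reference sample."""
    chart = RankControlChart(
        statistic="level",
        alpha=config.alpha,
        fap=config.fap,
        n_permutations=config.n_permutations,
        random_state=config.seed if seed is None else seed,
    )
    return chart.fit(reference_sample).evaluate(grouped_stream)


def scale_chart(reference_sample, grouped_stream, config: MonitorConfig, seed: int | None = None) -> ChartResult:
    """Scale (dispersion) chart of a grouped history against a reference sample."""
    chart = RankControlChart(
        statistic="scale",
        alpha=config.alpha,
        fap=config.fap,
        n_permutations=config.n_permutations,
        random_state=config.seed if seed is None else seed,
    )
    return chart.fit(reference_sample).evaluate(grouped_stream)


def chart_feature_history(
    feature: FeatureSpec,
    full_stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> tuple[ChartResult, ChartResult]:
    """Level and scale charts of one feature's full daily history.

    Groups are calendar days with missing values excluded per day; the two
    charts share a per-feature seed derivation from the config seed so a rerun
    is bit-identical.
    """
    if len(full_stream) == 0:
        raise ValueError("chart_feature_history requires a nonempty stream")
    ref = reference.feature_values(feature.name)
    groups = [(snap.date, snap.feature_values(feature.name)) for snap in full_stream]
    lvl = level_chart(ref, groups, config, seed=derive_seed(config.seed, feature.name, "level"))
    scl = scale_chart(ref, groups, config, seed=derive_seed(config.seed, feature.name, "scale"))
    return lvl, scl


def chart_missingness_history(
    feature: FeatureSpec,
    full_stream: Sequence[DailySnapshot],
    reference: TrainingReference,
    config: MonitorConfig,
) -> tuple[ChartResult, ChartResult]:
    """Level and scale charts of a feature's per-call missingness indicators.

    Each call contributes a 0/1 indicator; the reference missingness pattern
    comes from the training table. With no variation anywhere (never missing)
    the chart degenerates to an explicit green "no variation" result.
    """
    if len(full_stream) == 0:
        raise ValueError("chart_missingness_history requires a nonempty stream")
    ref = reference.missing_indicators(feature.name)
    groups = [(snap.date, snap.missing_indicators(feature.name)) for snap in full_stream]
    lvl = level_chart(ref, groups, config, seed=derive_seed(config.seed, feature.name, "na-level"))
    scl = scale_chart(ref, groups, config, seed=derive_seed(config.seed, feature.name, "na-scale"))
    return lvl, scl
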