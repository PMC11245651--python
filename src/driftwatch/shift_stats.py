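"""Window-vs-training two-sample shift statistics.

These are the numbers a monitoring analyst reads first: for every feature (and
for the predicted probabilities themselves), the incoming window pooled over
the last two weeks is compared against the frozen training sample via

* the standardized difference ``d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2)`` —
  the scale-free covariate-balance metric of clinical studies, with Bernoulli
  variances for binary features;
* a Kolmogorov–Smirnov test for continuous features, or a Pearson chi-square
  test (2x2 presence table, no continuity correction) for binary ones.

No multiple-testing correction is applied across features: rows are meant to
be ranked by importance and effect size and triaged by a human, not consumed
as a family of formal decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.base import BaseEstimator

from .datamodel import DailySnapshot, FeatureSpec, TrainingReference


class DegenerateStatisticError(ValueError):
    """A statistic is undefined for the given samples (e.g. all values missing)."""


@dataclass
class ComparisonStats:
    """One row of the feature-comparison table."""

    feature: str
    kind: str
    incoming_mean: float
    incoming_sd: float
    reference_mean: float
    reference_sd: float
    standardized_difference: float
    test_name: str
    statistic: float
    p_value: float
    n_incoming: int
    n_reference: int
    importance_rank: int | None = None
    degenerate: bool = False

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "kind": self.kind,
            "importance_rank": self.importance_rank,
            "n_incoming": self.n_incoming,
            "n_reference": self.n_reference,
            "incoming_mean": self.incoming_mean,
            "incoming_sd": self.incoming_sd,
            "reference_mean": self.reference_mean,
            "reference_sd": self.reference_sd,
            "standardized_difference": self.standardized_difference,
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[~np.isnan(x)]


def standardized_difference(a, b) -> float:
    """Signed standardized difference of means between two samples.

    ``(mean(a) - mean(b)) / sqrt((var(a) + var(b)) / 2)`` with sample (ddof=1)
    variances. Returns 0 when both variances vanish and the means agree, and
    signed infinity when the means differ with no variance to scale by.
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateStatisticError(
            "standardized difference needs >= 2 non-missing values per sample"
        )
    diff = a.mean() - b.mean()
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff)) * float("inf")
    return float(diff / pooled)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    The statistic is the sup-norm distance between the empirical CDFs (ties
    handled through the step CDFs as usual). The p-value is exact for small
    samples and asymptotic (effective n = n1*n2/(n1+n2)) at monitoring window
    sizes.
    """
    a, b = _clean(a), _clean(b)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateStatisticError("KS test needs >= 2 non-missing values per sample")
    res = _st.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_square_presence(a, b) -> tuple[float, float, bool]:
    """Pearson chi-square on the 2x2 presence table of two 0/1 samples.

    No continuity correction; df = 1. A zero margin (the feature present in
    neither group, or in every record of both) makes the statistic undefined;
    that case is reported as (0, 1) with the degenerate flag set.
    """
    a, b = _clean(a), _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateStatisticError("chi-square needs a nonempty sample per group")
    for name, x in (("a", a), ("b", b)):
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError(f"sample {name} is not coded 0/1")
    table = np.array(
        [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, _ = _st.chi2_contingency(table, correction=False)
    return float(stat), float(p), False


class WindowDriftTest(BaseEstimator):
    """Two-sample drift test against a frozen reference sample.

    A small sklearn-style estimator: ``fit`` binds the reference (training)
    sample, ``compare`` scores a new pooled window against it, and ``predict``
    returns the drift decision at ``alpha``. The test dispatches on ``kind``:
    KS for continuous data, chi-square on the presence table for binary data.

    Parameters
    ----------
    kind : {"continuous", "binary"}
    alpha : float
        Significance level for the drift decision.
    """

    def __init__(self, kind: str = "continuous", alpha: float = 0.05):
        self.kind = kind
        self.alpha = alpha

    def fit(self, X, y=None) -> "WindowDriftTest":
        X = _clean(X)
        if len(X) < 2:
            raise DegenerateStatisticError("reference sample needs >= 2 non-missing values")
        self.reference_ = X
        self.n_reference_ = len(X)
        return self

    def compare(self, X, feature_name: str = "", importance_rank: int | None = None) -> ComparisonStats:
        """Full comparison row for a pooled incoming sample."""
        ref = self.reference_
        x = _clean(X)
        if self.kind == "binary":
            test_name = "chi_square"
            ref_mean, ref_sd = _bernoulli_moments(ref)
            if len(x) < 2:
                return self._degenerate(x, feature_name, importance_rank, test_name)
            inc_mean, inc_sd = _bernoulli_moments(x)
            stat, p, degen = chi_square_presence(x, ref)
            d = _proportion_standardized_difference(inc_mean, ref_mean)
        else:
            test_name = "ks"
            ref_mean, ref_sd = float(ref.mean()), float(ref.std(ddof=1))
            if len(x) < 2:
                return self._degenerate(x, feature_name, importance_rank, test_name)
            inc_mean, inc_sd = float(x.mean()), float(x.std(ddof=1))
            stat, p = ks_two_sample(x, ref)
            degen = False
            d = standardized_difference(x, ref)
        return ComparisonStats(
            feature=feature_name,
            kind=self.kind,
            incoming_mean=inc_mean,
            incoming_sd=inc_sd,
            reference_mean=ref_mean,
            reference_sd=ref_sd,
            standardized_difference=d,
            test_name=test_name,
            statistic=stat,
            p_value=p,
            n_incoming=len(x),
            n_reference=len(ref),
            importance_rank=importance_rank,
            degenerate=degen,
        )

    def predict(self, X) -> bool:
        """True when the incoming window drifted from the reference at alpha."""
        res = self.compare(X)
        return (not res.degenerate) and res.p_value < self.alpha

    def _degenerate(self, x, feature_name, importance_rank, test_name) -> ComparisonStats:
        ref = self.reference_
        if self.kind == "binary":
            ref_mean, ref_sd = _bernoulli_moments(ref)
        else:
            ref_mean, ref_sd = float(ref.mean()), float(ref.std(ddof=1))
        return ComparisonStats(
            feature=feature_name,
            kind=self.kind,
            incoming_mean=float(x.mean()) if len(x) else float("nan"),
            incoming_sd=float("nan"),
            reference_mean=ref_mean,
            reference_sd=ref_sd,
            standardized_difference=float("nan"),
            test_name=test_name,
            statistic=float("nan"),
            p_value=float("nan"),
            n_incoming=len(x),
            n_reference=len(ref),
            importance_rank=importance_rank,
            degenerate=True,
        )


def _bernoulli_moments(x: np.ndarray) -> tuple[float, float]:
    p = float(x.mean())
    return p, float(np.sqrt(p * (1.0 - p)))


def _proportion_standardized_difference(p: float, q: float) -> float:
    denom = np.sqrt((p * (1 - p) + q * (1 - q)) / 2.0)
    if denom == 0.0:
        return 0.0 if p == q else float(np.sign(p - q)) * float("inf")
    return float((p - q) / denom)


# ---------------------------------------------------------------------------
# Windowed operations on streams
# ---------------------------------------------------------------------------

def pooled_window_values(feature: FeatureSpec, window: Sequence[DailySnapshot]) -> np.ndarray:
    """All non-missing values of a feature pooled across a window of days."""
    if len(window) == 0:
        return np.empty(0)
    return np.concatenate([snap.feature_values(feature.name) for snap in window])


def compare_window(
    feature: FeatureSpec,
    window: Sequence[DailySnapshot],
    reference: TrainingReference,
    alpha: float = 0.05,
) -> ComparisonStats:
    """Compare a feature's pooled window against its training sample.

    Pools calls across days (the window is read as one distribution, not a
    set of daily averages) and dispatches the test on the feature kind. A
    window with fewer than 2 non-missing values yields a degenerate row with
    an explicit flag rather than an exception — on a live dashboard a broken
    feature must still occupy its row.
    """
    if len(window) == 0:
        raise ValueError("compare_window requires a nonempty window")
    test = WindowDriftTest(kind=feature.kind, alpha=alpha).fit(
        reference.feature_values(feature.name)
    )
    return test.compare(
        pooled_window_values(feature, window),
        feature_name=feature.name,
        importance_rank=feature.importance_rank,
    )


def daily_standardized_differences(
    feature: FeatureSpec,
    window: Sequence[DailySnapshot],
    reference: TrainingReference,
) -> pd.Series:
    """Per-day standardized difference of a feature against training.

    One entry per present day; a day with fewer than 2 non-missing values
    yields NaN. For binary features the Bernoulli-variance form is used.
    """
    ref = reference.feature_values(feature.name)
    out = {}
    for snap in window:
        x = snap.feature_values(feature.name)
        if len(x) < 2:
            out[snap.date] = float("nan")
        elif feature.kind == "binary":
            out[snap.date] = _proportion_standardized_difference(
                float(x.mean()), float(ref.mean())
            )
        else:
            out[snap.date] = standardized_difference(x, ref)
    return pd.Series(out, name=feature.name, dtype=float)
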