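"""Domain types and delimited-table I/O for drift surveillance.

Everything downstream of this module speaks in three containers: a frozen
:class:`TrainingReference` (the yardstick every comparison is made against),
an ordered stream of :class:`DailySnapshot` objects (one per production day),
and a feature catalogue of :class:`FeatureSpec` entries carrying the model's
importance ranking and any source-code aliases.

File conventions are deliberately rigid: comma-separated tables with a header
row, ISO-8601 dates, ``.`` decimal separator, and an *empty field* as the one
and only missing marker. Internally missing values are ``NaN`` in float
columns — never a sentinel numeric, which would contaminate every shift
statistic computed later.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCORE_COLUMN = "score"
DATE_COLUMN = "date"

FEATURE_KINDS = ("continuous", "binary")


class SchemaError(ValueError):
    """A table is missing a required column or has an unknown layout."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. probability outside [0,1])."""


class FormatError(ValueError):
    """A cell cannot be parsed (bad date, bad number); carries the row number."""


@dataclass(frozen=True)
class FeatureSpec:
    """One catalogue entry for a model input.

    Parameters
    ----------
    name : str
        Canonical feature name, unique within a catalogue.
    kind : {"continuous", "binary"}
        Drives which two-sample test is used downstream (KS vs chi-square).
    importance_rank : int
        Relative-influence rank from the trained model; 1 = most influential.
    aliases : tuple of str
        Raw source-code column names that map onto this feature. This is the
        hook that absorbs upstream coding changes (a lab adopting a new code
        for the same analyte) without retraining.
    """

    name: str
    kind: str
    importance_rank: int
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValidationError("feature name must be a nonempty string")
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature {self.name!r}: kind must be one of {FEATURE_KINDS}, got {self.kind!r}"
            )
        if int(self.importance_rank) < 1:
            raise ValidationError(
                f"feature {self.name!r}: importance_rank must be a positive integer"
            )
        object.__setattr__(self, "importance_rank", int(self.importance_rank))
        object.__setattr__(self, "aliases", tuple(self.aliases))


def validate_catalogue(catalogue: Sequence[FeatureSpec]) -> None:
    """Check catalogue-level invariants: unique names, unique importance ranks."""
    names = [f.name for f in catalogue]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate feature names in catalogue: {dupes}")
    ranks = [f.importance_rank for f in catalogue]
    if len(set(ranks)) != len(ranks):
        raise ValidationError("importance_rank values must be unique within a catalogue")
    all_aliases: list[str] = []
    for f in catalogue:
        all_aliases.extend(f.aliases)
    clash = set(all_aliases) & set(names)
    overlap = {a for a in all_aliases if all_aliases.count(a) > 1}
    if clash:
        raise ValidationError(f"aliases shadow canonical feature names: {sorted(clash)}")
    if overlap:
        raise ValidationError(f"alias mapped to more than one feature: {sorted(overlap)}")


@dataclass
class TrainingReference:
    """Frozen training baseline: per-feature samples plus baseline scores.

    ``frame`` holds one float column per catalogue feature (NaN = missing);
    ``probabilities`` are the model's predicted probabilities on the training
    data, all in [0, 1].
    """

    catalogue: list[FeatureSpec]
    frame: pd.DataFrame
    probabilities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.validate()

    def validate(self) -> None:
        validate_catalogue(self.catalogue)
        for spec in self.catalogue:
            if spec.name not in self.frame.columns:
                raise SchemaError(f"reference table missing feature column {spec.name!r}")
            n_obs = int(self.frame[spec.name].notna().sum())
            if n_obs < 2:
                raise ValidationError(
                    f"feature {spec.name!r}: needs >= 2 non-missing reference values, has {n_obs}"
                )
        _check_probabilities(self.probabilities, "reference")
        if len(self.probabilities) != len(self.frame):
            raise ValidationError(
                "reference probabilities and feature table have different lengths"
            )

    def feature_values(self, name: str) -> np.ndarray:
        """Non-missing reference sample for one feature."""
        col = self.frame[name].to_numpy(dtype=float)
        return col[~np.isnan(col)]

    def missing_indicators(self, name: str) -> np.ndarray:
        """0/1 missingness indicator per training record for one feature."""
        return self.frame[name].isna().to_numpy().astype(float)


@dataclass
class DailySnapshot:
    """All model calls for one calendar day."""

    date: _dt.date
    frame: pd.DataFrame
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.probabilities) != len(self.frame):
            raise ValidationError(f"{self.date}: probabilities/records length mismatch")
        _check_probabilities(self.probabilities, str(self.date))

    @property
    def call_count(self) -> int:
        return len(self.frame)

    def feature_values(self, name: str) -> np.ndarray:
        col = self.frame[name].to_numpy(dtype=float)
        return col[~np.isnan(col)]

    def missing_indicators(self, name: str) -> np.ndarray:
        return self.frame[name].isna().to_numpy().astype(float)


@dataclass
class MonitorConfig:
    """Tunable thresholds for every monitor, with deployment-grade defaults.

    window_days
        Length of the look-back window compared against training (14 days:
        long enough to see gradual drift, short enough to read at a glance).
    alpha
        Significance level for window tests and chart flags.
    fap
        Family-wise false-alarm probability for the level/scale charts: the
        chance that an in-control feature history shows any red day.
    n_permutations
        Permutation draws calibrating each chart's null distribution.
    volume_mad_multiplier
        Half-width of the call-volume anomaly band in MADs around the median.
    log_floor
        Floor applied before log10 display of probabilities (scores cluster
        near 0 and may be exactly 0).
    sustained_days
        How long a performance-loss finding must persist before retraining is
        recommended.
    importance_cutoff
        Shifts confined to features with importance_rank strictly greater
        than this are treated as nuisance drift for retraining purposes.
    """

    window_days: int = 14
    alpha: float = 0.05
    fap: float = 0.05
    n_permutations: int = 2000
    seed: int = 0
    volume_mad_multiplier: float = 5.0
    log_floor: float = 1e-4
    sustained_days: int = 14
    importance_cutoff: int = 10
    min_trend_days: int = 30
    merge_duplicate_dates: bool = False

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        for name in ("alpha", "fap", "log_floor"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "MonitorConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def _check_probabilities(p: np.ndarray, context: str) -> None:
    if len(p) and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValidationError(f"{context}: predicted probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Catalogue I/O
# ---------------------------------------------------------------------------

def load_catalogue(path: str | Path) -> list[FeatureSpec]:
    """Read a feature catalogue CSV (columns name,kind,importance_rank,aliases)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"name", "kind", "importance_rank"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"catalogue missing columns: {sorted(missing)}")
    specs = []
    for _, row in df.iterrows():
        aliases = tuple(a for a in str(row.get("aliases", "")).split(";") if a)
        specs.append(
            FeatureSpec(
                name=row["name"],
                kind=row["kind"],
                importance_rank=int(row["importance_rank"]),
                aliases=aliases,
            )
        )
    validate_catalogue(specs)
    return specs


def save_catalogue(catalogue: Sequence[FeatureSpec], path: str | Path) -> Path:
    validate_catalogue(list(catalogue))
    df = pd.DataFrame(
        {
            "name": [f.name for f in catalogue],
            "kind": [f.kind for f in catalogue],
            "importance_rank": [f.importance_rank for f in catalogue],
            "aliases": [";".join(f.aliases) for f in catalogue],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Alias mapping
# ---------------------------------------------------------------------------

def apply_aliases(frame: pd.DataFrame, catalogue: Sequence[FeatureSpec]) -> pd.DataFrame:
    """Map raw source-code columns onto canonical feature names.

    Idempotent: a column already bearing the canonical name is left alone. If
    both an alias column and the canonical column are present (the overlap
    period of a code migration), values are merged row-wise, preferring the
    canonical column where both are observed.
    """
    alias_map = {a: f.name for f in catalogue for a in f.aliases}
    out = frame.copy()
    for raw, canonical in alias_map.items():
        if raw not in out.columns:
            continue
        moved = pd.to_numeric(out.pop(raw), errors="coerce")
        if canonical in out.columns:
            out[canonical] = out[canonical].combine_first(moved)
        else:
            out[canonical] = moved
    return out


# ---------------------------------------------------------------------------
# Reference / stream I/O
# ---------------------------------------------------------------------------

def _coerce_features(df: pd.DataFrame, catalogue: Sequence[FeatureSpec], context: str) -> pd.DataFrame:
    df = apply_aliases(df, catalogue)
    missing = [f.name for f in catalogue if f.name not in df.columns]
    if missing:
        raise SchemaError(f"{context}: table missing feature column(s) {missing}")
    for f in catalogue:
        df[f.name] = pd.to_numeric(df[f.name], errors="coerce")
    return df


def load_reference(
    path: str | Path,
    catalogue: str | Path | Sequence[FeatureSpec],
    label: str = "",
) -> TrainingReference:
    """Load a training-reference CSV (one row per training record).

    ``catalogue`` may be a path to a catalogue CSV or an in-memory list of
    :class:`FeatureSpec`. Raw columns named by an alias are remapped onto the
    canonical feature.
    """
    if isinstance(catalogue, (str, Path)):
        catalogue = load_catalogue(catalogue)
    catalogue = list(catalogue)
    df = pd.read_csv(path, float_precision="round_trip")
    if SCORE_COLUMN not in df.columns:
        raise SchemaError(f"reference table missing {SCORE_COLUMN!r} column")
    df = _coerce_features(df, catalogue, f"reference {path}")
    probs = df[SCORE_COLUMN].to_numpy(dtype=float)
    frame = df[[f.name for f in catalogue]].astype(float)
    return TrainingReference(
        catalogue=catalogue, frame=frame, probabilities=probs, label=label or str(path)
    )


def save_reference(reference: TrainingReference, path: str | Path) -> Path:
    out = reference.frame.copy()
    out[SCORE_COLUMN] = reference.probabilities
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def load_stream(
    path: str | Path,
    catalogue: Sequence[FeatureSpec] | str | Path,
    merge_duplicate_dates: bool = False,
) -> list[DailySnapshot]:
    """Load a dated production stream CSV into day snapshots, sorted ascending.

    One row per model call; a ``date`` column groups rows into days. Date gaps
    are preserved exactly as found — outage days must stay visible. Duplicate
    date *groups* cannot arise from a single CSV read (grouping collapses
    them), so the duplicate-date rule is enforced by :func:`merge_streams` and
    at simulation time; ``merge_duplicate_dates`` is accepted here for
    interface symmetry.
    """
    if isinstance(catalogue, (str, Path)):
        catalogue = load_catalogue(catalogue)
    catalogue = list(catalogue)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        logger.warning("stream file %s is empty; returning an empty stream", path)
        return []
    if DATE_COLUMN not in df.columns:
        raise SchemaError(f"stream table missing {DATE_COLUMN!r} column")
    if SCORE_COLUMN not in df.columns:
        raise SchemaError(f"stream table missing {SCORE_COLUMN!r} column")
    dates = pd.to_datetime(df[DATE_COLUMN], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise FormatError(
            f"stream {path}: unparseable date {df[DATE_COLUMN].iloc[row]!r} at data row {row + 1}"
        )
    df = _coerce_features(df, catalogue, f"stream {path}")
    df["_date"] = dates.dt.date
    snapshots = []
    for day, grp in df.groupby("_date", sort=True):
        frame = grp[[f.name for f in catalogue]].reset_index(drop=True).astype(float)
        snapshots.append(
            DailySnapshot(
                date=day,
                frame=frame,
                probabilities=grp[SCORE_COLUMN].to_numpy(dtype=float),
            )
        )
    return snapshots


def merge_streams(
    streams: Iterable[Sequence[DailySnapshot]], merge_duplicate_dates: bool = False
) -> list[DailySnapshot]:
    """Concatenate streams; duplicate dates are an error unless merging is requested."""
    by_date: dict[_dt.date, list[DailySnapshot]] = {}
    for stream in streams:
        for snap in stream:
            by_date.setdefault(snap.date, []).append(snap)
    dupes = sorted(d for d, snaps in by_date.items() if len(snaps) > 1)
    if dupes and not merge_duplicate_dates:
        raise ValidationError(f"duplicate snapshot dates: {[str(d) for d in dupes]}")
    out = []
    for day in sorted(by_date):
        snaps = by_date[day]
        if len(snaps) == 1:
            out.append(snaps[0])
        else:
            frame = pd.concat([s.frame for s in snaps], ignore_index=True)
            probs = np.concatenate([s.probabilities for s in snaps])
            out.append(DailySnapshot(date=day, frame=frame, probabilities=probs))
    return out


def save_stream(stream: Sequence[DailySnapshot], path: str | Path) -> Path:
    """Write a stream back to the one-row-per-call CSV dialect."""
    frames = []
    for snap in stream:
        f = snap.frame.copy()
        f.insert(0, DATE_COLUMN, snap.date.isoformat())
        f[SCORE_COLUMN] = snap.probabilities
        frames.append(f)
    path = Path(path)
    if not frames:
        cols = [DATE_COLUMN, SCORE_COLUMN]
        pd.DataFrame(columns=cols).to_csv(path, index=False)
        return path
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def validate_stream(stream: Sequence[DailySnapshot]) -> None:
    """Enforce stream-level invariants: unique, strictly increasing dates."""
    dates = [s.date for s in stream]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError("stream dates must be unique and strictly increasing")
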