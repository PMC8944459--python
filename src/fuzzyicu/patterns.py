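"""From raw administration/monitoring tables to deduplicated category patterns.

Therapy: one record per patient-day with at least one antimicrobial
administration, carrying the overall consecutive days of any therapy plus one
consecutive-day counter per vocabulary drug (0 = not given that day).

Monitoring: one record per patient-hour with at least one reading; multiple
readings of a parameter within the hour are reduced by an aggregator.

Both record kinds are normalized to category patterns (codes 0..5, 0 = absent)
against per-column fuzzy domains, then deduplicated: exact equality of integer
category vectors is provably equivalent to zero Euclidean distance, which is
the identity criterion used to shrink the clustering input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import FuzzyDomain, fuzzify

__all__ = [
    "consecutive_days",
    "build_therapy_records",
    "build_monitoring_records",
    "normalize_records",
    "dedup",
    "UniquePatternTable",
    "THERAPY_ID_COLS",
    "MONITORING_ID_COLS",
]

THERAPY_ID_COLS = ("patient_id", "date")
MONITORING_ID_COLS = ("patient_id", "date", "hour")


def consecutive_days(dates: Iterable, grace: int = 0) -> dict[pd.Timestamp, int]:
    """Per-day therapy-day counters for one (patient[, drug]) series of dates.

    The counter on day d is the length of the maximal block of consecutive
    calendar days ending at d; any gap wider than ``grace`` calendar days off
    resets it to 1.  Duplicated dates are collapsed.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize().unique().sort_values()
    out: dict[pd.Timestamp, int] = {}
    run = 0
    prev = None
    for d in idx:
        run = run + 1 if prev is not None and (d - prev).days <= 1 + grace else 1
        out[d] = run
        prev = d
    return out


def build_therapy_records(
    admins: pd.DataFrame,
    vocabulary: Sequence[str],
    grace: int = 0,
) -> pd.DataFrame:
    """Build per-day therapy records from an administrations table.

    ``admins`` needs columns patient_id, drug, date; duplicated
    patient x drug x day rows are collapsed.  The result has one row per
    patient-day with >= 1 administration and columns ``overall_days`` (run
    length on the union of drug days) plus one column per vocabulary drug.
    Unknown drug names raise, listing them.
    """
    required = {"patient_id", "drug", "date"}
    if not required.issubset(admins.columns):
        raise ValueError(f"administrations table must have columns {sorted(required)}")
    vocab = list(vocabulary)
    unknown = sorted(set(admins["drug"]) - set(vocab))
    if unknown:
        raise ValueError(f"unknown drug names: {unknown}")

    df = admins.loc[:, ["patient_id", "drug", "date"]].copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df = df.drop_duplicates()

    rows: dict[tuple, dict[str, int]] = {}
    for pid, g in df.groupby("patient_id", sort=True):
        overall = consecutive_days(g["date"], grace=grace)
        for day, count in overall.items():
            rows[(pid, day)] = {"overall_days": count}
        for drug, gd in g.groupby("drug", sort=True):
            for day, count in consecutive_days(gd["date"], grace=grace).items():
                rows[(pid, day)][drug] = count

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["patient_id", "date"])
    out = pd.DataFrame([rows[key] for key in sorted(rows)], index=index)
    out = out.reindex(columns=["overall_days", *vocab]).fillna(0).astype(np.int64)
    return out.reset_index()


def build_monitoring_records(
    readings: pd.DataFrame,
    schema: Sequence[str],
    aggregator: str = "median",
) -> pd.DataFrame:
    """Bucket readings into per patient x date x clock-hour records.

    ``readings`` needs columns patient_id, timestamp, parameter, value.
    Multiple readings of one parameter within an hour are reduced by the
    aggregator (``median`` or ``last`` in timestamp order); parameters not
    read in that hour stay missing.  Hours with no readings at all yield no
    record.  Parameters outside the schema raise.
    """
    if aggregator not in ("median", "last"):
        raise ValueError(f"unknown aggregator {aggregator!r} (expected 'median' or 'last')")
    required = {"patient_id", "timestamp", "parameter", "value"}
    if not required.issubset(readings.columns):
        raise ValueError(f"readings table must have columns {sorted(required)}")
    schema = list(schema)
    unknown = sorted(set(readings["parameter"]) - set(schema))
    if unknown:
        raise ValueError(f"unknown monitoring parameters: {unknown}")

    df = readings.loc[:, ["patient_id", "timestamp", "parameter", "value"]].copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.normalize()
    df["hour"] = ts.dt.hour.astype(np.int64)
    df = df.sort_values("timestamp", kind="stable")
    grouped = df.groupby(["patient_id", "date", "hour", "parameter"], sort=True)["value"]
    ser = grouped.median() if aggregator == "median" else grouped.last()
    wide = ser.unstack("parameter").reindex(columns=schema)
    wide = wide.dropna(how="all")
    return wide.reset_index()


def normalize_records(
    records: pd.DataFrame,
    domains: Mapping[str, FuzzyDomain],
    id_cols: Sequence[str] | None = None,
    zero_is_absent: bool = False,
) -> pd.DataFrame:
    """Fuzzify every value column of a record table into category codes 0..5.

    Missing cells map to 0; with ``zero_is_absent`` (therapy counters, where a
    0 means the drug was not given) zeros map to 0 as well instead of being
    fuzzified as numbers.  A value column without a domain raises.
    """
    if id_cols is None:
        id_cols = [c for c in ("patient_id", "date", "hour") if c in records.columns]
    value_cols = [c for c in records.columns if c not in id_cols]
    missing = [c for c in value_cols if c not in domains]
    if missing:
        raise ValueError(f"no fuzzy domain for columns: {missing}")

    out = records.loc[:, list(id_cols)].copy()
    for col in value_cols:
        vals = records[col].to_numpy(dtype=float)
        if zero_is_absent:
            vals = np.where(vals == 0, np.nan, vals)
        out[col] = fuzzify(domains[col], vals)
    return out


@dataclass(frozen=True)
class UniquePatternTable:
    """Deduplicated category patterns with multiplicities and a record back-map.

    ``patterns`` holds the unique vectors in lexicographic order (pattern_id =
    row index), ``multiplicity[i]`` how many source records collapsed onto
    pattern i, and ``record_ids[j]`` the pattern_id of source record j.
    """

    columns: tuple[str, ...]
    patterns: np.ndarray
    multiplicity: np.ndarray
    record_ids: np.ndarray

    @property
    def n_unique(self) -> int:
        return int(self.patterns.shape[0])

    @property
    def n_records(self) -> int:
        return int(self.record_ids.shape[0])

    def expand(self) -> np.ndarray:
        """Reconstruct the full (multi-)set of normalized records, in source order."""
        return self.patterns[self.record_ids]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.patterns, columns=list(self.columns))
        df.insert(0, "pattern_id", np.arange(self.n_unique))
        df.insert(1, "multiplicity", self.multiplicity)
        return df


def dedup(patterns, id_cols: Sequence[str] | None = None) -> UniquePatternTable:
    """Collapse identical category patterns (zero Euclidean distance = identity).

    Accepts a normalized-pattern DataFrame (id columns are dropped) or a 2-D
    integer array.  Ragged input raises.
    """
    if isinstance(patterns, pd.DataFrame):
        if id_cols is None:
            id_cols = [c for c in ("patient_id", "date", "hour") if c in patterns.columns]
        value_cols = [c for c in patterns.columns if c not in id_cols]
        X = patterns.loc[:, value_cols].to_numpy()
        columns = tuple(value_cols)
    else:
        try:
            X = np.asarray(patterns, dtype=np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError("ragged input: patterns must all have the same length") from exc
        if X.ndim != 2:
            raise ValueError("ragged input: patterns must form a 2-D array")
        columns = tuple(f"c{i}" for i in range(X.shape[1]))
    X = X.astype(np.int64, copy=False)
    uniq, inverse, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    return UniquePatternTable(
        columns=columns,
        patterns=uniq,
        multiplicity=counts.astype(np.int64),
        record_ids=inverse.reshape(-1).astype(np.int64),
    )
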