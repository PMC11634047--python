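"""Cohort ingestion, eligibility filtering, observation pairing, fall-rate
normalisation.

The analysis unit is the *observation pair*: two consecutive assessments of
the same resident (T1, T2) separated by 45-180 days.  Fall counts reported at
T2 cover the T1->T2 interval and are normalised to falls per day and per week
so that observations with different intervals are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical assessment-table columns.  Extra columns are carried through.
REQUIRED_COLUMNS = ("resident_id", "date", "age", "frs", "falls_since_last")

#: Covariates copied from the T1 assessment onto each observation pair.
PAIR_COVARIATES = (
    "age",
    "gender",
    "gait_speed",
    "dementia",
    "walking_aid",
    "fall_history",
    "disease_count",
    "assessment_mode",
)

#: Default eligible interval between consecutive assessments, in days.
INTERVAL_RANGE = (45, 180)


class InvalidPairError(ValueError):
    """An observation pair violates its interval/ordering invariants."""


class AmbiguousRecordError(ValueError):
    """Two assessments of the same resident share the same date."""


@dataclass(frozen=True)
class EligibilityRules:
    """Study entry rules applied to raw assessment records.

    ``allowed_versions = None`` accepts every schema/app-version tag;
    otherwise the tag must be a member of the set (standing in for the
    contiguous version range under which the score definition is stable).
    """

    min_age: float = 60.0
    min_assessments: int = 2
    allowed_versions: frozenset[str] | None = None


@dataclass
class ExclusionLog:
    """One entry per excluded assessment record, keyed by rule."""

    entries: list[dict] = field(default_factory=list)

    def add(self, index, resident_id, rule: str) -> None:
        self.entries.append(
            {"index": index, "resident_id": resident_id, "rule": rule}
        )

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e["rule"]] = out.get(e["rule"], 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["index", "resident_id", "rule"])


def load_assessments(
    source: str | Path | pd.DataFrame,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read an assessment table from delimited text (or pass through a frame).

    The delimiter is auto-detected (comma or tab) unless ``sep`` is given.
    ``column_map`` renames source columns onto the canonical schema, e.g.
    ``{"PatID": "resident_id"}``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assessment table missing required columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    for col, lo, hi in (("frs", 0, 100), ("age", 0, None), ("falls_since_last", 0, None)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < lo).any() or (hi is not None and (vals.dropna() > hi).any()):
            raise ValueError(f"column {col!r} outside valid range")
        df[col] = vals
    return df


def filter_eligible(
    assessments: pd.DataFrame,
    rules: EligibilityRules = EligibilityRules(),
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the study entry rules; return retained records + exclusion log.

    Rules, in order: a usable age field; age at or above ``min_age``; an
    accepted app/schema version tag; and at least ``min_assessments``
    assessments for the resident among records passing the first three rules.
    A record failing a rule is logged once, under the first rule it fails.
    """
    df = assessments
    log = ExclusionLog()
    keep = pd.Series(True, index=df.index)

    missing_age = df["age"].isna()
    for idx in df.index[missing_age]:
        log.add(idx, df.at[idx, "resident_id"], "missing-field")
    keep &= ~missing_age

    under_age = keep & (df["age"] < rules.min_age)
    for idx in df.index[under_age]:
        log.add(idx, df.at[idx, "resident_id"], "age")
    keep &= ~under_age

    if rules.allowed_versions is not None:
        if "app_version" in df.columns:
            bad_version = keep & ~df["app_version"].isin(rules.allowed_versions)
        else:
            bad_version = keep.copy()
        for idx in df.index[bad_version]:
            log.add(idx, df.at[idx, "resident_id"], "version")
        keep &= ~bad_version

    counts = df.loc[keep, "resident_id"].value_counts()
    lonely = df["resident_id"].map(counts).fillna(0) < rules.min_assessments
    lonely &= keep
    for idx in df.index[lonely]:
        log.add(idx, df.at[idx, "resident_id"], "repeat-assessment")
    keep &= ~lonely

    if log.entries:
        logger.info("eligibility exclusions: %s", log.counts())
    return df.loc[keep].copy(), log


def build_pairs(
    assessments: pd.DataFrame,
    interval_range: tuple[float, float] = INTERVAL_RANGE,
) -> pd.DataFrame:
    """Form (T1, T2) observation pairs from consecutive assessments.

    Records are sorted by resident and date; every consecutive pair whose
    interval lies inside the closed ``interval_range`` window (days) becomes
    one observation.  Out-of-window gaps are dropped and logged.  Residents
    may contribute several observations.

    Returns a frame with one row per pair: T1 covariates, ``frs_t1``,
    ``frs_t2``, ``interval_days``, ``falls`` (reported at T2 for the
    interval), ``rate_per_day`` and ``rate_per_week``.

    Raises
    ------
    AmbiguousRecordError
        If a resident has two assessments on the same date.
    """
    df = assessments.sort_values(["resident_id", "date"], kind="stable")
    dup = df.duplicated(subset=["resident_id", "date"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["resident_id", "date"]].drop_duplicates()
        raise AmbiguousRecordError(
            "duplicate (resident, date) assessments: "
            + "; ".join(f"{r.resident_id}@{r.date.date()}" for r in offending.itertuples())
        )

    g = df.groupby("resident_id", sort=False)
    nxt = g.shift(-1)
    has_next = nxt["date"].notna()
    interval = (nxt["date"] - df["date"]).dt.days.astype("float")

    in_window = has_next & (interval >= interval_range[0]) & (interval <= interval_range[1])
    n_dropped = int((has_next & ~in_window).sum())
    if n_dropped:
        logger.info(
            "dropped %d consecutive gaps outside %s days", n_dropped, interval_range
        )

    t1 = df.loc[in_window]
    t2 = nxt.loc[in_window]
    pairs = pd.DataFrame(
        {
            "resident_id": t1["resident_id"].to_numpy(),
            "date_t1": t1["date"].to_numpy(),
            "date_t2": t2["date"].to_numpy(),
            "interval_days": interval.loc[in_window].to_numpy(),
            "frs_t1": t1["frs"].to_numpy(float),
            "frs_t2": t2["frs"].to_numpy(float),
            "falls": t2["falls_since_last"].to_numpy(),
        }
    )
    for cov in PAIR_COVARIATES:
        if cov in t1.columns:
            pairs[cov] = t1[cov].to_numpy()
    per_day, per_week = normalize_falls(pairs["falls"], pairs["interval_days"])
    pairs["rate_per_day"] = per_day
    pairs["rate_per_week"] = per_week
    return pairs.reset_index(drop=True)


def normalize_falls(
    falls: Sequence[float] | np.ndarray | pd.Series | float,
    interval_days: Sequence[float] | np.ndarray | pd.Series | float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise fall counts over an interval to per-day and per-week rates.

    ``rate_per_day = falls / interval_days``; ``rate_per_week = 7 x`` that.
    Zero falls give rate 0.  The per-week rate is the analysis unit.
    """
    falls_arr = np.atleast_1d(np.asarray(falls, dtype=float))
    days = np.atleast_1d(np.asarray(interval_days, dtype=float))
    if (days <= 0).any():
        raise InvalidPairError("interval must be positive to normalise falls")
    if (falls_arr < 0).any():
        raise InvalidPairError("fall counts must be non-negative")
    per_day = falls_arr / days
    return per_day, 7.0 * per_day
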