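"""Minute-level accelerometer cohort I/O, wear-validity filtering, and imputation.

A participant contributes 7 consecutive days x 1440 minutes of MET values
(multiples of resting metabolic rate). A minute is "worn" iff a MET value was
recorded for it; non-wear minutes are missing (NaN), never zero. Days start at
local midnight (the device resets its buffer there), so minute 0 of each day is
00:00 and internal time is 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
DAYS_PER_WEEK = 7
WEEK_MINUTES = MINUTES_PER_DAY * DAYS_PER_WEEK  # 10,080


class CohortError(ValueError):
    """Raised for malformed cohort files or untenable filter outcomes."""


@dataclass
class ParticipantTrace:
    """One subject's week of minute-level METs.

    Parameters
    ----------
    participant_id : str
        Opaque identifier.
    mets : ndarray of float, shape (10080,)
        MET value per minute; NaN marks a missing (non-worn) minute.
        Observed values must be finite and >= 0.
    steps : ndarray of float, shape (10080,), optional
        Step counts per minute (NaN where missing); absent if the device
        channel was not exported.
    """

    participant_id: str
    mets: np.ndarray
    steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mets = np.asarray(self.mets, dtype=float)
        if self.mets.shape != (WEEK_MINUTES,):
            raise ValueError(
                f"trace {self.participant_id!r}: expected {WEEK_MINUTES} minutes, "
                f"got shape {self.mets.shape}"
            )
        observed = self.mets[~np.isnan(self.mets)]
        if observed.size and (not np.all(np.isfinite(observed)) or observed.min() < 0):
            raise ValueError(
                f"trace {self.participant_id!r}: observed METs must be finite and >= 0"
            )
        if self.steps is not None:
            self.steps = np.asarray(self.steps, dtype=float)
            if self.steps.shape != (WEEK_MINUTES,):
                raise ValueError(
                    f"trace {self.participant_id!r}: steps must have length {WEEK_MINUTES}"
                )
            obs = self.steps[~np.isnan(self.steps)]
            if obs.size and obs.min() < 0:
                raise ValueError(f"trace {self.participant_id!r}: steps must be >= 0")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the minute is missing (non-wear)."""
        return np.isnan(self.mets)

    @property
    def day_index(self) -> np.ndarray:
        """Day (0..6) of each of the 10,080 minutes."""
        return np.arange(WEEK_MINUTES) // MINUTES_PER_DAY

    @property
    def minute_of_day(self) -> np.ndarray:
        """Minute within the day (0..1439); 0 = midnight."""
        return np.arange(WEEK_MINUTES) % MINUTES_PER_DAY

    @property
    def days(self) -> np.ndarray:
        """METs reshaped to (7, 1440)."""
        return self.mets.reshape(DAYS_PER_WEEK, MINUTES_PER_DAY)


@dataclass
class CohortDataset:
    """Traces plus a covariate table keyed by participant id.

    ``covariates`` is indexed by participant_id; every trace id must appear in
    it (extra covariate-only rows are tolerated and exposed via
    :attr:`extra_covariate_ids`).
    """

    traces: list[ParticipantTrace]
    covariates: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [t.participant_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate participant ids: {dupes}")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
        missing = set(ids) - set(self.covariates.index)
        if missing:
            raise CohortError(
                f"traces without covariate rows: {sorted(missing)}"
            )

    @property
    def participant_ids(self) -> list[str]:
        return [t.participant_id for t in self.traces]

    @property
    def extra_covariate_ids(self) -> list[str]:
        """Covariate rows with no accelerometer trace."""
        return sorted(set(self.covariates.index) - set(self.participant_ids))

    def __len__(self) -> int:
        return len(self.traces)

    def trace(self, participant_id: str) -> ParticipantTrace:
        for t in self.traces:
            if t.participant_id == participant_id:
                return t
        raise KeyError(participant_id)

    def sorted_traces(self) -> list[ParticipantTrace]:
        return sorted(self.traces, key=lambda t: t.participant_id)


def _trace_from_long(pid: str, grp: pd.DataFrame, has_steps: bool) -> ParticipantTrace:
    mets = np.full(WEEK_MINUTES, np.nan)
    steps = np.full(WEEK_MINUTES, np.nan) if has_steps else None
    idx = (grp["day"].to_numpy(int) - 1) * MINUTES_PER_DAY + grp["minute"].to_numpy(int)
    mets[idx] = grp["mets"].to_numpy(float)
    if has_steps:
        steps[idx] = grp["steps"].to_numpy(float)
    return ParticipantTrace(pid, mets, steps)


def read_cohort(
    path,
    format: str = "long_csv",
    covariates: pd.DataFrame | None = None,
) -> CohortDataset:
    """Read a cohort from CSV.

    ``long_csv`` columns: participant_id, day (1-7), minute (0-1439), mets
    (empty cell = missing), optional steps. ``wide_csv``: one row per
    participant-day with columns participant_id, day, m0000..m1439.
    Minutes absent from the file are missing, never fabricated as 0.
    """
    if format == "long_csv":
        df = pd.read_csv(path, dtype={"participant_id": str})
        required = {"participant_id", "day", "minute", "mets"}
        if not required.issubset(df.columns):
            raise CohortError(f"long CSV must have columns {sorted(required)}")
        bad_day = ~df["day"].between(1, DAYS_PER_WEEK)
        if bad_day.any():
            row = int(df.index[bad_day][0])
            raise CohortError(f"row {row + 2}: day {df.loc[df.index[bad_day][0], 'day']} outside 1-7")
        bad_min = ~df["minute"].between(0, MINUTES_PER_DAY - 1)
        if bad_min.any():
            row = int(df.index[bad_min][0])
            raise CohortError(f"row {row + 2}: minute outside 0-1439")
        dupes = df.duplicated(subset=["participant_id", "day", "minute"])
        if dupes.any():
            r = df[dupes].iloc[0]
            raise CohortError(
                f"duplicate cell for participant {r['participant_id']!r}, "
                f"day {int(r['day'])}, minute {int(r['minute'])}"
            )
        neg = df["mets"].notna() & (df["mets"] < 0)
        if neg.any():
            row = int(df.index[neg][0])
            raise CohortError(f"row {row + 2}: negative METs value")
        df = df[df["mets"].notna()]
        has_steps = "steps" in df.columns
        traces = [
            _trace_from_long(pid, grp, has_steps)
            for pid, grp in df.groupby("participant_id", sort=True)
        ]
    elif format == "wide_csv":
        df = pd.read_csv(path, dtype={"participant_id": str})
        mcols = [f"m{m:04d}" for m in range(MINUTES_PER_DAY)]
        if not {"participant_id", "day"}.issubset(df.columns) or not set(mcols).issubset(df.columns):
            raise CohortError("wide CSV must have participant_id, day, m0000..m1439")
        if df.duplicated(subset=["participant_id", "day"]).any():
            raise CohortError("duplicate (participant_id, day) row in wide CSV")
        bad_day = ~df["day"].between(1, DAYS_PER_WEEK)
        if bad_day.any():
            raise CohortError(f"row {int(df.index[bad_day][0]) + 2}: day outside 1-7")
        traces = []
        for pid, grp in df.groupby("participant_id", sort=True):
            mets = np.full(WEEK_MINUTES, np.nan)
            for _, row in grp.iterrows():
                d = int(row["day"]) - 1
                vals = row[mcols].to_numpy(float)
                obsvals = vals[~np.isnan(vals)]
                if obsvals.size and obsvals.min() < 0:
                    raise CohortError(f"participant {pid!r} day {d + 1}: negative METs")
                mets[d * MINUTES_PER_DAY:(d + 1) * MINUTES_PER_DAY] = vals
            traces.append(ParticipantTrace(pid, mets))
    else:
        raise CohortError(f"unknown format {format!r}")
    return CohortDataset(traces, covariates)


def write_cohort(cohort: CohortDataset, path, format: str = "long_csv") -> None:
    """Write observed minutes to CSV (missing minutes are simply omitted)."""
    if format != "long_csv":
        raise CohortError("only long_csv writing is supported")
    frames = []
    for t in cohort.sorted_traces():
        obs = ~t.missing_mask
        frame = pd.DataFrame(
            {
                "participant_id": t.participant_id,
                "day": t.day_index[obs] + 1,
                "minute": t.minute_of_day[obs],
                "mets": t.mets[obs],
            }
        )
        if t.steps is not None:
            frame["steps"] = t.steps[obs]
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def wear_minutes_per_day(trace: ParticipantTrace) -> np.ndarray:
    """Count of recorded (non-missing) minutes in each of the 7 days."""
    return (~np.isnan(trace.days)).sum(axis=1)


def filter_valid_participants(
    cohort: CohortDataset,
    min_hours_per_day: float = 8.0,
    required_days: int = DAYS_PER_WEEK,
) -> tuple[CohortDataset, pd.DataFrame]:
    """Keep participants with >= ``required_days`` days of sufficient wear.

    A day is sufficient when it has at least ``min_hours_per_day * 60``
    recorded minutes (boundary inclusive). With the defaults this is the
    trial rule: all 7 days at >= 8 h of wear. Returns the surviving cohort and
    an exclusion report (participant_id, reason, first_failing_day; day 1-based).
    """
    min_minutes = min_hours_per_day * 60
    kept, excluded = [], []
    for t in cohort.traces:
        wear = wear_minutes_per_day(t)
        ok = wear >= min_minutes
        if ok.sum() >= required_days:
            kept.append(t)
        else:
            first_fail = int(np.argmin(ok)) + 1  # first False day, 1-based
            excluded.append(
                {
                    "participant_id": t.participant_id,
                    "reason": f"only {int(ok.sum())} days with >= {min_minutes:.0f} wear minutes",
                    "first_failing_day": first_fail,
                }
            )
    if not kept:
        raise CohortError(
            "no participants survive the wear filter; review min_hours_per_day/required_days"
        )
    report = pd.DataFrame(excluded, columns=["participant_id", "reason", "first_failing_day"])
    surviving_ids = {t.participant_id for t in kept}
    covs = cohort.covariates.loc[cohort.covariates.index.isin(surviving_ids) | ~cohort.covariates.index.isin(cohort.participant_ids)]
    return CohortDataset(kept, covs), report


def impute_missing(trace: ParticipantTrace, fill_value: float = 1.0) -> ParticipantTrace:
    """Replace missing minutes with ``fill_value`` METs.

    The default 1.0 is the MET reading of a stationary individual, the natural
    stand-in for overnight non-wear. Observed values are untouched.
    """
    mets = trace.mets.copy()
    mets[np.isnan(mets)] = fill_value
    return replace(trace, mets=mets)
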