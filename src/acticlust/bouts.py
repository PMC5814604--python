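"""Weekly MVPA bout totals and daily steps.

Three bout criteria are reported, mirroring how trial accelerometer software
summarizes moderate-to-vigorous activity:

* 1-minute criterion — every MVPA minute counts.
* 5-minute criterion — only minutes inside runs of >= 5 consecutive MVPA
  minutes count.
* 10-minute criterion with interruption allowance — gaps of at most 2
  consecutive sub-threshold minutes lying strictly between MVPA minutes are
  bridged; a bout is a maximal bridged segment spanning >= 10 minutes, and
  only its MVPA minutes (not the bridged gap minutes) are counted.

Bouts never span midnight: the device resets its day buffer there, so runs are
evaluated within each 1440-minute day. Note the 10-minute total is not
mathematically bounded by the 5-minute total under this definition (e.g. a
4-minute run, a 2-minute gap and a 7-minute run form one 13-minute bout with
11 MVPA minutes, while the 5-minute criterion counts only 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_cohort import MINUTES_PER_DAY, CohortDataset, ParticipantTrace
from .features import MVPA_THRESHOLD_METS, MvpaBinaryTrace, binarize_mvpa


@dataclass
class BoutSummary:
    """Per-participant weekly MVPA minutes under the three criteria."""

    participant_id: str
    weekly_mvpa_1min: int
    weekly_mvpa_5min: int
    weekly_mvpa_10min: int
    mean_daily_steps: float | None = None  # None when no steps channel

    def __post_init__(self) -> None:
        for v in (self.weekly_mvpa_1min, self.weekly_mvpa_5min, self.weekly_mvpa_10min):
            if not 0 <= v <= 7 * MINUTES_PER_DAY:
                raise ValueError("weekly totals must lie in [0, 10080]")
        if self.weekly_mvpa_5min > self.weekly_mvpa_1min:
            raise ValueError("5-min total cannot exceed 1-min total")
        if self.weekly_mvpa_10min > self.weekly_mvpa_1min:
            raise ValueError("10-min total cannot exceed 1-min total")


def _as_bits(binary) -> np.ndarray:
    if isinstance(binary, MvpaBinaryTrace):
        return binary.bits
    bits = np.asarray(binary, dtype=np.uint8)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("bits must be 0/1")
    return bits


def _runs(bits: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (values, starts, lengths)."""
    n = len(bits)
    if n == 0:
        return np.array([], np.uint8), np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    return bits[starts], starts, lengths


def _day_slices(bits: np.ndarray, day_length: int | None):
    day_length = day_length or MINUTES_PER_DAY
    for s in range(0, len(bits), day_length):
        yield bits[s:s + day_length]


def mvpa_minutes_1min(binary, day_length: int | None = None) -> int:
    """Total MVPA minutes over the week (every active minute counts)."""
    return int(_as_bits(binary).sum())


def mvpa_minutes_5min(
    binary, min_run: int = 5, day_length: int | None = None
) -> int:
    """MVPA minutes lying in runs of >= ``min_run`` consecutive active minutes."""
    total = 0
    for day in _day_slices(_as_bits(binary), day_length):
        vals, _, lens = _runs(day)
        total += int(lens[(vals == 1) & (lens >= min_run)].sum())
    return total


def mvpa_minutes_10min(
    binary,
    max_gap_run: int = 2,
    min_span: int = 10,
    day_length: int | None = None,
) -> int:
    """MVPA minutes in >= ``min_span``-minute bouts allowing short interruptions.

    Within each day, every maximal run of <= ``max_gap_run`` inactive minutes
    that sits strictly between active minutes is bridged; each maximal bridged
    segment whose first-to-last span is >= ``min_span`` is a bout, and the
    bout contributes its active minutes only.
    """
    total = 0
    for day in _day_slices(_as_bits(binary), day_length):
        vals, starts, lens = _runs(day)
        k = len(vals)
        i = 0
        while i < k:
            if vals[i] == 0:
                i += 1
                continue
            # grow a bridged segment of 1-runs linked by small interior gaps
            ones = int(lens[i])
            first = int(starts[i])
            last = int(starts[i] + lens[i] - 1)
            j = i + 1
            while j + 1 < k and vals[j] == 0 and lens[j] <= max_gap_run and vals[j + 1] == 1:
                ones += int(lens[j + 1])
                last = int(starts[j + 1] + lens[j + 1] - 1)
                j += 2
            if last - first + 1 >= min_span:
                total += ones
            i = j
    return total


def sliding_window_mvpa_minutes(
    binary,
    window: int = 10,
    min_active: int = 8,
    day_length: int | None = None,
) -> int:
    """Alternative bout reading: active minutes covered by any ``window``-minute
    window containing >= ``min_active`` active minutes (within a day)."""
    total = 0
    for day in _day_slices(_as_bits(binary), day_length):
        n = len(day)
        if n < window:
            continue
        csum = np.concatenate(([0], np.cumsum(day)))
        counts = csum[window:] - csum[:-window]  # active minutes per window start
        covered = np.zeros(n, dtype=bool)
        for s in np.flatnonzero(counts >= min_active):
            covered[s:s + window] = True
        total += int(day[covered].sum())
    return total


def mean_daily_steps(trace: ParticipantTrace) -> float | None:
    """Mean steps per day over the 7-day week; None if no steps channel.

    The denominator is fixed at 7: every retained participant has 7 valid
    wear days, and unworn minutes genuinely contribute zero steps.
    """
    if trace.steps is None:
        return None
    return float(np.nansum(trace.steps) / 7.0)


def bout_summary(
    trace: ParticipantTrace, threshold: float = MVPA_THRESHOLD_METS
) -> BoutSummary:
    binary = binarize_mvpa(trace, threshold)
    return BoutSummary(
        participant_id=trace.participant_id,
        weekly_mvpa_1min=mvpa_minutes_1min(binary),
        weekly_mvpa_5min=mvpa_minutes_5min(binary),
        weekly_mvpa_10min=mvpa_minutes_10min(binary),
        mean_daily_steps=mean_daily_steps(trace),
    )


def cohort_bout_summaries(
    cohort: CohortDataset, threshold: float = MVPA_THRESHOLD_METS
) -> pd.DataFrame:
    """BoutSummary for every participant, as a DataFrame sorted by id."""
    rows = [bout_summary(t, threshold) for t in cohort.sorted_traces()]
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "weekly_mvpa_1min": [r.weekly_mvpa_1min for r in rows],
            "weekly_mvpa_5min": [r.weekly_mvpa_5min for r in rows],
            "weekly_mvpa_10min": [r.weekly_mvpa_10min for r in rows],
            "mean_daily_steps": [
                np.nan if r.mean_daily_steps is None else r.mean_daily_steps for r in rows
            ],
        }
    )
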