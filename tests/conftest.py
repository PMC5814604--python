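"""Shared fixtures: small hand-built traces and cohorts, built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acticlust import (
    MINUTES_PER_DAY,
    WEEK_MINUTES,
    CohortDataset,
    ParticipantTrace,
)


def make_trace(
    pid: str = "P1",
    fill: float = 1.0,
    missing=None,
    values: dict | None = None,
    steps=None,
) -> ParticipantTrace:
    """A week-long trace: constant ``fill``, ``values`` at given indices,
    ``missing`` indices or slices set to NaN."""
    mets = np.full(WEEK_MINUTES, float(fill))
    if values:
        for idx, v in values.items():
            mets[idx] = v
    if missing is not None:
        for m in np.atleast_1d(missing) if not isinstance(missing, slice) else [missing]:
            mets[m] = np.nan
    return ParticipantTrace(pid, mets, steps)


def make_cohort(traces, covariates: pd.DataFrame | None = None) -> CohortDataset:
    return CohortDataset(list(traces), covariates)


def trace_with_day_window(pid: str, wake: int = 420, bed: int = 1380, fill: float = 1.0):
    """Trace observed only between wake and bed each day (overnight missing)."""
    mets = np.full(WEEK_MINUTES, np.nan)
    for d in range(7):
        mets[d * MINUTES_PER_DAY + wake:d * MINUTES_PER_DAY + bed] = fill
    return ParticipantTrace(pid, mets)


@pytest.fixture
def full_trace():
    return make_trace("P1")


@pytest.fixture
def small_cohort():
    """Three fully observed participants with distinct activity."""
    t1 = make_trace("A", values={600: 5.0, 601: 5.0})
    t2 = make_trace("B", values={900: 4.0})
    t3 = make_trace("C")
    return make_cohort([t1, t2, t3])
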