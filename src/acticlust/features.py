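"""Feature constructions for clustering minute-level activity.

Two representations are built:

* **raw** — each participant's week as a 10,080-dimensional vector of
  minute-level METs, with missing (non-wear) minutes imputed to 1.0, the MET
  level of a stationary person. Day and night are both kept: removing night
  minutes would discard real activity that happens at unusual hours.

* **normalized_mvpa** — each minute is binarized at the MVPA threshold
  (>= 3 METs), the seven days are averaged minute-of-day-wise into a
  1440-length MVPA-frequency profile for a "typical day", and the profile is
  scaled to unit Euclidean norm. The normalization removes overall activity
  volume so clustering responds to *when* in the day MVPA happens, not to how
  much of it there is.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .io_cohort import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    WEEK_MINUTES,
    CohortDataset,
    ParticipantTrace,
    filter_valid_participants,
    impute_missing,
)

MVPA_THRESHOLD_METS = 3.0

RAW = "raw"
NORMALIZED_MVPA = "normalized_mvpa"


@dataclass
class FeatureMatrix:
    """n_participants x p feature matrix with provenance tag.

    ``kind`` is ``"raw"`` (p = 10,080) or ``"normalized_mvpa"`` (p = 1440);
    ``participant_ids`` aligns with the rows.
    """

    values: np.ndarray
    kind: str
    participant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.participant_ids):
            raise ValueError("row count does not match participant_ids")
        if self.kind == RAW:
            if p != WEEK_MINUTES:
                raise ValueError(f"raw features must have p={WEEK_MINUTES}, got {p}")
            if np.isnan(self.values).any() or self.values.min() < 0:
                raise ValueError("raw features must be imputed and >= 0")
        elif self.kind == NORMALIZED_MVPA:
            if p != MINUTES_PER_DAY:
                raise ValueError(f"normalized features must have p={MINUTES_PER_DAY}, got {p}")
            if self.values.min() < 0:
                raise ValueError("normalized features must be >= 0")
            norms = np.linalg.norm(self.values, axis=1)
            nonzero = norms > 0
            if nonzero.any() and np.abs(norms[nonzero] - 1.0).max() > 1e-9:
                raise ValueError("nonzero normalized rows must have unit Euclidean norm")
        else:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class MvpaBinaryTrace:
    """Per-minute MVPA indicator (1 iff >= threshold METs) over the week."""

    participant_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (WEEK_MINUTES,):
            raise ValueError(f"bits must have length {WEEK_MINUTES}")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")


def _check_filtered(cohort: CohortDataset) -> None:
    _, report = filter_valid_participants(cohort)
    if len(report):
        bad = report["participant_id"].tolist()
        raise ValueError(f"cohort contains wear-invalid participants: {bad}; filter first")


def raw_feature_matrix(cohort: CohortDataset) -> FeatureMatrix:
    """Stack each participant's imputed 10,080-minute MET vector.

    Rows are ordered by sorted participant id for reproducibility. The cohort
    must already satisfy the wear-validity filter.
    """
    _check_filtered(cohort)
    traces = cohort.sorted_traces()
    values = np.stack([impute_missing(t).mets for t in traces])
    return FeatureMatrix(values, RAW, [t.participant_id for t in traces])


def binarize_mvpa(
    trace: ParticipantTrace, threshold: float = MVPA_THRESHOLD_METS
) -> MvpaBinaryTrace:
    """1 iff the minute's observed METs >= threshold; missing minutes are 0.

    Treating missing as 0 coincides with imputing 1.0 then thresholding,
    since 1.0 < 3.0.
    """
    with np.errstate(invalid="ignore"):
        bits = np.where(np.isnan(trace.mets), 0, trace.mets >= threshold)
    return MvpaBinaryTrace(trace.participant_id, bits.astype(np.uint8))


def daily_average_profile(binary: MvpaBinaryTrace) -> np.ndarray:
    """Average the 7 days minute-of-day-wise into an MVPA frequency profile.

    Entry m is the fraction of the 7 days on which minute m was MVPA, so
    values lie in {0, 1/7, ..., 1}.
    """
    return binary.bits.reshape(DAYS_PER_WEEK, MINUTES_PER_DAY).mean(axis=0)


def unit_normalize(profile: np.ndarray) -> np.ndarray | None:
    """Scale a nonnegative profile to unit Euclidean norm.

    Returns ``None`` when the profile is identically zero (a participant with
    no MVPA minutes at all) — a flagged degenerate outcome, not an error.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.min() < 0:
        raise ValueError("profile entries must be >= 0")
    norm = np.linalg.norm(profile)
    if norm == 0:
        return None
    return profile / norm


def normalized_feature_matrix(
    cohort: CohortDataset,
    threshold: float = MVPA_THRESHOLD_METS,
    degenerate_policy: str = "exclude",
) -> tuple[FeatureMatrix, list[str]]:
    """Binarize -> day-average -> unit-normalize each participant.

    ``degenerate_policy`` controls participants with zero MVPA minutes:
    ``"exclude"`` drops their rows, ``"keep_zero"`` keeps an all-zero row.
    Returns the matrix plus the list of degenerate participant ids.
    """
    if degenerate_policy not in ("exclude", "keep_zero"):
        raise ValueError(f"unknown degenerate_policy {degenerate_policy!r}")
    _check_filtered(cohort)
    rows, ids, degenerate = [], [], []
    for t in cohort.sorted_traces():
        vec = unit_normalize(daily_average_profile(binarize_mvpa(t, threshold)))
        if vec is None:
            degenerate.append(t.participant_id)
            if degenerate_policy == "keep_zero":
                rows.append(np.zeros(MINUTES_PER_DAY))
                ids.append(t.participant_id)
        else:
            rows.append(vec)
            ids.append(t.participant_id)
    if not rows:
        raise ValueError("every participant has zero MVPA minutes; nothing to cluster")
    return FeatureMatrix(np.stack(rows), NORMALIZED_MVPA, ids), degenerate


def write_feature_matrix(features: FeatureMatrix, csv_path, meta_path=None, **meta) -> None:
    """Write features as CSV (participant_id + p columns) with a JSON sidecar."""
    import pandas as pd

    df = pd.DataFrame(features.values, columns=[f"f{j}" for j in range(features.p)])
    df.insert(0, "participant_id", features.participant_ids)
    df.to_csv(csv_path, index=False)
    if meta_path is not None:
        payload = {"kind": features.kind, "n": features.n, "p": features.p, **meta}
        with open(meta_path, "w") as fh:
            json.dump(payload, fh, indent=2)
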