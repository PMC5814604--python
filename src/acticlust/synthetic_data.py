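"""Synthetic minute-level accelerometry cohorts with planted activity archetypes.

Each participant belongs to a temporal *archetype* — a recipe of Gaussian
activity bumps on the 1440-minute day (peak time, width, peak METs) over a
sedentary baseline near 1.2 METs. Per day, bump peak times are jittered,
per-minute Gaussian noise is added, METs are truncated at zero, and minutes
outside the wake-bed window are stored as missing (the only non-wear the
generator models is overnight, matching devices worn from rising to bed).
Steps are drawn per minute as Poisson counts proportional to METs above 1.

The generator exists so the full pipeline — validity filter, both feature
constructions, clustering, bouts, curves, comparison — can be exercised and
its cluster-recovery behaviour measured without any participant data. What it
does not emulate: daytime non-wear, device artefacts, autocorrelated
intensity within bouts, or weekday/weekend structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_cohort import (
    DAYS_PER_WEEK,
    MINUTES_PER_DAY,
    WEEK_MINUTES,
    CohortDataset,
    ParticipantTrace,
)


@dataclass
class ArchetypeSpec:
    """One temporal activity archetype.

    ``activity_windows`` is a list of (peak_minute, width_minutes, peak_mets)
    bumps; ``width`` is the Gaussian SD (half-width for square windows).
    ``baseline_mean``/``baseline_sd`` give the between-person distribution of
    the personal sedentary level; ``mvpa_prob_scale`` multiplies every bump
    amplitude; ``day_jitter_sd`` jitters each bump's peak time independently
    per day (large values scatter a bump to a different time every day).
    """

    name: str
    activity_windows: list = field(default_factory=list)
    baseline_mean: float = 1.2
    baseline_sd: float = 0.08
    mvpa_prob_scale: float = 1.0
    day_jitter_sd: float = 20.0

    def __post_init__(self) -> None:
        for peak, width, peak_mets in self.activity_windows:
            if not 0 <= peak < MINUTES_PER_DAY:
                raise ValueError(f"{self.name}: peak minute {peak} outside [0, 1440)")
            if width <= 0:
                raise ValueError(f"{self.name}: window width must be > 0")
            if peak_mets < self.baseline_mean:
                raise ValueError(f"{self.name}: peak METs below baseline")


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generation parameters (all randomness flows from ``seed``)."""

    n_participants: int
    archetypes: list
    proportions: list
    wake_minute: int = 420          # 07:00
    bed_minute: int = 1380          # 23:00 -> 960 observed minutes/day
    noise_sd: float = 0.30          # per-minute MET noise
    steps_rate: float = 11.0        # expected steps per minute per MET above 1
    window_shape: str = "gaussian"  # or "square"
    covariate_shifts: dict = field(default_factory=dict)  # var -> {archetype: shift}
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if len(self.archetypes) != len(self.proportions):
            raise ValueError("archetypes and proportions must align")
        props = np.asarray(self.proportions, dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")
        if not 0 <= self.wake_minute < self.bed_minute <= MINUTES_PER_DAY:
            raise ValueError("need 0 <= wake_minute < bed_minute <= 1440")
        if self.window_shape not in ("gaussian", "square"):
            raise ValueError(f"unknown window_shape {self.window_shape!r}")


def _allocate_counts(proportions, n: int) -> np.ndarray:
    """Largest-remainder allocation so archetype counts are exact for the
    stated proportions (ties broken by archetype index)."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _day_mets(
    arch: ArchetypeSpec,
    baseline: float,
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
) -> np.ndarray:
    m = np.arange(MINUTES_PER_DAY, dtype=float)
    mu = np.full(MINUTES_PER_DAY, baseline)
    for peak, width, peak_mets in arch.activity_windows:
        amp = (peak_mets - arch.baseline_mean) * arch.mvpa_prob_scale
        jittered = peak + rng.normal(0.0, arch.day_jitter_sd)
        jittered = float(np.clip(jittered, cfg.wake_minute + 30, cfg.bed_minute - 30))
        if cfg.window_shape == "gaussian":
            mu += amp * np.exp(-0.5 * ((m - jittered) / width) ** 2)
        else:
            mu += np.where(np.abs(m - jittered) <= width, amp, 0.0)
    mets = mu + rng.normal(0.0, cfg.noise_sd, MINUTES_PER_DAY)
    return np.maximum(mets, 0.0)


_NUMERIC_COVARIATES = {
    # name: (mean, sd, low, high) before archetype shifts
    "age": (52.4, 11.2, 25.0, 69.0),
    "bmi": (29.2, 6.0, 18.5, 43.0),
    "cesd": (8.5, 7.5, 0.0, 60.0),
}
_COLLEGE_PROB = 0.73  # default probability of college/graduate education


def _covariates(
    ids: list, arch_names: list, rng: np.random.Generator, shifts: dict
) -> pd.DataFrame:
    n = len(ids)
    cov = {"archetype": arch_names}
    for var, (mean, sd, lo, hi) in _NUMERIC_COVARIATES.items():
        shift = np.array([shifts.get(var, {}).get(a, 0.0) for a in arch_names])
        cov[var] = np.clip(rng.normal(mean + shift, sd), lo, hi).round(1)
    p_college = np.clip(
        _COLLEGE_PROB
        + np.array([shifts.get("education_college_prob", {}).get(a, 0.0) for a in arch_names]),
        0.0,
        1.0,
    )
    cov["education"] = np.where(
        rng.random(n) < p_college, "college_graduate", "high_school_some_college"
    )
    return pd.DataFrame(cov, index=pd.Index(ids, name="participant_id"))


def generate_cohort(
    config: SyntheticCohortConfig, seed: int | None = None
) -> tuple[CohortDataset, pd.Series]:
    """Simulate a cohort; returns (cohort, planted archetype labels by id).

    Archetype membership uses an exact largest-remainder allocation of the
    configured proportions (then a seeded shuffle), so the planted group sizes
    are deterministic. Bit-identical output for identical config and seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_participants
    counts = _allocate_counts(config.proportions, n)
    assignment = np.repeat(np.arange(len(config.archetypes)), counts)
    rng.shuffle(assignment)
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
    wear[config.wake_minute:config.bed_minute] = True
    wear_week = np.tile(wear, DAYS_PER_WEEK)

    traces = []
    for pid, a_idx in zip(ids, assignment):
        arch = config.archetypes[a_idx]
        baseline = max(0.5, rng.normal(arch.baseline_mean, arch.baseline_sd))
        week = np.concatenate(
            [_day_mets(arch, baseline, rng, config) for _ in range(DAYS_PER_WEEK)]
        )
        steps = rng.poisson(config.steps_rate * np.maximum(week - 1.0, 0.0)).astype(float)
        week[~wear_week] = np.nan
        steps[~wear_week] = np.nan
        traces.append(ParticipantTrace(pid, week, steps))

    arch_names = [config.archetypes[a].name for a in assignment]
    covariates = _covariates(ids, arch_names, rng, config.covariate_shifts)
    labels = pd.Series(assignment, index=pd.Index(ids, name="participant_id"), name="archetype")
    return CohortDataset(traces, covariates), labels


def default_trial_config(seed: int | None = None) -> SyntheticCohortConfig:
    """The reference cohort: 215 participants, three diel archetypes.

    Group sizes follow the 65/48/102 split of the cohort this generator
    emulates: an afternoon-engaged archetype (peak near 15:00), a
    morning-engaged archetype (peak near 09:00), and an unengaged archetype
    whose modest activity is scattered to a different time every day (large
    peak-time jitter), giving a flat average profile. Bump amplitudes are
    calibrated so mean weekly 1-minute-criterion MVPA per archetype lands
    near 372 / 401 / 206 minutes respectively; the unengaged archetype also
    gets a higher mean depression-score shift so group comparisons have
    signal to detect.
    """
    afternoon = ArchetypeSpec(
        name="afternoon",
        activity_windows=[(870, 20.0, 3.80), (950, 13.0, 3.45)],
        day_jitter_sd=25.0,
    )
    morning = ArchetypeSpec(
        name="morning",
        activity_windows=[(530, 21.0, 3.85), (610, 14.0, 3.50)],
        day_jitter_sd=25.0,
    )
    unengaged = ArchetypeSpec(
        name="unengaged",
        activity_windows=[(700, 13.0, 3.45), (950, 11.0, 3.40)],
        day_jitter_sd=220.0,
    )
    return SyntheticCohortConfig(
        n_participants=215,
        archetypes=[afternoon, morning, unengaged],
        proportions=[65 / 215, 48 / 215, 102 / 215],
        covariate_shifts={
            "cesd": {"unengaged": 4.0},
            "education_college_prob": {"unengaged": 0.10, "morning": -0.10},
        },
        seed=seed,
    )


def mvpa_trial_config(seed: int | None = None) -> SyntheticCohortConfig:
    """A cohort whose archetypes differ in *when* MVPA happens, not how much.

    Three MVPA-timing archetypes at the 46/61/108 split: morning-and-evening
    (two bumps), noon peak, and evening peak. Intended for exercising the
    normalized (unit-norm MVPA profile) feature pathway, where clusters are
    separated by time-of-day structure alone.
    """
    morning_evening = ArchetypeSpec(
        name="morning_and_evening",
        activity_windows=[(460, 22.0, 4.0), (1110, 22.0, 3.9)],
        day_jitter_sd=25.0,
    )
    noon = ArchetypeSpec(
        name="noon_peak",
        activity_windows=[(730, 30.0, 4.0)],
        day_jitter_sd=25.0,
    )
    evening = ArchetypeSpec(
        name="evening_peak",
        activity_windows=[(1080, 30.0, 4.0)],
        day_jitter_sd=25.0,
    )
    return SyntheticCohortConfig(
        n_participants=215,
        archetypes=[morning_evening, noon, evening],
        proportions=[46 / 215, 61 / 215, 108 / 215],
        covariate_shifts={"bmi": {"evening_peak": 1.5}},
        seed=seed,
    )


def config_to_dict(config: SyntheticCohortConfig) -> dict:
    """JSON/YAML-serializable form of a config."""
    return asdict(config)  # recurses into ArchetypeSpec entries


def config_from_dict(d: dict) -> SyntheticCohortConfig:
    d = dict(d)
    d["archetypes"] = [
        ArchetypeSpec(**{**a, "activity_windows": [tuple(w) for w in a["activity_windows"]]})
        for a in d["archetypes"]
    ]
    return SyntheticCohortConfig(**d)
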