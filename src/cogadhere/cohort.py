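"""Synthetic gameplay-log cohort generator.

Emulates daily interaction logs from a tablet-based cognitive training study:
each participant is prescribed 5 play days out of every 7 at 45 minutes a day
over a 60-day observation period, and the cohort drifts toward non-adherence
in the second half (days 31-60). Four time-dependent variables are recorded
per participant-day: play duration (seconds), number of sessions, maximum
task level reached, and number of tasks performed.

The generative model is deliberately minimal:

* each participant draws an adherence propensity ``p ~ Beta(a, b)``;
* a day is a play day with probability ``p * weekday_mult * decay`` where
  ``weekday_mult`` is 1 on the participant's preferred weekdays and
  ``off_day_multiplier`` otherwise, and ``decay = decay_rate**(day - 30)``
  for days after day 30;
* play duration on play days is ``max(0, Normal(45*60, sd^2))`` seconds;
  with small probability a non-play day becomes an "accidental open"
  (< 10 minutes, the adherence threshold's motivating case);
* session and task counts scale with play time; the maximum level reached
  ramps up noisily, never decreases, and plateaus at a per-cohort skill
  ceiling the way adaptive-difficulty games cap progression.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "DailyRecord",
    "ParticipantLog",
    "CohortError",
    "CohortParseError",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: Column order of the on-disk cohort CSV.
COHORT_COLUMNS = (
    "participant_id",
    "day",
    "play_seconds",
    "n_sessions",
    "max_level",
    "n_tasks",
)


class CohortError(ValueError):
    """Invalid cohort configuration or simulation parameters."""


class CohortParseError(ValueError):
    """A cohort file violates the log-format contract."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults encode the study prescription: 118 participants observed for 60
    days, asked to play 5 of every 7 days for 45 minutes, with per-participant
    adherence heterogeneity (Beta-distributed propensity) and a multiplicative
    per-day decline in propensity after day 30.
    """

    n_participants: int = 118
    n_days: int = 60
    adherence_base_rate_params: tuple[float, float] = (5.0, 2.0)
    weekly_period: int = 7
    preferred_days_per_week: int = 5
    target_play_minutes: float = 45.0
    play_noise_sd_minutes: float = 8.0
    decay_rate: float = 0.97
    off_day_multiplier: float = 0.1
    accidental_open_prob: float = 0.03
    max_level_cap: int = 12
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise CohortError("n_participants must be positive")
        if self.n_days < 4:  # window estimation needs at least 4 training days
            raise CohortError("n_days must be at least 4")
        a, b = self.adherence_base_rate_params
        if a <= 0 or b <= 0:
            raise CohortError("adherence_base_rate_params must be strictly positive")
        if self.weekly_period < 1:
            raise CohortError("weekly_period must be positive")
        if not 0 <= self.preferred_days_per_week <= self.weekly_period:
            raise CohortError(
                "preferred_days_per_week must lie in [0, weekly_period]"
            )
        if self.target_play_minutes <= 0:
            raise CohortError("target_play_minutes must be positive")
        if self.play_noise_sd_minutes < 0:
            raise CohortError("play_noise_sd_minutes must be non-negative")
        if not 0.0 <= self.decay_rate <= 1.0:
            raise CohortError("decay_rate must lie in [0, 1]")
        if not 0.0 <= self.off_day_multiplier <= 1.0:
            raise CohortError("off_day_multiplier must lie in [0, 1]")
        if not 0.0 <= self.accidental_open_prob <= 1.0:
            raise CohortError("accidental_open_prob must lie in [0, 1]")
        if self.max_level_cap < 1:
            raise CohortError("max_level_cap must be positive")


@dataclass(frozen=True)
class DailyRecord:
    """One participant-day of gameplay interaction."""

    day_index: int
    play_seconds: float
    n_sessions: int
    max_level: int
    n_tasks: int

    def validate(self) -> None:
        if self.play_seconds < 0:
            raise CohortError(f"day {self.day_index}: negative play_seconds")
        if min(self.n_sessions, self.max_level, self.n_tasks) < 0:
            raise CohortError(f"day {self.day_index}: negative count field")
        if self.play_seconds == 0 and (self.n_sessions != 0 or self.n_tasks != 0):
            raise CohortError(
                f"day {self.day_index}: zero play time with nonzero activity"
            )


@dataclass(frozen=True)
class ParticipantLog:
    """A complete, gap-free daily log for one participant.

    Non-play days are explicit zero rows so downstream sliding windows never
    contain gaps; ``records`` holds exactly one entry per calendar day with
    consecutive 1-based ``day_index``.
    """

    participant_id: str
    records: tuple[DailyRecord, ...]

    def validate(self) -> None:
        if not self.records:
            raise CohortError(f"{self.participant_id}: empty log")
        prev_level = 0
        for i, rec in enumerate(self.records, start=1):
            if rec.day_index != i:
                raise CohortError(
                    f"{self.participant_id}: day indices not consecutive "
                    f"(expected {i}, got {rec.day_index})"
                )
            rec.validate()
            if rec.max_level < prev_level:
                raise CohortError(
                    f"{self.participant_id}: max_level decreased on day {i}"
                )
            prev_level = rec.max_level

    @property
    def n_days(self) -> int:
        return len(self.records)

    def feature_matrix(self) -> np.ndarray:
        """(n_days, 4) float array in the fixed predictor order
        (play_seconds, n_sessions, max_level, n_tasks)."""
        return np.array(
            [
                (r.play_seconds, r.n_sessions, r.max_level, r.n_tasks)
                for r in self.records
            ],
            dtype=float,
        )

    def play_series(self) -> np.ndarray:
        return np.array([r.play_seconds for r in self.records], dtype=float)


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant draw from the cohort-level configuration."""

    propensity: float
    preferred_weekdays: frozenset[int]
    config: CohortConfig


def draw_participant_params(
    config: CohortConfig, rng: np.random.Generator
) -> ParticipantParams:
    a, b = config.adherence_base_rate_params
    propensity = float(rng.beta(a, b))
    # contiguous block at a random phase: participants play consecutive
    # "weekdays" and rest on the remaining days, as the 5-of-7 prescription
    # is followed in practice
    start = int(rng.integers(config.weekly_period))
    days = [
        (start + i) % config.weekly_period
        for i in range(config.preferred_days_per_week)
    ]
    return ParticipantParams(
        propensity=propensity,
        preferred_weekdays=frozenset(days),
        config=config,
    )


def simulate_participant(
    params: ParticipantParams,
    n_days: int,
    rng: np.random.Generator,
    participant_id: str = "P000",
) -> ParticipantLog:
    """Simulate one participant's daily log.

    Play days cluster on the participant's preferred weekdays; play time on
    play days is drawn around the 45-minute prescription; after day 30 the
    adherence propensity is multiplied by ``decay_rate`` each day, producing
    the late-phase drift toward non-adherence.
    """
    if n_days < 2:
        raise CohortError("n_days must be at least 2")
    cfg = params.config
    target_seconds = cfg.target_play_minutes * 60.0
    noise_sd = cfg.play_noise_sd_minutes * 60.0

    records = []
    level = 0
    for day in range(1, n_days + 1):
        weekday = (day - 1) % cfg.weekly_period
        mult = 1.0 if weekday in params.preferred_weekdays else cfg.off_day_multiplier
        decay = cfg.decay_rate ** max(0, day - 30)
        p_play = min(1.0, params.propensity * mult * decay)
        plays = rng.random() < p_play
        if plays:
            play_seconds = max(0.0, float(rng.normal(target_seconds, noise_sd)))
        elif rng.random() < cfg.accidental_open_prob:
            # opened the app and backed out: under the 10-minute threshold
            play_seconds = float(rng.uniform(20.0, 540.0))
        else:
            play_seconds = 0.0

        if play_seconds > 0:
            n_sessions = 1 + int(rng.poisson(play_seconds / 1800.0))
            n_tasks = int(rng.poisson(play_seconds / 300.0))
            # noisy learning-curve ramp: players plateau at a skill ceiling
            if level < cfg.max_level_cap:
                level += int(rng.random() < 0.5)
        else:
            n_sessions = 0
            n_tasks = 0
        records.append(
            DailyRecord(
                day_index=day,
                play_seconds=play_seconds,
                n_sessions=n_sessions,
                max_level=level,
                n_tasks=n_tasks,
            )
        )
    log = ParticipantLog(participant_id=participant_id, records=tuple(records))
    log.validate()
    return log


def simulate_cohort(config: CohortConfig) -> list[ParticipantLog]:
    """Simulate ``config.n_participants`` independent participant logs.

    Deterministic given ``config.seed``. With ``decay_rate < 1`` the expected
    number of non-adherent days over days 31-60 exceeds that over days 1-30.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    width = max(3, len(str(config.n_participants)))
    logs = []
    for i in range(config.n_participants):
        params = draw_participant_params(config, rng)
        logs.append(
            simulate_participant(
                params, config.n_days, rng, participant_id=f"P{i:0{width}d}"
            )
        )
    return logs


def cohort_frame(logs: Iterable[ParticipantLog]) -> pd.DataFrame:
    """Long-format DataFrame with one row per participant-day."""
    rows = [
        (log.participant_id, r.day_index, r.play_seconds, r.n_sessions,
         r.max_level, r.n_tasks)
        for log in logs
        for r in log.records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(
    logs: Iterable[ParticipantLog], destination: Union[str, Path, io.IOBase]
) -> None:
    """Write logs as a UTF-8 CSV with a header, one row per participant-day."""
    cohort_frame(logs).to_csv(destination, index=False)


def read_cohort(source: Union[str, Path, io.IOBase]) -> list[ParticipantLog]:
    """Read a cohort CSV back into validated :class:`ParticipantLog` objects.

    Raises :class:`CohortParseError` naming the offending participant/row for
    missing columns, gaps in day indices, or negative values; an empty file is
    an error, not an empty cohort.
    """
    try:
        # round_trip parsing keeps write -> read an exact identity on floats
        df = pd.read_csv(source, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError("cohort file is empty") from exc
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortParseError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise CohortParseError("cohort file has a header but no rows")

    logs = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        expected = np.arange(1, len(days) + 1)
        if not np.array_equal(days, expected):
            bad = int(days[np.argmax(days != expected)])
            raise CohortParseError(
                f"participant {pid}: day indices not consecutive near day {bad}"
            )
        records = []
        for row in grp.itertuples(index=False):
            if min(row.play_seconds, row.n_sessions, row.max_level, row.n_tasks) < 0:
                raise CohortParseError(
                    f"participant {pid} day {row.day}: negative value"
                )
            records.append(
                DailyRecord(
                    day_index=int(row.day),
                    play_seconds=float(row.play_seconds),
                    n_sessions=int(row.n_sessions),
                    max_level=int(row.max_level),
                    n_tasks=int(row.n_tasks),
                )
            )
        log = ParticipantLog(participant_id=str(pid), records=tuple(records))
        try:
            log.validate()
        except CohortError as exc:
            raise CohortParseError(str(exc)) from exc
        logs.append(log)
    return logs
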