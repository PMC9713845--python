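"""Adherence binarization, spectral window-size estimation, and sliding-window
supervised framing.

A participant-day is *adherent* when it carries at least 10 minutes of play
(600 s), the minimal adherence criterion that separates genuine training from
accidentally opening the app. Each participant's lookback length (window size)
is set to the period of the dominant spectral component of their training-phase
play-length series: de-mean, FFT, pick the non-constant frequency bin with
maximum amplitude, and convert it back to a time interval as round(T / k).
The 60-day log is then framed as supervised samples -- a (window_size x 4)
predictor matrix labelled by the next day's adherence class -- with days 1-30
providing training targets and days 31-60 test targets. Feature scaling is
fitted on training days only, so nothing from the test phase leaks backward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ParticipantLog

__all__ = [
    "LabelRule",
    "WindowSizeEstimate",
    "WindowSample",
    "SupervisedSplit",
    "ScalerStats",
    "WindowingError",
    "binarize",
    "estimate_window_size",
    "fit_scaler",
    "apply_scaler",
    "make_supervised",
    "TRAIN_DAYS",
]

#: Length of the training phase in days; test phase is the same length after it.
TRAIN_DAYS = 30

#: Fixed predictor order of every feature matrix in the pipeline.
FEATURE_NAMES = ("play_seconds", "n_sessions", "max_level", "n_tasks")


class WindowingError(ValueError):
    """Invalid input to binarization, window estimation, or framing."""


@dataclass(frozen=True)
class LabelRule:
    """Minimal adherence criterion: at least 10 minutes of play."""

    threshold_seconds: float = 600.0

    def __post_init__(self) -> None:
        if self.threshold_seconds <= 0:
            raise WindowingError("threshold_seconds must be positive")


def binarize(play_seconds: float, rule: LabelRule = LabelRule()) -> int:
    """1 if the day meets the minimal adherence criterion, else 0.

    The boundary counts as adherent ("at least 10 min").
    """
    if play_seconds < 0:
        raise WindowingError("play_seconds must be non-negative")
    return int(play_seconds >= rule.threshold_seconds)


@dataclass(frozen=True)
class WindowSizeEstimate:
    """Per-participant lookback length from the dominant spectral component.

    ``dominant_bin`` is the index of the maximum-amplitude non-constant
    frequency bin; ``window_size = round(T / dominant_bin)`` clamped to
    [2, w_max]. A flat (zero-variance) series has no cycle: ``is_fallback``
    is set and the configured fallback length is used instead.
    """

    participant_id: str
    window_size: int
    dominant_bin: int
    is_fallback: bool


def estimate_window_size(
    train_play_series: np.ndarray,
    w_max: int = 10,
    fallback: int = 3,
    participant_id: str = "",
) -> WindowSizeEstimate:
    """Estimate the dominant cycle length of a training-phase play series.

    Procedure: subtract the series mean; take the discrete Fourier transform;
    find the amplitude-maximal bin k in [1, floor(T/2)] (ties broken toward
    the smallest bin, i.e. the longest period); the window size is
    round(T / k) clamped to [2, w_max].
    """
    x = np.asarray(train_play_series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise WindowingError("need a 1-D series of at least 4 training days")
    if w_max < 2:
        raise WindowingError("w_max must be at least 2")
    if not 2 <= fallback <= w_max:
        raise WindowingError("fallback must lie in [2, w_max]")
    T = x.size
    centered = x - x.mean()
    if not np.any(np.abs(centered) > 1e-12 * max(1.0, np.abs(x).max())):
        return WindowSizeEstimate(participant_id, fallback, 0, True)
    amplitude = np.abs(np.fft.rfft(centered))
    k_max = T // 2
    # bin 0 is the (removed) mean; argmax over 1..floor(T/2), ties -> smallest k
    k_star = 1 + int(np.argmax(amplitude[1 : k_max + 1]))
    period = int(round(T / k_star))
    window = int(np.clip(period, 2, w_max))
    return WindowSizeEstimate(participant_id, window, k_star, False)


@dataclass(frozen=True)
class ScalerStats:
    """Per-feature min-max statistics fitted on training days only."""

    minimum: np.ndarray
    maximum: np.ndarray


def fit_scaler(train_days: np.ndarray) -> ScalerStats:
    """Fit per-feature min-max normalization on the training-day matrix."""
    m = np.asarray(train_days, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise WindowingError("train_days must be a non-empty 2-D matrix")
    return ScalerStats(minimum=m.min(axis=0), maximum=m.max(axis=0))


def apply_scaler(matrix: np.ndarray, stats: ScalerStats) -> np.ndarray:
    """Map each feature onto [0, 1] using training-phase extremes.

    Affine inside the training range; values beyond it (possible in the test
    phase, e.g. a cumulative level still rising after day 30) saturate at the
    range endpoints so the classifiers never see inputs outside the unit box
    their noise scales and weights were fitted for. Constant features map
    to 0. The map is monotone non-decreasing per feature.
    """
    m = np.asarray(matrix, dtype=float)
    span = stats.maximum - stats.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((m - stats.minimum) / safe, 0.0, 1.0)
    return np.where(span > 0, scaled, 0.0)


@dataclass(frozen=True)
class WindowSample:
    """One supervised sample: ``window_size`` days of the 4 normalized
    predictors and the next day's adherence label."""

    features: np.ndarray  # (window_size, 4)
    label: int
    target_day: int

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        if f.ndim != 2 or f.shape[1] != len(FEATURE_NAMES):
            raise WindowingError("features must be (window_size, 4)")
        if np.isnan(f).any():
            raise WindowingError("features contain missing values")
        if self.label not in (0, 1):
            raise WindowingError("label must be binary")


@dataclass(frozen=True)
class SupervisedSplit:
    """Sliding-window samples for both phases of one participant.

    Training samples target days w+1..30 (30 - w of them); test samples
    target every day 31..60 (30 of them), the first w windows reaching back
    into training days so the test phase stays a fixed 30 prediction points.
    """

    participant_id: str
    window_size: int
    train: tuple[WindowSample, ...]
    test: tuple[WindowSample, ...]
    scaler_stats: ScalerStats


def make_supervised(
    log: ParticipantLog,
    estimate: WindowSizeEstimate,
    rule: LabelRule = LabelRule(),
) -> SupervisedSplit:
    """Frame a 60-day log as sliding-window supervised samples (step 1).

    The scaler is fitted exclusively on days 1-30; both splits are normalized
    with those statistics. With window size w the training split has 30 - w
    samples (targets w+1..30) and the test split exactly 30 (targets 31..60).
    """
    w = estimate.window_size
    if w > TRAIN_DAYS:
        raise WindowingError(f"window_size {w} exceeds the {TRAIN_DAYS}-day phase")
    if not 2 <= w:
        raise WindowingError("window_size must be at least 2")
    if log.n_days < 2 * TRAIN_DAYS:
        raise WindowingError(
            f"log must cover {2 * TRAIN_DAYS} days, got {log.n_days}"
        )
    raw = log.feature_matrix()
    play = log.play_series()
    stats = fit_scaler(raw[:TRAIN_DAYS])
    norm = apply_scaler(raw, stats)

    def sample(target_day: int) -> WindowSample:
        # rows are 0-based: target day d uses days d-w .. d-1
        lo = target_day - 1 - w
        return WindowSample(
            features=norm[lo : target_day - 1],
            label=binarize(play[target_day - 1], rule),
            target_day=target_day,
        )

    train = tuple(sample(d) for d in range(w + 1, TRAIN_DAYS + 1))
    test = tuple(sample(d) for d in range(TRAIN_DAYS + 1, 2 * TRAIN_DAYS + 1))
    return SupervisedSplit(
        participant_id=log.participant_id,
        window_size=w,
        train=train,
        test=test,
        scaler_stats=stats,
    )
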