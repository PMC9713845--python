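"""Transform-based time-series augmentation for windowed training data.

Three label-preserving operators expand a participant's small training split:

* **jitter** -- add independent Gaussian noise N(0, sigma^2) to every time
  step of every feature (sigma = 0.01 by default);
* **scaling** -- multiply each feature column by a scalar drawn from
  N(1, sigma^2) (sigma = 0.1);
* **time warping** -- resample along a smooth, strictly increasing warp path
  built from a cubic spline through evenly spaced knots with Gaussian heights
  N(1, sigma^2) (sigma = 0.2).

Operators act on normalized features, where the default noise scales are
meaningful. Stacked variants (jitter + warp, scaling + warp) apply the
amplitude transform first, then the temporal one. ``augment_dataset`` appends
``folds`` synthetic copies of the training set, the study's 5-fold expansion
yielding six times the original sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .windowing import WindowSample

__all__ = [
    "AugmentationConfig",
    "AugmentationError",
    "TECHNIQUES",
    "jitter",
    "scale",
    "time_warp",
    "augment_dataset",
]

#: The six technique names of the comparison grid.
TECHNIQUES = (
    "none",
    "jitter",
    "scaling",
    "time_warp",
    "jitter_time_warp",
    "scaling_time_warp",
)

#: Lower clip on the warp speed curve; keeps the warp path strictly increasing
#: even when a sigma = 0.2 spline excursion dips negative.
_SPEED_FLOOR = 1e-3


class AugmentationError(ValueError):
    """Invalid augmentation configuration."""


@dataclass(frozen=True)
class AugmentationConfig:
    """Technique selector and hyperparameters of the augmentation operators."""

    technique: str = "none"
    sigma_jitter: float = 0.01
    sigma_scaling: float = 0.1
    sigma_warp: float = 0.2
    n_knots: int = 4
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise AugmentationError(
                f"unknown technique {self.technique!r}; expected one of {TECHNIQUES}"
            )
        if min(self.sigma_jitter, self.sigma_scaling, self.sigma_warp) < 0:
            raise AugmentationError("sigmas must be non-negative")
        if self.n_knots < 1:
            raise AugmentationError("n_knots must be at least 1")
        if self.folds < 0:
            raise AugmentationError("folds must be non-negative")


def jitter(sample: WindowSample, sigma: float, rng: np.random.Generator) -> WindowSample:
    """Add N(0, sigma^2) noise independently to every entry; label unchanged."""
    if sigma < 0:
        raise AugmentationError("sigma must be non-negative")
    noisy = sample.features + rng.normal(0.0, sigma, size=sample.features.shape)
    return replace(sample, features=noisy)


def scale(sample: WindowSample, sigma: float, rng: np.random.Generator) -> WindowSample:
    """Multiply each feature column by its own alpha ~ N(1, sigma^2)."""
    if sigma < 0:
        raise AugmentationError("sigma must be non-negative")
    alpha = rng.normal(1.0, sigma, size=(1, sample.features.shape[1]))
    return replace(sample, features=sample.features * alpha)


def _warp_path(length: int, sigma: float, n_knots: int, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing map of [0, length-1] onto itself.

    A cubic spline through n_knots + 2 evenly spaced knots with heights
    ~ N(1, sigma^2) gives a smooth speed curve (clipped at a small positive
    floor); its cumulative sum, rescaled to pin both endpoints, is the path.
    """
    knot_x = np.linspace(0.0, length - 1.0, n_knots + 2)
    knot_h = rng.normal(1.0, sigma, size=n_knots + 2)
    t = np.arange(length, dtype=float)
    speed = np.maximum(CubicSpline(knot_x, knot_h)(t), _SPEED_FLOOR)
    cum = np.cumsum(speed)
    cum -= cum[0]
    return cum * (length - 1.0) / cum[-1]


def time_warp(
    sample: WindowSample,
    sigma: float,
    n_knots: int,
    rng: np.random.Generator,
) -> WindowSample:
    """Deform the window along a smooth warp path; same path for all features.

    The output has the original length; endpoints are fixed; features are
    resampled at the warped time points by linear interpolation. Unit knot
    heights give the identity map.
    """
    if sigma < 0:
        raise AugmentationError("sigma must be non-negative")
    w = sample.features.shape[0]
    if w < 2:
        raise AugmentationError("window length must be at least 2 to warp")
    tau = _warp_path(w, sigma, n_knots, rng)
    t = np.arange(w, dtype=float)
    warped = np.column_stack(
        [np.interp(tau, t, sample.features[:, j]) for j in range(sample.features.shape[1])]
    )
    return replace(sample, features=warped)


def _apply_technique(
    sample: WindowSample, cfg: AugmentationConfig, rng: np.random.Generator
) -> WindowSample:
    out = sample
    if cfg.technique in ("jitter", "jitter_time_warp"):
        out = jitter(out, cfg.sigma_jitter, rng)
    if cfg.technique in ("scaling", "scaling_time_warp"):
        out = scale(out, cfg.sigma_scaling, rng)
    if cfg.technique in ("time_warp", "jitter_time_warp", "scaling_time_warp"):
        out = time_warp(out, cfg.sigma_warp, cfg.n_knots, rng)
    return out


def augment_dataset(
    train: tuple[WindowSample, ...] | list[WindowSample],
    config: AugmentationConfig,
) -> list[WindowSample]:
    """Expand a training split to (folds + 1) times its size.

    Technique ``none`` (or folds = 0) returns the input unchanged. Otherwise
    each fold applies the configured technique once to every original sample
    in order, so originals precede synthetics and labels are conserved fold
    by fold. Deterministic given ``config.seed``.
    """
    train = list(train)
    if config.technique == "none" or config.folds == 0:
        return train
    if not train:
        raise AugmentationError("cannot augment an empty training set")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    out = list(train)
    for _ in range(config.folds):
        out.extend(_apply_technique(s, config, rng) for s in train)
    return out
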