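"""Shared fixtures: small synthetic cohorts and windowed splits."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from cogadhere import (
    CohortConfig,
    LabelRule,
    estimate_cohort_windows,
    make_supervised,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants, 60 days, default generator settings."""
    return simulate_cohort(CohortConfig(n_participants=3, seed=7))


@pytest.fixture(scope="session")
def one_split(small_cohort):
    """A supervised split for the first participant of the small cohort."""
    log = small_cohort[0]
    est = estimate_cohort_windows([log])[0]
    return make_supervised(log, est, LabelRule())


def periodic_series(period: int, length: int = 30, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Noise-free (or noisy) sinusoid with an integral number of cycles."""
    t = np.arange(length)
    x = np.cos(2 * np.pi * t / period)
    if noise_sd > 0:
        assert rng is not None
        x = x + rng.normal(0.0, noise_sd, size=length)
    return x


def autocorr_period(x: np.ndarray, max_lag: int = 10, tol: float = 0.8) -> int:
    """Brute-force period oracle from the autocorrelation function.

    A period-p signal's autocorrelation peaks at every multiple of p, so the
    raw argmax can land on a harmonic under noise; the standard refinement is
    the smallest *local maximum* within a tolerance of the best peak.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    vals = {}
    for lag in range(1, max_lag + 2):
        a, b = x[:-lag], x[lag:]
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        vals[lag] = (a * b).sum() / denom if denom > 0 else -np.inf
    peaks = [
        lag for lag in range(2, max_lag + 1)
        if vals[lag] >= vals[lag - 1] and vals[lag] >= vals[lag + 1]
    ]
    if not peaks:
        return max(range(2, max_lag + 1), key=lambda lag: vals[lag])
    best = max(vals[lag] for lag in peaks)
    return min(lag for lag in peaks if vals[lag] >= tol * best)
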