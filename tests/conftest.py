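"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately use explicit Python loops over
the printed formulas, independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from igdi.gaze_io import GazeStream

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# loop oracles


def oracle_pairwise(V: np.ndarray, W: np.ndarray, euclidean: bool = False) -> float:
    """Quadruple-loop average pairwise (squared) distance between columns."""
    nv, nw = V.shape[1], W.shape[1]
    total = 0.0
    for n1 in range(nv):
        for n2 in range(nw):
            sq = 0.0
            for i in range(2):
                sq += (V[i, n1] - W[i, n2]) ** 2
            total += np.sqrt(sq) if euclidean else sq
    return total / (nv * nw)


def oracle_within(V: np.ndarray, euclidean: bool = False) -> float:
    """Ordered-pair loop over n1 != n2, normalized by N^2."""
    n = V.shape[1]
    total = 0.0
    for n1 in range(n):
        for n2 in range(n):
            if n1 == n2:
                continue
            sq = (V[0, n1] - V[0, n2]) ** 2 + (V[1, n1] - V[1, n2]) ** 2
            total += np.sqrt(sq) if euclidean else sq
    return total / (n * n)


def oracle_rmssd(intervals) -> float:
    r = list(intervals)
    acc = 0.0
    for i in range(len(r) - 1):
        acc += (r[i] - r[i + 1]) ** 2
    return float(np.sqrt(acc / (len(r) - 1)))


def oracle_pearson(x, y) -> float:
    """Textbook covariance-ratio Pearson correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


# ---------------------------------------------------------------------------
# stream factories


def make_stream(
    t_ms,
    x,
    y,
    valid=None,
    subject="s01",
    video="v01",
    viewing=1,
    rate_hz=60.0,
) -> GazeStream:
    t_ms = np.asarray(t_ms, dtype=float)
    if valid is None:
        valid = np.ones(t_ms.size, dtype=bool)
    return GazeStream(
        subject_id=subject,
        video_id=video,
        viewing=viewing,
        t_ms=t_ms,
        x_px=np.asarray(x, dtype=float),
        y_px=np.asarray(y, dtype=float),
        valid=np.asarray(valid, dtype=bool),
        nominal_rate_hz=rate_hz,
    )


def random_stream(
    rng: np.random.Generator,
    duration_ms: float = 2000.0,
    rate_hz: float = 60.0,
    invalid_fraction: float = 0.0,
    **kwargs,
) -> GazeStream:
    n = int(round(duration_ms * rate_hz / 1000.0))
    t = np.arange(n) * 1000.0 / rate_hz
    x = rng.uniform(0, 1024, n)
    y = rng.uniform(0, 758, n)
    valid = rng.random(n) >= invalid_fraction
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return make_stream(t, x, y, valid, rate_hz=rate_hz, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort with a designed divergent segment."""
    from igdi.synthetic import SynthConfig, generate_cohort

    cfg = SynthConfig(
        n_subjects=4,
        duration_ms=8000.0,
        divergent_segments=((2000.0, 4500.0),),
        seed=7,
    )
    v1, v2, truth = generate_cohort(cfg)
    return cfg, v1, v2, truth
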