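"""Synthetic gaze cohorts and inter-beat-interval series with known
ground truth, so the whole pipeline is testable without external data.

The gaze model is deliberately simple and parameter-sparse: a shared
attention path of piecewise-constant fixation targets (Gaussian target
jumps mean-reverting toward the screen center, exponential fixation
durations, linearly interpolated saccades) drives every subject in both
viewings.  Inside designed *divergent segments* each subject-viewing
follows its own independent exploration path whose fixation targets are
drawn uniformly over the screen — unguided viewing roams; guided viewing
stays center-biased, as filmed storyline content is.  This separation of
spatial scales is what makes divergent windows carry systematically
larger dispersion than the time-randomized null, so designed divergence
is recoverable.  Per-subject fixational/tracker noise is added, coordinates
are clipped to the screen (clip events logged), and a Poisson blink
process marks dropout samples invalid (coordinates NaN, as a tracker
would report).

The default configuration emulates the acquisition conditions the
analysis is designed for: 10 subjects x 2 viewings, 30-second spots at
60 Hz on a 1024x758 px screen, ~15 px gaze noise (about half a degree
at a typical 60 cm viewing distance) and ~0.25 blinks/s.

``generate_study`` builds a full 12-video fixture whose
divergent-segment coverage is a monotone decreasing function of a target
preference score (defaults: the twelve published Ad-Meter likeability
ratings of the 2014 Super Bowl story ads), plus per-subject baseline and
per-video IBI series whose variability decreases with coverage — giving
the end-to-end pipeline a known negative regression/correlation sign to
recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze_io import EventMarkers, GazeStream, WindowGrid
from .hrv import IBISeries

logger = logging.getLogger(__name__)

#: Published USA TODAY Ad-Meter likeability ratings of the twelve 2014
#: Super Bowl story advertisements used as the reference score fixture.
ADMETER_2014 = (6.75, 4.66, 7.21, 7.13, 6.24, 6.1, 8.29, 6.18, 7.58, 4.04, 6.87, 6.09)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic cohort (one video, S subjects, 2 viewings)."""

    n_subjects: int = 10
    duration_ms: float = 30000.0
    rate_hz: float = 60.0
    screen_px: tuple[int, int] = (1024, 758)
    mean_fixation_ms: float = 300.0
    target_jump_px: float = 100.0
    center_bias: float = 0.5
    saccade_ms: float = 40.0
    subject_noise_px: float = 15.0
    divergent_segments: tuple[tuple[float, float], ...] = ()
    blink_rate_hz: float = 0.25
    blink_duration_ms: tuple[float, float] = (100.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.duration_ms <= 0 or self.rate_hz <= 0:
            raise ValueError("n_subjects, duration_ms, rate_hz must be positive")
        for scale in (self.mean_fixation_ms, self.target_jump_px, self.saccade_ms):
            if scale <= 0:
                raise ValueError("all path scales must be positive")
        if not 0 <= self.center_bias < 1:
            raise ValueError("center_bias must lie in [0, 1)")
        if self.subject_noise_px < 0 or self.blink_rate_hz < 0:
            raise ValueError("noise and blink rate must be non-negative")
        for a, b in self.divergent_segments:
            if not (0 <= a < b <= self.duration_ms):
                raise ValueError(f"divergent segment ({a}, {b}) outside [0, duration]")


def _fixation_path(
    rng: np.random.Generator, n: int, cfg: SynthConfig, guided: bool = True
) -> np.ndarray:
    """One attention path: (2, n) pixel positions at the sampling rate.

    Guided (storyline) targets take Gaussian jumps mean-reverting toward
    the screen center with strength ``center_bias``; unguided
    (exploration) targets are drawn uniformly over the screen.
    """
    dt = 1000.0 / cfg.rate_hz
    w, h = cfg.screen_px
    lo = np.array([0.05 * w, 0.05 * h])
    hi = np.array([0.95 * w, 0.95 * h])
    center = np.array([w / 2.0, h / 2.0])
    pos = np.empty((2, n))
    cur = center.copy()
    i = 0
    while i < n:
        dur = float(np.clip(rng.exponential(cfg.mean_fixation_ms), 80.0, 1500.0))
        k = min(n - i, max(1, int(round(dur / dt))))
        pos[:, i : i + k] = cur[:, None]
        i += k
        if i >= n:
            break
        if guided:
            drift = center + cfg.center_bias * (cur - center)
            target = np.clip(drift + rng.normal(0.0, cfg.target_jump_px, size=2), lo, hi)
        else:
            target = rng.uniform(lo, hi)
        m = min(n - i, max(1, int(round(cfg.saccade_ms / dt))))
        frac = np.arange(1, m + 1) / m
        pos[:, i : i + m] = cur[:, None] + (target - cur)[:, None] * frac
        i += m
        cur = target
    return pos


def generate_cohort(
    config: SynthConfig,
    grid: WindowGrid | None = None,
) -> tuple[list[GazeStream], list[GazeStream], np.ndarray]:
    """Generate S subjects x 2 viewings of gaze plus per-window truth.

    Returns ``(viewing1, viewing2, truth)`` where ``truth[t]`` marks grid
    windows overlapping any designed divergent segment.  Same seed, same
    cohort, bit for bit.
    """
    if grid is None:
        grid = WindowGrid()
    root = np.random.SeedSequence(config.seed)
    shared_ss, *subject_ss = root.spawn(1 + 2 * config.n_subjects)

    n = int(round(config.duration_ms * config.rate_hz / 1000.0))
    t_ms = np.arange(n) * 1000.0 / config.rate_hz
    shared = _fixation_path(np.random.default_rng(shared_ss), n, config)

    div_mask = np.zeros(n, dtype=bool)
    for a, b in config.divergent_segments:
        div_mask |= (t_ms >= a) & (t_ms < b)

    w, h = config.screen_px
    streams: tuple[list[GazeStream], list[GazeStream]] = ([], [])
    clipped = 0
    for s in range(config.n_subjects):
        for v in (1, 2):
            rng = np.random.default_rng(subject_ss[2 * s + (v - 1)])
            path = shared.copy()
            if div_mask.any():
                own = _fixation_path(rng, n, config, guided=False)
                path[:, div_mask] = own[:, div_mask]
            path = path + rng.normal(0.0, config.subject_noise_px, size=(2, n))
            lo = np.array([[0.0], [0.0]])
            hi = np.array([[w - 1.0], [h - 1.0]])
            clipped += int(np.sum((path < lo) | (path > hi)))
            path = np.clip(path, lo, hi)
            valid = _blink_mask(rng, t_ms, config)
            x = np.where(valid, path[0], np.nan)
            y = np.where(valid, path[1], np.nan)
            streams[v - 1].append(
                GazeStream(
                    subject_id=f"s{s + 1:02d}",
                    video_id="synthetic",
                    viewing=v,
                    t_ms=t_ms.copy(),
                    x_px=x,
                    y_px=y,
                    valid=valid,
                    nominal_rate_hz=config.rate_hz,
                )
            )
    if clipped:
        logger.debug("clipped %d out-of-screen coordinates", clipped)

    truth = truth_windows(config.divergent_segments, grid, config.duration_ms)
    return streams[0], streams[1], truth


def _blink_mask(rng: np.random.Generator, t_ms: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """True where the sample is valid; blinks arrive as a Poisson process."""
    valid = np.ones(t_ms.size, dtype=bool)
    duration_s = cfg.duration_ms / 1000.0
    n_blinks = rng.poisson(cfg.blink_rate_hz * duration_s)
    lo, hi = cfg.blink_duration_ms
    for _ in range(n_blinks):
        start = rng.uniform(0.0, cfg.duration_ms)
        dur = rng.uniform(lo, hi)
        valid &= ~((t_ms >= start) & (t_ms < start + dur))
    return valid


def truth_windows(
    segments: Sequence[tuple[float, float]], grid: WindowGrid, duration_ms: float
) -> np.ndarray:
    """Boolean per-window indicator: window overlaps a divergent segment."""
    starts = grid.window_starts(duration_ms)
    truth = np.zeros(starts.size, dtype=bool)
    for a, b in segments:
        truth |= (starts < b) & (starts + grid.window_ms > a)
    return truth


def random_segments(
    rng: np.random.Generator,
    duration_ms: float,
    coverage: float,
    n_segments: int = 3,
) -> tuple[tuple[float, float], ...]:
    """Place non-overlapping divergent segments totaling ``coverage`` of
    the timeline, at uniformly random gap positions."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    if coverage == 0.0:
        return ()
    if coverage >= 1.0:
        return ((0.0, duration_ms),)
    k = max(1, min(n_segments, int(np.ceil(coverage * n_segments / 0.75))))
    seg_len = coverage * duration_ms / k
    free = duration_ms - k * seg_len
    # split the free time into k+1 random gaps (Dirichlet via exponentials)
    gaps = rng.exponential(1.0, size=k + 1)
    gaps = gaps / gaps.sum() * free
    segments = []
    t = 0.0
    for i in range(k):
        t += gaps[i]
        segments.append((t, t + seg_len))
        t += seg_len
    return tuple(segments)


# ---------------------------------------------------------------------------
# inter-beat intervals


def generate_ibi(
    minutes: float,
    mean_ms: float = 850.0,
    rmssd_target_ms: float = 30.0,
    seed: int | np.random.Generator | None = 0,
    phi: float = 0.5,
    **series_kwargs,
) -> IBISeries:
    """First-order autoregressive IBI series with a designed RMSSD.

    Intervals follow r_i = mean + phi*(r_{i-1} - mean) + eps with
    innovation SD chosen so the expected squared successive difference is
    rmssd_target_ms^2 (for AR(1), E[(r_i - r_{i+1})^2] = 2 s^2 / (1+phi)).
    A zero target yields a constant series.
    """
    if minutes <= 0 or mean_ms <= 0 or rmssd_target_ms < 0:
        raise ValueError("minutes and mean_ms must be positive, target non-negative")
    if not 0 <= phi < 1:
        raise ValueError("phi must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = max(2, int(round(minutes * 60.0 * 1000.0 / mean_ms)))
    s = rmssd_target_ms * np.sqrt((1.0 + phi) / 2.0)
    if s == 0:
        return IBISeries(intervals=np.full(n, mean_ms), **series_kwargs)
    stationary_sd = s / np.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = rng.normal(0.0, stationary_sd)
    eps = rng.normal(0.0, s, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    intervals = np.clip(mean_ms + x, 300.0, None)
    return IBISeries(intervals=intervals, **series_kwargs)


# ---------------------------------------------------------------------------
# full study fixture


@dataclass
class StudyBundle:
    """End-to-end fixture: gaze streams, markers, scores, IBI and truth."""

    streams: dict[str, tuple[list[GazeStream], list[GazeStream]]]
    markers: dict[str, EventMarkers]
    scores: pd.DataFrame
    coverage: dict[str, float]
    truth: dict[str, np.ndarray]
    ibi: list[IBISeries]
    grid: WindowGrid = field(default_factory=WindowGrid)

    @property
    def video_ids(self) -> list[str]:
        return sorted(self.streams)


def generate_study(
    scores: Sequence[float] = ADMETER_2014,
    n_subjects: int = 10,
    duration_ms: float = 30000.0,
    coverage_range: tuple[float, float] = (0.05, 0.7),
    score_noise_sd: float = 0.0,
    seed: int = 0,
    grid: WindowGrid | None = None,
    pre_roll_ms: float = 1000.0,
    baseline_rmssd_ms: float = 40.0,
    pc_intercept: float = 5.0,
    pc_slope: float = 30.0,
    pc_noise_sd: float = 3.0,
    **config_overrides,
) -> StudyBundle:
    """Generate a full multi-video study with known ground truth.

    Divergent-segment coverage maps monotonically *down* from the target
    score (higher-rated videos guide attention better), so the pipeline
    should recover a negative iGDI-score slope.  Each subject's video IBI
    variability is likewise designed to decrease with coverage, giving a
    negative iGDI-HRV correlation.  Emitted gaze streams live in
    recording time (video onset at ``pre_roll_ms``) with center-fixation
    padding before and after, so epoching against the markers table is
    exercised end to end.
    """
    if grid is None:
        grid = WindowGrid()
    scores = np.asarray(scores, dtype=float)
    n_videos = scores.size
    root = np.random.SeedSequence(seed)
    seg_ss, score_ss, ibi_ss, *video_ss = root.spawn(3 + n_videos)
    seg_rng = np.random.default_rng(seg_ss)

    smin, smax = scores.min(), scores.max()
    lo, hi = coverage_range
    coverage = {
        f"v{i + 1:02d}": float(lo + (hi - lo) * (smax - s) / (smax - smin))
        for i, s in enumerate(scores)
    }

    streams: dict[str, tuple[list[GazeStream], list[GazeStream]]] = {}
    markers: dict[str, EventMarkers] = {}
    truth: dict[str, np.ndarray] = {}
    for i, video in enumerate(sorted(coverage)):
        segments = random_segments(seg_rng, duration_ms, coverage[video])
        cfg = SynthConfig(
            n_subjects=n_subjects,
            duration_ms=duration_ms,
            divergent_segments=segments,
            seed=int(np.random.default_rng(video_ss[i]).integers(0, 2**31 - 1)),
            **config_overrides,
        )
        v1, v2, tr = generate_cohort(cfg, grid=grid)
        v1 = [_to_recording_time(s, video, pre_roll_ms, cfg) for s in v1]
        v2 = [_to_recording_time(s, video, pre_roll_ms, cfg) for s in v2]
        streams[video] = (v1, v2)
        markers[video] = EventMarkers(video, pre_roll_ms, pre_roll_ms + duration_ms)
        truth[video] = tr

    emitted = scores.copy()
    if score_noise_sd > 0:
        emitted = emitted + np.random.default_rng(score_ss).normal(
            0.0, score_noise_sd, size=n_videos
        )
    scores_df = pd.DataFrame({"video": sorted(coverage), "score": emitted})

    ibi = _study_ibi(
        np.random.default_rng(ibi_ss), sorted(coverage), coverage, n_subjects,
        duration_ms, baseline_rmssd_ms, pc_intercept, pc_slope, pc_noise_sd,
    )
    return StudyBundle(
        streams=streams, markers=markers, scores=scores_df,
        coverage=coverage, truth=truth, ibi=ibi, grid=grid,
    )


def _to_recording_time(
    s: GazeStream, video: str, pre_roll_ms: float, cfg: SynthConfig
) -> GazeStream:
    """Shift a video-time stream into recording time and pad both ends
    with center-fixation samples (what a tracker records around a spot)."""
    dt = 1000.0 / cfg.rate_hz
    n_pad = int(round(pre_roll_ms / dt))
    w, h = cfg.screen_px
    n_total = len(s) + 2 * n_pad
    t_ms = np.arange(n_total) * dt  # exact grid; first padded sample at 0
    pad = lambda center: np.full(n_pad, center)  # noqa: E731
    return replace(
        s,
        video_id=video,
        t_ms=t_ms,
        x_px=np.concatenate([pad(w / 2.0), s.x_px, pad(w / 2.0)]),
        y_px=np.concatenate([pad(h / 2.0), s.y_px, pad(h / 2.0)]),
        valid=np.concatenate(
            [np.ones(n_pad, bool), s.valid, np.ones(n_pad, bool)]
        ),
    )


def _study_ibi(
    rng, videos, coverage, n_subjects, duration_ms,
    baseline_rmssd, pc_intercept, pc_slope, pc_noise_sd,
) -> list[IBISeries]:
    out: list[IBISeries] = []
    for s in range(n_subjects):
        subject = f"s{s + 1:02d}"
        out.append(
            generate_ibi(
                minutes=5.0, rmssd_target_ms=baseline_rmssd, seed=rng,
                context="baseline", subject_id=subject,
            )
        )
        for video in videos:
            for viewing in (1, 2):
                pc = pc_intercept - pc_slope * coverage[video] + rng.normal(0, pc_noise_sd)
                target = max(1.0, baseline_rmssd * (1.0 + pc / 100.0))
                out.append(
                    generate_ibi(
                        minutes=duration_ms / 60000.0, rmssd_target_ms=target,
                        seed=rng, context="video", subject_id=subject,
                        video_id=video, viewing=viewing,
                    )
                )
    return out


def write_study(bundle: StudyBundle, out_dir) -> dict[str, str]:
    """Write the bundle in the canonical on-disk formats; returns paths."""
    import os

    from .gaze_io import write_gaze_table
    from .hrv import write_ibi_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gaze": os.path.join(out_dir, "gaze.csv"),
        "markers": os.path.join(out_dir, "markers.csv"),
        "scores": os.path.join(out_dir, "scores.csv"),
        "ibi": os.path.join(out_dir, "ibi.csv"),
    }
    all_streams = [s for v1, v2 in bundle.streams.values() for s in (*v1, *v2)]
    write_gaze_table(all_streams, paths["gaze"])
    pd.DataFrame(
        [
            {"video": m.video_id, "t_start_ms": m.t_start_ms, "t_end_ms": m.t_end_ms}
            for m in bundle.markers.values()
        ]
    ).to_csv(paths["markers"], index=False)
    bundle.scores.to_csv(paths["scores"], index=False)
    write_ibi_table(bundle.ibi, paths["ibi"])
    return paths
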