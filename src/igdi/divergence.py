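"""Monte-Carlo null model, divergent-window classification and the iGDI.

The null hypothesis is that video frames do not guide viewers' attention
in any systematic pattern.  Each null sample destroys temporal alignment
while preserving every stream's marginal gaze statistics: every
contributing stream is independently assigned a uniform-random usable
window start within the same video, the surrogate renditions are pooled,
and their dispersion is scored.  The mean of the fitted normal (sample
moments) is the per-video, per-mode classification threshold: a window
is divergent iff its dispersion is >= that mean (ties divergent).

The eye-gaze Divergence Index (iGDI) of a video is, by default, the
fraction of usable windows labeled divergent (``fraction`` variant); the
``weighted`` variant instead averages d^T f over usable windows
(divergence-weighted sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError, NullDegeneracyError, UndefinedIndexError
from .gaze_io import GazeStream, WindowGrid, common_duration_ms
from .dispersion import (
    DispersionSeries,
    dispersion_series,
    pairwise_dispersion,
    pairwise_from_moments,
    window_stats,
    within_dispersion,
    within_from_moments,
)

IGDI_VARIANTS = ("fraction", "weighted")


@dataclass
class NullModel:
    """Monte-Carlo sample of dispersion scores under the no-guidance null.

    ``mu`` (the sample mean; the classification threshold) and ``sigma``
    are the moments of the fitted normal.  Only ``mu`` is consumed by the
    decision rule.
    """

    samples: np.ndarray
    mu: float
    sigma: float
    n_samples: int
    mode: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.isclose(self.mu, self.samples.mean()):
            raise ValueError("mu must equal the sample mean")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def sem(self) -> float:
        """Standard error of the threshold estimate."""
        n = self.samples.size
        return float(self.sigma / np.sqrt(n)) if n else float("nan")


@dataclass
class DivergenceLabels:
    """Binary divergence labels per window; forced 0 on unusable windows."""

    f: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=int)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.f.size != self.usable.size:
            raise ContractError("f and usable must align")
        if not np.isin(self.f, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if np.any(self.f[~self.usable] != 0):
            raise ValueError("unusable windows must be labeled 0")


@dataclass
class IGDIScore:
    video_id: str
    mode: str
    value: float
    t_usable: int
    variant: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "fraction" and not (0.0 <= self.value <= 1.0):
            raise ValueError("fraction iGDI must lie in [0, 1]")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_null(
    streams_a: Sequence[GazeStream],
    streams_b: Sequence[GazeStream] | None = None,
    grid: WindowGrid | None = None,
    n_samples: int = 1000,
    rng: np.random.Generator | int | None = None,
    metric_mode: str = "as_printed",
    min_valid_fraction: float = 0.5,
    duration_ms: float | None = None,
    mode: str | None = None,
) -> NullModel:
    """Draw the Monte-Carlo null distribution of dispersion scores.

    Each draw gives every contributing stream an independent
    uniform-random usable window of the same video (windows are drawn
    only from the usable pool of the rendition the stream belongs to),
    pools the surrogate renditions, and scores their dispersion.
    """
    if grid is None:
        grid = WindowGrid()
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    gen = _as_rng(rng)
    seed = rng if isinstance(rng, int) else None
    all_streams = list(streams_a) + (list(streams_b) if streams_b else [])
    if duration_ms is None:
        duration_ms = common_duration_ms(all_streams)
    starts = grid.window_starts(duration_ms)
    if mode is None:
        mode = "between" if streams_b else "within"

    stats_a = window_stats(streams_a, starts, grid.window_ms)
    usable_a = np.flatnonzero(stats_a.usable_mask(min_valid_fraction))
    if usable_a.size < 2:
        raise NullDegeneracyError("fewer than 2 usable windows to randomize over")
    if streams_b:
        stats_b = window_stats(streams_b, starts, grid.window_ms)
        usable_b = np.flatnonzero(stats_b.usable_mask(min_valid_fraction))
        if usable_b.size < 2:
            raise NullDegeneracyError("fewer than 2 usable windows to randomize over")

    if metric_mode == "as_printed":
        if streams_b:
            na, sqa, sxa, sya = _draw_pooled(gen, stats_a, usable_a, n_samples)
            nb, sqb, sxb, syb = _draw_pooled(gen, stats_b, usable_b, n_samples)
            d = pairwise_from_moments(na, sqa, sxa, sya, nb, sqb, sxb, syb)
            ok = (na >= 1) & (nb >= 1)
        else:
            na, sqa, sxa, sya = _draw_pooled(gen, stats_a, usable_a, n_samples)
            d = within_from_moments(na, sqa, sxa, sya)
            ok = na >= 1
        samples = d[ok]
        samples = np.where((samples < 0) & (samples > -1e-6), 0.0, samples)
    else:
        samples = _sample_null_slow(
            gen, streams_a, streams_b, starts, grid, usable_a,
            usable_b if streams_b else None, n_samples, metric_mode,
        )

    mu = float(samples.mean())
    sigma = float(samples.std(ddof=0))
    return NullModel(
        samples=samples, mu=mu, sigma=sigma, n_samples=int(samples.size),
        mode=mode, seed=seed,
    )


def _draw_pooled(gen, stats, usable_idx, n_samples):
    """Sum per-stream moments at independently drawn usable windows.

    Fancy-indexes the (S, T) moment arrays with an (n_samples, S) draw
    matrix, so each surrogate rendition mixes every stream at its own
    random time.
    """
    S = stats.n_valid.shape[0]
    idx = usable_idx[gen.integers(0, usable_idx.size, size=(n_samples, S))]
    rows = np.arange(S)[None, :]
    n = stats.n_valid[rows, idx].sum(axis=1)
    sq = stats.sq[rows, idx].sum(axis=1)
    sx = stats.sx[rows, idx].sum(axis=1)
    sy = stats.sy[rows, idx].sum(axis=1)
    return n, sq, sx, sy


def _sample_null_slow(
    gen, streams_a, streams_b, starts, grid, usable_a, usable_b, n_samples, metric_mode
):
    """Per-draw matrix assembly for metric modes without moment shortcuts."""
    from .gaze_io import build_window_matrix

    out = []
    for _ in range(n_samples):
        ma = _assemble(gen, streams_a, starts, grid, usable_a)
        if streams_b:
            mb = _assemble(gen, streams_b, starts, grid, usable_b)
            if ma.shape[1] and mb.shape[1]:
                out.append(pairwise_dispersion(ma, mb, metric_mode))
        else:
            if ma.shape[1]:
                out.append(within_dispersion(ma, metric_mode))
    return np.asarray(out)


def _assemble(gen, streams, starts, grid, usable_idx):
    cols = []
    for s in streams:
        start = starts[usable_idx[gen.integers(0, usable_idx.size)]]
        lo = int(np.searchsorted(s.t_ms, start, side="left"))
        hi = int(np.searchsorted(s.t_ms, start + grid.window_ms, side="left"))
        sel = s.valid[lo:hi]
        if sel.any():
            cols.append(np.vstack([s.x_px[lo:hi][sel], s.y_px[lo:hi][sel]]))
    return np.hstack(cols) if cols else np.empty((2, 0))


def classify_windows(series: DispersionSeries, null: NullModel) -> DivergenceLabels:
    """Label each window divergent (1) iff its dispersion >= the null mean.

    Ties are divergent per the decision rule's ">=".  Unusable windows
    are labeled 0 and excluded from downstream fractions.
    """
    base_mode = series.mode.split("_")[0]  # within_v1/within_v2 -> within
    if null.mode not in (series.mode, base_mode):
        raise ContractError(
            f"null mode {null.mode!r} inconsistent with series mode {series.mode!r}"
        )
    with np.errstate(invalid="ignore"):
        f = ((series.d >= null.mu) & series.usable).astype(int)
    return DivergenceLabels(f=f, usable=series.usable.copy())


def compute_igdi(
    series: DispersionSeries,
    labels: DivergenceLabels,
    variant: str = "fraction",
) -> IGDIScore:
    """Reduce labels (and scores) to the per-video divergence index."""
    if variant not in IGDI_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if labels.f.size != series.d.size:
        raise ContractError("series and labels must align")
    u = labels.usable
    t_usable = int(u.sum())
    if t_usable == 0:
        raise UndefinedIndexError(f"video {series.video_id}: zero usable windows")
    if variant == "fraction":
        value = float(labels.f[u].sum() / t_usable)
    else:
        value = float(series.d[u] @ labels.f[u]) / t_usable
    return IGDIScore(
        video_id=series.video_id, mode=series.mode, value=value,
        t_usable=t_usable, variant=variant,
    )


def model_agreement(labels_1: DivergenceLabels, labels_2: DivergenceLabels) -> float:
    """Proportion of jointly-usable windows with identical labels."""
    if labels_1.f.size != labels_2.f.size:
        raise ContractError("label vectors must have equal length")
    joint = labels_1.usable & labels_2.usable
    if not joint.any():
        raise UndefinedIndexError("no jointly-usable windows")
    return float(np.mean(labels_1.f[joint] == labels_2.f[joint]))


@dataclass
class VideoResult:
    """Everything computed for one video and one mode."""

    series: DispersionSeries
    null: NullModel
    labels: DivergenceLabels
    igdi: IGDIScore


def analyze_video(
    streams_v1: Sequence[GazeStream],
    streams_v2: Sequence[GazeStream] | None = None,
    grid: WindowGrid | None = None,
    n_null_samples: int = 1000,
    rng: np.random.Generator | int | None = None,
    metric_mode: str = "as_printed",
    min_valid_fraction: float = 0.5,
    variant: str = "fraction",
    duration_ms: float | None = None,
) -> dict[str, VideoResult]:
    """Run series -> null -> labels -> iGDI for between, within_v1 and
    within_v2 modes of one video (between/within_v2 skipped without a
    second viewing).  Returns a mode-keyed dict; each score carries its
    threshold."""
    if grid is None:
        grid = WindowGrid()
    gen = _as_rng(rng)
    jobs: list[tuple[str, Sequence[GazeStream], Sequence[GazeStream] | None]] = []
    if streams_v2:
        jobs.append(("between", streams_v1, streams_v2))
    jobs.append(("within_v1", streams_v1, None))
    if streams_v2:
        jobs.append(("within_v2", streams_v2, None))

    out: dict[str, VideoResult] = {}
    for mode, a, b in jobs:
        series = dispersion_series(
            a, b, grid=grid, metric_mode=metric_mode,
            min_valid_fraction=min_valid_fraction, duration_ms=duration_ms, mode=mode,
        )
        null = sample_null(
            a, b, grid=grid, n_samples=n_null_samples, rng=gen,
            metric_mode=metric_mode, min_valid_fraction=min_valid_fraction,
            duration_ms=duration_ms, mode=mode,
        )
        labels = classify_windows(series, null)
        igdi = compute_igdi(series, labels, variant=variant)
        igdi.threshold = null.mu
        out[mode] = VideoResult(series=series, null=null, labels=labels, igdi=igdi)
    return out
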