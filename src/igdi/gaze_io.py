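"""Reading, validating, epoching and windowing of multi-subject gaze recordings.

The on-disk gaze format is a delimited text table (CSV/TSV, autodetected)
with header columns ``subject, video, viewing, t_ms, x_px, y_px, valid``.
Coordinates are screen pixels with the origin at the top-left corner, x
increasing rightward and y downward.  Each (subject, video, viewing)
triple becomes one :class:`GazeStream`.

Companion tables use the same dialect:

* markers table: ``video, t_start_ms, t_end_ms`` (video on/offset in
  recording time);
* scores table: ``video, score`` (one audience-preference score per video).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyEpochError,
    EmptyInputError,
    GazeFormatError,
)

logger = logging.getLogger(__name__)

REQUIRED_GAZE_COLUMNS = ("subject", "video", "viewing", "t_ms", "x_px", "y_px", "valid")
REQUIRED_MARKER_COLUMNS = ("video", "t_start_ms", "t_end_ms")
REQUIRED_SCORE_COLUMNS = ("video", "score")


class GazeSample(NamedTuple):
    """One gaze fixation sample: time (ms), screen coordinates (px), validity."""

    t_ms: float
    x_px: float
    y_px: float
    valid: bool


@dataclass
class GazeStream:
    """One subject's gaze trace for one viewing of one video.

    Samples are stored as parallel numpy arrays; ``t_ms`` is strictly
    increasing.  Invalid samples (blinks, track loss) keep their slot so
    stream length reflects the recording, but their coordinates may be NaN.
    After :func:`epoch_stream`, t_ms is re-referenced so 0 is video onset.
    """

    subject_id: str
    video_id: str
    viewing: int
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    nominal_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.size
        if not (self.x_px.size == self.y_px.size == self.valid.size == n):
            raise ValueError("t_ms, x_px, y_px, valid must have equal length")
        if n and not np.all(np.isfinite(self.t_ms)):
            raise ValueError("t_ms must be finite")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("t_ms must be strictly increasing")
        # a sample flagged valid must carry finite coordinates
        bad = self.valid & ~(np.isfinite(self.x_px) & np.isfinite(self.y_px))
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} samples are flagged valid but have non-finite coordinates"
            )

    def __len__(self) -> int:
        return int(self.t_ms.size)

    def samples(self) -> Iterable[GazeSample]:
        for t, x, y, v in zip(self.t_ms, self.x_px, self.y_px, self.valid):
            yield GazeSample(float(t), float(x), float(y), bool(v))

    @property
    def duration_ms(self) -> float:
        """Span covered by the recording: last timestamp plus one sample period."""
        if len(self) == 0:
            return 0.0
        return float(self.t_ms[-1] + 1000.0 / self.nominal_rate_hz)

    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.video_id, self.viewing)


@dataclass(frozen=True)
class EventMarkers:
    """Video on/offset in recording time (milliseconds)."""

    video_id: str
    t_start_ms: float
    t_end_ms: float

    def __post_init__(self) -> None:
        if not self.t_end_ms > self.t_start_ms:
            raise ValueError("t_end_ms must exceed t_start_ms")

    @property
    def duration_ms(self) -> float:
        return self.t_end_ms - self.t_start_ms


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid: 250 ms windows shifted every 50 ms by default
    (80% overlap between successive windows), anchored at video onset."""

    window_ms: float = 250.0
    step_ms: float = 50.0
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.window_ms > 0:
            raise ValueError("window_ms must be positive")
        if not 0 < self.step_ms <= self.window_ms:
            raise ValueError("step_ms must satisfy 0 < step_ms <= window_ms")

    def n_windows(self, duration_ms: float) -> int:
        """Count of windows fitting in ``[t0, t0 + duration_ms]``."""
        usable = duration_ms - self.window_ms
        if usable < 0:
            return 0
        return int(math.floor(usable / self.step_ms)) + 1

    def window_starts(self, duration_ms: float) -> np.ndarray:
        n = self.n_windows(duration_ms)
        return self.t0_ms + self.step_ms * np.arange(n)


@dataclass
class GazeMatrix:
    """2xN matrix of pooled gaze positions for one time window.

    ``coords`` row 0 is x, row 1 is y; every column is finite (invalid
    samples are excluded before construction).  ``insufficient`` flags a
    window whose pooled valid-sample fraction fell below threshold; such
    windows are excluded downstream from both the null sample and the
    divergence index.
    """

    coords: np.ndarray
    origin: list[tuple[str, int]] = field(default_factory=list)
    n_total: int = 0
    insufficient: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != 2:
            raise ValueError("coords must be a 2xN array")
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise ValueError("all matrix columns must be finite")

    @property
    def n_cols(self) -> int:
        return int(self.coords.shape[1])

    @property
    def valid_fraction(self) -> float:
        if self.n_total == 0:
            return 0.0
        return self.n_cols / self.n_total


def _sniff_read(path, sep: str | None) -> pd.DataFrame:
    import csv

    if sep is None:
        with open(path, newline="") as fh:
            head = fh.readline()
        if not head.strip():
            raise EmptyInputError(f"{path}: file is empty")
        try:
            sep = csv.Sniffer().sniff(head, delimiters=",;\t| ").delimiter
        except csv.Error:
            sep = ","
    try:
        # round_trip float parsing so tables reproduce to full precision
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: file is empty") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_gaze_table(path, sep: str | None = None) -> list[GazeStream]:
    """Parse a delimited gaze table into one stream per (subject, video, viewing).

    Rows whose ``x_px``/``y_px`` fail numeric parsing are kept with
    ``valid=False`` (stream length unchanged); rows whose ``t_ms`` fails to
    parse cannot be ordered and are dropped with a warning.  Streams are
    sorted by ``t_ms`` and returned sorted by their (subject, video,
    viewing) key.
    """
    df = _sniff_read(path, sep)
    _require_columns(df, REQUIRED_GAZE_COLUMNS, path)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: table has no rows")

    t = pd.to_numeric(df["t_ms"], errors="coerce")
    x = pd.to_numeric(df["x_px"], errors="coerce")
    y = pd.to_numeric(df["y_px"], errors="coerce")
    valid = _parse_valid(df["valid"])

    drop = t.isna()
    if drop.any():
        logger.warning("%s: dropping %d rows with unparseable t_ms", path, int(drop.sum()))
    keep = ~drop
    work = pd.DataFrame(
        {
            "subject": df["subject"].astype(str),
            "video": df["video"].astype(str),
            "viewing": pd.to_numeric(df["viewing"], errors="raise").astype(int),
            "t_ms": t,
            "x_px": x,
            "y_px": y,
            "valid": valid & x.notna() & y.notna(),
        }
    )[keep]

    streams = []
    for (subject, video, viewing), g in work.groupby(
        ["subject", "video", "viewing"], sort=True
    ):
        g = g.sort_values("t_ms", kind="mergesort")
        streams.append(
            GazeStream(
                subject_id=subject,
                video_id=video,
                viewing=int(viewing),
                t_ms=g["t_ms"].to_numpy(),
                x_px=g["x_px"].to_numpy(),
                y_px=g["y_px"].to_numpy(),
                valid=g["valid"].to_numpy(),
            )
        )
    return streams


def _parse_valid(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    as_str = col.astype(str).str.strip().str.lower()
    truthy = as_str.isin({"1", "true", "t", "yes"})
    return truthy


def write_gaze_table(streams: Iterable[GazeStream], path, sep: str = ",") -> None:
    """Write streams back to the canonical table; numeric fields round-trip
    to full precision (shortest-repr float formatting)."""
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject_id,
                    "video": s.video_id,
                    "viewing": s.viewing,
                    "t_ms": s.t_ms,
                    "x_px": s.x_px,
                    "y_px": s.y_px,
                    "valid": s.valid.astype(int),
                }
            )
        )
    if not frames:
        raise EmptyInputError("no streams to write")
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_markers_table(path, sep: str | None = None) -> dict[str, EventMarkers]:
    df = _sniff_read(path, sep)
    _require_columns(df, REQUIRED_MARKER_COLUMNS, path)
    out: dict[str, EventMarkers] = {}
    for row in df.itertuples(index=False):
        video = str(row.video)
        out[video] = EventMarkers(video, float(row.t_start_ms), float(row.t_end_ms))
    return out


def read_scores_table(path, sep: str | None = None) -> pd.DataFrame:
    df = _sniff_read(path, sep)
    _require_columns(df, REQUIRED_SCORE_COLUMNS, path)
    return pd.DataFrame(
        {"video": df["video"].astype(str), "score": pd.to_numeric(df["score"])}
    )


def epoch_stream(
    stream: GazeStream,
    markers: EventMarkers,
    pre_ms: float = 1000.0,
    post_ms: float = 1000.0,
) -> GazeStream:
    """Cut a stream to ``[t_start - pre, t_end + post]`` (inclusive) and
    re-reference timestamps so the video onset maps to 0."""
    lo = markers.t_start_ms - pre_ms
    hi = markers.t_end_ms + post_ms
    mask = (stream.t_ms >= lo) & (stream.t_ms <= hi)
    if not mask.any():
        raise EmptyEpochError(
            f"stream {stream.key()}: no samples inside epoch [{lo}, {hi}] ms"
        )
    return replace(
        stream,
        t_ms=stream.t_ms[mask] - markers.t_start_ms,
        x_px=stream.x_px[mask],
        y_px=stream.y_px[mask],
        valid=stream.valid[mask],
    )


def build_window_matrix(
    streams: Sequence[GazeStream],
    window_start_ms: float,
    grid: WindowGrid,
    min_valid_fraction: float = 0.5,
) -> GazeMatrix:
    """Pool the valid gaze samples of every stream falling in
    ``[start, start + window_ms)``, concatenated subject-after-subject.

    Invalid samples are dropped.  The matrix is flagged ``insufficient``
    when the pooled valid-sample fraction falls below
    ``min_valid_fraction`` (including the zero-valid-samples case, which is
    a signal rather than an exception: downstream marks the window
    unusable).
    """
    cols: list[np.ndarray] = []
    origin: list[tuple[str, int]] = []
    n_total = 0
    for s in streams:
        lo = int(np.searchsorted(s.t_ms, window_start_ms, side="left"))
        hi = int(np.searchsorted(s.t_ms, window_start_ms + grid.window_ms, side="left"))
        n_total += hi - lo
        sel = s.valid[lo:hi]
        if sel.any():
            cols.append(np.vstack([s.x_px[lo:hi][sel], s.y_px[lo:hi][sel]]))
            origin.append((s.subject_id, s.viewing))
    coords = np.hstack(cols) if cols else np.empty((2, 0))
    n_valid = coords.shape[1]
    insufficient = n_total == 0 or n_valid == 0 or (n_valid / n_total) < min_valid_fraction
    return GazeMatrix(coords=coords, origin=origin, n_total=n_total, insufficient=insufficient)


def common_duration_ms(streams: Sequence[GazeStream], cap_ms: float | None = None) -> float:
    """Shortest epoched duration across streams, optionally capped by the
    marker-derived video duration.  The window grid is truncated to this
    span so every rendition covers the same segment."""
    if not streams:
        raise EmptyInputError("no streams")
    dur = min(s.duration_ms for s in streams)
    if cap_ms is not None:
        dur = min(dur, cap_ms)
    return dur
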