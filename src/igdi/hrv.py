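"""Heart-rate-variability analysis: RMSSD, baseline percent change, and
the correlation between HRV change and the gaze-divergence index.

RMSSD (root mean square of successive differences of inter-beat
intervals, in ms) is a time-domain HRV statistic tied to parasympathetic
influence on the heart; attention allocation is associated with cardiac
deceleration and hence higher RMSSD.  Video-period RMSSD is normalized
against a resting baseline via percent change before group analysis.

The on-disk IBI format is a delimited table with columns
``subject, context, video, viewing, interval_ms`` where ``context`` is
``baseline`` or ``video`` (video/viewing blank for baseline rows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import (
    ConstantInputError,
    GazeFormatError,
    InsufficientBeatsError,
    InsufficientSignalError,
    UndefinedChangeError,
)

logger = logging.getLogger(__name__)

REQUIRED_IBI_COLUMNS = ("subject", "context", "video", "viewing", "interval_ms")


@dataclass
class IBISeries:
    """A vector of consecutive inter-beat intervals (milliseconds)."""

    intervals: np.ndarray
    context: str = "video"
    subject_id: str | None = None
    video_id: str | None = None
    viewing: int | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all inter-beat intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass
class HRVChange:
    """Video RMSSD relative to resting baseline, as percent change."""

    rmssd_baseline: float
    rmssd_video: float
    percent_change: float


@dataclass
class CorrelationReport:
    """Pearson correlation with df reported the r_(df) way, plus the
    Shapiro-Wilk normality pre-checks (reported, not enforced)."""

    r: float
    p: float
    df: int
    n: int
    shapiro_w_x: float
    shapiro_p_x: float
    shapiro_w_y: float
    shapiro_p_y: float


def _intervals(ibi) -> np.ndarray:
    if isinstance(ibi, IBISeries):
        return ibi.intervals
    return np.asarray(ibi, dtype=float)


def rmssd(ibi) -> float:
    """Root mean square of successive IBI differences:
    sqrt( (1/(I-1)) * sum_{i=1}^{I-1} (r(i) - r(i+1))^2 )."""
    r = _intervals(ibi)
    if r.size < 2:
        raise InsufficientBeatsError("RMSSD needs at least 2 intervals")
    return float(np.sqrt(np.mean(np.diff(r) ** 2)))


def percent_change(video: IBISeries, baseline: IBISeries) -> HRVChange:
    """100 * (video RMSSD - baseline RMSSD) / baseline RMSSD."""
    rb = rmssd(baseline)
    rv = rmssd(video)
    if rb <= 0:
        raise UndefinedChangeError("baseline RMSSD is zero; percent change undefined")
    return HRVChange(
        rmssd_baseline=rb, rmssd_video=rv,
        percent_change=100.0 * (rv - rb) / rb,
    )


def correlate_igdi_hrv(igdi_values, hrv_changes) -> CorrelationReport:
    """Pearson product-moment correlation between divergence-index values
    and RMSSD percent changes, with two-tailed p on n-2 df."""
    x = np.asarray(igdi_values, dtype=float)
    y = np.asarray(hrv_changes, dtype=float)
    if x.size != y.size:
        raise ValueError("sequences must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    wx, px = stats.shapiro(x)
    wy, py = stats.shapiro(y)
    return CorrelationReport(
        r=float(r), p=float(p), df=int(x.size - 2), n=int(x.size),
        shapiro_w_x=float(wx), shapiro_p_x=float(px),
        shapiro_w_y=float(wy), shapiro_p_y=float(py),
    )


def paired_viewing_ttest(values_v1, values_v2) -> tuple[float, float, int]:
    """Paired t-test between first- and second-viewing HRV (emitted for
    transparency before the default pooling of the two viewings)."""
    a = np.asarray(values_v1, dtype=float)
    b = np.asarray(values_v2, dtype=float)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), int(a.size - 1)


def clean_ibi(
    intervals,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    spike_factor: float = 1.3,
    median_window: int = 11,
) -> np.ndarray:
    """Programmatic IBI sanity filter.

    Drops intervals outside the plausibility band [min_ms, max_ms] and
    spikes exceeding ``spike_factor`` times the running median; both are
    logged.  A deterministic stand-in for manual beat editing.
    """
    r = np.asarray(intervals, dtype=float)
    band = (r >= min_ms) & (r <= max_ms)
    if (~band).any():
        logger.info("IBI band filter dropped %d/%d intervals", int((~band).sum()), r.size)
    r = r[band]
    if r.size >= 3:
        k = min(median_window, r.size if r.size % 2 else r.size - 1)
        run_med = signal.medfilt(r, kernel_size=k)
        spikes = r > spike_factor * run_med
        if spikes.any():
            logger.info("IBI spike filter dropped %d intervals", int(spikes.sum()))
        r = r[~spikes]
    return r


def ppg_to_ibi(
    waveform,
    rate_hz: float,
    cutoff_hz: float = 7.0,
    order: int = 4,
    min_interval_ms: float = 300.0,
    max_interval_ms: float = 2000.0,
    **series_kwargs,
) -> IBISeries:
    """Extract inter-beat intervals from a raw photoplethysmography trace.

    The trace is low-pass filtered (Butterworth, zero-phase, 7 Hz cutoff
    by default) to suppress high-frequency noise, pulse peaks are found
    above an adaptive amplitude threshold with a refractory distance of
    ``min_interval_ms``, and successive peak-to-peak intervals outside
    the plausibility band are dropped and logged.
    """
    x = np.asarray(waveform, dtype=float)
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("rate_hz must exceed twice the filter cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    filt = signal.sosfiltfilt(sos, x)

    spread = float(filt.std())
    if spread == 0:
        raise InsufficientSignalError("flat signal: no peaks exist")
    height = float(filt.mean()) + 0.3 * spread
    distance = max(1, int(round(min_interval_ms / 1000.0 * rate_hz)))
    peaks, _ = signal.find_peaks(filt, height=height, distance=distance)
    if peaks.size < 3:
        raise InsufficientSignalError(f"only {peaks.size} peaks detected; need >= 3")

    intervals = np.diff(peaks) * 1000.0 / rate_hz
    intervals = clean_ibi(intervals, min_ms=min_interval_ms, max_ms=max_interval_ms)
    return IBISeries(intervals=intervals, **series_kwargs)


# ---------------------------------------------------------------------------
# table I/O


def read_ibi_table(path, sep: str | None = None) -> pd.DataFrame:
    from .gaze_io import _sniff_read, _require_columns

    df = _sniff_read(path, sep)
    _require_columns(df, REQUIRED_IBI_COLUMNS, path)
    df = df.copy()
    df["subject"] = df["subject"].astype(str)
    df["context"] = df["context"].astype(str)
    df["interval_ms"] = pd.to_numeric(df["interval_ms"])
    return df


def write_ibi_table(series_list: Sequence[IBISeries], path, sep: str = ",") -> None:
    rows = []
    for s in series_list:
        rows.append(
            pd.DataFrame(
                {
                    "subject": s.subject_id,
                    "context": s.context,
                    "video": s.video_id if s.video_id is not None else "",
                    "viewing": s.viewing if s.viewing is not None else "",
                    "interval_ms": s.intervals,
                }
            )
        )
    if not rows:
        raise GazeFormatError("no IBI series to write")
    pd.concat(rows, ignore_index=True).to_csv(path, sep=sep, index=False)
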