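"""Gaze table parsing, epoching and window-matrix construction."""

import numpy as np
import pytest

from igdi.errors import EmptyEpochError, EmptyInputError, GazeFormatError
from igdi.gaze_io import (
    EventMarkers,
    WindowGrid,
    build_window_matrix,
    epoch_stream,
    read_gaze_table,
    write_gaze_table,
)

from conftest import make_stream, random_stream


HEADER = "subject,video,viewing,t_ms,x_px,y_px,valid\n"


def write(tmp_path, body, name="gaze.csv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadGazeTable:
    def test_single_stream_parse(self, tmp_path):
        rows = "".join(
            f"s1,v1,1,{t * 100},{10 + t},{20 + t},1\n" for t in range(6)
        )
        streams = read_gaze_table(write(tmp_path, rows))
        assert len(streams) == 1
        s = streams[0]
        assert len(s) == 6
        assert s.key() == ("s1", "v1", 1)
        np.testing.assert_allclose(s.t_ms, np.arange(6) * 100.0)
        assert s.valid.all()

    def test_unparseable_coordinate_marks_invalid(self, tmp_path):
        rows = "s1,v1,1,0,1.0,2.0,1\ns1,v1,1,100,NaN,2.0,1\ns1,v1,1,200,3.0,4.0,1\n"
        (s,) = read_gaze_table(write(tmp_path, rows))
        assert len(s) == 3  # stream length unchanged
        assert list(s.valid) == [True, False, True]

    def test_missing_column_names_offender(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject,video,viewing,t_ms,x_px,valid\ns1,v1,1,0,1,1\n")
        with pytest.raises(GazeFormatError, match="y_px"):
            read_gaze_table(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_gaze_table(p)

    def test_tsv_autodetected(self, tmp_path):
        p = tmp_path / "gaze.tsv"
        p.write_text(HEADER.replace(",", "\t") + "s1\tv1\t1\t0\t1.5\t2.5\t1\n")
        (s,) = read_gaze_table(p)
        assert s.x_px[0] == 1.5

    def test_round_trip_full_precision(self, tmp_path, rng):
        streams = [
            random_stream(rng, subject=f"s{i}", viewing=v, invalid_fraction=0.1)
            for i in range(2)
            for v in (1, 2)
        ]
        path = tmp_path / "rt.csv"
        write_gaze_table(streams, path)
        back = read_gaze_table(path)
        assert len(back) == 4
        by_key = {s.key(): s for s in back}
        for s in streams:
            r = by_key[s.key()]
            np.testing.assert_array_equal(s.t_ms, r.t_ms)
            np.testing.assert_array_equal(s.valid, r.valid)
            np.testing.assert_array_equal(
                s.x_px[s.valid], r.x_px[r.valid]
            )  # exact, not approximate


class TestEpochStream:
    def test_epoch_window_and_rereference(self):
        t = np.arange(0, 40001, 100, dtype=float)
        s = make_stream(t, t * 0 + 5, t * 0 + 5)
        out = epoch_stream(s, EventMarkers("v1", 5000, 35000), 1000, 1000)
        assert out.t_ms[0] == 4000 - 5000
        assert out.t_ms[-1] == 36000 - 5000
        assert out.t_ms.min() == -1000 and out.t_ms.max() == 31000

    def test_marker_at_stream_start_zero_pre(self):
        t = np.arange(0, 1000, 100, dtype=float)
        s = make_stream(t, t, t)
        out = epoch_stream(s, EventMarkers("v1", 0, 900), pre_ms=0, post_ms=0)
        assert out.t_ms[0] == 0.0

    def test_no_samples_in_epoch_raises(self):
        s = make_stream([0.0, 100.0], [1, 1], [1, 1])
        with pytest.raises(EmptyEpochError):
            epoch_stream(s, EventMarkers("v1", 5000, 6000), 100, 100)

    def test_matches_filter_and_shift_oracle(self, rng):
        for _ in range(20):
            s = random_stream(rng, duration_ms=3000)
            start = float(rng.uniform(200, 1500))
            end = start + float(rng.uniform(300, 1200))
            pre = float(rng.uniform(0, 300))
            post = float(rng.uniform(0, 300))
            out = epoch_stream(s, EventMarkers("v1", start, end), pre, post)
            keep = (s.t_ms >= start - pre) & (s.t_ms <= end + post)
            np.testing.assert_allclose(out.t_ms, s.t_ms[keep] - start)
            np.testing.assert_array_equal(out.valid, s.valid[keep])


class TestWindowGrid:
    def test_defaults_overlap_and_count(self):
        g = WindowGrid()
        assert g.window_ms == 250 and g.step_ms == 50
        assert 1 - g.step_ms / g.window_ms == pytest.approx(0.8)
        assert g.n_windows(10000) == 196

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            WindowGrid(window_ms=0)
        with pytest.raises(ValueError):
            WindowGrid(window_ms=100, step_ms=200)

    def test_short_duration_zero_windows(self):
        assert WindowGrid().n_windows(100) == 0


class TestBuildWindowMatrix:
    def two_streams(self, valid_a=None, valid_b=None):
        n = 30
        t = np.arange(n) * 1000.0 / 60.0
        a = make_stream(t, np.full(n, 1.0), np.full(n, 2.0), valid_a, subject="a")
        b = make_stream(t, np.full(n, 3.0), np.full(n, 4.0), valid_b, subject="b")
        return [a, b]

    def test_column_count_60hz_250ms(self):
        m = build_window_matrix(self.two_streams(), 0.0, WindowGrid())
        assert m.n_cols == 2 * 15
        assert not m.insufficient

    def test_boundary_valid_fraction_not_flagged(self):
        # one subject fully blinking: pooled fraction exactly 0.5 >= threshold
        blink = np.zeros(30, dtype=bool)
        streams = self.two_streams(valid_b=blink)
        streams[1].x_px[:] = np.nan
        streams[1].y_px[:] = np.nan
        m = build_window_matrix(streams, 0.0, WindowGrid(), min_valid_fraction=0.5)
        assert m.n_cols == 15
        assert m.valid_fraction == pytest.approx(0.5)
        assert not m.insufficient

    def test_zero_valid_samples_flagged_not_raised(self):
        blink = np.zeros(30, dtype=bool)
        streams = self.two_streams(valid_a=blink, valid_b=blink)
        m = build_window_matrix(streams, 0.0, WindowGrid())
        assert m.n_cols == 0
        assert m.insufficient

    def test_matches_per_sample_filter_oracle(self, rng):
        for _ in range(20):
            streams = [
                random_stream(rng, duration_ms=1000, invalid_fraction=0.3, subject=f"s{i}")
                for i in range(3)
            ]
            start = float(rng.uniform(0, 700))
            m = build_window_matrix(streams, start, WindowGrid())
            cols = []
            for s in streams:
                for t, x, y, v in zip(s.t_ms, s.x_px, s.y_px, s.valid):
                    if v and start <= t < start + 250:
                        cols.append((x, y))
            assert m.n_cols == len(cols)
            if cols:
                np.testing.assert_allclose(m.coords, np.array(cols).T)

    def test_column_count_equals_sum_of_valid_counts(self, rng):
        streams = [
            random_stream(rng, duration_ms=1000, invalid_fraction=0.2, subject=f"s{i}")
            for i in range(4)
        ]
        m = build_window_matrix(streams, 100.0, WindowGrid())
        expected = sum(
            int(np.sum(s.valid & (s.t_ms >= 100) & (s.t_ms < 350))) for s in streams
        )
        assert m.n_cols == expected


def test_epoch_then_window_equals_shifted_window(rng):
    """Epoching followed by windowing matches windowing the raw stream
    with shifted window starts."""
    for _ in range(10):
        s = random_stream(rng, duration_ms=4000, invalid_fraction=0.1)
        onset = float(rng.uniform(500, 1500))
        mk = EventMarkers("v1", onset, onset + 2000)
        ep = epoch_stream(s, mk, pre_ms=0, post_ms=0)
        grid = WindowGrid()
        m_epoched = build_window_matrix([ep], 250.0, grid)
        m_shifted = build_window_matrix([s], onset + 250.0, grid)
        np.testing.assert_allclose(m_epoched.coords, m_shifted.coords)
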