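"""Null model, decision rule, divergence index and model agreement."""

import itertools

import numpy as np
import pytest

from igdi.dispersion import DispersionSeries, dispersion_series
from igdi.divergence import (
    DivergenceLabels,
    NullModel,
    classify_windows,
    compute_igdi,
    model_agreement,
    sample_null,
)
from igdi.errors import ContractError, NullDegeneracyError, UndefinedIndexError
from igdi.gaze_io import WindowGrid, build_window_matrix

from conftest import make_stream, oracle_pairwise


def series_of(d, usable=None, mode="between"):
    d = np.asarray(d, dtype=float)
    if usable is None:
        usable = np.ones(d.size, dtype=bool)
    return DispersionSeries(
        video_id="v01",
        mode=mode,
        window_starts_ms=50.0 * np.arange(d.size),
        d=d,
        usable=np.asarray(usable, dtype=bool),
    )


def null_of(mu, mode="between", sigma=1.0):
    samples = np.array([mu - sigma, mu + sigma])
    return NullModel(samples=samples, mu=mu, sigma=float(np.std(samples)), n_samples=2, mode=mode)


def constant_cohort(n_subjects=3, duration_ms=2000.0):
    n = int(duration_ms * 60 / 1000)
    t = np.arange(n) * 1000.0 / 60.0
    mk = lambda v: [  # noqa: E731
        make_stream(t, np.full(n, 100.0), np.full(n, 200.0), subject=f"s{s}", viewing=v)
        for s in range(n_subjects)
    ]
    return mk(1), mk(2)


class TestSampleNull:
    def test_constant_fixation_gives_degenerate_null(self):
        v1, v2 = constant_cohort()
        null = sample_null(v1, v2, n_samples=200, rng=0)
        assert null.mu == 0.0
        assert null.sigma == 0.0
        np.testing.assert_array_equal(null.samples, 0.0)

    def test_two_seeds_agree_within_monte_carlo_error(self, small_cohort):
        _, v1, v2, _ = small_cohort
        n1 = sample_null(v1, v2, n_samples=1000, rng=1)
        n2 = sample_null(v1, v2, n_samples=1000, rng=2)
        combined_sem = np.hypot(n1.sem, n2.sem)
        assert abs(n1.mu - n2.mu) < 3 * combined_sem

    def test_two_window_toy_matches_exhaustive_enumeration(self, rng):
        """A 2-window video: the Monte-Carlo null mean must match the
        average over all per-stream window-assignment combinations."""
        grid = WindowGrid(window_ms=250, step_ms=250)
        n = 30  # 500 ms at 60 Hz
        t = np.arange(n) * 1000.0 / 60.0
        streams = {}
        for v in (1, 2):
            streams[v] = [
                make_stream(
                    t,
                    rng.uniform(0, 1024, n),
                    rng.uniform(0, 758, n),
                    subject=f"s{s}",
                    viewing=v,
                )
                for s in range(2)
            ]

        def window(stream, w):
            sel = (stream.t_ms >= 250.0 * w) & (stream.t_ms < 250.0 * (w + 1))
            return np.vstack([stream.x_px[sel], stream.y_px[sel]])

        exact = []
        for assign in itertools.product((0, 1), repeat=4):
            V = np.hstack([window(streams[1][i], assign[i]) for i in range(2)])
            W = np.hstack([window(streams[2][i], assign[2 + i]) for i in range(2)])
            exact.append(oracle_pairwise(V, W))
        exact_mean = np.mean(exact)

        null = sample_null(streams[1], streams[2], grid=grid, n_samples=2000, rng=3)
        assert null.mu == pytest.approx(exact_mean, abs=3 * null.sem)

    def test_too_few_usable_windows_raises(self):
        v1, v2 = constant_cohort(duration_ms=260.0)  # single window fits
        with pytest.raises(NullDegeneracyError):
            sample_null(v1, v2, n_samples=100, rng=0)


class TestClassifyWindows:
    def test_tie_with_threshold_is_divergent(self):
        labels = classify_windows(series_of([5.0, 4.9]), null_of(5.0))
        assert list(labels.f) == [1, 0]

    def test_all_below_threshold_all_zero(self):
        labels = classify_windows(series_of([1.0, 2.0, 3.0]), null_of(10.0))
        assert labels.f.sum() == 0

    def test_unusable_windows_forced_zero(self):
        labels = classify_windows(
            series_of([9.0, 9.0], usable=[True, False]), null_of(5.0)
        )
        assert list(labels.f) == [1, 0]

    def test_matches_elementwise_oracle(self, rng):
        d = rng.uniform(0, 10, 200)
        mu = 5.0
        labels = classify_windows(series_of(d), null_of(mu))
        expected = [1 if di >= mu else 0 for di in d]
        assert list(labels.f) == expected

    def test_length_mismatch_raises(self):
        series = series_of([1.0, 2.0])
        null = null_of(1.0)
        labels = DivergenceLabels(f=np.array([0, 1, 0]), usable=np.ones(3, bool))
        with pytest.raises(ContractError):
            compute_igdi(series, labels)
        with pytest.raises(ContractError):
            classify_windows(series_of([1.0], mode="within_v1"), null)


class TestComputeIgdi:
    def test_saturated_labels_give_one(self):
        s = series_of([1.0] * 4)
        labels = DivergenceLabels(f=np.ones(4, int), usable=np.ones(4, bool))
        assert compute_igdi(s, labels).value == 1.0

    def test_half_labels_give_half(self):
        s = series_of([1.0] * 4)
        labels = DivergenceLabels(f=np.array([1, 0, 1, 0]), usable=np.ones(4, bool))
        assert compute_igdi(s, labels).value == 0.5

    def test_weighted_variant_is_dot_product(self, rng):
        d = rng.uniform(0, 100, 50)
        f = rng.integers(0, 2, 50)
        s = series_of(d)
        labels = DivergenceLabels(f=f, usable=np.ones(50, bool))
        got = compute_igdi(s, labels, variant="weighted").value
        assert got == pytest.approx(float(d @ f) / 50)

    def test_zero_usable_raises(self):
        s = series_of([1.0], usable=[False])
        labels = DivergenceLabels(f=np.zeros(1, int), usable=np.zeros(1, bool))
        with pytest.raises(UndefinedIndexError):
            compute_igdi(s, labels)

    def test_monotone_transform_invariance(self, rng):
        """Fraction iGDI is unchanged by a strictly monotone transform of
        all scores and the threshold together."""
        d = rng.uniform(0.1, 10, 100)
        mu = 5.0
        s1 = series_of(d)
        base = compute_igdi(s1, classify_windows(s1, null_of(mu))).value
        g = lambda x: np.log1p(x) ** 3  # noqa: E731  strictly increasing on (0, inf)
        s2 = series_of(g(d))
        transformed = compute_igdi(s2, classify_windows(s2, null_of(float(g(mu))))).value
        assert transformed == base

    def test_adding_window_moves_index_weakly(self):
        d = [1.0, 9.0, 2.0]
        mu = 5.0
        s = series_of(d)
        base = compute_igdi(s, classify_windows(s, null_of(mu))).value
        s_hi = series_of(d + [7.0])
        s_lo = series_of(d + [0.5])
        hi = compute_igdi(s_hi, classify_windows(s_hi, null_of(mu))).value
        lo = compute_igdi(s_lo, classify_windows(s_lo, null_of(mu))).value
        assert hi >= base >= lo

    def test_degenerate_null_labels_everything_divergent(self):
        """With a zero-variance null every usable window ties the
        threshold and the index saturates at 1."""
        v1, v2 = constant_cohort(duration_ms=2000.0)
        series = dispersion_series(v1, v2)
        null = sample_null(v1, v2, n_samples=200, rng=0)
        assert null.sigma == 0.0
        igdi = compute_igdi(series, classify_windows(series, null))
        assert igdi.value == 1.0


class TestModelAgreement:
    def mk(self, f, usable=None):
        f = np.asarray(f, int)
        if usable is None:
            usable = np.ones(f.size, bool)
        return DivergenceLabels(f=f, usable=np.asarray(usable, bool))

    def test_identical_labels(self):
        a = self.mk([1, 0, 1, 0])
        assert model_agreement(a, self.mk([1, 0, 1, 0])) == 1.0

    def test_complementary_labels(self):
        assert model_agreement(self.mk([1, 1, 0, 0]), self.mk([0, 0, 1, 1])) == 0.0

    def test_half_agreement(self):
        assert model_agreement(self.mk([1, 1, 0, 0]), self.mk([1, 0, 0, 1])) == 0.5

    def test_only_jointly_usable_counted(self):
        # windows 1 and 2 are not jointly usable; only window 0 is compared
        a = self.mk([1, 1, 0], usable=[True, True, False])
        b = self.mk([1, 0, 0], usable=[True, False, True])
        assert model_agreement(a, b) == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ContractError):
            model_agreement(self.mk([1, 0]), self.mk([1, 0, 1]))
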