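"""Extrema segmentation and piece-wise rate estimation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from viroprod.series import (
    IncubationSeries,
    InvalidSeriesError,
    RateSet,
    UndefinedResultError,
    detect_extrema,
    dilution_correction_factor,
    loss_rate,
    net_rate,
    production_rate,
    rates_for_series,
    summarize_duplicates,
    turnover_time,
)

from conftest import make_series


def brute_force_extrema(times, values):
    """Independent definition: plateau-merge, then compare each neighbour.

    Interior maxima exceed both neighbours, minima lie below both;
    endpoints are typed by the direction of the adjacent segment.
    """
    merged = [
        (t, v)
        for i, (t, v) in enumerate(zip(times, values))
        if i == len(values) - 1 or values[i + 1] != v
    ]
    if len(merged) < 2:
        return []
    out = []
    for i, (t, v) in enumerate(merged):
        if i == 0:
            kind = "min" if merged[1][1] > v else "max"
        elif i == len(merged) - 1:
            kind = "max" if merged[i - 1][1] < v else "min"
        elif merged[i - 1][1] < v and merged[i + 1][1] < v:
            kind = "max"
        elif merged[i - 1][1] > v and merged[i + 1][1] > v:
            kind = "min"
        else:
            continue
        out.append((t, v, kind))
    return out


class TestDetectExtrema:
    def test_monotone_rise_has_two_boundary_extrema(self):
        s = make_series(np.linspace(1e5, 1.1e6, 9))
        seg = detect_extrema(s)
        assert [(p.time, p.kind) for p in seg.points] == [(0.0, "min"), (40.0, "max")]

    def test_interior_alternation_on_zigzag(self):
        s = make_series([5, 3, 6, 4], times=[0, 5, 10, 15])
        seg = detect_extrema(s)
        assert [(p.time, p.value, p.kind) for p in seg.points] == [
            (0.0, 5.0, "max"), (5.0, 3.0, "min"),
            (10.0, 6.0, "max"), (15.0, 4.0, "min"),
        ]

    def test_plateau_merged_to_last_point(self):
        s = make_series([1, 1, 2, 2, 1], times=[0, 5, 10, 15, 20])
        seg = detect_extrema(s)
        assert [(p.time, p.value, p.kind) for p in seg.points] == [
            (5.0, 1.0, "min"), (15.0, 2.0, "max"), (20.0, 1.0, "min"),
        ]

    def test_constant_series_is_degenerate(self):
        seg = detect_extrema(make_series([7, 7, 7, 7]))
        assert seg.degenerate and seg.points == ()

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidSeriesError):
            detect_extrema(make_series([1, 2], times=[0, 5]))

    def test_exhaustive_equivalence_with_brute_force(self):
        """All integer-grid series up to length 6 match the naive definition."""
        for n in (3, 4, 5, 6):
            times = [5.0 * i for i in range(n)]
            for values in itertools.product((0.0, 1.0, 2.0), repeat=n):
                s = make_series(values, times=times)
                seg = detect_extrema(s)
                expected = brute_force_extrema(times, list(values))
                got = [(p.time, p.value, p.kind) for p in seg.points]
                assert got == expected, values


class TestRates:
    def test_constant_series_has_zero_rates(self):
        s = make_series([5e5] * 9)
        assert production_rate(s) == 0.0
        assert loss_rate(s) == 0.0

    def test_single_rise_rate(self):
        s = make_series([5e5, 1.0e6, 1.5e6], times=[0, 20, 40])
        assert production_rate(s) == pytest.approx(2.5e4)
        assert loss_rate(s) == 0.0

    def test_single_fall_rate(self):
        s = make_series([9e5, 7e5, 5e5], times=[0, 20, 40])
        assert loss_rate(s) == pytest.approx(1.0e4)
        assert production_rate(s) == 0.0

    def test_sawtooth_rates(self, sawtooth):
        assert production_rate(sawtooth) == pytest.approx(5e5 / 40)
        assert loss_rate(sawtooth) == pytest.approx(7.5e3)
        assert net_rate(production_rate(sawtooth), loss_rate(sawtooth)) == (
            pytest.approx((5e5 - 3e5) / 40)
        )

    def test_production_equals_sum_of_positive_differences(self, rng):
        """Independent formula: sum of positive first differences / duration."""
        for _ in range(50):
            vals = rng.integers(0, 20, size=rng.integers(3, 12)).astype(float)
            s = make_series(vals)
            diffs = np.diff(vals)
            assert production_rate(s) == pytest.approx(
                diffs[diffs > 0].sum() / s.duration
            )
            assert loss_rate(s) == pytest.approx(
                -diffs[diffs < 0].sum() / s.duration
            )

    @given(
        hst.lists(
            hst.floats(min_value=0, max_value=1e7, allow_nan=False),
            min_size=3, max_size=12,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_telescoping_conservation(self, values):
        s = make_series(values)
        net = production_rate(s) - loss_rate(s)
        assert net * s.duration == pytest.approx(
            values[-1] - values[0], abs=1e-6 * max(max(values), 1.0)
        )

    @given(
        hst.lists(hst.integers(min_value=0, max_value=50), min_size=3, max_size=9),
        hst.floats(min_value=0.1, max_value=1e4),
        hst.floats(min_value=-30, max_value=30),
    )
    @settings(deadline=None, max_examples=100)
    def test_scale_and_time_shift_equivariance(self, values, c, dt):
        s = make_series(values)
        scaled = make_series([v * c for v in values])
        shifted = make_series(values, times=[t + dt for t in s.times])
        assert production_rate(scaled) == pytest.approx(c * production_rate(s))
        assert loss_rate(scaled) == pytest.approx(c * loss_rate(s))
        assert production_rate(shifted) == pytest.approx(production_rate(s))

    def test_dilution_correction_recovers_unscaled_rates(self, sawtooth):
        c = 2.5
        diluted = sawtooth.scaled(1.0 / c)
        assert c * production_rate(diluted) == pytest.approx(
            production_rate(sawtooth)
        )


class TestCorrectionAndTurnover:
    def test_correction_factor_identity_and_algebra(self):
        assert dilution_correction_factor(7.3e5, 7.3e5) == 1.0
        assert dilution_correction_factor(7.3e5, 1.46e6) == pytest.approx(0.5)
        with pytest.raises(InvalidSeriesError):
            dilution_correction_factor(0.0, 1e6)

    def test_turnover_examples(self):
        assert turnover_time(1.9e7, 1.872e4) == pytest.approx(42.3, abs=0.05)
        assert turnover_time(1000.0, 1000.0 / 24.0) == pytest.approx(1.0)
        with pytest.raises(UndefinedResultError):
            turnover_time(1e6, 0.0)

    def test_summarize_duplicates(self):
        s = summarize_duplicates([4, 6])
        assert (s.average, s.low, s.high) == (5.0, 4.0, 6.0)
        s = summarize_duplicates([3.03, 3.03])
        assert s.range_width == 0.0
        s = summarize_duplicates([3.2, 1.2])
        assert (s.average, s.low, s.high) == (pytest.approx(2.2), 1.2, 3.2)
        with pytest.raises(InvalidSeriesError):
            summarize_duplicates([])


class TestRateSet:
    def test_full_rate_set_with_correction(self, sawtooth):
        prok = make_series(
            [6e5, 7e5, 6.5e5, 8e5, 7.5e5], times=[0, 10, 20, 30, 40],
            population="prokaryote",
        )
        rs = rates_for_series(prok, sawtooth, correction_factor=0.8)
        assert rs.corrected
        assert rs.VP == pytest.approx(0.8 * production_rate(sawtooth))
        assert rs.VP_net == pytest.approx(rs.VP - rs.VD)
        assert rs.PG_net == pytest.approx(rs.PG - rs.mortality)

    def test_inconsistent_net_rate_rejected(self):
        with pytest.raises(ValueError):
            RateSet(PG=10, mortality=2, PG_net=5, VP=0, VD=0, VP_net=0)

    def test_invalid_series_inputs_rejected(self):
        with pytest.raises(InvalidSeriesError):
            IncubationSeries("s", "anoxic", "dilution", 1, "virus",
                             (0, 5, 10), (1.0, -2.0, 3.0))
        with pytest.raises(InvalidSeriesError):
            IncubationSeries("s", "anoxic", "dilution", 1, "virus",
                             (0, 5, 5), (1.0, 2.0, 3.0))
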