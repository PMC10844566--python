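"""Topographic prominence: analytic cases, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calwave.prominence_peaks import (
    PeakCallParams,
    detect_peaks,
    estimate_noise,
    find_local_maxima,
    topographic_prominence,
)
from calwave.roi_traces import Trace

from conftest import random_trace
from oracles import (
    oracle_all_prominences,
    oracle_local_maxima,
    oracle_prominence_linear,
)


def _trace(values, dt=1.0):
    return Trace("t", np.asarray(values, float), dt)


class TestLocalMaxima:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3, 3, 3, 3], []),
            ([0, 1, 5, 1, 0], [2]),
            ([0, 2, 2, 2, 0], [1]),  # plateau -> leftmost index
            ([5, 0, 5, 0, 9], [0, 2, 4]),  # boundary maxima allowed
            ([1, 2, 3], [2]),
            ([3, 2, 1], [0]),
            ([2, 2, 1], [0]),  # boundary plateau with lower inner neighbor
            ([1, 2, 2], [1]),
            ([7], []),  # single sample has no non-equal neighbor
            ([0, 1, 1, 2, 1], [3]),
        ],
    )
    def test_conventions(self, values, expected):
        assert find_local_maxima(values) == expected

    def test_matches_independent_enumeration(self, rng):
        for _ in range(200):
            v = random_trace(rng, int(rng.integers(1, 60)))
            assert find_local_maxima(v) == oracle_local_maxima(v)


class TestProminence:
    def test_single_peak_is_height_above_global_min(self):
        prom, lb, rb = topographic_prominence([0, 1, 5, 1, 0], 2)
        assert (prom, lb, rb) == (5.0, 0, 4)

    def test_two_peak_trace(self):
        # lower peak's contour sits at the intervening minimum
        assert topographic_prominence([0, 4, 1, 6, 0], 1)[0] == 3.0
        assert topographic_prominence([0, 4, 1, 6, 0], 3)[0] == 6.0

    def test_global_max_open_end_convention(self):
        # walls would give 5 - max(1, 0) = 4; open ends give height - global min
        assert topographic_prominence([3, 1, 5, 2, 0], 2)[0] == 5.0

    def test_non_maximum_rejected(self):
        with pytest.raises(ValueError, match="not a local maximum"):
            topographic_prominence([0, 1, 5, 1, 0], 1)

    def test_base_invariants(self, rng):
        for _ in range(100):
            v = random_trace(rng, int(rng.integers(5, 80)))
            gmin = v.min()
            for p in find_local_maxima(v):
                prom, lb, rb = topographic_prominence(v, p)
                assert 0 <= prom <= v[p] - gmin + 1e-12
                assert lb <= p <= rb
                assert v[lb] <= v[p] and v[rb] <= v[p]

    def test_global_max_attains_full_prominence_exactly_once(self, rng):
        for _ in range(100):
            v = rng.normal(size=int(rng.integers(5, 80)))  # ties a.s. absent
            full = v.max() - v.min()
            proms = [topographic_prominence(v, p)[0] for p in find_local_maxima(v)]
            assert sum(abs(pr - full) < 1e-12 for pr in proms) == 1

    def test_oracle_equivalence_seeded(self, rng):
        for _ in range(300):
            v = random_trace(rng, int(rng.integers(5, 120)))
            expected = oracle_all_prominences(v)
            got = {p: topographic_prominence(v, p)[0] for p in find_local_maxima(v)}
            assert got == pytest.approx(expected)

    def test_binary_and_linear_oracles_agree(self, rng):
        for _ in range(300):
            v = random_trace(rng, int(rng.integers(3, 14)))
            for p, prom in oracle_all_prominences(v).items():
                assert prom == oracle_prominence_linear(v, p)

    def test_scipy_agreement_on_interior_peaks(self, rng):
        # scipy's convention coincides with ours whenever strictly higher
        # samples exist on both sides of the peak
        from scipy.signal import peak_prominences

        checked = 0
        for _ in range(100):
            v = rng.normal(size=200)
            for p in find_local_maxima(v):
                higher_left = np.any(v[:p] > v[p])
                higher_right = np.any(v[p + 1 :] > v[p])
                if higher_left and higher_right:
                    (sp,), _, _ = peak_prominences(v, [p])
                    assert topographic_prominence(v, p)[0] == pytest.approx(sp)
                    checked += 1
        assert checked > 500

    @given(st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=25))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_flood_fill_oracle_property(self, values):
        v = np.asarray(values, float)
        expected = {p: oracle_prominence_linear(v, p) for p in oracle_local_maxima(v)}
        got = {p: topographic_prominence(v, p)[0] for p in find_local_maxima(v)}
        assert got == expected

    def test_translation_invariance_and_scale_equivariance(self, rng):
        v = random_trace(rng, 100)
        peaks = find_local_maxima(v)
        base = [topographic_prominence(v, p)[0] for p in peaks]
        shifted = [topographic_prominence(v + 7.3, p)[0] for p in peaks]
        scaled = [topographic_prominence(v * 2.5, p)[0] for p in peaks]
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx([2.5 * b for b in base])


class TestEstimateNoise:
    def test_constant_trace_is_zero(self):
        assert estimate_noise(_trace([4.0] * 10)) == 0.0

    def test_gaussian_scale_recovered(self, rng):
        v = rng.normal(0, 1.0, size=10_000)
        assert 0.9 <= estimate_noise(_trace(v)) <= 1.1

    def test_robust_to_one_transient(self, rng):
        v = rng.normal(0, 1.0, size=10_000)
        clean = estimate_noise(_trace(v))
        v2 = v.copy()
        v2[5000:5010] += 50.0 * np.exp(-np.arange(10) / 3.0)
        assert abs(estimate_noise(_trace(v2)) - clean) < 0.1 * clean

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise(_trace([1.0, 2.0]))


class TestDetectPeaks:
    def test_threshold_above_range_yields_nothing(self, rng):
        v = rng.normal(size=50)
        tr = _trace(v)
        params = PeakCallParams(min_prominence=float(v.max() - v.min()) + 1)
        assert detect_peaks(tr, params) == []

    def test_vanishing_threshold_returns_all_maxima(self, rng):
        v = rng.normal(size=50)
        tr = _trace(v)
        got = detect_peaks(tr, PeakCallParams(min_prominence=1e-12))
        assert [p.t_index for p in got] == find_local_maxima(v)

    def test_monotone_in_threshold(self, rng):
        v = rng.normal(size=200)
        tr = _trace(v)
        previous = None
        for thr in (0.1, 0.5, 1.0, 2.0, 4.0):
            idx = {p.t_index for p in detect_peaks(tr, PeakCallParams(min_prominence=thr))}
            if previous is not None:
                assert idx <= previous
            previous = idx

    def test_min_separation_keeps_more_prominent(self):
        v = np.array([0, 10, 8, 9, 0], float)
        tr = _trace(v)
        got = detect_peaks(
            tr, PeakCallParams(min_prominence=0.5, min_separation=3)
        )
        assert [p.t_index for p in got] == [1]

    def test_time_base_carried(self):
        tr = _trace([0, 1, 5, 1, 0], dt=5.0)
        (pk,) = detect_peaks(tr, PeakCallParams(min_prominence=1.0))
        assert pk.t_index == 2 and pk.t_seconds == 10.0

    def test_auto_threshold_on_flat_trace_rejected(self):
        tr = _trace([3.0] * 20)
        with pytest.raises(ValueError, match="not positive"):
            detect_peaks(tr, PeakCallParams(min_prominence="auto"))
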