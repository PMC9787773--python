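import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acmems.config import AcmeConfig
from acmems.detect import DetectionResult, PeakProperties
from acmems.errors import ConfigError, ValidationError
from acmems.priority import (
    DdVector,
    compute_dd,
    compute_sue,
    dd_distance,
    extract_sue_features,
    normalize_feature,
    observation_sue,
    rank_downlink,
)


def det_result(peaks):
    return DetectionResult(valid=peaks, candidates=list(peaks))


def peak(mz=100.0, time=50.0, z=20.0, bg_sd=10.0):
    return PeakProperties(
        center_mz=mz, center_time=time, height=z * bg_sd, volume=2000.0,
        width=6.0, z_score=z, gauss_loss=0.005, bg_level=50.0, bg_sd=bg_sd,
        bg_diff=0.0, bg_ratio=1.0, valid=True,
    )


class TestNormalization:
    def test_zero_maps_to_zero(self):
        assert normalize_feature(0.0, 100.0) == 0.0

    def test_saturation_branch(self):
        assert normalize_feature(100.0, 100.0) == 1.0
        assert normalize_feature(250.0, 100.0) == 1.0

    def test_square_root_rise(self):
        assert normalize_feature(25.0, 100.0) == pytest.approx(0.5)

    def test_bad_saturation_rejected(self):
        with pytest.raises(ConfigError):
            normalize_feature(1.0, 0.0)


class TestSue:
    def test_bounds(self):
        assert compute_sue([(1.0, 1.0), (1.0, 0.5)]) == 1.0
        assert compute_sue([(0.0, 1.0), (0.0, 0.5)]) == 0.0

    def test_weighted_average_by_hand(self):
        assert compute_sue([(1.0, 1.0), (0.0, 0.5)]) == pytest.approx(2 / 3)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ConfigError):
            compute_sue([(0.5, 0.0)])


class TestSueFeatures:
    def test_zero_peaks_zero_sue(self):
        result = det_result([])
        feats = extract_sue_features(result)
        assert all(v == 0.0 for v in feats.values())
        assert observation_sue(result) == 0.0

    def test_migration_time_bucketing_at_36s(self):
        result = det_result([peak(time=10.0), peak(mz=101.0, time=20.0)])
        feats = extract_sue_features(result)
        assert feats["unique_migration_times"] == 1.0

    def test_mz_bucketing_at_1amu(self):
        result = det_result([peak(mz=132.1, time=50.0), peak(mz=132.9, time=300.0)])
        feats = extract_sue_features(result)
        assert feats["unique_mz"] == 1.0

    def test_compound_list_matching(self):
        cfg = AcmeConfig()
        result = det_result([peak(mz=76.2), peak(mz=300.0)])  # glycine-ish + none
        feats = extract_sue_features(result, cfg)
        assert feats["priority_compound_peaks"] == 1.0

    def test_sue_monotone_in_peak_count(self):
        few = det_result([peak(mz=90.0 + i, time=40.0 * i) for i in range(3)])
        many = det_result([peak(mz=90.0 + i, time=40.0 * i) for i in range(9)])
        assert observation_sue(many) >= observation_sue(few)


class TestDd:
    def test_empty_observation_zero_vector(self):
        dd = compute_dd(det_result([]), bg_mean=0.0)
        np.testing.assert_allclose(dd.values, 0.0)

    def test_presence_bin_arithmetic(self):
        dd = compute_dd(det_result([peak(mz=132.0)]), bg_mean=0.0)
        presence = dd.values[2:]
        assert presence[6] == 1.0          # floor((132-70)/10) = 6
        assert presence.sum() == 1.0

    def test_background_saturation(self):
        dd = compute_dd(det_result([]), bg_mean=80.0)
        assert dd.values[0] == 1.0         # saturates at 50

    def test_linear_clamp_below_saturation(self):
        dd = compute_dd(det_result([]), bg_mean=25.0)
        assert dd.values[0] == pytest.approx(0.5)


class TestDdDistance:
    def mk(self, values, weights=None):
        values = np.asarray(values, dtype=float)
        w = np.ones_like(values) if weights is None else np.asarray(weights, float)
        return DdVector(values=values, weights=w)

    def test_identical_gives_zero(self):
        a = self.mk([0.3, 0.7, 1.0])
        assert dd_distance(a, a) == 0.0

    def test_maximal_difference_gives_one(self):
        a = self.mk([1.0, 1.0, 1.0])
        b = self.mk([0.0, 0.0, 0.0])
        assert dd_distance(a, b) == pytest.approx(1.0)

    def test_hand_derived_value(self):
        a = self.mk([1.0, 0.0])
        b = self.mk([0.0, 0.0])
        assert dd_distance(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            dd_distance(self.mk([1.0]), self.mk([1.0, 0.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8))
    def test_pseudometric_properties(self, values):
        rng = np.random.default_rng(0)
        n = len(values)
        a = self.mk(values)
        b = self.mk(rng.uniform(0, 1, n))
        c = self.mk(rng.uniform(0, 1, n))
        assert dd_distance(a, b) == pytest.approx(dd_distance(b, a))
        assert dd_distance(a, a) == 0.0
        assert dd_distance(a, c) <= dd_distance(a, b) + dd_distance(b, c) + 1e-12
        assert 0.0 <= dd_distance(a, b) <= 1.0


class _Bundle:
    def __init__(self, sue, dd, nbytes):
        self.sue = sue
        self.dd = np.asarray(dd, dtype=float)
        self.total_bytes = nbytes


class TestRanking:
    def test_single_bundle(self):
        assert rank_downlink([_Bundle(0.5, [0.0], 1000)]) == [0]

    def test_sue_per_byte_with_zero_penalty(self):
        small = _Bundle(0.5, [0.0], 1024)
        large = _Bundle(0.5, [0.0], 2048)
        assert rank_downlink([large, small], dd_penalty=0.0) == [1, 0]

    def test_zero_penalty_matches_full_sort_oracle(self):
        rng = np.random.default_rng(4)
        bundles = [
            _Bundle(float(rng.uniform(0, 1)), [0.0], int(rng.integers(500, 5000)))
            for _ in range(12)
        ]
        got = rank_downlink(bundles, dd_penalty=0.0)
        expected = sorted(range(12), key=lambda i: (-bundles[i].sue / bundles[i].total_bytes, i))
        assert got == expected

    def test_large_penalty_promotes_diversity(self):
        twin_a = _Bundle(0.9, [1.0, 0.0], 1000)
        twin_b = _Bundle(0.9, [1.0, 0.0], 1000)
        distinct = _Bundle(0.3, [0.0, 1.0], 1000)
        order = rank_downlink([twin_a, twin_b, distinct], dd_penalty=10.0)
        assert order[0] in (0, 1)
        assert order[1] == 2

    def test_priority_bins_strictly_first(self):
        low = _Bundle(0.99, [0.0], 100)
        high = _Bundle(0.01, [0.0], 10_000)
        order = rank_downlink([low, high], dd_penalty=0.0, bins=[0, 1])
        assert order == [1, 0]
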