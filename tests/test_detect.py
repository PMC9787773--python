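import numpy as np
import pytest
from scipy import ndimage

from acmems.config import DetectConfig
from acmems.detect import (
    apply_filter,
    characterize_peak,
    detect_peaks,
    dog_filter,
    estimate_background,
    find_candidates,
    subtract_background,
    PeakProperties,
)
from acmems.errors import ConfigError
from acmems.evaluate import match_detections

from conftest import make_obs, gaussian_peak_grid


class TestBackgroundEstimation:
    def test_constant_grid_reproduced(self):
        obs = make_obs(np.full((4, 300), 7.0))
        np.testing.assert_allclose(estimate_background(obs, 36.0), 7.0)

    def test_sliding_median_by_hand(self):
        # window of 3 bins at 1 s resolution: the spike is rejected
        obs = make_obs([[1.0, 1.0, 9.0, 1.0, 1.0]], dt=1.0)
        np.testing.assert_allclose(estimate_background(obs, 3.0), 1.0)

    def test_median_robust_to_narrow_peak(self):
        grid = gaussian_peak_grid((1, 400), 0, 200, height=100.0,
                                  sigma_mz_bins=1, sigma_t_bins=6, background=20.0)
        obs = make_obs(grid)
        bg = estimate_background(obs, 36.0)   # 73-bin window vs 36-bin peak
        assert abs(bg[0, 200] - 20.0) < 5.0   # < 5% of peak height

    def test_window_too_short_rejected(self):
        obs = make_obs(np.ones((2, 100)), dt=36.0)
        with pytest.raises(ConfigError):
            estimate_background(obs, 36.0)

    def test_window_longer_than_axis_rejected(self):
        obs = make_obs(np.ones((2, 10)))
        with pytest.raises(ConfigError):
            estimate_background(obs, 36.0)


class TestSubtraction:
    @pytest.mark.parametrize("counts,background,expected", [
        (5.0, 7.0, 0.0),    # clamped at zero
        (10.0, 3.0, 7.0),
        (4.0, 4.0, 0.0),
    ])
    def test_elementwise_clamped(self, counts, background, expected):
        out = subtract_background(np.full((2, 2), counts), np.full((2, 2), background))
        np.testing.assert_allclose(out, expected)


class TestDogFilter:
    def test_zero_sum_on_constant_field(self):
        out = dog_filter(np.full((160, 300), 50.0), DetectConfig())
        assert np.max(np.abs(out)) < 1e-9 * 50.0

    def test_impulse_reproduces_kernel(self):
        cfg = DetectConfig()
        field = np.zeros((201, 201))
        field[100, 100] = 1.0
        out = dog_filter(field, cfg)
        # independent kernel construction from normalized Gaussians
        def kern(sig_mz, sig_t):
            r = np.arange(201) - 100
            gm = np.exp(-0.5 * (r / (sig_mz / 0.08)) ** 2)
            gt = np.exp(-0.5 * (r / (sig_t / 0.5)) ** 2)
            k = np.outer(gm / gm.sum(), gt / gt.sum())
            return k
        expected = kern(*cfg.dog_sigma_small) - kern(*cfg.dog_sigma_large)
        center = expected[95:106, 95:106]
        np.testing.assert_allclose(out[95:106, 95:106], center, atol=3e-5)

    def test_positive_response_at_matched_blob(self):
        cfg = DetectConfig()
        grid = gaussian_peak_grid((160, 300), 80, 150, 100.0,
                                  cfg.dog_sigma_small[0] / 0.08,
                                  cfg.dog_sigma_small[1] / 0.5)
        out = dog_filter(grid, cfg)
        assert out[80, 150] > 0

    def test_kernel_larger_than_grid_rejected(self):
        with pytest.raises(ConfigError):
            dog_filter(np.ones((10, 10)), DetectConfig())


class TestCandidates:
    def test_all_zero_gives_empty(self):
        assert find_candidates(np.zeros((30, 30)), DetectConfig()) == []

    def test_single_impulse_single_candidate(self):
        dog = np.zeros((30, 30))
        dog[12, 17] = 3.0
        assert find_candidates(dog, DetectConfig()) == [(12, 17)]

    def test_equal_maxima_ordered_by_position(self):
        dog = np.zeros((40, 40))
        dog[5, 5] = 2.0
        dog[30, 30] = 2.0
        assert find_candidates(dog, DetectConfig()) == [(5, 5), (30, 30)]

    def test_agrees_with_bruteforce_enumeration(self):
        cfg = DetectConfig()
        hr, hc = 7, 2   # one small-kernel SD per axis at default resolutions
        rng = np.random.default_rng(11)
        for _ in range(20):
            dog = rng.normal(0, 1, size=(30, 50))
            got = set(find_candidates(dog, cfg))
            expected = set()
            for r in range(30):
                for c in range(50):
                    if dog[r, c] <= 0:
                        continue
                    window = dog[max(0, r - hr):r + hr + 1, max(0, c - hc):c + hc + 1]
                    if np.sum(window >= dog[r, c]) == 1:
                        expected.add((r, c))
            assert got == expected


class TestCharacterization:
    def test_noiseless_gaussian_self_fit(self):
        # height 100, sigma_t = 2 s on zero background
        grid = gaussian_peak_grid((60, 400), 30, 200, 100.0, 2.5, 4.0)
        obs = make_obs(grid)
        props = characterize_peak(obs, (30, 200), DetectConfig())
        assert props.height == pytest.approx(100.0, rel=0.02)
        assert props.width == pytest.approx(12.0, rel=0.05)
        assert props.gauss_loss < 1e-4
        assert props.bg_diff == pytest.approx(0.0, abs=1e-9)
        assert props.bg_ratio == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma_t_s", [1.0, 2.0, 3.5, 4.5])
    def test_width_recovery_within_5pct(self, sigma_t_s):
        sigma_bins = sigma_t_s / 0.5
        grid = gaussian_peak_grid((40, 400), 20, 200, 500.0, 2.0, sigma_bins)
        obs = make_obs(grid)
        props = characterize_peak(obs, (20, 200), DetectConfig())
        assert abs(props.width - 6 * sigma_t_s) / (6 * sigma_t_s) < 0.05

    def test_z_score_from_asymmetric_flanks(self):
        # B1 noise SD 2, B2 noise SD 4, peak height 40 -> z = 10
        rng = np.random.default_rng(0)
        crop = np.zeros((13, 121))
        noise1 = rng.normal(0, 1, size=(13, 56))
        noise2 = rng.normal(0, 1, size=(13, 56))
        # scale each flank so its robust (MAD-based) SD is exact
        for noise, target, cols in ((noise1, 2.0, slice(0, 56)),
                                    (noise2, 4.0, slice(65, 121))):
            med = np.median(noise)
            mad_sd = 1.4826 * np.median(np.abs(noise - med))
            crop[:, cols] = noise * (target / mad_sd)
        crop[:, 56:65] += gaussian_peak_grid((13, 9), 6, 4, 40.0, 2.0, 1.5)
        obs = make_obs(crop - crop.min())
        props = characterize_peak(obs, (6, 60), DetectConfig())
        assert props.z_score == pytest.approx(10.0, rel=0.15)
        assert props.bg_sd == pytest.approx(4.0, rel=0.15)

    def test_center_time_tracks_fitted_peak(self):
        grid = gaussian_peak_grid((40, 400), 20, 203, 300.0, 2.0, 4.0)
        obs = make_obs(grid)
        props = characterize_peak(obs, (20, 200), DetectConfig())
        assert props.center_time == pytest.approx(obs.time_axis[203], abs=0.6)


class TestFilter:
    CFG = DetectConfig()

    def make(self, **kw):
        base = dict(center_mz=100.0, center_time=50.0, height=50.0, volume=1000.0,
                    width=2.0, z_score=12.0, gauss_loss=0.01, bg_level=10.0,
                    bg_sd=2.0, bg_diff=0.0, bg_ratio=1.0)
        base.update(kw)
        return PeakProperties(**base)

    @pytest.mark.parametrize("kw,expected", [
        (dict(z_score=12.0, volume=1000.0, width=2.0, gauss_loss=0.01), True),
        (dict(z_score=6.0, volume=1000.0, width=2.0, gauss_loss=0.01), False),   # width rule for 5<z<=10
        (dict(z_score=6.0, volume=1000.0, width=3.0, gauss_loss=0.01), True),
        (dict(z_score=6.0, volume=400.0, width=3.0, gauss_loss=0.01), False),    # volume too small
        (dict(z_score=4.0, volume=1000.0, width=3.0, gauss_loss=0.01), False),   # z too small
        (dict(z_score=12.0, volume=1000.0, width=2.0, gauss_loss=0.03), False),  # non-Gaussian
        (dict(z_score=10.0, volume=1000.0, width=2.0, gauss_loss=0.01), False),  # z=10 uses low-z rule
        (dict(z_score=10.0, volume=1000.0, width=2.5, gauss_loss=0.01), True),
    ])
    def test_expert_system_rules(self, kw, expected):
        assert apply_filter(self.make(**kw), self.CFG) is expected


class TestDetectPipeline:
    def test_empty_grid_yields_nothing(self):
        obs = make_obs(np.zeros((160, 300)))
        result = detect_peaks(obs)
        assert result.valid == [] and result.candidates == []

    def test_valid_subset_of_candidates(self, mini_golden):
        result = detect_peaks(mini_golden.obs)
        assert set(id(p) for p in result.valid) <= set(id(p) for p in result.candidates)

    def test_recall_on_mini_golden(self, mini_golden):
        result = detect_peaks(mini_golden.obs)
        m = match_detections(result.valid, mini_golden.truth)
        assert m.fn <= 1
        assert m.fp <= 1

    def test_pure_noise_below_fp_requirement(self):
        from acmems.simulate import generate_golden
        s = generate_golden(seed=21, n_peaks=0, grid_shape=(300, 900))
        result = detect_peaks(s.obs)
        assert len(result.valid) < 50 * (300 * 900) / (600 * 2000)  # area-scaled

    def test_translation_equivariance(self):
        base = gaussian_peak_grid((160, 400), 80, 180, 400.0, 2.5, 4.0, background=0.0)
        shifted = np.roll(base, 30, axis=1)
        cfg = DetectConfig()
        c1 = detect_peaks(make_obs(base), cfg).valid
        c2 = detect_peaks(make_obs(shifted), cfg).valid
        assert len(c1) == len(c2) == 1
        assert c2[0].col - c1[0].col == 30

    def test_raising_z_threshold_never_adds_peaks(self, mini_golden):
        from dataclasses import replace
        result = detect_peaks(mini_golden.obs)
        counts = []
        for thr in [5.0, 8.0, 12.0, 20.0, 40.0]:
            cfg = replace(DetectConfig(), z_threshold=thr)
            counts.append(sum(apply_filter(p, cfg) for p in result.candidates))
        assert counts == sorted(counts, reverse=True)

    def test_over_sensitive_flag(self, mini_golden):
        from dataclasses import replace
        cfg = replace(DetectConfig(), max_peaks=2)
        result = detect_peaks(mini_golden.obs, cfg)
        assert result.over_sensitive
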