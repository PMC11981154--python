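"""Localization index, kinetochore quantification and trace classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sacsim as s
from sacsim import traces as tra


def _rise_plateau_fall(t_fall=400.0, rate=0.05, plateau=100.0,
                       t_end=800.0, budding=30.0, rise=30.0):
    t = np.arange(0.0, t_end, 10.0)
    up = np.clip((t - budding) / rise, 0.0, 1.0) * plateau
    sig = np.where(t < t_fall, up,
                   plateau * np.exp(-rate * (t - t_fall)))
    return t, sig


class TestLocalizationIndex:
    def test_uniform_image_responds_with_kernel_sum(self):
        v = 50.0
        img = np.full((9, 9), v)
        mask = np.ones_like(img, dtype=bool)
        ks = tra.LOG_KERNEL.sum()
        assert tra.log_localization_index(img, mask) == pytest.approx(
            ks * v, abs=1e-9)
        assert abs(ks * v) < 0.01  # near-zero response to diffuse signal

    def test_single_bright_pixel_scales_with_center_weight(self):
        img = np.zeros((9, 9))
        img[4, 4] = 200.0
        mask = np.ones_like(img, dtype=bool)
        assert tra.log_localization_index(img, mask) == pytest.approx(
            0.0187 * 200.0)

    def test_all_zero_image(self):
        img = np.zeros((5, 5))
        assert tra.log_localization_index(img, img == 0) == 0.0

    def test_empty_mask_rejected(self):
        img = np.zeros((5, 5))
        with pytest.raises(ValueError):
            tra.log_localization_index(img, img > 1)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(0.1, 1e3), st.integers(3, 9), st.integers(3, 9))
    def test_linear_in_intensity_and_translation_invariant(self, a, r, c):
        img = np.zeros((13, 13))
        img[r, c] = 1.0
        mask = np.ones_like(img, dtype=bool)
        base = tra.log_localization_index(img, mask)
        scaled = tra.log_localization_index(a * img, mask)
        assert scaled == pytest.approx(a * base, rel=1e-9)
        assert base == pytest.approx(0.0187, rel=1e-9)


class TestKinetochoreSignal:
    def test_delta_spot_sums_to_itself(self):
        img = np.zeros((11, 11))
        img[5, 5] = 77.0
        total, clipped = tra.kinetochore_signal(img, (5, 5))
        assert total == 77.0 and not clipped

    def test_uniform_image_sums_window_area(self):
        img = np.full((11, 11), 3.0)
        total, clipped = tra.kinetochore_signal(img, (5, 5))
        assert total == pytest.approx(25 * 3.0) and not clipped

    def test_gaussian_spot_recovers_96_percent_of_integral(self):
        # numerically, a sigma=1 px Gaussian keeps ~96% of its mass in 5x5
        img, _, truth = s.make_spot_image(size=21, amplitude=40.0,
                                          background=0.0, noise=0.0)
        total, _ = tra.kinetochore_signal(img, truth["center"])
        assert total == pytest.approx(0.96 * 2 * np.pi * 40.0, rel=0.03)

    def test_border_window_renormalized_and_flagged(self):
        img = np.full((11, 11), 2.0)
        total, clipped = tra.kinetochore_signal(img, (0, 0))
        assert clipped
        assert total == pytest.approx(25 * 2.0)  # area-renormalized

    def test_peak_outside_image_rejected(self):
        with pytest.raises(ValueError):
            tra.kinetochore_signal(np.zeros((7, 7)), (9, 3))


class TestMad2Localization:
    def test_flat_series_never_localized(self):
        t = np.arange(0.0, 300.0, 10.0)
        trace = tra.CellTrace(t, np.ones_like(t), np.ones_like(t))
        assert not tra.mad2_localized(trace).any()

    def test_doubling_after_g1_is_localized(self):
        t = np.arange(0.0, 300.0, 10.0)
        idx = np.where(t > 30.0, 2.0, 1.0)
        trace = tra.CellTrace(t, np.ones_like(t), idx)
        loc = tra.mad2_localized(trace)
        assert loc[t > 30.0].all() and not loc[t <= 30.0].any()

    def test_boundary_is_strict(self):
        t = np.arange(0.0, 300.0, 10.0)
        idx = np.where(t > 30.0, 1.10, 1.0)  # exactly at the 110% threshold
        trace = tra.CellTrace(t, np.ones_like(t), idx)
        assert not tra.mad2_localized(trace).any()

    def test_missing_calibration_window_rejected(self):
        t = np.arange(100.0, 300.0, 10.0)
        trace = tra.CellTrace(t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError):
            tra.mad2_threshold(trace)


class TestDegradationDetection:
    def test_monotone_rise_has_no_onset(self):
        t = np.arange(0.0, 500.0, 10.0)
        trace = tra.CellTrace(t, np.linspace(0, 100, t.size),
                              np.ones_like(t), budding_time=30.0)
        assert tra.clb2_degradation_time(trace) is None

    def test_noise_free_onset_recovered_exactly(self):
        t, sig = _rise_plateau_fall(t_fall=400.0)
        trace = tra.CellTrace(t, sig, np.ones_like(t), budding_time=30.0)
        assert tra.clb2_degradation_time(trace) == 400.0

    def test_noisy_onset_within_one_frame(self):
        t, sig = _rise_plateau_fall(t_fall=400.0)
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = sig + rng.normal(0.0, 2.0, t.size)  # 2% of plateau
            trace = tra.CellTrace(t, noisy, np.ones_like(t),
                                  budding_time=30.0)
            td = tra.clb2_degradation_time(trace)
            hits += td is not None and abs(td - 400.0) <= 10.0
        assert hits / 200 >= 0.95

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 50.0, 10.0)
        trace = tra.CellTrace(t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError):
            tra.clb2_degradation_time(trace)


class TestDegradationRate:
    @pytest.mark.parametrize("rate", [0.005, 0.01, 0.05, 0.1, 0.2])
    def test_unbiased_on_noise_free_exponentials(self, rate):
        t, sig = _rise_plateau_fall(t_fall=400.0, rate=rate)
        trace = tra.CellTrace(t, sig, np.ones_like(t), budding_time=30.0)
        assert tra.clb2_degradation_rate(trace, 400.0) == pytest.approx(
            rate, rel=1e-6)

    def test_constant_signal_has_zero_rate(self):
        t = np.arange(0.0, 500.0, 10.0)
        trace = tra.CellTrace(t, np.full(t.size, 80.0), np.ones_like(t))
        assert tra.clb2_degradation_rate(trace, 100.0) == pytest.approx(0.0)

    def test_rising_signal_has_negative_rate(self):
        t = np.arange(0.0, 500.0, 10.0)
        trace = tra.CellTrace(t, np.linspace(1.0, 100.0, t.size),
                              np.ones_like(t))
        assert tra.clb2_degradation_rate(trace, 100.0) < 0.0

    def test_too_few_points_rejected(self):
        t, sig = _rise_plateau_fall()
        trace = tra.CellTrace(t, sig, np.ones_like(t))
        with pytest.raises(ValueError):
            tra.clb2_degradation_rate(trace, 790.0)


class TestClb2Classification:
    def test_never_degrading_is_arrested(self):
        t = np.arange(0.0, 800.0, 10.0)
        up = np.clip((t - 30.0) / 30.0, 0.0, 1.0) * 100.0
        trace = tra.CellTrace(t, up, np.ones_like(t), budding_time=30.0)
        assert tra.classify_clb2_behavior(trace) == "arrested"

    def test_slow_rate_is_partial(self):
        t, sig = _rise_plateau_fall(rate=0.005)
        trace = tra.CellTrace(t, sig, np.ones_like(t), budding_time=30.0)
        assert tra.classify_clb2_behavior(trace) == "partial"

    def test_fast_and_complete_is_full(self):
        t, sig = _rise_plateau_fall(rate=0.05)
        trace = tra.CellTrace(t, sig, np.ones_like(t), budding_time=30.0)
        assert tra.classify_clb2_behavior(trace) == "full"


class TestAdaptationCall:
    def _trace(self, deloc_offset):
        t, sig = _rise_plateau_fall(t_fall=400.0)
        idx = np.where(t < 400.0 + deloc_offset, 2.0, 1.0)
        idx[t <= 60.0] = 1.0  # G1 baseline
        return tra.CellTrace(t, sig, idx, budding_time=30.0)

    def test_localized_at_onset_is_adaptation(self):
        assert tra.classify_adaptation(self._trace(+40.0)) == "adapted"

    def test_delocalized_at_onset_is_exit(self):
        assert tra.classify_adaptation(self._trace(-40.0)) == "exited"

    def test_partial_trace_not_applicable(self):
        t, sig = _rise_plateau_fall(rate=0.005)
        trace = tra.CellTrace(t, sig, np.full(t.size, 2.0),
                              budding_time=30.0)
        assert tra.classify_adaptation(trace) == "not-applicable"


class TestMissegregation:
    def test_boundary_probabilities(self):
        assert tra.missegregation_probability(0.0, 16) == 0.0
        assert tra.missegregation_probability(1.0, 16) == 1.0

    def test_sixteen_chromosomes_at_observed_rate(self):
        assert tra.missegregation_probability(0.075, 16) == pytest.approx(
            0.712745, abs=5e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tra.missegregation_probability(1.5, 16)
        with pytest.raises(ValueError):
            tra.missegregation_probability(0.5, 0)

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(0.0, 1.0), st.integers(1, 32))
    def test_monotone_in_both_arguments(self, p, n):
        q = tra.missegregation_probability(p, n)
        assert 0.0 <= q <= 1.0
        assert tra.missegregation_probability(p, n + 1) >= q
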