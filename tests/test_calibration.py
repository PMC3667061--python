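import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import cawave as cw
from cawave.calibration import (
    DecayFit,
    apply_shift,
    correct_marker_decay,
    starlet_decompose,
)
from cawave.exceptions import (
    DecayCorrectionError,
    InsufficientDataError,
    ParameterError,
)
from cawave.io_seq import FrameSequence
from cawave.synthgen import _texture


def textured_frame(shape=(64, 64), seed=0, amplitude=0.3):
    rng = np.random.default_rng(seed)
    return 0.4 * _texture(shape, amplitude, rng)


def ratio_seq_from(stack, frame_period=1.0, stimulus_frame=None, **kw):
    stack = np.asarray(stack, dtype=np.float64)
    if stimulus_frame is None:
        stimulus_frame = len(stack) - 1
    elif stimulus_frame == len(stack):
        # all frames pre-stimulus: pad a dummy post-stimulus frame
        stack = np.concatenate([stack, stack[-1:]])
    return FrameSequence(stack, ["ratio"] * len(stack), frame_period, stimulus_frame, **kw)


class TestStarlet:
    def test_constant_image_gives_zero_layer(self):
        out = cw.starlet_prefilter(np.full((32, 32), 0.7))
        np.testing.assert_array_equal(out, 0.0)

    def test_impulse_response_maximal_at_impulse(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        for scale in (1, 2):
            out = cw.starlet_prefilter(img, keep_scale=scale)
            assert np.unravel_index(np.argmax(out), out.shape) == (16, 16)

    def test_reconstruction_against_convolution_oracle(self, rng):
        """Sum of detail layers + final smooth equals the input (a trous oracle)."""
        img = rng.random((40, 37))
        # independent oracle: explicit 2-D convolution with the dilated B3 kernel
        b3 = np.array([1, 4, 6, 4, 1]) / 16.0
        c = img.copy()
        details = []
        for j in range(3):
            k1 = np.zeros(4 * 2**j + 1)
            k1[:: 2**j] = b3
            kernel2d = np.outer(k1, k1)
            smooth = ndimage.convolve(c, kernel2d, mode="reflect")
            details.append(c - smooth)
            c = smooth
        mine_details, mine_smooth = starlet_decompose(img, 3)
        for a, b in zip(details, mine_details):
            np.testing.assert_allclose(a, b, atol=1e-10)
        np.testing.assert_allclose(sum(mine_details) + mine_smooth, img, atol=1e-6)

    def test_output_range_and_keep_scale_validation(self, rng):
        out = cw.starlet_prefilter(rng.random((20, 20)), keep_scale=2)
        assert out.min() >= 0.0 and out.max() <= 1.0
        with pytest.raises(ParameterError):
            cw.starlet_prefilter(rng.random((20, 20)), keep_scale=3)


class TestRegistration:
    @pytest.mark.parametrize("shift", [(3, 0), (0, -4), (5, 5), (-2, 3)])
    def test_exact_circular_shift_recovered(self, shift):
        frame = textured_frame(seed=1)
        rolled = np.roll(frame, shift, axis=(0, 1))
        assert cw.register_translation(frame, rolled) == shift

    def test_cross_channel_vertical_misregistration(self):
        """3 px vertical offset between a 340 and a 380 frame is recovered
        despite the different intensity mappings of the two filters."""
        base = textured_frame(seed=2)
        f340 = 1.0 * base
        f380 = 0.4 * base + 0.05  # different gain and offset
        assert cw.register_translation(f340, np.roll(f380, (3, 0), axis=(0, 1)))[0] == 3

    def test_monte_carlo_shift_recovery_with_noise(self):
        rng = np.random.default_rng(42)
        hits = 0
        frame = textured_frame(seed=3)
        for _ in range(50):
            true = (int(rng.integers(-5, 6)), int(rng.integers(-5, 6)))
            noisy = np.roll(frame, true, axis=(0, 1)) + rng.normal(0, 0.01, frame.shape)
            if cw.register_translation(frame, noisy) == true:
                hits += 1
        assert hits >= 48

    def test_featureless_input_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert cw.register_translation(np.zeros((16, 16)), np.zeros((16, 16))) == (0, 0)

    def test_apply_negated_shift_aligns(self):
        frame = textured_frame(seed=4)
        moved = np.roll(frame, (2, -3), axis=(0, 1))
        s = cw.register_translation(frame, moved)
        aligned = apply_shift(moved, (-s[0], -s[1]))
        # interior agrees exactly; edges are replicated
        np.testing.assert_allclose(aligned[5:-5, 5:-5], frame[5:-5, 5:-5], atol=1e-12)

    def test_register_sequence_undoes_generator_shifts(self):
        rng = np.random.default_rng(0)
        shifts = [(0, 0)] + [tuple(rng.integers(-4, 5, 2)) for _ in range(23)]
        truth = cw.make_truth((64, 64), noise_sigma=0.0,
                              shift_per_frame=[(int(a), int(b)) for a, b in shifts])
        seq, _ = cw.generate_experiment((64, 64), 12, 1.25, truth, seed=5)
        _, est = cw.register_sequence(seq)
        assert est == [(int(a), int(b)) for a, b in shifts]


class TestComputeRatio:
    def test_constant_channels(self):
        frames = np.stack([np.full((8, 8), 0.5), np.full((8, 8), 0.25)] * 2)
        seq = FrameSequence(frames, ["340", "380"] * 2, 1.0, 0)
        ratio = cw.compute_ratio(seq)
        assert ratio.channel_labels == ["ratio", "ratio"]
        np.testing.assert_allclose(ratio.frames, 2.0, rtol=1e-5)

    def test_zero_denominator_guarded(self):
        frames = np.stack([np.full((4, 4), 0.5), np.zeros((4, 4))])
        seq = FrameSequence(frames, ["340", "380"], 1.0, 0)
        out = cw.compute_ratio(seq).frames
        assert np.all(np.isfinite(out))
        assert np.all(out <= 0.5 / 1e-6 + 1)

    def test_matches_ground_truth_ratio(self, noiseless_seq, noiseless_truth):
        ratio = cw.compute_ratio(noiseless_seq).frames.astype(np.float64)
        t = np.arange(40) * 1.25
        truth = noiseless_truth
        expected = np.empty_like(ratio)
        for i, ti in enumerate(t):
            dt = ti - truth.t0_map
            gate = (dt >= 0) & truth.footprint
            f = np.where(gate, truth.amplitude_map * np.exp(-np.clip(dt, 0, None) / truth.tau_map), 0.0)
            expected[i] = truth.basal_ratio + f
        assert np.max(np.abs(ratio - expected)) < 1e-3

    def test_negative_intensity_rejected(self):
        frames = np.stack([np.full((4, 4), -0.1), np.full((4, 4), 0.2)])
        with pytest.raises(ParameterError):
            cw.compute_ratio(FrameSequence(frames, ["340", "380"], 1.0, 0))


class TestMarkerDecay:
    def test_exact_exponential_recovered(self):
        t = np.arange(30) * 1.0
        flux = 10.0 * np.exp(-t / 50.0)
        stack = flux[:, None, None] * np.ones((1, 1)) / 1.0  # 1x1 frames carry the flux
        fit = cw.fit_marker_decay(ratio_seq_from(stack, stimulus_frame=30))
        assert fit.amplitude == pytest.approx(10.0, rel=1e-6)
        assert fit.efold_time == pytest.approx(50.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.0, abs=1e-4)

    def test_constant_flux_gives_unit_correction(self):
        stack = np.ones((10, 4, 4)) * 0.3
        seq = ratio_seq_from(stack, stimulus_frame=10)
        fit = cw.fit_marker_decay(seq)
        corrected = correct_marker_decay(seq, fit)
        np.testing.assert_allclose(corrected.frames, seq.frames, rtol=1e-6)

    def test_noisy_efold_recovery(self):
        rng = np.random.default_rng(3)
        t = np.arange(50) * 2.5  # 50 basal frames, ~2 e-folds of span
        errs = []
        for _ in range(100):
            flux = 100.0 * np.exp(-t / 60.0)
            flux = flux * (1 + rng.normal(0, 0.01, flux.shape))
            stack = flux[:, None, None] * np.ones((1, 1))
            fit = cw.fit_marker_decay(ratio_seq_from(stack, frame_period=2.5, stimulus_frame=50))
            errs.append(abs(fit.efold_time - 60.0) / 60.0)
        assert np.median(errs) < 0.05

    def test_insufficient_basal_frames(self):
        with pytest.raises(InsufficientDataError):
            cw.fit_marker_decay(ratio_seq_from(np.ones((6, 2, 2)), stimulus_frame=3))

    def test_self_correction_flattens_flux(self):
        t = np.arange(20) * 1.0
        flux = 5.0 * np.exp(-t / 30.0) + 2.0
        stack = flux[:, None, None] * np.ones((3, 3)) / 9.0
        seq = ratio_seq_from(stack, stimulus_frame=20)
        corrected = correct_marker_decay(seq, cw.fit_marker_decay(seq))
        total = corrected.frames[:20].sum(axis=(1, 2))
        np.testing.assert_allclose(total, total[0], rtol=1e-6)

    def test_zero_amplitude_is_identity(self):
        stack = np.random.default_rng(0).random((8, 4, 4))
        seq = ratio_seq_from(stack)
        fit = DecayFit(0.0, 10.0, 1.0, (0, 8))
        np.testing.assert_allclose(
            correct_marker_decay(seq, fit).frames, stack.astype(np.float32), rtol=1e-6
        )

    def test_nonpositive_extrapolated_flux_refused(self):
        stack = np.ones((8, 2, 2))
        seq = ratio_seq_from(stack, frame_period=10.0)
        fit = DecayFit(5.0, 10.0, -4.9, (0, 8))  # goes negative within the span
        with pytest.raises(DecayCorrectionError):
            correct_marker_decay(seq, fit)

    def test_corrects_channel_decay_bias(self):
        """With different 340/380 bleach rates, correction flattens the
        pre-stimulus flux slope to <= 5% of its uncorrected value."""
        truth = cw.make_truth((48, 48), noise_sigma=0.0, decay_340=120.0, decay_380=300.0)
        seq, _ = cw.generate_experiment((48, 48), 25, 1.25, truth, seed=2)
        ratio = cw.compute_ratio(seq)
        pre = slice(0, truth.stimulus_frame)
        t = ratio.times()[pre]

        def slope(frames):
            return np.polyfit(t, frames[pre].sum(axis=(1, 2)), 1)[0]

        raw_slope = slope(ratio.frames)
        fit = cw.fit_marker_decay(ratio)
        corr_slope = slope(correct_marker_decay(ratio, fit).frames)
        assert abs(corr_slope) <= 0.05 * abs(raw_slope)


class TestEstimateBasal:
    def test_identical_frames(self):
        frame = np.random.default_rng(1).random((8, 8))
        seq = ratio_seq_from(np.stack([frame] * 5), stimulus_frame=5)
        np.testing.assert_allclose(cw.estimate_basal(seq), frame, rtol=1e-6)

    def test_gross_outlier_rejected(self):
        series = np.array([1.0, 1.0, 1.0, 1.0, 100.0])
        stack = series[:, None, None] * np.ones((2, 2))
        basal = cw.estimate_basal(ratio_seq_from(stack, stimulus_frame=5), sigma=2.0)
        np.testing.assert_allclose(basal, 1.0)

    def test_brute_force_oracle_exact(self, rng):
        seq = ratio_seq_from(rng.random((20, 12, 12)), stimulus_frame=20)
        basal = cw.estimate_basal(seq, sigma=2.0)
        stored = np.asarray(seq.frames[:20], dtype=np.float64)  # 32-bit stored frames
        for r, c in rng.integers(0, 12, size=(50, 2)):
            v = stored[:, r, c]
            m, s = v.mean(), v.std()
            kept = v[np.abs(v - m) < 2.0 * s]
            expected = kept.mean() if kept.size else m
            assert basal[r, c] == expected

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(3.0, 50.0))
    def test_huge_sigma_equals_plain_mean(self, seed, sigma_big):
        seq = ratio_seq_from(np.random.default_rng(seed).random((8, 4, 4)), stimulus_frame=8)
        basal = cw.estimate_basal(seq, sigma=1e9)
        plain = np.asarray(seq.frames[:8], dtype=np.float64).mean(axis=0)
        np.testing.assert_array_equal(basal, plain)

    def test_gaussian_noise_statistical_accuracy(self):
        rng = np.random.default_rng(8)
        n = 30
        truth = 2.0
        stack = truth + rng.normal(0, 0.05, (n, 32, 32))
        basal = cw.estimate_basal(ratio_seq_from(stack, stimulus_frame=n))
        bound = 3 * 0.05 / np.sqrt(n)
        assert np.mean(np.abs(basal - truth) <= bound) >= 0.99

    def test_single_frame_warns(self):
        with pytest.warns(UserWarning):
            basal = cw.estimate_basal(ratio_seq_from(np.ones((2, 3, 3)), stimulus_frame=1))
        np.testing.assert_array_equal(basal, 1.0)


class TestExtractWave:
    def test_ratio_equal_basal_gives_zero_wave(self):
        basal = np.random.default_rng(2).random((8, 8))
        seq = ratio_seq_from(np.stack([basal] * 4))
        wave = cw.extract_wave(seq, basal, median_kernel=1)
        np.testing.assert_allclose(wave.wave, 0.0, atol=1e-6)
        np.testing.assert_allclose(wave.stats.maximum, 0.0, atol=1e-6)

    def test_truncation_of_negative_excess(self):
        basal = np.full((4, 4), 1.0)
        seq = ratio_seq_from(np.full((3, 4, 4), 0.8))
        wave = cw.extract_wave(seq, basal, median_kernel=1)
        np.testing.assert_array_equal(wave.wave, 0.0)

    def test_stats_against_direct_arithmetic(self):
        series = np.array([0.0, 0.3, 0.1])
        stack = series[:, None, None] * np.ones((2, 2))
        seq = ratio_seq_from(stack, frame_period=1.0)
        wave = cw.extract_wave(seq, np.zeros((2, 2)), median_kernel=1)
        assert wave.stats.maximum[0, 0] == pytest.approx(0.3)
        assert wave.stats.time_of_maximum[0, 0] == pytest.approx(1.0)
        assert wave.stats.mean[0, 0] == pytest.approx(series.mean())
        assert wave.stats.std[0, 0] == pytest.approx(series.std())

    def test_even_or_large_kernel_rejected(self, calibrated):
        seq = ratio_seq_from(np.ones((3, 4, 4)))
        for k in (2, 7):
            with pytest.raises(ParameterError):
                cw.extract_wave(seq, np.ones((4, 4)), median_kernel=k)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-0.5, 0.5))
    def test_nonnegative_and_offset_invariant(self, seed, offset):
        rng = np.random.default_rng(seed)
        stack = rng.random((5, 8, 8))
        basal = rng.random((8, 8))
        a = cw.extract_wave(ratio_seq_from(stack), basal, 3)
        b = cw.extract_wave(ratio_seq_from(stack + offset), basal + offset, 3)
        assert (a.wave >= 0).all()
        np.testing.assert_allclose(a.wave, b.wave, atol=1e-7)

    def test_time_of_max_monotone_with_radius_on_clean_wave(
        self, calibrated, noiseless_truth
    ):
        """The wave front arrives later farther out: ring-averaged time of
        maximum increases with distance from the source."""
        rt = cw.ring_profile(
            calibrated.wave, noiseless_truth.source, 25, frame_period=1.25
        )
        t_of_max = np.argmax(rt.values, axis=0)
        diffs = np.diff(t_of_max.astype(float))
        assert (diffs >= 0).all()


class TestCalibratePipeline:
    def test_basal_matches_truth_under_clean_conditions(self, noiseless_seq, noiseless_truth):
        cal = cw.calibrate(noiseless_seq, register=True, decay_correct=False)
        np.testing.assert_allclose(
            cal.basal, noiseless_truth.basal_ratio, atol=2e-3
        )

    def test_decay_correction_idempotent_on_flat_sequences(self):
        stack = np.full((12, 6, 6), 0.5)
        seq = ratio_seq_from(stack, stimulus_frame=12)
        fit = cw.fit_marker_decay(seq)
        once = correct_marker_decay(seq, fit)
        twice = correct_marker_decay(once, cw.fit_marker_decay(once))
        np.testing.assert_allclose(once.frames, twice.frames, rtol=1e-6)
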