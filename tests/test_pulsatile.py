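import numpy as np
import pytest

import pulsemap as pm
from pulsemap import EHRResult, NonSquareClipError, VideoClip
from pulsemap.pulsatile import PAD, min_peak_distance

from _oracles import brute_min_distance_peaks


def clip_of(frames, labels=("B", "G", "R"), fps=30.0):
    return VideoClip(frames=frames, fps=fps, channel_labels=labels)


def sinusoid_stack(f0=1.25, t=120, h=6, w=6, fs=30.0, amp=5.0, noise=0.0, seed=0,
                   phase=0.0):
    rng = np.random.default_rng(seed)
    tt = np.arange(t) / fs
    sig = amp * np.sin(2 * np.pi * f0 * tt + phase)
    stack = np.tile(sig[:, None, None], (1, h, w)) + 128.0
    if noise:
        stack += rng.normal(0, noise, stack.shape)
    return stack


class TestReshaping:
    def test_constant_clip_stays_constant(self):
        clip = clip_of(np.full((4, 60, 60, 3), 77.0))
        low = pm.reshape_low_res(clip)
        high = pm.reshape_high_res(clip)
        np.testing.assert_allclose(low.frames, 77.0, rtol=1e-6)
        np.testing.assert_allclose(high.frames, 77.0, rtol=1e-6)
        assert low.frames.shape == (4, 56, 56, 3)
        assert high.frames.shape == (4, 224, 224, 3)

    def test_non_square_rejected(self):
        clip = clip_of(np.zeros((2, 40, 50, 3)))
        with pytest.raises(NonSquareClipError):
            pm.reshape_low_res(clip)

    def test_nir_uses_smaller_block(self):
        clip = clip_of(np.full((2, 40, 40, 1), 10.0), labels=("NIR",))
        low = pm.reshape_low_res(clip)  # 5x5 block -> 8x8 -> 56x56
        assert low.frames.shape == (2, 56, 56, 1)
        np.testing.assert_allclose(low.frames, 10.0, rtol=1e-6)

    def test_noise_variance_reduced_by_block_averaging(self):
        rng = np.random.default_rng(0)
        clip = clip_of(rng.normal(100, 4, size=(200, 60, 60, 3)))
        low = pm.reshape_low_res(clip)
        centre = low.frames[:, 20:36, 20:36, 1]
        ratio = centre.var(axis=0).mean() / 16.0
        # 10x10 averaging alone gives 1/100; bi-cubic mixing keeps the order
        assert ratio < 0.05

    def test_pulse_frequency_survives_reshaping(self):
        geo = pm.SceneGeometry(height=160, width=160)
        model = pm.SyntheticSkinModel(pulse_frequency_hz=1.5, noise_sd=0.0)
        clip, truth = pm.generate_synthetic_clip(model, geo, 120, 30.0, seed=0)
        low = pm.reshape_low_res(clip)
        sig = low.frames[:, 28, 28, 1]
        sig = sig - sig.mean()
        freqs = np.fft.rfftfreq(120, d=1 / 30.0)
        assert freqs[np.argmax(np.abs(np.fft.rfft(sig)))] == pytest.approx(1.5)


class TestMinDistance:
    def test_formula(self):
        # T_HR / T_S = 24 samples at 1.25 Hz, 30 fps -> d = floor(18) = 18
        assert min_peak_distance(EHRResult(1.25), 30.0) == 18

    def test_floor_and_lower_bound(self):
        assert min_peak_distance(EHRResult(3.5), 30.0) == 6  # floor(6.43)
        assert min_peak_distance(EHRResult(100.0), 30.0) == 1


class TestDetectPeaksTroughs:
    def test_sinusoid_yields_five_peaks(self):
        clip = clip_of(sinusoid_stack()[..., None], labels=("G",))
        idx = pm.detect_peaks_troughs(clip, "G", EHRResult(1.25))
        assert idx.min_distance == 18
        # 1.25 Hz over 4 s = 5 cycles -> 5 peaks at every pixel
        assert (idx.peak_idx != PAD).sum(axis=-1).min() == 5
        assert (idx.trough_idx != PAD).sum(axis=-1).min() == 5

    def test_constant_pixel_fully_padded(self):
        frames = np.full((120, 4, 4, 1), 55.0)
        clip = clip_of(frames, labels=("G",))
        idx = pm.detect_peaks_troughs(clip, "G", EHRResult(1.2))
        assert (idx.peak_idx == PAD).all()
        assert (idx.trough_idx == PAD).all()

    def test_peaks_and_troughs_interleave(self):
        clip = clip_of(sinusoid_stack(f0=1.4, phase=0.7)[..., None], labels=("G",))
        idx = pm.detect_peaks_troughs(clip, "G", EHRResult(1.4))
        peaks = idx.peak_idx[0, 0][idx.peak_idx[0, 0] != PAD]
        troughs = idx.trough_idx[0, 0][idx.trough_idx[0, 0] != PAD]
        for a, b in zip(peaks, peaks[1:]):
            assert ((troughs > a) & (troughs < b)).sum() == 1

    def test_min_distance_respected(self):
        clip = clip_of(sinusoid_stack(f0=3.0, noise=0.5)[..., None], labels=("G",))
        idx = pm.detect_peaks_troughs(clip, "G", EHRResult(3.0))
        stored = idx.peak_idx[2, 3]
        stored = stored[stored != PAD]
        assert np.diff(stored).min() >= idx.min_distance

    @pytest.mark.parametrize("case_seed", range(4))
    def test_matches_greedy_oracle_on_noisy_clips(self, case_seed):
        rng = np.random.default_rng(case_seed)
        f0 = float(rng.uniform(1.0, 3.0))
        stack = sinusoid_stack(f0=f0, h=5, w=5, noise=1.0, seed=case_seed)
        clip = clip_of(stack[..., None], labels=("G",))
        ehr = EHRResult(f0)
        idx = pm.detect_peaks_troughs(clip, "G", ehr)
        d = idx.min_distance
        filtered = pm.bandpass_filter(stack, 30.0, axis=0)
        for i in range(5):
            for j in range(5):
                expected = brute_min_distance_peaks(filtered[:, i, j], d)[:5]
                stored = idx.peak_idx[i, j][idx.peak_idx[i, j] != PAD]
                np.testing.assert_array_equal(stored, expected)
                expected_tr = brute_min_distance_peaks(-filtered[:, i, j], d)[:5]
                stored_tr = idx.trough_idx[i, j][idx.trough_idx[i, j] != PAD]
                np.testing.assert_array_equal(stored_tr, expected_tr)

    def test_keep_highest_flag(self):
        stack = sinusoid_stack(f0=3.0, noise=0.2, seed=1)
        clip = clip_of(stack[..., None], labels=("G",))
        idx_first = pm.detect_peaks_troughs(clip, "G", EHRResult(3.0), keep="first")
        idx_high = pm.detect_peaks_troughs(clip, "G", EHRResult(3.0), keep="highest")
        # 12 cycles in 4 s: both keep 5, but possibly different ones
        assert (idx_first.peak_idx != PAD).sum() == (idx_high.peak_idx != PAD).sum()
        with pytest.raises(ValueError):
            pm.detect_peaks_troughs(clip, "G", EHRResult(3.0), keep="best")


class TestUpsampleIndices:
    def test_repeat_four_rule_exhaustive(self):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, 120, size=(6, 6, 5))
        up = pm.upsample_indices(idx, factor=4)
        assert up.shape == (24, 24, 5)
        for i in range(6):
            for j in range(6):
                block = up[4 * i : 4 * i + 4, 4 * j : 4 * j + 4]
                assert (block == idx[i, j]).all()

    def test_all_padded_stays_padded(self):
        idx = np.full((3, 3, 5), PAD)
        assert (pm.upsample_indices(idx) == PAD).all()


class TestExtractStacks:
    def test_pure_indexing_identity(self):
        rng = np.random.default_rng(2)
        frames = rng.integers(0, 255, size=(20, 8, 8, 1)).astype(float)
        clip = clip_of(frames, labels=("G",))
        idx = rng.integers(0, 20, size=(8, 8, 5))
        stack = pm.extract_stacks(clip, idx, idx, "G")
        for n in range(5):
            for i in range(8):
                for j in range(8):
                    assert stack.i_max[i, j, n] == frames[idx[i, j, n], i, j, 0]
        np.testing.assert_array_equal(stack.i_max, stack.i_min)

    def test_pad_positions_are_zero(self):
        frames = np.full((10, 4, 4, 1), 200.0)
        clip = clip_of(frames, labels=("G",))
        idx = np.full((4, 4, 5), PAD)
        idx[0, 0, 0] = 3
        stack = pm.extract_stacks(clip, idx, idx, "G")
        assert stack.i_max[0, 0, 0] == 200.0
        assert stack.i_max[0, 0, 1:].sum() == 0.0
        assert not stack.valid_max[1:].any()

    def test_out_of_range_index_rejected(self):
        clip = clip_of(np.zeros((10, 4, 4, 1)), labels=("G",))
        idx = np.full((4, 4, 5), 10)
        with pytest.raises(IndexError):
            pm.extract_stacks(clip, idx, idx, "G")

    def test_peak_values_exceed_trough_values_on_sinusoid(self):
        stack_frames = sinusoid_stack(f0=1.25)
        clip = clip_of(stack_frames[..., None], labels=("G",))
        idx = pm.detect_peaks_troughs(clip, "G", EHRResult(1.25))
        stack = pm.extract_stacks(clip, idx.peak_idx, idx.trough_idx, "G")
        both = stack.valid_max & stack.valid_min
        assert (stack.i_max[both] > stack.i_min[both]).all()


class TestLWIRStack:
    def test_uniform_sampling_indices(self):
        frames = np.arange(120, dtype=float)[:, None, None, None] * np.ones((1, 6, 6, 1))
        clip = clip_of(frames, labels=("LWIR",))
        stack = pm.lwir_uniform_stack(clip)
        np.testing.assert_array_equal(stack[0, 0], [0, 30, 60, 90, 119])

    def test_five_frame_clip_identity(self):
        frames = np.arange(5, dtype=float)[:, None, None, None] * np.ones((1, 2, 2, 1))
        clip = clip_of(frames, labels=("LWIR",))
        np.testing.assert_array_equal(pm.lwir_uniform_stack(clip)[0, 0], [0, 1, 2, 3, 4])

    def test_constant_clip_gives_identical_frames(self):
        clip = clip_of(np.full((40, 3, 3, 1), 9.0), labels=("LWIR",))
        stack = pm.lwir_uniform_stack(clip)
        assert np.ptp(stack) == 0

    def test_too_short_and_wrong_channels(self):
        with pytest.raises(ValueError):
            pm.lwir_uniform_stack(clip_of(np.zeros((4, 3, 3, 1)), labels=("LWIR",)))
        with pytest.raises(ValueError):
            pm.lwir_uniform_stack(clip_of(np.zeros((10, 3, 3, 3))))
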