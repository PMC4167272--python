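"""Threshold and FWHM classifiers, volume percentage, transmurality."""

import numpy as np
import pytest

from dwcmr import (
    PhantomConfig,
    fwhm_classify,
    generate_phantom,
    infarct_volume_pct,
    threshold_classify,
    transmurality,
)
from conftest import dice


def strip(values):
    """A 1-voxel-high 'image' for hand-executable examples."""
    return np.asarray(values, dtype=float)[None, None, :]


class TestThreshold:
    def test_cutoff_is_remote_mean_plus_six_sd(self):
        # remote at 1.4 with SD 0.1 -> cutoff 2.0; a 2.4 voxel is infarct
        remote_vals = np.array([1.3, 1.5, 1.3, 1.5])  # mean 1.4, sd ~0.1155
        data = strip(list(remote_vals) + [2.4, 1.9])
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(myo)
        roi[0, 0, :4] = True
        mask = threshold_classify(data, roi, myo)
        cutoff = 1.4 + 6.0 * remote_vals.std(ddof=1)
        assert mask.provenance["cutoff"] == pytest.approx(cutoff)
        assert mask.mask[0, 0].tolist() == [False] * 4 + [2.4 > cutoff, 1.9 > cutoff]

    def test_uniform_map_yields_empty_mask(self):
        data = strip([1.4] * 6)
        myo = np.ones_like(data, bool)
        roi = myo.copy()
        mask = threshold_classify(data, roi, myo)
        assert not mask.mask.any()

    def test_zero_sd_degenerates_to_mean_cutoff(self):
        data = strip([1.4, 1.4, 1.4, 1.5])
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(myo)
        roi[0, 0, :3] = True
        mask = threshold_classify(data, roi, myo)
        assert mask.mask[0, 0].tolist() == [False, False, False, True]

    def test_empty_and_single_voxel_rois_rejected(self):
        data = strip([1.0, 2.0])
        myo = np.ones_like(data, bool)
        with pytest.raises(ValueError):
            threshold_classify(data, np.zeros_like(myo), myo)
        single = np.zeros_like(myo)
        single[0, 0, 0] = True
        with pytest.raises(ValueError):
            threshold_classify(data, single, myo)

    def test_raising_the_multiplier_shrinks_the_mask(self):
        rng = np.random.default_rng(1)
        data = rng.normal(1.4, 0.2, (1, 20, 20))
        myo = np.ones_like(data, bool)
        roi = np.zeros_like(myo)
        roi[0, :5] = True
        masks = [threshold_classify(data, roi, myo, n_sd=k).mask for k in (1.0, 2.0, 4.0)]
        assert masks[0].sum() >= masks[1].sum() >= masks[2].sum()
        assert not np.any(masks[2] & ~masks[1])


class TestFWHM:
    def test_hand_executable_strip_example(self):
        # strip [1,1,4,8,6,1,1], seed at the 4: seed region {4,8,6} (>= 2),
        # region max 8, final = voxels >= 4 -> the same {4,8,6}
        data = strip([1, 1, 4, 8, 6, 1, 1])
        myo = np.ones_like(data, bool)
        mask = fwhm_classify(data, (0, 0, 2), myo)
        assert mask.mask[0, 0].tolist() == [False, False, True, True, True, False, False]
        assert mask.provenance["half_maxima"] == [4.0]

    def test_uniform_map_floods_the_myocardium(self):
        data = strip([5.0] * 7)
        myo = np.ones_like(data, bool)
        mask = fwhm_classify(data, (0, 0, 3), myo)
        assert mask.mask[myo].all()

    def test_seed_outside_myocardium_rejected(self):
        data = strip([1, 2, 3])
        myo = np.ones_like(data, bool)
        myo[0, 0, 0] = False
        with pytest.raises(ValueError):
            fwhm_classify(data, (0, 0, 0), myo)

    def test_lowering_the_fraction_grows_the_mask(self):
        rng = np.random.default_rng(2)
        data = np.abs(rng.normal(2, 1, (1, 16, 16)))
        data[0, 8, 8] = 10.0
        myo = np.ones_like(data, bool)
        big = fwhm_classify(data, (0, 8, 8), myo, fraction=0.3).mask
        small = fwhm_classify(data, (0, 8, 8), myo, fraction=0.7).mask
        assert not np.any(small & ~big)
        assert big.sum() >= small.sum()

    def test_seed_choice_within_the_core_does_not_change_the_mask(self, noisy_trace, noisy_study):
        st = noisy_study
        myo = st.true_myocardium
        core = np.argwhere(st.true_infarct & (st.true_adc.data > 2.8) & (noisy_trace.data > 2.9))
        s, r, c = core[0]
        base = fwhm_classify(noisy_trace, (s, r, c), myo).mask
        for s2, r2, c2 in core[1:6]:
            if s2 != s:
                continue
            other = fwhm_classify(noisy_trace, (s2, r2, c2), myo).mask
            assert np.array_equal(base[s], other[s])


class TestDiceAgainstGroundTruth:
    def _seeds(self, trace, myo):
        return [
            (s, *np.unravel_index(np.argmax(np.where(myo[s], trace.data[s], -np.inf)), myo[s].shape))
            for s in range(myo.shape[0])
        ]

    def test_noise_free_classifiers_are_exact(self, noise_free_trace, noise_free_study):
        st = noise_free_study
        myo = st.true_myocardium
        roi = np.zeros_like(myo)
        _, theta = st.b0.polar_grid(0.0)
        from dwcmr.core import angle_difference

        roi[0] = myo[0] & (angle_difference(theta, 270.0) <= 30.0)
        thr = threshold_classify(noise_free_trace, roi, myo)
        fw = fwhm_classify(noise_free_trace, self._seeds(noise_free_trace, myo), myo)
        assert dice(thr.mask, st.true_infarct) == 1.0
        assert dice(fw.mask, st.true_infarct) == 1.0

    def test_noisy_fwhm_dice_exceeds_0p8(self, noisy_trace, noisy_study):
        st = noisy_study
        fw = fwhm_classify(noisy_trace, self._seeds(noisy_trace, st.true_myocardium), st.true_myocardium)
        assert dice(fw.mask, st.true_infarct) >= 0.8


class TestVolume:
    def test_limits(self, noise_free_study):
        myo = noise_free_study.true_myocardium
        assert infarct_volume_pct(myo, myo) == 100.0
        assert infarct_volume_pct(np.zeros_like(myo), myo) == 0.0
        with pytest.raises(ValueError):
            infarct_volume_pct(np.zeros_like(myo), np.zeros_like(myo))

    def test_phantom_fraction_recovered_within_two_points(self, noisy_trace, noisy_study):
        st = noisy_study
        myo = st.true_myocardium
        seeds = [
            (s, *np.unravel_index(np.argmax(np.where(myo[s], noisy_trace.data[s], -np.inf)), myo[s].shape))
            for s in range(3)
        ]
        fw = fwhm_classify(noisy_trace, seeds, myo)
        assert infarct_volume_pct(fw) == pytest.approx(st.meta["infarct_fraction_pct"], abs=2.0)


class TestTransmurality:
    def test_full_wedge_is_transmural(self, noise_free_study):
        st = noise_free_study
        flags = transmurality(st.true_infarct, st.contours(st.config.dwi_phase), st.b0)
        assert flags == [True]

    def test_half_thickness_wedge_is_not(self):
        cfg = PhantomConfig(snr=None, infarct_transmural=False, infarct_transmural_fraction=0.5)
        st = generate_phantom(cfg)
        flags = transmurality(st.true_infarct, st.contours(cfg.dwi_phase), st.b0, tolerance_px=2.0)
        assert flags == [False]

    def test_empty_mask_reports_no_infarcts(self, noise_free_study):
        st = noise_free_study
        flags = transmurality(
            np.zeros_like(st.true_infarct), st.contours(st.config.dwi_phase), st.b0
        )
        assert flags == []
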