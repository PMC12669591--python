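"""Entropy focus criterion, SNR/CNR and cohort outlier screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from orbitmorph.io_formats import IntensityVolume, LabelVolume
from orbitmorph.phantom import PhantomSpec, true_air_mask
from orbitmorph.qc import cnr, efc, flag_outliers, make_masks, qc_structure, snr


def efc_by_direct_summation(x):
    """Independent oracle: term-by-term evaluation of the entropy sum."""
    x = np.asarray(x, dtype=float)
    x_max = np.sqrt((x**2).sum())
    total = 0.0
    for v in x:
        p = v / x_max
        if p > 0:  # 0 ln 0 := 0, including ratios that underflow to 0
            total -= p * np.log(p)
    return total / (np.sqrt(len(x)) * np.log(np.sqrt(len(x))))


class TestEFC:
    def test_one_hot_is_zero(self):
        x = np.zeros(10)
        x[3] = 5.0
        assert efc(x) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_is_one(self):
        assert efc(np.full(100, 7.0)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_voxel_example(self):
        # x=(3,4): E = -(0.6 ln 0.6 + 0.8 ln 0.8) = 0.485
        e = -(0.6 * np.log(0.6) + 0.8 * np.log(0.8))
        expected = e / (np.sqrt(2) * np.log(np.sqrt(2)))
        assert efc([3.0, 4.0]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.990, abs=5e-4)

    @given(
        arrays(
            float,
            st.integers(5, 60),
            elements=st.floats(0.0, 1e3, allow_nan=False),
        ).filter(lambda a: a.sum() > 1e-6),
        st.floats(1e-3, 1e3),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_scale_invariance_and_bounds(self, x, c):
        val = efc(x)
        assert 0.0 <= val <= 1.0 + 1e-12
        assert efc(c * x) == pytest.approx(val, rel=1e-9, abs=1e-9)

    @given(
        arrays(
            float,
            st.integers(3, 40),
            elements=st.floats(0.0, 100.0, allow_nan=False),
        ).filter(lambda a: a.sum() > 1e-6)
    )
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_matches_direct_summation_oracle(self, x):
        assert efc(x) == pytest.approx(efc_by_direct_summation(x), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            efc(np.zeros(5))
        with pytest.raises(ValueError):
            efc([1.0])


def _toy_volume():
    """16^3 volume: an ROI cube, a distinct comparison region, air elsewhere."""
    data = np.zeros((16, 16, 16))
    labels = np.zeros((16, 16, 16), dtype=np.int16)
    data[6:10, 6:10, 6:10] = 100.0
    labels[6:10, 6:10, 6:10] = 1
    vol = IntensityVolume(data, np.eye(4))
    lab = LabelVolume(labels, np.eye(4), {("globe", "right"): 1})
    return vol, lab


class TestSNRCNR:
    def test_snr_direct_ratio(self):
        vol, _ = _toy_volume()
        roi = vol.data == 100.0
        bg = np.zeros_like(roi)
        bg[0, :, :] = True
        rng = np.random.default_rng(0)
        vol.data[bg] = rng.normal(0, 5.0, bg.sum())
        assert snr(vol, roi, bg) == pytest.approx(100.0 / vol.data[bg].std())

    def test_cnr_and_identity_case(self):
        vol, _ = _toy_volume()
        roi = vol.data == 100.0
        comp = np.zeros_like(roi)
        comp[1, :, :] = True
        vol.data[comp] = 60.0
        bg = np.zeros_like(roi)
        bg[15, :, :] = True
        rng = np.random.default_rng(1)
        vol.data[bg] = rng.normal(0, 5.0, bg.sum())
        sigma = vol.data[bg].std()
        assert cnr(vol, roi, comp, bg) == pytest.approx(40.0 / sigma)
        # identical intensity distributions in roi and comparison -> 0
        vol.data[comp] = 100.0
        assert cnr(vol, roi, comp, bg) == pytest.approx(0.0)

    def test_sigma_zero_rejected(self):
        vol, _ = _toy_volume()
        roi = vol.data == 100.0
        bg = np.zeros_like(roi)
        bg[0, :, :] = True
        with pytest.raises(ValueError):
            snr(vol, roi, bg)

    def test_phantom_recovery_within_5pct(self, default_phantom):
        labels, intensity, _, truth = default_phantom
        for structure in ("globe", "optic_nerve"):
            rec = qc_structure(intensity, labels, structure, "right")
            assert rec.snr == pytest.approx(truth.snr[structure], rel=0.05)
            assert rec.cnr == pytest.approx(truth.cnr[structure], rel=0.05)
            assert 0.0 <= rec.efc <= 1.0
            assert rec.n_roi_voxels > 100


class TestMakeMasks:
    def test_shell_matches_shift_dilation_oracle(self):
        """Comparison shell equals the brute-force 26-neighbourhood
        dilation (by shifted ORs) minus the ROI."""
        _, lab = _toy_volume()
        roi, comp, _ = make_masks(lab, "globe", "right", shell_width=3, air_margin=2)
        brute = roi.copy()
        for _ in range(3):
            grown = brute.copy()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        grown |= np.roll(brute, (dx, dy, dz), axis=(0, 1, 2))
            brute = grown
        assert np.array_equal(comp, brute & ~roi)

    def test_absent_structure_errors(self):
        _, lab = _toy_volume()
        with pytest.raises(KeyError):
            make_masks(lab, "lens", "right")

    def test_background_subset_of_true_air(self, default_phantom):
        labels, intensity, _, _ = default_phantom
        _, _, bg = make_masks(labels, "globe", "right", intensity=intensity)
        air = true_air_mask(labels, PhantomSpec().orbit_margin)
        assert bg.any()
        assert (bg & ~air).sum() == 0

    def test_masks_pairwise_disjoint(self, default_phantom):
        labels, intensity, _, _ = default_phantom
        roi, comp, bg = make_masks(labels, "optic_nerve", "left", intensity=intensity)
        assert not (roi & comp).any()
        assert not (roi & bg).any()
        assert not (comp & bg).any()


class TestOutlierFlags:
    def test_single_extreme_value_flagged(self):
        flags = flag_outliers([1.0, 1.0, 1.0, 1.0, 10.0])
        assert list(flags) == [False, False, False, False, True]

    def test_all_equal_no_flags(self):
        assert not flag_outliers([3.0] * 5).any()

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(42)
        frac = flag_outliers(rng.standard_normal(10_000)).mean()
        # two-sided 2 SD tail of the standard normal: 2*Phi(-2) = 4.55%
        assert frac == pytest.approx(0.0455, abs=0.006)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([1.0, 2.0])
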