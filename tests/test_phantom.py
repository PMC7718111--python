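"""Synthetic phantom: relaxation fitting, segment geometry, motion artefacts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t1qc.phantom import (
    AcquisitionConfig,
    ConfigurationError,
    LabelRule,
    MotionSchedule,
    apply_motion,
    fit_relaxation,
    generate_dataset,
    generate_phantom,
    make_segment_masks,
)

TIS = AcquisitionConfig().inversion_times


class TestFitRelaxation:
    def test_noiseless_parameter_recovery(self):
        # forward-generate from known (A, B, T1*) and refit
        a, b, t1 = 2.0, 4.0, 950.0
        tis = np.asarray(TIS)
        signal = a - b * np.exp(-tis / t1)
        stack = np.tile(signal[:, None, None], (1, 4, 4))
        t1_map, r2_map = fit_relaxation(stack, tis)
        assert np.allclose(t1_map, 950.0, atol=1e-3)
        assert np.allclose(r2_map, 1.0, atol=1e-6)

    def test_pure_noise_pixels_fit_poorly(self):
        # Monte-Carlo over 1000 pixels: noise carries no inversion-recovery
        # structure, so its R² distribution sits far below the ≈1 of tissue.
        # (With 3 parameters fit to 7 samples, chance alone explains a
        # sizeable share of variance, so individual pixels can reach
        # moderate R²; the distribution, not every pixel, is what separates.)
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(7, 25, 40))
        _, r2 = fit_relaxation(stack, TIS)
        assert np.median(r2) < 0.5
        assert (r2 < 0.9).mean() > 0.95
        assert r2.mean() < 0.5

    def test_constant_pixel_is_degenerate(self):
        stack = np.ones((7, 2, 2)) * 3.0
        t1_map, r2_map = fit_relaxation(stack, TIS)
        assert np.all(r2_map == 0.0)
        assert np.all(np.isnan(t1_map))

    def test_rejects_bad_inversion_times(self):
        stack = np.zeros((7, 2, 2))
        with pytest.raises(ConfigurationError):
            fit_relaxation(stack, [100, 90, 260, 1100, 1180, 2100, 3180])

    @pytest.mark.parametrize("t1_true", [300.0, 950.0, 1600.0, 2400.0])
    def test_recovery_across_t1_range(self, t1_true):
        tis = np.asarray(TIS)
        signal = 1.0 - 2.0 * np.exp(-tis / t1_true)
        stack = np.tile(signal[:, None, None], (1, 2, 2))
        t1_map, _ = fit_relaxation(stack, tis)
        assert np.allclose(t1_map, t1_true, atol=1e-3)


class TestSegmentMasks:
    def test_partition_of_annulus(self):
        ms = make_segment_masks((32.0, 32.0), 10, 20, 60.0, 64)
        total = ms.masks.sum(axis=0)
        assert total.max() == 1  # pairwise disjoint
        rows, cols = np.mgrid[0:64, 0:64]
        r = np.hypot(rows - 32.0, cols - 32.0)
        annulus = (r >= 10) & (r < 20)
        assert np.array_equal(ms.annulus, annulus)

    def test_rotation_by_60_degrees_permutes_cyclically(self):
        a = make_segment_masks((32.0, 32.0), 10, 20, 60.0, 64)
        b = make_segment_masks((32.0, 32.0), 10, 20, 120.0, 64)
        for s in range(6):
            assert np.array_equal(b.masks[s], a.masks[(s + 1) % 6])

    def test_sector_pixel_counts_balanced(self):
        ms = make_segment_masks((80.0, 80.0), 27, 48, 60.0, 160)
        counts = ms.masks.sum(axis=(1, 2))
        expected = ms.annulus.sum() / 6
        assert np.all(np.abs(counts - expected) <= 0.02 * expected)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ConfigurationError):
            make_segment_masks((32.0, 32.0), 20, 10, 0.0, 64)
        with pytest.raises(ConfigurationError):
            make_segment_masks((32.0, 32.0), 10, 40, 0.0, 64)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        cy=st.floats(24, 40),
        cx=st.floats(24, 40),
        inner=st.floats(4, 12),
        width=st.floats(3, 10),
        angle=st.floats(0, 360),
    )
    def test_partition_property_across_geometries(self, cy, cx, inner, width, angle):
        ms = make_segment_masks((cy, cx), inner, inner + width, angle, 64)
        assert ms.masks.sum(axis=0).max() <= 1
        assert ms.masks.any(axis=0).sum() == ms.annulus.sum()


class TestGeneratePhantom:
    def test_noiseless_r2_is_one_and_t1_exact(self, case64_noiseless, acq64_noiseless):
        case = case64_noiseless
        assert np.all(case.r2_map >= 1.0 - 1e-6)
        myo = case.segment_masks.annulus
        assert np.allclose(case.t1_map[myo], acq64_noiseless.t1_myocardium, atol=1e-3)
        assert not case.labels.any()

    def test_seeded_determinism_is_bit_identical(self, acq64):
        a = generate_phantom(acq64, seed=5)
        b = generate_phantom(acq64, seed=5)
        assert np.array_equal(a.irw_stack, b.irw_stack)
        assert np.array_equal(a.t1_map, b.t1_map)
        assert np.array_equal(a.segment_masks.masks, b.segment_masks.masks)
        assert a.lv_centroid == b.lv_centroid

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            AcquisitionConfig(inversion_times=(100, 90, 260, 1100, 1180, 2100, 3180))
        with pytest.raises(ConfigurationError):
            AcquisitionConfig(image_size=31)
        with pytest.raises(ConfigurationError):
            AcquisitionConfig(n_frames=6)


def _shift_schedule(dy, dx, frame=3):
    shifts = [(0.0, 0.0)] * 7
    shifts[frame] = (float(dy), float(dx))
    return MotionSchedule(per_frame_shift=tuple(shifts))


class TestApplyMotion:
    def test_zero_schedule_is_identity(self, case64):
        out = apply_motion(case64, MotionSchedule.still())
        assert np.array_equal(out.irw_stack, case64.irw_stack)
        assert np.array_equal(out.r2_map, case64.r2_map)
        assert not out.labels.any()

    def test_single_frame_shift_lowers_segment_r2(self, case64):
        moved = apply_motion(case64, _shift_schedule(8.0, 0.0))
        drops = [
            case64.r2_map[m].mean() - moved.r2_map[m].mean()
            for m in case64.segment_masks.masks
        ]
        assert max(drops) > 0  # some segment degraded
        # myocardial mean R2 strictly lower overall
        myo = case64.segment_masks.annulus
        assert moved.r2_map[myo].mean() < case64.r2_map[myo].mean()

    def test_r2_monotone_nonincreasing_in_shift(self, case64):
        myo = case64.segment_masks.annulus
        means = []
        for mag in [0.0, 2.0, 4.0, 8.0]:
            if mag == 0:
                means.append(float(case64.r2_map[myo].mean()))
            else:
                moved = apply_motion(case64, _shift_schedule(mag, 0.0))
                means.append(float(moved.r2_map[myo].mean()))
        assert all(means[i + 1] <= means[i] + 1e-6 for i in range(3))

    def test_nonphysical_shift_rejected(self, case64):
        with pytest.raises(ConfigurationError):
            apply_motion(case64, _shift_schedule(20.0, 0.0))  # > 64/4

    def test_reference_frame_must_stay_still(self):
        with pytest.raises(ConfigurationError):
            MotionSchedule(per_frame_shift=((1.0, 0.0),) * 7)

    def test_labels_follow_r2_drop_rule(self, case64):
        moved = apply_motion(case64, _shift_schedule(8.0, 8.0), LabelRule())
        drops = np.array(
            [
                case64.r2_map[m].mean() - moved.r2_map[m].mean()
                for m in case64.segment_masks.masks
            ]
        )
        expected = (drops >= 0.05).astype(int)
        assert np.array_equal(moved.labels, expected)


class TestGenerateDataset:
    def test_zero_prevalence_all_negative(self, acq64):
        _, table = generate_dataset(10, 0.0, acq64, seed=0)
        assert not table.any_motion.any()
        seg_cols = [f"seg{i}" for i in range(1, 7)]
        assert not table[seg_cols].values.any()

    def test_seeded_label_table_reproducible(self, acq64):
        _, a = generate_dataset(15, 0.3, acq64, seed=9)
        _, b = generate_dataset(15, 0.3, acq64, seed=9)
        assert a.equals(b)

    def test_prevalence_within_binomial_interval(self, acq64):
        # 99% binomial interval for n=150, p=0.3: +-2.58*sqrt(p(1-p)/n) ~ 0.097
        _, table = generate_dataset(150, 0.3, acq64, seed=21)
        assert abs(table.any_motion.mean() - 0.3) < 0.097

    def test_invalid_arguments(self, acq64):
        with pytest.raises(ConfigurationError):
            generate_dataset(0, 0.3, acq64, seed=0)
        with pytest.raises(ConfigurationError):
            generate_dataset(5, 1.5, acq64, seed=0)
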