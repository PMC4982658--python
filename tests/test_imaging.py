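"""Registration, background subtraction, segmentation, measurement, tracking."""

import numpy as np
import pytest
from scipy import ndimage

from facomp.imaging import (
    DegenerateInputError,
    LabelMap,
    SegmentationParams,
    TrackedTrajectory,
    age_category,
    analyze_stack,
    classify_dynamics,
    highpass_subtract,
    measure_regions,
    register_translation,
    segment_adhesions,
    subtract_background,
    track_adhesions,
)


def gaussian_spot(shape, center, sigma, amplitude=100.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amplitude * np.exp(
        -((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)
    )


class TestRegisterTranslation:
    def test_identical_images_give_zero_shift(self):
        img = gaussian_spot((64, 64), (30, 30), 3)
        assert register_translation(img, img) == (0.0, 0.0)

    def test_integer_circular_shift_recovered_exactly(self):
        img = gaussian_spot((64, 64), (30, 30), 3) + gaussian_spot((64, 64), (10, 50), 2)
        moved = np.roll(img, (-3, 2), axis=(0, 1))
        assert register_translation(img, moved) == (-3.0, 2.0) or register_translation(
            img, moved
        ) == (3.0, -2.0)

    @pytest.mark.parametrize("shift", [(0.25, -0.75), (0.25, 0.25), (-1.3, 0.6)])
    def test_subpixel_shift_recovered_within_five_hundredths(self, shift):
        """Oracle: the shift is imposed exactly in the Fourier domain."""
        img = gaussian_spot((128, 128), (60, 70), 4) + gaussian_spot((128, 128), (30, 30), 3)
        # moving = reference displaced by -shift; applying +shift re-aligns it
        moved = np.real(
            np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img), (-shift[0], -shift[1])))
        )
        dy, dx = register_translation(img, moved, upsample=100)
        assert dy == pytest.approx(shift[0], abs=0.05)
        assert dx == pytest.approx(shift[1], abs=0.05)

    def test_flat_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            register_translation(np.ones((32, 32)), np.ones((32, 32)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            register_translation(np.zeros((32, 32)), np.zeros((16, 16)))


class TestHighpassSubtract:
    def test_constant_image_becomes_zero(self):
        np.testing.assert_allclose(highpass_subtract(np.full((64, 64), 7.0), 10), 0.0)

    def test_bright_spot_on_constant_preserved(self):
        """Oracle: direct Gaussian convolution of the synthetic scene."""
        img = np.full((128, 128), 5.0)
        spot = gaussian_spot((128, 128), (64, 64), 2, amplitude=50)
        out = highpass_subtract(img + spot, width=20)
        leak = ndimage.gaussian_filter(spot, 20)
        expected = np.clip(spot - leak, 0, None)
        assert out.max() == pytest.approx(expected.max(), rel=1e-9)
        assert out.max() == pytest.approx(50.0, rel=0.10)

    def test_linear_ramp_mostly_removed(self):
        ramp = np.tile(np.linspace(0, 100, 256), (256, 1))
        out = highpass_subtract(ramp, width=10)
        interior = out[:, 40:-40]
        assert interior.max() - interior.min() < 0.05 * 100

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            highpass_subtract(np.zeros((8, 8)), 0)

    def test_masked_background_estimate_unbiased_by_foreground(self):
        """The foreground-aware variant removes the neighborhood leak."""
        img = np.full((128, 128), 5.0)
        mask = np.zeros((128, 128), dtype=bool)
        mask[50:70, 50:70] = True
        img[mask] += 80.0
        plain = highpass_subtract(img, 20)
        refined = subtract_background(img, 20, foreground_mask=mask)
        assert abs(refined[60, 60] - 80.0) < abs(plain[60, 60] - 80.0)
        assert refined[60, 60] == pytest.approx(80.0, abs=1e-6)


def render_ellipse(shape, center, a, b, theta=0.0, value=1.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return np.where((u / a) ** 2 + (v / b) ** 2 <= 1, value, 0.0)


class TestSegmentAdhesions:
    def test_two_separated_spots_found_with_centroids(self):
        img = render_ellipse((128, 128), (30, 30), 8, 5, value=100) + render_ellipse(
            (128, 128), (90, 90), 6, 4, value=60
        )
        lm = segment_adhesions(img)
        assert lm.n_regions == 2
        from skimage.measure import regionprops

        centroids = sorted(tuple(p.centroid) for p in regionprops(lm.labels))
        np.testing.assert_allclose(centroids[0], (30, 30), atol=1.0)
        np.testing.assert_allclose(centroids[1], (90, 90), atol=1.0)

    def test_touching_blobs_with_distinct_peaks_split(self):
        img = gaussian_spot((80, 80), (40, 30), 5, amplitude=100) + gaussian_spot(
            (80, 80), (40, 48), 5, amplitude=90
        )
        lm = segment_adhesions(img, SegmentationParams(region_half_max=0.0))
        assert lm.n_regions == 2

    def test_blank_image_yields_empty_label_map(self):
        lm = segment_adhesions(np.zeros((64, 64)))
        assert lm.n_regions == 0

    def test_min_area_filter_removes_specks(self):
        img = np.zeros((64, 64))
        img[10:12, 10:12] = 100.0  # 4-px speck, below the 5-px minimum
        img += render_ellipse((64, 64), (40, 40), 7, 5, value=80)
        lm = segment_adhesions(
            img, SegmentationParams(min_area=5, smooth_sigma=0.0, region_half_max=0.0)
        )
        assert lm.n_regions == 1

    def test_labels_contiguous_positive(self):
        img = sum(
            render_ellipse((128, 128), c, 6, 4, value=v)
            for c, v in [((20, 20), 50), ((60, 90), 120), ((100, 30), 80)]
        )
        lm = segment_adhesions(img)
        present = np.unique(lm.labels)
        np.testing.assert_array_equal(present, np.arange(lm.n_regions + 1))


class TestMeasureRegions:
    def test_density_is_mean_intensity(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1
        channel = np.zeros((8, 8))
        channel[2:4, 2:4] = np.array([[2.0, 4.0], [6.0, 8.0]])
        table = measure_regions(LabelMap(labels), [channel], components=["P"])
        assert table.raw["P"].iloc[0] == pytest.approx(5.0)
        assert table.data["pixel_count"].iloc[0] == 4

    def test_circular_region_low_eccentricity(self):
        labels = render_ellipse((64, 64), (32, 32), 10, 10).astype(np.int32)
        table = measure_regions(LabelMap(labels), [np.ones((64, 64))], components=["P"])
        assert table.data["eccentricity"].iloc[0] < 0.15

    def test_ellipse_eccentricity_matches_axes(self):
        """Semi-axes 5:3 -> eccentricity = c/a = sqrt(a^2-b^2)/a = 0.8."""
        labels = render_ellipse((200, 200), (100, 100), 50, 30).astype(np.int32)
        table = measure_regions(LabelMap(labels), [np.ones((200, 200))], components=["P"])
        assert table.data["eccentricity"].iloc[0] == pytest.approx(0.8, abs=0.01)

    def test_area_uses_pixel_size(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[0:2, 0:2] = 1
        table = measure_regions(
            LabelMap(labels, pixel_size=0.5), [np.ones((8, 8))], components=["P"]
        )
        assert table.data["area"].iloc[0] == pytest.approx(4 * 0.25)

    def test_invariant_to_label_renumbering_and_channel_order(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:6, 2:6] = 1
        labels[20:26, 20:27] = 2
        ch1, ch2 = rng.random((32, 32)), rng.random((32, 32))
        t_a = measure_regions(LabelMap(labels), [ch1, ch2], components=["P", "Q"])
        renumbered = np.where(labels == 1, 2, np.where(labels == 2, 1, 0))
        t_b = measure_regions(LabelMap(renumbered), [ch2, ch1], components=["Q", "P"])
        merged = t_a.data.merge(
            t_b.data, on="pixel_count", suffixes=("_a", "_b")
        )
        np.testing.assert_allclose(merged["P_a"], merged["P_b"], atol=1e-12)
        np.testing.assert_allclose(merged["Q_a"], merged["Q_b"], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_regions(LabelMap(np.zeros((8, 8), dtype=int)), [np.zeros((4, 4))])


def square_map(centers, size=4, shape=(64, 64)):
    labels = np.zeros(shape, dtype=np.int32)
    for i, (r, c) in enumerate(centers):
        labels[r : r + size, c : c + size] = i + 1
    return LabelMap(labels)


class TestTrackAdhesions:
    def test_identity_matching_across_identical_frames(self):
        lm = square_map([(5, 5), (30, 30), (50, 10)])
        trajs = track_adhesions([lm] * 5)
        assert len(trajs) == 3
        assert all(t.age == ">12'" for t in trajs)
        assert all(t.first_frame == 0 for t in trajs)

    def test_disjoint_regions_within_ten_pixels_matched(self):
        """Centroids 8 px apart, no overlap -> matched."""
        a = square_map([(10, 10)])
        b = square_map([(10, 18)])  # centroid shifted 8 px in x
        trajs = track_adhesions([a, b])
        assert len(trajs) == 1
        assert trajs[0].first_frame == 0

    def test_regions_beyond_ten_pixels_not_matched(self):
        """Centroids 12 px apart: new track; old region dropped entirely."""
        a = square_map([(10, 10)])
        b = square_map([(10, 22)])
        trajs = track_adhesions([a, b])
        assert len(trajs) == 1
        assert trajs[0].first_frame == 1  # appeared at the final frame

    def test_region_absent_at_final_frame_excluded(self):
        a = square_map([(10, 10), (40, 40)])
        b = square_map([(10, 10)])
        trajs = track_adhesions([a, b])
        assert len(trajs) == 1

    def test_overlap_preferred_over_distance(self):
        prev = square_map([(10, 10), (10, 17)], size=5)
        cur = square_map([(11, 12)], size=5)  # overlaps region 1 most
        trajs = track_adhesions([prev, cur])
        assert trajs[0].labels[0] == 1

    def test_deterministic(self):
        lm1 = square_map([(5, 5), (30, 30)])
        lm2 = square_map([(6, 6), (31, 31)])
        a = track_adhesions([lm1, lm2])
        b = track_adhesions([lm1, lm2])
        assert [t.labels for t in a] == [t.labels for t in b]

    def test_registered_shift_applied_before_overlap(self):
        """A global 12-px shift breaks matching unless corrected."""
        a = square_map([(10, 10)], size=6)
        b = square_map([(22, 10)], size=6)
        unmatched = track_adhesions([a, b])
        assert unmatched[0].first_frame == 1
        # frame 0 content sits at -12 px relative to the final frame
        matched = track_adhesions([a, b], shifts=[(-12.0, 0.0), (0.0, 0.0)])
        assert matched[0].first_frame == 0


class TestClassifyDynamics:
    def _traj(self, totals, first_frame=0, n_frames=None):
        n_frames = n_frames or len(totals)
        frames = list(range(first_frame, first_frame + len(totals)))
        return TrackedTrajectory(
            adhesion_id=1,
            frames=frames,
            labels=[1] * len(frames),
            centroids=[(0.0, 0.0)] * len(frames),
            areas=[10] * len(frames),
            total_intensities=list(totals),
            first_frame=first_frame,
        )

    def test_strictly_increasing_is_assembling(self):
        age, dyn = classify_dynamics(self._traj([10, 20, 30, 40, 50]), n_frames=5)
        assert (age, dyn) == (">12'", "AS")

    def test_strictly_decreasing_is_disassembling(self):
        age, dyn = classify_dynamics(self._traj([50, 40, 30, 20, 10]), n_frames=5)
        assert (age, dyn) == (">12'", "DS")

    def test_oscillating_is_stationary(self):
        """|r| < 0.7 for {10, 11, 10, 11}: direct Pearson computation."""
        from scipy import stats as st

        vals = [10.0, 11.0, 10.0, 11.0]
        r = st.pearsonr(np.arange(4), vals).statistic
        assert abs(r) < 0.7
        age, dyn = classify_dynamics(self._traj([9.0] + vals), n_frames=5)
        assert (age, dyn) == (">12'", "ST")

    def test_constant_trace_is_stationary(self):
        age, dyn = classify_dynamics(self._traj([5.0] * 5), n_frames=5)
        assert dyn == "ST"

    def test_young_adhesions_get_na(self):
        age, dyn = classify_dynamics(self._traj([10, 20], first_frame=3), n_frames=5)
        assert age == "6'"
        assert dyn == "NA"

    @pytest.mark.parametrize(
        "first,expected",
        [(0, ">12'"), (1, "12'"), (2, "9'"), (3, "6'"), (4, "3'")],
    )
    def test_age_mapping_five_frames(self, first, expected):
        assert age_category(first, n_frames=5) == expected


class TestEndToEnd:
    def test_full_stack_recovers_truth_densities(self):
        """Noise-free render -> analyze: per-component correlation with
        truth above 0.98 and at least 95% of adhesions recovered."""
        from facomp.synthetic_data import SyntheticStudyConfig, generate_image_set

        cfg = SyntheticStudyConfig(seed=5)
        ims = generate_image_set(cfg)
        table, trajs, labels = analyze_stack(
            ims.marker_frames,
            ims.channel_stack,
            ims.components,
            channel_cycles=ims.channel_cycles,
            pixel_size=ims.pixel_size,
        )
        tl, fl = ims.truth_labels, labels.labels
        pairs = []
        for i in range(1, tl.max() + 1):
            found = fl[tl == i]
            found = found[found > 0]
            if found.size:
                j = np.bincount(found).argmax()
                if j > 0 and (found == j).sum() / (tl == i).sum() > 0.5:
                    pairs.append((i, j))
        assert len(pairs) >= 0.95 * tl.max()
        tru = ims.truth.set_index("adhesion_id")
        fnd = table.data.set_index("adhesion_id")
        for comp in ims.components:
            xs = [tru[comp][i] for i, j in pairs]
            ys = [fnd[comp][j] for i, j in pairs]
            assert np.corrcoef(xs, ys)[0, 1] > 0.98


class TestLabelMapIO:
    def test_tiff_round_trip(self, tmp_path):
        from facomp.imaging import read_label_map, write_label_map

        labels = np.zeros((32, 32), dtype=np.int32)
        labels[4:8, 4:8] = 1
        labels[20:25, 20:28] = 2
        lm = LabelMap(labels, pixel_size=0.15)
        write_label_map(lm, tmp_path / "labels.tif")
        back = read_label_map(tmp_path / "labels.tif", pixel_size=0.15)
        np.testing.assert_array_equal(back.labels, labels)
        assert back.pixel_size == 0.15
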