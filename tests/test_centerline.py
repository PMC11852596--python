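"""Segmentation, skeleton tracing, and arc length."""

import numpy as np
import pytest

from colmorph.centerline import (Centerline, SegmentationParams, arc_length,
                                 collagen_analysis_params, extract_centerline,
                                 segment_molecules, trace_image)
from colmorph.errors import UndefinedLengthError
from colmorph.image import AFMImage
from colmorph.synthetic import ImageSpec, render_image

FIXED = SegmentationParams(threshold_mode="fixed", fixed_threshold=0.15,
                           smooth_sigma=0.0)


class TestSegmentMolecules:
    def test_flat_noise_image_has_no_components(self):
        rng = np.random.default_rng(0)
        img = AFMImage(rng.normal(0.0, 0.1, (256, 256)), 2.0)
        params = SegmentationParams(threshold_mode="fixed",
                                    fixed_threshold=0.75, min_area=20,
                                    smooth_sigma=0.0)
        assert segment_molecules(img, params).max() == 0

    def test_single_filament_single_component(self, straight_image):
        img, _ = straight_image
        labels = segment_molecules(img, FIXED)
        assert labels.max() == 1

    def test_three_filaments_three_components_reproducible(self,
                                                           three_filament_image):
        img = three_filament_image.images[0]
        a = segment_molecules(img)
        b = segment_molecules(img)
        assert a.max() == 3
        assert np.array_equal(a, b)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold_mode="fixed")  # no threshold given
        with pytest.raises(ValueError):
            SegmentationParams(fixed_threshold=0.5)     # threshold w/o mode
        with pytest.raises(ValueError):
            SegmentationParams(min_area=0)


def _mask_image(mask: np.ndarray, pixel_size: float = 2.0) -> AFMImage:
    return AFMImage(mask.astype(float), pixel_size, id="mask")


class TestExtractCenterline:
    def test_horizontal_rod_middle_row(self):
        mask = np.zeros((64, 128), bool)
        mask[30:35, 10:110] = True  # 5 px tall, 100 px long
        img = _mask_image(mask)
        c = extract_centerline(mask, img, SegmentationParams(smooth_sigma=0.0,
                               threshold_mode="fixed", fixed_threshold=0.5))
        assert c.is_clean
        assert 95 <= len(c.points) <= 102
        # middle row is row 32 -> y = (32 + 0.5) * 2 nm
        assert np.allclose(c.points[:, 1], 65.0, atol=2.0)
        assert np.all(np.diff(c.points[:, 0]) > 0)  # ordered left to right

    def test_t_shape_flags_branched_and_keeps_longest_path(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 5:55] = True   # 50 px bar
        mask[10:40, 30] = True  # 30 px stem
        img = _mask_image(mask)
        c = extract_centerline(mask, img, SegmentationParams(smooth_sigma=0.0,
                               threshold_mode="fixed", fixed_threshold=0.5,
                               extend_ends=False))
        assert "branched" in c.qc_flags
        # longest leaf-to-leaf path is stem + half bar (~55 px), not the bar
        assert len(c.points) > 50

    def test_tiny_component_flagged_too_short(self):
        mask = np.zeros((32, 32), bool)
        mask[10:12, 10:13] = True
        img = _mask_image(mask)
        c = extract_centerline(mask, img, SegmentationParams(smooth_sigma=0.0,
                               threshold_mode="fixed", fixed_threshold=0.5))
        assert "too_short" in c.qc_flags

    def test_border_touching_flagged(self):
        mask = np.zeros((64, 64), bool)
        mask[0:3, 10:50] = True
        img = _mask_image(mask)
        c = extract_centerline(mask, img, SegmentationParams(smooth_sigma=0.0,
                               threshold_mode="fixed", fixed_threshold=0.5))
        assert "border_touch" in c.qc_flags

    def test_curved_filament_tracks_ground_truth(self, small_dataset):
        img = small_dataset.images[0]
        truths = small_dataset.truths_for(img.id)
        centerlines = [c for c in trace_image(img) if c.is_clean]
        assert centerlines
        for c in centerlines:
            best = min(
                np.hypot(c.points[:, 0][:, None] - t.polyline[:, 0][None],
                         c.points[:, 1][:, None] - t.polyline[:, 1][None])
                .min(axis=1).mean()
                for t in truths)
            assert best <= img.pixel_size  # mean deviation <= 1 px


class TestOrderingInvariants:
    def test_spacing_and_uniqueness(self, three_filament_image):
        img = three_filament_image.images[0]
        for c in trace_image(img):
            if len(c.points) < 2:
                continue
            steps = np.hypot(*np.diff(c.points, axis=0).T)
            assert steps.max() <= np.sqrt(2) * img.pixel_size + 1e-9
            assert steps.min() > 0
            assert len(np.unique(c.points, axis=0)) == len(c.points)

    def test_centerline_points_inside_component(self, three_filament_image):
        img = three_filament_image.images[0]
        labels = segment_molecules(img)
        for lab in range(1, labels.max() + 1):
            c = extract_centerline(labels == lab, img,
                                   molecule_id=f"{img.id}:{lab}")
            cols = np.round(c.points[:, 0] / img.pixel_size - 0.5).astype(int)
            rows = np.round(c.points[:, 1] / img.pixel_size - 0.5).astype(int)
            assert (labels[rows, cols] == lab).all()


class TestArcLength:
    def test_three_four_five_path(self):
        c = Centerline("m", np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 9.0]]))
        assert arc_length(c) == pytest.approx(10.0)

    def test_single_diagonal_step(self):
        c = Centerline("m", np.array([[0.0, 0.0], [2.0, 2.0]]), pixel_size=2.0)
        assert arc_length(c) == pytest.approx(2 * np.sqrt(2))

    def test_single_point_undefined(self):
        with pytest.raises(UndefinedLengthError):
            arc_length(Centerline("m", np.array([[1.0, 1.0]])))

    def test_straight_filament_pipeline_end_to_end(self, straight_image):
        img, poly = straight_image
        cls = trace_image(img, FIXED)
        assert len(cls) == 1 and cls[0].is_clean
        assert 294.0 <= arc_length(cls[0]) <= 306.0


class TestDegradation:
    def test_noise_never_increases_clean_count(self, small_dataset):
        """More height noise cannot yield more flag-free molecules."""
        ispec = small_dataset.image_spec
        polys = [t.polyline for t in small_dataset.truths_for("img_000")]
        counts = []
        for noise in (0.05, 0.1, 0.15, 0.25, 0.5):
            spec = ImageSpec(size=ispec.size, pixel_size=ispec.pixel_size,
                             tip_sigma=ispec.tip_sigma, noise_sigma=noise)
            img = render_image(polys, spec, np.random.default_rng(99),
                               id=f"noise_{noise}")
            counts.append(sum(c.is_clean for c in
                              trace_image(img, collagen_analysis_params())))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
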