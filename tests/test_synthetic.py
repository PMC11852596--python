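"""Worm-like-chain sampling, rendering, and dataset generation."""

import numpy as np
import pytest

from colmorph.errors import InvalidSpecificationError, PlacementError
from colmorph.synthetic import (FilamentSpec, ImageSpec, generate_dataset,
                                load_ground_truth, polyline_arc_length,
                                render_image, sample_wlc_chain, save_dataset)


class TestFilamentSpec:
    @pytest.mark.parametrize("kw", [
        {"contour_length": -1.0}, {"persistence_length": 0.0},
        {"segment_length": -3.0}, {"height": 0.0}, {"tube_radius": -0.1},
        {"segment_length": 40.0},  # > contour/10
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(InvalidSpecificationError):
            FilamentSpec(**kw)

    @pytest.mark.parametrize("kw", [
        {"size": 32}, {"pixel_size": 0.0}, {"tip_sigma": -1.0},
        {"noise_sigma": -0.1}, {"margin": -1}, {"filaments_per_image": (3, 2)},
    ])
    def test_invalid_image_specs_rejected(self, kw):
        with pytest.raises(InvalidSpecificationError):
            ImageSpec(**kw)


class TestWLCChain:
    def test_infinite_persistence_gives_straight_segment(self):
        spec = FilamentSpec(persistence_length=1e12)
        poly = sample_wlc_chain(spec, np.random.default_rng(0))
        end_to_end = np.hypot(*(poly[-1] - poly[0]))
        assert end_to_end == pytest.approx(300.0, abs=1e-6)

    def test_segment_count_and_exact_arc_length(self):
        spec = FilamentSpec(contour_length=300.0, segment_length=3.0)
        poly = sample_wlc_chain(spec, np.random.default_rng(1))
        assert len(poly) == 101  # 100 segments
        steps = np.hypot(*np.diff(poly, axis=0).T)
        assert np.allclose(steps, 3.0, rtol=1e-12)
        assert polyline_arc_length(poly) == pytest.approx(300.0, rel=1e-9)

    def test_turning_angle_variance_matches_generative_law(self):
        # Monte Carlo: variance of each turn should be segment/persistence
        spec = FilamentSpec(contour_length=300.0, persistence_length=6000.0,
                            segment_length=3.0)
        rng = np.random.default_rng(2)
        sq = []
        for _ in range(10_000):
            poly = sample_wlc_chain(spec, rng)
            steps = np.diff(poly, axis=0)
            ang = np.arctan2(steps[:, 1], steps[:, 0])
            turns = np.angle(np.exp(1j * np.diff(ang)))
            sq.append(np.mean(turns ** 2))
        assert np.mean(sq) == pytest.approx(3.0 / 6000.0, rel=0.05)


class TestRenderImage:
    def test_noise_only_field(self):
        spec = ImageSpec(size=256, noise_sigma=0.1, background_height=2.0)
        img = render_image([], spec, np.random.default_rng(0))
        assert img.heights.mean() == pytest.approx(2.0, abs=0.01)
        assert img.heights.std() == pytest.approx(0.1, rel=0.05)
        assert img.pixel_size == spec.pixel_size

    def test_straight_filament_no_blur_no_noise(self):
        spec = ImageSpec(size=256, tip_sigma=0.0, noise_sigma=0.0)
        fspec = FilamentSpec()
        y = (128 + 0.5) * spec.pixel_size  # through pixel centres
        poly = np.column_stack([np.linspace(100.0, 400.0, 101),
                                np.full(101, y)])
        img = render_image([poly], spec, filament_spec=fspec)
        assert img.heights.max() == pytest.approx(fspec.height, abs=1e-9)
        # supra-background pixels lie within tube_radius + 1 px of the line
        rows, cols = np.nonzero(img.heights > 0)
        x = (cols + 0.5) * spec.pixel_size
        yy = (rows + 0.5) * spec.pixel_size
        d = np.where(x < 100.0, np.hypot(x - 100.0, yy - y),
                     np.where(x > 400.0, np.hypot(x - 400.0, yy - y),
                              np.abs(yy - y)))
        assert d.max() <= fspec.tube_radius + spec.pixel_size

    def test_half_maximum_ridge_length_about_150_px(self):
        spec = ImageSpec(size=256, tip_sigma=0.0, noise_sigma=0.0)
        y = 128 * spec.pixel_size
        poly = np.column_stack([np.linspace(100.0, 400.0, 101),
                                np.full(101, y)])
        img = render_image([poly], spec)
        half = img.heights.max() / 2
        ridge_cols = (img.heights > half).any(axis=0).sum()
        assert 148 <= ridge_cols <= 152  # 300 nm at 2 nm/px

    def test_margin_violation_raises(self):
        spec = ImageSpec(size=256, margin=20)
        poly = np.array([[1.0, 100.0], [50.0, 100.0]])  # inside the margin band
        with pytest.raises(PlacementError):
            render_image([poly], spec, np.random.default_rng(0))

    def test_separation_violation_raises(self):
        spec = ImageSpec(size=256, min_separation=30.0)
        a = np.array([[100.0, 100.0], [200.0, 100.0]])
        b = a + [0.0, 10.0]  # 10 nm apart
        with pytest.raises(PlacementError):
            render_image([a, b], spec, np.random.default_rng(0))


class TestGenerateDataset:
    def test_empty_dataset(self):
        ds = generate_dataset(FilamentSpec(), ImageSpec(), 0, seed=0)
        assert ds.images == [] and ds.truths == [] and ds.n_dropped == 0

    def test_determinism_bit_identical(self):
        spec = ImageSpec(size=256, filaments_per_image=(1, 2))
        a = generate_dataset(FilamentSpec(), spec, 2, seed=5)
        b = generate_dataset(FilamentSpec(), spec, 2, seed=5)
        assert all(np.array_equal(x.heights, y.heights)
                   for x, y in zip(a.images, b.images))
        assert all(np.array_equal(s.polyline, t.polyline)
                   for s, t in zip(a.truths, b.truths))

    def test_rotate_pairs_emit_rotated_copies(self):
        spec = ImageSpec(size=256, filaments_per_image=(1, 1))
        ds = generate_dataset(FilamentSpec(), spec, 5, seed=5, rotate_pairs=True)
        assert len(ds.images) == 10
        for base, rot in zip(ds.images[::2], ds.images[1::2]):
            assert rot.id == f"{base.id}_rot90"
            assert np.array_equal(rot.heights, np.rot90(base.heights))
        rot_truths = [t for t in ds.truths if t.base_id is not None]
        assert {t.base_id for t in rot_truths} == \
            {t.id for t in ds.truths if t.base_id is None}

    def test_ground_truth_geometry_invariants(self, small_dataset):
        for t in small_dataset.truths:
            assert t.contour_length == pytest.approx(
                polyline_arc_length(t.polyline), rel=1e-12)
            assert t.contour_length == pytest.approx(300.0, rel=1e-9)
            assert t.contour_length >= t.end_to_end

    def test_crowded_config_reports_drops(self):
        # a 300 nm filament cannot fit a 128 px field inside 20 px margins
        spec = ImageSpec(size=128, filaments_per_image=(2, 2))
        ds = generate_dataset(FilamentSpec(), spec, 1, seed=0)
        assert ds.n_dropped == 2
        assert ds.truths == []

    def test_save_and_reload_ground_truth(self, tmp_path):
        spec = ImageSpec(size=256, filaments_per_image=(1, 1))
        ds = generate_dataset(FilamentSpec(), spec, 2, seed=3, rotate_pairs=True)
        save_dataset(ds, tmp_path)
        assert sorted(p.name for p in tmp_path.glob("*.tif")) == [
            "img_000.tif", "img_000_rot90.tif",
            "img_001.tif", "img_001_rot90.tif"]
        truths = load_ground_truth(tmp_path / "ground_truth.json")
        assert len(truths) == len(ds.truths)
        for got, want in zip(truths, ds.truths):
            assert got.id == want.id
            assert np.allclose(got.polyline, want.polyline)
            assert got.contour_length == pytest.approx(want.contour_length)
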