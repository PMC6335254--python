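"""Measurement chain: contrast, segmentation, calibration, area conversion."""

import numpy as np
import pytest

from pigplanim.planimetry import (
    Calibration,
    HeightMismatchError,
    NoContrastError,
    NoObjectError,
    SegmentationConfig,
    calibrate,
    enhance_contrast,
    measure_area,
    measure_batch,
    segment,
    write_measurements,
)
from pigplanim.scene import (
    ArtifactSpec,
    BoardSpec,
    SceneSpec,
    SilhouetteSpec,
    project_scale,
    render_scene,
    write_scene,
)


def _truth_raster(camera, truths, mag):
    """Rasterize ground-truth polygons with the same pixel-center rule."""
    from pigplanim.scene import _pixel_centers_inside, _project
    mask = np.zeros((camera.image_height, camera.image_width), dtype=bool)
    for t in truths:
        mask |= _pixel_centers_inside(_project(t.polygon, mag), camera)
    return mask


class TestEnhanceContrast:
    def test_two_level_image_stretched_to_extremes(self):
        img = np.full((50, 50), 40.0)
        img[10:20, 10:20] = 200.0
        out = enhance_contrast(img)
        assert out.min() == 0.0 and out.max() == 255.0

    def test_monotone_order_preserving(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(20, 210, size=(40, 40))
        out = enhance_contrast(img)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= 0).all()

    def test_idempotent_on_full_range_image(self):
        img = np.linspace(0, 255, 256).reshape(16, 16)
        once = enhance_contrast(img)
        twice = enhance_contrast(once)
        assert np.allclose(once, twice, atol=1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(NoContrastError):
            enhance_contrast(np.full((10, 10), 7.0))


class TestSegment:
    def test_silhouette_iou_against_ground_truth(self, camera, coefficients):
        spec = SilhouetteSpec("C", 110.0, shape_seed=21)
        img, truths = render_scene(SceneSpec(camera=camera, objects=[spec]),
                                   coefficients)
        mask = segment(enhance_contrast(img))
        truth = _truth_raster(camera, truths, project_scale(camera, 69.0))
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.99

    def test_exclusion_mask_removes_shadow_exactly(self, camera, coefficients):
        spec = SilhouetteSpec("B", 105.0, shape_seed=8)
        shadow = ArtifactSpec(center_m=(1.2, 0.8), semi_axes_m=(0.2, 0.12),
                              angle_deg=30.0, level=140)
        clean, _ = render_scene(SceneSpec(camera=camera, objects=[spec]),
                                coefficients)
        dirty, _ = render_scene(
            SceneSpec(camera=camera, objects=[spec], artifacts=[shadow]),
            coefficients)
        # rectangle around the shadow blob, clear of the animal
        excl = np.zeros(dirty.shape, dtype=bool)
        excl[850:, 1280:] = True
        cfg = SegmentationConfig(min_component_fraction=0.0)
        n_clean = segment(enhance_contrast(clean), cfg).sum()
        n_dirty = segment(enhance_contrast(dirty), cfg).sum()
        n_fixed = segment(enhance_contrast(dirty), cfg, exclusion_mask=excl).sum()
        assert n_dirty > n_clean  # the shadow is bright enough to pollute
        assert n_fixed == n_clean

    def test_exclusion_never_increases_count(self, camera, coefficients):
        img, _ = render_scene(
            SceneSpec(camera=camera, objects=[SilhouetteSpec("A", 100.0)]),
            coefficients)
        base = segment(enhance_contrast(img)).sum()
        excl = np.zeros(img.shape, dtype=bool)
        excl[::7] = True
        cfg = SegmentationConfig(fill_holes=False)
        assert segment(enhance_contrast(img), cfg, excl).sum() <= base

    def test_uniform_image_raises(self):
        with pytest.raises(NoObjectError):
            segment(np.full((30, 30), 25.0))

    def test_fixed_threshold_mode(self):
        img = np.full((30, 30), 10.0)
        img[5:25, 5:25] = 240.0
        mask = segment(img, SegmentationConfig(threshold_mode="fixed",
                                               fixed_threshold=128))
        assert mask.sum() == 400


class TestCalibrate:
    def test_pixels_per_m2_arithmetic(self):
        cal = Calibration(pixels_per_m2=210_000 / 0.420, reference_area_m2=0.420,
                          reference_height_cm=69.0, reference_pixel_count=210_000)
        assert cal.pixels_per_m2 == pytest.approx(500_000.0)

    def test_exposure_invariance_within_half_percent(self, camera):
        board = BoardSpec(height_cm=69.0)
        bright, _ = render_scene(SceneSpec(camera=camera, objects=[board],
                                           background_level=25,
                                           foreground_level=230))
        dim, _ = render_scene(SceneSpec(camera=camera, objects=[board],
                                        background_level=60,
                                        foreground_level=140))
        c1 = calibrate(bright, 0.420, 69.0)
        c2 = calibrate(dim, 0.420, 69.0)
        assert c1.pixels_per_m2 == pytest.approx(c2.pixels_per_m2, rel=0.005)

    def test_nonpositive_area_rejected(self, camera):
        img, _ = render_scene(SceneSpec(camera=camera,
                                        objects=[BoardSpec(height_cm=0.0)]))
        with pytest.raises(ValueError):
            calibrate(img, 0.0, 69.0)


class TestMeasureArea:
    def test_count_over_density_arithmetic(self):
        cal = Calibration(238_095.24, 0.420, 69.0, 100_000)
        mask = np.zeros((400, 400), dtype=bool)
        mask[:280, :250] = True  # 70,000 px
        m = measure_area(mask, cal, "A", subject_id="p1")
        assert m.area_m2 == pytest.approx(0.294, abs=5e-4)

    def test_standing_pig_within_one_percent_of_truth(self, camera, coefficients):
        board, _ = render_scene(SceneSpec(camera=camera,
                                          objects=[BoardSpec(height_cm=69.0)]))
        cal = calibrate(board, 0.420, 69.0)
        img, truths = render_scene(
            SceneSpec(camera=camera, objects=[SilhouetteSpec("D", 115.0,
                                                             shape_seed=4)]),
            coefficients)
        m = measure_area(img, cal, "D")
        assert m.area_m2 == pytest.approx(truths[0].planform_area_m2, rel=0.01)

    def test_height_mismatch_strict_raises_lenient_warns(self, camera):
        cal = Calibration(1e5, 0.420, 29.0, 42_000)
        mask = np.ones((10, 10), dtype=bool)
        with pytest.raises(HeightMismatchError):
            measure_area(mask, cal, "A",
                         config=SegmentationConfig(strict_heights=True))
        with pytest.warns(UserWarning):
            measure_area(mask, cal, "A")

    def test_scale_invariance_of_measured_area(self, coefficients):
        from pigplanim.scene import CameraModel
        areas = []
        for s in (400.0, 800.0):
            cam = CameraModel(image_width=int(3.2 * s),
                              image_height=int(2.2 * s), floor_scale=s)
            board, _ = render_scene(SceneSpec(camera=cam,
                                              objects=[BoardSpec(height_cm=29.0)]))
            cal = calibrate(board, 0.420, 29.0)
            img, _ = render_scene(
                SceneSpec(camera=cam,
                          objects=[SilhouetteSpec("LSL", 110.0, shape_seed=6)]),
                coefficients)
            areas.append(measure_area(img, cal, "LSL").area_m2)
        assert areas[0] == pytest.approx(areas[1], rel=0.005)

    def test_monotonic_in_silhouette_size(self, camera, coefficients):
        board, _ = render_scene(SceneSpec(camera=camera,
                                          objects=[BoardSpec(height_cm=69.0)]))
        cal = calibrate(board, 0.420, 69.0)
        prev = 0.0
        for w in (80.0, 100.0, 120.0):
            img, _ = render_scene(
                SceneSpec(camera=camera,
                          objects=[SilhouetteSpec("C", w, shape_seed=2)]),
                coefficients)
            area = measure_area(img, cal, "C").area_m2
            assert area > prev
            prev = area


class TestMeasureBatch:
    @pytest.fixture()
    def batch_dir(self, tmp_path, camera, coefficients):
        rows = ["filename,subject_id,posture,weight_kg"]
        for i, code in enumerate(["A", "CS", "LL"]):
            spec = SilhouetteSpec(code, 100.0 + i, shape_seed=i)
            img, truths = render_scene(SceneSpec(camera=camera, objects=[spec]),
                                       coefficients)
            write_scene(img, truths, tmp_path / f"{code}.png")
            rows.append(f"{code}.png,pig{i},{code},{100.0 + i}")
        (tmp_path / "manifest.csv").write_text("\n".join(rows) + "\n")
        cals = {}
        for h in (69.0, 29.0):
            img, _ = render_scene(SceneSpec(camera=camera,
                                            objects=[BoardSpec(height_cm=h)]))
            cals[h] = calibrate(img, 0.420, h)
        return tmp_path, cals

    def test_batch_measures_all_and_lying_exceeds_standing(self, batch_dir):
        tmp_path, cals = batch_dir
        res = measure_batch(tmp_path, tmp_path / "manifest.csv", cals)
        assert len(res.measurements) == 3 and not res.failures
        by = {m.posture: m.area_m2 for m in res.measurements}
        assert by["LL"] > max(by["A"], by["CS"])

    def test_missing_file_reported_not_dropped(self, batch_dir):
        tmp_path, cals = batch_dir
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(manifest.read_text()
                            + "ghost.png,pigx,B,101.0\n")
        res = measure_batch(tmp_path, manifest, cals)
        assert len(res.measurements) == 3
        assert len(res.failures) == 1 and "ghost.png" in res.failures[0][0]

    def test_empty_manifest_warns(self, tmp_path, batch_dir):
        _, cals = batch_dir
        empty = tmp_path / "empty.csv"
        empty.write_text("filename,subject_id,posture,weight_kg\n")
        with pytest.warns(UserWarning):
            res = measure_batch(tmp_path, empty, cals)
        assert res.measurements == []

    def test_measurements_csv_round_trip(self, batch_dir, tmp_path):
        dir_, cals = batch_dir
        res = measure_batch(dir_, dir_ / "manifest.csv", cals)
        out = tmp_path / "meas.csv"
        write_measurements(res.measurements, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 4 and lines[0].startswith("subject_id")
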