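"""Mask extraction, scoring and full-pipeline behavior."""

import numpy as np
import pytest

from echocalc.enhance import EnhanceConfig
from echocalc.image import RectROI, ValidationError
from echocalc.normalize import NormalizationContext
from echocalc.phantom import (AcquisitionSettings, Ellipse, PhantomScene,
                              default_scene, render)
from echocalc.quantify import (CalciumMask, PipelineConfig,
                               extract_calcium_mask, quantify, run_pipeline)


class TestExtractMask:
    def test_all_black_roi_gives_empty_mask(self):
        binary = np.zeros((6, 6), np.uint8)
        assert extract_calcium_mask(binary, RectROI(1, 1, 3, 3)).count == 0

    def test_all_white_roi_counts_every_pixel(self):
        binary = np.full((6, 6), 255, np.uint8)
        assert extract_calcium_mask(binary, RectROI(2, 2, 3, 3)).count == 9

    def test_checkerboard_enumeration(self):
        binary = np.indices((4, 4)).sum(axis=0) % 2 * 255
        mask = extract_calcium_mask(binary.astype(np.uint8), RectROI(0, 0, 4, 4))
        assert mask.count == 8
        expected = {(r, c) for r in range(4) for c in range(4) if (r + c) % 2}
        assert {tuple(rc) for rc in mask.coords} == expected

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            extract_calcium_mask(np.zeros((4, 4), np.uint8), RectROI(2, 2, 4, 4))

    def test_coordinate_outside_roi_rejected(self):
        with pytest.raises(ValidationError):
            CalciumMask(roi=RectROI(0, 0, 2, 2), coords=np.array([[5, 5]]))


class TestQuantify:
    def test_empty_mask_reports_absent_statistics(self):
        mask = CalciumMask(roi=RectROI(0, 0, 2, 2), coords=np.empty((0, 2)))
        rep = quantify(np.zeros((4, 4), np.uint8), mask, NormalizationContext())
        assert rep.white_pixel_count == 0
        assert rep.raw_mean is None and rep.normalized_mean is None

    def test_two_pixel_hand_arithmetic(self):
        img = np.zeros((4, 4), np.uint8)
        img[1, 1], img[1, 2] = 180, 190
        mask = CalciumMask(roi=RectROI(0, 0, 4, 4),
                           coords=np.array([[1, 1], [1, 2]]))
        ctx = NormalizationContext(dark_reference=10.0)
        rep = quantify(img, mask, ctx)
        assert rep.white_pixel_count == 2
        assert rep.raw_mean == 185 and rep.raw_median == 185
        assert rep.normalized_mean == 175
        assert rep.normalized_median == 175

    def test_coordinate_outside_image_rejected(self):
        mask = CalciumMask(roi=RectROI(0, 0, 9, 9), coords=np.array([[8, 8]]))
        with pytest.raises(ValidationError):
            quantify(np.zeros((4, 4), np.uint8), mask, NormalizationContext())


def _scene_with_blobs(blobs):
    return PhantomScene(
        tissue_level=80.0,
        cavities=(Ellipse(cy=120, cx=60, ry=20, rx=14, intensity=18.0),),
        calcium_blobs=blobs,
        speckle_sigma=0.0,
        seed=0,
    )


class TestRunPipeline:
    def test_blank_image_yields_zero_count(self):
        img = np.zeros((64, 64), np.uint8)
        cfg = PipelineConfig(valve_roi=RectROI(10, 10, 20, 20),
                             dark_roi=RectROI(40, 40, 8, 8))
        rep = run_pipeline(img, cfg)
        assert rep.white_pixel_count == 0
        assert rep.effective_threshold == 160

    def test_phantom_count_within_calibrated_band(self, noisy_scene):
        rend = render(noisy_scene, AcquisitionSettings(seed=11))
        cfg = PipelineConfig(valve_roi=noisy_scene.valve_roi(),
                             dark_roi=noisy_scene.dark_roi())
        rep = run_pipeline(rend.image, cfg)
        assert 0.8 * rend.truth_count <= rep.white_pixel_count <= 1.3 * rend.truth_count

    def test_count_additivity_for_disjoint_blobs(self):
        blob_a = Ellipse(cy=100, cx=120, ry=9, rx=9, intensity=220.0)
        blob_b = Ellipse(cy=140, cx=110, ry=7, rx=7, intensity=220.0)
        valve = RectROI(x0=95, y0=85, width=45, height=70)
        counts = {}
        for name, blobs in [("a", (blob_a,)), ("b", (blob_b,)),
                            ("ab", (blob_a, blob_b))]:
            scene = _scene_with_blobs(blobs)
            rend = render(scene)
            cfg = PipelineConfig(valve_roi=valve, dark_roi=scene.dark_roi())
            counts[name] = run_pipeline(rend.image, cfg).white_pixel_count
        assert counts["ab"] == counts["a"] + counts["b"]

    def test_two_blobs_reported_as_two_components(self):
        scene = _scene_with_blobs((
            Ellipse(cy=100, cx=120, ry=9, rx=9, intensity=220.0),
            Ellipse(cy=140, cx=110, ry=7, rx=7, intensity=220.0)))
        rend = render(scene)
        cfg = PipelineConfig(valve_roi=RectROI(95, 85, 45, 70),
                             dark_roi=scene.dark_roi())
        rep = run_pipeline(rend.image, cfg)
        assert len(rep.component_sizes) == 2
        assert sum(rep.component_sizes) == rep.white_pixel_count

    def test_identical_inputs_give_identical_reports(self, noisy_scene):
        rend = render(noisy_scene, AcquisitionSettings(seed=2))
        cfg = PipelineConfig(valve_roi=noisy_scene.valve_roi(),
                             dark_roi=noisy_scene.dark_roi())
        rep1 = run_pipeline(rend.image, cfg)
        rep2 = run_pipeline(rend.image, cfg)
        assert rep1.to_dict() == rep2.to_dict()

    def test_count_monotone_in_base_threshold(self, noisy_scene):
        rend = render(noisy_scene, AcquisitionSettings(seed=3))
        counts = []
        for base in (120, 150, 180, 210):
            cfg = PipelineConfig(valve_roi=noisy_scene.valve_roi(),
                                 dark_roi=noisy_scene.dark_roi(),
                                 enhance=EnhanceConfig(base_threshold=base))
            counts.append(run_pipeline(rend.image, cfg).white_pixel_count)
        assert counts == sorted(counts, reverse=True)

    def test_quantifies_unblurred_gain_compensated_image(self):
        # reported intensities come from the pre-blur image: with a noiseless
        # blob the raw mean equals the blob level exactly even though the
        # blurred image decided the mask
        scene = default_scene(seed=0, speckle_sigma=0.0)
        rend = render(scene, AcquisitionSettings(postproc_gain=20.0))
        cfg = PipelineConfig(valve_roi=scene.valve_roi(),
                             dark_roi=scene.dark_roi(),
                             outside_roi=scene.outside_roi(),
                             compensate_gain=True, apply_dilation=False)
        rep = run_pipeline(rend.image, cfg)
        assert rep.context.postproc_gain == 20.0
        assert rep.raw_mean == 220.0
        assert rep.normalized_mean == pytest.approx(220.0 - 18.0)

    def test_compensation_config_requires_outside_roi(self):
        with pytest.raises(ValidationError):
            PipelineConfig(valve_roi=RectROI(0, 0, 4, 4),
                           dark_roi=RectROI(5, 5, 4, 4),
                           compensate_gain=True)


def test_report_writers_roundtrip(tmp_path, noisy_scene):
    import csv
    import json

    from echocalc.quantify import write_report_json, write_reports_csv

    rend = render(noisy_scene, AcquisitionSettings(seed=4))
    cfg = PipelineConfig(valve_roi=noisy_scene.valve_roi(),
                         dark_roi=noisy_scene.dark_roi())
    rep = run_pipeline(rend.image, cfg, image_id="phantom0")
    write_reports_csv([rep], tmp_path / "reports.csv")
    with open(tmp_path / "reports.csv") as fh:
        rows = list(csv.DictReader(fh))
    assert rows[0]["image_id"] == "phantom0"
    assert int(rows[0]["white_pixel_count"]) == rep.white_pixel_count
    write_report_json(rep, tmp_path / "rep.json", config_echo={"x": 1})
    payload = json.loads((tmp_path / "rep.json").read_text())
    assert payload["white_pixel_count"] == rep.white_pixel_count
    assert payload["config"] == {"x": 1}
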