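"""Cross-sections, Feret diameters, thrombus volume, and the case pipeline."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from aortascreen.errors import ValidationError
from aortascreen.morphometry import (CrossSection, generate_sections,
                                     max_abdominal_diameter,
                                     section_diameter_of_contour, thrombus_volume,
                                     write_case_report)
from aortascreen.volume_io import LabelVolume


def _circle(r, n=100, z=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t), np.full(n, z)])


class TestFeretDiameter:
    def test_circle(self):
        assert section_diameter_of_contour(_circle(12.5)) == pytest.approx(25.0, abs=0.05)

    def test_ellipse_feret_is_major_axis(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ellipse = np.column_stack([20 * np.cos(t), 8 * np.sin(t), np.zeros_like(t)])
        assert section_diameter_of_contour(ellipse) == pytest.approx(40.0, abs=0.1)

    def test_wall_to_wall_not_equivalent_circle(self):
        # an elongated contour: max Feret exceeds the equivalent-circle diameter
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        ellipse = np.column_stack([20 * np.cos(t), 8 * np.sin(t), np.zeros_like(t)])
        feret = section_diameter_of_contour(ellipse)
        d_eq = 2 * np.sqrt(np.pi * 20 * 8 / np.pi)
        assert feret > d_eq + 10.0

    def test_degenerate_contour(self):
        with pytest.raises(ValidationError):
            section_diameter_of_contour(np.zeros((2, 3)))


class TestMaxDiameter:
    def _sec(self, d, z):
        return CrossSection(center=np.array([0.0, 0.0, z]), normal=np.array([0, 0, 1.0]),
                            contour=_circle(d / 2, z=z), diameter=d,
                            equivalent_diameter=d, area=np.pi * (d / 2) ** 2,
                            arc_length=100.0 - z)

    def test_picks_largest(self):
        sections = [self._sec(20, 80.0), self._sec(45, 60.0), self._sec(30, 40.0)]
        d, best = max_abdominal_diameter(sections)
        assert d == 45 and best.z == 60.0

    def test_tie_breaks_superior(self):
        sections = [self._sec(30, 40.0), self._sec(30, 70.0)]
        _, best = max_abdominal_diameter(sections)
        assert best.z == 70.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            max_abdominal_diameter([])


class TestThrombusVolume:
    def test_none_is_zero(self):
        assert thrombus_volume(None) == 0.0

    def test_counts_times_voxel_volume(self):
        v = np.zeros((10, 10, 10), np.uint8)
        v[:5, :5, :4] = 1  # 100 voxels
        vol = LabelVolume(v, (1.0, 2.0, 2.5))  # 5 mm^3 per voxel
        assert thrombus_volume(vol) == pytest.approx(0.5)


class TestGenerateSections:
    def test_straight_tube_sections(self):
        from aortascreen.centerline import compute_centerline
        from aortascreen.phantoms import PhantomSpec, generate_phantom
        from aortascreen.surface import extract_surface

        lumen, _, _ = generate_phantom(PhantomSpec(
            trunk="straight", straight_length=80.0, lumen_radius=8.0,
            spacing=(0.75,) * 3))
        cal = compute_centerline(lumen, np.array([0.0, 0.0, 80.0]),
                                 [np.array([0.0, 0.0, 0.0])])
        surf = extract_surface(lumen)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sections = generate_sections(surf, cal, step=5.0)
        assert len(sections) >= 10
        mid = [s for s in sections if 15.0 < s.z < 65.0]
        diam = np.array([s.diameter for s in mid])
        assert np.all(np.abs(diam - 16.0) < 1.0)
        areas = np.array([s.area for s in mid])
        assert np.all(np.abs(areas - np.pi * 64.0) / (np.pi * 64.0) < 0.1)

    def test_exclusion_tube_skips_stations(self):
        from aortascreen.centerline import compute_centerline
        from aortascreen.phantoms import PhantomSpec, generate_phantom
        from aortascreen.surface import extract_surface

        lumen, _, _ = generate_phantom(PhantomSpec(
            trunk="straight", straight_length=60.0, lumen_radius=7.0,
            spacing=(0.75,) * 3))
        cal = compute_centerline(lumen, np.array([0.0, 0.0, 60.0]),
                                 [np.array([0.0, 0.0, 0.0])])
        surf = extract_surface(lumen)
        tube = (np.array([[0.0, 0.0, 30.0]]), np.array([6.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = generate_sections(surf, cal, step=5.0)
            excl = generate_sections(surf, cal, step=5.0, exclusion_tubes=[tube])
        assert len(excl) < len(base)
        assert all(abs(s.z - 30.0) > 5.0 for s in excl)


class TestMeasureCase:
    def test_aaa_diameter_matches_truth(self, aaa_case):
        res, truth = aaa_case["result"], aaa_case["truth"]
        tol = max(0.02 * truth.max_outer_diameter, 1.3)
        assert abs(res.max_diameter - truth.max_outer_diameter) <= tol
        assert abs(res.max_z - truth.max_z) < 10.0
        assert res.used_thrombus

    def test_aaa_thrombus_volume_matches_truth(self, aaa_case):
        res, truth = aaa_case["result"], aaa_case["truth"]
        assert res.thrombus_volume_ml == pytest.approx(truth.thrombus_volume_ml, rel=0.05)

    def test_control_diameter_matches_truth(self, control_case):
        res, truth = control_case["result"], control_case["truth"]
        tol = max(0.02 * truth.max_outer_diameter, 1.3)
        assert abs(res.max_diameter - truth.max_outer_diameter) <= tol
        assert not res.used_thrombus
        assert res.thrombus_volume_ml == 0.0

    def test_stage_log_and_report(self, aaa_case, tmp_path):
        res = aaa_case["result"]
        for name in ("validate", "fuse", "smooth", "axial_bounds", "crop", "skeleton",
                     "centerline", "surface", "branches", "clip_abdominal",
                     "sections", "maximum"):
            assert name in res.stage_log
            assert res.stage_log[name]["seconds"] >= 0
        jpath = tmp_path / "report.json"
        cpath = tmp_path / "profile.csv"
        write_case_report(res, str(jpath), str(cpath))
        import json

        report = json.loads(jpath.read_text())
        assert report["max_diameter_mm"] == pytest.approx(res.max_diameter)
        assert report["thrombus_volume_ml"] == pytest.approx(res.thrombus_volume_ml)
        import pandas as pd

        prof = pd.read_csv(cpath)
        assert len(prof) == res.n_sections
        assert {"arc_length_mm", "diameter_mm", "area_mm2"} <= set(prof.columns)

    def test_empty_lumen_rejected(self):
        from aortascreen.errors import StageError
        from aortascreen.morphometry import measure_case

        empty = LabelVolume(np.zeros((5, 5, 5), np.uint8), (1, 1, 1))
        with pytest.raises(StageError):
            measure_case(empty)
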