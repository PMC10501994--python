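"""Phantom generator: determinism, analytic truth, and the cohort factory."""

from __future__ import annotations

import json

import numpy as np
import pytest

from aortascreen.errors import ValidationError
from aortascreen.phantoms import (BranchSpec, BulgeSpec, PhantomSpec, cohort_factory,
                                  cohort_specs, generate_phantom, standard_spec)


class TestGeneration:
    def test_deterministic_for_fixed_seed(self):
        spec = standard_spec(40.0, with_thrombus=True, seed=9, noise=0.3)
        l1, t1, _ = generate_phantom(spec)
        l2, t2, _ = generate_phantom(standard_spec(40.0, with_thrombus=True, seed=9, noise=0.3))
        assert np.array_equal(l1.voxels, l2.voxels)
        assert np.array_equal(t1.voxels, t2.voxels)

    def test_straight_tube_volume_matches_analytic(self):
        spec = PhantomSpec(trunk="straight", straight_length=60.0, lumen_radius=8.0,
                           spacing=(0.75,) * 3)
        lumen, _, _ = generate_phantom(spec)
        v_vox = lumen.count_foreground() * lumen.voxel_volume_mm3
        # cylinder plus two hemispherical end caps (distance-to-curve model)
        v_true = np.pi * 64.0 * 60.0 + 4 / 3 * np.pi * 8.0 ** 3
        assert v_vox == pytest.approx(v_true, rel=0.03)

    def test_thrombus_is_annulus_outside_lumen(self):
        lumen, thrombus, _ = generate_phantom(standard_spec(50.0, with_thrombus=True))
        assert not np.any(lumen.voxels.astype(bool) & thrombus.voxels.astype(bool))
        assert thrombus.count_foreground() > 0

    def test_control_has_no_thrombus(self):
        _, thrombus, truth = generate_phantom(standard_spec(24.0, with_thrombus=False))
        assert thrombus.count_foreground() == 0
        assert truth.thrombus_volume_ml == 0.0
        assert truth.label == "control"


class TestAnalyticTruth:
    def test_requested_diameter_is_exact(self):
        for d in (24.0, 35.0, 60.0):
            spec = standard_spec(d, with_thrombus=d > 30)
            _, _, truth = generate_phantom(spec)
            assert truth.max_outer_diameter == pytest.approx(d, abs=0.05)

    def test_truth_levels_present(self):
        _, _, truth = generate_phantom(standard_spec(50.0))
        assert len(truth.renal_z) == 2
        assert truth.renal_z[0] == pytest.approx(115.0, abs=0.5)
        assert truth.iliac_z == pytest.approx(25.0, abs=0.5)
        assert truth.iliac_detect_z is not None and truth.iliac_detect_z < truth.iliac_z
        assert truth.arch_apex_z == pytest.approx(215.0, abs=0.5)
        assert truth.arch_merge_z is not None and truth.arch_merge_z < truth.arch_apex_z
        assert truth.label == "AAA"

    def test_thrombus_volume_is_annulus_integral(self):
        # spot check against the closed-form Gaussian-annulus integral:
        # integral of pi*((r+t)^2 - r^2) ds with r, t Gaussian profiles
        spec = standard_spec(50.0, with_thrombus=True)
        _, _, truth = generate_phantom(spec)
        r0, a_l = spec.lumen_radius, spec.lumen_bulge.amplitude
        a_t, sig = spec.thrombus_bulge.amplitude, spec.thrombus_bulge.sigma
        # pi * (2*r*t + t^2), with r = r0 + a_l*g(s), t = a_t*g(s), g Gaussian
        s2pi = np.sqrt(2 * np.pi) * sig
        v = np.pi * (2 * r0 * a_t * s2pi
                     + (2 * a_l * a_t + a_t ** 2) * s2pi / np.sqrt(2))
        assert truth.thrombus_volume_ml == pytest.approx(v / 1000.0, rel=0.01)

    def test_max_location_in_abdomen(self):
        _, _, truth = generate_phantom(standard_spec(60.0))
        assert truth.max_z == pytest.approx(65.0, abs=1.0)

    def test_truth_dict_is_json_serializable(self):
        _, _, truth = generate_phantom(standard_spec(40.0))
        json.dumps(truth.to_dict())


class TestValidation:
    def test_negative_radius(self):
        with pytest.raises(ValidationError):
            PhantomSpec(lumen_radius=-1.0)

    def test_bulge_overlapping_branch_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PhantomSpec(trunk="straight", straight_length=100.0,
                        lumen_bulge=BulgeSpec(center=50.0, amplitude=5.0, sigma=10.0),
                        branches=[BranchSpec(arc_length=55.0, direction=(0, 1, 0),
                                             radius=3.0, length=10.0)])

    def test_points_trunk_requires_control_points(self):
        from aortascreen.phantoms import trunk_curve

        with pytest.raises(ValidationError):
            trunk_curve(PhantomSpec(trunk="points"))


class TestCohortFactory:
    def test_cohort_specs_respect_margin(self):
        specs = cohort_specs(5, 5, seed=1, threshold_margin_mm=3.0)
        assert len(specs) == 10
        for cid, spec, d in specs:
            if cid.startswith("aaa"):
                assert d >= 33.0
            else:
                assert d <= 27.0

    def test_factory_writes_manifest_and_truth(self, tmp_path):
        from aortascreen.volume_io import load_case_masks, read_manifest

        out = tmp_path / "cohort"
        manifest = cohort_factory(1, 1, seed=5, out_dir=str(out))
        assert len(manifest) == 2
        df = read_manifest(str(out / "manifest.csv"))
        assert set(df["case_id"]) == {"aaa_000", "ctl_000"}
        lum, thr = load_case_masks(df.iloc[0])
        assert lum.count_foreground() > 0
        truth = json.loads((out / "aaa_000_truth.json").read_text())
        assert truth["max_outer_diameter"] == pytest.approx(
            float(df.iloc[0]["manual_diameter_mm"]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            cohort_specs(-1, 0)
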