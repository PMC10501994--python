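"""Axial bounding, skeletonization, seeds, and the refined centerline."""

from __future__ import annotations

import numpy as np
import pytest

from aortascreen.centerline import (compute_centerline, crop_mask_to_bounds,
                                    find_axial_bounds, find_endpoints,
                                    largest_component, pick_seeds, prune_skeleton,
                                    skeletonize_lumen)
from aortascreen.errors import ValidationError
from aortascreen.phantoms import PhantomSpec, generate_phantom
from aortascreen.volume_io import LabelVolume


def _straight_tube(length=80.0, radius=8.0, spacing=0.75):
    spec = PhantomSpec(trunk="straight", straight_length=length,
                       lumen_radius=radius, spacing=(spacing,) * 3)
    lumen, _, _ = generate_phantom(spec)
    return lumen


class TestAxialBounds:
    def test_candy_cane_bounds_match_analytic_levels(self, aaa_case):
        from aortascreen.surface import fuse_lumen_thrombus, smooth_mask

        truth = aaa_case["truth"]
        fused = fuse_lumen_thrombus(aaa_case["lumen"], aaa_case["thrombus"])
        bounds = find_axial_bounds(smooth_mask(fused, 1.5))
        assert not bounds.degenerate
        # arch level: slice where the ascending and descending limbs merge
        assert bounds.z_arch == pytest.approx(truth.arch_merge_z, abs=2.5)
        # iliac level: slice where the iliac limbs separate
        assert bounds.z_iliac == pytest.approx(truth.iliac_detect_z, abs=2.5)

    def test_straight_tube_degenerates_to_extent(self):
        lumen = _straight_tube()
        bounds = find_axial_bounds(lumen)
        assert bounds.degenerate
        z = np.flatnonzero(lumen.voxels.any(axis=(0, 1)))
        assert bounds.z_iliac == pytest.approx(lumen.z_of_slice(int(z[0])))
        assert bounds.z_arch == pytest.approx(lumen.z_of_slice(int(z[-1])))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            find_axial_bounds(LabelVolume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))


class TestCrop:
    def test_crop_mask_keeps_z_window(self):
        lumen = _straight_tube(length=60.0)
        out = crop_mask_to_bounds(lumen, z_arch=40.0, z_iliac=10.0)
        zs = [out.z_of_slice(k) for k in range(out.shape[2])
              if out.voxels[:, :, k].any()]
        assert min(zs) >= 10.0 - 1e-9 and max(zs) <= 40.0 + 1e-9

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            crop_mask_to_bounds(_straight_tube(), 10.0, 40.0)

    def test_largest_component(self):
        v = np.zeros((10, 10, 10), np.uint8)
        v[1:5, 1:5, 1:5] = 1
        v[8, 8, 8] = 1
        out = largest_component(LabelVolume(v, (1, 1, 1)))
        assert out.count_foreground() == 64
        assert out.voxels[8, 8, 8] == 0


class TestSkeleton:
    def test_straight_tube_skeleton_has_two_endpoints(self):
        lumen = _straight_tube()
        skel = prune_skeleton(skeletonize_lumen(lumen))
        eps = find_endpoints(skel)
        assert len(eps) == 2
        z = sorted(lumen.index_to_mm(np.asarray(eps, float))[:, 2])
        assert z[0] < 20.0 and z[1] > 60.0

    def test_anisotropic_spacing_rejected(self):
        v = np.ones((5, 5, 5), np.uint8)
        with pytest.raises(ValidationError, match="isotropic"):
            skeletonize_lumen(LabelVolume(v, (1.0, 1.0, 2.0)))

    def test_prune_removes_short_limb(self):
        v = np.zeros((30, 30, 30), np.uint8)
        v[15, 15, 5:26] = 1  # main chain along z
        for i in range(1, 4):  # 3-voxel diagonal spur off the middle
            v[15 + i, 15 + i, 15] = 1
        skel = LabelVolume(v, (1, 1, 1))
        pruned = prune_skeleton(skel, min_length_mm=5.0)
        assert pruned.voxels[18, 18, 15] == 0
        assert len(find_endpoints(pruned)) == 2

    def test_prune_keeps_long_limbs(self):
        v = np.zeros((30, 30, 30), np.uint8)
        v[15, 15, 5:26] = 1
        skel = LabelVolume(v, (1, 1, 1))
        pruned = prune_skeleton(skel, min_length_mm=5.0)
        assert pruned.count_foreground() == 21


class TestSeeds:
    def test_source_is_most_superior(self):
        pts = np.array([[0, 0, 10.0], [5, 5, 80.0], [1, 1, 30.0]])
        source, targets = pick_seeds(pts)
        assert np.allclose(source, [5, 5, 80.0])
        assert len(targets) == 2
        assert not any(np.allclose(t, source) for t in targets)

    def test_needs_two_endpoints(self):
        with pytest.raises(ValidationError):
            pick_seeds(np.array([[0, 0, 0.0]]))


class TestComputeCenterline:
    def test_straight_cylinder_axis_recovery(self):
        lumen = _straight_tube(length=80.0, radius=8.0)
        cal = compute_centerline(lumen, np.array([0.0, 0.0, 80.0]),
                                 [np.array([0.0, 0.0, 0.0])])
        assert len(cal.branches) == 1
        b = cal.branches[0]
        radial = np.hypot(b.points[:, 0], b.points[:, 1])
        assert radial.max() < 0.5
        assert b.arc_length[-1] == pytest.approx(80.0, rel=0.02)
        # arc-length resampling at the default 2.5 mm step
        steps = np.diff(b.arc_length)
        assert np.all(steps[:-1] == pytest.approx(2.5, abs=0.3))
        # tangents follow the axis
        assert np.abs(b.tangents[:, 2]).min() > 0.95

    def test_inscribed_radius_estimate(self):
        lumen = _straight_tube(length=80.0, radius=8.0)
        cal = compute_centerline(lumen, np.array([0.0, 0.0, 80.0]),
                                 [np.array([0.0, 0.0, 0.0])])
        mid = cal.branches[0].radius[2:-2]
        assert np.all(mid > 5.5) and np.all(mid < 8.5)

    def test_seed_projection_and_limits(self):
        lumen = _straight_tube(length=40.0, radius=6.0)
        # seeds slightly off the interior are projected onto it
        cal = compute_centerline(lumen, np.array([2.0, 2.0, 41.0]),
                                 [np.array([-2.0, 1.0, -1.0])])
        assert cal.branches[0].length > 30.0
        with pytest.raises(ValidationError):
            compute_centerline(lumen, np.array([100.0, 100.0, 100.0]),
                               [np.array([0.0, 0.0, 0.0])])

    def test_empty_interior_rejected(self):
        vol = LabelVolume(np.zeros((5, 5, 5), np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError):
            compute_centerline(vol, np.zeros(3), [np.ones(3)])

    def test_exports(self, tmp_path):
        lumen = _straight_tube(length=40.0, radius=6.0)
        cal = compute_centerline(lumen, np.array([0.0, 0.0, 40.0]),
                                 [np.array([0.0, 0.0, 0.0])])
        csv = tmp_path / "cal.csv"
        vtp = tmp_path / "cal.vtp"
        cal.export_csv(str(csv))
        cal.export_vtp(str(vtp))
        import pandas as pd

        df = pd.read_csv(csv)
        assert {"branch_id", "x", "y", "z", "arc_length_mm", "radius_mm"} <= set(df.columns)
        assert len(df) == len(cal.branches[0].points)
        assert "<VTKFile" in vtp.read_text()[:200]
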