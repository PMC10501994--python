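"""Label-volume geometry, I/O round-trips, resampling, and manifests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aortascreen.errors import ValidationError
from aortascreen.volume_io import (LabelVolume, ProbabilityMap, load_case_masks,
                                   read_label_volume, read_manifest,
                                   resample_isotropic, split_labels,
                                   write_label_volume)


def _ball(shape=(20, 20, 20), r=6.0, spacing=(1.0, 1.0, 1.0)):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    c = [a.mean() for a in ax]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    m = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2) <= r ** 2
    return m.astype(np.uint8)


class TestLabelVolume:
    def test_index_mm_roundtrip(self):
        vol = LabelVolume(np.zeros((4, 5, 6), np.uint8), (0.5, 0.75, 2.0), (1.0, -2.0, 3.0))
        idx = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        mm = vol.index_to_mm(idx)
        assert np.allclose(mm[0], [1.5, -0.5, 9.0])
        assert np.allclose(vol.mm_to_index(mm), idx)

    def test_z_of_slice_and_voxel_volume(self):
        vol = LabelVolume(np.zeros((2, 2, 4), np.uint8), (0.5, 0.5, 2.0), (0, 0, 10.0))
        assert vol.z_of_slice(3) == pytest.approx(16.0)
        assert vol.voxel_volume_mm3 == pytest.approx(0.5)

    def test_rejects_bad_shapes_and_spacing(self):
        with pytest.raises(ValidationError):
            LabelVolume(np.zeros((4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(ValidationError):
            LabelVolume(np.zeros((4, 4, 4), np.uint8), (1, 0, 1))

    def test_validate_labels(self):
        v = np.zeros((3, 3, 3), np.uint8)
        v[1, 1, 1] = 3
        with pytest.raises(ValidationError, match="3"):
            LabelVolume(v, (1, 1, 1)).validate_labels()

    def test_probability_map_range(self):
        with pytest.raises(ValidationError):
            ProbabilityMap(np.full((2, 2, 2), 1.5), (1, 1, 1))


class TestFileRoundtrips:
    @pytest.mark.parametrize("ext", ["nii.gz", "mha"])
    def test_write_read_roundtrip(self, tmp_path, ext):
        voxels = _ball()
        voxels[2, 2, 2] = 2
        vol = LabelVolume(voxels, (0.8, 0.9, 1.1), (-3.0, 4.0, 7.0))
        path = str(tmp_path / f"case.{ext}")
        write_label_volume(vol, path)
        back = read_label_volume(path)
        assert np.array_equal(back.voxels, vol.voxels)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)

    def test_missing_file_raises_ioerror(self, tmp_path):
        with pytest.raises(IOError):
            read_label_volume(str(tmp_path / "nope.nii.gz"))

    def test_unknown_extension(self, tmp_path):
        with pytest.raises(ValidationError):
            write_label_volume(LabelVolume(np.zeros((2, 2, 2), np.uint8), (1, 1, 1)),
                               str(tmp_path / "case.npy"))

    def test_bad_labels_rejected_on_read(self, tmp_path):
        v = np.zeros((4, 4, 4), np.uint8)
        v[1, 1, 1] = 7
        import nibabel as nib

        nib.save(nib.Nifti1Image(v, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValidationError, match="7"):
            read_label_volume(str(tmp_path / "bad.nii.gz"))


class TestSplitAndResample:
    def test_split_labels(self):
        v = np.zeros((4, 4, 4), np.uint8)
        v[0, 0, 0] = 1
        v[1, 1, 1] = 2
        lum, thr = split_labels(LabelVolume(v, (1, 1, 1)))
        assert lum.count_foreground() == 1 and lum.voxels[0, 0, 0] == 1
        assert thr.count_foreground() == 1 and thr.voxels[1, 1, 1] == 1

    def test_resample_isotropic_preserves_volume(self):
        m = _ball(shape=(30, 30, 16), r=9.0, spacing=(1.0, 1.0, 2.0))
        vol = LabelVolume(m, (1.0, 1.0, 2.0), (5.0, 5.0, 5.0))
        iso = resample_isotropic(vol, 1.0)
        assert iso.spacing == (1.0, 1.0, 1.0)
        v_old = vol.count_foreground() * vol.voxel_volume_mm3
        v_new = iso.count_foreground() * iso.voxel_volume_mm3
        assert v_new == pytest.approx(v_old, rel=0.05)
        # physical extent preserved to within one voxel per axis
        old_ext = np.asarray(vol.shape) * np.asarray(vol.spacing)
        new_ext = np.asarray(iso.shape) * np.asarray(iso.spacing)
        assert np.all(np.abs(old_ext - new_ext) <= 1.0 + 1e-9)

    def test_resample_noop_when_isotropic(self):
        vol = LabelVolume(_ball(), (1.0, 1.0, 1.0))
        assert resample_isotropic(vol, 1.0) is vol


class TestManifest:
    def test_read_manifest_and_load_multilabel(self, tmp_path):
        v = _ball()
        v[v > 0] = 1
        v[10, 10, 10] = 2
        path = str(tmp_path / "case.nii.gz")
        write_label_volume(LabelVolume(v, (1, 1, 1)), path)
        mpath = tmp_path / "manifest.csv"
        pd.DataFrame([{"case_id": "c1", "lumen_path": path}]).to_csv(mpath, index=False)
        df = read_manifest(str(mpath))
        assert {"case_id", "lumen_path", "thrombus_path", "manual_diameter_mm"} <= set(df.columns)
        lum, thr = load_case_masks(df.iloc[0])
        assert lum.count_foreground() == int((v == 1).sum())
        assert thr.count_foreground() == 1

    def test_read_manifest_requires_columns(self, tmp_path):
        mpath = tmp_path / "manifest.csv"
        pd.DataFrame([{"foo": 1}]).to_csv(mpath, index=False)
        with pytest.raises(ValidationError):
            read_manifest(str(mpath))
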