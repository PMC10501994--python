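"""Label-volume I/O with physical metadata.

Volumes are stored in (x, y, z) index order with a diagonal voxel-to-mm
mapping ``pos_mm = origin + index * spacing``; z increases toward superior.
Files whose headers encode a different axis order or flipped axes are
reoriented on read so that every downstream "highest z" rule operates in a
single canonical orientation.

Label convention: 0 = background, 1 = aortic lumen, 2 = intraluminal
thrombus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

ALLOWED_LABELS = frozenset({0, 1, 2})


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing (mm) and origin (mm).

    ``voxels[i, j, k]`` sits at physical position ``origin + (i, j, k) * spacing``
    (voxel centers); axis 2 is the superior direction.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "RAS"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive numbers, got {self.spacing}")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices (possibly fractional) -> physical mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Physical mm coordinates -> fractional voxel indices."""
        return (np.asarray(pos, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def z_of_slice(self, k: int) -> float:
        return self.origin[2] + k * self.spacing[2]

    def count_foreground(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def is_empty(self) -> bool:
        return not self.voxels.any()

    def with_voxels(self, voxels: np.ndarray) -> "LabelVolume":
        return replace(self, voxels=voxels)

    def validate_labels(self) -> None:
        offending = set(np.unique(self.voxels)) - ALLOWED_LABELS
        if offending:
            raise ValidationError(f"labels outside {{0, 1, 2}}: {sorted(int(v) for v in offending)}")


@dataclass
class ProbabilityMap:
    """Per-voxel probability volume in [0, 1] with the same geometry model."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError(f"expected a 3D map, got ndim={self.values.ndim}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValidationError("probability values must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _format_from_path(path: str) -> str:
    low = str(path).lower()
    if low.endswith((".nii", ".nii.gz")):
        return "nifti"
    if low.endswith((".mha", ".mhd")):
        return "metaimage"
    raise ValidationError(f"cannot infer volume format from path {path!r}")


def _read_nifti(path: str):
    import nibabel as nib

    img = nib.load(str(path))
    # reorient to RAS so z increases toward superior
    img = nib.as_closest_canonical(img)
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diagonal(rot)), atol=1e-3):
        raise ValidationError(f"{path}: oblique affines are not supported; reorient the volume first")
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(abs(d)) for d in np.diagonal(rot))
    origin = tuple(float(t) for t in affine[:3, 3])
    return data, spacing, origin


def _read_metaimage(path: str):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.diag(np.diagonal(direction)), atol=1e-3):
        raise ValidationError(f"{path}: oblique direction matrices are not supported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(arr, (2, 1, 0))
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = list(img.GetOrigin())
    # flip axes with negative direction so every axis increases physically
    for ax, d in enumerate(np.diagonal(direction)):
        if d < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] - spacing[ax] * (data.shape[ax] - 1)
    return data, spacing, tuple(float(o) for o in origin)


def read_label_volume(path: str, format: str | None = None) -> LabelVolume:
    """Read a label volume from NIfTI or MetaImage, canonically oriented.

    Raises :class:`ValidationError` if the file carries labels outside
    {0, 1, 2} (the offending labels are listed) and ``IOError`` if the file
    is missing or unreadable.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    fmt = format or _format_from_path(path)
    if fmt == "nifti":
        data, spacing, origin = _read_nifti(path)
    elif fmt == "metaimage":
        data, spacing, origin = _read_metaimage(path)
    else:
        raise ValidationError(f"unknown format {fmt!r} (expected 'nifti' or 'metaimage')")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValidationError(f"{path}: non-integer voxel values in a label volume")
        data = rounded
    vol = LabelVolume(data.astype(np.uint8, copy=False), spacing, origin)
    vol.validate_labels()
    return vol


def write_label_volume(vol: LabelVolume, path: str, format: str | None = None) -> None:
    fmt = format or _format_from_path(path)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.uint8), affine), str(path))
    elif fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.transpose(vol.voxels.astype(np.uint8), (2, 1, 0)))
        img.SetSpacing(vol.spacing)
        img.SetOrigin(vol.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def read_probability_map(path: str, format: str | None = None) -> ProbabilityMap:
    fmt = format or _format_from_path(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if fmt == "nifti":
        data, spacing, origin = _read_nifti(path)
    elif fmt == "metaimage":
        data, spacing, origin = _read_metaimage(path)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return ProbabilityMap(np.asarray(data, dtype=float), spacing, origin)


# ---------------------------------------------------------------------------
# mask manipulation
# ---------------------------------------------------------------------------

def split_labels(vol: LabelVolume) -> tuple[LabelVolume, LabelVolume]:
    """Split a multi-label volume into binary lumen (==1) and thrombus (==2) masks."""
    vol.validate_labels()
    lumen = vol.with_voxels((vol.voxels == 1).astype(np.uint8))
    thrombus = vol.with_voxels((vol.voxels == 2).astype(np.uint8))
    return lumen, thrombus


def resample_isotropic(vol: LabelVolume, target_spacing: float) -> LabelVolume:
    """Nearest-neighbour resample onto an isotropic grid of the given spacing.

    The physical extent (voxel count x spacing per axis) is preserved to
    within one voxel per axis; label values are preserved exactly.
    """
    if target_spacing <= 0:
        raise ValidationError(f"target spacing must be positive, got {target_spacing}")
    if np.allclose(vol.spacing, target_spacing, atol=1e-9):
        return vol
    from scipy.ndimage import map_coordinates

    old = np.asarray(vol.spacing)
    shape = np.asarray(vol.shape)
    extent = shape * old
    new_shape = np.maximum(1, np.rint(extent / target_spacing)).astype(int)
    # sample new voxel centers in the old index frame (cell-centered grids)
    grids = [
        ((np.arange(n) + 0.5) * target_spacing) / old[ax] - 0.5
        for ax, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = map_coordinates(vol.voxels, coords, order=0, mode="nearest")
    new_origin = tuple(
        vol.origin[ax] + 0.5 * (target_spacing - old[ax]) for ax in range(3)
    )
    return LabelVolume(out.astype(vol.voxels.dtype), (target_spacing,) * 3, new_origin,
                       vol.axis_convention)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["case_id", "lumen_path", "thrombus_path", "manual_diameter_mm"]


def read_manifest(path: str) -> pd.DataFrame:
    """Read a cohort manifest CSV (case_id, lumen_path[, thrombus_path, manual_diameter_mm]).

    ``lumen_path`` may point at a multi-label file holding both lumen (1) and
    thrombus (2); in that case ``thrombus_path`` is left empty.
    """
    df = pd.read_csv(path)
    if "case_id" not in df.columns or "lumen_path" not in df.columns:
        raise ValidationError("manifest must have at least 'case_id' and 'lumen_path' columns")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]]


def load_case_masks(row, base_dir: str = "") -> tuple[LabelVolume, LabelVolume]:
    """Load (lumen, thrombus) binary masks for one manifest row.

    Accepts either a multi-label file in ``lumen_path`` or two separate
    binary files.
    """
    lumen_path = os.path.join(base_dir, str(row["lumen_path"]))
    vol = read_label_volume(lumen_path)
    thrombus_path = row.get("thrombus_path")
    if thrombus_path is None or (isinstance(thrombus_path, float) and np.isnan(thrombus_path)) \
            or str(thrombus_path).strip() in ("", "nan"):
        return split_labels(vol)
    lumen = vol.with_voxels((vol.voxels > 0).astype(np.uint8))
    tvol = read_label_volume(os.path.join(base_dir, str(thrombus_path)))
    if tvol.shape != lumen.shape:
        raise ValidationError(
            f"case {row['case_id']}: lumen and thrombus grids differ "
            f"({lumen.shape} vs {tvol.shape})")
    thrombus = tvol.with_voxels((tvol.voxels > 0).astype(np.uint8))
    return lumen, thrombus
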