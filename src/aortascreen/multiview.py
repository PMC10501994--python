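"""Closed-form segmentation-side computations: 2.5D multi-view fusion and Dice.

The upstream networks predict per-voxel probabilities independently on the
axial, sagittal and coronal planes; the fused map is the voxelwise arithmetic
mean of the three views. Training and inference of the networks themselves
are out of scope — these utilities operate on already-computed maps.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .volume_io import LabelVolume, ProbabilityMap


def fuse_multiview(p_axial: ProbabilityMap, p_sagittal: ProbabilityMap,
                   p_coronal: ProbabilityMap) -> ProbabilityMap:
    """Voxelwise mean of the three single-view prediction maps.

    p_final(x) = (p_axial(x) + p_sagittal(x) + p_coronal(x)) / 3
    """
    maps = (p_axial, p_sagittal, p_coronal)
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValidationError(f"view maps disagree in shape: {sorted(shapes)}")
    spacings = {m.spacing for m in maps}
    if len(spacings) != 1:
        raise ValidationError(f"view maps disagree in spacing: {sorted(spacings)}")
    fused = (maps[0].values + maps[1].values + maps[2].values) / 3.0
    return ProbabilityMap(fused, p_axial.spacing, p_axial.origin)


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> LabelVolume:
    """Threshold a probability map into a binary mask (strict ``>``)."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return LabelVolume((p.values > threshold).astype(np.uint8), p.spacing, p.origin)


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity coefficient, 2|A∩B| / (|A| + |B|).

    Ranges from 0 (no overlap) to 1 (perfect overlap). Two empty masks are
    defined to agree perfectly (returns 1.0).
    """
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    av = a.voxels.astype(bool)
    bv = b.voxels.astype(bool)
    na, nb = int(av.sum()), int(bv.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(av & bv))
    return 2.0 * inter / (na + nb)
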