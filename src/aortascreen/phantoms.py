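"""Synthetic vascular phantoms with analytic ground truth.

Phantoms are generalized cylinders: a parametric trunk curve (straight,
arched "candy-cane", or explicit control points) carrying a lumen-radius
profile with an optional fusiform Gaussian bulge, a thrombus-thickness
profile (annulus between lumen and outer wall), and side branches (renal
pair, iliac pair, arch vessels). A voxel is lumen iff its distance to the
curve is at most the local lumen radius; thrombus fills between lumen and
outer radius along the trunk. The ground-truth record carries the analytic
centerline, maximum outer diameter and its location, thrombus volume
(numerical annulus integral at 0.01 mm arc step — the independent oracle),
and the branch/arch z-levels, so every pipeline stage is testable without
clinical data.

The default geometry emulates a thoraco-abdominal screening segmentation:
arch bend, short ascending stub, descending trunk, paired renal take-offs,
iliac bifurcation, isotropic 0.75 mm spacing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .volume_io import LabelVolume, write_label_volume

_CURVE_STEP = 0.25  # mm, curve sampling for voxelization
_TRUTH_STEP = 0.01  # mm, arc step of the annulus volume integral


@dataclass
class BulgeSpec:
    """Gaussian radial bulge: added radius amplitude*exp(-((s-center)/sigma)^2/2)."""

    center: float  # arc-length position along the trunk, mm
    amplitude: float  # mm added at the peak
    sigma: float  # mm


@dataclass
class BranchSpec:
    arc_length: float  # take-off position along the trunk, mm
    direction: tuple[float, float, float]
    radius: float  # mm
    length: float  # mm


@dataclass
class PhantomSpec:
    trunk: str = "candy_cane"  # {straight, candy_cane, points}
    control_points: np.ndarray | None = None  # for trunk == "points"
    straight_length: float = 120.0  # for trunk == "straight"
    lumen_radius: float = 9.0  # baseline, mm
    lumen_bulge: BulgeSpec | None = None
    thrombus_bulge: BulgeSpec | None = None  # thickness profile (>= 0)
    branches: list[BranchSpec] = field(default_factory=list)
    spacing: tuple[float, float, float] = (0.75, 0.75, 0.75)
    noise: float = 0.0  # radial jitter amplitude, mm
    seed: int = 0
    margin: float = 6.0  # empty border around the geometry, mm
    # candy-cane geometry (mm)
    arch_radius: float = 25.0
    arch_top_z: float = 190.0  # z where the bend begins (apex = arch_top_z + arch_radius)
    ascending_stub: float = 25.0
    trunk_bottom_z: float = 25.0  # iliac bifurcation apex

    def __post_init__(self):
        if self.lumen_radius <= 0:
            raise ValidationError("lumen radius must be positive")
        if self.thrombus_bulge is not None and self.thrombus_bulge.amplitude < 0:
            raise ValidationError("thrombus thickness must be >= 0")
        for b in self.branches:
            if b.radius <= 0:
                raise ValidationError("branch radii must be positive")
        for bulge in (self.lumen_bulge, self.thrombus_bulge):
            if bulge is None:
                continue
            for b in self.branches:
                if abs(bulge.center - b.arc_length) < 3.0 * bulge.sigma + b.radius:
                    raise ValidationError(
                        f"bulge at arc {bulge.center:.1f} overlaps branch take-off at "
                        f"arc {b.arc_length:.1f}; ground truth would be ambiguous")


@dataclass
class PhantomTruth:
    max_outer_diameter: float  # mm (over the abdominal tract)
    max_arc_length: float  # mm along the trunk
    max_z: float  # mm
    thrombus_volume_ml: float
    centerline: np.ndarray  # (N, 3) mm, 0.5 mm sampling
    centerline_arc: np.ndarray  # (N,)
    lumen_radius_profile: np.ndarray  # (N,) mm at centerline samples
    outer_radius_profile: np.ndarray  # (N,)
    renal_z: list[float]  # take-off z of branches flagged renal-level
    iliac_z: float | None  # bifurcation apex z (None without iliac pair)
    iliac_detect_z: float | None  # analytic z where the limbs separate in-slice
    arch_apex_z: float | None
    arch_merge_z: float | None  # analytic z of the slice-wise 2->1 merge (apex - radius)
    label: str  # {AAA, control}

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items()
             if k not in ("centerline", "centerline_arc", "lumen_radius_profile",
                          "outer_radius_profile")}
        return d


# ---------------------------------------------------------------------------
# trunk curves
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    stations = np.arange(0.0, arc[-1] + step / 2, step)
    out = np.column_stack([np.interp(stations, arc, points[:, c]) for c in range(3)])
    return out, stations


def trunk_curve(spec: PhantomSpec, step: float = _CURVE_STEP) -> tuple[np.ndarray, np.ndarray]:
    """Dense trunk polyline (mm) and its arc-length stations."""
    if spec.trunk == "straight":
        z = np.arange(0.0, spec.straight_length + step / 2, step)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z[::-1]])
        return pts, np.arange(len(z)) * step
    if spec.trunk == "points":
        if spec.control_points is None:
            raise ValidationError("trunk='points' requires control_points")
        return _resample_polyline(np.asarray(spec.control_points, dtype=float), step)
    if spec.trunk != "candy_cane":
        raise ValidationError(f"unknown trunk kind {spec.trunk!r}")
    R = spec.arch_radius
    z_top = spec.arch_top_z
    pieces = []
    # ascending stub, x = -2R, rising to the bend
    z_asc = np.arange(z_top - spec.ascending_stub, z_top, step)
    pieces.append(np.column_stack([np.full_like(z_asc, -2 * R), np.zeros_like(z_asc), z_asc]))
    # arch: semicircle in the x-z plane from (-2R, z_top) over (-R, z_top+R) to (0, z_top)
    n_arc = max(8, int(np.pi * R / step))
    theta = np.linspace(np.pi, 0.0, n_arc, endpoint=False)
    pieces.append(np.column_stack([-R + R * np.cos(theta),
                                   np.zeros(n_arc),
                                   z_top + R * np.sin(theta)]))
    # descending trunk down to the iliac apex
    z_desc = np.arange(z_top, spec.trunk_bottom_z - step / 2, -step)
    pieces.append(np.column_stack([np.zeros_like(z_desc), np.zeros_like(z_desc), z_desc]))
    return _resample_polyline(np.vstack(pieces), step)


def descending_arc_of_z(spec: PhantomSpec, z: float) -> float:
    """Arc-length position on the candy-cane trunk of a descending-limb z."""
    if spec.trunk == "straight":
        return spec.straight_length - z
    asc = spec.ascending_stub
    bend = np.pi * spec.arch_radius
    return asc + bend + (spec.arch_top_z - z)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _profile(base: float, bulge: BulgeSpec | None, arc: np.ndarray) -> np.ndarray:
    r = np.full_like(arc, base, dtype=float)
    if bulge is not None:
        r = r + bulge.amplitude * np.exp(-0.5 * ((arc - bulge.center) / bulge.sigma) ** 2)
    return r


def _thickness(bulge: BulgeSpec | None, arc: np.ndarray) -> np.ndarray:
    if bulge is None:
        return np.zeros_like(arc)
    return bulge.amplitude * np.exp(-0.5 * ((arc - bulge.center) / bulge.sigma) ** 2)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _grid_from_geometry(all_pts: np.ndarray, all_r: np.ndarray, spec: PhantomSpec):
    lo = (all_pts - all_r[:, None]).min(axis=0) - spec.margin
    hi = (all_pts + all_r[:, None]).max(axis=0) + spec.margin
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = np.maximum(2, np.ceil((hi - lo) / spacing).astype(int) + 1)
    return lo, spacing, shape


def _paint_tube(mask: np.ndarray, pts: np.ndarray, radii: np.ndarray,
                origin: np.ndarray, spacing: np.ndarray) -> None:
    """OR a generalized cylinder (samples + per-sample radii) into the mask."""
    shape = np.asarray(mask.shape)
    rmax = float(radii.max())
    lo_idx = np.maximum(0, np.floor(((pts - rmax).min(axis=0) - origin) / spacing - 1)).astype(int)
    hi_idx = np.minimum(shape - 1,
                        np.ceil(((pts + rmax).max(axis=0) - origin) / spacing + 1)).astype(int)
    axes = [origin[a] + spacing[a] * np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    q = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(np.float32)
    tree = cKDTree(pts)
    dist, idx = tree.query(q, k=1)
    inside = dist <= radii[idx]
    sub = mask[lo_idx[0]:hi_idx[0] + 1, lo_idx[1]:hi_idx[1] + 1, lo_idx[2]:hi_idx[2] + 1]
    sub |= inside.reshape(sub.shape)


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, LabelVolume, PhantomTruth]:
    """Voxelize a phantom and return (lumen mask, thrombus mask, truth).

    Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    curve, arc = trunk_curve(spec)
    r_lumen = _profile(spec.lumen_radius, spec.lumen_bulge, arc)
    t_thr = _thickness(spec.thrombus_bulge, arc)
    if spec.noise > 0:
        jitter = rng.normal(0.0, spec.noise, size=len(arc))
        # smooth the jitter over ~5 mm so the surface stays tubular
        w = max(3, int(5.0 / _CURVE_STEP) | 1)
        jitter = np.convolve(jitter, np.ones(w) / w, mode="same")
        r_lumen = np.clip(r_lumen + jitter, 1.0, None)
    r_outer = r_lumen + t_thr

    branch_samples = []
    for b in spec.branches:
        i0 = int(np.clip(round(b.arc_length / _CURVE_STEP), 0, len(curve) - 1))
        d = np.asarray(b.direction, dtype=float)
        d = d / np.linalg.norm(d)
        s = np.arange(0.0, b.length + _CURVE_STEP / 2, _CURVE_STEP)
        pts = curve[i0][None, :] + s[:, None] * d[None, :]
        branch_samples.append((pts, np.full(len(pts), b.radius)))

    all_pts = np.vstack([curve] + [p for p, _ in branch_samples])
    all_r = np.concatenate([r_outer] + [r for _, r in branch_samples])
    origin, spacing, shape = _grid_from_geometry(all_pts, all_r, spec)

    lumen = np.zeros(shape, dtype=bool)
    _paint_tube(lumen, curve, r_lumen, origin, spacing)
    if spec.trunk == "candy_cane":
        # flat trunk terminus at the iliac apex: the limbs, not a rounded
        # end-cap, fill the space below the bifurcation
        k_bottom = int(np.ceil((spec.trunk_bottom_z - origin[2]) / spacing[2] - 1e-9))
        if 0 < k_bottom < shape[2]:
            lumen[:, :, :k_bottom] = False
    for pts, radii in branch_samples:
        _paint_tube(lumen, pts, radii, origin, spacing)
    if t_thr.max() > 0:
        outer = np.zeros(shape, dtype=bool)
        sel = r_outer > r_lumen + 1e-9
        # paint the full outer tube around the thickened stretch for a clean annulus
        lo = max(0, int(np.flatnonzero(sel)[0]) - 1) if sel.any() else 0
        hi = min(len(curve), int(np.flatnonzero(sel)[-1]) + 2) if sel.any() else 0
        if hi > lo:
            _paint_tube(outer, curve[lo:hi], r_outer[lo:hi], origin, spacing)
        if spec.trunk == "candy_cane":
            k_bottom = int(np.ceil((spec.trunk_bottom_z - origin[2]) / spacing[2] - 1e-9))
            if 0 < k_bottom < shape[2]:
                outer[:, :, :k_bottom] = False
        thrombus = outer & ~lumen
    else:
        thrombus = np.zeros(shape, dtype=bool)

    lumen_vol = LabelVolume(lumen.astype(np.uint8), tuple(spacing), tuple(origin))
    thr_vol = LabelVolume(thrombus.astype(np.uint8), tuple(spacing), tuple(origin))
    truth = _analytic_truth(spec, curve, arc, r_lumen, r_outer)
    return lumen_vol, thr_vol, truth


def _analytic_truth(spec: PhantomSpec, curve, arc, r_lumen, r_outer) -> PhantomTruth:
    # restrict the diameter maximum to the abdominal tract when it exists
    renal_z = []
    iliac_z = None
    iliac_detect_z = None
    iliac_branches = []
    for b in spec.branches:
        d = np.asarray(b.direction, dtype=float)
        d = d / np.linalg.norm(d)
        i0 = int(np.clip(round(b.arc_length / _CURVE_STEP), 0, len(curve) - 1))
        if abs(d[2]) < 0.45:  # near-lateral take-off: renal-level branch
            renal_z.append(float(curve[i0][2]))
        else:
            iliac_branches.append((b, d, curve[i0]))
    if len(iliac_branches) >= 2:
        (b1, d1, p1) = iliac_branches[0]
        iliac_z = float(p1[2])
        lat = float(np.linalg.norm(d1[:2]))
        if lat > 1e-6:
            # limbs separate in-slice once the center gap exceeds the in-slice
            # ellipse widths; the tilt factors cancel, leaving radius / lateral rate
            iliac_detect_z = iliac_z - b1.radius / lat
    arch_apex_z = None
    arch_merge_z = None
    if spec.trunk == "candy_cane":
        arch_apex_z = spec.arch_top_z + spec.arch_radius
        i_apex = int(np.argmax(curve[:, 2]))
        arch_merge_z = arch_apex_z - float(r_lumen[i_apex])

    sel = np.ones(len(arc), dtype=bool)
    if renal_z and iliac_z is not None:
        z = curve[:, 2]
        on_desc = arc > descending_arc_of_z(spec, spec.arch_top_z) if spec.trunk == "candy_cane" \
            else np.ones(len(arc), dtype=bool)
        sel = on_desc & (z <= min(renal_z)) & (z >= iliac_z)
    i_max = int(np.flatnonzero(sel)[np.argmax(r_outer[sel])])
    # annulus integral at fine arc step (independent volume oracle)
    fine = np.arange(0.0, arc[-1] + _TRUTH_STEP / 2, _TRUTH_STEP)
    r_f = _profile(spec.lumen_radius, spec.lumen_bulge, fine)
    t_f = _thickness(spec.thrombus_bulge, fine)
    vol_mm3 = float(np.trapezoid(np.pi * ((r_f + t_f) ** 2 - r_f ** 2), fine))

    cl, cl_arc = _resample_polyline(curve, 0.5)
    label = "AAA" if 2.0 * r_outer[i_max] > 30.0 else "control"
    return PhantomTruth(
        max_outer_diameter=float(2.0 * r_outer[i_max]),
        max_arc_length=float(arc[i_max]),
        max_z=float(curve[i_max][2]),
        thrombus_volume_ml=vol_mm3 / 1000.0,
        centerline=cl,
        centerline_arc=cl_arc,
        lumen_radius_profile=np.interp(cl_arc, arc, r_lumen),
        outer_radius_profile=np.interp(cl_arc, arc, r_outer),
        renal_z=renal_z,
        iliac_z=iliac_z,
        iliac_detect_z=iliac_detect_z,
        arch_apex_z=arch_apex_z,
        arch_merge_z=arch_merge_z,
        label=label,
    )


# ---------------------------------------------------------------------------
# standard anatomy + cohort factory
# ---------------------------------------------------------------------------

def standard_spec(outer_diameter_mm: float, with_thrombus: bool = True,
                  base_radius: float = 9.0, bulge_sigma: float = 12.0,
                  spacing: float = 0.75, seed: int = 0,
                  noise: float = 0.0) -> PhantomSpec:
    """Thoraco-abdominal phantom whose abdominal maximum outer diameter is
    exactly ``outer_diameter_mm``.

    Geometry (mm): arch bend radius 25 topping at z=215, ascending stub,
    descending trunk to the iliac apex at z=25, renal pair at z=115, iliac
    pair at 50 degrees from vertical. The fusiform bulge (if any) is centered
    at z=65, mid-abdomen. For aneurysmal phantoms with thrombus, 65% of the
    dilation is lumen and 35% thrombus annulus.
    """
    spec = PhantomSpec(trunk="candy_cane", lumen_radius=base_radius,
                       spacing=(spacing,) * 3, seed=seed, noise=noise)
    extra = outer_diameter_mm / 2.0 - base_radius
    if extra < 0:
        spec.lumen_radius = outer_diameter_mm / 2.0
        extra = 0.0
    bulge_arc = descending_arc_of_z(spec, 65.0)
    if extra > 0:
        if with_thrombus:
            spec.lumen_bulge = BulgeSpec(center=bulge_arc, amplitude=0.65 * extra,
                                         sigma=bulge_sigma)
            spec.thrombus_bulge = BulgeSpec(center=bulge_arc, amplitude=0.35 * extra,
                                            sigma=bulge_sigma)
        else:
            spec.lumen_bulge = BulgeSpec(center=bulge_arc, amplitude=extra, sigma=bulge_sigma)
    renal_arc = descending_arc_of_z(spec, 115.0)
    iliac_arc = descending_arc_of_z(spec, spec.trunk_bottom_z)
    spec.branches = [
        BranchSpec(arc_length=renal_arc, direction=(0.0, 1.0, -0.15), radius=3.0, length=16.0),
        BranchSpec(arc_length=renal_arc, direction=(0.0, -1.0, -0.15), radius=3.0, length=16.0),
        BranchSpec(arc_length=iliac_arc, direction=(1.2, 0.0, -1.0), radius=3.0, length=30.0),
        BranchSpec(arc_length=iliac_arc, direction=(-1.2, 0.0, -1.0), radius=3.0, length=30.0),
    ]
    return spec


@dataclass
class PhantomCase:
    case_id: str
    lumen: LabelVolume
    thrombus: LabelVolume
    truth: PhantomTruth


def cohort_specs(n_aaa: int, n_control: int, seed: int = 0,
                 threshold_margin_mm: float = 0.0) -> list[tuple[str, PhantomSpec, float]]:
    """Case ids, specs and target diameters for a synthetic screening cohort.

    AAA outer diameters are drawn uniformly in [32, 90] mm (with a thrombus
    annulus), controls in [16, 28] mm (lumen only), emulating the diameter
    ranges of a screening population; ``threshold_margin_mm`` shrinks both
    ranges away from the 30 mm decision threshold.
    """
    if n_aaa < 0 or n_control < 0:
        raise ValidationError("cohort counts must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    lo_aaa = max(32.0, 30.0 + threshold_margin_mm)
    hi_ctrl = min(28.0, 30.0 - threshold_margin_mm)
    for i in range(n_aaa):
        d = float(rng.uniform(lo_aaa, 90.0))
        out.append((f"aaa_{i:03d}", standard_spec(d, with_thrombus=True,
                                                  seed=int(rng.integers(2 ** 31))), d))
    for i in range(n_control):
        d = float(rng.uniform(16.0, hi_ctrl))
        out.append((f"ctl_{i:03d}",
                    standard_spec(d, with_thrombus=False,
                                  base_radius=min(9.0, d / 2.0),
                                  seed=int(rng.integers(2 ** 31))), d))
    return out


def cohort_factory(n_aaa: int, n_control: int, seed: int = 0,
                   out_dir: str | None = None,
                   threshold_margin_mm: float = 0.0):
    """Generate a synthetic cohort.

    With ``out_dir`` the masks are written as NIfTI alongside per-case truth
    JSON and a manifest CSV (compatible with volume_io.read_manifest; the
    analytic diameter fills ``manual_diameter_mm``) and the manifest
    DataFrame is returned. Without ``out_dir`` a list of in-memory
    :class:`PhantomCase` is returned.
    """
    specs = cohort_specs(n_aaa, n_control, seed, threshold_margin_mm)
    cases = []
    rows = []
    for case_id, spec, target in specs:
        lumen, thrombus, truth = generate_phantom(spec)
        if out_dir is None:
            cases.append(PhantomCase(case_id, lumen, thrombus, truth))
            continue
        os.makedirs(out_dir, exist_ok=True)
        lpath = os.path.join(out_dir, f"{case_id}_lumen.nii.gz")
        tpath = os.path.join(out_dir, f"{case_id}_thrombus.nii.gz")
        write_label_volume(lumen, lpath)
        write_label_volume(thrombus, tpath)
        with open(os.path.join(out_dir, f"{case_id}_truth.json"), "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
        rows.append({"case_id": case_id, "lumen_path": lpath, "thrombus_path": tpath,
                     "manual_diameter_mm": truth.max_outer_diameter})
    if out_dir is None:
        return cases
    manifest = pd.DataFrame(rows, columns=["case_id", "lumen_path", "thrombus_path",
                                           "manual_diameter_mm"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
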