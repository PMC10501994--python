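"""Perpendicular cross-sections, wall-to-wall diameters, thrombus volume,
and the per-case measurement pipeline.

The wall-to-wall diameter of a section is its maximum Feret diameter (the
largest pairwise distance between contour points in the section plane),
matching the clinical ground-truth definition; the equivalent-circle
diameter is carried alongside for comparison. The case measurement is the
maximum over sections perpendicular to the abdominal centerline.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .abdominal import (BifurcationPlane, bifurcation_planes, clip_abdominal,
                        find_renal_plane, label_iliac_planes, split_branches,
                        terminal_iliac_plane)
from .centerline import (CenterlineParams, _plane_basis, compute_centerline,
                         crop_mask_to_bounds, find_axial_bounds, find_endpoints,
                         largest_component, pick_seeds, prune_skeleton,
                         skeletonize_lumen)
from .errors import (DegenerateGeometryError, RenalPlaneNotFoundError,
                     StageError, ValidationError)
from .surface import SurfaceMesh, extract_surface, fuse_lumen_thrombus, smooth_mask
from .volume_io import LabelVolume, resample_isotropic


@dataclass
class CrossSection:
    center: np.ndarray  # (3,) mm — the centerline point the plane passes through
    normal: np.ndarray  # unit tangent
    contour: np.ndarray  # (N, 3) mm, ordered, closed (first != last stored)
    diameter: float  # mm, max Feret in the section plane
    equivalent_diameter: float  # mm, 2*sqrt(area/pi)
    area: float  # mm^2
    arc_length: float  # mm along the centerline

    @property
    def z(self) -> float:
        return float(self.center[2])


@dataclass
class MeasurementResult:
    case_id: str
    max_diameter: float  # mm
    max_arc_length: float  # mm along abdominal centerline
    max_z: float  # mm
    max_equivalent_diameter: float  # mm at the maximal section
    thrombus_volume_ml: float
    n_sections: int
    used_thrombus: bool
    sections: list[CrossSection] = field(default_factory=list, repr=False)
    diagnostics: dict = field(default_factory=dict, repr=False)
    stage_log: dict = field(default_factory=dict, repr=False)

    def profile_rows(self) -> list[dict]:
        return [{"arc_length_mm": s.arc_length, "diameter_mm": s.diameter,
                 "equivalent_diameter_mm": s.equivalent_diameter, "area_mm2": s.area,
                 "z_mm": s.z} for s in self.sections]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "max_diameter_mm": float(self.max_diameter),
            "max_equivalent_diameter_mm": float(self.max_equivalent_diameter),
            "max_arc_length_mm": float(self.max_arc_length),
            "max_z_mm": float(self.max_z),
            "thrombus_volume_ml": float(self.thrombus_volume_ml),
            "n_sections": int(self.n_sections),
            "used_thrombus": bool(self.used_thrombus),
            "planes": {k: v.to_dict() for k, v in self.diagnostics.items()
                       if isinstance(v, BifurcationPlane)},
        }


@dataclass
class PipelineConfig:
    """Every constant of the measurement pipeline, overridable.

    smoothing_radius_mm: ball radius of the closing+opening regularisation.
    section_step_mm: spacing of perpendicular sections; None uses the
        centerline resampling step.
    renal_fallback_offset_mm: distance above the iliac plane at which to
        place the renal plane when no bifurcation is detected.
    """

    smoothing_radius_mm: float = 1.5
    centerline: CenterlineParams = field(default_factory=CenterlineParams)
    section_step_mm: float | None = None
    renal_fallback_offset_mm: float = 90.0
    keep_intermediates: bool = False

    @property
    def section_step(self) -> float:
        return self.section_step_mm if self.section_step_mm is not None \
            else self.centerline.resampling_step


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

def _resample_branch(branch, step: float):
    """Equidistant stations (points + tangents + arcs) along a branch."""
    arc = branch.arc_length
    total = float(arc[-1])
    if total <= 0:
        raise ValidationError("degenerate centerline branch (zero length)")
    if total < step:
        stations = np.linspace(0.0, total, 2)
    else:
        stations = np.append(np.arange(0.0, total, step), total)
    # inset the terminal stations slightly so the end planes are not
    # coplanar with the clip caps (a coincident cut is numerically degenerate)
    eps = min(0.5, 0.25 * total)
    stations[0] = eps
    stations[-1] = total - eps
    stations = stations[np.concatenate([[True], np.diff(stations) > 1e-9])]
    pts = np.column_stack([np.interp(stations, arc, branch.points[:, c]) for c in range(3)])
    tans = np.column_stack([np.interp(stations, arc, branch.tangents[:, c]) for c in range(3)])
    norms = np.linalg.norm(tans, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return stations, pts, tans / norms


def _loop_metrics(loop: np.ndarray, center: np.ndarray, normal: np.ndarray):
    """(contains_center, signed distance, area, in-plane 2D coords) of a loop."""
    from shapely.geometry import Point, Polygon

    u, v = _plane_basis(normal)
    rel = loop - center
    coords2d = np.column_stack([rel @ u, rel @ v])
    poly = Polygon(coords2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area) if len(poly.geoms) else None
    pt = Point(0.0, 0.0)
    if poly is None or poly.is_empty or poly.exterior is None:
        return False, np.inf, 0.0, coords2d
    return poly.contains(pt), poly.exterior.distance(pt), abs(poly.area), coords2d


def generate_sections(surface: SurfaceMesh, centerline, step: float | None = None,
                      exclusion_tubes: list[tuple[np.ndarray, np.ndarray]] | None = None,
                      ) -> list[CrossSection]:
    """Sections of the surface perpendicular to the centerline.

    At each equidistant centerline station the surface is cut by the plane
    through the station with normal along the local tangent; only the
    intersection loop containing the station is kept (other loops — e.g. a
    plane grazing an iliac limb — are discarded). Stations whose plane
    misses the surface are skipped with a warning.

    ``exclusion_tubes`` — (points, radii) pairs describing detected side
    branches — silently removes stations whose plane cuts one of the tubes:
    branch remnants left inside the clipped model (e.g. renal ostia just
    below the renal plane) would otherwise widen the wall-to-wall contour.
    """
    import warnings

    branches = centerline.branches if hasattr(centerline, "branches") else [centerline]
    branch = max(branches, key=lambda b: b.length)
    step = step if step is not None else getattr(centerline, "params", CenterlineParams()).resampling_step
    if step <= 0:
        raise ValidationError("section step must be > 0")
    stations, pts, tans = _resample_branch(branch, step)
    tm = surface.to_trimesh()
    sections: list[CrossSection] = []
    for s, p, t in zip(stations, pts, tans):
        if exclusion_tubes and any(
                np.any(np.abs((tube_pts - p) @ t) <= tube_r)
                for tube_pts, tube_r in exclusion_tubes):
            continue
        try:
            path = tm.section(plane_origin=p, plane_normal=t)
        except Exception:
            path = None
        if path is None or not len(path.entities):
            warnings.warn(f"section plane at arc {s:.1f} mm misses the surface; skipped")
            continue
        best = None
        for loop in path.discrete:
            if len(loop) < 4:
                continue
            contains, dist, area, _ = _loop_metrics(loop, p, t)
            if contains or dist < 1.0:
                if best is None or area > best[1]:
                    best = (loop, area)
        if best is None:
            warnings.warn(f"no section loop contains the centerline point at arc {s:.1f} mm; skipped")
            continue
        loop = best[0]
        contour = loop[:-1] if np.allclose(loop[0], loop[-1]) else loop
        diam = section_diameter_of_contour(contour)
        area = best[1]
        sections.append(CrossSection(
            center=p, normal=t, contour=contour, diameter=diam,
            equivalent_diameter=2.0 * float(np.sqrt(area / np.pi)), area=float(area),
            arc_length=float(s)))
    return sections


def section_diameter_of_contour(contour: np.ndarray) -> float:
    """Maximum Feret diameter: largest pairwise distance between contour points."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise ValidationError(f"degenerate contour with {len(pts)} points")
    if len(pts) > 8:
        try:
            hull = ConvexHull(pts[:, :2] if np.ptp(pts[:, 2]) < 1e-9 else pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except Exception:
            pass
    diffs = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(axis=2).max()))


def section_diameter(section: CrossSection) -> float:
    """Wall-to-wall (maximum Feret) diameter of a cross-section."""
    return section_diameter_of_contour(section.contour)


def max_abdominal_diameter(sections: list[CrossSection]) -> tuple[float, CrossSection]:
    """The section with the largest diameter; ties break toward superior z."""
    if not sections:
        raise ValidationError("no sections to maximize over")
    best = max(sections, key=lambda s: (s.diameter, s.z))
    return best.diameter, best


def thrombus_volume(thrombus: LabelVolume | None) -> float:
    """Thrombus volume in mL (foreground voxels x voxel volume); 0 if absent."""
    if thrombus is None:
        return 0.0
    return float(thrombus.count_foreground() * thrombus.voxel_volume_mm3 / 1000.0)


# ---------------------------------------------------------------------------
# per-case pipeline
# ---------------------------------------------------------------------------

def _renal_fallback(cal, iliac: BifurcationPlane, offset_mm: float) -> BifurcationPlane:
    """Renal plane at a fixed offset above the iliac plane, on the trunk."""
    branch = max(cal.branches, key=lambda b: b.length)
    target_z = iliac.z + offset_mm
    i = int(np.argmin(np.abs(branch.points[:, 2] - target_z)))
    return BifurcationPlane(origin=branch.points[i], normal=branch.tangents[i], label="renal")


def measure_case(lumen: LabelVolume, thrombus: LabelVolume | None = None,
                 config: PipelineConfig | None = None,
                 case_id: str = "case") -> MeasurementResult:
    """Full measurement of one case: fuse, smooth, bound, skeletonize,
    centerline, abdominal isolation, perpendicular sections, maximum
    diameter and thrombus volume.

    When thrombus is present the diameter is measured on the fused
    lumen+thrombus model; otherwise on the lumen surface alone
    (``used_thrombus`` records which).
    """
    config = config or PipelineConfig()
    log: dict = {}
    diagnostics: dict = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log[name] = {}
                return self_

            def __exit__(self_, exc_type, exc, tb):
                log[name]["seconds"] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False
        return _Ctx()

    with stage("validate"):
        if lumen.is_empty():
            raise ValidationError("empty lumen mask")
        used_thrombus = thrombus is not None and bool(thrombus.voxels.any())
        if used_thrombus and thrombus.shape != lumen.shape:
            raise ValidationError("lumen and thrombus grids differ")

    with stage("fuse"):
        aorta = fuse_lumen_thrombus(lumen, thrombus) if used_thrombus else lumen

    with stage("thrombus_volume"):
        vol_ml = thrombus_volume(thrombus if used_thrombus else None)

    with stage("smooth"):
        aorta_s = smooth_mask(aorta, config.smoothing_radius_mm)

    with stage("axial_bounds"):
        bounds = find_axial_bounds(aorta_s)
        diagnostics["bounds"] = bounds

    with stage("crop"):
        # cut one slice below the detected arch merge so the two arch limbs
        # disconnect and the descending side carries a true top endpoint
        z_top = bounds.z_arch - (0.0 if bounds.degenerate else aorta_s.spacing[2])
        aorta_c = largest_component(crop_mask_to_bounds(aorta_s, z_top, bounds.z_iliac))
        # the raw (unsmoothed) lumen feeds skeletonization: smoothing can thin
        # small side branches below the thickness the thinning preserves
        lumen_raw_c = largest_component(crop_mask_to_bounds(lumen, z_top, bounds.z_iliac))
        log["crop"]["aorta_voxels"] = aorta_c.count_foreground()

    with stage("isotropic"):
        iso = float(min(aorta_c.spacing))
        aorta_c = resample_isotropic(aorta_c, iso)
        lumen_raw_c = resample_isotropic(lumen_raw_c, iso)

    with stage("skeleton"):
        skel = prune_skeleton(skeletonize_lumen(lumen_raw_c), config.centerline.prune_mm)
        endpoints = find_endpoints(skel)
        if len(endpoints) < 2:
            raise DegenerateGeometryError(
                f"skeleton yields {len(endpoints)} endpoint(s); need at least 2 seeds")
        endpoints_mm = lumen_raw_c.index_to_mm(np.asarray(endpoints, dtype=float))
        log["skeleton"]["n_endpoints"] = len(endpoints)

    with stage("centerline"):
        source, targets = pick_seeds(endpoints_mm)
        cal = compute_centerline(aorta_c, source, targets, config.centerline)

    with stage("surface"):
        surf = extract_surface(aorta_c, provenance="aorta" if used_thrombus else "lumen")
        log["surface"]["n_vertices"] = len(surf.vertices)

    with stage("branches"):
        branched = split_branches(cal)
        planes = label_iliac_planes(bifurcation_planes(surf, branched), branched)
        iliac_planes = [p for p in planes if p.label == "iliac"]
        if iliac_planes:
            # the split survived inside the crop: take its most superior plane
            iliac = max(iliac_planes, key=lambda p: p.z)
        else:
            iliac = terminal_iliac_plane(branched, at_z=bounds.z_iliac)
        try:
            renal = find_renal_plane(planes, iliac)
        except RenalPlaneNotFoundError:
            renal = _renal_fallback(cal, iliac, config.renal_fallback_offset_mm)
            diagnostics["renal_fallback"] = True
        diagnostics["renal_plane"] = renal
        diagnostics["iliac_plane"] = iliac
        diagnostics["bifurcation_planes"] = planes
        # side branches (everything off the trunk chain) become exclusion
        # tubes: their remnants inside the clip must not contaminate sections
        by_id = {b.branch_id: b for b in branched.branches}
        trunk_ids = set()
        cur = min(branched.branches, key=lambda b: float(b.end[2]))
        while cur is not None and cur.branch_id not in trunk_ids:
            trunk_ids.add(cur.branch_id)
            cur = by_id.get(cur.parent_id)
        exclusion = [(b.points, b.radius) for b in branched.branches
                     if b.branch_id not in trunk_ids]

    with stage("clip_abdominal"):
        abd_surf, abd_cal = clip_abdominal(surf, cal, renal, iliac, config.centerline)
        if config.keep_intermediates:
            diagnostics["cropped_surface"] = surf
            diagnostics["abdominal_surface"] = abd_surf
            diagnostics["abdominal_centerline"] = abd_cal
            diagnostics["cal"] = cal

    with stage("sections"):
        # terminal clearance: within one typical vessel radius of the iliac
        # plane a perpendicular section cuts into the limb split (saddle
        # region) and is not a well-defined single-tube cross-section
        abd_branch = max(abd_cal.branches, key=lambda b: b.length)
        r_end = float(np.median(abd_branch.radius))
        exclusion = exclusion + [(abd_branch.points[-1][None, :], np.array([r_end]))]
        sections = generate_sections(abd_surf, abd_cal, config.section_step,
                                     exclusion_tubes=exclusion)
        if not sections:
            raise DegenerateGeometryError("no valid perpendicular sections")

    with stage("maximum"):
        max_d, best = max_abdominal_diameter(sections)

    return MeasurementResult(
        case_id=case_id,
        max_diameter=float(max_d),
        max_arc_length=float(best.arc_length),
        max_z=float(best.z),
        max_equivalent_diameter=float(best.equivalent_diameter),
        thrombus_volume_ml=vol_ml,
        n_sections=len(sections),
        used_thrombus=used_thrombus,
        sections=sections,
        diagnostics=diagnostics,
        stage_log=log,
    )


def write_case_report(result: MeasurementResult, json_path: str,
                      profile_csv_path: str | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    if profile_csv_path:
        import pandas as pd

        pd.DataFrame(result.profile_rows()).to_csv(profile_csv_path, index=False)
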