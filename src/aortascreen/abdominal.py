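"""Abdominal-tract isolation: branch decomposition of the centerline,
bifurcation planes, renal-level identification, and clipping.

After the arch and iliac axial crop, the centerline paths to the remaining
target seeds share a trunk and diverge toward the renal arteries; the most
inferior divergence plane marks the renal level ("the last bifurcation
plane"). The aortic model is clipped between that plane (normal facing
inferior) and the iliac plane (normal facing superior), and the centerline
is recomputed between the two plane origins on the isolated tract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline import (Branch, Centerline, CenterlineParams, _GridContext,
                         _recenter_path, _spline_resample, compute_centerline)
from .errors import RenalPlaneNotFoundError, ValidationError
from .surface import SurfaceMesh, slice_with_plane
from .volume_io import LabelVolume


@dataclass
class BifurcationPlane:
    origin: np.ndarray  # (3,) mm, on the centerline
    normal: np.ndarray  # unit vector along the local centerline tangent
    label: str = "other"  # {renal, iliac, other}
    junction_z: float | None = None  # z of the junction this plane derives from

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValidationError("plane normal must be nonzero")
        self.normal = n / norm

    @property
    def z(self) -> float:
        return float(self.origin[2])

    def to_dict(self) -> dict:
        return {"origin": [float(v) for v in self.origin],
                "normal": [float(v) for v in self.normal],
                "label": self.label}


@dataclass
class Junction:
    point: np.ndarray  # (3,) mm, last common trunk point
    parent_id: int
    child_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# branch decomposition
# ---------------------------------------------------------------------------

def _common_prefix_len(paths: list[np.ndarray]) -> int:
    n = min(len(p) for p in paths)
    first = paths[0][:n]
    agree = np.ones(n, dtype=bool)
    for p in paths[1:]:
        agree &= np.all(first == p[:n], axis=1)
    bad = np.flatnonzero(~agree)
    return int(bad[0]) if len(bad) else n


def split_branches(cal: Centerline) -> Centerline:
    """Decompose a multi-target centerline into trunk/child branches.

    The raw voxel paths share exact prefixes up to each divergence; each
    tract between consecutive divergences becomes one branch (refined and
    resampled independently). A single-path centerline yields one branch.
    """
    if not cal.raw_paths or cal.grid is None:
        raise ValidationError("centerline carries no raw paths; recompute with compute_centerline")
    segments: list[tuple[np.ndarray, int]] = []  # (voxel path, parent segment id)
    junctions: list[Junction] = []

    def decompose(paths: list[np.ndarray], parent: int) -> None:
        paths = [p for p in paths if len(p) > 1]
        if not paths:
            return
        if len(paths) == 1:
            segments.append((paths[0], parent))
            return
        L = _common_prefix_len(paths)
        if L < 2:
            L = 2  # force a minimal trunk to keep segments connected
        trunk = paths[0][:L]
        seg_id = len(segments)
        segments.append((trunk, parent))
        junction_pt = trunk[-1]
        groups: dict[tuple, list[np.ndarray]] = {}
        terminated = False
        for p in paths:
            rest = p[L - 1:]  # include junction voxel for continuity
            if len(rest) < 2:
                terminated = True
                continue
            groups.setdefault(tuple(rest[1]), []).append(rest)
        child_start = len(segments)
        for g in groups.values():
            decompose(g, seg_id)
        child_ids = list(range(child_start, len(segments)))
        if len(groups) >= 2 or (terminated and groups):
            junctions.append(Junction(point=junction_pt.astype(float), parent_id=seg_id,
                                      child_ids=child_ids))

    decompose(list(cal.raw_paths), -1)
    grid = cal.grid
    spacing = grid.spacing
    origin = grid.origin
    branches = []
    for bid, (vox, parent) in enumerate(segments):
        mm = vox * spacing + origin
        refined = _recenter_path(mm, grid)
        b = _spline_resample(refined, cal.params, grid)
        b.branch_id = bid
        b.parent_id = parent
        branches.append(b)
    out = Centerline(kind="CAL", branches=branches, raw_paths=cal.raw_paths,
                     grid=grid, params=cal.params)
    out.junctions = [
        Junction(point=j.point * spacing + origin, parent_id=j.parent_id,
                 child_ids=j.child_ids)
        for j in junctions
    ]
    return out


# ---------------------------------------------------------------------------
# bifurcation planes
# ---------------------------------------------------------------------------

def _dist_to_polyline(p: np.ndarray, poly: np.ndarray) -> float:
    """Euclidean distance from a point to a polyline (segment-wise)."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def _closest_on_branch(p: np.ndarray, branch: Branch) -> int:
    return int(np.argmin(np.linalg.norm(branch.points - p, axis=1)))


def bifurcation_planes(surface: SurfaceMesh, branched: Centerline) -> list[BifurcationPlane]:
    """One plane per divergence of the branched centerline.

    The plane sits where the diverging child leaves the parent vessel: the
    child path is walked from the junction until its distance to the
    continuing trunk exceeds the local trunk radius, and the plane origin is
    the trunk point closest to that exit, with normal along the trunk
    tangent. Planes are returned ordered by decreasing z.
    """
    junctions = getattr(branched, "junctions", [])
    by_id = {b.branch_id: b for b in branched.branches}
    planes: list[BifurcationPlane] = []
    for j in junctions:
        children = [by_id[c] for c in j.child_ids if c in by_id]
        parent = by_id.get(j.parent_id)
        if parent is None or not children:
            continue
        # continuation = child heading most inferior; the rest are take-offs
        cont = min(children, key=lambda b: float(b.end[2]))
        side = [c for c in children if c is not cont]
        if not side:
            side = [cont]
            cont = None
        main_poly = parent.points if cont is None else np.vstack([parent.points, cont.points])
        i_j = _closest_on_branch(j.point, parent)
        r_trunk = float(parent.radius[i_j]) if parent.radius[i_j] > 0 else 5.0
        for child in side:
            exit_pt = None
            for p in child.points:
                if _dist_to_polyline(p, main_poly) > r_trunk:
                    exit_pt = p
                    break
            anchor = exit_pt if exit_pt is not None else j.point
            # closest point on the trunk polyline to the exit point
            d = np.linalg.norm(main_poly - anchor, axis=1)
            i_near = int(np.argmin(d))
            origin = main_poly[i_near]
            if i_near < len(parent.points):
                normal = parent.tangents[min(i_near, len(parent.tangents) - 1)]
            else:
                normal = cont.tangents[i_near - len(parent.points)]
            planes.append(BifurcationPlane(origin=origin, normal=normal, label="other",
                                           junction_z=float(j.point[2])))
    planes.sort(key=lambda pl: -pl.z)
    return planes


def label_iliac_planes(planes: list[BifurcationPlane], branched: Centerline,
                       ) -> list[BifurcationPlane]:
    """Label planes belonging to the terminal (iliac) split as ``iliac``.

    After the axial crop the iliac bifurcation, when it survives inside the
    cropped volume, is the divergence sitting just above the centerline's
    inferior terminus — within one local vessel radius of it. Take-off
    divergences (renal level) lie far above. Labeling is in place; the list
    is returned for convenience.
    """
    if not branched.branches:
        return planes
    z_bottom = min(float(b.end[2]) for b in branched.branches)
    all_pts = np.vstack([b.points for b in branched.branches])
    all_r = np.concatenate([b.radius for b in branched.branches])
    for p in planes:
        i = int(np.argmin(np.linalg.norm(all_pts - p.origin, axis=1)))
        r_local = float(all_r[i]) if all_r[i] > 0 else 5.0
        z_ref = p.junction_z if p.junction_z is not None else p.z
        if z_ref - z_bottom <= r_local:
            p.label = "iliac"
    return planes


def terminal_iliac_plane(cal: Centerline, at_z: float | None = None) -> BifurcationPlane:
    """Iliac-level plane on the most inferior centerline branch.

    By default the plane sits at the branch terminus. When ``at_z`` is given
    (the iliac z found by the axial slice analysis) the plane is anchored at
    the trunk point closest to that height instead, which keeps the normal
    on the straight trunk rather than at the skeleton tip inside the merged
    iliac region.
    """
    ends = [(float(b.end[2]), b) for b in cal.branches]
    _, b = min(ends, key=lambda t: t[0])
    i = len(b.points) - 1 if at_z is None \
        else int(np.argmin(np.abs(b.points[:, 2] - at_z)))
    # the local tangent can curl inside the merged iliac region; take the
    # chord over the last two local radii of trunk as the plane normal
    r_local = float(b.radius[i]) if b.radius[i] > 0 else 5.0
    arc = b.arc_length
    j = int(np.searchsorted(arc, arc[i] - 2.0 * r_local))
    j = min(max(j, 0), max(i - 1, 0))
    chord = b.points[i] - b.points[j]
    norm = float(np.linalg.norm(chord))
    normal = chord / norm if norm > 1e-6 else b.tangents[i]
    return BifurcationPlane(origin=b.points[i], normal=normal, label="iliac")


def find_renal_plane(planes: list[BifurcationPlane],
                     iliac_plane: BifurcationPlane) -> BifurcationPlane:
    """The most inferior non-iliac bifurcation plane, labeled renal.

    After the arch crop the last (lowest) divergence above the iliac split
    belongs to the renal arteries.
    """
    candidates = [p for p in planes
                  if p.label != "iliac"
                  and p.z > iliac_plane.z + 1.0
                  and np.linalg.norm(p.origin - iliac_plane.origin) > 1.0]
    if not candidates:
        raise RenalPlaneNotFoundError("renal level not found: no candidate bifurcation plane")
    best = min(candidates, key=lambda p: p.z)
    return BifurcationPlane(origin=best.origin, normal=best.normal, label="renal")


# ---------------------------------------------------------------------------
# clipping
# ---------------------------------------------------------------------------

def _halfspace_mask(vol: LabelVolume, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Boolean array of voxels on the positive side of the plane."""
    nx, ny, nz = vol.shape
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    xs = (ox + sx * np.arange(nx) - origin[0]) * normal[0]
    ys = (oy + sy * np.arange(ny) - origin[1]) * normal[1]
    zs = (oz + sz * np.arange(nz) - origin[2]) * normal[2]
    return (xs[:, None, None] + ys[None, :, None] + zs[None, None, :]) >= 0


def clip_mask_between_planes(vol: LabelVolume, renal: BifurcationPlane,
                             iliac: BifurcationPlane) -> LabelVolume:
    n_r = renal.normal if renal.normal[2] < 0 else -renal.normal
    n_i = iliac.normal if iliac.normal[2] > 0 else -iliac.normal
    keep = _halfspace_mask(vol, renal.origin, n_r) & _halfspace_mask(vol, iliac.origin, n_i)
    return vol.with_voxels((vol.voxels.astype(bool) & keep).astype(np.uint8))


def clip_abdominal(surface: SurfaceMesh, cal: Centerline,
                   renal: BifurcationPlane, iliac: BifurcationPlane,
                   params: CenterlineParams | None = None,
                   ) -> tuple[SurfaceMesh, Centerline]:
    """Isolate the abdominal tract between the renal and iliac planes.

    The surface is clipped by the renal plane with normal facing inferior
    and the iliac plane with normal facing superior (cut rings capped); the
    centerline is recomputed between the two plane origins on the clipped
    interior.
    """
    if renal.z <= iliac.z:
        raise ValidationError(
            f"renal plane (z={renal.z:.1f}) must be superior to iliac plane (z={iliac.z:.1f})")
    n_renal = renal.normal if renal.normal[2] < 0 else -renal.normal
    n_iliac = iliac.normal if iliac.normal[2] > 0 else -iliac.normal
    clipped = slice_with_plane(surface, renal.origin, n_renal)
    clipped = slice_with_plane(clipped, iliac.origin, n_iliac)
    if cal.grid is None:
        raise ValidationError("centerline carries no grid context; recompute with compute_centerline")
    vol = LabelVolume(cal.grid.mask.astype(np.uint8), tuple(cal.grid.spacing),
                      tuple(cal.grid.origin))
    clipped_vol = clip_mask_between_planes(vol, renal, iliac)
    params = params or cal.params
    abd_cal = compute_centerline(clipped_vol, source=renal.origin,
                                 targets=[iliac.origin], params=params)
    return clipped, abd_cal
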