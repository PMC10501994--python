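"""Centerline extraction: axial bounding, skeletonization, seed detection,
and the refined center aortic line (CAL).

The raw center lumen line (CLL) is a 3D thinning skeleton of the lumen mask;
its end-point voxels (fewer than two foreground 26-neighbors) seed the
refined centerline. The refined line is the minimum-cost path on the
interior voxel graph with edge cost ``length / (DT + eps)^2`` — DT being the
Euclidean distance transform in mm — which presses the path onto the medial
axis; each path is then re-centered by perpendicular-section centroids,
smoothed with a spline controlled by ``smooth_factor`` and resampled at
``resampling_step`` (defaults 0.5 and 2.5 mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.interpolate import splev, splprep
from scipy.ndimage import convolve, distance_transform_edt, label, map_coordinates
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import DegenerateGeometryError, ValidationError
from .surface import SurfaceMesh, slice_with_plane
from .volume_io import LabelVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class CenterlineParams:
    """Tunables of the refined-centerline computation.

    resampling_step: arc-length spacing of output points, mm.
    smooth_factor: 0 = no spline smoothing, 1 = maximal; mapped monotonically
        to the smoothing-spline penalty.
    prune_mm: skeleton limbs shorter than this are discarded before endpoint
        extraction (thinning noise creates false seeds).
    """

    resampling_step: float = 2.5
    smooth_factor: float = 0.5
    prune_mm: float = 5.0
    neighborhood: int = 26
    voxel_pitch: float = 1.0  # pitch used when voxelizing a SurfaceMesh input

    def __post_init__(self):
        if self.resampling_step <= 0:
            raise ValidationError("resampling_step must be > 0")
        if not (0.0 <= self.smooth_factor <= 1.0):
            raise ValidationError("smooth_factor must be in [0, 1]")
        if self.neighborhood != 26:
            raise ValidationError("only 26-neighborhood skeleton adjacency is supported")


@dataclass
class Branch:
    """One ordered polyline of a centerline."""

    points: np.ndarray  # (N, 3) mm
    arc_length: np.ndarray  # (N,) mm, strictly increasing from 0
    tangents: np.ndarray  # (N, 3) unit vectors
    radius: np.ndarray  # (N,) maximal inscribed radius, mm
    branch_id: int = 0
    parent_id: int = -1

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def start(self) -> np.ndarray:
        return self.points[0]

    @property
    def end(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class _GridContext:
    """Voxel-grid context a centerline was computed on (used for branch
    re-decomposition and abdominal re-computation)."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    dt: np.ndarray


@dataclass
class Centerline:
    kind: str  # {"CLL", "CAL"}
    branches: list[Branch]
    raw_paths: list[np.ndarray] = field(default_factory=list, repr=False)  # voxel-index paths
    grid: _GridContext | None = field(default=None, repr=False)
    params: CenterlineParams = field(default_factory=CenterlineParams, repr=False)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def all_points(self) -> np.ndarray:
        return np.vstack([b.points for b in self.branches])

    def export_csv(self, path: str) -> None:
        import pandas as pd

        rows = []
        for b in self.branches:
            for i in range(len(b.points)):
                rows.append((b.branch_id, i, *b.points[i], b.arc_length[i], b.radius[i]))
        pd.DataFrame(rows, columns=["branch_id", "point_index", "x", "y", "z",
                                    "arc_length_mm", "radius_mm"]).to_csv(path, index=False)

    def export_vtp(self, path: str) -> None:
        write_vtp_polylines(self, path)


@dataclass
class AxialBounds:
    z_arch: float
    z_iliac: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# axial bounding (arch / iliac levels)
# ---------------------------------------------------------------------------

def find_axial_bounds(aorta: LabelVolume, min_component_voxels: int = 4) -> AxialBounds:
    """Locate arch and iliac z-levels from per-slice connected components.

    Scanning the axial slices, the ascending+descending limbs of the arch
    appear as two components that merge into one at the top of the bend;
    symmetrically the iliac limbs split from one component into two below
    the bifurcation. The arch level is the most superior 2-to-1 transition,
    the iliac level the most inferior one. With no such transition (e.g. a
    single straight tube) the bounds degenerate to the full foreground z
    extent.
    """
    m = aorta.voxels.astype(bool)
    if not m.any():
        raise ValidationError("empty mask: cannot find axial bounds")
    nz = m.shape[2]
    counts = np.zeros(nz, dtype=int)
    for k in range(nz):
        sl = m[:, :, k]
        if not sl.any():
            continue
        lab, n = label(sl, structure=_STRUCT8)
        if min_component_voxels > 1 and n:
            sizes = np.bincount(lab.ravel())[1:]
            n = int((sizes >= min_component_voxels).sum())
        counts[k] = n
    candidates = [k for k in range(1, nz) if counts[k] == 1 and counts[k - 1] >= 2]
    occupied = np.flatnonzero(counts > 0)
    z_lo = aorta.z_of_slice(int(occupied[0]))
    z_hi = aorta.z_of_slice(int(occupied[-1]))
    if len(candidates) < 2:
        return AxialBounds(z_arch=z_hi, z_iliac=z_lo, degenerate=True)
    z_arch = aorta.z_of_slice(max(candidates))
    z_iliac = aorta.z_of_slice(min(candidates))
    if z_arch <= z_iliac:
        return AxialBounds(z_arch=z_hi, z_iliac=z_lo, degenerate=True)
    return AxialBounds(z_arch=z_arch, z_iliac=z_iliac, degenerate=False)


def crop_to_bounds(mesh: SurfaceMesh, z_arch: float, z_iliac: float) -> SurfaceMesh:
    """Clip a surface between two horizontal planes (z_iliac <= z <= z_arch),
    capping the cut rings."""
    if z_arch <= z_iliac:
        raise ValidationError(f"z_arch ({z_arch}) must exceed z_iliac ({z_iliac})")
    z_min, z_max = mesh.z_extent
    out = mesh
    if z_iliac > z_min:
        if z_iliac >= z_max:
            warnings.warn("iliac plane above mesh extent; crop skipped")
        else:
            out = slice_with_plane(out, (0, 0, z_iliac), (0, 0, 1.0))
    if z_arch < z_max:
        if z_arch <= z_min:
            warnings.warn("arch plane below mesh extent; crop skipped")
        else:
            out = slice_with_plane(out, (0, 0, z_arch), (0, 0, -1.0))
    return out


def crop_mask_to_bounds(vol: LabelVolume, z_arch: float, z_iliac: float) -> LabelVolume:
    """Restrict a volume to axial slices with z_iliac <= z <= z_arch."""
    if z_arch <= z_iliac:
        raise ValidationError(f"z_arch ({z_arch}) must exceed z_iliac ({z_iliac})")
    z0, sz = vol.origin[2], vol.spacing[2]
    k_lo = max(0, int(np.ceil((z_iliac - z0) / sz - 1e-9)))
    k_hi = min(vol.shape[2] - 1, int(np.floor((z_arch - z0) / sz + 1e-9)))
    if k_hi < k_lo:
        raise ValidationError("crop range contains no slices")
    voxels = vol.voxels[:, :, k_lo:k_hi + 1]
    origin = (vol.origin[0], vol.origin[1], z0 + k_lo * sz)
    return LabelVolume(voxels.copy(), vol.spacing, origin, vol.axis_convention)


def largest_component(vol: LabelVolume) -> LabelVolume:
    """Keep only the largest 26-connected foreground component."""
    lab, n = label(vol.voxels > 0, structure=_STRUCT26)
    if n <= 1:
        return vol
    sizes = np.bincount(lab.ravel())
    keep = int(np.argmax(sizes[1:])) + 1
    return vol.with_voxels((lab == keep).astype(np.uint8))


# ---------------------------------------------------------------------------
# skeleton (raw center lumen line)
# ---------------------------------------------------------------------------

def skeletonize_lumen(lumen: LabelVolume) -> LabelVolume:
    """3D thinning skeleton of the lumen mask (the raw CLL).

    Thinning assumes isotropic adjacency; resample the mask isotropically
    first (``resample_isotropic``).
    """
    if lumen.is_empty():
        raise ValidationError("empty lumen: cannot skeletonize")
    sp = lumen.spacing
    if max(sp) / min(sp) > 1.05:
        raise ValidationError(
            f"skeletonization requires near-isotropic spacing, got {sp}; "
            "resample with resample_isotropic first")
    from skimage.morphology import skeletonize

    skel = skeletonize(lumen.voxels.astype(bool))
    return lumen.with_voxels(skel.astype(np.uint8))


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return convolve(skel.astype(np.uint8), _STRUCT26.astype(np.uint8),
                    mode="constant", cval=0) - skel.astype(np.uint8)


def find_endpoints(skeleton: LabelVolume) -> list[tuple[int, int, int]]:
    """Skeleton voxels with fewer than 2 foreground 26-neighbors."""
    skel = skeleton.voxels.astype(bool)
    counts = _neighbor_counts(skel)
    eps = np.argwhere(skel & (counts < 2))
    return [tuple(int(v) for v in p) for p in eps]


def prune_skeleton(skeleton: LabelVolume, min_length_mm: float = 5.0,
                   max_passes: int = 3) -> LabelVolume:
    """Remove terminal skeleton limbs shorter than ``min_length_mm``.

    A limb is the chain from an endpoint to the first junction voxel
    (3 or more neighbors); limbs ending at another endpoint (isolated
    chains) are kept.
    """
    skel = skeleton.voxels.astype(bool).copy()
    spacing = np.asarray(skeleton.spacing)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for _ in range(max_passes):
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts < 2))
        removed_any = False
        for ep in endpoints:
            path = [tuple(int(v) for v in ep)]
            length = 0.0
            prev = None
            cur = path[0]
            hit_junction = False
            while True:
                nbrs = []
                for off in offsets:
                    q = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                    if any(c < 0 or c >= s for c, s in zip(q, skel.shape)):
                        continue
                    if skel[q] and q != prev:
                        nbrs.append(q)
                if len(nbrs) != 1:
                    break  # endpoint (0) or junction reached via multiple (handled below)
                nxt = nbrs[0]
                if counts[nxt] >= 3:
                    hit_junction = True
                    break
                length += float(np.linalg.norm((np.array(nxt) - np.array(cur)) * spacing))
                path.append(nxt)
                prev, cur = cur, nxt
                if length >= min_length_mm:
                    break
            if hit_junction and length < min_length_mm:
                for p in path:
                    skel[p] = False
                removed_any = True
        if not removed_any:
            break
    return skeleton.with_voxels(skel.astype(np.uint8))


def pick_seeds(endpoint_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Source seed = endpoint with the highest z; the rest are target seeds."""
    pts = np.atleast_2d(np.asarray(endpoint_mm, dtype=float))
    if len(pts) < 2:
        raise ValidationError(f"need at least 2 endpoints to seed a centerline, got {len(pts)}")
    i_src = int(np.argmax(pts[:, 2]))
    source = pts[i_src]
    targets = np.delete(pts, i_src, axis=0)
    return source, targets


# ---------------------------------------------------------------------------
# refined centerline (CAL)
# ---------------------------------------------------------------------------

_EPS_DT = 1e-2


def _interior_graph(mask: np.ndarray, spacing: np.ndarray, dt: np.ndarray):
    """Sparse 26-connected graph over foreground voxels with medial weighting."""
    idx = np.argwhere(mask)
    n = len(idx)
    ids = np.full(mask.shape, -1, dtype=np.int32)
    ids[tuple(idx.T)] = np.arange(n, dtype=np.int32)
    w = 1.0 / (dt[mask] + _EPS_DT) ** 2
    rows, cols, data = [], [], []
    shape = mask.shape
    for off in [(i, j, k) for i in (0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                if (i, j, k) > (0, 0, 0)]:
        sl_a = tuple(slice(max(0, o), s + min(0, o)) for o, s in zip(off, shape))
        sl_b = tuple(slice(max(0, -o), s + min(0, -o)) for o, s in zip(off, shape))
        both = mask[sl_a] & mask[sl_b]
        a = ids[sl_a][both]
        b = ids[sl_b][both]
        step = float(np.linalg.norm(np.asarray(off) * spacing))
        rows.append(a)
        cols.append(b)
        data.append(step * 0.5 * (w[a] + w[b]))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    graph = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    return graph, idx, ids


def _snap_to_interior(point_mm, mask_idx_mm: np.ndarray, max_dist: float = 15.0) -> int:
    d2 = np.sum((mask_idx_mm - np.asarray(point_mm, dtype=float)) ** 2, axis=1)
    i = int(np.argmin(d2))
    if d2[i] > max_dist ** 2:
        raise ValidationError(
            f"seed {point_mm} is {np.sqrt(d2[i]):.1f} mm from the interior; projection failed")
    return i


def _moving_average(points: np.ndarray, window: int = 5) -> np.ndarray:
    if len(points) < window:
        return points
    kernel = np.ones(window) / window
    sm = np.empty_like(points, dtype=float)
    for c in range(points.shape[1]):
        sm[:, c] = np.convolve(points[:, c], kernel, mode="same")
    half = window // 2
    sm[:half] = points[:half]
    sm[-half:] = points[-half:]
    return sm


def _tangents_of(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _recenter_path(points_mm: np.ndarray, grid: _GridContext) -> np.ndarray:
    """Re-center each path point at the centroid of its perpendicular
    in-plane lumen cross-section (sub-voxel medialization)."""
    mask = grid.mask
    spacing = grid.spacing
    origin = grid.origin
    step = float(min(spacing))
    smoothed = _moving_average(points_mm, 5)
    tangents = _tangents_of(smoothed)
    out = points_mm.copy()
    for i, (p, t) in enumerate(zip(points_mm, tangents)):
        idx = (p - origin) / spacing
        r_local = map_coordinates(grid.dt, idx.reshape(3, 1), order=1, mode="nearest")[0]
        half = float(np.clip(2.5 * r_local + 3.0, 4.0, 60.0))
        u, v = _plane_basis(t)
        axes = np.arange(-half, half + step / 2, step)
        aa, bb = np.meshgrid(axes, axes, indexing="ij")
        pts = p[None, None, :] + aa[..., None] * u[None, None, :] + bb[..., None] * v[None, None, :]
        coords = (pts.reshape(-1, 3) - origin) / spacing
        vals = map_coordinates(mask.astype(np.uint8), coords.T, order=0,
                               mode="constant", cval=0).reshape(aa.shape)
        lab, n = label(vals, structure=_STRUCT8)
        ci = len(axes) // 2
        comp = lab[ci, ci]
        if comp == 0:
            continue
        sel = lab == comp
        a_bar = float(aa[sel].mean())
        b_bar = float(bb[sel].mean())
        # a valid centroid of the section containing p lies within the local
        # inscribed radius; larger shifts mean the in-plane sampling was
        # corrupted (e.g. the plane grazing a clip boundary) — keep p then
        if np.hypot(a_bar, b_bar) > max(float(r_local), step):
            continue
        out[i] = p + a_bar * u + b_bar * v
    return out


def _spline_resample(points_mm: np.ndarray, params: CenterlineParams,
                     grid: _GridContext) -> Branch:
    """Smoothing-spline fit + arc-length resampling of a refined path."""
    pts = points_mm
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if len(pts) < 2:
        raise ValidationError("degenerate path: fewer than 2 distinct points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    k = min(3, len(pts) - 1)
    sigma = 0.4 * params.smooth_factor  # mm of allowed smoothing deviation
    s = len(pts) * sigma ** 2
    # pin the endpoints: free ends of a smoothing spline can overshoot and
    # hook, which corrupts the terminal tangents (and any plane built there)
    w = np.ones(len(pts))
    w[0] = w[-1] = 1e3
    tck, _ = splprep(pts.T, u=u, w=w, k=k, s=s)
    # fine sampling for arc length
    uf = np.linspace(0, 1, max(200, 4 * len(pts)))
    fine = np.column_stack(splev(uf, tck))
    seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_out = max(2, int(np.floor(total / params.resampling_step)) + 1)
    stations = np.linspace(0.0, total, n_out) if total < params.resampling_step else \
        np.append(np.arange(0.0, total, params.resampling_step), total)
    u_out = np.interp(stations, arc, uf)
    out = np.column_stack(splev(u_out, tck))
    # tangents from central differences of the resampled points: the spline
    # derivative oscillates between stations (sub-mm wiggles over a 2.5 mm
    # step tilt it by tens of degrees), while differencing over whole steps
    # averages that noise away
    tangents = _tangents_of(out)
    seg_out = np.linalg.norm(np.diff(out, axis=0), axis=1)
    arc_out = np.concatenate([[0.0], np.cumsum(seg_out)])
    radius = _inscribed_radius(out, grid)
    return Branch(points=out, arc_length=arc_out, tangents=tangents, radius=radius)


def _inscribed_radius(points: np.ndarray, grid: _GridContext) -> np.ndarray:
    """Maximal inscribed radius at off-grid points.

    Linear interpolation of the distance transform underestimates at its
    ridge (the medial axis), so instead the 1-Lipschitz lower bound
    ``DT(v) - |p - v|`` is maximized over the 8 surrounding voxel centers;
    half a voxel is subtracted because DT measures to background voxel
    centers, half a voxel beyond the label boundary.
    """
    shape = np.asarray(grid.dt.shape)
    idx = (points - grid.origin) / grid.spacing
    base = np.floor(idx).astype(int)
    best = np.full(len(points), -np.inf)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                vi = np.clip(base + (di, dj, dk), 0, shape - 1)
                v_mm = vi * grid.spacing + grid.origin
                cand = grid.dt[vi[:, 0], vi[:, 1], vi[:, 2]] \
                    - np.linalg.norm(points - v_mm, axis=1)
                best = np.maximum(best, cand)
    return np.clip(best - 0.5 * float(np.mean(grid.spacing)), 0.0, None)


def _voxelize_mesh(mesh: SurfaceMesh, pitch: float) -> LabelVolume:
    vg = mesh.to_trimesh().voxelized(pitch).fill()
    # voxel centers in mm
    dense = np.asarray(vg.matrix, dtype=np.uint8)
    origin = np.asarray(vg.transform[:3, 3], dtype=float)
    return LabelVolume(dense, (pitch,) * 3, tuple(origin))


def compute_centerline(interior, source, targets,
                       params: CenterlineParams | None = None) -> Centerline:
    """Refined centerline from a source seed to each target seed.

    ``interior`` is the binary whole-aorta mask (:class:`LabelVolume`) or a
    closed :class:`SurfaceMesh` (voxelized internally). Each path maximizes
    distance from the wall (minimum cost ``length/(DT+eps)^2`` on the voxel
    graph), is re-centered on perpendicular-section centroids, spline
    smoothed, and resampled at ``params.resampling_step``; the maximal
    inscribed radius is recorded per point. Seeds off the interior are
    projected to the nearest interior voxel.
    """
    params = params or CenterlineParams()
    if isinstance(interior, SurfaceMesh):
        vol = _voxelize_mesh(interior, params.voxel_pitch)
    else:
        vol = interior
    mask = vol.voxels.astype(bool)
    if not mask.any():
        raise ValidationError("empty interior: cannot compute a centerline")
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    dt = distance_transform_edt(mask, sampling=spacing)
    grid = _GridContext(mask=mask, spacing=spacing, origin=origin, dt=dt)
    graph, idx, _ = _interior_graph(mask, spacing, dt)
    idx_mm = idx * spacing + origin
    i_src = _snap_to_interior(source, idx_mm)
    tgt_list = np.atleast_2d(np.asarray(targets, dtype=float))
    i_tgts = [_snap_to_interior(t, idx_mm) for t in tgt_list]
    dist, pred = _csgraph_dijkstra(graph, directed=False, indices=i_src,
                                   return_predecessors=True)
    branches = []
    raw_paths = []
    for bid, i_t in enumerate(i_tgts):
        if not np.isfinite(dist[i_t]):
            raise DegenerateGeometryError(
                "no interior path between source and target (disconnected mask)")
        chain = [i_t]
        while chain[-1] != i_src:
            chain.append(int(pred[chain[-1]]))
        chain.reverse()
        path_vox = idx[chain]
        raw_paths.append(path_vox)
        path_mm = path_vox * spacing + origin
        refined = _recenter_path(path_mm, grid)
        branch = _spline_resample(refined, params, grid)
        branch.branch_id = bid
        branches.append(branch)
    return Centerline(kind="CAL", branches=branches, raw_paths=raw_paths,
                      grid=grid, params=params)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_vtp_polylines(cl: Centerline, path: str) -> None:
    """Minimal ASCII XML PolyData (.vtp) writer for centerline polylines."""
    all_pts = []
    lines = []
    offset = 0
    for b in cl.branches:
        n = len(b.points)
        all_pts.append(b.points)
        lines.append(np.arange(offset, offset + n))
        offset += n
    pts = np.vstack(all_pts)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
        fh.write('  <PolyData>\n')
        fh.write(f'    <Piece NumberOfPoints="{len(pts)}" NumberOfLines="{len(lines)}">\n')
        fh.write('      <Points>\n        <DataArray type="Float32" NumberOfComponents="3" format="ascii">\n')
        for p in pts:
            fh.write(f"          {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write('        </DataArray>\n      </Points>\n')
        fh.write('      <Lines>\n        <DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for ln in lines:
            fh.write("          " + " ".join(str(i) for i in ln) + "\n")
        fh.write('        </DataArray>\n        <DataArray type="Int64" Name="offsets" format="ascii">\n')
        ends = np.cumsum([len(ln) for ln in lines])
        fh.write("          " + " ".join(str(e) for e in ends) + "\n")
        fh.write('        </DataArray>\n      </Lines>\n')
        fh.write('    </Piece>\n  </PolyData>\n</VTKFile>\n')
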