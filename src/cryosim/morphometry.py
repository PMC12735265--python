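"""Ice-ball morphometrics: isotherm regions, caliper axes, warm zones, merges.

The ice ball is operationally the region at or below 0 degC; the lethal zone
is bounded by a colder isotherm (-40 degC in the layout comparisons, -50 degC
as the necrosis temperature).  Extents are measured the way a bench caliper
measures a cut specimen: the longitudinal extent is the span of the largest
connected frozen component along the probe axis, the transverse extent the
maximal width in any perpendicular direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage.measure import marching_cubes, find_contours

__all__ = [
    "EmptyRegionError",
    "IsothermRegion",
    "IceballMetrics",
    "extract_isotherm_region",
    "measure_axes",
    "warm_zone_volume",
    "track_merge_events",
    "dimensional_error",
    "sample_thermocouples",
    "compute_metrics",
    "axisymmetric_extents",
    "surface_volume",
    "write_stl",
]


class EmptyRegionError(ValueError):
    """The requested isotherm region contains no cells."""


@dataclass
class IsothermRegion:
    """A thresholded temperature region plus its triangulated isosurface.

    ``mask`` flags cells at or below ``level``; ``verts``/``faces`` are the
    marching-cubes surface in physical coordinates (empty when the level does
    not cross the field).
    """

    level: float
    mask: np.ndarray
    verts: np.ndarray
    faces: np.ndarray
    grid: object

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def voxel_volume(self) -> float:
        """Region volume from the cell count (m^3)."""
        return float(np.sum(self.grid.cell_volumes()[self.mask]))

    def component_count(self) -> int:
        _, n = ndimage.label(self.mask)
        return int(n)

    def touches_boundary(self) -> bool:
        m = self.mask
        return bool(
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or (m.ndim == 3 and (m[:, :, 0].any() or m[:, :, -1].any()))
        )


def extract_isotherm_region(T: np.ndarray, level: float, grid) -> IsothermRegion:
    """Cells with ``T <= level`` plus the interpolated isosurface at ``level``."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature field contains non-finite values")
    mask = T <= level
    verts = np.empty((0, T.ndim))
    faces = np.empty((0, 3), dtype=int)
    if T.ndim == 3 and T.min() < level < T.max():
        h = grid.spacing
        verts, faces, _, _ = marching_cubes(T, level=level, spacing=(h, h, h))
        verts = verts + np.asarray(grid.origin) + h / 2.0
    return IsothermRegion(level=level, mask=mask, verts=verts, faces=faces, grid=grid)


def _largest_component(mask: np.ndarray):
    labels, n = ndimage.label(mask)
    if n == 0:
        raise EmptyRegionError("isotherm region is empty")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _component_points(region: IsothermRegion) -> np.ndarray:
    """Physical points describing the largest connected component boundary."""
    comp = _largest_component(region.mask)
    grid = region.grid
    h = grid.spacing
    if len(region.verts):
        idx = np.rint((region.verts - np.asarray(grid.origin)) / h - 0.5).astype(int)
        idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
        keep = comp[tuple(idx.T)]
        pts = region.verts[keep]
        if len(pts) >= 3:
            return pts
    # degenerate / tiny region: use cell centers of the component
    centers = grid.cell_centers()[comp]
    return centers


def measure_axes(region: IsothermRegion, probe_axis=(0.0, 0.0, -1.0)):
    """(longitudinal, transverse) caliper extents of the largest component, m.

    Longitudinal is the span along ``probe_axis``; transverse the maximal
    support-function width along any perpendicular direction (the diameter of
    the projection onto the plane normal to the axis).
    """
    if region.is_empty:
        raise EmptyRegionError("cannot measure axes of an empty region")
    axis = np.asarray(probe_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pts = _component_points(region)
    proj = pts @ axis
    longitudinal = float(proj.max() - proj.min())
    # orthonormal basis of the perpendicular plane
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    plane = np.column_stack([pts @ e1, pts @ e2])
    transverse = _planar_diameter(plane)
    return longitudinal, transverse


def _planar_diameter(pts2: np.ndarray) -> float:
    if len(pts2) < 2:
        return 0.0
    cand = pts2
    if len(pts2) > 16:
        try:
            hull = ConvexHull(pts2)
            cand = pts2[hull.vertices]
        except QhullError:  # collinear projection
            pass
    d2 = np.sum((cand[:, None, :] - cand[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def warm_zone_volume(T: np.ndarray, hull_level: float = 0.0,
                     lethal_level: float = -40.0, grid=None) -> float:
    """Volume of under-cooled tissue trapped inside the frozen hull, m^3.

    Cells inside the convex hull of the ``hull_level`` region whose
    temperature exceeds ``lethal_level`` (incomplete-ablation pockets between
    probes).  Returns 0 for an empty hull.
    """
    if lethal_level >= hull_level:
        raise ValueError("lethal_level must be below hull_level")
    T = np.asarray(T, dtype=float)
    mask = T <= hull_level
    if not mask.any():
        return 0.0
    inside = _convex_hull_mask(mask)
    warm = inside & (T > lethal_level)
    return float(np.sum(grid.cell_volumes()[warm]))


def _convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    pts = np.argwhere(mask).astype(float)
    if len(pts) <= mask.ndim + 1:
        return mask.copy()
    try:
        hull = ConvexHull(pts)
        tri = Delaunay(pts[hull.vertices])
    except QhullError:  # degenerate (flat) point cloud
        return mask.copy()
    grid_pts = np.indices(mask.shape).reshape(mask.ndim, -1).T.astype(float)
    inside = tri.find_simplex(grid_pts) >= 0
    return inside.reshape(mask.shape)


def track_merge_events(result, level: float = 0.0) -> pd.DataFrame:
    """Connected-component count of the frozen region per snapshot.

    Multi-probe freezes show the characteristic sequence independent growth
    (one component per probe) -> fusion (count drops) -> collective expansion
    (single component).  Merge events are the strict decreases.
    """
    times, counts = [], []
    for t, snap in zip(result.snapshot_times, result.snapshots):
        _, n = ndimage.label(np.asarray(snap.T) <= level)
        times.append(t)
        counts.append(int(n))
    df = pd.DataFrame({"t_s": times, "n_components": counts})
    df["merge_event"] = df["n_components"].diff().fillna(0) < 0
    return df


def dimensional_error(sim, ref) -> float:
    """Mean absolute relative deviation between measured axes, percent."""
    sim = np.atleast_1d(np.asarray(sim, dtype=float))
    ref = np.atleast_1d(np.asarray(ref, dtype=float))
    if sim.shape != ref.shape:
        raise ValueError("sim and ref must have matching shapes")
    if np.any(ref <= 0):
        raise ValueError("reference dimensions must be positive")
    return float(np.mean(np.abs(sim - ref) / ref) * 100.0)


def sample_thermocouples(result, points) -> pd.DataFrame:
    """Temperature and damage fraction at probe-side monitor points.

    Trilinearly interpolates every stored snapshot at each point; continuous
    1 Hz traces are recorded during the run itself via ``simulate(monitors=)``
    and live in ``result.traces``.
    """
    grid = result.grid
    coords = grid.axis_coords()
    los = np.array([c[0] for c in coords])
    his = np.array([c[-1] for c in coords])
    pts = []
    for p in points:
        p = np.asarray(p, dtype=float)
        lo = np.asarray(grid.origin)
        hi = lo + np.asarray(grid.shape) * grid.spacing
        if np.any(p < lo) or np.any(p > hi):
            raise ValueError(f"thermocouple point {p.tolist()} lies outside the domain")
        pts.append(np.clip(p, los, his))
    pts = np.asarray(pts)
    from scipy.interpolate import RegularGridInterpolator

    rows = {"t_s": list(result.snapshot_times)}
    Tcols = {j: [] for j in range(len(pts))}
    thcols = {j: [] for j in range(len(pts))}
    for snap in result.snapshots:
        fT = RegularGridInterpolator(coords, snap.T, method="linear")
        fth = RegularGridInterpolator(coords, snap.theta_d, method="linear")
        vT = fT(pts)
        vth = fth(pts)
        for j in range(len(pts)):
            Tcols[j].append(float(vT[j]))
            thcols[j].append(float(vth[j]))
    for j in range(len(pts)):
        rows[f"T_p{j}_C"] = Tcols[j]
    for j in range(len(pts)):
        rows[f"theta_p{j}"] = thcols[j]
    return pd.DataFrame(rows)


@dataclass
class IceballMetrics:
    """Morphometric summary of one isotherm level."""

    isotherm_level: float
    longitudinal_extent: float
    transverse_extent: float
    volume: float
    connected_component_count: int
    warm_zone_volume: float
    boundary_clipped: bool

    def to_dict(self) -> dict:
        return {
            "isotherm_level_C": self.isotherm_level,
            "longitudinal_extent_m": self.longitudinal_extent,
            "transverse_extent_m": self.transverse_extent,
            "volume_m3": self.volume,
            "connected_component_count": self.connected_component_count,
            "warm_zone_volume_m3": self.warm_zone_volume,
            "boundary_clipped": self.boundary_clipped,
        }


def compute_metrics(T: np.ndarray, grid, levels=(0.0, -20.0, -40.0, -50.0),
                    probe_axis=(0.0, 0.0, -1.0), hull_level: float = 0.0) -> list:
    """IceballMetrics rows for several isotherm levels of one snapshot.

    ``warm_zone_volume`` of each row counts cells warmer than that row's level
    inside the convex hull of the ``hull_level`` (ice ball) region.
    """
    T = np.asarray(T, dtype=float)
    out = []
    for level in levels:
        region = extract_isotherm_region(T, level, grid)
        if region.is_empty:
            out.append(IceballMetrics(level, 0.0, 0.0, 0.0, 0, 0.0, False))
            continue
        if T.ndim == 2:  # axisymmetric (r, z) snapshot
            lon, tra = axisymmetric_extents(T, level, grid)
            wz = warm_zone_volume(T, hull_level, level, grid) if level < hull_level else 0.0
            m = region.mask
            clipped = bool(m[-1].any() or m[:, 0].any())  # outer wall or bottom
            out.append(
                IceballMetrics(level, lon, tra, region.voxel_volume(),
                               region.component_count(), wz, clipped)
            )
            continue
        lon, tra = measure_axes(region, probe_axis)
        wz = warm_zone_volume(T, hull_level, level, grid) if level < hull_level else 0.0
        out.append(
            IceballMetrics(
                isotherm_level=level,
                longitudinal_extent=lon,
                transverse_extent=tra,
                volume=region.voxel_volume(),
                connected_component_count=region.component_count(),
                warm_zone_volume=wz,
                boundary_clipped=region.touches_boundary(),
            )
        )
    return out


def axisymmetric_extents(T: np.ndarray, level: float, grid):
    """(longitudinal, transverse) extents of a ``T <= level`` region on an (r,z) grid.

    Sub-cell accurate via contour interpolation; spans clipped by a domain
    boundary are extended to the wall (the region genuinely reaches it).
    """
    T = np.asarray(T, dtype=float)
    mask = T <= level
    if not mask.any():
        raise EmptyRegionError("isotherm region is empty")
    h = grid.spacing
    r, z = grid.axis_coords()
    pts = []
    for c in find_contours(T, level):
        rr = (c[:, 0] + 0.5) * h
        zz = grid.z_top - grid.shape[1] * h + (c[:, 1] + 0.5) * h
        pts.append(np.column_stack([rr, zz]))
    if pts:
        pts = np.vstack(pts)
        z_min, z_max = pts[:, 1].min(), pts[:, 1].max()
        r_max = pts[:, 0].max()
    else:  # whole field below level
        z_min, z_max = z[0], z[-1]
        r_max = r[-1]
    if mask[:, -1].any():
        z_max = grid.z_top
    if mask[:, 0].any():
        z_min = grid.z_top - grid.shape[1] * h
    if mask[-1, :].any():
        r_max = grid.shape[0] * h
    return float(z_max - z_min), float(2.0 * r_max)


def surface_volume(region: IsothermRegion) -> float:
    """Volume enclosed by the triangulated isosurface (divergence theorem), m^3."""
    if not len(region.faces):
        return 0.0
    v = region.verts
    f = region.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(abs(np.sum(np.einsum("ij,ij->i", a, np.cross(b, c)))) / 6.0)


def write_stl(region: IsothermRegion, path) -> None:
    """Export the isosurface as ASCII STL."""
    v, f = region.verts, region.faces
    with open(path, "w") as fh:
        fh.write(f"solid isotherm_{region.level}\n")
        for tri in f:
            a, b, c = v[tri[0]], v[tri[1]], v[tri[2]]
            n = np.cross(b - a, c - a)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            fh.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            fh.write("    outer loop\n")
            for p in (a, b, c):
                fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid isotherm_{region.level}\n")
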