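"""Voxel grids, ellipsoid rasterization and Boolean accessibility volumes.

Space is discretized into a regular grid of rectangular voxels. A voxel
belongs to a segment's accessibility spheroid iff its *center* satisfies the
containment test; the trajectory-level volume is the voxelwise OR (union)
over segments, and a population-level volume the OR over trajectories.
Only voxels intersecting a segment's bounding box are tested, which bounds
the per-segment work by the box size rather than the whole grid, without
changing the result.

Volumes are resolution- and alignment-dependent; both are explicit,
logged parameters of every computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InfeasibleSegmentError
from .geometry import EllipsoidParams, ellipsoid_bbox, ellipsoid_params
from .trajectory_io import Trajectory, segments

__all__ = [
    "VoxelGrid",
    "PPVVolume",
    "make_grid",
    "default_extent",
    "default_voxel_size",
    "rasterize_segment",
    "ppv_trajectory",
    "ppv_union",
    "clip_vertical",
    "volume_size",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular grid: min corner, per-axis voxel edge lengths and counts.

    Voxel (i, j, k) has center origin + ((i+0.5)dx, (j+0.5)dy, (k+0.5)dz),
    0-based. This convention is normative: volumes depend on it.
    """

    origin: np.ndarray
    voxel_size: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "voxel_size", np.asarray(self.voxel_size, dtype=float))
        if (self.voxel_size <= 0).any():
            raise ConfigurationError("voxel_size components must be > 0")
        if any(n < 1 for n in self.dims):
            raise ConfigurationError("grid dims must be >= 1 in every axis")

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel (m^3)."""
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def same_as(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.voxel_size, other.voxel_size)
        )


@dataclass
class PPVVolume:
    """Boolean occupancy (1 = reachable) over a voxel grid.

    ``z_scale`` records any vertical stretch applied to the input trajectory,
    so :func:`volume_size` can report in original physical units.
    """

    grid: VoxelGrid
    occupancy: np.ndarray
    z_scale: float = 1.0

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != self.grid.dims:
            raise ConfigurationError(
                f"occupancy shape {self.occupancy.shape} != grid dims {self.grid.dims}"
            )


def make_grid(extent_min, extent_max, voxel_size) -> VoxelGrid:
    """Grid covering [extent_min, extent_max], dims = ceil(extent / edge).

    The grid may overshoot the extent by less than one voxel per axis.
    ``voxel_size`` may be a scalar (cubic voxels) or a 3-vector.
    """
    lo = np.asarray(extent_min, dtype=float)
    hi = np.asarray(extent_max, dtype=float)
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if (hi <= lo).any():
        raise ConfigurationError("extent max must exceed extent min in every axis")
    if (vs <= 0).any():
        raise ConfigurationError("voxel_size must be > 0")
    dims = tuple(int(n) for n in np.ceil((hi - lo) / vs - 1e-12))
    dims = tuple(max(n, 1) for n in dims)
    return VoxelGrid(origin=lo, voxel_size=vs, dims=dims)


def default_extent(
    trajs: list[Trajectory], v_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fix bounding box padded by the largest semi-major axis.

    Every ellipsoid point lies within a = v_max*dt/2 of its center, and the
    center (a segment midpoint) lies inside the fix bounding box, so this
    extent never clips a volume.
    """
    if not trajs:
        raise ConfigurationError("default_extent needs at least one trajectory")
    lo = np.min([tr.xyz.min(axis=0) for tr in trajs], axis=0)
    hi = np.max([tr.xyz.max(axis=0) for tr in trajs], axis=0)
    max_dt = max(float(np.diff(tr.t).max()) for tr in trajs)
    pad = v_max * max_dt / 2.0
    return lo - pad, hi + pad


def default_voxel_size(extent_min, extent_max, divisions: int = 200) -> float:
    """Cubic voxel edge: the extent's largest edge / ``divisions``.

    The default keeps grids at desk scale (<= ~8M voxels) while resolving
    typical minor axes; override for precision work.
    """
    span = np.asarray(extent_max, dtype=float) - np.asarray(extent_min, dtype=float)
    return float(span.max() / divisions)


def _bbox_slices(grid: VoxelGrid, lo: np.ndarray, hi: np.ndarray):
    """Index slices of voxels whose centers may fall inside [lo, hi].

    Expanded by one voxel each way so pruning can never drop a center that
    the exhaustive sweep would test positively.
    """
    first = np.floor((lo - grid.origin) / grid.voxel_size - 0.5).astype(int) - 1
    last = np.ceil((hi - grid.origin) / grid.voxel_size - 0.5).astype(int) + 1
    first = np.maximum(first, 0)
    last = np.minimum(last, np.array(grid.dims) - 1)
    if (last < first).any():
        return None
    return tuple(slice(int(f), int(l) + 1) for f, l in zip(first, last))


def _rasterize_into(occ: np.ndarray, grid: VoxelGrid, params: EllipsoidParams) -> bool:
    """OR one ellipsoid into an occupancy array; False if fully off-grid."""
    lo, hi = ellipsoid_bbox(params)
    sl = _bbox_slices(grid, lo, hi)
    if sl is None:
        return False
    xs = grid.axis_centers(0)[sl[0]]
    ys = grid.axis_centers(1)[sl[1]]
    zs = grid.axis_centers(2)[sl[2]]
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    inside = contains_block(params, pts)
    occ[sl] |= inside
    return bool(inside.any())


def contains_block(params: EllipsoidParams, pts: np.ndarray) -> np.ndarray:
    """Vectorized containment over an (..., 3) block of points."""
    q = (pts - params.center) @ params.rotation.T
    if params.b == 0.0:
        s = np.linalg.norm(pts - params.foci[0], axis=-1) + np.linalg.norm(
            pts - params.foci[1], axis=-1
        )
        return s <= 2 * params.a * (1 + 1e-9)
    form = (
        (q[..., 0] / params.a) ** 2
        + (q[..., 1] / params.b) ** 2
        + (q[..., 2] / params.b) ** 2
    )
    return form <= 1.0 + 1e-12


def rasterize_segment(grid: VoxelGrid, params: EllipsoidParams) -> np.ndarray:
    """Boolean occupancy of one ellipsoid over the grid (center-point rule).

    Tests only the voxels intersecting the ellipsoid's bounding box; the
    result is bit-identical to an exhaustive all-voxel sweep. An ellipsoid
    wholly outside the grid yields all zeros with a warning (so clipping by
    a reduced extent is usable deliberately).
    """
    occ = np.zeros(grid.dims, dtype=bool)
    any_hit = _rasterize_into(occ, grid, params)
    if not any_hit:
        warnings.warn("ellipsoid does not occupy any voxel of the grid", stacklevel=2)
    return occ


def ppv_trajectory(traj: Trajectory, v_max: float, grid: VoxelGrid) -> PPVVolume:
    """Union of per-segment ellipsoid rasterizations for one trajectory."""
    occ = np.zeros(grid.dims, dtype=bool)
    for i, seg in enumerate(segments(traj)):
        try:
            params = ellipsoid_params(seg, v_max)
        except InfeasibleSegmentError as exc:
            raise InfeasibleSegmentError(f"{traj.id}, segment {i}: {exc}") from exc
        _rasterize_into(occ, grid, params)
    return PPVVolume(grid=grid, occupancy=occ, z_scale=traj.z_scale)


def ppv_union(volumes: list[PPVVolume]) -> PPVVolume:
    """Voxelwise OR of volumes sharing one grid (no resampling)."""
    if not volumes:
        raise ConfigurationError("ppv_union needs at least one volume")
    first = volumes[0]
    occ = first.occupancy.copy()
    for vol in volumes[1:]:
        if not vol.grid.same_as(first.grid):
            raise ConfigurationError("ppv_union requires identical grids")
        if vol.z_scale != first.z_scale:
            raise ConfigurationError("ppv_union requires identical z_scale")
        occ |= vol.occupancy
    return PPVVolume(grid=first.grid, occupancy=occ, z_scale=first.z_scale)


def clip_vertical(vol: PPVVolume, z_min: float, z_max: float) -> PPVVolume:
    """Zero every voxel whose center lies outside [z_min, z_max].

    Mirrors the case-study practice of bounding the volume between a floor
    (GPS error below the surface) and a flight ceiling.
    """
    if not (z_min < z_max):
        raise ConfigurationError("z_min must be < z_max")
    zc = vol.grid.axis_centers(2)
    keep = (zc >= z_min) & (zc <= z_max)
    occ = vol.occupancy & keep[np.newaxis, np.newaxis, :]
    return PPVVolume(grid=vol.grid, occupancy=occ, z_scale=vol.z_scale)


def volume_size(vol: PPVVolume) -> float:
    """Occupied volume in km^3, corrected for any vertical rescaling.

    count * dx*dy*dz / 1e9 / z_scale — dividing by z_scale undoes the
    vertical stretch so rescaled volumes report in original units.
    """
    count = int(vol.occupancy.sum())
    return count * vol.grid.voxel_volume / 1e9 / vol.z_scale
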