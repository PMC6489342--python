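"""Per-segment speeds, robust maximum-speed estimation and z-rescaling.

The accessibility ellipsoid of a segment is sized by the mover's maximum
speed v_max. Using the raw maximum observed speed makes the fastest segment's
ellipsoid degenerate (zero minor axis), so the robust estimator

    v_max = 2 * v_m - v_{m-1}

extrapolates just beyond the maximum observed speed v_m using the next
largest observed speed v_{m-1}.

Because most species move much faster horizontally than vertically, separate
horizontal (v_xy_max) and vertical (v_z_max) maxima can be estimated, and the
vertical coordinate stretched by their ratio before volume construction so a
single isotropic speed budget applies in the rescaled space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PPVError
from .trajectory_io import Segment, Trajectory

__all__ = [
    "SpeedModel",
    "segment_speed",
    "segment_speeds",
    "estimate_vmax",
    "split_speeds",
    "rescale_z",
    "validate_vmax_override",
]


def segment_speed(seg: Segment) -> float:
    """Mean 3D speed over a segment: Euclidean displacement / elapsed time."""
    if not (seg.dt > 0):
        raise PPVError(f"segment dt must be > 0, got {seg.dt}")
    d = np.hypot(
        np.hypot(seg.end.x - seg.start.x, seg.end.y - seg.start.y),
        seg.end.z - seg.start.z,
    )
    return float(d / seg.dt)


def segment_speeds(traj: Trajectory) -> np.ndarray:
    """3D speeds of all segments of a trajectory, in order (m/s)."""
    disp = np.diff(traj.xyz, axis=0)
    dts = np.diff(traj.t)
    return np.linalg.norm(disp, axis=1) / dts


def split_speeds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal (xy-plane) and vertical (|dz|) speeds per segment.

    For every segment, horizontal**2 + vertical**2 == segment_speed**2.
    """
    disp = np.diff(traj.xyz, axis=0)
    dts = np.diff(traj.t)
    horizontal = np.hypot(disp[:, 0], disp[:, 1]) / dts
    vertical = np.abs(disp[:, 2]) / dts
    return horizontal, vertical


def estimate_vmax(speeds) -> float:
    """Robust maximum speed 2*v_m - v_{m-1} from the two largest speeds.

    With a single observed speed the estimator falls back to that speed
    (with a warning), so two-fix trajectories remain processable. Always
    >= max(speeds), with equality only when the two largest speeds tie.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise PPVError("cannot estimate v_max from an empty speed list")
    if not np.isfinite(speeds).all() or (speeds < 0).any():
        raise PPVError("speeds must be finite and non-negative")
    if speeds.size == 1:
        warnings.warn(
            "single observed speed: v_max falls back to it and the segment's "
            "ellipsoid is degenerate",
            stacklevel=2,
        )
        return float(speeds[0])
    top2 = np.partition(speeds, -2)[-2:]
    v_m1, v_m = float(top2[0]), float(top2[1])
    return 2.0 * v_m - v_m1


def validate_vmax_override(v_max: float, speeds) -> float:
    """Check a user-supplied v_max against the observed speeds.

    A v_max below the maximum observed speed would give some segment an
    imaginary minor axis, so it is rejected.
    """
    speeds = np.asarray(speeds, dtype=float)
    if not (v_max > 0):
        raise ConfigurationError("v_max override must be positive")
    if speeds.size and v_max < speeds.max():
        raise ConfigurationError(
            f"v_max override {v_max:g} m/s is below the maximum observed "
            f"speed {speeds.max():g} m/s"
        )
    return float(v_max)


@dataclass(frozen=True)
class SpeedModel:
    """Observed speeds and robust maxima for one trajectory.

    Attributes
    ----------
    per_segment : segment 3D speeds (m/s), in order.
    v_m, v_m_minus_1 : the two largest observed 3D speeds.
    v_max : robust 3D maximum, 2*v_m - v_{m-1} (or a user override).
    v_xy_max, v_z_max : robust maxima of the horizontal / vertical speed
        components, estimated with the same two-largest rule.
    """

    per_segment: np.ndarray
    v_m: float
    v_m_minus_1: float
    v_max: float
    v_xy_max: float
    v_z_max: float

    @classmethod
    def from_trajectory(cls, traj: Trajectory, v_max: float | None = None) -> "SpeedModel":
        speeds = segment_speeds(traj)
        h, v = split_speeds(traj)
        if speeds.size >= 2:
            top2 = np.partition(speeds, -2)[-2:]
            v_m1, v_m = float(top2[0]), float(top2[1])
        else:
            v_m = v_m1 = float(speeds[0])
        vmax = (
            validate_vmax_override(v_max, speeds)
            if v_max is not None
            else estimate_vmax(speeds)
        )
        return cls(
            per_segment=speeds,
            v_m=v_m,
            v_m_minus_1=v_m1,
            v_max=vmax,
            v_xy_max=estimate_vmax(h) if h.size else 0.0,
            v_z_max=estimate_vmax(v) if v.size else 0.0,
        )


def rescale_z(traj: Trajectory, v_xy_max: float, v_z_max: float) -> Trajectory:
    """Stretch the vertical coordinate by v_xy_max / v_z_max.

    In the rescaled space the mover's vertical and horizontal speed capacities
    are comparable, so one isotropic v_max sizes the accessibility ellipsoids.
    The applied factor accumulates in ``z_scale`` on the returned trajectory;
    volumes computed in rescaled space are reported in original physical units
    by dividing the raw voxel volume by ``z_scale``.
    """
    if not (v_xy_max > 0 and v_z_max > 0):
        raise ConfigurationError("v_xy_max and v_z_max must both be positive")
    factor = v_xy_max / v_z_max
    xyz = traj.xyz.copy()
    xyz[:, 2] = xyz[:, 2] * factor
    return Trajectory(
        id=traj.id,
        xyz=xyz,
        t=traj.t.copy(),
        nominal_interval=traj.nominal_interval,
        labels=dict(traj.labels),
        z_scale=traj.z_scale * factor,
    )
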