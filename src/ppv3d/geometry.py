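"""The analytic core: per-segment accessibility ellipsoids.

Between two fixes P_i and P_{i+1} observed dt seconds apart, a mover with
maximum speed v_max can only have visited points p with

    |p - P_i| + |p - P_{i+1}|  <=  v_max * dt,

the locus of which is a prolate spheroid with the fixes at its foci ("string
construction"): semi-major axis a = v_max*dt/2 along the segment direction,
and two equal semi-minor axes b = sqrt(a^2 - d^2/4), where d is the focal
separation. This module constructs the spheroid, maps points into its
principal-axis frame (translation to the midpoint, then a yaw and a pitch
rotation), and tests containment via the standard quadratic form

    x'^2/a^2 + y'^2/b^2 + z'^2/b^2 <= 1.

The frame convention is pinned by the endpoint contract: the foci map to
(-d/2, 0, 0) and (+d/2, 0, 0). The focal-distance inequality doubles as an
independent containment oracle — the two tests are exactly equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleSegmentError
from .trajectory_io import Segment

__all__ = [
    "EllipsoidParams",
    "ellipsoid_params",
    "to_ellipsoid_frame",
    "contains",
    "contains_focal",
    "ellipsoid_bbox",
]

#: Relative tolerance for boundary inclusivity of the containment test.
EPS_REL = 1e-12


@dataclass(frozen=True)
class EllipsoidParams:
    """One segment's prolate spheroid.

    center is the midpoint of the foci; d their separation; a >= d/2 the
    semi-major axis; b = sqrt(a^2 - d^2/4) the common semi-minor axis;
    alpha the azimuth (yaw) and beta the elevation (pitch) of the segment
    direction. ``rotation`` maps data-frame offsets into the ellipsoid frame.
    """

    center: np.ndarray
    d: float
    a: float
    b: float
    alpha: float
    beta: float
    foci: np.ndarray
    rotation: np.ndarray = field(init=False)

    def __post_init__(self):
        ca, sa = np.cos(self.alpha), np.sin(self.alpha)
        cb, sb = np.cos(self.beta), np.sin(self.beta)
        # R = Ry(beta) @ Rz(-alpha): sends the unit segment direction
        # (cb*ca, cb*sa, sb) to (1, 0, 0).
        rot = np.array(
            [
                [cb * ca, cb * sa, sb],
                [-sa, ca, 0.0],
                [-sb * ca, -sb * sa, cb],
            ]
        )
        object.__setattr__(self, "rotation", rot)


def ellipsoid_params(seg: Segment, v_max: float) -> EllipsoidParams:
    """Construct the accessibility spheroid of one segment.

    Raises :class:`InfeasibleSegmentError` when the observed displacement
    exceeds the speed budget v_max*dt (typically a bad v_max override). A
    zero-displacement segment yields a ball of radius a; a segment moving
    exactly at v_max yields the degenerate b = 0 spheroid (the segment
    itself).
    """
    if not (seg.dt > 0):
        raise InfeasibleSegmentError(f"segment dt must be > 0, got {seg.dt}")
    if not (v_max > 0):
        raise InfeasibleSegmentError(f"v_max must be > 0, got {v_max}")
    p0 = np.array([seg.start.x, seg.start.y, seg.start.z], dtype=float)
    p1 = np.array([seg.end.x, seg.end.y, seg.end.z], dtype=float)
    delta = p1 - p0
    d = float(np.linalg.norm(delta))
    budget = v_max * seg.dt
    if d > budget * (1.0 + 1e-12):
        raise InfeasibleSegmentError(
            f"segment from t={seg.start.t} to t={seg.end.t}: displacement "
            f"{d:.6g} m exceeds v_max*dt = {budget:.6g} m"
        )
    a = budget / 2.0
    b = float(np.sqrt(max(a * a - d * d / 4.0, 0.0)))
    if d > 0.0:
        alpha = float(np.arctan2(delta[1], delta[0]))
        beta = float(np.arcsin(np.clip(delta[2] / d, -1.0, 1.0)))
    else:
        alpha = beta = 0.0
    return EllipsoidParams(
        center=(p0 + p1) / 2.0,
        d=d,
        a=a,
        b=b,
        alpha=alpha,
        beta=beta,
        foci=np.vstack([p0, p1]),
    )


def to_ellipsoid_frame(p, params: EllipsoidParams) -> np.ndarray:
    """Map point(s) into the ellipsoid's principal-axis frame.

    Rigid motion: translate by -center, then rotate so the foci land on
    (-d/2, 0, 0) and (+d/2, 0, 0). Accepts a single (3,) point or an (n, 3)
    array.
    """
    p = np.asarray(p, dtype=float)
    return (p - params.center) @ params.rotation.T


def contains(params: EllipsoidParams, p, eps: float = EPS_REL):
    """Quadratic-form containment test (boundary inclusive).

    For the degenerate b = 0 spheroid the form is undefined, so the test
    falls back to the focal-distance inequality; the "ellipsoid" is then
    the segment itself, still rasterizable as a one-voxel-thick line.
    """
    p = np.asarray(p, dtype=float)
    if params.b == 0.0:
        return _focal_form(params.foci[0], params.foci[1], p) <= 2 * params.a * (1 + 1e-9)
    q = to_ellipsoid_frame(p, params)
    form = (
        (q[..., 0] / params.a) ** 2
        + (q[..., 1] / params.b) ** 2
        + (q[..., 2] / params.b) ** 2
    )
    return form <= 1.0 + eps


def _focal_form(f0: np.ndarray, f1: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.linalg.norm(p - f0, axis=-1) + np.linalg.norm(p - f1, axis=-1)


def contains_focal(seg: Segment, v_max: float, p, eps: float = EPS_REL):
    """String-construction oracle: summed focal distances within the budget.

    True iff |p - P_i| + |p - P_{i+1}| <= v_max * dt (up to eps). Exactly
    equivalent to :func:`contains`; kept as an independent brute-force check.
    """
    p = np.asarray(p, dtype=float)
    f0 = np.array([seg.start.x, seg.start.y, seg.start.z], dtype=float)
    f1 = np.array([seg.end.x, seg.end.y, seg.end.z], dtype=float)
    budget = v_max * seg.dt
    return _focal_form(f0, f1, p) <= budget * (1.0 + eps)


def ellipsoid_bbox(params: EllipsoidParams) -> tuple[np.ndarray, np.ndarray]:
    """Conservative axis-aligned bounding box: center +/- a on every axis.

    Always sufficient (every ellipsoid point is within a of the center);
    exactly tight for the spherical d = 0 case. Used to prune the voxel
    sweep to the segment's neighbourhood.
    """
    pad = np.full(3, params.a)
    return params.center - pad, params.center + pad
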