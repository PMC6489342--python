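"""Reading, validating, filtering and thinning 3D trajectories.

A trajectory is an ordered sequence of timestamped fixes (x, y, z, t) for one
individual, in a projected metric coordinate system. This module owns the
tabular (CSV) interchange dialect — column names default to Movebank-style
export headers — and the simple structural operations on trajectories:
splitting into segments, rejecting tracks with large temporal gaps, and
regular subsampling.

Coordinates must arrive already projected (metres). The package never
reprojects: all downstream geometry is Euclidean, so the projection choice
belongs upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TrajectoryError

__all__ = [
    "TrackPoint",
    "Segment",
    "Trajectory",
    "DEFAULT_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "segments",
    "filter_gaps",
    "subsample",
]

#: Default column mapping, matching Movebank CSV export headers.  The
#: longitude/latitude columns are expected to hold *pre-projected* metric
#: easting/northing values (the tool does not project).
DEFAULT_COLUMNS = {
    "id": "individual-local-identifier",
    "time": "timestamp",
    "x": "location-long",
    "y": "location-lat",
    "z": "height-above-msl",
}


class TrackPoint(NamedTuple):
    """One fix: easting, northing, altitude (m) and time (s)."""

    x: float
    y: float
    z: float
    t: float


class Segment(NamedTuple):
    """A consecutive fix pair — the unit of PPV construction."""

    start: TrackPoint
    end: TrackPoint

    @property
    def dt(self) -> float:
        """Elapsed time between the endpoints (s)."""
        return self.end.t - self.start.t


@dataclass
class Trajectory:
    """An ordered 3D track for one individual.

    Parameters
    ----------
    id
        Individual / track identifier.
    xyz
        ``(n, 3)`` float array of projected coordinates in metres.
    t
        ``(n,)`` strictly increasing times in seconds.
    nominal_interval
        The nominal sampling interval in seconds (programmed tag interval
        or the inferred median inter-fix interval).
    labels
        Free-form tags, e.g. ``{"trip": "departure"}``.
    z_scale
        Vertical stretch factor applied to ``z`` relative to the original
        data (1.0 if none); see :func:`ppv3d.speed_model.rescale_z`.
    """

    id: str
    xyz: np.ndarray
    t: np.ndarray
    nominal_interval: float
    labels: dict = field(default_factory=dict)
    z_scale: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise TrajectoryError(f"{self.id}: xyz must be (n, 3)")
        n = self.xyz.shape[0]
        if self.t.shape != (n,):
            raise TrajectoryError(f"{self.id}: t must have one entry per fix")
        if n < 2:
            raise TrajectoryError(f"{self.id}: a trajectory needs >= 2 fixes")
        if not (np.isfinite(self.xyz).all() and np.isfinite(self.t).all()):
            raise TrajectoryError(f"{self.id}: non-finite coordinate or time")
        dts = np.diff(self.t)
        if (dts <= 0).any():
            raise TrajectoryError(
                f"{self.id}: times must be strictly increasing "
                "(duplicate or out-of-order timestamps)"
            )
        if not (self.nominal_interval > 0):
            raise TrajectoryError(f"{self.id}: nominal_interval must be > 0")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def point(self, i: int) -> TrackPoint:
        x, y, z = self.xyz[i]
        return TrackPoint(x, y, z, self.t[i])


def _parse_times(raw: pd.Series, time_format: str | None) -> np.ndarray:
    """Parse a timestamp column to float seconds.

    Numeric columns are taken as seconds as-is; anything else goes through
    pandas' datetime parser (ISO-8601 by default) and is converted to seconds
    since the Unix epoch.
    """
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric.to_numpy(dtype=float)
    try:
        ts = pd.to_datetime(raw, format=time_format, utc=True)
    except (ValueError, TypeError) as exc:
        bad = raw.index[pd.to_datetime(raw, format=time_format, utc=True,
                                       errors="coerce").isna()]
        row = int(bad[0]) if len(bad) else -1
        raise TrajectoryError(f"unparseable timestamp at row {row}: {exc}") from exc
    return ts.astype("int64").to_numpy() / 1e9


def read_trajectories(
    path,
    columns: dict | None = None,
    time_format: str | None = None,
    nominal_interval: float | None = None,
) -> list[Trajectory]:
    """Read one :class:`Trajectory` per distinct id from a delimited file.

    Rows are sorted by time within each id. Ids with fewer than two usable
    fixes are skipped with a warning; duplicate timestamps within an id are
    an error (a zero-length time step breaks the segment speed). The nominal
    sampling interval is the median inter-fix interval unless supplied.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(colmap)
        if unknown:
            raise ConfigurationError(f"unknown column keys: {sorted(unknown)}")
        colmap.update(columns)

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing columns {missing}; present: {list(df.columns)}"
        )

    t_all = _parse_times(df[colmap["time"]], time_format)
    coords = df[[colmap["x"], colmap["y"], colmap["z"]]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        raise TrajectoryError(
            f"{path}: non-finite coordinate at row {int(np.flatnonzero(bad)[0])}"
        )

    out: list[Trajectory] = []
    for tid, idx in df.groupby(colmap["id"], sort=True).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            warnings.warn(f"id {tid!r}: fewer than 2 fixes, skipped", stacklevel=2)
            continue
        order = np.argsort(t_all[idx], kind="stable")
        t = t_all[idx][order]
        if (np.diff(t) == 0).any():
            raise TrajectoryError(f"id {tid!r}: duplicate timestamps")
        interval = nominal_interval if nominal_interval is not None else float(
            np.median(np.diff(t))
        )
        out.append(
            Trajectory(
                id=str(tid),
                xyz=coords[idx][order],
                t=t,
                nominal_interval=interval,
            )
        )
    return out


def write_trajectories(trajs: list[Trajectory], path, columns: dict | None = None) -> None:
    """Write trajectories back to the canonical CSV dialect (times as seconds).

    Numeric round-trip through :func:`read_trajectories` is exact: values are
    serialised with full ``repr`` precision.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    colmap["id"]: tr.id,
                    colmap["time"]: tr.t,
                    colmap["x"]: tr.xyz[:, 0],
                    colmap["y"]: tr.xyz[:, 1],
                    colmap["z"]: tr.xyz[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def segments(traj: Trajectory) -> list[Segment]:
    """The n−1 consecutive fix pairs of an n-fix trajectory, in order."""
    return [Segment(traj.point(i), traj.point(i + 1)) for i in range(len(traj) - 1)]


def filter_gaps(
    trajs: list[Trajectory], max_gap_multiple: float = 3.0
) -> tuple[list[Trajectory], list[tuple[str, str]]]:
    """Partition trajectories by the temporal-gap rule.

    A trajectory is rejected iff any inter-fix interval *strictly* exceeds
    ``max_gap_multiple`` times its nominal sampling interval (so an exactly
    3x interval, common after thinning, survives the default rule). Gappy
    segments would otherwise produce ellipsoids so large they swallow the
    rest of the accessibility volume.
    """
    if not (max_gap_multiple > 0):
        raise ConfigurationError("max_gap_multiple must be positive")
    kept: list[Trajectory] = []
    rejected: list[tuple[str, str]] = []
    for tr in trajs:
        gaps = np.diff(tr.t)
        limit = max_gap_multiple * tr.nominal_interval
        worst = float(gaps.max())
        if worst > limit:
            rejected.append(
                (tr.id, f"max gap {worst:.0f} s exceeds {max_gap_multiple:g} x "
                        f"nominal interval {tr.nominal_interval:.0f} s")
            )
        else:
            kept.append(tr)
    return kept, rejected


def subsample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th fix (always keeping the last one).

    Emulates a coarser programmed sampling interval: the nominal interval is
    multiplied by ``factor``. ``factor=1`` is the identity.
    """
    if int(factor) != factor or factor < 1:
        raise ConfigurationError("subsample factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return replace(traj)
    idx = list(range(0, len(traj), factor))
    if idx[-1] != len(traj) - 1:
        idx.append(len(traj) - 1)
    if len(idx) < 2:
        raise TrajectoryError(f"{traj.id}: subsampling by {factor} leaves < 2 fixes")
    return Trajectory(
        id=traj.id,
        xyz=traj.xyz[idx],
        t=traj.t[idx],
        nominal_interval=traj.nominal_interval * factor,
        labels=dict(traj.labels),
        z_scale=traj.z_scale,
    )
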