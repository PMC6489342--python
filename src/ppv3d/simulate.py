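"""Synthetic 3D correlated random walks (CRW).

A CRW keeps a persistent heading: at each step the azimuth and the elevation
angle each receive an independent von Mises(0, kappa) increment, so larger
concentrations kappa give straighter paths. Elevation is clamped to
(-pi/2 + delta, pi/2 - delta) rather than wrapped, forbidding loop-the-loop
steps. Step speeds are drawn per step (uniform by default), which produces
the alternation of thick (slow) and thin (fast) accessibility ellipsoids the
volume construction is designed to reveal.

Draw order per step is fixed and documented — horizontal turn, vertical
turn, speed — so a given seed reproduces the same trajectory everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .trajectory_io import Trajectory

__all__ = ["CRWConfig", "simulate_crw3d", "demo_walk"]

#: Elevation clamp margin (rad), keeping arcsin well-defined downstream.
ELEVATION_MARGIN = 1e-3

_SPEED_DISTS = {"uniform", "constant"}


@dataclass(frozen=True)
class CRWConfig:
    """Configuration of a 3D correlated random walk.

    speed_dist is ("uniform", {"low": .., "high": ..}) or
    ("constant", {"value": ..}), in m/s.
    """

    n_steps: int = 40
    dt: float = 60.0
    kappa_h: float = 4.0
    kappa_v: float = 8.0
    speed_dist: tuple = ("uniform", {"low": 2.0, "high": 12.0})
    start: tuple = (0.0, 0.0, 0.0)
    initial_heading: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 2:
            raise ConfigurationError("n_steps must be >= 2")
        if not (self.dt > 0):
            raise ConfigurationError("dt must be > 0")
        if self.kappa_h < 0 or self.kappa_v < 0:
            raise ConfigurationError("turning concentrations must be >= 0")
        name, params = self.speed_dist
        if name not in _SPEED_DISTS:
            raise ConfigurationError(
                f"unknown speed distribution {name!r}; choose from {sorted(_SPEED_DISTS)}"
            )
        if name == "uniform":
            if not (0 <= params["low"] <= params["high"]):
                raise ConfigurationError("uniform speed bounds need 0 <= low <= high")
        elif name == "constant" and params["value"] < 0:
            raise ConfigurationError("constant speed must be >= 0")
        if not (-np.pi / 2 < self.initial_heading[1] < np.pi / 2):
            raise ConfigurationError("initial elevation must lie in (-pi/2, pi/2)")


def _turn(rng: np.random.Generator, kappa: float, n: int) -> np.ndarray:
    if np.isinf(kappa):  # degenerate no-turning limit
        return np.zeros(n)
    return rng.vonmises(0.0, kappa, size=n)


def _speeds(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    name, params = spec
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size=n)
    return np.full(n, float(params["value"]))


def simulate_crw3d(config: CRWConfig) -> Trajectory:
    """Generate one CRW trajectory of n_steps uniform time steps.

    Returns n_steps + 1 fixes at t = 0, dt, 2*dt, ...; a given seed always
    yields the identical trajectory.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_steps
    turns_h = _turn(rng, config.kappa_h, n)
    turns_v = _turn(rng, config.kappa_v, n)
    speeds = _speeds(rng, config.speed_dist, n)

    theta = float(config.initial_heading[0])
    phi = float(config.initial_heading[1])
    lo, hi = -np.pi / 2 + ELEVATION_MARGIN, np.pi / 2 - ELEVATION_MARGIN
    pos = np.asarray(config.start, dtype=float)
    pts = [pos.copy()]
    for k in range(n):
        theta = theta + turns_h[k]
        phi = float(np.clip(phi + turns_v[k], lo, hi))
        step = speeds[k] * config.dt * np.array(
            [np.cos(phi) * np.cos(theta), np.cos(phi) * np.sin(theta), np.sin(phi)]
        )
        pos = pos + step
        pts.append(pos.copy())
    return Trajectory(
        id=f"crw-{config.seed}",
        xyz=np.vstack(pts),
        t=np.arange(n + 1, dtype=float) * config.dt,
        nominal_interval=config.dt,
        labels={"source": "crw"},
    )


def demo_walk() -> Trajectory:
    """The package's standard demonstration walk: a fixed-seed 40-step CRW.

    Heterogeneous per-step speeds make slower segments visibly thicker in
    the resulting volume. Byte-identical across runs (internal fixed seed);
    the parameter values are fixture choices, not estimates.
    """
    return simulate_crw3d(CRWConfig(n_steps=40, dt=60.0, kappa_h=4.0,
                                    kappa_v=8.0, seed=7))
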