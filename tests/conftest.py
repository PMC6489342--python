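import numpy as np
import pytest

from ppv3d import Trajectory

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_traj(xyz, t, tid="t", interval=None, **kw):
    xyz = np.asarray(xyz, dtype=float)
    t = np.asarray(t, dtype=float)
    if interval is None:
        interval = float(np.median(np.diff(t)))
    return Trajectory(id=tid, xyz=xyz, t=t, nominal_interval=interval, **kw)


@pytest.fixture
def straight_traj():
    """Three fixes along x at 300 s spacing, 1 m/s then 2 m/s."""
    return make_traj([[0, 0, 0], [300, 0, 0], [900, 0, 0]], [0, 300, 600])


@pytest.fixture
def movebank_csv(tmp_path):
    """A tiny Movebank-dialect CSV: id A (3 fixes), id B (1 fix)."""
    path = tmp_path / "tracks.csv"
    path.write_text(
        "individual-local-identifier,timestamp,location-long,location-lat,"
        "height-above-msl\n"
        "A,0,0.0,0.0,10.0\n"
        "A,300,100.0,50.0,20.0\n"
        "A,600,200.0,100.0,30.0\n"
        "B,0,5.0,5.0,5.0\n"
    )
    return path
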