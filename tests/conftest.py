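import numpy as np
import pandas as pd
import pytest

from migkit import TrackSet, make_fixture, toy_printed_expectations


@pytest.fixture(scope="session")
def toy():
    ts, labels = make_fixture("toy_printed")
    return ts, labels, toy_printed_expectations()


@pytest.fixture()
def simple_trackset():
    """Two cells stepping with known vectors: A by (3,4,0), B by (0,-5,0)."""
    rows = []
    for f in range(3):
        rows.append(("A", f, 15.0 * f, 3.0 * f, 4.0 * f, 0.0))
        rows.append(("B", f, 15.0 * f, 50.0, 10.0 - 5.0 * f, 0.0))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_min", "x_um", "y_um", "z_um"])
    return TrackSet(df, frame_interval=15.0)


def make_trackset(positions_by_track, frame_interval=15.0):
    """Build a TrackSet from {track_id: [(x, y, z), ...]} (frames 0, 1, ...)."""
    rows = []
    for tid, pts in positions_by_track.items():
        for f, (x, y, z) in enumerate(pts):
            rows.append((tid, f, f * frame_interval, x, y, z))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_min", "x_um", "y_um", "z_um"])
    return TrackSet(df, frame_interval=frame_interval)


def random_rotation(rng):
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
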