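import numpy as np
import pandas as pd
import pytest

from mitosocial.io import CHLOROPLAST, MITOCHONDRION, TrajectorySet


def make_ts(rows, n_frames=None, frame_interval_s=1.0, kind=MITOCHONDRION):
    """Build a TrajectorySet from (track_id, frame, x, y) tuples."""
    spots = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    if n_frames is None:
        n_frames = int(spots["frame"].max()) + 1 if len(spots) else 0
    return TrajectorySet(
        spots, n_frames=n_frames, frame_interval_s=frame_interval_s, organelle_kind=kind
    )


def uniform_ts(rng, n_tracks, n_frames, size=50.0, kind=MITOCHONDRION, resample=False):
    """Tracks at uniform random positions; ``resample`` redraws every frame (CSR)."""
    if resample:
        xy = rng.uniform(0, size, size=(n_frames * n_tracks, 2))
    else:
        base = rng.uniform(0, size, size=(n_tracks, 2))
        xy = np.tile(base, (n_frames, 1))
    spots = pd.DataFrame(
        {
            "track_id": np.tile(np.arange(n_tracks), n_frames),
            "frame": np.repeat(np.arange(n_frames), n_tracks),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    return TrajectorySet(spots, n_frames=n_frames, frame_interval_s=1.0, organelle_kind=kind)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
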