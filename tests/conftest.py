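import numpy as np
import pytest

from vesikin.trackcore import Track, TrackDataset


@pytest.fixture
def simple_dataset():
    """Three 2D tracks of lengths 5/10/20 at 60 ms frame interval."""
    dt = 0.06
    tracks = []
    rng = np.random.default_rng(7)
    for i, n in enumerate([5, 10, 20]):
        frames = np.arange(n)
        tracks.append(Track(
            id=str(i),
            frames=frames,
            times=frames * dt,
            positions=rng.uniform(0, 10, size=(n, 2)),
            intensities=rng.uniform(50, 150, size=n),
        ))
    return TrackDataset(tracks=tracks, frame_interval=dt, pixel_size=0.11,
                        field_extent=(10.0, 10.0))


@pytest.fixture
def straight_track():
    """10 unit steps along x, 1 s apart."""
    n = 11
    frames = np.arange(n)
    pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return Track(id="straight", frames=frames, times=frames.astype(float),
                 positions=pos)


def brownian_track(D, n_steps, dt, seed, ndim=2):
    """Direct Brownian reference trajectory (no boundary), independent of
    the simulator under test."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n_steps, ndim))
    pos = np.vstack([np.zeros(ndim), np.cumsum(steps, axis=0)])
    frames = np.arange(n_steps + 1)
    return Track(id=f"bm{seed}", frames=frames, times=frames * dt, positions=pos)
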