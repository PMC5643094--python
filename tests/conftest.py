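import numpy as np
import pytest

from ootrack.geometry import ellipse_geometry
from ootrack.tracks import Track, TrackSet


@pytest.fixture(scope="session")
def geom():
    """Standard 50 x 40 um elliptical oocyte with the pole at (+25, 0)."""
    return ellipse_geometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_track(xy, dt=1.7, track_id="t0", kind="eb1"):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return Track(track_id=track_id, kind=kind, frame=np.arange(n), t=np.arange(n) * dt, xy=xy)


def random_trackset(rng, n_tracks=100, geom=None, dt=1.7, kind="eb1"):
    """Uncorrelated random-walk tracks inside the geometry's bounding box."""
    tracks = []
    if geom is not None:
        minx, miny, maxx, maxy = geom.polygon.bounds
    else:
        minx, miny, maxx, maxy = -25.0, -20.0, 25.0, 20.0
    for i in range(n_tracks):
        n = int(rng.integers(2, 30))
        start = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        steps = rng.normal(0.0, 0.4, (n - 1, 2))
        xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
        tracks.append(make_track(xy, dt=dt, track_id=f"r{i:04d}", kind=kind))
    return TrackSet.from_tracks(tracks)
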