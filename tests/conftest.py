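import numpy as np
import pytest

from vinearch.core import SegmentList


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


def random_segments(rng, n_roots=8, n_points=8, scale=60.0, z_offset=-40.0):
    """Random polyline cloud flattened to segments: broad spatial coverage,
    both above- and below-surface z, duplicate points occasionally."""
    starts, ends = [], []
    for _ in range(n_roots):
        steps = rng.normal(0.0, scale / n_points, size=(n_points - 1, 3))
        origin = rng.normal([0.0, 0.0, z_offset], [scale / 2, scale / 2, 15.0])
        poly = origin + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if rng.random() < 0.3:  # inject a zero-length segment
            poly = np.vstack([poly[:2], poly[1], poly[2:]])
        starts.append(poly[:-1])
        ends.append(poly[1:])
    return SegmentList(np.vstack(starts), np.vstack(ends))


@pytest.fixture
def segments(rng):
    return random_segments(rng)
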