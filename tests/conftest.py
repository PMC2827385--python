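import numpy as np
import pytest

from aortaflow.geometry import PlaneGeometry, normalize


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_plane(rng, normal=None) -> PlaneGeometry:
    """A random oriented plane with random (orthonormalized) pixel axes."""
    n = random_unit(rng) if normal is None else normalize(normal)
    a = rng.normal(size=3)
    row = a - np.dot(a, n) * n
    row = row / np.linalg.norm(row)
    col = np.cross(n, row)
    return PlaneGeometry(origin=rng.normal(scale=50.0, size=3),
                         row_dir=row, col_dir=col,
                         spacing_row=float(rng.uniform(0.5, 2.0)),
                         spacing_col=float(rng.uniform(0.5, 2.0)))


def axis_aligned_plane(origin=(0.0, 0.0, 0.0), spacing=1.0) -> PlaneGeometry:
    return PlaneGeometry(origin=np.asarray(origin, float),
                         row_dir=(1.0, 0.0, 0.0), col_dir=(0.0, 1.0, 0.0),
                         spacing_row=spacing, spacing_col=spacing)
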