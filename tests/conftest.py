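import numpy as np
import pytest

from vesselmorph import GridSpec, PhantomSpec, make_tube_phantom


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Axis-aligned cylinder, radius 3 mm, 1 mm isotropic grid, axis through
    voxel centers (x = y = 12)."""
    grid = GridSpec(shape=(24, 24, 30), spacing=(1.0, 1.0, 1.0))
    spec = PhantomSpec(segments=[((12.0, 12.0, 4.0), (12.0, 12.0, 25.0), 3.0)],
                       grid=grid, seed=0)
    return spec, make_tube_phantom(spec)


@pytest.fixture(scope="session")
def two_cylinder_phantom():
    """Two well-separated tubes (radii 2 and 4 mm) on a 1 mm grid."""
    grid = GridSpec(shape=(36, 24, 30), spacing=(1.0, 1.0, 1.0))
    spec = PhantomSpec(
        segments=[
            ((8.0, 12.0, 4.0), (8.0, 12.0, 25.0), 2.0),
            ((26.0, 12.0, 4.0), (26.0, 12.0, 25.0), 4.0),
        ],
        grid=grid, seed=0,
    )
    return spec, make_tube_phantom(spec)


def random_tube_spec(rng: np.random.Generator, max_shape: int = 26) -> PhantomSpec:
    """A random valid 1-2 segment phantom spec on a small anisotropic grid."""
    shape = tuple(int(rng.integers(18, max_shape + 1)) for _ in range(3))
    spacing = tuple(float(rng.choice([0.7, 1.0])) for _ in range(3))
    grid = GridSpec(shape=shape, spacing=spacing)
    ext = np.array(grid.extent_mm)
    nseg = int(rng.integers(1, 3))
    segments = []
    for _ in range(nseg):
        r = float(rng.uniform(max(spacing), 2.5))
        a = rng.uniform(0.2, 0.8, 3) * ext
        b = rng.uniform(0.2, 0.8, 3) * ext
        if np.linalg.norm(b - a) < 4:
            b = a + 4 * (b - a + 1e-3) / (np.linalg.norm(b - a) + 1e-3)
            b = np.clip(b, 0.1 * ext, 0.9 * ext)
        segments.append((tuple(a), tuple(b), r))
    return PhantomSpec(segments=segments, grid=grid,
                       seed=int(rng.integers(0, 2**31)))
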