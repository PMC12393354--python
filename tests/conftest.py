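import numpy as np
import pytest

from tractshape.phantom import PhantomSpec, build_phantom
from tractshape.tracking import TrackingParams


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A compact noise-free arc phantom used across tracking tests."""
    return PhantomSpec(
        grid_shape=(44, 30, 12),
        voxel_size=1.0,
        arc_radius=12.0,
        arc_center=(22.0, 5.0, 6.0),
        arc_span=(0.0, float(np.pi)),
        tube_radius=2.5,
        angular_noise_sd=0.0,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def slab_volume():
    """A uniform +x orientation slab: the analytic straight-line substrate."""
    from tractshape.phantom import OrientationVolume

    shape = (40, 12, 12)
    axes = np.zeros(shape + (3,))
    axes[..., 0] = 1.0
    fa = np.full(shape, 0.8)
    return OrientationVolume(orientations=axes, fa=fa, affine=np.eye(4))


@pytest.fixture
def det_params() -> TrackingParams:
    return TrackingParams(mode="deterministic", rng_seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_streamline(rng: np.random.Generator, n_points: int = 12, scale: float = 30.0):
    """A smooth random polyline: cumulative sum of small random steps."""
    steps = rng.normal(size=(n_points, 3))
    return np.cumsum(steps, axis=0) * scale / n_points


def random_bundle(rng: np.random.Generator, n_streamlines: int = 8, n_points: int = 12):
    center = rng.normal(scale=10.0, size=3)
    base = random_streamline(rng, n_points) + center
    return [base + rng.normal(scale=1.5, size=3) for _ in range(n_streamlines)]
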