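import numpy as np
import pytest

from defectometer import Box, Frame, SoapParams


@pytest.fixture
def cube10():
    return Box(lengths=[10.0, 10.0, 10.0])


@pytest.fixture
def small_params():
    """Cheap SOAP parameters for oracle comparisons."""
    return SoapParams(nmax=4, lmax=4, rcut=0.8)


@pytest.fixture
def full_params():
    """The production descriptor size (324 components)."""
    return SoapParams(nmax=8, lmax=8, rcut=0.8)


@pytest.fixture
def random_cluster_frame(cube10):
    """A center at the box middle with 5 random neighbours inside rcut."""
    rng = np.random.default_rng(3)
    pts = np.vstack([[5.0, 5.0, 5.0], 5.0 + rng.uniform(-0.45, 0.45, (5, 3))])
    return Frame(coords=pts, box=cube10)


def stack_frame(n=8, spacing=0.5, box_xy=6.0):
    """Perfect periodic 1-D stack along z; every site equivalent."""
    z = np.arange(n) * spacing
    coords = np.column_stack([np.full(n, box_xy / 2), np.full(n, box_xy / 2), z])
    return Frame(coords=coords, box=Box(lengths=[box_xy, box_xy, n * spacing]))
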