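import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracles importable

from ctfiber import PhantomSpec, Primitive, Volume3D, make_phantom


@pytest.fixture
def cylinder_phantom():
    """Straight fibre analogue: radius-2 cylinder along z spanning a 64^3 grid."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        primitives=[
            Primitive("cylinder", {"axis": 2, "center": (32, 32), "radius": 2}, class_id=1)
        ],
    )
    return make_phantom(spec)


@pytest.fixture
def slab_phantom():
    """Sheet analogue: 3-voxel-thick slab normal to z in a 64^3 grid."""
    spec = PhantomSpec(
        shape=(64, 64, 64),
        primitives=[
            Primitive("slab", {"axis": 2, "center": 32, "thickness": 3}, class_id=1)
        ],
    )
    return make_phantom(spec)


@pytest.fixture
def random_masks():
    """Seeded batch of small random binary volumes for oracle comparisons."""
    rng = np.random.default_rng(20240917)

    def _make(n, shape=(16, 16, 16), density=0.5):
        return [
            Volume3D((rng.random(shape) < density).astype(np.uint8)) for _ in range(n)
        ]

    return _make
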