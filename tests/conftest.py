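import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from deltarad import BinaryMask, ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def sphere_phantom():
    """Textured sphere (radius 6 vox) in a 24^3 volume at 1 mm isotropic."""
    n = 24
    rng = np.random.default_rng(7)
    idx = np.indices((n, n, n), dtype=float)
    r = np.sqrt(((idx - (n - 1) / 2.0) ** 2).sum(axis=0))
    mask = r <= 6.0
    values = np.where(mask, 200.0, 50.0) + rng.normal(0, 5.0, (n, n, n))
    return (
        ImageVolume(values.astype(np.float32)),
        BinaryMask(mask.astype(np.uint8)),
    )


@pytest.fixture
def random_levels(rng):
    """Random 5^3 gray-level lattice (levels 1..4) with an irregular mask."""
    levels = rng.integers(1, 5, size=(5, 5, 5))
    mask = rng.random((5, 5, 5)) < 0.8
    mask[2, 2, 2] = True
    return np.where(mask, levels, 0).astype(np.int64)
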