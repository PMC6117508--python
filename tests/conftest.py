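import numpy as np
import pytest

from neurofuse import BrainMask, Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume(rng):
    """A 4x4x4x30 noise volume with a positive offset and full mask."""
    data = rng.standard_normal((4, 4, 4, 30)) + 100.0
    vol = Volume4D(data, tr_seconds=2.0, voxel_size_mm=(3, 3, 3),
                   affine=np.eye(4))
    return vol, BrainMask(np.ones((4, 4, 4), dtype=bool))


def correlated_series(rng, T: int, target_r: np.ndarray) -> np.ndarray:
    """Rows with exact correlations target_r to row 0 (via orthonormal basis)."""
    n = len(target_r) + 1
    basis, _ = np.linalg.qr(rng.standard_normal((T, n)))
    base = basis[:, 0]
    out = [base]
    for i, r in enumerate(target_r, start=1):
        out.append(r * base + np.sqrt(1 - r**2) * basis[:, i])
    return np.asarray(out)
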