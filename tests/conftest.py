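import numpy as np
import pytest

from voxseg import SelectionMask, normalize, preset_fossil_cheek


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def fossil_phantom():
    """The 64³ specimen-in-matrix phantom at its default study conditions."""
    return preset_fossil_cheek((64, 64, 64), seed=7)


@pytest.fixture(scope="session")
def fossil_normalized(fossil_phantom):
    vol, _ = fossil_phantom
    return normalize(vol)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def digital_ball():
    """Radius-10 digital ball centred in a 26³ grid, 1 µm voxels."""
    n = 26
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 10.0**2
    return SelectionMask(ball, (1.0, 1.0, 1.0))
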