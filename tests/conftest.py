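import numpy as np
import pytest

from blastopack import ModelParams


@pytest.fixture
def params30() -> ModelParams:
    return ModelParams(theta=np.radians(30.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_four_cells(rng, spread=1.2, R_lo=0.5, R_hi=0.8, min_sep=0.25):
    """Random 4-cell configuration with distinct centres (shared helper for
    the Voronoi oracle tests)."""
    while True:
        pos = rng.uniform(-spread, spread, size=(4, 3))
        ok = True
        for i in range(4):
            for j in range(i + 1, 4):
                if np.linalg.norm(pos[i] - pos[j]) < min_sep:
                    ok = False
        if ok:
            break
    radii = rng.uniform(R_lo, R_hi, size=4)
    return pos, radii
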