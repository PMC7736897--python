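import numpy as np
import pytest

from ofsca import FGnSpec, Trajectory2D, generate_fgn
from ofsca.synthetic import split_seed


@pytest.fixture
def rng():
    return np.random.default_rng(20231207)


def isotropic_fgn_trajectory(n: int, hurst: float, seed: int) -> Trajectory2D:
    """Two independent equal-H fGn streams: an isotropic 2D trajectory."""
    s1, s2 = split_seed(seed, 2)
    e1 = generate_fgn(FGnSpec(hurst=hurst, n=n, seed=s1))
    e2 = generate_fgn(FGnSpec(hurst=hurst, n=n, seed=s2))
    return Trajectory2D(e1.values, e2.values, kind="increments")
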