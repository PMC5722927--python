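import numpy as np
import pytest

from zipbind import ChainSpec


@pytest.fixture
def spec_single():
    """A bare 100-segment chain with one ligand at its end."""
    return ChainSpec(N=100)


@pytest.fixture
def spec_dense():
    """Twenty receptors with vanishing spacing (no entropic penalty)."""
    return ChainSpec(N=100, M=20, delta_a=0.0)


@pytest.fixture
def spec_spaced():
    """Five receptors right at the well-separated regime boundary.

    delta_N = 20 and delta_a = sqrt(delta_N) b, i.e. delta_a^2 = delta_N b^2.
    """
    return ChainSpec(N=100, M=5, delta_a=np.sqrt(20.0))
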