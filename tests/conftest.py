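import numpy as np
import pytest

from divsel.simulator import FixedParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240207)


@pytest.fixture
def small_fixed():
    """A fast desk-scale parameter set (t_final = 19)."""
    return FixedParams(r=3.0e-4, t_star=5, n_cycles=4, Ne=50, L=12, snp_spacing=165)


@pytest.fixture
def tiny_r_fixed():
    """Recombination rate so small that crossovers essentially never occur."""
    return FixedParams(r=1e-12, t_star=5, n_cycles=4, Ne=40, L=10, snp_spacing=165)
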