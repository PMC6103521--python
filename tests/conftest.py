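"""Shared fixtures: the expensive response profiles are computed once per
session and reused by several acceptance tests."""

import numpy as np
import pytest

from resonet.experiments import (frequency_sweep, scaled_sweep,
                                 single_cell_ladder)
from resonet.network import lif_network


@pytest.fixture(scope="session")
def square_profile():
    """Control network, high-synchrony fixed-mean square sweep, 16-32 Hz."""
    return frequency_sweep(scaled_sweep(kind="square_fixed_mean",
                                        delta_inp=1.0, base_seed=1))


@pytest.fixture(scope="session")
def sine_profile():
    """Control network, sinusoidal sweep (mean-matched), 16-32 Hz."""
    return frequency_sweep(scaled_sweep(kind="sine", delta_inp=None,
                                        base_seed=1))


@pytest.fixture(scope="session")
def d10_profile():
    """Control network, medium-synchrony square sweep, 20-36 Hz."""
    return frequency_sweep(scaled_sweep(kind="square_fixed_mean",
                                        delta_inp=10.0,
                                        grid=tuple(range(20, 37, 2)),
                                        base_seed=1))


@pytest.fixture(scope="session")
def lif_profile():
    """Integrate-and-fire control network sweep, 16-32 Hz."""
    return frequency_sweep(scaled_sweep(network=lif_network(),
                                        kind="square_fixed_mean",
                                        delta_inp=1.0, base_seed=1))


@pytest.fixture(scope="session")
def ladder():
    """Single-PC subthreshold and suprathreshold resonance ladder."""
    return single_cell_ladder(grid=tuple(range(1, 11)), seeds=(1, 2, 3),
                              supra_strengths=(300.0,))
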