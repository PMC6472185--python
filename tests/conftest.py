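import pytest

from nctools.normalize import normalize_cartridge
from nctools.simulate import SimulationSpec, simulate_cartridge


@pytest.fixture(scope="session")
def small_spec():
    """A 6-lane, 48-gene cartridge: fast but structurally complete."""
    return SimulationSpec(
        n_lanes=6, n_endogenous=40, n_housekeeping=8, seed=11, cartridge_id="SMALL"
    )


@pytest.fixture(scope="session")
def small_cartridge(small_spec):
    cartridge, truth = simulate_cartridge(small_spec)
    return cartridge, truth


@pytest.fixture(scope="session")
def default_cartridge():
    """The full default: 12 lanes, 770 gene probes."""
    cartridge, truth = simulate_cartridge(SimulationSpec(seed=1))
    return cartridge, truth


@pytest.fixture(scope="session")
def normalized_small(small_cartridge):
    cartridge, _ = small_cartridge
    return normalize_cartridge(cartridge)


@pytest.fixture(scope="session")
def normalized_default(default_cartridge):
    cartridge, _ = default_cartridge
    return normalize_cartridge(cartridge)
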