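import numpy as np
import pytest

from eetml.hamiltonian import (BathParameters, FrenkelHamiltonian,
                               SinkParameters, load_hamiltonian)


@pytest.fixture(scope="session")
def paper_bath():
    """Drude-Lorentz bath at lambda=35 cm^-1, nu^-1=50 fs, T=300 K."""
    return BathParameters.from_correlation_time(35.0, 50.0, 300.0)


@pytest.fixture(scope="session")
def zero_bath(paper_bath):
    """lambda -> 0 limit with the same cutoff and temperature."""
    return BathParameters(0.0, paper_bath.nu, paper_bath.temperature)


@pytest.fixture
def default_sink():
    """Donor site 1, acceptor site 3, 1/1 ps trapping, 1/0.25 ns loss."""
    return SinkParameters(donor_index=0, acceptor_index=2)


@pytest.fixture
def dimer_sink():
    return SinkParameters(donor_index=0, acceptor_index=1)


def make_dimer(gap=100.0, coupling=50.0, base=12000.0):
    return FrenkelHamiltonian(
        energies=np.array([base + gap, base]),
        couplings=np.array([[0.0, coupling], [coupling, 0.0]]))


@pytest.fixture
def detuned_dimer():
    return make_dimer(gap=100.0, coupling=50.0)


@pytest.fixture(scope="session")
def fmo_biological():
    """Bundled literature 8-site FMO Hamiltonian (donor pigment 8)."""
    from importlib.resources import files
    return load_hamiltonian(files("eetml") / "data" / "fmo_8site.txt")
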