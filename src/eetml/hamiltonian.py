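"""Frenkel exciton Hamiltonians: containers, sampling, permutation, I/O.

A single-excitation Frenkel exciton Hamiltonian collects pigment excitation
energies ``eps_m`` (cm^-1) on the diagonal and electronic couplings ``V_mn``
(cm^-1) off the diagonal.  Random Hamiltonians are drawn uniformly within
per-dataset ranges around four pigment-protein complexes (FMO, the
photosystem-II reaction-center core, and the RC extended by CP43 or CP47).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .units import CM1_TO_ANGFS, FS_PER_PS

__all__ = [
    "FrenkelHamiltonian",
    "SinkParameters",
    "BathParameters",
    "SamplingRanges",
    "DATASET_RANGES",
    "sample_hamiltonian",
    "flatten",
    "unflatten",
    "permute_sites",
    "load_hamiltonian",
    "save_hamiltonian",
]


@dataclass
class FrenkelHamiltonian:
    """Site-basis exciton Hamiltonian (energies and couplings in cm^-1).

    Parameters
    ----------
    energies : (n,) array
        Site excitation energies ``eps_m``.
    couplings : (n, n) array
        Symmetric inter-site couplings with a zero diagonal.
    label : str
        Free-text tag, e.g. the dataset name.
    """

    energies: np.ndarray
    couplings: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        n = self.energies.shape[0]
        if self.energies.ndim != 1 or n < 2:
            raise ValueError("need a 1-D energy vector with at least 2 sites")
        if self.couplings.shape != (n, n):
            raise ValueError("couplings must be an (n, n) matrix")
        if not np.allclose(self.couplings, self.couplings.T, atol=0.0):
            raise ValueError("couplings must be exactly symmetric")
        if np.any(np.diag(self.couplings) != 0.0):
            raise ValueError("couplings must have a zero diagonal")

    @property
    def n_sites(self) -> int:
        return self.energies.shape[0]

    def matrix(self) -> np.ndarray:
        """Full n x n Hamiltonian matrix in cm^-1."""
        return np.diag(self.energies) + self.couplings

    @classmethod
    def from_matrix(cls, matrix, label: str = "") -> "FrenkelHamiltonian":
        matrix = np.asarray(matrix, dtype=float)
        energies = np.diag(matrix).copy()
        couplings = matrix - np.diag(energies)
        couplings = 0.5 * (couplings + couplings.T)  # enforce exact symmetry
        np.fill_diagonal(couplings, 0.0)
        return cls(energies=energies, couplings=couplings, label=label)


@dataclass
class SinkParameters:
    """Irreversible trapping at the acceptor and uniform exciton loss.

    ``gamma_trap`` and ``gamma_loss`` are population decay rates in ps^-1:
    an isolated population subject to rate ``gamma`` decays as
    ``exp(-gamma * t)``.  Site indices are 0-based internally; file formats
    and logs use 1-based pigment numbers.
    """

    donor_index: int
    acceptor_index: int
    gamma_trap: float = 1.0      # ps^-1  (1/1 ps)
    gamma_loss: float = 0.004    # ps^-1  (1/0.25 ns)

    def __post_init__(self):
        if self.donor_index == self.acceptor_index:
            raise ValueError("donor and acceptor must be distinct sites")
        if self.gamma_trap <= 0.0:
            raise ValueError("gamma_trap must be positive")
        if self.gamma_loss < 0.0:
            raise ValueError("gamma_loss must be non-negative")

    @property
    def gamma_trap_fs(self) -> float:
        """Trapping rate in fs^-1."""
        return self.gamma_trap / FS_PER_PS

    @property
    def gamma_loss_fs(self) -> float:
        """Loss rate in fs^-1."""
        return self.gamma_loss / FS_PER_PS


@dataclass
class BathParameters:
    """Drude-Lorentz bath: reorganization energy, cutoff, temperature.

    ``nu`` is the Drude cutoff in cm^-1.  It is commonly quoted as a bath
    correlation time ``nu^-1`` in fs; use :meth:`from_correlation_time`
    for that convention.
    """

    lambda_reorg: float  # cm^-1
    nu: float            # cm^-1
    temperature: float   # K

    def __post_init__(self):
        if self.lambda_reorg < 0.0:
            raise ValueError("lambda_reorg must be non-negative")
        if self.nu <= 0.0:
            raise ValueError("nu must be positive")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_correlation_time(cls, lambda_reorg: float, nu_inv_fs: float,
                              temperature: float) -> "BathParameters":
        """Build from a correlation time ``nu^-1`` in fs (e.g. 50 fs)."""
        nu_cm1 = (1.0 / nu_inv_fs) / CM1_TO_ANGFS
        return cls(lambda_reorg=lambda_reorg, nu=nu_cm1, temperature=temperature)

    @property
    def correlation_time_fs(self) -> float:
        return 1.0 / (self.nu * CM1_TO_ANGFS)


@dataclass
class SamplingRanges:
    """Uniform sampling box for random Hamiltonians.

    Site energies are drawn from ``[eps_low, eps_high]`` and couplings from
    ``[-v_abs, +v_abs]`` (cm^-1), independently for every element.
    """

    n_sites: int
    eps_low: float
    eps_high: float
    v_abs: float
    label: str = ""

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if self.eps_low > self.eps_high:
            raise ValueError("eps_low must not exceed eps_high")
        if self.v_abs < 0.0:
            raise ValueError("v_abs must be non-negative")


#: Sampling boxes for the four datasets around biological complexes.
DATASET_RANGES = {
    "RC": SamplingRanges(8, 14800.0, 15000.0, 50.0, label="RC"),
    "FMO": SamplingRanges(8, 12000.0, 12800.0, 100.0, label="FMO"),
    "CP43": SamplingRanges(21, 14800.0, 15100.0, 60.0, label="CP43"),
    "CP47": SamplingRanges(24, 14500.0, 15300.0, 100.0, label="CP47"),
}


def sample_hamiltonian(ranges: SamplingRanges, seed) -> FrenkelHamiltonian:
    """Draw one Hamiltonian uniformly within ``ranges``.

    ``seed`` may be an integer or a ``numpy.random.Generator``; an integer
    fixes the stream so the draw is reproducible.
    """
    rng = np.random.default_rng(seed)
    n = ranges.n_sites
    energies = rng.uniform(ranges.eps_low, ranges.eps_high, size=n)
    v = rng.uniform(-ranges.v_abs, ranges.v_abs, size=(n, n))
    couplings = np.triu(v, k=1)
    couplings = couplings + couplings.T
    return FrenkelHamiltonian(energies=energies, couplings=couplings,
                              label=ranges.label)


def flatten(h: FrenkelHamiltonian) -> np.ndarray:
    """Row-major vectorization of the full matrix (length n^2)."""
    return h.matrix().reshape(-1).copy()


def unflatten(features: np.ndarray, label: str = "") -> FrenkelHamiltonian:
    """Inverse of :func:`flatten`."""
    features = np.asarray(features, dtype=float)
    n = int(round(np.sqrt(features.size)))
    if n * n != features.size:
        raise ValueError("feature length is not a perfect square")
    return FrenkelHamiltonian.from_matrix(features.reshape(n, n), label=label)


def permute_sites(h: FrenkelHamiltonian, perm) -> FrenkelHamiltonian:
    """Relabel pigments: ``H'[i, j] = H[perm[i], perm[j]]``.

    Eigenvalues are invariant; transfer statistics are invariant when the
    donor/acceptor indices are co-permuted.
    """
    perm = np.asarray(perm, dtype=int)
    n = h.n_sites
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("perm must be a bijection on {0..n-1}")
    m = h.matrix()[np.ix_(perm, perm)]
    return FrenkelHamiltonian.from_matrix(m, label=h.label)


def save_hamiltonian(h: FrenkelHamiltonian, path) -> None:
    """Write the JSON dialect {n_sites, energies_cm1, couplings_cm1, label}."""
    payload = {
        "n_sites": h.n_sites,
        "energies_cm1": h.energies.tolist(),
        "couplings_cm1": h.couplings.tolist(),
        "label": h.label,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_hamiltonian(path) -> FrenkelHamiltonian:
    """Read a Hamiltonian from JSON or a whitespace-delimited n x n matrix.

    The plain-text dialect stores the full matrix with site energies on the
    diagonal, the layout used by published FMO matrices.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        payload = json.loads(text)
        return FrenkelHamiltonian(
            energies=np.asarray(payload["energies_cm1"], dtype=float),
            couplings=np.asarray(payload["couplings_cm1"], dtype=float),
            label=payload.get("label", ""),
        )
    matrix = np.loadtxt(path, comments="#")
    return FrenkelHamiltonian.from_matrix(matrix, label=path.stem)
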