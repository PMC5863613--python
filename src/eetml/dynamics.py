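"""Shared open-system machinery: bath functions, sink Hamiltonian, observables.

The acceptor couples to an energy sink with trapping rate ``gamma_trap`` and
every pigment loses its excitation at ``gamma_loss``; both enter as
anti-Hermitian parts of the Hamiltonian.  Transfer efficiency and mean
transfer time are moments of the acceptor population:

    eta  = gamma_trap * int_0^inf rho_acc(t) dt
    tbar = (gamma_trap / eta) * int_0^inf t * rho_acc(t) dt

with the convention that an isolated population subject to rate ``gamma``
decays as ``exp(-gamma t)`` (so the printed trapping rate is the observable
population decay rate).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hamiltonian import BathParameters, FrenkelHamiltonian, SinkParameters
from .units import CM1_TO_ANGFS, FS_PER_PS, thermal_energy_cm1

__all__ = [
    "PopulationTrajectory",
    "TransferStatistics",
    "PropagationGrid",
    "NoTransferError",
    "PropagationError",
    "drude_lorentz",
    "bose_occupation",
    "effective_hamiltonian",
    "transfer_statistics",
    "unitary_sink_statistics",
    "propagate_unitary_sink",
]


class NoTransferError(RuntimeError):
    """Raised when essentially no population ever reaches the sink."""


class PropagationError(RuntimeError):
    """Raised when a fixed-step integration becomes unstable."""


@dataclass
class PropagationGrid:
    """Fixed-step integration control.

    Propagation runs to ``t_max_fs`` but stops early once the surviving
    excited-state population drops below ``stop_population`` (the remainder
    is handled by the exponential tail correction in
    :func:`transfer_statistics`).  Only every ``store_every``-th step is
    recorded.
    """

    dt_fs: float = 1.0
    t_max_fs: float = 200_000.0
    store_every: int = 10
    stop_population: float = 1e-4


@dataclass
class PopulationTrajectory:
    """Site populations of the reduced density matrix on a time grid."""

    times: np.ndarray            # fs, strictly increasing, t0 = 0
    site_populations: np.ndarray  # (n_times, n_sites)
    total_excited: np.ndarray     # trace of the excited-state density matrix

    def validate(self, tol: float = 1e-6) -> None:
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and increase strictly")
        if np.any(self.site_populations < -tol) or np.any(self.site_populations > 1 + tol):
            raise ValueError("site populations outside [0, 1]")
        if abs(self.total_excited[0] - 1.0) > tol:
            raise ValueError("initial excited population must be 1")
        if np.any(np.diff(self.total_excited) > 1e-8):
            raise ValueError("total excited population must be non-increasing")

    def to_csv(self, path) -> None:
        n = self.site_populations.shape[1]
        header = "time_fs," + ",".join(f"pop_site_{m + 1}" for m in range(n)) + ",total_excited"
        data = np.column_stack([self.times, self.site_populations, self.total_excited])
        np.savetxt(path, data, delimiter=",", header=header, comments="")


@dataclass
class TransferStatistics:
    """Efficiency eta, mean transfer time (ps) and unconverged tail."""

    efficiency: float
    transfer_time_ps: float
    tail_fraction: float
    converged: bool = True

    def to_json(self, path=None) -> str:
        payload = {
            "efficiency": self.efficiency,
            "transfer_time_ps": self.transfer_time_ps,
            "tail_fraction": self.tail_fraction,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def drude_lorentz(omega_cm1, bath: BathParameters):
    """Drude-Lorentz spectral density J(w) = 2 lambda nu w / (w^2 + nu^2).

    ``omega_cm1`` is the transition energy in cm^-1 (any sign); the result
    is in cm^-1 as well.  J is odd and peaks at J(nu) = lambda.
    """
    omega = np.asarray(omega_cm1, dtype=float)
    return 2.0 * bath.lambda_reorg * bath.nu * omega / (omega ** 2 + bath.nu ** 2)


def bose_occupation(omega_cm1, temperature):
    """Thermal occupation n(w) = 1 / (exp(hbar w / kT) - 1) for w != 0."""
    omega = np.asarray(omega_cm1, dtype=float)
    if np.any(omega == 0.0):
        raise ValueError("bose_occupation undefined at omega = 0; use the limit branch")
    return 1.0 / np.expm1(omega / thermal_energy_cm1(temperature))


def effective_hamiltonian(h: FrenkelHamiltonian, sink: SinkParameters) -> np.ndarray:
    """Complex site-basis Hamiltonian with trapping and loss (cm^-1).

    H_eff = H - i(G_trap/2)|acc><acc| - i(G_loss/2) sum_m |m><m|, with the
    rates expressed as imaginary energies so that populations decay at the
    stated rates.
    """
    n = h.n_sites
    if not (0 <= sink.acceptor_index < n and 0 <= sink.donor_index < n):
        raise ValueError("sink indices out of range")
    heff = h.matrix().astype(complex)
    trap_cm1 = sink.gamma_trap_fs / CM1_TO_ANGFS
    loss_cm1 = sink.gamma_loss_fs / CM1_TO_ANGFS
    heff[sink.acceptor_index, sink.acceptor_index] -= 0.5j * trap_cm1
    heff -= 0.5j * loss_cm1 * np.eye(n)
    return heff


def _exponential_tail(times, rho_acc, fit_fraction=0.2):
    """Fit A*exp(-k t) to the last stretch of the acceptor population.

    Returns (amplitude, rate_fs) or None when no decaying fit is possible.
    """
    n = len(times)
    i0 = max(int(n * (1.0 - fit_fraction)), 0)
    t = times[i0:]
    y = rho_acc[i0:]
    mask = y > 0
    if mask.sum() < 4:
        return None
    t, y = t[mask], y[mask]
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        return None
    return np.exp(intercept), -slope


def transfer_statistics(traj: PopulationTrajectory, sink: SinkParameters,
                        tail_tolerance: float = 1e-4) -> TransferStatistics:
    """Efficiency and mean transfer time from an acceptor-population trajectory.

    Moments are composite-trapezoid integrals on the stored grid plus an
    exponential tail correction fitted to the final stretch of the acceptor
    population (exact for a monoexponential tail).
    """
    times = np.asarray(traj.times, dtype=float)
    rho_acc = np.asarray(traj.site_populations[:, sink.acceptor_index], dtype=float)
    gamma = sink.gamma_trap_fs

    i0 = np.trapezoid(rho_acc, times)
    i1 = np.trapezoid(times * rho_acc, times)

    tail_fraction = float(traj.total_excited[-1])
    converged = True
    t_end = times[-1]
    if tail_fraction > 0.0:
        fit = _exponential_tail(times, rho_acc)
        if fit is not None:
            amp, k = fit
            decay = amp * np.exp(-k * t_end)
            i0 += decay / k
            i1 += decay * (t_end / k + 1.0 / k ** 2)
        elif tail_fraction > tail_tolerance:
            converged = False
            warnings.warn("tail fit failed with significant population remaining; "
                          "transfer statistics may be unconverged")

    eta = gamma * i0
    if eta < 1e-12:
        raise NoTransferError("no population reached the sink (eta < 1e-12)")
    tbar_fs = gamma * i1 / eta
    return TransferStatistics(efficiency=float(eta),
                              transfer_time_ps=float(tbar_fs / FS_PER_PS),
                              tail_fraction=tail_fraction,
                              converged=converged)


def unitary_sink_statistics(h: FrenkelHamiltonian, sink: SinkParameters,
                            initial_site: int | None = None) -> TransferStatistics:
    """Exact transfer statistics for the coherent (lambda -> 0) limit.

    The initial state is pure and stays pure under H_eff, so
    psi(t) = sum_k a_k exp(-i z_k t) v_k with the complex eigenvalues z_k of
    H_eff, and the acceptor-population moments reduce to closed-form sums
    over eigenvalue pairs.
    """
    start = sink.donor_index if initial_site is None else initial_site
    heff = effective_hamiltonian(h, sink) * CM1_TO_ANGFS
    vals, vecs = np.linalg.eig(heff)
    amps = np.linalg.solve(vecs, np.eye(h.n_sites)[:, start])
    c = vecs[sink.acceptor_index, :] * amps      # acceptor amplitude terms
    # rho_acc(t) = sum_{k,l} c_k conj(c_l) exp(z_kl t), z_kl = -i(z_k - conj(z_l))
    z = -1j * (vals[:, None] - np.conj(vals)[None, :])
    w = np.outer(c, np.conj(c))
    i0 = float(np.real(np.sum(-w / z)))
    i1 = float(np.real(np.sum(w / z ** 2)))
    gamma = sink.gamma_trap_fs
    eta = gamma * i0
    if eta < 1e-12:
        raise NoTransferError("no population reached the sink (eta < 1e-12)")
    return TransferStatistics(efficiency=eta,
                              transfer_time_ps=gamma * i1 / eta / FS_PER_PS,
                              tail_fraction=0.0)


def propagate_unitary_sink(h: FrenkelHamiltonian, sink: SinkParameters,
                           grid: PropagationGrid | None = None,
                           initial_site: int | None = None) -> PopulationTrajectory:
    """Coherent evolution under H_eff only (the lambda -> 0 reference).

    Integrates drho/dt = -i(H_eff rho - rho H_eff^dagger) with fixed-step
    RK4.  Serves as the zero-reorganization limit of both the Redfield and
    HEOM engines.
    """
    if grid is None:
        grid = PropagationGrid(dt_fs=1.0)
    n = h.n_sites
    start = sink.donor_index if initial_site is None else initial_site
    heff_cm1 = effective_hamiltonian(h, sink)
    # A constant diagonal shift cancels in the commutator; keep frequencies small.
    shift = np.mean(np.real(np.diag(heff_cm1)))
    heff = (heff_cm1 - shift * np.eye(n)) * CM1_TO_ANGFS
    heff_ct = heff.conj().T

    rho = np.zeros((n, n), dtype=complex)
    rho[start, start] = 1.0

    def rhs(r):
        return -1j * (heff @ r - r @ heff_ct)

    dt = grid.dt_fs
    n_steps = int(np.ceil(grid.t_max_fs / dt))
    times = [0.0]
    pops = [np.real(np.diag(rho)).copy()]
    for step in range(1, n_steps + 1):
        k1 = rhs(rho)
        k2 = rhs(rho + 0.5 * dt * k1)
        k3 = rhs(rho + 0.5 * dt * k2)
        k4 = rhs(rho + dt * k3)
        rho = rho + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        trace = float(np.real(np.trace(rho)))
        if trace > 1.0 + 1e-3:
            raise PropagationError(
                f"population overshoot at step {step}; reduce dt below {dt} fs")
        if step % grid.store_every == 0 or step == n_steps:
            times.append(step * dt)
            pops.append(np.real(np.diag(rho)).copy())
            if trace < grid.stop_population:
                break

    pops = np.asarray(pops)
    return PopulationTrajectory(times=np.asarray(times),
                                site_populations=pops,
                                total_excited=pops.sum(axis=1))
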