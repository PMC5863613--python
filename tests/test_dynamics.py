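import numpy as np
import pytest

from eetml.dynamics import (NoTransferError, PopulationTrajectory,
                            PropagationGrid, bose_occupation, drude_lorentz,
                            effective_hamiltonian, propagate_unitary_sink,
                            transfer_statistics, unitary_sink_statistics)
from eetml.hamiltonian import (BathParameters, FrenkelHamiltonian,
                               SinkParameters)
from eetml.units import CM1_TO_ANGFS, thermal_energy_cm1

from conftest import make_dimer


class TestBathFunctions:
    def test_drude_peak_value(self, paper_bath):
        assert drude_lorentz(paper_bath.nu, paper_bath) == pytest.approx(35.0)

    def test_drude_odd_and_zero(self, paper_bath):
        assert drude_lorentz(0.0, paper_bath) == 0.0
        w = np.linspace(10.0, 800.0, 15)
        np.testing.assert_allclose(drude_lorentz(-w, paper_bath),
                                   -drude_lorentz(w, paper_bath))

    def test_drude_at_twice_cutoff(self, paper_bath):
        assert drude_lorentz(2 * paper_bath.nu, paper_bath) == pytest.approx(28.0)

    def test_bose_identity_and_limits(self):
        w = np.array([5.0, 50.0, 500.0])
        n = bose_occupation(w, 300.0)
        n_neg = bose_occupation(-w, 300.0)
        np.testing.assert_allclose(n_neg + n, -1.0)
        assert bose_occupation(50 * thermal_energy_cm1(300.0), 300.0) < 1e-20

    def test_bose_at_thermal_energy(self):
        w = thermal_energy_cm1(300.0)
        assert bose_occupation(w, 300.0) == pytest.approx(0.581977, abs=1e-6)

    def test_bose_rejects_zero(self):
        with pytest.raises(ValueError):
            bose_occupation(0.0, 300.0)


class TestEffectiveHamiltonian:
    def test_zero_rates_recover_h(self):
        h = make_dimer()
        sink = SinkParameters(0, 1, gamma_trap=1e-300, gamma_loss=0.0)
        heff = effective_hamiltonian(h, sink)
        np.testing.assert_allclose(heff, h.matrix(), atol=1e-280)

    def test_anti_hermitian_part_negative_semidefinite(self, default_sink):
        h = FrenkelHamiltonian(energies=np.full(4, 12000.0),
                               couplings=np.zeros((4, 4)))
        heff = effective_hamiltonian(h, default_sink)
        anti = (heff - heff.conj().T) / 2j
        assert np.all(np.linalg.eigvalsh(anti) <= 1e-15)

    def test_decoupled_sites_decay_at_loss_rate(self):
        """V = 0, no trapping: every population decays as exp(-G_loss t)."""
        h = FrenkelHamiltonian(energies=[12000.0, 12500.0, 12100.0],
                               couplings=np.zeros((3, 3)))
        sink = SinkParameters(0, 2, gamma_trap=1e-12, gamma_loss=0.05)
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=5000.0, store_every=50,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, sink, grid)
        expected = np.exp(-0.05e-3 * traj.times)
        np.testing.assert_allclose(traj.site_populations[:, 0], expected,
                                   atol=1e-8)


class TestTransferStatistics:
    def make_traj(self, rho_acc, times, n_sites=2, acc=1):
        pops = np.zeros((len(times), n_sites))
        pops[:, acc] = rho_acc
        return PopulationTrajectory(times=times, site_populations=pops,
                                    total_excited=np.maximum(rho_acc, 1e-300))

    def test_monoexponential_closed_form(self):
        """rho_acc = exp(-t/tau) gives eta = G*tau and tbar = tau."""
        tau, gamma_ps = 500.0, 1.0
        times = np.linspace(0.0, 20 * tau, 4001)
        traj = self.make_traj(np.exp(-times / tau), times)
        sink = SinkParameters(0, 1, gamma_trap=gamma_ps)
        stats = transfer_statistics(traj, sink)
        assert stats.efficiency == pytest.approx(1e-3 * tau, rel=1e-5)
        assert stats.transfer_time_ps == pytest.approx(tau / 1000.0, rel=1e-5)

    def test_tail_correction_recovers_truncated_exponential(self):
        """Truncating at 3 tau is healed by the exponential tail fit."""
        tau = 800.0
        times = np.linspace(0.0, 3 * tau, 1201)
        traj = self.make_traj(np.exp(-times / tau), times)
        sink = SinkParameters(0, 1, gamma_trap=1.0)
        stats = transfer_statistics(traj, sink)
        assert stats.transfer_time_ps == pytest.approx(tau / 1000.0, rel=1e-4)

    def test_single_site_toy_efficiency(self):
        """G_trap^-1 = 1 ps, G_loss^-1 = 250 ps: eta = 250/251, tbar = eta ps."""
        gamma_t, gamma_l = 1.0e-3, 0.004e-3  # fs^-1
        rate = gamma_t + gamma_l
        times = np.linspace(0.0, 30.0 / rate, 8001)
        traj = self.make_traj(np.exp(-rate * times), times)
        sink = SinkParameters(0, 1, gamma_trap=1.0, gamma_loss=0.004)
        stats = transfer_statistics(traj, sink)
        assert stats.efficiency == pytest.approx(250.0 / 251.0, rel=1e-5)
        assert stats.transfer_time_ps == pytest.approx(1.0 / (1.0 + 0.004),
                                                       rel=1e-5)

    def test_no_transfer_raises(self):
        times = np.linspace(0.0, 100.0, 11)
        traj = self.make_traj(np.zeros(11), times)
        with pytest.raises(NoTransferError):
            transfer_statistics(traj, SinkParameters(0, 1))


class TestUnitaryPropagation:
    def test_diagonal_hamiltonian_static(self):
        h = FrenkelHamiltonian(energies=[12000.0, 12500.0],
                               couplings=np.zeros((2, 2)))
        sink = SinkParameters(0, 1, gamma_trap=1e-12, gamma_loss=0.0)
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=500.0, store_every=10,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, sink, grid)
        np.testing.assert_allclose(traj.site_populations[:, 0], 1.0, atol=1e-12)

    def test_symmetric_dimer_rabi_oscillation(self):
        v = 50.0
        h = make_dimer(gap=0.0, coupling=v)
        sink = SinkParameters(0, 1, gamma_trap=1e-12, gamma_loss=0.0)
        grid = PropagationGrid(dt_fs=0.5, t_max_fs=600.0, store_every=20,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, sink, grid)
        expected = np.cos(v * CM1_TO_ANGFS * traj.times) ** 2
        np.testing.assert_allclose(traj.site_populations[:, 0], expected,
                                   atol=1e-6)

    def test_three_site_chain_matches_expm_oracle(self):
        """RK4 trajectory equals the vectorized-Liouvillian matrix exponential."""
        from scipy.linalg import expm
        h = FrenkelHamiltonian(
            energies=[12100.0, 12000.0, 11900.0],
            couplings=[[0.0, 60.0, 0.0], [60.0, 0.0, 60.0], [0.0, 60.0, 0.0]])
        sink = SinkParameters(0, 2, gamma_trap=1.0, gamma_loss=0.004)
        grid = PropagationGrid(dt_fs=0.5, t_max_fs=2000.0, store_every=100,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, sink, grid)

        heff = effective_hamiltonian(h, sink) * CM1_TO_ANGFS
        heff -= np.mean(np.diag(heff)).real * np.eye(3)
        liou = -1j * (np.kron(heff, np.eye(3)) - np.kron(np.eye(3), heff.conj()))
        rho0 = np.zeros(9, dtype=complex)
        rho0[0] = 1.0
        for i, t in enumerate(traj.times):
            rho = (expm(liou * t) @ rho0).reshape(3, 3)
            np.testing.assert_allclose(traj.site_populations[i],
                                       np.real(np.diag(rho)), atol=1e-6)

    def test_exact_statistics_match_trajectory_route(self, dimer_sink):
        h = make_dimer(gap=50.0, coupling=40.0)
        exact = unitary_sink_statistics(h, dimer_sink)
        grid = PropagationGrid(dt_fs=0.5, t_max_fs=80_000.0, store_every=20,
                               stop_population=1e-6)
        traj = propagate_unitary_sink(h, dimer_sink, grid)
        stats = transfer_statistics(traj, dimer_sink)
        assert stats.transfer_time_ps == pytest.approx(exact.transfer_time_ps,
                                                       rel=2e-3)
        assert stats.efficiency == pytest.approx(exact.efficiency, rel=2e-3)

    def test_conservation_ledger(self, dimer_sink):
        """d/dt excited = -G_trap rho_acc - G_loss excited on the trajectory."""
        h = make_dimer(gap=100.0, coupling=50.0)
        grid = PropagationGrid(dt_fs=0.5, t_max_fs=20_000.0, store_every=1,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, dimer_sink, grid)
        trapped = np.concatenate([[0.0], np.cumsum(
            0.5 * (traj.site_populations[1:, 1] + traj.site_populations[:-1, 1])
            * np.diff(traj.times))]) * dimer_sink.gamma_trap_fs
        lost = np.concatenate([[0.0], np.cumsum(
            0.5 * (traj.total_excited[1:] + traj.total_excited[:-1])
            * np.diff(traj.times))]) * dimer_sink.gamma_loss_fs
        ledger = traj.total_excited + trapped + lost
        np.testing.assert_allclose(ledger, 1.0, atol=1e-6)

    def test_trajectory_csv_roundtrip(self, tmp_path, dimer_sink):
        h = make_dimer()
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=100.0, store_every=10,
                               stop_population=0.0)
        traj = propagate_unitary_sink(h, dimer_sink, grid)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 0], traj.times)
        np.testing.assert_allclose(data[:, 1:3], traj.site_populations)
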