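import math

import numpy as np
import pytest

from eetml.dynamics import (PropagationGrid, propagate_unitary_sink,
                            transfer_statistics, unitary_sink_statistics)
from eetml.hamiltonian import (BathParameters, DATASET_RANGES,
                               FrenkelHamiltonian, SinkParameters,
                               sample_hamiltonian)
from eetml.heom import (ConvergenceError, ResourceError, build_hierarchy,
                        converged_transfer_time, heom_transfer_statistics,
                        propagate_heom)
from eetml.redfield import redfield_transfer_statistics

from conftest import make_dimer
from _oracles import naive_heom_populations


class TestHierarchy:
    def test_depth_zero_single_ado(self):
        hier = build_hierarchy(8, 0)
        assert hier.n_ados == 1

    def test_binomial_count(self):
        hier = build_hierarchy(8, 4)
        assert hier.n_ados == math.comb(12, 4) == 495

    def test_raise_lower_involution(self):
        hier = build_hierarchy(3, 5)
        for m in range(3):
            for pos in range(hier.n_ados):
                up = hier.plus_idx[m, pos]
                if up >= 0:
                    assert hier.minus_idx[m, up] == pos

    def test_memory_cap(self):
        with pytest.raises(ResourceError):
            build_hierarchy(24, 10, max_ados=1000)


class TestLimits:
    def test_zero_bath_matches_unitary_trajectory(self, zero_bath, dimer_sink):
        h = make_dimer(gap=100.0, coupling=50.0)
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=2000.0, store_every=100,
                               stop_population=0.0)
        traj_h = propagate_heom(h, zero_bath, dimer_sink, depth=2, grid=grid)
        traj_u = propagate_unitary_sink(h, dimer_sink, grid)
        idx = np.searchsorted(traj_u.times, traj_h.times)
        np.testing.assert_allclose(traj_h.site_populations,
                                   traj_u.site_populations[idx], atol=1e-6)

    def test_zero_bath_three_way_transfer_time(self, zero_bath, default_sink):
        """Unitary-sink, Redfield and HEOM agree in tbar at lambda -> 0."""
        h = sample_hamiltonian(DATASET_RANGES["FMO"], seed=21)
        t_u = unitary_sink_statistics(h, default_sink).transfer_time_ps
        t_r = redfield_transfer_statistics(h, zero_bath,
                                           default_sink).transfer_time_ps
        t_h = heom_transfer_statistics(h, zero_bath, default_sink,
                                       depth=2).transfer_time_ps
        assert abs(t_r - t_u) / t_u < 1e-3
        assert abs(t_h - t_u) / t_u < 1e-3


class TestAgainstNaiveOracle:
    def test_dimer_matches_brute_force_hierarchy(self, paper_bath, dimer_sink):
        """Scaled, vectorized engine equals a naive dict-based integrator."""
        h = make_dimer(gap=100.0, coupling=50.0)
        depth, t_max, dt = 6, 1000.0, 0.5
        grid = PropagationGrid(dt_fs=dt, t_max_fs=t_max, store_every=1,
                               stop_population=0.0)
        traj = propagate_heom(h, paper_bath, dimer_sink, depth=depth, grid=grid)
        times, pops = naive_heom_populations(
            h.matrix(), paper_bath.lambda_reorg, paper_bath.nu,
            paper_bath.temperature, dimer_sink.gamma_trap_fs,
            dimer_sink.gamma_loss_fs, acceptor=1, donor=0, depth=depth,
            t_max_fs=t_max, dt_fs=dt)
        np.testing.assert_allclose(traj.times, times)
        np.testing.assert_allclose(traj.site_populations, pops, atol=1e-6)

    def test_lt_correction_off_also_matches(self, paper_bath, dimer_sink):
        h = make_dimer(gap=200.0, coupling=30.0)
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=500.0, store_every=1,
                               stop_population=0.0)
        traj = propagate_heom(h, paper_bath, dimer_sink, depth=4, grid=grid,
                              lt_correction=False)
        _, pops = naive_heom_populations(
            h.matrix(), paper_bath.lambda_reorg, paper_bath.nu,
            paper_bath.temperature, dimer_sink.gamma_trap_fs,
            dimer_sink.gamma_loss_fs, acceptor=1, donor=0, depth=4,
            t_max_fs=500.0, dt_fs=1.0, lt_correction=False)
        np.testing.assert_allclose(traj.site_populations, pops, atol=1e-6)


class TestBiologicalFMO:
    def test_redfield_to_heom_ratio(self, paper_bath, fmo_biological):
        """Cross-engine consistency on the eight-site FMO complex.

        The engine-to-engine ratio is insensitive to the exact literature
        matrix digits: secular Redfield comes out a few percent faster
        than the converged hierarchy, with both transfer times in the
        picosecond range expected for donor pigment 8.
        """
        sink = SinkParameters(donor_index=7, acceptor_index=2,
                              gamma_trap=1.0, gamma_loss=1.0 / 250.0)
        heom, _ = converged_transfer_time(fmo_biological, paper_bath, sink,
                                          tolerance=0.01)
        red = redfield_transfer_statistics(fmo_biological, paper_bath, sink)
        ratio = red.transfer_time_ps / heom.transfer_time_ps
        assert 0.90 < ratio < 0.99
        assert 2.0 < heom.transfer_time_ps < 12.0
        assert heom.efficiency > 0.95


class TestRoutesAndConvergence:
    def test_resolvent_matches_trajectory_statistics(self, paper_bath,
                                                     dimer_sink):
        h = make_dimer(gap=150.0, coupling=60.0)
        exact = heom_transfer_statistics(h, paper_bath, dimer_sink, depth=6,
                                         method="resolvent")
        traj_stats = heom_transfer_statistics(h, paper_bath, dimer_sink,
                                              depth=6, method="trajectory")
        assert traj_stats.transfer_time_ps == pytest.approx(
            exact.transfer_time_ps, rel=5e-3)
        assert traj_stats.efficiency == pytest.approx(exact.efficiency,
                                                      rel=5e-3)

    def test_zero_bath_converges_immediately(self, zero_bath, default_sink):
        h = sample_hamiltonian(DATASET_RANGES["FMO"], seed=30)
        stats, report = converged_transfer_time(h, zero_bath, default_sink)
        assert len(report) == 2  # first depth pair already agrees

    def test_dimer_depth_oversampling(self, paper_bath, dimer_sink):
        """The converged tbar stays within tolerance of a much deeper run."""
        for gap in (100.0, 500.0):
            h = make_dimer(gap=gap, coupling=50.0)
            stats, report = converged_transfer_time(h, paper_bath, dimer_sink,
                                                    tolerance=0.01)
            deep = heom_transfer_statistics(h, paper_bath, dimer_sink,
                                            depth=report[-1]["depth"] + 4)
            assert abs(stats.transfer_time_ps - deep.transfer_time_ps) \
                / deep.transfer_time_ps < 0.01

    def test_convergence_error_reports_partial(self, paper_bath, dimer_sink):
        h = make_dimer(gap=100.0, coupling=50.0)
        with pytest.raises(ConvergenceError) as err:
            converged_transfer_time(h, paper_bath, dimer_sink,
                                    tolerance=1e-12, max_depth=4)
        assert len(err.value.partial) >= 2

    def test_trace_ledger(self, paper_bath, dimer_sink):
        """Excited + trapped + lost stays 1 along the HEOM trajectory."""
        h = make_dimer(gap=100.0, coupling=50.0)
        grid = PropagationGrid(dt_fs=1.0, t_max_fs=10_000.0, store_every=1,
                               stop_population=0.0)
        traj = propagate_heom(h, paper_bath, dimer_sink, depth=4, grid=grid)
        dt = np.diff(traj.times)
        acc = traj.site_populations[:, 1]
        trapped = np.concatenate([[0.0], np.cumsum(
            0.5 * (acc[1:] + acc[:-1]) * dt)]) * dimer_sink.gamma_trap_fs
        lost = np.concatenate([[0.0], np.cumsum(
            0.5 * (traj.total_excited[1:] + traj.total_excited[:-1]) * dt)]) \
            * dimer_sink.gamma_loss_fs
        np.testing.assert_allclose(traj.total_excited + trapped + lost, 1.0,
                                   atol=1e-5)

    def test_physical_ado_hermitian_populations_bounded(self, paper_bath,
                                                        default_sink):
        h = sample_hamiltonian(DATASET_RANGES["RC"], seed=5)
        grid = PropagationGrid(dt_fs=2.0, t_max_fs=5000.0, store_every=50,
                               stop_population=0.0)
        traj = propagate_heom(h, paper_bath, default_sink, depth=2, grid=grid)
        assert np.all(traj.site_populations > -1e-6)
        assert np.all(traj.site_populations < 1.0 + 1e-6)
        assert np.all(np.diff(traj.total_excited) <= 1e-8)
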