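"""Independent brute-force oracles used by the test suite only."""

import itertools
import math

import numpy as np

TWO_PI_C = 2.0 * math.pi * 2.99792458e-5  # rad/fs per cm^-1
KB = 0.695034800                          # cm^-1 / K


def naive_heom_populations(h_matrix_cm1, lambda_cm1, nu_cm1, temperature_k,
                           gamma_trap_fs, gamma_loss_fs, acceptor, donor,
                           depth, t_max_fs, dt_fs, lt_correction=True):
    """Straightforward unscaled HEOM integrator for tiny systems.

    Dictionary-of-ADOs bookkeeping, unscaled auxiliaries, plain RK4 — no
    vectorization or scaling tricks.  Returns (times, site_populations).
    """
    n = h_matrix_cm1.shape[0]
    lam = lambda_cm1 * TWO_PI_C
    nu = nu_cm1 * TWO_PI_C
    kbt = KB * temperature_k * TWO_PI_C
    cot = 1.0 / math.tan(nu / (2.0 * kbt))
    c = lam * nu * (cot - 1j)
    delta = (2.0 * lam * kbt / nu - lam * cot) if lt_correction else 0.0

    heff = h_matrix_cm1.astype(complex) * TWO_PI_C
    heff -= np.mean(np.diag(heff)).real * np.eye(n)
    heff[acceptor, acceptor] -= 0.5j * gamma_trap_fs
    heff -= 0.5j * gamma_loss_fs * np.eye(n)
    heff_ct = heff.conj().T

    projectors = [np.zeros((n, n)) for _ in range(n)]
    for m in range(n):
        projectors[m][m, m] = 1.0

    indices = [idx for idx in itertools.product(range(depth + 1), repeat=n)
               if sum(idx) <= depth]
    state = {idx: np.zeros((n, n), dtype=complex) for idx in indices}
    top = (0,) * n
    state[top][donor, donor] = 1.0

    def rhs(s):
        out = {}
        for idx, rho in s.items():
            d = -1j * (heff @ rho - rho @ heff_ct) - sum(idx) * nu * rho
            for m in range(n):
                v = projectors[m]
                if delta:
                    d -= delta * (v @ (v @ rho - rho @ v) - (v @ rho - rho @ v) @ v)
                up = idx[:m] + (idx[m] + 1,) + idx[m + 1:]
                if up in s:
                    d -= 1j * (v @ s[up] - s[up] @ v)
                if idx[m] > 0:
                    dn = idx[:m] + (idx[m] - 1,) + idx[m + 1:]
                    d -= 1j * idx[m] * (c * v @ s[dn] - np.conj(c) * s[dn] @ v)
            out[idx] = d
        return out

    def axpy(s, ks, a):
        return {idx: s[idx] + a * ks[idx] for idx in s}

    steps = int(round(t_max_fs / dt_fs))
    times = [0.0]
    pops = [np.real(np.diag(state[top])).copy()]
    for step in range(1, steps + 1):
        k1 = rhs(state)
        k2 = rhs(axpy(state, k1, dt_fs / 2))
        k3 = rhs(axpy(state, k2, dt_fs / 2))
        k4 = rhs(axpy(state, k3, dt_fs))
        for idx in state:
            state[idx] = state[idx] + (dt_fs / 6.0) * (
                k1[idx] + 2 * k2[idx] + 2 * k3[idx] + k4[idx])
        times.append(step * dt_fs)
        pops.append(np.real(np.diag(state[top])).copy())
    return np.asarray(times), np.asarray(pops)


def brute_force_dispersion(points, k):
    """Exhaustive max-min-distance subset of size k (tiny instances only)."""
    points = np.asarray(points, dtype=float)
    best_val, best_subset = -1.0, None
    for subset in itertools.combinations(range(len(points)), k):
        sub = points[list(subset)]
        dists = [np.linalg.norm(sub[i] - sub[j])
                 for i in range(k) for j in range(i + 1, k)]
        val = min(dists)
        if val > best_val:
            best_val, best_subset = val, subset
    return best_val, best_subset


def min_pairwise_distance(points, subset):
    points = np.asarray(points, dtype=float)
    sub = points[list(subset)]
    k = len(sub)
    return min(np.linalg.norm(sub[i] - sub[j])
               for i in range(k) for j in range(i + 1, k))


def sympy_dimer_redfield_rates(gap_cm1, coupling_cm1, lambda_cm1, nu_cm1,
                               temperature_k):
    """Symbolic evaluation of the secular dimer rates (downhill, uphill).

    Diagonalizes the 2x2 Hamiltonian in closed form and evaluates
    k = 2 J(w) (n(w)+1) * sum_m c_m_a^2 c_m_b^2 with exact arithmetic,
    returning floats in fs^-1.
    """
    import sympy as sp

    d, v = sp.Rational(str(gap_cm1)), sp.Rational(str(coupling_cm1))
    lam, nu = sp.Rational(str(lambda_cm1)), sp.nsimplify(nu_cm1)
    kbt = sp.Rational("0.695034800") * sp.Rational(str(temperature_k))
    # closed-form eigenvectors of [[d, v], [v, 0]]
    omega = sp.sqrt(d ** 2 + 4 * v ** 2)          # exciton splitting
    theta = sp.atan2(2 * v, d) / 2                # mixing angle
    c_up = sp.Matrix([sp.cos(theta), sp.sin(theta)])
    c_dn = sp.Matrix([-sp.sin(theta), sp.cos(theta)])
    overlap = sum((c_up[m] * c_dn[m]) ** 2 for m in range(2))
    j = 2 * lam * nu * omega / (omega ** 2 + nu ** 2)
    n_occ = 1 / (sp.exp(omega / kbt) - 1)
    conv = 2 * sp.pi * sp.Rational("2.99792458e-5")
    k_down = 2 * j * (n_occ + 1) * overlap * conv
    k_up = 2 * j * n_occ * overlap * conv
    return float(k_down), float(k_up)
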