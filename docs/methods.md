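# Methods

## The model

Excitation energy transfer (EET) in a pigment–protein complex is described
by a single-excitation Frenkel exciton Hamiltonian

    H = sum_m eps_m |m><m| + sum_{m != n} V_mn |m><n|,

with site excitation energies `eps_m` and electronic couplings `V_mn` in
cm⁻¹.  Each pigment couples linearly to its own harmonic bath with an
overdamped Drude–Lorentz spectral density

    J(w) = 2 lambda nu w / (w² + nu²),

parameterized by the reorganization energy `lambda` (default 35 cm⁻¹) and
the inverse bath correlation time `nu` (default `nu⁻¹` = 50 fs, i.e.
`nu` ≈ 106.2 cm⁻¹) at temperature `T` = 300 K.  Irreversible capture at the
acceptor pigment and radiative/non-radiative loss are modelled by
anti-Hermitian terms

    H_eff = H − i(Γ_trap/2)|acc><acc| − i(Γ_loss/2) Σ_m |m><m|,

with the convention that an isolated population subject to rate Γ decays as
`exp(−Γ t)`: the printed trapping rate (default Γ_trap⁻¹ = 1 ps) is the
observable population decay rate, and Γ_loss⁻¹ = 0.25 ns.

The observables are moments of the acceptor-site population ρ_acc(t) from a
fully populated donor site:

    eta  = Γ_trap ∫₀^∞ ρ_acc(t) dt            (transfer efficiency)
    t̄    = (Γ_trap/eta) ∫₀^∞ t ρ_acc(t) dt    (mean transfer time, ps)

## Engines

**Unitary + sink** (`propagate_unitary_sink`, `unitary_sink_statistics`):
pure coherent evolution under `H_eff`, the λ → 0 reference for both open
engines.  Statistics are available exactly from the eigendecomposition of
`H_eff`.

**Secular Redfield** (`redfield.py`): second-order, Markovian rates in the
exciton eigenbasis.  The downhill population rate between excitons a and b
(gap ω_ab > 0) is

    k_{a→b} = 2 J(ω_ab) (n(ω_ab) + 1) Σ_m (c_m^a)² (c_m^b)²

in angular-frequency units; uphill rates follow by detailed balance via the
Bose factor n(ω), and gaps below 10⁻⁶ cm⁻¹ take the analytic ω → 0 limit
4λk_BT/ν of the spectrum (which also supplies the pure-dephasing rate).
Trapping enters as per-exciton rates Γ_trap (c_acc^a)².  Populations follow
a Pauli master equation; coherences decay independently and are retained in
the site-basis readout because the initial state is site-local.  Both a
trajectory route and closed-form resolvent moments (∫p dt = −M⁻¹p₀,
∫t p dt = M⁻²p₀; each coherence integrates to −ρ_ab(0)/z_ab) are provided;
they agree to better than 0.5% and the moments route is exact and fast
(milliseconds per Hamiltonian).

A known artifact of the secular trap treatment: the trapped flux within the
model is Σ_a Γ_a p_a, which equals Γ_trap times the *population part* of
ρ_acc.  The transient site-coherence contribution to ρ_acc (retained in the
reported efficiency for consistency with the trajectory definition) is
therefore not part of the conservation ledger; its integrated size is below
0.5% at the default trapping rate, and `redfield_moments` exposes the
decomposition.  Likewise, the λ → 0 limit reproduces the exact coherent
site populations only up to first order in Γ_trap divided by the exciton
splitting (≈1% at Γ_trap⁻¹ = 1 ps for a 100 cm⁻¹ dimer, tightening
linearly as the trap weakens); transfer-time moments agree to 0.1%.

**HEOM** (`heom.py`): the numerically exact reference.  At 300 K with
ν⁻¹ = 50 fs (βħν/2 ≈ 0.25) a single exponential bath mode per site
suffices,

    C_m(t) = λν (cot(βħν/2) − i) e^{−νt},

and the truncated Matsubara tail is folded into the time-local
(Ishizaki–Tanimura) correction −Δ[V_m,[V_m,·]] with
Δ = 2λk_BT/ν − λcot(βħν/2); the correction is on by default and changes
8-site transfer times by ≲1%.  Auxiliary density operators are indexed by
per-site excitation numbers with triangular truncation Σn_m ≤ D and scaled
for stability; trapping and loss act on every ADO through `H_eff`.

Two routes compute the observables:

- *Trajectory*: fixed-step RK4 (default dt = 2 fs) of the full hierarchy
  with a numba-compiled kernel; site energies are shifted by their mean
  (exactly population-preserving) to keep phase frequencies small.
  Propagation stops once the surviving excited population falls below a
  threshold and the remainder is handled by an exponential tail fit over
  the final 20% of the grid (exact for a monoexponential tail).
- *Resolvent*: the hierarchy is one sparse linear generator A, so
  ∫σ dt = −A⁻¹σ₀ and ∫t σ dt = A⁻²σ₀ follow from two solves with one
  sparse LU — no time grid, horizon or tail error.  The two routes agree
  to 0.05% on 8-site problems.

LU fill-in grows steeply with hierarchy depth, so the resolvent is used
automatically up to generator dimension 16 000 (depth 3 for 8 sites) and
the trajectory beyond.  `converged_transfer_time` sweeps consecutive depths
(2, 3, 4, …) until t̄ changes by less than 1%; the single-exponential Drude
hierarchy has no odd/even parity structure that would require steps of two.
At λ = 35 cm⁻¹ the sweep terminates at depth 3 for 8-site systems; spot
checks against depth-6 trajectories and a depth-14 dimer sweep agree to
0.1%.  Sweep refinements that fall on the trajectory route use a slightly
coarser grid (dt = 3 fs, 90 ps horizon, 0.2% stop threshold); the
resulting route-plus-step bias is below 0.3%, well inside the 1%
convergence tolerance.

## Validation strategy

- The HEOM kernel is checked element-wise (1e-6) against an independent,
  deliberately naive dictionary-based hierarchy integrator on dimers, with
  and without the low-temperature correction.
- Redfield rates are checked against a closed-form symbolic (sympy)
  evaluation for a detuned dimer; detailed balance, the generator property
  and Boltzmann stationarity are asserted numerically.
- All three engines are required to agree in t̄ to 0.1% in the λ → 0 limit.
- The RK4 unitary propagator is checked against a matrix-exponential
  oracle on a 3-site chain.

## Random Hamiltonian datasets

Four sampling boxes around natural complexes (energies / couplings in
cm⁻¹, drawn uniformly and independently per element):

| label | sites | eps range        | |V| ≤ |
|-------|------:|------------------|------:|
| RC    | 8     | 14800 – 15000    | 50    |
| FMO   | 8     | 12000 – 12800    | 100   |
| CP43  | 21    | 14800 – 15100    | 60    |
| CP47  | 24    | 14500 – 15300    | 100   |

Database generation labels each sampled Hamiltonian (record seed =
base seed + index) with one engine; desk-scale runs default to Redfield
labels, ground-truth runs to depth-converged HEOM.  The synthetic sampler
reproduces the *ranges* of the study; it does not model correlations
between site energies and couplings that real pigment geometries induce,
so tests passing on sampled data say nothing about the accuracy of any
particular structural model.

Published-scale databases hold 12 000 records per dataset with 2000-record
validation and test splits; desk-scale reproductions in the test suite use
3000 records (500/500 splits), which the methods below treat as the study
conditions for runtime reasons of scale, with sizes always stated
explicitly in the tests.

## Training-set selection, scaling, surrogate

Training Hamiltonians are either drawn at random from the pool or chosen by
greedy farthest-point (max–min Euclidean) selection in a PCA space of the
standardized flattened Hamiltonians, keeping the smallest number of
components explaining ≥95% variance (configurable).  The greedy rule starts
from the point farthest from the pool centroid and is the classic factor-2
dispersion heuristic, checked against brute force on small instances.

Features are standardized per dimension on the training split; targets
(t̄ in ps, eta) are divided by their training means, preserving positivity.

The surrogate is a fully connected MLP mapping the flattened n² Hamiltonian
to (t̄, eta).  Hidden layers choose from {rectifier, tanh, logistic,
softsign, softplus}; the output layer is always softplus so predictions are
strictly positive.  Training uses ADAM with mini-batches of 200 and stops
once the validation relative error has increased over three full
consecutive epochs, restoring the best-validation weights.  L2
regularization acts on all hidden-layer weights but not the output layer.

The training loss is, by default, the mean squared *relative* residual on
the scaled targets rather than the plain MSE.  The transfer-time
distribution of sampled datasets is strongly right-skewed (roughly 3–70 ps
for FMO ranges), so an absolute-scale loss is dominated by the slow tail
while the evaluation metric is relative; on the desk-scale FMO pipeline the
relative loss lowers the held-out transfer-time error from 15–22% (seed
dependent) to a stable 13–14%.  Plain MSE remains available
(`loss="mse"`).  The default architecture — one hidden layer of 512
rectifier units, learning rate 3e-4, L2 1e-4 — was chosen with the
package's own hyperparameter search plus a seed-robustness sweep on that
same pipeline.

Hyperparameter optimization models the validation relative error with a
Gaussian process (Matern 5/2) over the encoded space (log-scale learning
rate and L2, integer layers/width/training-set size, one categorical
activation slot per potential layer) and picks candidates by expected
improvement over 512 random proposals per iteration, after a seeded Sobol
initial design of 5 points; a pure random-search fallback exists for quick
runs.  Objective failures are penalized with a large finite value.

## Evaluation

The headline metric is Δτ = 100·mean(|t_pred − t_ref| / t_ref) per split;
signed deviations (t_ref − t_approx)/t_ref are positive when the
approximation is too fast, and the quadrant fraction counts records where
the network's |deviation| is strictly smaller than Redfield's (ties are not
wins).

## Engine disagreement by regime (an observed property, not an assertion)

Comparing the two open-system engines over FMO-range samples, secular
Redfield is *faster* than HEOM (positive signed deviation) for
typical small-gap Hamiltonians, but *slower* for slowly transferring
Hamiltonians whose donor is separated by gaps well above the bath cutoff —
dimer scans make this explicit (at a 400–800 cm⁻¹ gap the high-temperature
Drude hierarchy transfers up to 40% faster than Bose-factor Redfield
rates).  Over 100 sampled FMO-range Hamiltonians the mean
|Redfield−HEOM|/HEOM transfer-time error is ≈4–6% with ≈2/3 of deviations
positive; over RC-range samples (small gaps) deviations are positive for
essentially every sample.  The acceptance checks report exactly what these
engines produce.

## Numerical choices and degenerate inputs

- Units: cm⁻¹ for energies, fs for propagation, ps for reported times;
  ω[fs⁻¹] = 2πc·Ẽ[cm⁻¹], k_B = 0.6950348 cm⁻¹/K.
- Exciton-basis sign convention: the largest-magnitude eigenvector
  component is made positive, so repeated diagonalizations are bit-stable.
- Exact energy degeneracies (gap < 1e-6 cm⁻¹) take the ω → 0 rate branch.
- Zero-variance feature dimensions pass through scaling unchanged; a
  zero-coupling Hamiltonian yields a no-transfer error rather than a
  spurious record, and such records are excluded (logged with their seeds)
  from generated databases.
- HEOM divergence (any ADO norm above 1e3) halves the step once, then
  raises; hierarchy sizes are capped (default 200 000 ADOs) before
  allocation.
- Farthest-point ties break toward the lowest index, making selection
  deterministic and permutation-equivariant.

## Known limitations

- Single Drude–Lorentz bath shared by all sites; no structured spectral
  densities, polaron or variational treatments.  Predictions across
  varying bath parameters are out of scope.
- The high-temperature single-mode hierarchy (with time-local correction)
  is the ground-truth *model*; at energy gaps much larger than k_BT its
  one-sided spectrum deviates from the true quantum Drude bath, which is
  visible in the Redfield comparison above.
- The bundled 8-site FMO matrix is a literature reconstruction (Schmidt am
  Busch et al. 2011 parameter set); transfer times for the biological
  complex depend on the exact published matrix and trapping conventions,
  and the package's values for it (depth-converged HEOM ≈ 4.65 ps,
  Redfield ≈ 4.33 ps, ratio ≈ 0.93) should be compared with published
  values primarily through the engine-to-engine ratio.
- The surrogate does not transfer across system sizes; one model per
  dataset dimensionality.
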