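# Methods

## Model and assumptions

`synbal` operates on continuous-time rate networks
tau dx/dt = -x + J phi(x) + W_in u, y = W_out x, with activity initialized
at the origin and a *homogeneous* scalar activation (linear or ReLU).
Homogeneity — phi(a x) = a phi(x) for a > 0 — is the structural assumption
behind everything in the package: it makes the per-neuron rescaling
pi_h(W) = (e^-H W_in, e^-H J e^H, W_out e^H) an exact symmetry of the
input-output map, and it makes the neuronal gains phi'(x) scale invariant,
so the gain moments (mu, sigma^2) that weight the synaptic costs are
constant along the symmetry orbit.  Non-homogeneous activations (tanh,
sigmoid), spiking models, delays, and non-diagonal similarity
transformations for linear networks are out of scope; the last of these is
a real generalization for purely linear dynamics but does not yield a local
rule, and is deliberately not implemented.

Simulation uses explicit forward Euler on a uniform grid.  This is a
deliberate choice rather than a limitation: under a shared Euler grid the
rescaling symmetry holds exactly *per step* (each update is a homogeneous
function of the state), so task-preservation checks are exact to rounding
instead of being limited by solver error.  The grid spacing of the input
trajectory must be an integer multiple of the Euler step; inputs are held
constant between grid points.

Hidden-state noise is additive i.i.d. N(0, eps^2) applied to every neuron
after each Euler step.  The stochastic discretization is a convention, not
a derivation: a diffusion-style sqrt(dt) scaling would simply relabel the
eps axis of any robustness curve.  Users comparing noise levels across
different dt should keep this in mind.

## Costs, the flow, and its invariants

Synaptic costs are power-law: c_ij = alpha_ij |J_ij|^p with p > 0.  Two
modes are built in: *robustness* (alpha_ij = sigma2_j, the presynaptic
second gain moment, p = 2), whose total is the noise sensitivity S up to
the additive constant -2 sum_i mu_i J_ii + N, and *l2* (alpha = 1, p = 2),
the regularizer convention used in the training experiment.  The index
convention is presynaptic: the coefficient on synapse j -> i is sigma2 of
the *source* neuron j, which is both the algebraically consistent reading
of the sensitivity identity and the locally computable one (a synapse can
estimate its own presynaptic gain statistics).

The balancing flow integrates dh/dt = g(h) in manifold coordinates with
h(0) = 0, and realizes weights by applying pi_h — never by integrating
dJ/dt directly.  This guarantees the trajectory stays exactly on the
task-preserving manifold regardless of solver error; the Lax form
dJ/dt = [J, diag g] then holds by construction and is only *checked*
(via `lax_residual`) rather than trusted.  Gradients satisfy
sum_k g_k = 0 identically (every cost appears once with each sign), so
sum_i h_i = 0 is conserved to rounding by any linear integrator.

Gain moments are estimated once, on noiseless simulations of held-out task
inputs, and frozen during balancing.  Freezing is exact, not an
approximation, because the moments are invariant on the manifold for
homogeneous activations.  The t = 0 sample is excluded from the estimate
(x(0) = 0 is the imposed initial condition; with the phi'(0) := 0 ReLU
convention it would bias mu downward by a 1/L term).  Noisy estimation is
possible by passing a noisy `SimSettings` but is not the default protocol.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| tau | 1 (time units) | neural time constant; all flow times are in units where gamma p = 1 |
| dt | 0.1 tau | Euler step; first-order convergence, halving dt halves the error |
| p | 2 | cost exponent; robustness mode requires p = 2 |
| gamma | 1/p | descent rate, fixed by the gamma p = 1 convention |
| rtol / atol | 1e-8 / 1e-10 | LSODA tolerances for the flow |
| g_tol | 1e-10 C0 / N | termination on \|\|g\|\|_inf; scales with cost per neuron |
| t_max | 1e5 | horizon for non-convergent (not strongly connected) flows |

A note on rate conventions: with gamma p = 1 the two-neuron relaxation rate
is 2 p c^ (c^ the geometric-mean equilibrium cost) and the single-synapse
feedforward cost decays as c(t) = c0 / (2 p c0 t + 1).  Both constants were
fixed by validating the closed forms against direct numerical integration
of the cost ODE; `two_neuron_solution` re-runs that validation at call time
by default.  When the initial cost ratio q(0) = sqrt(c12/c21) exceeds 1 the
relaxation follows the hyperbolic-cotangent branch (same Riccati equation,
range q > 1); the tanh expression alone cannot represent that half of the
initial-condition space.

## Synthetic data

Two generators define the study conditions.

**Random networks** (`random_fixture`): sparse Gaussian J with
J_ij ~ N(0, 1/N) on present synapses (the standard random-network scaling
that keeps the spectral radius near 1), optional random Hamiltonian-cycle
backbone guaranteeing a strongly connected cost graph.  These emulate the
generic, unstructured recurrent connectivity on which the flow theory is
exercised; they do not emulate Dale's law, sparse excitatory/inhibitory
structure, or any trained functional organization.

**Context-dependent integration task** (`generate_cdi_trials`): three
Boolean variables (context a, signals s1, s2), each encoded as an
indicator pair, held fixed over T = 50 unit time steps with additive
Gaussian input noise; the 2-D target is the unit-step running integral of
the noisy signal selected by the context (left Riemann sum, so z(0) = 0
matches x(0) = 0; with zero input noise this is exactly the cumulative sum
of the selected clean pair).  Trial counts, the train/held-out split
(256 / 64 trials) and the input noise level (std 0.1) are package choices —
values a practitioner would call routine for a desk-scale integration
task — made once and surfaced as arguments.

Training is full-batch gradient descent with gradients from a hand-written
backprop through the unrolled Euler dynamics (dt = tau = 1, so one step per
task time step), verified against central finite differences in the test
suite.  Because the task drives J toward the edge of stability (an
integrator mode), unrolled task gradients can spike by many orders of
magnitude; the trainer clips the global norm of the *task* gradient (default
10) while applying the well-scaled l2 penalty gradient 2 lambda J in full.
Clipping rescales the task gradient without changing its direction, so the
conservation of per-neuron imbalance under unregularized descent — the
lambda = 0 diagnostic — is unaffected.  Reference scale is N = 256 with
lr = 0.003 and 1600 iterations; the desk-scale default is N = 64, 300
iterations, lr = 0.01, the learning rate chosen so that regularized runs
approach a regularized minimum within the shorter budget.

What passing the desk-scale training tests does and does not show: the
trends (conserved imbalance without regularization; significant balance
under the permutation null with it; noise-robustness ratios that do not
increase with noise) are qualitative properties expected at any scale, but
trained desk-scale ReLU networks have a handful of permanently inactive
units (sigma^2 = 0), so their robustness-cost graphs are *not* strongly
connected: the flow then has no finite equilibrium, the incoming costs of
dead units decay algebraically, and those units' outgoing weights grow
without bound.  The experiment therefore balances over a finite horizon
(t = 1e3), mirroring the fact that any numerical treatment of this regime
stops at a finite time, and the package warns rather than fails on
non-strongly-connected inputs.  The sensitivity S is also a first-order
proxy measured on noiseless activity; on individual desk-scale networks the
realized noisy-loss improvement can be small or occasionally slightly
negative even though the cost reduction is real, which is why the
robustness claim is asserted as a median trend over seeds.

## Numerical choices

- Flow integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
  the cost Hessian p^2 L can have widely spread eigenvalues), terminal
  event on ||g||_inf - g_tol.
- Equilibrium detection vs. balance checking are separate: `check_balance`
  reports per-neuron residuals against tol * max(1, C).
- Laplacian eigendecomposition uses the symmetric solver; eigenvalues below
  1e-10 * lambda_max are treated as the kernel (component indicators), and
  the pseudoinverse is formed on the positive modes only.
- Diagonal symmetrizability is tested by least squares on the incidence
  system p (h_j - h_i) = log(c_ji / c_ij) / 2 over reciprocal pairs
  (residual tolerance 1e-8 relative to the log-cost scale).  This is the
  robust generalization of checking forward/backward cycle-product
  equality, and it degrades gracefully to a certificate: on success it
  returns the achieving h and the geometric-mean cost matrix.
- ReLU derivative at exactly 0 is defined as 0 (subgradient convention;
  measure-zero under task activity).
- Loop products are evaluated on user-supplied cycles (plus 2-cycles and
  self-loops in the tests); enumerating all directed cycles is exponential
  and deliberately avoided.
- Perturbation specs warn above |eta| = 0.2, where first-order predictions
  visibly degrade; the resistance-distance reversal formula uses the
  Laplacian of the *post*-perturbation cost matrix by default (a flag
  selects the pre-perturbation one for sensitivity analysis).

## Known limitations

- No guarantee is made about the sensitivity of the *output* to input or
  hidden noise (S^{u->y}, S^{x->y}, S^{u->x}); the optimized quantity is the
  sensitivity of the hidden dynamics, the dominant term for long recurrent
  computations.  The input/output sensitivities trade off along h and are
  documented here only.
- Exact trajectories exist only for N = 2; the heat-kernel expressions are
  quadratic (frozen-Laplacian) approximations whose error grows with the
  distance from balance.
- Networks with embedded feedforward (not strongly connected) cost
  structure have no finite equilibrium; the flow still decreases the cost
  and the package integrates to the horizon with a warning.
- The training experiment is scaffolding for studying balance in trained
  networks, not a statement about optimal RNN training practice.
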