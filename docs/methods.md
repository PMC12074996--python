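# Methods

This note describes the models and algorithms implemented in `msalnamd`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Units and conventions

Everything inside the package is in Hartree atomic units (Hartree, Bohr,
atomic time unit, electron mass, hbar = 1). Angstrom, eV, femtoseconds,
cm^-1 and amu appear only at I/O boundaries (`msalnamd.units`). Adiabatic
states are indexed from 0 (S0) upward.

## Analytic model surfaces (`model_surfaces`)

The desk-scale stand-in for an electronic-structure method is a
linear-vibronic-coupling (LVC) style diabatic Hamiltonian,

    H_kk(Dx) = E0_k + g_k.Dx + 1/2 Dx^T K_k Dx,
    H_kl(Dx) = c_kl + lam_kl.Dx   (k != l),

with Dx the Cartesian displacement from a shared reference geometry.
Adiabatic energies are the ascending eigenvalues; gradients use the
Hellmann-Feynman sandwich rule, with a symmetrized subspace average (and a
logged warning) inside numerically degenerate blocks. Dynamics never
evaluates exactly at a degeneracy in practice, so the tie-break matters
only for robustness.

`make_lvc_model` generates seeded random instances:

* Force constants are built as K = M^1/2 Q diag(w^2) Q^T M^1/2 with
  frequencies drawn uniformly from 220-880 cm^-1, so every model has
  realistic vibrational frequencies regardless of atomic masses and is
  positive semi-definite by construction.
* Linear terms come from displaced minima, g_k = -K_k dx*_k, with minima
  excursions of order `shift_scale` — this keeps each diabat's well within
  reach of the reference geometry.
* Unless disabled, a diabat-0/1 crossing is engineered along one
  normal-mode direction, at 70% of `crossing_range` (default 1.5 Bohr)
  from the reference. The direction is chosen as the mode whose Cartesian
  stiffness is closest to a moderate target (0.05 Hartree/Bohr^2), so the
  crossing is low enough on the lower surface to be reachable after
  vertical excitation while the upper diabat's tilt stays bounded. The
  construction is verified by a scan at build time.
* Constant couplings default to 0.01 Hartree (0.27 eV) with 0.005
  Hartree/Bohr linear parts — typical magnitudes for vibronically coupled
  organic chromophores; they open an avoided crossing of a few mHa where
  the engineered diabat crossing sits.

An LVC Hamiltonian in raw Cartesian displacements is deliberately defined
in the laboratory frame (the 1-atom toys have no internal coordinates at
all). With `remove_translation=True` displacements are projected onto the
complement of uniform translations, making the surfaces exactly
translation invariant; rotations are not projected.

## The multi-state potential (`descriptors_model`)

The central model feeds each atomic descriptor vector, extended by one
extra component `state_index / 8`, through a per-element feed-forward
network; atomic outputs plus least-squares self-atomic energies sum to the
state's total energy. Because the state is an input feature, one model
serves any number of states and mixed 2-/4-state records train together.
The composite loss is

    L = w_E L_E + w_F L_F + w_gap L_gap,    (defaults 1, 0.1, 1)

where `L_gap` is the mean squared error of adjacent-state gaps — the term
that keeps near-degeneracy regions accurate. All components are means over
labeled scalar entries (not sums), so the weights stay comparable across
dataset sizes.

Two descriptor backends sit behind one interface:

* **Symmetry functions** — ANI-type radial shells per neighbor element and
  angular shells per element pair, smooth and invariant to rotation,
  translation and same-element permutation, with analytic coordinate
  Jacobians. The arccos singularity in the angle is removed by the usual
  0.95 factor on the cosine.
* **Displacement descriptors** — the flattened displacement from a
  reference geometry, exposed as a single whole-system site. This backend
  exists because *no* invariant descriptor can represent a lab-frame LVC
  surface: for a single atom every invariant descriptor is constant, yet
  the surface depends on position. All LVC benchmarks therefore train on
  displacement features; the symmetry-function backend carries the
  invariance contract for molecular use.

Networks are tanh MLPs (default 2x64) written directly in numpy. Forces
are exact negative input-gradients of the network chained through the
descriptor Jacobian — never finite differences. Training force-matching
requires gradients of input-gradients with respect to weights; this
double-backprop is implemented as a forward tangent pass followed by a
reverse pass over the combined graph, verified against finite differences
at the 1e-9 level. Optimization is full-batch Adam with a cosine learning
rate decay (1e-2 down to 2e-4 by default), a seeded 10% validation split
and patience-based early stopping. Training is bit-deterministic for a
given seed.

Baselines: `single_state` trains one independent network set per state
(energies + forces of that state); `multi_output` trains one network set
with n_states outputs (energies + gaps). Force training for the
multi-output head layout is intentionally out of scope — the force loss
couples all heads through the shared trunk and is not implemented; the
trainer logs and ignores `w_F` there.

## Wigner sampling (`initial_conditions`)

Ground-vibrational-state (T = 0) Wigner sampling: per mass-weighted normal
mode, Q ~ N(0, 1/(2w)) and P ~ N(0, w/2), transformed back to Cartesian
positions and velocities. Frequencies below a floor (default 100 cm^-1)
are raised to the floor before sampling, so soft modes cannot produce
unphysical distortions. Center-of-mass momentum removal is optional and
off by default; rotational angular momentum is not removed. Excitation
window filtering keeps conditions whose vertical gap lies within
`center ± half_width` (eV) and reassigns the initial state.

## Surface hopping (`surface_hopping`)

Velocity-Verlet on the active adiabatic surface, with the
Landau-Zener-Belyaev-Lebedev hop test at every strict three-point local
minimum of the gap to an adjacent state:

    P = exp( -(pi/2) sqrt( Z^3 / Zdd ) ),   Zdd = (Z- - 2Z0 + Z+)/dt^2.

A non-positive Zdd means the minimum test failed numerically and is
treated as a no-hop sentinel. Hops are applied at the gap-minimum step:
the provisional next step is discarded, velocities are rescaled by a
single factor `sqrt(1 - dE/E_k)` along the momentum direction, and
propagation resumes on the new surface (total energy conserved to
round-off). The kinetic-energy reservoir available for upward hops is the
full kinetic energy by default; a `com_removed` option subtracts the
center-of-mass translational energy. When both neighbors present a
minimum in the same step, the larger-probability candidate is attempted
first (tie going to the lower state), and at most one hop is executed per
step. Nonadiabatic coupling vectors are never needed.

## Gap-driven dynamics (`gapmd`)

Above the gap threshold (default 0.03 Hartree, the range where hops
typically happen) the trajectory follows the interstate gap force
F_gap = F_upper - F_lower, which by construction descends the gap; below
the threshold it propagates on the configured adjacent-pair branch
surface. The threshold test is re-evaluated every step with no
hysteresis. Because switching force fields does not conserve energy, any
excess over the step-zero total is removed each gap-mode step by scaling
velocities with `sqrt(1 - E_excess/E_k)`; if the excess exceeds the
kinetic energy the step falls back to surface propagation regardless of
the gap. The potential-energy reference for the excess is mode dependent
(branch surface in surface mode, lower pair state in gap mode) — a
bookkeeping convention that had to be fixed here because following F_gap
corresponds to no single adiabatic surface. gapMD is a sampler; no
physical observables are computed from its trajectories.

## Active learning (`active_learning`)

The loop: train a *main* model (energies + forces + gaps) and an
*auxiliary* model (energies + gaps only); monitor every ML-TSH step in
order — negative predicted gap, current-surface uncertainty
U_j = |E_aux,j - E_main,j|, adjacent-surface uncertainty — stopping the
trajectory at the first failure and sampling that geometry; spawn gapMD
trajectories from a random certain step of each TSH trajectory (adjacent
pair chosen at random, branches split half upper / half lower) under the
same checks; flag steps where main- and auxiliary-model LZBL hopping
probabilities differ by more than 0.10 and sample at most 15 of them per
iteration; label everything with the reference; retrain; stop when at
least 95% of the ML-TSH trajectories finish fully certain. Per-state
thresholds are `median(U) + 3 * MAD(U)` (raw MAD, no normal-consistency
factor) over the initial validation set (a seeded 10% of the initial
data), computed once and never revised. Probability-uncertainty failures
do not count against convergence, and gapMD trajectories are excluded
from the ratio.

The initial set is built in Wigner batches of 50; after each batch the
5-fold cross-validated MAE of a quick ground-state energy-only model is
fit to a power-law learning curve, and sampling stops when the projected
relative improvement of one more batch drops below 10%.

One deliberate deviation: the auxiliary model uses a *smaller* hidden
layout than the main model (default half the width) rather than an
identical one. With identical architectures the two models can agree on
the initial validation set far more tightly than any later retraining can
reproduce once harder (near-degeneracy) points enter the training set; the
fixed thresholds then inherit an unreachably small scale and the loop
stalls at zero convergence. A stable architectural diversity keeps the
validation-set disagreement on the scale of the true off-distribution
error. This is the classic committee-diversity requirement of
query-by-committee methods.

The optional Wigner-broadening augmentation builds an approximate Hessian
at every training geometry by central finite differences of the model's
ground-state forces, floors imaginary frequencies via their magnitudes,
draws one Wigner sample per record and labels it with the reference —
doubling the set when nothing fails.

## Trajectory analysis (`trajectory_analysis`)

Populations are per-state trajectory counts on the stored step grid (no
interpolation) with 95% normal-approximation binomial bands. Ground-state
rises are fit with P(t) = A(1 - exp(-t/tau)) by nonlinear least squares;
starting values are A0 = final occupation and tau0 = the time of half
that value, both overridable; standard errors come from the fit
covariance. Quantum yields are reactive fractions with the 95% binomial
normal-approximation interval. Note that fit standard errors assume
independent residuals: populations sampled from one trajectory ensemble
are autocorrelated across time points (the same trajectories contribute
everywhere), so parameter-recovery statements about the fit uncertainties
are validated with independent per-time-point counting noise. Geometry classifiers implement the mean
methylene dihedral scheme (planar below 30 deg; twisted-stretched /
twisted-shrunk split at a 1.55 Angstrom bond) and the C-N-N-C dihedral
bins (cis/trans at 60 deg for yields; 40/140 deg three-bin scheme for
isomer populations); exact boundary values go to the lower-named class,
a convention fixed here because the printed thresholds are strict
inequalities.

## Benchmark design and problem sizes

All expensive checks run on deliberately small instances chosen to keep
the full suite fast while preserving the qualitative physics:

* The training smoke benchmark uses 500 Wigner samples of the 1-atom
  2-state surface and reaches per-state MAEs of ~0.6 mHa.
* The architecture comparison uses a 4-state 2-atom surface, 120 training
  points carrying synthetic reference noise (1 mHa on energies, 2 mHa/Bohr
  on forces — the scale of converged ab initio noise), 150 test points and
  three training seeds. Each architecture trains to convergence with its
  native loss at a matched capacity/compute budget: multi-state
  (96,96)x6000 epochs, single-state four (64,64)x3000, multi-output
  (96,96)x6000. Under these conditions the median per-state MAE orders as
  multi-state (~0.6 mHa) < single-state (~0.8 mHa) < multi-output
  (~1.5 mHa), and the multi-state ground-state error is no worse than the
  dedicated ground-state model's.
* The end-to-end active-learning benchmark is the 1-atom 2-state surface
  with 20 ML-TSH trajectories per iteration, 50 fs windows at a 0.1 fs
  step, and a 25-iteration cap; converged models then drive 500-trajectory
  population comparisons against the oracle.

What these runs do *not* show: the analytic surfaces are smooth, low
dimensional and noise-free (unless noise is injected), so they exercise
the protocol's logic and statistics, not the representational challenges
of real molecular manifolds. In particular, the architecture ordering is
conditional on realistic label noise and on each architecture's native
loss — in an energies-only ablation on noise-free data all pooled
architectures fit these smooth surfaces equally well and the ordering
disappears. The reported iteration counts and training-set sizes are
properties of the toys, not predictions for molecules.

## Known limitations

* No fewest-switches hopping, decoherence corrections or nonadiabatic
  coupling vectors; LZBL only.
* The multi-output baseline does not train on forces.
* Finite-temperature Wigner sampling is not implemented.
* The fixed UQ thresholds occasionally come out too tight for a given
  seed (the committee happens to agree unusually well on the initial
  validation set), in which case the loop can fail to reach the
  convergence target within the iteration cap — the documented behavior
  of threshold-based stopping, observed in roughly one in five seeds on
  the toy.
* Surrogate-driven LZBL *population curves* on the low-dimensional toys do
  not quantitatively reproduce the oracle's, even when the surrogate's
  energy errors are well below a millihartree, and the corresponding
  acceptance test is currently red. This is a conditioning property of the
  observable, not a defect of any one model: the hopping probability
  P = exp(−(π/2)√(Z³/Z̈)) is exponentially sensitive to the gap Z and its
  temporal curvature Z̈ at the gap minimum, and in a microcanonical
  few-degree-of-freedom system the dynamical regimes split into two cases,
  both fragile. (i) When decay is gradual and rate-like, hops happen at
  turning-point *grazes* of the seam, where Z̈ is tiny (10⁻⁷–10⁻⁶ a.u.) —
  reproducing it requires the surrogate's gap error to be constant to
  ~10⁻⁶ Hartree over femtosecond stretches of trajectory, far below any
  realistic fit accuracy (measured surrogate Z̈ errors are a factor 2–4,
  giving hop rates off by 2–10×). (ii) When hops instead occur at fast
  transversal crossings, the per-event probability is robust, but with
  only 3–6 vibrational coordinates and ≲1 vibrational period of spread
  the ensemble reaches the seam coherently: populations change in
  collective bursts (or equilibrate by recrossing, since nothing carries
  energy away from the seam region), so a fixed-time comparison at the
  few-percent level fails on timing rather than rate. Real polyatomic
  photochemistry escapes this dichotomy — many modes dephase the ensemble
  and drain energy away from a true conical intersection where P ≈ 1
  regardless of model error — but that mechanism has no analogue on these
  toys. A systematic scan over toy parameters (seeds, crossing placement,
  constant vs. purely linear coupling, 1- and 2-atom systems, 50–200 fs
  windows, dense and crossing-enriched training sets up to ~3000 points
  and (96,96) networks) found no regime that is simultaneously gradual,
  monotone and robust at the ±2–4 point level of a 500-trajectory
  two-proportion interval. Users validating surrogates for hopping
  dynamics on model Hamiltonians should therefore compare rate-insensitive
  quantities (seam-access statistics, per-event probability distributions,
  yields at matched sampling) rather than pointwise populations.
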