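# Methods

## Model

The core estimator is kernel ridge regression on molecular descriptors.
Training solves `(K + λI) α = y` by factorization (Cholesky by default;
Bunch–Kaufman via LAPACK `dsysv` and LU as fallbacks, tried in that order
with a warning when the preferred factorization fails). The matrix is never
inverted explicitly. The infinity-norm residual of the solve is stored on
the fitted model, and a residual above 1e-6 (relative to the target scale)
triggers an ill-conditioning warning rather than a refusal — severely
regularized or duplicated data still trains, but the user is told.
An exactly singular system (duplicate geometries with conflicting targets at
λ = 0) raises rather than silently averaging.

Predictions are `f̂(x) = Σⱼ αⱼ k(x, xⱼ)`; Cartesian derivatives come from the
chain rule `∂f̂/∂M = Σⱼ αⱼ (∂k/∂x) (∂x/∂M)` with analytic kernel gradients
and descriptor Jacobians. Laplacian and exponential kernels (and Matérn
n = 0, which equals the exponential kernel identically) are non-smooth at
zero distance and are refused for derivative prediction with a typed error.

### Kernels

All kernels use the Euclidean (Gaussian: squared-Euclidean) distance between
descriptors and a length scale σ. The Matérn family carries an integer
smoothness n; its factorial coefficients are evaluated through log-gamma
above n = 10 and n is capped at 20, where the coefficients would otherwise
lose all precision. Kernel matrices are assembled on one triangle and
mirrored so symmetry is exact in floating point; the diagonal is set to 1
identically.

### Descriptors

RE and ID descriptors enumerate atom pairs in lexicographic order (a, b)
with a < b — the convention is arbitrary but must be fixed and is documented
here. The Coulomb matrix converts distances to Bohr with
1 Å = 1/0.52917721067 Bohr and is vectorized row-major *including both
symmetric halves*, keeping the redundant entries of the full matrix; its
dimension is `max_atoms²` with zero padding. Sorting variants (row-norm
sorted CM, repulsion-sorted RE) break ties by original atom index via stable
sorts, making them deterministic; they are discontinuous functions of the
coordinates, so both refuse Jacobians with a typed error.

### Permutational invariance

The symmetrized kernel averages the base kernel over all permutations of
user-declared groups of equivalent atoms and normalizes so that
k̄(M, M) = 1. Permutations are enumerated group-by-group in lexicographic
order; the product of group factorials is capped at 10!. The gradient is
the quotient-rule derivative of the normalized sum; the self-term
`∂k(x(M), x(P M))/∂M` receives contributions through *both* kernel
arguments and is evaluated with the permuted-descriptor Jacobian, whose
column blocks are mapped through the permutation. Every path is validated
against central finite differences in the test suite.

One subtlety: exact invariance of the *RE-based* symmetrized kernel under a
permutation of the query requires the reference geometry itself to be
symmetric under the declared groups (otherwise the reference pair distances
distinguish the equivalent atoms at the 1e-16 level and the invariance error
is amplified by the regression coefficients). The synthetic XH3 fixture
therefore places its hydrogens at (d,0,0), (0,d,0), (0,0,d) with the heavy
atom on the threefold axis, making all equivalent reference distances
bitwise equal. Real equilibrium geometries are symmetric to optimization
tolerance, which bounds the invariance error correspondingly.

## Sampling and model selection

Splits are uniform without replacement via numpy's PCG64 generator
(`default_rng(seed)`); the generator is the single source of randomness per
call, so every split is reproducible cross-platform. Defaults follow the
80:20 training:test and sub-training:validation convention. Farthest-point
sampling seeds with the globally most distant pair and greedily maximizes
the minimum distance to the selected set, ties resolved toward the lowest
index; the full ordering is returned so every prefix is itself an FPS
sample. Structure-based sampling sorts by distance to the equilibrium
descriptor, slices into `n_slices` (default 5) contiguous near-equal
deformation regions, seeds the equilibrium slice with the equilibrium point
and the others with their point nearest equilibrium, and interleaves the
per-slice greedy orders proportionally to slice size (largest-deficit rule,
deterministic). Distances are always between descriptor vectors, never raw
coordinates.

Hyperparameter search evaluates an exhaustive log₂ grid in (σ, λ) —
defaults: σ exponents 2…9, λ exponents −35…−6, 11 points per axis — and
re-centers the grid one step on each side of the best point for each of 3
refinement passes, in log space. Validation loss ties prefer smaller λ, then
smaller σ (a smoothness bias). The final model is retrained on
sub-training ∪ validation with the winning hyperparameters. Value and
gradient losses combine as a weighted sum or as the geometric mean
`√(L_val · L_grxyz)`; RMSE is the default base metric.

## Statistics

The error report carries MAE, mean signed error, RMSE, means, extreme
outliers of ŷ − y with their indices, and the least-squares regression
ŷ = a + b·y with SE(a), SE(b), R, and R². Degenerate inputs (N < 2, or zero
variance in either series) set the regression block to a typed `UNDEFINED`
singleton instead of emitting NaN — the formulas divide by zero silently
otherwise, and a typed marker survives serialization and comparison
honestly. Gradient RMSE treats every Cartesian component of every atom of
every geometry as one data point and equals the flat-array RMSE bitwise.

## Multi-step tasks

Δ-learning trains the correction model on `y_target − y_baseline` and
predicts `baseline + correction` with no hidden scaling; baseline values
are caller-supplied inputs at both train and predict time. Self-correction
trains layer i on the residual of layers 1…i−1; with interpolating layers
the second layer's targets collapse to the solve residual.

Learning curves run fresh seeded sampling per (size, repeat) cell — 5
repeats by default — and record RMSE/MAE plus wall-clock timings in a CSV.
The default test set is one fixed held-out sample shared across all cells so
size comparisons are paired; per-repeat redrawing is available and flagged
in the output. The power law `ε(N) = ε_a + a/N^b` is fitted by trust-region
least squares under ε_a, a ≥ 0, b > 0, initialized from the log–log linear
fit with ε_a = 0 and refined from 10 deterministic multi-starts around that
seed, keeping the lowest residual. Constant curves return ε_a = ε, a = 0
with b flagged unidentifiable. Parameter (not curve) recovery under
multiplicative noise is intrinsically ill-conditioned: (a, b) are nearly
collinear on a log–log grid, so percent-level curve noise amplifies roughly
tenfold into the amplitude — the tests assert this scaling rather than a
tighter bound the fit cannot deliver.

## ML nuclear-ensemble spectra

The loop adds `N_batch` (default 50, also the initial batch) ensemble points
per iteration in farthest-point order over the ensemble descriptors, trains
one excitation-energy and one oscillator-strength model per excited state on
an 80:20 split of the labeled set, and stops when the relative change of the
geometric-mean validation RMSE satisfies |rRMSE| < 0.1. The relative change
is signed — improvement makes it negative — so the absolute value is used by
default; a literal signed mode is provided as an option. Validation RMSEs
are floored at 1e-15 so an exactly-zero RMSE cannot annihilate the geometric
mean.

The cross section sums Gaussian lineshapes of standard deviation δ/2
(δ = 0.01 eV default) over all points and states, weighted by
ΔE·f/(N_p·E) and the prefactor πe²ħ/(2m c ε₀), evaluated from CODATA
constants (scipy.constants); output is cm² per molecule against photon
energy in eV. Negative predicted oscillator strengths are set to zero
before summation. The 1/E factor is evaluated at the grid energy, not the
transition energy, matching the printed form of the working equation; the
difference is a sub-percent asymmetry across a narrow band. The default
energy grid spans the labeled ΔE range ± 10δ at step δ/5. Labeled points
keep their reference labels in the final spectrum; only unlabeled ensemble
points are ML-predicted, and a fully labeled ensemble short-circuits to the
direct cross section.

## Synthetic data

The generators define the study conditions for every test: a Morse diatomic
(D = 4.75 eV, r_eq = 0.741 Å, a = 1.95 Å⁻¹ — H₂-like; r sampled uniformly
on [0.5, 2.2] Å), a pair-spring harmonic polyatomic, the permutation-
symmetric XH3 system (Morse terms over X–H and H–H distances, symmetric
functions of same-element pairs, hence exactly invariant under H
permutations), and a water-like labeled nuclear ensemble whose excitation
energies and oscillator strengths are smooth functions of the O–H
stretches, with a stated fraction (2% default) of strengths shifted
negative to exercise the clipping rule. Gradients are exact analytic
derivatives of the generated energies; optional Gaussian noise applies to
labels only, never geometries, so descriptor-level tests stay exact. Each
call uses one seeded generator recorded in the dataset metadata.

What the synthetic data does *not* emulate: quantum-chemistry noise
correlated with geometry, multi-minimum surfaces, conical intersections,
Wigner-distribution sampling (the ensemble uses plain Gaussian
displacements), and basis-set or method errors. Passing tests therefore
demonstrate correctness of the machinery — solvers, derivatives,
invariances, convergence logic — not accuracy claims on real molecules.

## Numerical choices and problem sizes

Default λ is 2⁻³⁵ — small enough not to bias smooth fits, large enough to
keep Cholesky stable on clean data — and overridable everywhere. Derivative
tests use central differences with h of 1e-5–1e-4 Å and compare at 1e-6
relative tolerance against the relevant field scale; finite-difference
cancellation noise grows as Σ|α|·ε/h, so those comparisons use models with
moderate coefficient norms. The test suite and the acceptance script run on
desk-scale problems (50–400 points, 2–4 atoms, ≤ 5 excited states), chosen
so the full suite completes in well under a minute of compute per module
while still exercising every code path; the algorithms scale as O(N³) in
training points like any dense-kernel method.

## Known limitations

Training on gradient labels (kernel-Hessian systems) is out of scope, as
are variance estimates, sparse/low-rank approximations, and descriptor
families beyond RE/CM/ID (user-supplied vectors cover external descriptors
but cannot provide Jacobians, so gradient prediction is refused for them).
The sorted descriptor variants are intentionally non-differentiable. Model
files are a versioned container specific to this package.
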