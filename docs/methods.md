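# Methods

## The data-generating model

Metabolite concentrations follow a kinetic ODE system, dx/dt = S·v(x; θ),
x(0) = x₀, where S is the stoichiometric matrix and v the flux vector with
kinetic parameters θ. The built-in reference system is a **linear open
chain** of 11 metabolites, dx/dt = A·x + b, with a tridiagonal rate matrix
A (units 1/min): influx b = 10³·[0.1, 0, …, 0]ᵀ into M1, exchange rates on
the sub- and superdiagonal between 10² and 3·10³, diagonal entries derived
so that columns 1–10 sum to zero (mass conservation — everything leaving a
metabolite enters a neighbour), and A(11,11) = −10³ pinned to make the
system open at the far end. Initial state x₀ = 1. Linear systems are solved
in closed form, x(t) = x_ss + e^{At}(x₀ − x_ss) with x_ss = −A⁻¹b; generic
plug-in systems are integrated with LSODA at rtol 10⁻⁸ / atol 10⁻¹⁰
(kinetic rate constants span several orders of magnitude, so a
stiff-capable method is the safe default). The two routes agree to < 10⁻⁶
relative error on the reference system, which the test suite checks against
a matrix-exponential oracle.

A second built-in variant (`linear_degenerate`) with uniform off-diagonal
rates of 10³ and influx 500 into M1 reproduces a regime in which the
2-component CP model becomes two-factor degenerate.

## Cohorts: individual and induced variation

A cohort is defined by ordered groups (label, size, variation spec), a
sampling grid and one root seed.

* **Individual variation** (level β): every perturbable parameter of a
  subject is multiplied by 1 + u, u ~ Uniform(−β, β), independently per
  parameter and subject. The uniform law is the simplest distribution
  consistent with a hard "within β of the default" bound. For the linear
  system the perturbable parameters are the off-diagonal rates; diagonals
  are re-derived afterwards so every realized subject satisfies the mass
  constraint exactly.
* **Induced variation** (level α): a named parameter is multiplied by
  1 − α for all subjects of a group (e.g. `A(7,6)` halved, α = 0.5 — a
  knock-down of the M6→M7 flux). Applied after the individual perturbation;
  diagonals are again re-derived. Since the operations are multiplicative
  the order does not change the distribution of the targeted rate.
* **Mutant initialization**: groups may start from the unmodified model's
  steady state instead of x₀ (`init_from_steady_state`), the convention for
  in-silico mutants of plug-in models; the reference linear scenarios do
  not use it.

Per-subject RNG streams are spawned hierarchically
(`SeedSequence(seed) → group → subject`), so appending a group or extending
a group at its tail never changes previously generated subjects, and the
whole cohort is a pure function of (config, system).

Default study design (the built-in scenarios): 10 normal + 10 knock-down
subjects, sampling grid (6 + 5k)·0.002 for k = 0..19 (0.012 … 0.202 min —
the grid extends marginally past 0.2; the printed sampling rule is taken as
operative), β ∈ {0.01, 0.3}, α = 0.5 on A(7,6).

What the generator does **not** emulate: measurement error with
metabolite-specific variance structure, limit-of-detection censoring,
missing-at-random driven by intensity, or subject covariates. Noise is
added only in the cross-validation procedure, as i.i.d. Gaussian scaled to
a fixed relative Frobenius norm (‖X_noise − X‖/‖X‖ = η exactly). Passing
tests therefore demonstrate correctness of the machinery and
reproducibility of the simulation results, not robustness to real assay
artifacts.

## Preprocessing

Center across the subjects mode (per metabolite × time fiber), then scale
within the metabolites mode by each slice's root-mean-square. Scaling
multiplies whole slices by constants, so centering survives it and one pass
suffices. With an observation mask, means and RMS are computed over
observed entries only (count = observed entries, not I·K), and the affine
transform is applied to all entries so that held-out values live on the
same scale as the model's reconstruction. The transform is stored
(offsets J×K, scales J) and exactly invertible.

## CP fitting

The R-component CP model X ≈ Σ_r λ_r a_r∘b_r∘c_r is fitted by alternating
least squares on the (optionally masked) objective ‖W ∗ (X − X̂)‖².
Choices that matter:

* **Missing data** is handled by EM imputation: before every sweep the
  missing entries are replaced by the current model's prediction, which
  makes each sweep decrease the masked objective; at a fixed point this
  minimizes the identical objective as a direct weighted (cp-wopt-style)
  solver.
* **Non-negativity** (time mode by default — concentration-profile
  components) is imposed by row-wise NNLS. Implementation detail: the
  unconstrained row solution is accepted whenever it is already
  non-negative (it is then the NNLS optimum); only violating rows go
  through the active-set solver.
* **Orthogonality** (optional per mode; used by the Paralind comparison)
  is imposed via the orthogonal-Procrustes solution of the mode subproblem.
  A zero cross-product matrix leaves the subproblem undetermined and keeps
  the previous iterate.
* **Initialization / multi-start**: the first start is the deterministic
  HOSVD initialization (leading left singular vectors of each unfolding,
  missing entries zero-filled); the remaining n_starts − 1 starts are
  i.i.d. standard normal (absolute values on non-negative modes, QR on
  orthogonal modes). Default n_starts = 20. The start with the lowest
  final objective wins; ties go to the earliest start.
* **Stopping**: objective decrease ≤ 10⁻¹⁰·‖X‖² per sweep (a scale-free
  relative criterion), or 10⁴ sweeps.
* **Normalization and signs**: unit-norm columns, magnitudes absorbed into
  λ ≥ 0, components ordered by descending |λ|, and each metabolites column
  flipped (compensated in the subjects column) to a non-negative sum so
  that similarity scores such as C12 are comparable across runs.

Near-collinear optima (the rank-deficient β = 0.01 regime) are ALS
"swamps": convergence there takes a few thousand sweeps, which the default
iteration cap accommodates.

## Paralind fitting

Paralind(S, R, R) replaces the subjects factor by Ã = A·H with a basis
A (I×S) and a binary dependency matrix H (S×R) assigning each component to
one basis column (e.g. H = [1 1] for two components sharing one subject
profile; H = [[1,1,0],[0,0,1]] for Paralind(2,3,3)). Alternating updates:
A from the reduced least-squares problem with H fixed, B from the
orthogonal-Procrustes subproblem (orthogonality in the metabolites mode
makes the restricted model unique), C by NNLS (time mode), with the same
EM masking, HOSVD-first multi-start, stopping rule and normalization as CP.
Only Ã is identified; A and H individually are not. After normalization
the basis columns of A and the columns of C have unit norm, B is
orthonormal, and λ carries the magnitudes (well-defined because H is
binary). By construction the Paralind fit can never exceed the matched CP
fit, and rank(Ã) ≤ S.

## Model-selection diagnostics

* **Fit** = 100·(1 − ‖X − X̂‖²/‖X‖²), restricted to observed entries when
  masked.
* **Core consistency**: with λ folded into the subjects factor, the
  least-squares Tucker core G for the fixed factors is solved via
  mode-wise pseudoinverses and compared to the superdiagonal target T of
  ones: CC = 100·(1 − Σ(G−T)²/R), the Bro–Kiers normalization
  (denominator ΣT² = R). CC ≈ 100 flags an adequate trilinear model; large
  negative values flag overfactoring. The identity "CC = 100 for R = 1"
  holds for least-squares-fitted models (the optimal scalar core is then
  exactly 1); for an arbitrary non-fitted model the solved core absorbs
  the misfit and CC < 100 — the diagnostic is defined for fitted models.
* **Tucker congruence** TC_ij: product over modes of component cosine
  similarities; the reported scalar is the off-diagonal entry of maximal
  magnitude, signed. TC below −0.85 raises an advisory two-factor
  degeneracy flag ("close to −1"; the threshold is this package's choice
  and is reported alongside the raw value).
* **C12**: cosine similarity of the first two subject-mode components;
  |C12| ≈ 1 is the rank-deficiency signature that motivates Paralind.
* **Tensor completion score** TCS =
  ‖(1−W) ∗ (X̂ − X_noise)‖ / ‖(1−W) ∗ X_noise‖ — relative error at
  deliberately hidden entries.

**Cross-validation protocol**: per replicate, add noise at level η to the
raw cohort tensor, hide a fraction of entries (one mask shared by all
candidate models, so scores are paired), preprocess the masked noisy data,
fit each candidate with the mask, back-transform the reconstruction with
the replicate's preprocessing state, and evaluate the TCS *on the original
(noisy-data) scale*. The scale choice was genuinely open; scoring the
back-transformed reconstruction against the noisy data is the literal
reading of the TCS definition, yields TCS magnitudes ≈ 0.3 in the
reference setting (η = 0.3, 20% missing), and produces consistently paired
CP-vs-Paralind differences. Scoring on the preprocessed scale instead
yields ≈ 0.34 with the model difference buried in replicate noise. The
paired two-sided t-test compares the first two candidates; identical
score lists short-circuit to p = 1.

## Problem sizes and defaults used by the shipped checks

The acceptance-style tests and `scripts/acceptance.py` average over 10
seeded cohorts per condition (20 × 11 × 20 tensors). CP fits in the sweeps
use 8 random starts (20 for the script's reported Paralind and CP runs);
cross-validation comparisons use 20 replicates per cohort, 5 cohorts,
3 starts and a 10⁻⁹ stopping tolerance per fit — with the HOSVD first
start, additional random starts change the winning objective only in the
fourth significant digit, so the smaller start counts are a runtime choice,
not an accuracy concession. Example scripts use 8–10 replicates/starts for
the same reason.

## Known limitations

* The ALS/EM solver converges to stationary points; multi-start mitigates
  but cannot guarantee global optimality, and fits in the degenerate
  regime (TC → −1) are intrinsically unstable — that instability is what
  the diagnostics are for.
* Core consistency requires full-column-rank factor matrices; it raises on
  exactly rank-deficient ones (the Tucker core solve is ill-posed there).
* Only third-order tensors and dependencies in the subjects mode are
  supported (Paralind(S,R,R)); general multi-mode dependency patterns and
  PARAFAC2-style evolving factors are out of scope.
* Published nonlinear pathway models are supported through the plug-in
  registry but their kinetic parameter sets are not shipped; the package's
  quantitative reference results concern the linear open system only.
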