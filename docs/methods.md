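# Methods

## The model

A tetrameric channel with one activator site per subunit populates five
binding configurations CF0..CF4.  Treating the bath as a dilute lattice of
ligand at concentration [L] (reference concentration 1 M, so the activity
x = K_A·[L] is dimensionless) and the channel at binding equilibrium, the
statistical weight of configuration k is

    W_k = g_k · w_k · x^k,      w_k = γ^C(k,2) · μ^C(k,3) · ν^C(k,4)

where g_k is the configuration multiplicity and γ, μ, ν are Boltzmann
factors of the pair, triple and quadruple coupling energies
(γ = e^(−βJ), μ = e^(−βK), ν = e^(−βM), β = 1/k_BT with
k_B·T ≈ 0.5922 kcal/mol at the default 298 K).  Occupancy probabilities
are p_k = W_k / Σ_j W_j; the observable normalized potentiation is the
conductance-weighted sum

    ΔI/ΔImax = a·p1 + b·p2 + c·p3 + d·p4

with conductance coefficients a–d ∈ (0, 1] (fractions of the maximal
current; the upper bound is configurable, since nothing in the physics
forbids a super-conducting intermediate).  The mean number of bound ligands
is ⟨N⟩ = Σ k·p_k = x·∂lnZ/∂x.

Assumptions inherited from the underlying physics: binding only to the
open state; binding equilibrates much faster than gating, so an
equilibrium ensemble applies; the five configurations are the only states
(the two geometric arrangements of the doubly-bound configuration —
adjacent vs diagonal — share one weight and are not distinguished).

## Ensembles and multiplicities

- Homomeric tetramer: g = (1, 4, 6, 4, 1), the binomial counts.
- WT–mutant heteromer (binding-deficient mutant, 1:1 cotransfection):
  subunits assemble independently, so a composition with m wild-type
  subunits occurs C(4,m) ways and contributes C(m,k) placements of k
  ligands.  Aggregating gives g_k = Σ_m C(4,m)·C(m,k) =
  (16, 32, 24, 8, 1); `enumerate_microstates` rederives this by explicit
  enumeration and serves as the test oracle.
- `published` mode (the default) instead uses (2, 32, 24, 8, 1), the
  multiplicity set reported with the original heteromeric prediction; only
  this set reproduces the published prediction column, so it is the
  reference behaviour, with the first-principles `combinatorial` mode one
  flag away.  The two differ only in the unliganded count, which rescales
  the low-concentration foot of the curve.
- For mutant fractions other than 1:1 the combinatorial weights are
  binomial-weighted and generally non-integer; they are rescaled so the
  fully-liganded multiplicity is 1 (only ratios enter the probabilities).

The heteromeric response uses the same conductance coefficients as the
wild-type channel — the mutation removes binding, not conduction.  Its
curve is bi-sigmoidal in log concentration: high-WT tetramers respond at
low concentration (more effective cooperative recruitment per remaining
site), low-WT tetramers only at high concentration.  `inflection_count`
quantifies this by counting sign changes of a central-difference second
derivative on a uniform log10 grid (default 601 points over −9..−3, with a
1e-6 magnitude floor below which curvature is treated as numerical noise);
a Hill curve scores exactly 1, the heteromeric ensemble ≥ 2.

## Parameters

| parameter | meaning | units | default / bounds |
|---|---|---|---|
| K_A | site association constant | M⁻¹ | fit; bounds 1e2–1e9 |
| γ, μ, ν | pair/triple/quadruple cooperativity | — | fit; bounds 1e-4–1e4 |
| a, b, c, d | conductance of CF1–CF4 | fraction of max | fit; (0, 1] |
| T | temperature for energy conversion | K | 298 |

The bundled reference parameter set (`ZTZ240_KCNQ2_BEST_FIT`) is the
published best fit for the activator ztz240 on wild-type KCNQ2:
K_A = 1.805×10⁵ M⁻¹, γ = 0.928, μ = 0.4529, ν = 65.24,
a = 0.3083, b = 0.2375, c = 0.4011, d = 0.9863.

## Fitting

`fit_thermo` / `fit_hill` minimize unweighted SSE on the normalized
responses (optional 1/SEM² weighting is available but off by default,
matching how the reference SSE values are defined) with scipy's
Trust Region Reflective least squares under box constraints.  K_A, γ, μ, ν
(and the Hill EC50) are optimized on a log10 scale; conductances,
Hill slope and amplitude are linear.  Per-start stopping follows the
reference tool settings — 600 function evaluations, ftol = xtol = gtol =
1e-6 — and the winning start is then polished once at 1e-14 tolerances
(kept only if it does not increase the SSE), so the reported optimum does
not depend on the coarse per-start stopping rule.

Multi-start design: `n_starts` (default 50) initial points drawn from a
seeded `numpy` Generator — log-uniform across the bounds for the scale
parameters, uniform for conductances, and EC50 guesses confined to the
observed concentration window ± 2 decades.  Results are bitwise
reproducible for a given seed.  A fit is reported `converged` only when
the optimizer succeeded *and* the curve explains some variance (R² > 0):
TRF "succeeds" on hopeless data (e.g. monotonically decreasing responses
under positivity bounds) by stopping at the boundary, and that outcome is
flagged rather than returned silently.

With six data points the eight-parameter vector is not identifiable; the
package warns and only the fitted curve, SSE and R² should be interpreted.
The Hill baseline is the three-parameter form (amplitude free) by default;
fixing the amplitude at 1 is a flag, and the free form nests it.

EC50 is defined as the concentration where the response reaches half of
the asymptotic plateau d (`definition="asymptotic"`); half of the largest
response on the search bracket (`"observed"`) is available because the two
differ whenever the curve is non-monotone or truncated.  The crossing is
bracketed on a 600-point log grid and refined by Brent's method to
relative tolerance ~1e-12 (xtol scaled below the bracket so the relative
criterion governs).  If the response crosses the target more than once,
the error lists every crossing instead of picking one.

## Synthetic data

`simulate_dataset` evaluates the forward model at the requested
concentrations and adds i.i.d. Gaussian noise of standard deviation
`noise_sd` per replicate, reporting the replicate mean and sample SEM.
This emulates the structure of normalized whole-cell dose-response tables
(mean ± SEM over cells) but not their real error process: per-cell
normalization, heteroscedasticity (errors grow with the response), rundown
and correlated perfusion artefacts are all absent.  Passing recovery tests
therefore demonstrates correctness of the estimator under the stated noise
model, not robustness to everything electrophysiology can produce.

The curve-recovery property test samples 15 concentrations bracketing each
random parameter draw's K_D by three decades on either side — the standard
assay design — because a fixed window leaves some random curves' transitions
outside the data, where no estimator can pin the curve between points.

## Numerical choices

- Statistical weights are divided by their maximum before normalization so
  extreme parameter/concentration combinations cannot overflow.
- Probability normalization is exact to < 1e-12 across twelve decades of
  concentration (property-tested against a 2⁴-microstate Boltzmann sum).
- CSV I/O writes 17 significant digits and parses through Python's
  correctly-rounded `float`, so datasets round-trip bit-exactly.
- Problem sizes: property tests use 10⁴ random draws for normalization,
  50 draws for the microstate-oracle equivalence, 20 draws × 12 starts for
  curve recovery, and 50 starts for fits to the six-point reference data —
  the whole suite runs in about two minutes on one core.

## Known limitations

- Equilibrium only: no gating kinetics, voltage dependence or closed-state
  binding; the model cannot describe use-dependent or state-dependent
  activators.
- Mutant subunits are all-or-none non-binding; graded per-subunit affinity
  changes are out of scope.
- Tetramers only (`n_subunits = 4`); the combinatorial machinery
  generalizes but is not exposed.
- No uncertainty quantification on fitted parameters (bootstrap/profile
  likelihood would be the natural extension); with typical 6–8 point
  datasets the parameter vector is underdetermined anyway.
- The published EC50 of ~7.41 µM for the reference system is not
  reproducible from the published parameters under either implemented
  half-maximum definition (the asymptotic definition gives 9.00 µM); the
  exact procedure behind the published number is unknown, so `ec50`
  documents its definitions explicitly.
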