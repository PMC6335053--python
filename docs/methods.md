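# Methods

## Scope and units

The package models membrane-delimited Gβγ signaling from GPCRs to GIRK
channels at two levels: a well-mixed kinetic model of a receptor hotspot
(densities only, no space) and a spatial steady-state model of the Gβγ
concentration field (space only, first-order Gβγ removal). The two are
linked through the per-receptor Gβγ generation rate.

Everything internal is two-dimensional: densities in molecules µm⁻²,
bimolecular rate constants in µm² molecule⁻¹ s⁻¹. Literature constants
quoted in M⁻¹ s⁻¹ are converted on load with the exact Avogadro-based
factor for a sub-membrane slab of thickness h (default 80 Å): one
molecule µm⁻² corresponds to 1/(N_A · 1 µm² · h) ≈ 2.0757 × 10⁻⁷ M at
80 Å. The slab thickness is a parameter, not a constant, because it is
an idealization of "the solution volume a membrane-attached protein
samples"; conclusions should be checked for sensitivity to it.

## Kinetic model

Species (all µm⁻²): free active receptor R\*, receptor–trimer complex,
trimer Gα(GDP)βγ, Gα(GTP), Gα(GDP), free Gβγ, and GIRK with 0–4 Gβγ
bound. Mass-action rates follow the scheme in the README. Reference
constants (Gi-coupled receptor, converted to 2D at 80 Å):

| symbol | value | meaning |
|---|---|---|
| k12 | 0.2076 µm² s⁻¹ (1 µM⁻¹ s⁻¹) | receptor–trimer association; the specificity locus |
| k21 | 1 s⁻¹ | complex dissociation |
| k23 | 1 s⁻¹ | lumped exchange + release (per-complex Gβγ generation) |
| k34 | 2 s⁻¹ | GTP hydrolysis |
| k45 | 0.1453 µm² s⁻¹ (0.7 × 10⁶ M⁻¹ s⁻¹) | trimer re-association |
| k54 | 0.002 s⁻¹ | trimer dissociation (= k45 × K_d, K_d = 3 nM) |
| k56 | 2.0757 µm² s⁻¹ (10⁷ M⁻¹ s⁻¹) | GIRK site on-rate |
| k65 | 600 s⁻¹ | GIRK first-site off-rate |
| µ | 0.3 | per-step cooperativity on the off-rate |

The Gs-coupled parameter set differs only in k12/10. Reverse exchange
and reverse hydrolysis are fixed at zero (nucleotide pools are implicit
and saturating; inorganic phosphate is not tracked). k54 is kept at the
tabulated 0.002 s⁻¹ rather than the derived 0.0021 s⁻¹; the derivation
is exposed as `derive_k54` and the 5% difference is far below any
conclusion drawn from the model. A known internal tension in the source
constants: the GIRK first-site K_d implied by k65/k56 is 60 µM, not the
1.9 mM sometimes quoted alongside them; the tabulated rates are used.

Default densities: 50 receptors µm⁻² and 100 trimers µm⁻² (hotspot
values). GIRK density is not given anywhere authoritative; the default
is 1 µm⁻², low enough that channel binding never depletes the Gβγ budget
(the bound pool at steady state is < 1% of total Gβγ). A
"non-depleting probe" mode (`deplete_gbg=False`) removes the back-action
entirely and is used to clamp free Gβγ in tests. Only free Gβγ can be
re-sequestered by Gα(GDP); channel-bound Gβγ is protected.

**Stimulus.** k12(t) is piecewise constant (`StimulusProtocol`); the
standard experiment is a step from 0 at t = 0. Two initial conditions
are provided because the rest state is genuinely ambiguous: "naive"
(all Gα in trimer, no free Gβγ — the default) and "basal" (the k12 = 0
fixed point, which at k54 = 0.002 s⁻¹ holds ≈ 1.17 µm⁻² free Gβγ). The
difference is invisible in the activated steady state and small during
the rise.

**Integration.** `scipy.integrate.solve_ivp` with the implicit BDF
method, analytic Jacobian, rtol = 10⁻⁸, atol = 10⁻¹⁰ µm⁻². The four
conservation laws (receptor, Gα, Gβγ, GIRK totals) are algebraically
exact in the right-hand side and drift < 10⁻⁶ (observed ~10⁻¹⁵) over
10 s runs. Trajectories are clamped at zero for reporting; excursions
below −10⁻¹² never occurred at default tolerances.

**Steady states** are found by integration to convergence (relative
change < 10⁻⁸ over 1 s of model time, verified against the derivative
norm), not by root finding — slower but unconditionally stable and
automatically selects the physical branch. `sweep_k12` warm-starts each
grid point from the previous solution. The basal (k12 = 0) equilibrium
has a semi-closed form: free Gβγ solves a scalar balance (Brent root);
with negligible GIRK it reduces to the quadratic
x² + K·x − K·G_tot = 0, K = k54/k45, used as the test oracle.

**Cooperative occupancy.** Detailed balance along the binding ladder
gives equilibrium weights
wₙ = w₀ ∏ₘ₌₁..ₙ (5−m)·k56·g / (m·µᵐ⁻¹·k65); at µ = 1 this is the
binomial independent-sites limit. This closed form is the oracle for
the ODE binding subsystem at clamped Gβγ (agreement to 10⁻⁶).

## Spatial model

Steady state of D∇²C + s(r) − kC = 0 on the membrane plane,
axisymmetric, with λ = √(D/k). Defaults: D = 0.2 µm² s⁻¹, k = 1 s⁻¹
(λ ≈ 0.447 µm).

*Point source.* A receptor of turnover Q inside a circle of radius
r₀ = 0.01 µm imposes an inward perimeter flux Q/(2πr₀)
(15.9 µm⁻¹ s⁻¹ for Q = 1 s⁻¹); the decaying solution is
C(r) = A·K₀(r/λ) with A = flux·λ/(D·K₁(r₀/λ)).

*Disk (hotspot) source.* s is uniform over r ≤ R; the default
s = receptor_density × 1 Gβγ s⁻¹ per receptor (50 µm⁻² s⁻¹), with the
option of deriving the per-receptor rate from the kinetic model's
steady-state k23·RT/receptor_density (≈ 0.77 s⁻¹ at the Gi reference).
The infinite-domain closed form, C(0) = (s/k)[1 − (R/λ)K₁(R/λ)], is
implemented independently as the oracle. The production solver is a
second-order finite-difference discretization of the radial two-point
boundary-value problem with C′(0) = 0 (regularity; the r = 0 stencil
uses the 2C″ limit of the Laplacian) and C = 0 at an outer radius
defaulting to max(10λ, 10R). The mesh is graded — uniform inside the
disk and across the rim, geometrically stretched outside — and the
banded system is solved directly. Observed behavior at defaults:
2× refinement moves C(0) by 0.03%, doubling the outer boundary moves it
by < 1%, global generation/removal balance closes to 0.1%, and a thin
annular source reproduces the analytic point kernel to 0.3%. The
reference hotspot (R = 0.3 µm, s = 50 µm⁻² s⁻¹) gives
C(0) = 12.56 µm⁻² ≈ 2.5 µM in the 80 Å slab, vs 12.5 claimed at
unspecified mesh/domain — agreement assessed at ±10%.

The spatial model deliberately uses first-order Gβγ decay rather than
the full binding kinetics in space; it is a linear model (C is exactly
proportional to s), so superposition over hotspots is valid.

## Synthetic traces and the inverse problem

The generator scales the GIRK·βγ₄ trajectory (the quantity compared to
measured currents; no conductance model) and adds i.i.d. Gaussian noise;
everything is reproducible from the seed. It emulates the step response
and noise amplitude of agonist-evoked recordings but not cell-to-cell
kinetic variability, drift, autocorrelated noise or series-resistance
artifacts — a green recovery test therefore establishes the estimator's
self-consistency at the stated noise model, not robustness to real
recordings. The default noise level in studies is 5% of the plateau.

`fit_k12` is bounded least squares over (log₁₀ k12, scale) with bounds
[ref/1000, ref×100]; the scale is profiled out analytically. For speed
the forward map is cached on a 40-points-per-decade log₁₀ k12 grid
shared across bootstrap resamples and replicates; the point estimate is
then refined by a bounded scalar search using exact ODE solves, while
the 200 residual-bootstrap refits use the cached grid with parabolic
interpolation around the argmin (grid quantization ≈ 0.025 dex, well
below the sampling noise it propagates). Percentile intervals are
reported; the interval is widened to include the point estimate if
resampling skews past it. A flatness flag fires when the curvature of
the normalized loss profile in log₁₀ k12 falls below 10⁻³ — the
saturated regime where the steady response plateaus and k12 is only
weakly identified (observed for true k12 ≳ 10× the Gi reference;
there bias and RMSE grow accordingly). Calibration at the defaults
(50 replicates, 5% noise): median relative bias < 2.5%, 95% interval
coverage 94–98%.

## Numerical and design choices, summarized

- Exact layer factor everywhere; the printed "0.2 µM per µm⁻²" is a
  rounded display value only.
- Steady states by integration, not Newton; robustness over speed.
- Zero-Dirichlet far boundary at max(10λ, 10R), validated by the
  boundary-doubling insensitivity check rather than fixed a priori.
- Parameter JSON echoes the canonical symbol names (k12…k65, mu) with an
  explicit units block, because unit confusion is the dominant failure
  mode in this model family.
- No stochastic (molecule-number) simulation, no receptor
  desensitization or RGS acceleration, no time-dependent diffusion, no
  non-circular hotspots.
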