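# Methods

## Data model and units

A solubility point is (T [K], P [MPa], ρ_CO₂ [kg/m³], y₂, sd(y₂)), with
an informational g/L column. Internally all thermodynamic computation is
SI (Pa, K, m³, mol); MPa and g/L appear only at I/O boundaries, and the
pressure inside the Bartle/MST products y·P is expressed in bar
(P_ref = 1 bar, ρ_ref = 700 kg/m³), the prevailing convention for those
correlations. CO₂ densities are *data*, never computed from (T, P): the
bundled grid carries the measured densities, and synthetic grids carry
user-supplied ones, so every fitting stage treats density identically.

The bundled sumatriptan dataset (28 points, 4 isotherms × 7 pressures)
is shipped as plain CSV with a provenance note
(`src/scfsol/data/PROVENANCE.md`) documenting three transcription
decisions: temperatures stored as 308.2/…/338.2 K, one run-together
pressure field read as 30 MPa, and one physically impossible duplicated
density corrected by a single digit. The note also documents that the
informational g/L column is not exactly reproducible from the printed
mole fractions on the low-pressure rows; the mole-fraction column is the
single source of truth for all fits.

## Density-based correlations

Four three-parameter forms (Chrastil, Bartle, MST, K-J) are fitted with
two objectives:

- `aard` (default): minimize mean |y_calc − y_exp|/y_exp. This matches
  the statistic the models are ranked by, and is the objective used for
  every reported number.
- `sse_log`: ordinary least squares in each model's linearized space
  (closed form), provided because much of the literature fits in log
  space.

The AARD objective is non-smooth, so the optimizer is a Nelder–Mead
simplex restarted from a fixed 8-point grid of multiplicative
perturbations around the linearized least-squares solution. No random
numbers are involved; repeated fits agree bitwise, and fits are invariant
to row order.

Enthalpies follow the sign convention ΔH = −R × (coefficient of 1/T),
which yields positive (endothermic) ΔH_total ≈ 41 kJ/mol and
ΔH_vap ≈ 60 kJ/mol for this system and ΔH_sol = ΔH_total − ΔH_vap ≈
−19 kJ/mol (exothermic solvation) — consistent with the magnitudes the
enthalpies are known to take here, whereas the opposite convention would
flip all signs. Statistics (R², adjusted R²) are computed on the linear
y scale for every model, including those fitted in log space, so
cross-model comparison uses one ruler; n_params is 3 for density models,
2 for cubic-EoS isotherm fits, 1 for PC-SAFT isotherm fits.

The MST self-consistency transform plots T·ln(y₂P) − a₂T against ρ;
under the MST form this is a₀ + a₁ρ, so consistent data collapse onto a
straight line across isotherms (fixture R² ≈ 0.98). The crossover is
reported as the grid interval where the Spearman correlation of y with T
flips sign — (15, 18) MPa for the bundled data. An interpolated point
would overstate what a 7-pressure grid can resolve. (The crossover is
sometimes quoted for this system as 12–15 MPa, but the tabulated data
place the inversion between 15 and 18 MPa; the package reports what the
data show.)

## Solute properties and sublimation pressure

Sumatriptan's critical constants (T_c = 1160.3 K, P_c = 3.39 MPa,
ω = 0.647, T_b = 830.5 K) are group-contribution estimates taken as
given, with solid molar volume 305.2 cm³/mol. The sublimation pressure is
a Clausius–Clapeyron line, ln P_sub linear in 1/T through the two anchors
(308.2 K, 2.88e-8 Pa) and (338.2 K, 3.45e-6 Pa); interior temperatures
interpolate on that line (the one non-printed input to the 318.2/328.2 K
EoS regressions), and extrapolation beyond the anchors ± 5 K is refused.
Note an internal tension carried without adjustment: the anchor slope
implies ΔH_sub ≈ 138 kJ/mol, while the Bartle-derived value is
≈ 60 kJ/mol; both are reported as what they are.

CO₂'s acentric factor (0.225) is a standard literature value — a
non-measured input, pinned in config.

## Cubic equations of state

PR and SRK are implemented as the generic two-parameter cubic
P = RT/(v−b) − a/((v+δ₁b)(v+δ₂b)). vdW2 mixing applies quadratic
composition rules to both a and b, so the covolume is
composition-dependent and the fugacity expression uses the partial-molar
forms ā_i = 2Σⱼ yⱼa_ij and b̄_i = 2Σⱼ yⱼb_ij − b_m. The closed-form
ln φ_i was derived from the residual-Helmholtz route and is verified in
the tests against an independent adaptive-quadrature evaluation of the
pressure-derivative volume integral (agreement ≲ 1e-12; asserted at
1e-8), plus a Gibbs–Duhem check.

Roots of the cubic in Z: all real roots > B are found; with several
candidates the root minimizing the mixture residual Gibbs energy
Σ yᵢ ln φᵢ is selected — unambiguous and standard.

The solid solubility solves the isofugacity fixed point
y₂ = (P_sub/P)(1/φ₂)exp[v_s(P−P_sub)/RT] (solute saturated-vapor
fugacity coefficient taken as 1, justified by the tiny P_sub) starting
from y₂ = 1e-8, relative tolerance 1e-10, max 200 iterations, with the
damping factor halved whenever the update direction oscillates or the
step grows. (k_ij, l_ij) are regressed per isotherm by direct AARD
minimization with deterministic multi-start Nelder–Mead from a fixed 5×5
grid inside [−1, 1]²; the 338.2 K l_ij presses against the −1 bound, as
the large reported magnitudes (−0.81/−0.94) already suggest.

## PC-SAFT

Non-associating PC-SAFT: hard-chain (Boublík–Mansoori hard-sphere
mixture + site–site contact correlation) plus second-order dispersion
with the published universal constant tables and C₁ correction;
temperature-dependent diameter d = σ(1 − 0.12e^{−3ε/kT}); conventional
combining rules σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_iε_j)(1−k_ij). The
association term is omitted — no association parameters exist for this
system and the solute/CO₂ pair is treated as non-associating.

All derivative quantities (Z = 1 + η ∂ã/∂η, and the composition
derivatives in ln φ_k) are obtained by **complex-step differentiation**
of the single residual-Helmholtz implementation: the step (h = 1e-20)
incurs no subtractive cancellation, so the derivatives are exact to
machine precision while staying structurally identical to the energy
itself. The test suite checks them against real central differences of an
independently coded loop-based re-implementation of ã_res (double-entry
bookkeeping), against mole-number differences of the total residual
Helmholtz energy for ln φ, and against Gibbs–Duhem.

The density solver brackets all packing-fraction roots of
P_calc(η) = P on a fixed scan grid (η ∈ (1e-11, 0.72)) and refines by
Brent's method; a phase hint (or minimum mixture Gibbs energy, for
fugacities) selects among multiple roots. Inside the solubility fixed
point the solve is warm-started from the previous iteration's η by a
guarded secant refinement — an accelerator only, with fallback to the
full scan. With literature CO₂ parameters (m = 2.0729, σ = 2.7852 Å,
ε/k = 169.21 K — non-measured inputs) the model reproduces the measured
CO₂ density at 308.2 K / 30 MPa within ~1.3%.

**Solute parameters.** No regressed PC-SAFT parameter set for sumatriptan
is available. The shipped default (m = 5.5, σ = 3.8 Å, ε/k = 250 K) is a
synthetic calibrated stand-in: values in the typical range for rigid
drug-like organics, chosen once so that the regressed per-isotherm k_ij
reproduces the reported qualitative behaviour — negative and decreasing
with temperature (≈ −0.150 → −0.165 across 308.2–338.2 K). With a
stand-in solute the per-isotherm AARD (~40–60%) is not meaningful as a
measure of PC-SAFT's correlation quality and is far above what fitted
solute parameters achieve; users with better parameters should supply
them via config. k_ij is regressed per isotherm over [−0.5, 0.5] by
seeded differential evolution followed by a Nelder–Mead polish; the
polished optimum is seed-independent to well below 1e-6.

## Synthetic data

Generators wrap any forward model (density correlation, cubic EoS,
PC-SAFT). Noise is multiplicative lognormal, y_obs = y_true·e^ε with
σ = √(ln(1+rsd²)), so the relative standard deviation equals the nominal
`noise_rsd` and positivity is preserved for solubilities spanning an
order of magnitude. The default noise_rsd = 0.03 emulates the replicate
reproducibility of careful gravimetric measurements (RSD below 5%). The
generator emulates the *statistical* structure of the data only: state
points are error-free, noise is uncorrelated across points, and the
measurement chain (balance error, CO₂ retention, equilibration kinetics)
is not simulated — so recovery tests demonstrate estimator correctness
under the assumed noise model, not robustness to instrument systematics.

Recovery experiments use fixture-scale coefficient magnitudes as truth.
At 3% noise on the 28-point grid, 200 replicate fits per model give
median coefficient biases below 0.5% (asserted < 3%).

## Problem sizes and numerical defaults

Reported analyses use the full 28-point dataset; oracle-equivalence and
derivative checks use 100 random states each; the replicate-noise
recovery uses 200 datasets per model. Fixed-point tolerance 1e-10
(relative), density-solve residual ≲ 1e-8·P, simplex tolerances 1e-6 to
1e-10 depending on stage. All optimizers are deterministic or explicitly
seeded; reports are byte-reproducible from (dataset, config, seed).

## Known limitations

- Pure CO₂ density from PC-SAFT carries the model's own ~1–2% error; the
  package therefore never substitutes computed densities for measured
  ones.
- The cubic-EoS regressions bound, rather than match, any previously
  reported per-isotherm deviations: the regression objective used to
  produce published tables is rarely stated, so an AARD-minimizing refit
  can only do as well or better.
- No uncertainty quantification on fitted parameters (no bootstrap), no
  information criteria, no cosolvent/ternary systems, no association or
  polar PC-SAFT variants, no volume-translated cubics or advanced mixing
  rules.
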