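# Model and methods

## The model

`rodcascade` implements a globally well-stirred (single-compartment)
deterministic model of the mouse rod photoresponse, built to study the
*saturation* regime: flashes bright enough to close essentially all CNG
channels, analysed through the Pepperberg plot (time in saturation T_sat
against ln of flash strength Φ).

State variables (all volumetric concentrations in µM referred to the
outer-segment cytosolic volume `V_cyt`):

* `cg` — free cGMP; `ca` — free Ca²⁺;
* `r_1 … r_{n+1}` — photoexcited rhodopsin R\* in its phosphorylation
  states (state *j* carries *j−1* phosphates; state *n+1* is
  arrestin-quenched and inert);
* `T, T*` — inactive/active transducin; `E` — free PDE catalytic
  subunits; `T*--E` — the active transducin–effector complex;
  `RGS9`, `RGS9--T*--E` — the GTPase-accelerating complex, free and
  engaged.

Reactions:

* **Activation.** A flash is an instantaneous jump of `r_1` by Φ (converted
  to µM). Each R\* state activates transducin at rate ν_j·(T/T₀)
  (default ν_j ≡ ν_RT); T\* binds a free effector subunit at rate
  k_TE·E·T\*.
* **R\* shutoff.** States advance at Ca²⁺-dependent phosphorylation rates
  λ_j(Ca) = λ_j,max · [RK]/[RK]_tot, where the free-kinase fraction follows
  from the two-Ca²⁺ recoverin equilibrium (a quadratic in free recoverin,
  solved in closed form with the stable root formula). Arrestin caps states
  with ≥ 3 phosphates at the Ca²⁺-independent rate µ_max.
* **T\*--E shutoff.** RGS9 binds T\*--E at k_f, dissociates at k_b, and
  triggers GTP hydrolysis at k_cat, returning T and E to their basal pools.
  An effector subunit is counted as catalytically active (E\*) while
  complexed with T\*, *including* while RGS9-bound: only the k_cat step
  ends hydrolysis. (This is the only reading under which the E pool is
  conserved by the reaction scheme; a toggle is deliberately not offered.)
* **Messengers.** d[cGMP]/dt = α(Ca) − k_hyd(E_tot−E\*)·cg −
  k_σ,hyd·E\*·cg with a two-component, GCAP1/GCAP2-weighted Hill form for
  the cyclase rate α(Ca); d[Ca²⁺]/dt = η(½f_Ca·J_cG − J_ex) with
  η = (B_Ca·F·V_cyt)⁻¹. The CNG current is a Hill function of cGMP whose
  affinity K_cG(Ca) is calmodulin-modulated between K_cG_min (13 µM) and
  K_cG_max (32 µM); the exchanger current is Michaelis in Ca²⁺.

A **simplified variant** replaces the RGS9 scheme with first-order E\*
decay at rate k_E = 1/τ_E\*; it serves as a validation target — in the
irreversible-binding, fast-hydrolysis limit (k_b → 0, k_cat ≫ k_f·RGS9₀)
the full model converges to it with k_E = k_f·RGS9₀ (tested).

### Units

Everything is referred to `V_cyt` (default 18 µm³). One molecule in
`V_cyt` is 1/(602.214·V_cyt) µM; volumetric catalytic rates (µm³ s⁻¹ in
the parameter file) convert to µM⁻¹ s⁻¹ by the factor 602.214. Currents
convert to concentration fluxes through η; Faraday's constant is fixed at
96 500 C mol⁻¹.

## Saturation analysis

`measure_tsat` reports the first time the total photocurrent
J = J_cG + J_ex rises back through a criterion fraction of the dark
current after the response minimum, localized by root-finding on the
solver's dense interpolant (not on the step grid). Under the
instantaneous-flash idealization, "mid-flash" and "flash-onset" origins
coincide at t = 0; both are accepted and recorded. For finite experimental
flashes (10–20 ms) this idealization shifts T_sat by about half the flash
width — far below the tolerances used anywhere here.

`fit_linear` regresses T_sat on lnΦ inside a window whose default is
[just-saturating lnΦ + 0.5, 8.0]; the upper edge reflects the empirical
limit of linearity (a few thousand photoisomerizations). The slope
estimates the dominant shutoff time constant τ_D ≈ τ_E\*; the X-intercept
estimates lnΦ₀, the just-saturating flash strength.

`curve_shape` characterizes departures from linearity: local slopes by
centered differences (adjacent-point secants for the maximum), bend onset
where the local slope exceeds the fitted τ_D by 20%, plateau where it
falls below 5% of its own maximum. Both thresholds are configurable
defaults; the data do not dictate unique values.

### Closed-form theory

With cGMP and Ca²⁺ quasi-steady during saturation, the exit state
(cg_sat, ca_sat) solves (1+½f_Ca)·J_cG = ε·J_max together with the Ca²⁺
flux balance ½f_Ca·J_cG = J_ex (ε default 0.02). The characteristic
effector level at exit is E\*_char = (α − k_hyd·E_tot·cg_sat)/(k_σ,hyd·cg_sat),
with α evaluated at ca_sat by default (the strict α_max limit is exposed as
a variant; for the defaults they differ by < 5%). With the lumped
activation gain ν_RE (derived from the front end as ν_RT times the
T\*→T\*--E coupling efficiency, ≈ 0.996 here) and τ_R\* = 1/λ₁ at
saturation Ca²⁺, the theory gives Φ₀ = E\*_char/(ν_RE·τ_R\*) and
T_sat = τ_E\*·ln(Φ/Φ₀). The un-approximated two-exponential crossing is
solved numerically for comparison; it agrees with the logarithmic form to
≪ 2% for τ_R\* ≪ τ_E\*.

## Numerical choices

* **Integrator.** LSODA with finite-difference Jacobian, rtol 1e-8, and a
  per-species absolute tolerance of 1e-12 times each species' scale. The
  cascade spans rates from ~0.01 s⁻¹ to ~10³ s⁻¹, so a stiff method is
  required; halving the tolerances moves measured T_sat by < 0.5 ms
  (tested). Dense output is kept for criterion-crossing localization.
* **Steady states.** The dark state and the saturation exit state reduce to
  scalar root-finds (monotone residuals), solved by Brent's method to near
  machine precision; the dark-state full-RHS residual is verified < 1e-10.
* **Recoverin quadratic.** Solved with the cancellation-free quadratic
  formula; for positive parameters exactly one root lies in [0, 1]
  (sign argument; property-tested against bisection at 1e-10).
* **Determinism.** There is no randomness anywhere; rerunning any protocol
  reproduces output bitwise.

## Parameter defaults and calibration

The defaults describe a wild-type mouse rod. Fixed, well-established
values (channel affinities 13/32 µM, GCAP Ca²⁺ K_1/2 of 47/133 nM, f_Ca,
collecting area 0.45 µm², n = 6 phosphorylation sites, dark hydrolysis
rate ~4 s⁻¹, E₀ from PDE content) are marked `[lit]` in the parameter
file. The remaining constants are marked `[cal]`: they were chosen inside
published mouse-rod ranges and then jointly calibrated so that the full
pipeline reproduces the measured saturation behaviour of wild-type and
mutant rods — a WT Pepperberg slope near 0.38 s; slopes near 0.21/0.19 s
at 2×/4× RGS9 expression; criterion-study X-intercepts near lnΦ 5.3 (2%)
and 3.3 (20%); a WT plateau appearing only beyond lnΦ ≈ 15; and a maximal
local slope near 4 s for the 0.1× PDE mutant. Flash-strength grids for the
scripted protocols are 11–19 log-spaced points spanning each protocol's
range, recorded explicitly in the recipe definitions.

The mutant presets scale or replace only the fields their biology touches:
RGS9 expression scales RGS9₀; kinase mutants scale all λ_j,max by 3;
GCAP2 knockout reduces α_max to 40% and sets the remaining K_1/2 to 47 nM;
full GCAPs knockout freezes the cyclase at the parameter set's own dark
rate (preserving dark current while removing feedback); the
calmodulin-null channel pins K_cG at 13 µM; PDE expression scales E₀
(basal hydrolysis follows automatically); recoverin knockout sets
Rec_tot = 0, which collapses the RK equilibrium to "all kinase free".

## What the simulations do and do not show

The simulator *is* the data generator: all protocols are in-silico flash
series from the dark-adapted state. Passing tests therefore demonstrate
internal consistency of the model and agreement with published summary
numbers, not agreement with raw electrophysiology. Real recordings add
finite flash durations, photoreceptor-to-photoreceptor variation in
collecting area and expression levels, recording noise, and slow
light-adaptation processes — none of which are modeled.

## Known limitations

* **0.2× RGS9 expression.** With shutoff kinetics matched to the 1×/2×/4×
  expression series, the linearized shutoff eigenvalue at 0.2× expression
  is necessarily ≈ 1.7–1.9 s (the eigenvalue family is concave in the
  expression scale), and the simulated fitted slope lands there. Reported
  values near 0.8 s for strong RGS9 *under*expression cannot be produced
  by scaling RGS9 content alone in this reaction scheme; reproducing them
  would require an additional mechanism (or per-line kinetic differences)
  that the model deliberately does not include.
* **Criterion-invariance of the slope.** The fitted slope at a 2% criterion
  exceeds the 20%-criterion slope by ~5–6% here, not < 1%: the shallow
  criterion samples the E\* decay within ~1.5 e-folds of its peak, where a
  fast decay mode still contributes. Forcing exact invariance would require
  an exit-state effector level nearly an order of magnitude smaller, which
  pushes channel/cyclase constants outside physiological ranges.
* Bleaching-range phenomena (photoproduct activity, regeneration), spatial
  cGMP/Ca²⁺ gradients, stochastic single-photon variability, and flash
  trains/steps are out of scope.
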