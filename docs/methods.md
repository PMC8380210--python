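# Methods

## Model structure and assumptions

The simulator predicts the tumor concentration of a residualizing radiolabel
(e.g. ⁸⁹Zr) carried by a monoclonal antibody, and its standardized uptake
value (SUV), from eight ordinary differential equations: plasma and
remainder-of-body amounts for a labeled and an unlabeled antibody species,
interstitial amounts of both in a single tumor, the free-target
concentration, and the residualized label.

Assumptions, and what they imply:

- **Identical kinetics for labeled and unlabeled antibody.** Labeling does
  not alter disposition, so all amounts of the two species stay in the fixed
  ratio of their injected doses. This is asserted as a regression property
  (relative tolerance 10⁻⁶).
- **Shared binding equilibrium.** The *combined* interstitial concentration
  of both species competes for target; a single unbound fraction f_u applies
  to both. The interstitial term of the target balance therefore uses the
  summed amount Xi,l + Xi,u.
- **Quasi-equilibrium binding.** Association/dissociation are fast relative
  to transport and turnover, so bound antibody is the physical root of the
  mass-action quadratic in the total antibody concentration A, target T and
  affinity K_D. Monovalent binding stoichiometry is assumed (one target per
  antibody); avidity effects are not modeled.
- **Residualizing label.** Internalized label never leaves the cell and the
  signal is decay-corrected, so no radioactive-decay bookkeeping is needed
  and Xr only accumulates. Internalization moves labeled antibody from the
  interstitial pool to Xr without changing the total tumor signal
  Xi,l + Xr directly — its influence on uptake is indirect, through freeing
  extravasation driving force and consuming target.
- **Concentration-gradient extravasation.** Transfer between plasma and
  interstitium is first-order in the difference between plasma concentration
  and the *unbound* interstitial concentration f_u·Xi/(ivf·V_t), with a
  single lumped rate constant k_ev combining permeability and
  vascularization. The reverse term also appears in the plasma balance even
  though V_t/V_p ≈ 3·10⁻⁴ makes it negligible for a 1 mL tumor: fidelity
  over simplification.
- **Two-compartment plasma PK.** The systemic driver is a standard central
  compartment with exchange (k₁, k₂) and first-order clearance (k_cl). The
  tumor is too small to perturb it measurably.

## Parameters

| key     | meaning                                   | unit  | default |
|---------|-------------------------------------------|-------|---------|
| pvf     | tumor plasma (vascular) volume fraction   | —     | 0.04    |
| ivf     | antibody-accessible interstitial fraction | —     | 0.2     |
| k_ev    | extravasation rate constant               | h⁻¹   | 0.012   |
| T0      | initial target concentration              | nM    | 0       |
| KD      | equilibrium binding affinity              | nM    | 5       |
| k_syn   | target synthesis rate                     | nM/h  | k_deg·T0 (derived) |
| k_deg   | target degradation rate                   | h⁻¹   | 0.19    |
| k_int   | complex internalization rate              | h⁻¹   | 0.19    |
| ID_l_mg | injected labeled antibody mass            | mg    | 3       |
| ID_u_mg | injected unlabeled antibody mass          | mg    | 47      |
| MW      | antibody molar mass                       | g/mol | 150 000 |
| k1, k2  | plasma↔normal-tissue exchange rates       | h⁻¹   | 0.0722, 0.1366 |
| k_cl    | plasma clearance rate                     | h⁻¹   | 0.0083  |
| V_p     | plasma volume                             | L     | 3       |
| V_t     | tumor volume                              | L     | 0.001   |
| BW      | body weight                               | kg    | 80      |

Units are hours, nmole, nM and litres throughout; SUV is dimensionless under
the usual tissue-density-1 g/mL convention (nM ≈ nmol/kg). The molar mass is
not part of the published parameter table; 150 kg/mol is the standard IgG
approximation. It converts the mg doses to nmole and therefore sets where
dose-driven target saturation occurs, but cancels out of SUV in the linear
(target-free) regime. All scalar readouts default to 120 h post-injection,
the standard late imaging time point.

With the default k_int = k_deg, the complex-removal term of the target
balance cancels and T(t) ≡ T0 exactly — the target level is a true constant
of the default model, which the suite asserts.

## Numerical choices

- **Unbound fraction.** The quadratic root is evaluated in the conjugate
  form f_u = 1 − 2T/(s + √(s² − 4AT)), s = K_D + T + A, which avoids
  catastrophic cancellation when A ≫ T or T ≫ A (both occur in the
  concentration sweeps) and yields the correct continuous limit
  K_D/(K_D + T) as A → 0 with no special-casing (at A = 0 the printed
  quadratic is 0/0; the limit is what multiplies the zero fluxes anyway).
  A property test checks it against an independent scalar root finder on
  the mass-action fixed point across nine decades of A and T.
- **Integration.** `scipy.integrate.solve_ivp` with LSODA, rtol 10⁻⁸,
  atol 10⁻¹⁰ nmole; the system becomes mildly stiff for large k_ev with
  high target. Agreement with an independent fixed-step classical
  Runge–Kutta integration at 0.01 h steps is asserted to 10⁻⁴ relative on
  SUV(120 h) for target-free, intermediate and saturated scenarios.
- **Negative-state guard.** Solver excursions a few ulp below zero are
  clamped before the binding equilibrium (square-root domain safety);
  states are clamped once more in the returned trajectory.
- **Biexponential fitting** is done in log-concentration space (multiplicative
  error across orders of magnitude), with positivity enforced by a
  log-parameterization and starting values from curve stripping (terminal
  phase from the tail third of the samples, fast phase from the stripped
  residual). Non-positive concentrations are dropped; fewer than five usable
  samples (one residual degree of freedom for the 4-parameter model) is an
  error.
- **Macro↔micro conversion.** k₂ = (Aβ + Bα)/(A + B), k_cl = αβ/k₂,
  k₁ = α + β − k₂ − k_cl — the unique inversion for this model topology; the
  reverse direction is the eigen-decomposition of the 2×2 rate matrix. The
  round trip is exact to 10⁻⁶ (property-tested over random rate sets); a
  near-degenerate α ≈ β triggers an ill-conditioning warning.
- **Inverse extravasation rate.** SUV(120 h) is monotone increasing in k_ev,
  so the inverse is a bracketed scalar root (Brent's method, relative
  tolerance 10⁻⁶, asserted round-trip accurate to 10⁻⁴ over
  k_ev ∈ [10⁻⁴, 0.05] h⁻¹). Requests below the vascular-only floor
  (k_ev = 0, SUV = pvf·SUV_plasma) are rejected as infeasible rather than
  returning a boundary value.
- **IHC banding.** The published concentration bands touch at 30, 120 and
  590 nM; intervals are taken left-closed/right-open so every concentration
  has exactly one class.
- **Sensitivity coupling.** The synthesis rate is by default a derived
  quantity (k_syn = k_deg·T0, the pre-dose steady state), so perturbing T0
  or k_deg re-derives it; an uncoupled mode freezes k_syn at its baseline
  instead. Perturbation is one-sided (+10%) by design — no central
  differences — and zero-valued parameters are reported as not assessable
  rather than silently skipped. The "tumor/target" and "systemic driver"
  parameter scopes are exposed separately, because the systemic scope is
  trivially sensitive (body weight enters SUV exactly linearly).
- **Dose–response grid.** 60 log-spaced points over [0.1, 1000] nM plus the
  target-free point: enough to resolve the rising limb (~1–50 nM) and the
  plateau with one simulation per point.

## Synthetic plasma fixtures

`generate_pk_fixture` emulates digitized literature plasma curves: log-spaced
sample times over 1–240 h and multiplicative lognormal noise with a chosen
coefficient of variation, deterministic per seed. It reproduces the sampling
geometry and error structure of digitized decay data, but not digitization
artifacts (plot-reading bias, axis-calibration error) or true inter-patient
variability — passing the calibration tests shows the fit machinery recovers
known macro rates from data of that shape, not that any specific published
curve is matched.

## Expected behavior and known limitations

Three regimes organize every output. With no target, uptake equilibrates to
roughly (pvf + ivf) times the plasma signal and then tracks plasma decline;
the simulated 120 h tumor/plasma ratio (≈ 26%) sits slightly above the
static sum pvf + ivf = 24% because the interstitial pool relaxes at rate
k_ev/ivf toward a plasma curve that is itself decaying at the terminal rate
β — the closed-form lag factor (k_ev/ivf)/(k_ev/ivf − β) ≈ 1.10, which the
unit suite checks against the simulation. In target excess, every
extravasated antibody binds and is retained, uptake is extravasation-limited
and near-linear in k_ev (a +10% perturbation moves SUV(120 h) by +9.8%), and
no other target parameter moves it by even 0.01%. In between, SUV rises with
target concentration up to roughly 50 nM and plateaus above it, which is
what limits immuno-PET's ability to grade expression rather than merely
detect it.

Not modeled: radioactive decay (readouts are decay-corrected SUVs), image
formation and partial-volume effects, spatial gradients within the tumor
(the interstitium is well-mixed; no penetration barrier), antigen sinks or
other target-mediated plasma clearance, multiple lesions, and bivalent
avidity. The plasma PK is an input — predictions for a different dose or
antibody require supplying the corresponding two-compartment rates, for
which the fitting path exists.
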