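# Methods

`ncrfit` quantifies the catabolic energy cost of microbial growth from
black-box chemostat data.  This note documents the model, its assumptions,
the numerical choices, what the synthetic generator does and does not
emulate, and known limitations.

## The model

### Exchange vector

Each steady-state chemostat experiment is summarized by an exchange vector
`e = (e_0, …, e_n)` with biomass at index 0.  All entries are per carbon-mole
of biomass formed: C-mol (C-mol X)⁻¹ for carbon-containing compounds and mol
(C-mol X)⁻¹ for carbon-free compounds (O₂).  Consumption is negative, so
`e_0 = +1` always and the substrate entry is negative.  Volumetric rates
(mol L⁻¹ h⁻¹) are converted by dividing by the biomass C-molar concentration
times the dilution rate, then multiplying carbon species by their carbon
count.

### Route basis

Growth is decomposed onto a convex basis of chemically explicit conversions,
all expressed per C-mol so they compose directly with `e`:

* **Catabolic product routes** `v_1 … v_k`, one per observed catabolic
  product.  These are biochemical, not algebraic, choices (glucose → 3
  acetate is elementally balanced too); the bundled registry ships the
  classical conversions (respiration, acetate overflow, ethanol, lactate,
  mixed-acid formate/acetate/ethanol, glycerol, succinate, pyruvate, ethanol
  → acetate) as data, each validated at load for full elemental balance and
  degree-of-reduction electron balance.  Users can register additional
  routes; unbalanced ones are rejected with per-element residuals.
* **The respiration route** (complete oxidation): per C-mol of substrate
  with degree of reduction γ_S, `−1 S − γ_S/4 O₂ + 1 CO₂ + H/(2C) H₂O`.
* **The idealized anabolic route** `v_0`, normalized to +1 C-mol biomass.
  With γ_X the biomass degree of reduction: if γ_X > γ_S, the electron
  deficit is met by oxidizing extra substrate carbon,
  `(γ_X/γ_S) S → X + (γ_X/γ_S − 1) CO₂`; if γ_X < γ_S, oxygen accepts the
  surplus, `S + ¼(γ_S − γ_X) O₂ → X` (this presumes aerobic growth —
  anaerobic growth on a substrate more reduced than biomass is rejected);
  if equal, `S → X`.  The maximal theoretical carbon yield is
  min(1, γ_S/γ_X).  The anabolic route is carbon- and redox-balanced but
  deliberately ignores N/P/S balances (they would require explicit nutrient
  uptake terms that black-box data cannot constrain).

Degrees of reduction use the classical valence weights C = +4, H = +1,
O = −2 with the nitrogen weight set by the nitrogen source of growth
(−3 for ammonia, +5 for nitrate, 0 for dinitrogen), so CO₂, H₂O and the
nitrogen source have γ = 0 exactly.  Sulfur and phosphorus are excluded from
γ by default: biomass S/P contents are small and no standard convention
exists for them; fit reports carry a `gamma_excludes_SP` flag.

### Fit

Non-negative coefficients minimize the residual squares over the measured
axes only,

    min_{α ≥ 0}  Σ_j ( e_j − Σ_i α_i v_{i,j} )²,

a convex non-negative least-squares problem solved with the deterministic
active-set algorithm of `scipy.optimize.nnls` (global minimum; no
randomness).  Routes whose projections on the measured axes are parallel are
rejected by name rather than silently splitting α between them.  Optional
per-measurement weights are supported; the default objective is unweighted.
Unmeasured species (H₂O, sometimes CO₂) are reconstructed afterwards from
the full route stoichiometries.

The fitted combination, normalized to one C-mol of biomass
(`m_j = Σ_i α_i v_{i,j} / Σ_i α_i v_{i,0}`, so `m_0 = 1` exactly), is the
balanced macrochemical growth equation.  Subtracting the anabolic
contribution leaves the **net catabolic reaction (NCR)**
`v_NCR = Σ_{i≥1} α_i v_i / α_0` — a biomass-free, fully mass-balanced
conversion per C-mol of biomass formed.

### Catabolic Gibbs energy

ΔG_X/S is the reaction Gibbs energy of the NCR: with mole-based coefficients
ν (C-mol entries divided by carbon counts),

    ΔrG'° = Σ ν·ΔfG'°,      ΔG_X/S = ΔrG'° + RT Σ_solutes ν·ln(c/1 M).

Formation energies are standard transformed values (pH 7.0, ionic strength
0.25 M, Mg²⁺ 1 mM, 298.15 K) shipped as a versioned, provenance-tagged
fixture assembled from component-contribution estimates via well-known
anchor reactions (glucose combustion −2930.5, ethanol fermentation −224.9,
homolactic fermentation −189.5, acetate overflow −1195, ATP hydrolysis
−26.5 kJ mol⁻¹, with the absolute gauge fixed by the H₂O/O₂/CO₂ entries).
Only differences along balanced reactions are meaningful, and the
reaction-energy evaluator refuses elementally unbalanced input, so ΔG_X/S is
only ever reported for mass-balanced conversions.  Internal-consistency
checks (per-electron combustion energies, redox couples, Hess additivity)
run in the test suite.

Conventions: water at activity 1; dissolved gases treated as solutes at the
default 1 mM like everything else; one decade of concentration change of one
species shifts ΔrG by RT·ln10 = 5.708 kJ mol⁻¹ at 298.15 K — the scale of
the error made by not knowing real extracellular concentrations.  Dataset
temperature and pH enter the context (the RT terms use the dataset
temperature), but no Legendre re-transform of ΔfG'° across T/pH/I is
attempted; evaluations away from 298.15 K are flagged in the result notes.
Group-contribution uncertainty is systematic across datasets and is not
propagated.

ΔG_X/S is additionally partitioned into the **respiratory component**
(the complete-oxidation route's share, `α_resp·E(v_resp)/α_0`) and the
non-respiratory remainder; by Hess's law the two sum exactly to the total.

### Carbon-recovery error bracket

Real datasets have carbon recovery ≠ 100%.  The mismatch
δ = |measured| − |fitted| substrate uptake (both per C-mol biomass, the
fitted value from `m`) is corrected under two extreme assumptions:

* **to biomass** — the missing carbon formed biomass via the anabolic route
  (the only biomass-forming conversion the model defines).  Adding
  λ = δ/|v_{0,S}| units of `v_0` leaves the NCR unchanged but renormalizes
  it to (1 + λ) C-mol biomass: ΔG → ΔG/(1 + λ), smaller in magnitude.
* **to respiration** — the missing carbon was completely respired:
  ΔG → ΔG + δ·E(v_resp), larger in magnitude.

The same formulas run in reverse when the fitted uptake exceeds the measured
one.  The bracket `[lower, upper]` is the two extremes in numerical order;
it always contains the point estimate and collapses to it at 100% recovery.
Degenerate case: if the mismatch exceeds the entire anabolic consumption
(possible in noisy high-flux data; the corrected biomass would be ≤ 0), the
biomass-side extreme diverges and is reported unbounded (`null` in JSON).
Datasets without measured gas exchange cannot support the correction at all;
their bracket is marked unavailable.

An alternative bracket based on the raw substrate-row residual (before
biomass normalization) was evaluated and found badly miscalibrated on
synthetic data (coverage far below nominal), because the dominant error in
the point estimate is exactly the normalization component that the
`m`-based mismatch captures; the `m`-based definition is therefore used.

## Synthetic data generator

The generator emulates what the analysis assumes about chemostat data: a
steady-state exchange vector composed from known route coefficients α*,
independent multiplicative Gaussian noise (relative σ, default 0.02) on
every measured flux except the biomass reference row, and a carbon-recovery
distortion factor multiplying the substrate row only (recovery mismatch in
practice shows up as substrate uptake the balanced fit cannot absorb).  All
randomness flows through an explicit seed; regeneration is byte-identical.

It does **not** emulate: kinetic/dynamic chemostat behavior (steady state
only), correlated measurement errors (e.g. shared off-gas calibration),
systematic biases other than the substrate-row distortion, pH/temperature
variation within a run, or products outside the bundled route registry.
Passing tests therefore demonstrate correctness of the estimator under the
stated error model, not robustness to structured real-world artifacts.

Twelve bundled presets span yeast-like (aerobic and anaerobic; C/N/P/S
limitation; ethanol overflow) and bacterium-like (aerobic; C/N/P/K
limitation; acetate overflow) scenarios.  The coefficients were chosen once
so that carbon-limited scenarios dissipate ≈330–370 kJ per C-mol biomass and
every anabolic limitation strictly more, up to ≈1550 kJ per C-mol for the
potassium-limited bacterium — the qualitative pattern and magnitude range of
published chemostat compilations.  Presets use 298.15 K (the constants'
reference temperature) and pH 7; real chemostats often run at 30 °C and
lower pH, which would only enter through the RT terms and a flagged note.

## Numerical choices

* Elemental balance tolerance 1e−9 absolute (inputs are exact rationals of
  measured reals); electron balance tolerance 1e−6 (γ arithmetic compounds
  a few more roundings); Hess additivity of the partition holds to 1e−9.
* NNLS is deterministic; noise-free synthetic data round-trips α, m, NCR and
  ΔG_X/S to better than 1e−9, and fits agree with an exhaustive two-stage
  grid-search oracle (step 1e−3) on 3-route instances.
* Compositions are stored per mole; per-C-mol views are computed on demand,
  never stored, so nothing can be normalized twice.
* Ties/degeneracies: identical route projections are an error, not a
  warning; an all-catabolic fit (α_0 = 0) refuses to normalize rather than
  dividing by zero; a CO₂ "substrate" is rejected (γ = 0, nothing to
  oxidize).

## Problem sizes

The test suite and the acceptance script run synthetic studies at modest
sizes chosen to characterize the estimator precisely while staying quick on
a laptop: 100-seed replicate sets for parameter-recovery and ordering
properties, 200 replicates for bracket calibration, and 60-replicate sweeps
for noise-monotonicity.  These sizes give binomial standard errors of a few
percent on coverage rates, adequate for the properties asserted.

## Known limitations

* The idealized anabolic route is an abstraction with maximal yield; real
  anabolism costs ATP, so ΔG_X/S lumps true catabolic demand with
  maintenance, futile cycling and transport costs — that empirical lumping
  is the point of the measure, but it means ΔG_X/S is not a pathway ATP
  yield and cannot discriminate between catabolic pathways with identical
  net conversions.
* Formation energies are fixed at the 298.15 K / pH 7 / I 0.25 M / 1 mM
  convention; no Legendre transform across conditions, no activity
  coefficients, no measured concentrations.
* Charge/proton bookkeeping is implicit in the pH-7 pseudoisomer convention;
  routes are written in neutral form and no proton balancing is attempted.
* The route registry is finite and biochemical; products without a
  registered route simply contribute residual (they are reported, not
  silently absorbed).
* Nitrogen-source redox enters only through the γ weight; ammonia oxidation
  or other lithotrophic electron donors are out of scope.
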