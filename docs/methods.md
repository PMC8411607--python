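# Methods

## Model structure and assumptions

The package implements a steady-state, leaf-level model of NADP-ME-type
C4 photosynthesis.  Net CO2 assimilation *A* must simultaneously satisfy
a bundle-sheath demand balance, *A* = *V*c − 0.5 *V*o − *R*d, and a
mesophyll supply balance, *A* = *V*p − *L* − *R*m, where the leak
*L* = *g*bs(*C*s − *C*m) couples the two compartments.  Standing
assumptions:

* steady state — PEP carboxylation equals C4-acid decarboxylation;
* HCO3⁻ leakage from the bundle sheath is negligible and carbonic
  anhydrase is non-limiting (PEPC is the rate-limiting mesophyll step);
* bundle-sheath O2 is set by a flux balance: O2 evolved by the fraction α
  of PSII in the bundle sheath leaves through the conductance
  *g*o = *a*o·*g*bs, so *O*s = α*A*/(*a*o *g*bs) + *O*m;
* electron transport is pooled leaf-wide and allocated by a fraction *x*
  to PEP regeneration, rather than compartmented per cell type;
* respiration splits as *R*m = 0.5 *R*d with *R*s = *R*d − *R*m.

Two limiting regimes are solved in closed form and combined by
*A* = min(*A*c, *A*j).

**Enzyme-limited.**  *V*p = min(*C*m*V*pmax/(*C*m + *K*p), *V*pr) and
RuBP-saturated Rubisco kinetics.  Substituting
*C*s = *C*m + (*V*p − *A* − *R*m)/*g*bs and the O2 balance into the
Rubisco equation gives a quadratic *aA*² + *bA* + *c* = 0 with

    a = α·Kc/(ao·Ko) − 1
    b = (Vp − Rm + gbs·Cm) + (Vcmax − Rd) + gbs·Kc(1 + Om/Ko)
        + (α/ao)(γ*·Vcmax + Rd·Kc/Ko)
    c = Rd[(Vp − Rm + gbs·Cm) + gbs·Kc(1 + Om/Ko)]
        − Vcmax[(Vp − Rm + gbs·Cm) − γ*·gbs·Om]

(all O2 quantities converted to µbar before entering products).  With
this sign convention the root (−*b* + √(*b*² − 4*ac*))/(2*a*) is the
physical branch: for α = 0, a = −1 and the expression reduces to the
smaller root of *A*² − *bA* − *c*.

**Electron-transport-limited.**  Linear electron flow *J* comes from the
non-rectangular hyperbola θ*J*² − *J*(*I*₂ + *J*max) + *I*₂*J*max = 0
(smaller root, evaluated in the rationalized form
2*I*₂*J*max/(S + √(S² − 4θ*I*₂*J*max)) which is continuous at θ = 0),
with *I*₂ = *I*·absorptance·ρ·(1 − *f*).  Cyclic PSI flow enters twice:
the ATP yield per linear electron is *z* = (3 − *f*cyc)/(*h*(1 − *f*cyc))
(Q-cycle, 3 H⁺ per linear electron, 2 H⁺ per cyclic electron, *h* H⁺ per
ATP), and the PSII share of absorbed light is
ρ = (1 − *f*cyc)/(2 − *f*cyc).  ATP supply *zJ* splits *x* : (1 − *x*);
the C4 branch gives *V*p = *zxJ*/2 (2 ATP per PEP) and the C3 branch
*V*c = *z*(1 − *x*)*J* / [3(1 + 7γ\**O*s/3*C*s)] (3 ATP per
carboxylation plus the photorespiratory surcharge).  Eliminating *C*s
and *O*s yields the quadratic coded in
`light_limited_assimilation`, with a = 7γ\*α/(3*a*o) − 1 under the same
sign convention.

The printed renderings of all three coefficient sets (enzyme, light,
and the *J*a inversion) are recovered here by re-derivation from the
balance systems; correctness is defined operationally by the test-suite
oracles, which solve the balance systems directly by bracketing
bisection on the scalar residual and must agree with the closed forms to
1 µmol m⁻² s⁻¹ × 10⁻⁶ across randomized parameter draws.

**Mesophyll conductance.**  *A* = *g*m(*C*i − *C*m) closed with the min
rule leads to a cubic, so `net_assimilation` solves the scalar equation
*A*(*C*m) − *g*m(*C*i − *C*m) = 0 by Brent's method on
*C*m ∈ [0, *C*i] (tolerance 10⁻⁸ µbar), extending the bracket above
*C*i when the leaf is below compensation and effluxes CO2.  The
analytic low-CO2 approximation (`lowco2_assimilation_with_gm`) is
exposed separately; it drops the *g*bs·*C*m inward-diffusion term and
the *V*pr cap and is valid only on the initial slope.

**Inverse diagnostics.**  Because a measured *A* fixes *O*s and makes
*C*s linear in *J*, the light-limited system inverts to a quadratic in
*J*; `actual_electron_transport` validates the returned root per call by
the forward round trip (tolerance 10⁻⁶) and falls back to the companion
root with a warning if needed.  Leakiness processing uses
*V*p = (*A* + *R*m)/(1 − ϕ), *L* = ϕ*V*p, *C*s = *C*m + *L*/*g*bs, which
restores the mesophyll balance exactly by construction.

## Parameters

Defaults are the cohesive *Setaria viridis* set at 25 °C, with the O2
partial pressure defaulting to 200 mbar (the usual measurement
condition):

| symbol | default | units | role |
|---|---|---|---|
| *V*cmax | 40 | µmol m⁻² s⁻¹ | maximum Rubisco carboxylation |
| *K*c / *K*o | 1210 µbar / 292 mbar | | Rubisco Michaelis constants |
| γ\* | 0.5/1310 | – | half reciprocal Rubisco specificity |
| *V*pmax | 200 | µmol m⁻² s⁻¹ | maximum PEPC activity |
| *K*p | 82 | µbar | PEPC Michaelis constant (CO2 basis, cytosolic pH 7.2) |
| *V*pr | 80 | µmol m⁻² s⁻¹ | PEP-regeneration ceiling (temperature invariant) |
| *g*bs | 0.003 | mol m⁻² s⁻¹ bar⁻¹ | bundle-sheath CO2 conductance (temperature invariant) |
| *a*o | 0.047 | – | O2/CO2 solubility–diffusivity ratio |
| *R*d | 0.01·*V*cmax | µmol m⁻² s⁻¹ | mitochondrial respiration (*R*m = 0.5 *R*d) |
| α | 0 | – | bundle-sheath PSII fraction (NADP-ME default) |
| *x* | 0.4 | – | electron-transport share of the C4 cycle |
| *J*max@*T*o, *T*o, Ω | 400, 43 °C, 26 °C | | Gaussian electron-transport response |
| *h*, *f*cyc, θ | 4, 0.3, 0.7 | | H⁺/ATP, cyclic fraction, light-response curvature |
| absorptance, *f* | 0.85, 0.15 | – | light capture and spectral correction |
| *g*m | 1 | mol m⁻² s⁻¹ bar⁻¹ | mesophyll conductance |

Temperature scaling uses the single-exponential Arrhenius form
`v(T) = v25·exp[(T − 25)·E/(298·R·(273 + T))]` with activation energies
(kJ mol⁻¹): *V*cmax 78, *K*c 64.2, *K*o 10.5, γ\* 31.1, *V*pmax 50.1,
*K*p 38.3, *R*d 66.4, *a*o 1.63, *g*m 49.8.  *J*max follows the Gaussian
*J*max(*T*o)·exp(−((T − *T*o)/Ω)²); no other high-temperature
deactivation is modelled.  `Jmax25` defaults to the Gaussian evaluated at
25 °C (≈247.7) and, when set explicitly (e.g. as a fit parameter),
anchors the response via the normalized Gaussian so the printed shape is
preserved.  `rescale_kp_for_ph` converts *K*p between assumed cytosolic
pH values (the constant is a bicarbonate Km; 82 µbar at pH 7.2 becomes
≈51.7 µbar at pH 7.4 under pure Henderson–Hasselbalch rescaling).

Unit convention throughout: CO2 pressures in µbar, O2 pressures in mbar
at every interface; γ\*·O products are formed after converting O2 to
µbar, so Γ\* = γ\**O*s emerges in µbar (≈76 µbar at 200 mbar O2).  This
is the single most error-prone aspect of the model and the reason CSV
columns carry unit suffixes.

## Numerical choices

* Quadratics use the printed root form (−*b* + √disc)/(2*a*) under the
  sign convention above; |a| < 10⁻¹² falls back to the linear root −c/b,
  and a discriminant negative by less than 10⁻¹² of the coefficient
  scale (an exactly co-limiting double root) is clamped to zero.  A
  genuinely negative discriminant raises a `DegenerateInputError` naming
  the coefficients.
* PEPC ties (Michaelis–Menten rate equal to *V*pr) are labelled
  regeneration-limited; approximation-branch ties in
  `light_limited_approx` are labelled C3-limited.  Both are arbitrary but
  deterministic.
* The limitation flag reads "co-limited" when |*A*c − *A*j| < 10⁻³
  µmol m⁻² s⁻¹ (float comparability); diagnostics then come from the
  enzyme branch.
* ϕ and overcycling are reported as undefined (`None`) when *A* ≤ 0 or
  *V*p = 0 rather than clamped.
* `optimal_partitioning` maximizes *A*j over *x* ∈ [0, 1] by bounded
  golden-section/Brent search (xatol 10⁻⁶, reported tolerance 10⁻⁴); the
  objective has a kink at the branch crossing, which bounded search
  handles without derivatives.
* γ\* = 0 is admitted as the exact no-photorespiration limit (the
  simplified co-limitation identity *A*j = 0.2·*z*·*J* holds exactly
  there); the Arrhenius scaling maps 0 to 0.

## Limitation structure near ambient CO2

With the default parameter set at 25 °C and saturating light the two
limiting rates lie within ~1 µmol m⁻² s⁻¹ of each other over the entire
CO2-saturated plateau (e.g. *A*c = 34.70 vs *A*j = 35.59 at
*C*m = 200 µbar, *I* = 2000): the parameterization is deliberately
balanced, and the arg-min flag is therefore knife-edge sensitive there.
As coded, the model is electron-transport limited at *C*m = 200 µbar for
irradiances up to ≈1700 µmol m⁻² s⁻¹ and enzyme (PEP-regeneration)
limited above; the structure tests assert the robust parts of the
pattern (enzyme limitation everywhere at 15 °C; a single enzyme→electron
transport transition along warm A–Ci sweeps; electron-transport
limitation at *C*m = 200 µbar for *I* ≤ 1500).  Users comparing
limitation flags against published curve annotations should expect the
flag, not the rate, to be sensitive to small parameter changes in this
region — at full sunlight a ~2% change in *J* flips it.

## Synthetic data and fitting

The generator (`synthesize`) evaluates the forward model on a strictly
increasing grid of one driver and adds homoscedastic Gaussian noise to
*A* — the simplest defensible model of infra-red gas-analyser noise —
from one seeded generator per call (seed recorded in the curve
metadata).  It emulates clean steady-state curves only: no drift, no
stomatal kinetics, no heteroscedasticity, no leak artefacts, no
chamber-boundary effects.  Recovery results on synthetic curves
therefore bound what real-data fits can achieve from below in noise
complexity.

`fit` wraps bounded trust-region-reflective least squares over any
subset of {*V*pmax25, *V*cmax25, *V*pr, *J*max25, *g*m25}, with *R*d
kept tied to 0.01·*V*cmax25 while *V*cmax25 moves (unless *R*d was set
explicitly).  Standard errors come from the Gauss–Newton curvature;
a column-normalized curvature condition number above 10 (two-parameter
correlation ≈0.82) raises `WeakIdentifiabilityWarning` — the canonical
trigger is fitting (*g*m, *V*pmax) from initial-slope-only data, where
the two parameters trade off almost exactly.

The default A–Ci design (`DEFAULT_ACI_GRID`) spans 20–1500 µbar with 10
of 15 points below 200 µbar, because *V*pmax information lives in the
PEPC-limited initial slope while the plateau constrains
*V*cmax/*V*pr/*J*max.  Two caveats for (*V*pmax, *V*cmax) fits at
default truth values: start *V*cmax below ~40, since the objective is
flat in *V*cmax once *A*c exceeds *A*j (the plateau becomes
electron-transport limited and the gradient vanishes); and expect ~3%
relative scatter in *V*pmax at 0.5 µmol m⁻² s⁻¹ noise on 15 points.
Under that design the recovery simulation (100 replicates) returns both
parameters within 5% of truth in ≈96 replicates.

## Problem sizes

The test suite verifies the closed forms against the balance-system
oracles on 200 randomized draws (parameters ±50% of defaults,
*C*m ∈ [0, 2000] µbar, *O*m ∈ {50, 200, 400} mbar, α ∈ {0, 0.5, 1}),
runs 40-point inversion round trips, and a 100-replicate × 15-point
recovery study; the whole suite completes in well under a minute on one
CPU.  The acceptance script reports only desk-scale, deterministic
quantities.

## Known limitations

* No triose-phosphate limitation at high CO2 and no stomatal or
  boundary-layer model (*C*i is an input).
* NAD-ME and PCK subtypes are only approximated through α; the reduced
  mitochondrial ATP demand for PEP regeneration in PCK types is not
  implemented.
* Carbonic-anhydrase hydration kinetics are assumed non-limiting; the
  known reduction of the initial slope in CA-deficient plants is outside
  the model.
* Leakiness predicted by the forward flux model pins the non-limiting
  cycle at capacity and overestimates real ϕ; the model is meant to
  *consume* measured leakiness, not predict it.
* Steady state only — no dynamics under fluctuating light.
* ϕ from isotope discrimination must be supplied externally; the
  discrimination theory itself is not implemented.
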