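# c4photo

A steady-state model of C4 leaf photosynthesis for gas-exchange analysis:
forward simulation of net CO2 assimilation, inverse diagnostics from
measured rates, and synthetic-curve generation with least-squares
parameter estimation.  The default parameterization describes *Setaria
viridis*, an NADP-ME C4 monocot, with Arrhenius temperature responses for
the kinetic constants and a Gaussian temperature response for electron
transport.

The package is aimed at plant physiologists analysing A–Ci and light
response curves of C4 species, and at modellers who need a tested,
scriptable leaf-level C4 submodel.

## The model

C4 photosynthesis runs a biochemical CO2 pump: PEP carboxylase (PEPC)
fixes HCO3⁻ in the mesophyll at rate *V*p, the C4 acids are decarboxylated
inside the nearly gas-tight bundle sheath where Rubisco operates at high
CO2, and a fraction of that CO2 leaks back out at rate
*L* = *g*bs (*C*s − *C*m).  Two flux balances describe the net rate *A*:

    A = Vc − 0.5 Vo − Rd          (bundle-sheath demand)
    A = Vp − L − Rm               (mesophyll supply)

At high light the rate is **enzyme limited**: *V*p follows
Michaelis–Menten kinetics capped by the PEP-regeneration rate *V*pr, and
*V*c is the RuBP-saturated Rubisco rate.  Eliminating *C*s and the
bundle-sheath O2 pressure *O*s (raised above ambient when a fraction α of
PSII activity sits in the bundle sheath) gives a quadratic in *A*c.

Under limiting light, ATP supply governs both cycles.  Linear electron
flow *J* follows a non-rectangular hyperbola of the PSII-absorbed
irradiance with curvature θ and maximum *J*max(*T*); cyclic PSI flow
(fraction *f*cyc) changes both the ATP yield per linear electron,
*z* = (3 − *f*cyc)/(*h*(1 − *f*cyc)), and the fraction of light useful to
PSII, ρ = (1 − *f*cyc)/(2 − *f*cyc).  A fraction *x* ≈ 0.4 of the ATP
drives PEP regeneration (*V*p = *z x J*/2), the rest the C3 cycle; the
resulting quadratic yields the light-limited rate *A*j.  The leaf
assimilates at *A* = min(*A*c, *A*j), and a finite mesophyll conductance
couples *C*m to the intercellular pressure through *A* = *g*m(*C*i − *C*m).

The inverse routines recover the actual electron transport *J*a required
to sustain a measured *A*, and convert isotope-derived leakiness
ϕ = *L*/*V*p into C4-cycle fluxes via *V*p = (*A* + *R*m)/(1 − ϕ).

## Worked example

Simulate one observation at *C*i = 400 µbar, 25 °C, 2000 µmol quanta
m⁻² s⁻¹ with the default parameters:

```sh
c4photo simulate --ci 400
```

or equivalently in Python:

```python
from c4photo import Environment, default_parameters, net_assimilation

state = net_assimilation(Environment(Ci=400.0), default_parameters())
print(state.A, state.limitation, state.Cm, state.phi)
```

Key columns of the one-row output:

```
 Ci_ubar  Cm_ubar  A_umol_m2_s limitation   Cs_ubar   phi      J
   400.0  365.256       34.744     enzyme 15383.915 0.563 212.34
```

Reading: diffusion through *g*m = 1 mol m⁻² s⁻¹ bar⁻¹ drops CO2 by
~35 µbar to *C*m = 365 µbar, where PEP carboxylation runs at its
regeneration cap (*V*p = 80 µmol m⁻² s⁻¹).  The pump concentrates CO2 to
*C*s ≈ 15 400 µbar in the bundle sheath.  Net assimilation is
34.74 µmol m⁻² s⁻¹, enzyme limited though the electron-transport-limited
rate (35.80) lies less than 1.1 µmol m⁻² s⁻¹ above it — the two
limitations nearly co-limit at ambient CO2 and saturating light.  The flux
model pins the non-limiting C4 cycle at its cap, so the implied leakiness
(ϕ = 0.56) is an upper envelope, not a prediction of measured leakiness;
for real leaves, feed measured ϕ into `c4_cycle_from_leakiness` instead.

Other entry points: `c4photo aci`, `c4photo light`, `c4photo temperature`
(response curves), `c4photo synth` / `c4photo fit` (synthetic data and
parameter estimation), `c4photo invert-j` / `c4photo leakiness` (inverse
processing of measured CSV tables).

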