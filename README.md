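# gtpase-dora

Dose-response alignment (DoRA) analysis of coupled GTPase switches with
negative feedback.

Cell-surface receptors relay dose information through cascades of molecular
switches.  A pathway exhibits **dose-response alignment** when the normalized
steady-state response of a downstream species closely tracks receptor
occupancy across doses — a property linked to faithful dose sensing.  This
package implements and analyses a six-variable model of an experimentally
characterized circuit in which a receptor drives a monomeric GTPase switch
(mG, e.g. Arf1) which drives a heterotrimeric GTPase switch (tG, e.g.
Giαβγ), with negative feedback from tGEF and active tG onto the mGTPase's
GAP.  It is written for systems biologists who want to reproduce, probe or
extend the circuit's design-principle analysis.

## Model

Fractional activations R\*, mG\*, tG\* and concentrations mGEF, tGEF, mGAP
evolve as

```
dR*/dt   = k_on^R  f(S) (1 − R*)      − k_off^R  R*
dmGEF/dt = k_on^mGEF f(R*)            − k_off^mGEF mGEF
dmG*/dt  = k_on^mG f(mGEF) (1 − mG*)  − k_off^mG f(mGAP) mG*
dtGEF/dt = k_on^tGEF f(mG*)           − k_off^tGEF tGEF
dtG*/dt  = k_on^tG f(tGEF) (1 − tG*)  − k_off^tG f(tGAP) tG*
dmGAP/dt = k_on^mGAP + k_fb·F(tGEF, tG*) − k_off^mGAP mGAP
```

with `f(x) = x` (mass action) or `f(x) = xⁿ/(Kⁿ + xⁿ)` (Hill), and the
feedback crosstalk `F` equal to 0, `f(tGEF)·f(tG*)` (AND gate) or
`f(tGEF) + f(tG*)` (OR gate) — six model variants in total.

Alignment of a species Y ∈ {mG\*, tG\*} is scored by the **distance metric**

```
D_Y = ∫ | Y_ss/Y_ss,max − R*_ss/R*_ss,max | d(R*_ss/R*_ss,max)
```

the area between the normalized species-vs-receptor curve and the diagonal:
0 means perfect alignment, 1/2 is the saturated worst case.

Steady states are computed three ways and cross-checked: stiff ODE
integration (BDF with an analytic Jacobian), a bracketed scalar fixed point
on mG\*_ss, and closed forms for the no-feedback variants.

## Worked example

```python
import numpy as np
from gtpase_dora import (KineticParameters, ModelSpec, dose_response,
                         normalize, distance_metric)

params = KineticParameters(k_on_mGAP=0.5)      # all other constants = 1
curve = dose_response(params, ModelSpec())     # mass action, no feedback
norm = normalize(curve)
print(f"mG activation level: {curve.mG_max:.4f}")
print(f"metric mG*: {distance_metric(norm, 'mG'):.4f}")
print(f"metric tG*: {distance_metric(norm, 'tG'):.4f}")
```

prints

```
mG activation level: 0.6667
metric mG*: 0.1755
metric tG*: 0.2464
```

With `k_on_mGAP = 0.5` the composite deactivation constant is a_M = 0.5, so
the mGTPase activation level (its steady state at saturating stimulus) is
1/(1 + a_M) = 2/3.  The mGTPase metric (0.176) beats the tGTPase metric
(0.246): under mass action the longer cascade always aligns worse.  Raising
`k_on_mGAP` lowers the activation level and shrinks both metrics.

The same pipeline is scriptable from the shell:

```
gtpase-dora dose_response -o out/ --seed 0
gtpase-dora feedback_sweep -c my_config.yaml -o out/
```

Each run writes tidy CSVs, a JSON summary, a log and a content-hash
manifest; repeated runs of one config hash identically.

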