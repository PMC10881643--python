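# sflt1kin

Kinetic modelling of constitutive sFLT1 secretion from endothelial cells.

sFLT1 (soluble FLT1/VEGFR1) is a secreted decoy receptor that sequesters
VEGF-A in the extracellular space; endothelial cells release it
continuously, without stimulation. `sflt1kin` is for quantitative cell
biologists who want to turn sparse secretion time courses — densitometry
fold changes, conditioned-media ELISAs, pulse-chase series — into rate
constants: how fast is sFLT1 made, how long does it take to become
secretable, what fraction is secreted versus degraded, and how strongly
does a pharmacological inhibitor block each step.

## The model

Two pools, intracellular `S_i` and extracellular `S_x` (molecules/cell),
coupled by four first-order processes with a discrete synthesis-to-
availability delay τ (ER→Golgi transit):

```
dS_i/dt = k_prod · u(t − τ) − (k_out_Si + k_deg_Si) · S_i
dS_x/dt = k_out_Si · S_i − k_deg_Sx · S_x
```

`u(t) ∈ {0, 1}` is the production gate (constitutively 1; a pulse for
labeling experiments). At steady state

```
S_i* = k_prod / (k_out_Si + k_deg_Si)        secretion flux = k_out_Si · S_i*
φ    = k_out_Si / (k_out_Si + k_deg_Si)      (fraction secreted)
```

Because the system is linear with piecewise-constant input, the default
simulation engine propagates the exact closed-form solution between events
(media changes, inhibition onsets); an independent method-of-steps ODE
integrator cross-checks it. Every trajectory carries cumulative
production/secretion/degradation audit channels, so conservation of mass
is verified on every run.

On top of the core sit: protocol simulators (media-change accumulation,
pulse-chase fold changes, cell-free media decay, 18 h inhibitor windows),
weighted least-squares fitting with multi-start Nelder–Mead and
profile-likelihood intervals, a synthetic-data generator with
densitometry-style multiplicative noise and per-replicate normalization,
and inversion of an observed treated/control media ratio into the
fractional inhibition of a rate constant.

## Worked example

```python
import numpy as np
from sflt1kin import (DEFAULT_PARAMS, steady_state, run_accumulation,
                      invert_inhibition, run_inhibitor_treatment)

ss = steady_state(DEFAULT_PARAMS)
print(f"secretion flux: {ss.secretion_flux_star:.0f} molecules/cell/hr")
print(f"fraction secreted: {ss.fraction_secreted:.2f}")

# secreted protein accumulating in fresh media over 24 h
traj = run_accumulation(DEFAULT_PARAMS, np.array([6.0, 12.0, 24.0]))
print("media sFLT1 (molecules/cell):", traj.S_x.round(0))

# a drug lowers 18 h media sFLT1 to ~17% of control; how much secretion block?
r_x, _ = run_inhibitor_treatment(DEFAULT_PARAMS, "k_out_Si", 0.9)
f = invert_inhibition(DEFAULT_PARAMS, "k_out_Si", r_x)
print(f"observed ratio {r_x:.3f} -> fractional inhibition {f:.2f}")
```

prints

```
secretion flux: 30000 molecules/cell/hr
fraction secreted: 0.50
media sFLT1 (molecules/cell): [179461. 357849. 711429.]
observed ratio 0.168 -> fractional inhibition 0.90
```

The reference parameter set secretes 30,000 molecules/cell/hr at steady
state with an even split between secretion and intracellular degradation
(φ = 0.5); a drug that reduces 18 h media accumulation to ~17% of control
corresponds to a 90% block of the secretion rate constant `k_out_Si` — the
dose curve is much shallower than 1:1 because blocked protein backs up
intracellularly and partially compensates.

The same operations are available from the shell:

```sh
sflt1kin sweep --params params.json --target k_out_Si --out sweep.csv
sflt1kin invert --params params.json --target k_out_Si --ratio 0.17
sflt1kin generate --params params.json --protocol accumulation \
    --times 2,8,24 --unit molecules_per_cell --cv 0.2 --n 3 --seed 7 --out data.csv
sflt1kin fit --data pulse.csv --data media.csv --out fit.json
```

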