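# pistar — mechanistic models of the rice phosphate-starvation response

Phosphate (Pi) starvation in rice roots triggers a signalling cascade in
which the SUMO-ligase SIZ1 activates the master regulator PHR2, whose
active form drives transcription of the systemic microRNA miR399 and the
decoy lncRNA IPS1. miR399 silences the mRNA of PHO2, a ubiquitin-conjugating
enzyme that restrains the Pi transporters PHT and PHO1; IPS1 sequesters
miR399 by target mimicry (forming the IPS1·miR399 complex, IMC) and thereby
buffers PHO2 silencing. `pistar` is a toolkit for researchers who want to
confront mechanistic hypotheses about this network with qRT-PCR fold-change
time courses.

The package provides:

* **Model core** — the ten-species base ODE model (PiOM) with Hill-type
  transcriptional regulation, reversible IPS1·miR399 binding, catalytic
  miR399-mediated PHO2 mRNA decay, PHO2-protein repression of PHT/PHO1 and
  a cytosolic-Pi balance `dCytoPi/dt = u_max·PHT·extPi(t) − U·CytoPi −
  e1·PHO1·CytoPi`, forced by a piecewise-constant external-Pi protocol
  (320 µM under +Pi; 0 under starvation).
* **Five hypothesis variants** for the early loss of PHO2 mRNA — PdTA,
  PdRP, PsMD, PsTR, PsRA — plus the **RNA-protection (RP)** modification in
  which IPS1/IMC decay becomes `d7/CytoPi0 · CytoPi(t)` so that IPS1 is
  shielded under starvation and collapses on Pi re-supply.
* **Inference** — lognormal (proportional-error) maximum likelihood for
  fold-change tables, multi-start bounded optimisation in log-parameter
  space, AIC = −2LL + 2T with T counting free structural plus statistical
  parameters.
* **Model selection** — comparison tables with ΔAIC = AIC(base) − AIC(model),
  extra-parameter count k, and the χ² tail P = Pr(χ²_k > ΔAIC + 2k),
  alongside a qualitative early-PHO2-drop flag so statistically best and
  dynamically correct can disagree.
* **Prediction intervals** — Gaussian parameter sampling truncated at
  bounds, pointwise quantile envelopes (80/85/90/95/100%).
* **Sensitivity & robustness** — normalised local sensitivities by central
  differences in log-parameter space; inverse-CV robustness under lognormal
  parameter perturbation.
* **Synthetic data** — a generator reproducing the study's replicate design
  and temporal signatures (PHO2 halving over 264 h with ~80% lost by 3 h
  and partial recovery; IPS1 >1000-fold by 21 days; miR399 delayed ≥24 h;
  post-repletion collapse), with median-1 lognormal noise.

## Worked example

```python
import numpy as np
from pistar import (EnvironmentProtocol, ModelVariant, default_parameters,
                    simulate, to_fold_change)

flagship = ModelVariant("PSTR", rp=True)      # Pi-sensitive repressor + RP
params = default_parameters(flagship)
protocol = EnvironmentProtocol.starvation(504.0)
grid = np.array([0.0, 3.0, 6.0, 24.0, 264.0, 504.0])
curves = to_fold_change(simulate(params, flagship, protocol, grid))
for target in ("PHO2", "IPS1", "miR399"):
    print(target, np.round(curves[target].fold_change, 3))
```

prints

```
PHO2 [1.    0.505 0.229 0.487 0.479 0.476]
IPS1 [1.000000e+00 1.481000e+00 3.028000e+00 7.076800e+01 3.302752e+03
 6.802352e+03]
miR399 [  1.      1.001   1.007   1.284 305.029 747.408]
```

PHO2 mRNA collapses within hours of starvation (0.23 of baseline at 6 h)
and partially recovers toward ~0.5 — the signature of a Pi-sensitive
repressor held in check by PHO2's own feedback on its activator. IPS1
climbs beyond 1000-fold by 21 days because RNA protection suppresses its
decay as cytosolic Pi drains, while miR399 stays flat for the first day
before its sigmoid rise.

The same study recipe is scriptable end to end:

```bash
pistar generate --scenario long_starvation --seed 1 --out obs.csv
pistar fit --data obs.csv --hypothesis PIOM --seed 1 --out fit_piom.json
pistar fit --data obs.csv --hypothesis PSTR --warm-from fit_piom.json --out fit_pstr.json
pistar compare --base fit_piom.json --alt fit_pstr.json --out table.csv
pistar pipeline --outdir run/ --seed 1     # generate → fit all → compare → intervals → sensitivity
```

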