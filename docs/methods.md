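# Methods

## The model family

The base model (PiOM) is a system of ten coupled nonlinear ODEs in
arbitrary concentration units (au) with time in hours. The state is
(SIZ1, PHR2a, miR399, PHO2m, PHO2p, IPS1, IMC, PHT, PHO1, CytoPi):

* SIZ1 is synthesised and degraded constitutively (`m1 − d1·SIZ1`); a flag
  clamps it constant instead.
* Active PHR2 forms at a rate `m2·SIZ1·K2^h2/(K2^h2 + CytoPi^h2)` — the
  SPX4-proteolysis/sumoylation steps are abstracted into a single
  decreasing Hill dependence on cytosolic Pi — and decays at `d2`.
* miR399 and IPS1 transcription are increasing Hill functions of PHR2a with
  coefficients `q` and `r`; miR399 additionally has a basal term `m3b`.
* IPS1 and miR399 bind reversibly into the complex IMC (`k7`, `k7_rev`).
  `k7` is stored at its literature magnitude (1.9e-5, per-second scale for
  a weak RNA–miRNA association) and converted ×3600 to au⁻¹ h⁻¹ inside the
  right-hand side; the printed unit is dimensionally ambiguous for a
  bimolecular constant, so the stored value plus declared conversion keeps
  the provenance explicit.
* PHO2 mRNA is lost at `d5·PHO2m + k_m·miR399·PHO2m`; miR399 acts
  catalytically (it is recycled, consistent with non-cleavable target
  mimicry) unless the co-degradation flag is set. Degradation of IMC
  destroys the IPS1 moiety and returns miR399 to the free pool — this is
  what converts the complex into a loaded spring on Pi re-supply.
* PHO2 protein is translated from its mRNA and represses PHT and PHO1
  synthesis through decreasing Hill terms.
* Cytosolic Pi obeys `u_max·PHT·extPi(t) − U·CytoPi − e1·PHO1·CytoPi`,
  with the utilisation rate `U` always held fixed during fitting: it lumps
  vacuolar storage and incorporation into lipids/nucleic acids and is not
  identifiable from RNA fold changes.

External Pi is a piecewise-constant protocol (default +Pi level 320 µM,
starvation 0); integration restarts at every segment boundary so the
discontinuity never corrupts the step-size control.

### Hypothesis variants

Each variant adds a candidate mechanism for the early loss of PHO2 mRNA
and a fixed number of extra free structural parameters (the k column of
the comparison table):

| variant | mechanism | extra species | k |
|---------|-----------|---------------|---|
| PdTA | Pi-dependent transcriptional activator Z of PHO2 | Z | 2 |
| PdRP | Pi-dependent protector Z slowing basal mRNA decay by 1/(1+Z/K_zp) | Z | 4 |
| PsMD | Pi-sensitive binder Z, second-order mutual degradation with PHO2m | Z | 8 |
| PsTR | Pi-sensitive repressor Z of the PHO2 activator TA; TA degraded ∝ PHO2p | TA, Z | 8 |
| PsRA | Pi-sensitive RNase term −d_r·PHO2m·(decreasing Hill in CytoPi) | — | 2 |

PsTR includes the PHO2p→TA degradation feedback: without it the model
cannot produce the observed partial recovery of PHO2 mRNA between 3 and
12 h — the mRNA collapse lowers PHO2 protein, which releases TA, which
partially restores transcription against the repressor. The feedback also
creates the set point that keeps PHO2 mRNA near half its baseline for the
rest of the starvation period.

Every variant admits a neutral parameter limit (interaction rates → 0,
repression constants → ∞, activation Hills saturated) in which it
reproduces the base-model trajectory exactly; the test suite verifies this
reduction to 1e-6 relative.

### RNA protection (RP)

Any variant can carry the RP modification: the IPS1 and IMC degradation
rate becomes `(d7/CytoPi0)·CytoPi(t)` — equal to `d7` at the +Pi steady
state, falling linearly as cytosolic Pi drains. Under starvation IPS1 then
accumulates essentially linearly at its synthesis rate (>1000-fold by 21
days without invoking a super-promoter), and on re-supply the restored
decay destroys the large IMC pool within hours, releasing sequestered
miR399 in a burst that silences PHO2 mRNA — the RP-specific double
collapse. RP variants ship re-estimated IPS1 synthesis defaults (maximum
18.8 au/h, Hill coefficient r = 2) in place of the non-RP values
(696 au/h, r = 4), since protection rather than super-synthesis then
carries the amplitude.

## Calibrated defaults

The shipped parameter set was calibrated once, by construction, to the
study conditions: a +Pi steady state with order-unity RNA levels and
CytoPi0 = 10 au; ~80% PHO2 mRNA loss by 3–6 h of starvation with partial
recovery (PsTR variants); PHO2 near half baseline at 264 h; a ≥24 h miR399
delay followed by a sigmoid rise; IPS1 ≥1000-fold at 504 h (RP); and
collapse of IPS1 and PHO2 within 24 h of re-supply under RP but not
without it. Noteworthy choices:

* `d2 = 0.02 h⁻¹` makes active PHR2 the slow variable (~2-day timescale),
  which is what delays miR399 induction; the steep induction Hill
  (`q = 6`, K3 at the PHR2a saturation level) converts that slow rise into
  the observed sigmoid.
* `d3 = 0.02 h⁻¹`: miRNAs are long-lived; a fast-turnover miR399 would
  leak out of the IMC buffer and break the 24 h delay.
* `d5 = 0.75 h⁻¹` puts basal PHO2 mRNA turnover at the fast end of mRNA
  half-lives, as required for an 80% drop within 3 h once transcription is
  repressed.
* `U = 0.3 h⁻¹` drains cytosolic Pi with a ~2 h half-time after uptake
  stops, so Pi-sensing species respond within the first hours.

Known deviation: with the IMC included in the miR399 observable (the
default, since sequestration does not destroy the RNA), the protected
miR399 pool overshoots the measured late-time amplitude (hundreds-fold
rather than tens-fold). The delay, sigmoid shape and monotonicity — the
features the data constrain qualitatively — are reproduced; the free-pool
observable flag is available.

## Observables and fold change

qPCR-style observables are PHO2 = PHO2m, IPS1 = IPS1 + IMC and
miR399 = miR399 + IMC (flags switch either RNA to its free pool). Fold
change divides by the +Pi steady-state observable, so every curve starts
at 1. Observable values are floored at 1e-12 au before division: the stiff
integrator can leave |values| ~ atol below zero, and a negative RNA level
is reported as (numerically) zero rather than propagated.

## Likelihood and fitting

Replicate fold changes are modelled as lognormal around the model
prediction (density on the log fold change) with one residual scale per
target RNA; an additive-Gaussian alternative exists. Residual scales are
profiled analytically at every structural parameter vector — the profiled
optimum coincides with the joint MLE — and are counted as free statistical
parameters in T, so AIC = −2LL + 2T holds exactly by construction.
σ² estimates are floored at 1e-12 to keep the degenerate noiseless limit
finite.

Fitting is Powell search in log-parameter space within box bounds (default
one decade either side of the shipped value; Hill coefficients in
[1, 12]), from the supplied initial point plus seeded Latin-hypercube
starts. Variant fits follow the warm-start convention: shared parameters
initialise from a prior base-model fit. Integration failures at proposed
points return +inf, which Powell treats as a wall. Standard deviations
come from the inverse observed information (central finite differences of
−2LL/2 in log space, step 5e-3), converted to natural scale by the delta
method.

The default free structural set for the base model is {d2, q, r, k_m, k7}.
Fold-change data cannot identify pure scale parameters (a rescaling of
m8 cancels in IPS1 fold change), so the free set contains the timescales
and interaction strengths that shape the curves; everything else stays at
its calibrated value, mirroring a design in which most rates come from
prior knowledge. The mixed-effects machinery of the original estimation
software is approximated by this fixed-effects MLE; the AIC calculus is
agnostic to that substitution.

## Model comparison

ΔAIC is reported as AIC(base) − AIC(model), positive when the hypothesis
improves on the base (the operational convention of the published table,
whose footnote sign is inconsistent with its entries). P = Pr(χ²_k >
ΔAIC + 2k) with k = T(model) − T(base); since ΔAIC + 2k = Δ(−2LL) this is
the likelihood-ratio tail for the nested comparison. P-values print to
three significant figures; JSON artifacts carry full precision.
`best_model` returns the minimum-AIC hypothesis and, separately, a
per-model flag for whether the fitted trajectory drops below a threshold
(default 0.5) at 6 h of starvation — the statistically best and the
qualitatively correct model need not coincide.

## Prediction intervals

Parameter vectors are drawn from independent Gaussians with the fitted
means and standard deviations, truncated at the box bounds (rejection with
a clamped fallback); each draw is simulated and pointwise central
quantiles form the bands. Levels are pointwise, not simultaneous; the
"100%" band is the sampled min–max envelope. Bands are bit-reproducible
given the seed.

## Sensitivity and robustness

Local sensitivities are normalised coefficients ∂ln x/∂ln p by central
differences in log-parameter space (default relative step 0.01,
second-order accurate; halving the step quarters the error on the analytic
test model). Failures at perturbed points are flagged as NaN, never
silently zeroed. Robustness is the inverse coefficient of variation of an
observable under independent lognormal perturbation of all rates and
binding/half-saturation constants (Hill coefficients excluded as
integer-like); a spread at summation round-off level returns a capped
sentinel (1e12). Robustness rankings are condition-dependent in this
calibration: at the +Pi operating state IPS1 is clearly the least robust
readout (its basal level sits on the steep low tail of its activation Hill
downstream of a long multiplicative chain — which is also why it is
insensitive to its own Hill coefficient), whereas at the end of starvation
the miR399 amplification cascade is the most fragile.

## Synthetic data

The generator emulates the study's measurement design, not its raw
chemistry: no Ct values or normalisation arithmetic, just fold changes.
Reference curves are closed-form interpolants through the anchor values
(PHO2 0.5 + 0.5·e^(−t/40); IPS1 e^(t/70); miR399 a baseline-anchored
sigmoid centred at 120 h; early-time PHO2 through (1, 0.2, 0.3, 0.38) at
(0, 3, 6, 12) h with a monotone shape-preserving interpolant; repletion
relaxations with 5–8 h time constants). Replicate counts default to the
study design (PHO2 n = 3 throughout; IPS1/miR399 n = 2 at 0–72 h and n = 4
at 168/264 h; n = 3 elsewhere). Noise is multiplicative lognormal with
median 1; the CV default of 0.2 is a stand-in, as the study does not
report its measurement CV. Model-simulated curves can replace the built-in
references, which is how the recovery experiments generate data from known
parameters.

What passing tests show — and do not show: the synthetic tables share the
real data's design, noise law and qualitative temporal signatures, so they
exercise the full fitting/selection/interval machinery; they do not carry
real biological replicate correlation, plate effects, or the unknown true
noise level, so recovery results bound what is achievable under the
assumed error model only.

## Problem sizes and numerical settings

Default integration is LSODA with rtol 1e-8/atol 1e-10 (fitting uses
rtol 1e-6). Steady states come from a damped Newton solve seeded by an
analytic heuristic, with a long-relaxation fallback. The recovery
experiments in the test suite use 20 seeded data sets (two optimizer
starts, 400 function evaluations each) for parameter recovery and 10
seeded data sets for hypothesis recovery — sizes chosen so the full suite
stays a desk-scale computation while the Monte-Carlo error on the
recovery medians remains small.

## Limitations

* Single compartment: no vacuole, shoot–root translocation or phloem
  transport; miR399 arrives implicitly through its root transcription
  term.
* The absolute concentration scale is arbitrary (au); only fold changes
  are data-constrained, so scale parameters are deliberately fixed.
* Fixed-effects MLE instead of the original mixed-effects estimation; T
  for the paper's real-data fits (e.g. 48 for the base model) is not
  reconstructable from the main text, so only the k differences are
  pinned.
* The PsMD mutual-degradation and PsTR repressor modules are minimal
  kinetic sketches; their extra-parameter counts, not their detailed
  forms, are constrained by the comparison table.
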