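# Methods

## The model

The digitalizer is a mutual-inhibition module appended downstream of an
inducible promoter P1. P1 transcribes a bicistronic mRNA `mR` encoding a
transcriptional repressor R translationally coupled to a gene of interest
(readout G). R represses a strong constitutive promoter P2 that transcribes
a small antisense RNA `mS`; `mS` pairs with `mR` and the duplex is degraded,
removing one molecule of each. The two RNA pools are therefore mutually
exclusive: whichever species dominates extinguishes the other, pushing the
circuit into a clean OFF (sRNA-dominated) or ON (mRNA-dominated) regime.

With `tf_a` the concentration of active (inducer-bound) transcription factor,
treated as an external control input, the deterministic model is

    dmR/dt = beta_R + alpha_R * h+(tf_a; K_TF, n_act)
             - (delta_mR + mu) * mR - k_pair * mR * mS
    dmS/dt = alpha_S * h-(R; K_R, n_rep)
             - (delta_mS + mu) * mS - k_pair * mR * mS
    dR/dt  = lambda_R * mR - (delta_R + mu) * R
    dG/dt  = lambda_G * mR - (delta_G + mu) * G

where `h+(x; K, n) = x^n/(K^n + x^n)` and `h- = 1 - h+`. Units are nM and
minutes; `mu` is an optional dilution rate, 0 by default (the growth-free
model — growth effects are deliberately outside the kinetic description).
The stochastic counterpart converts the same rate laws into nine reaction
channels (plus four dilution channels when `mu > 0`) with a system-size
parameter `omega` (molecules per nM) and is sampled exactly with the
Gillespie direct method; Hill propensities are used as-is at the count
level, a standard reduction that forgoes elementary operator-binding
reactions.

## Regimes of the switch, and the choice of baseline

Two inequalities organise the behaviour:

1. **Switchability.** The OFF state survives as long as the sRNA supply can
   absorb all incoming mRNA, i.e. while `alpha_S * h-(R_off) >` mRNA
   production. If `alpha_S` exceeds the maximal production
   `alpha_R + beta_R`, the OFF branch persists at every dose and the module
   can never switch ON from below — it becomes a pure repressor of
   expression, not a switch. A functioning digitalizer therefore requires
   `alpha_S < alpha_R + beta_R`: induction then overwhelms the sRNA sink at
   a threshold dose, which is exactly what makes the response digital
   (threshold-linear behaviour of sRNA-regulated genes).
2. **Monostability.** The R→P2 leg closes a positive feedback loop (more
   mR → more R → less sRNA → more mR). A fold bifurcation (bistability and
   hysteresis) appears when the feedback slope
   `alpha_S * |h-'| * lambda_R/delta_R` exceeds the mRNA relaxation rate
   `delta_mR`; with `n_rep = 2` this bounds `K_R` from below at roughly
   `alpha_S * (lambda_R/delta_R) * 0.65 / delta_mR` (~1.6e3 nM at the
   values below). The baseline sits above that bound, so up- and
   down-continuation coincide to solver precision — consistent with the
   de-induction experiments that rule out hysteresis in the real construct.
   A strongly repressing corner of parameter space
   (`bistable_example_params`: `alpha_S = 50`, `K_R = 20`) violates both
   inequalities and serves as the positive control for hysteresis
   detection.

Baseline values (nM, min): `alpha_R = 10`, `beta_R = 0.15`, `K_TF = 50`,
`n_act = 2`, `alpha_S = 5`, `K_R = 2000`, `n_rep = 2`, `k_pair = 1`,
RNA decays `0.2`, protein decays `0.02`, `lambda_R = lambda_G = 2`,
`mu = 0`. These are round placeholder magnitudes for a plasmid-borne
bacterial circuit chosen once to satisfy the two inequalities with margin;
`beta_R` is ~1.5% of the induced rate so that the basal floor stays below
the resolution of the normalised de-induction comparison. Every quantitative
property in the test-suite and acceptance script is stated relative to this
published-in-repo baseline.

**Repression-strength sweeps** scale the two inhibitory arms jointly: a
strength `s` multiplies the pairing rate `k_pair` and the repressor
strength `1/K_R`. `alpha_S` is deliberately left fixed: it sets the
position of the switching threshold, and holding it fixed is what makes
the dose-response curves of different strengths pivot around a common
EC50 (in the rescaled variable `u = s * mR` the OFF-branch equations are
independent of `s`). The sharpening of the 10–90% transition width with
`s` is strong between 0.3 and 3 and then saturates — once the threshold
corner is sharp, the residual width is set by the P1 activation curve —
so the strict decrease at strengths 10 and 30 is a small effect resolved
on the canonical dense dose grid (0 plus 81 log-spaced doses, 0.1–1000 nM).

## Numerical choices

* ODE integration: LSODA at `rtol = 1e-8`, `atol = 1e-10`; piecewise
  protocols are integrated segment-by-segment so the solver never steps
  across an input discontinuity.
* Steady states: long integration in blocks followed by Newton (hybr)
  refinement; accepted only if `max|dy/dt| <= 1e-9 * (1 + |y|)`. The
  initial condition is honoured deliberately, so coexisting branches are
  reachable by continuation (up: seeded from the OFF state dose-by-dose;
  down: from a fully ON state). A system is called bistable when the
  branch gap exceeds `1e-3` of the dynamic range.
* Response metrics: EC50 and the 10–90% transition width are read off by
  monotone linear interpolation on the linear dose axis; the effective
  Hill exponent comes from a least-squares Hill fit with OFF/ON levels
  pinned to the curve ends. Flat curves raise a degenerate-curve error
  rather than returning NaNs.
* The fit objective uses a jitted Cash-Karp RK45 (`rtol = 1e-6`) instead
  of LSODA: the network is only mildly stiff at realistic parameters and
  the objective is evaluated thousands of times per fit; agreement with
  LSODA is ~1e-4 relative on the fitted medians.
* Per-cell SSA streams derive from `SeedSequence((seed, cell_index))`, so
  populations are reproducible and independent of simulation order.

## Synthetic measurements

Per-cell fluorescence is `AU = gain * G * exp(eps) + A` with
`eps ~ N(0, sigma_ext^2)` (lognormal extrinsic noise) and `A` lognormal
autofluorescence, clipped at an instrument floor — matching the log-scale
unimodal histograms such instruments produce. Defaults: `gain = 1` AU per
molecule, `sigma_ext = 0.3`, autofluorescence median 50 AU with log-SD
0.4, floor 1 AU, `omega = 3` molecules per nM-equivalent (a multi-copy
reporter). The promoterless preset (`alpha_R = beta_R = 0`) generates the
pure-autofluorescence control; its 99.5th percentile defines the
no-fluorescence gate, computed per time point, so the control's own ON
fraction is 0.5% by construction. Summaries use the sample median, sample
SD (n−1), CV*100 on linear AU, and the fraction of events strictly above
the gate; dead cells are excluded from fluorescence but retained in
survival denominators.

Large event tables use an ODE-mean shortcut (Poisson molecule counts
around `omega * G_ode(t)`) instead of per-cell SSA; `mode="ssa"` runs the
exact sampler. The default design seeds cells at the uninduced steady
state, so the t = 0 aliquot is the basal population.

For one-hit toxin killing the readout G is a toxin with `lambda_G = 0.005`
per min (weakly translated, so sub-threshold expression is survivable over
a 120-min assay) and a cell dies the moment its toxin count reaches 1.
Survival-curve steepness is compared via the 10–90% width *relative to the
curve's midpoint dose*: the non-digitalized curve sits at ~10-fold lower
doses, so absolute widths are not comparable across constructs.

## What the generator does and does not emulate

The synthetic data reproduce the measurement structure of the benchmark
experiments: three constructs, dose × time designs with ≥25,000 events per
aliquot by default, autofluorescent control, lognormal cell-to-cell noise,
OD-normalised plate-reader tables. They do not emulate scatter gating,
spectral spillover, doublets, cell division and lineage correlations,
escaper mutations, or regulator-level extrinsic noise. Two experimental
observations are consequently outside what passing tests can show:
the *faster onset* of the digitalized construct upon induction (the model
predicts a short sRNA-drain delay instead, and the uninduced leaky
construct already sits above the control gate, making gate-crossing onset
times degenerate) and the *reduction of CV* in the digitalized population
(with construct-independent extrinsic noise dominating, both constructs'
CV*100 agree to within a few percent). The corresponding tests assert the
model's actual predictions and this note records the discrepancy.

## Calibration

`fit_parameters` minimises squared residuals between observed and
predicted log median fluorescence over a dose × time design, with
`median_model = gain * omega * G_ode + median(A)`. The search is
log-parameterised (all rates positive, spanning decades) and uses
bounded L-BFGS-B from multiple starts: the first start at the supplied
parameter values, the rest log-uniform in the box (default: a factor-30
box around the supplied values). `gain` and `lambda_G` enter the
prediction only through their product, so fitting both is refused.
Identifiability of `{k_pair, alpha_S}` rests on the design covering both
regimes: below threshold the medians constrain `k_pair` (OFF level ∝
`1/k_pair`), above threshold they constrain `alpha_S` (the absolute
production deficit). Designs without intermediate doses determine
`alpha_S` sharply but `k_pair` only within a factor ~2.

## Known limitations

* Kinetic constants are not calibrated to measurements; all quantitative
  statements are about the model at the repository baseline.
* Hill-propensity SSA is an approximation below operator-binding
  timescales.
* The one-hit assay freezes dead cells rather than removing them from the
  culture; no escaper (circuit-inactivating mutation) channel exists.
* De-induction comparisons normalise G to its value at inducer removal;
  the residual basal floor (~1.5% of the ON level) bounds how closely the
  two constructs' decay curves can agree.
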