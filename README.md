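# digisim

Simulation and analysis of an **expression digitalizer**: a portable
mutual-inhibition module that converts the graded, leaky response of an
inducible bacterial promoter into a clean ON/OFF switch.

The circuit couples two antagonists downstream of an inducible promoter P1:

* `mR` — the bicistronic mRNA of a transcriptional repressor R,
  translationally coupled to the gene of interest (readout G);
* `mS` — a small antisense RNA transcribed from a strong promoter P2 that
  is itself repressed by R. `mS` pairs with `mR` and the duplex is
  degraded (co-degradation), so the two RNA pools are mutually exclusive.

With Hill functions `h+(x; K, n) = x^n/(K^n + x^n)` and `h- = 1 - h+`, and
the active transcription factor `tf_a` as external input:

```
dmR/dt = beta_R + alpha_R * h+(tf_a; K_TF, n_act) - (delta_mR + mu) mR - k_pair mR mS
dmS/dt = alpha_S * h-(R; K_R, n_rep)              - (delta_mS + mu) mS - k_pair mR mS
dR/dt  = lambda_R mR - (delta_R + mu) R
dG/dt  = lambda_G mR - (delta_G + mu) G
```

Below a threshold dose the sRNA absorbs all mRNA (expression pinned to the
autofluorescence background); above it, transcription outruns the sRNA
supply and expression switches ON sharply. The package provides:

* `digisim.model` / `digisim.ode` — rate laws, LSODA integration, steady
  states by continuation, dose–response metrics (EC50, 10–90% transition
  width, fold change, effective Hill slope), repression-strength sweeps,
  hysteresis scans, de-induction protocols;
* `digisim.ssa` — exact Gillespie simulation of the same network,
  population snapshots, and one-hit toxin killing (a single toxin molecule
  kills the cell);
* `digisim.cytometry` — synthetic flow-cytometry event tables and
  plate-reader tables with lognormal cell-to-cell noise over an
  autofluorescent background (three constructs: digitalized,
  non-digitalized, promoterless control);
* `digisim.stats` — the benchmark population statistics: median
  fluorescence, CV·100, a no-fluorescence gate at the control's 99.5th
  percentile, fraction of events above the gate;
* `digisim.calibrate` — multi-start least-squares recovery of kinetic
  parameters from summarised time courses;
* a `digisim` command line (`simulate`, `sweep`, `hysteresis`, `ssa`,
  `synth`, `stats`, `fit`, `demo`, `init-config`) driven by one TOML
  configuration.

Intended users: synthetic biologists and modellers who want to explore
when a repressor/sRNA cross-inhibition module digitalizes expression, and
to test population-level analysis pipelines against data with known
ground truth.

## Worked example

```python
import numpy as np
from digisim import baseline_params, repression_sweep

doses = np.concatenate([[0.0], np.logspace(-1, 3, 81)])
sweep = repression_sweep(baseline_params(), np.array([0.3, 1, 3, 10, 30]), doses)
for s, m in zip([0.3, 1, 3, 10, 30], sweep.metrics):
    print(f"strength {s:>4}: OFF={m.off_level:.2e} nM  fold={m.fold_change:9.0f}  "
          f"EC50={m.ec50:5.1f} nM  width={m.transition_width:5.1f} nM")
```

prints

```
strength  0.3: OFF=2.01e-02 nM  fold=     1514  EC50= 85.5 nM  width=171.9 nM
strength    1: OFF=6.13e-03 nM  fold=     7627  EC50= 70.2 nM  width=116.0 nM
strength    3: OFF=2.06e-03 nM  fold=    24412  EC50= 52.1 nM  width=104.2 nM
strength   10: OFF=6.18e-04 nM  fold=    81851  EC50= 50.0 nM  width=102.1 nM
strength   30: OFF=2.06e-04 nM  fold=   245581  EC50= 50.0 nM  width=101.8 nM
```

Each line is the steady-state dose response of the switch with both
inhibitory arms scaled by the given strength (`k_pair` multiplied, `K_R`
divided). Stronger mutual repression drives the uninduced (OFF) mRNA
level down ~proportionally and the ON/OFF fold up, sharpens the
transition, and leaves the half-maximal dose pinned near a common pivot
(~50 nM for strengths ≥ 3) — the digital regime. An end-to-end synthetic
experiment (events → summaries → parameter recovery) is one command:

```bash
digisim demo --outdir demo_out
```

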