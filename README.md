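# oncolattice

A hybrid multiscale simulator of vascular tumour growth for computational
systems-biology work: discrete cell agents (healthy, cancerous, and the
tip/stalk endothelial cells of angiogenic sprouts) on a 3D cubic lattice
with Moore (26-neighbour) interactions, coupled to five continuum
chemical fields — oxygen, glucose, TGFα, TNFα and VEGF — and to a
per-cell phenotype-decision engine in which each cell learns which
phenotype to express from its own experience.

## The model in brief

* **Tissue scale.** A 40×40×40 lattice at 20 µm spacing (one cell
  diameter), with eight parallel parent vessels: four arteries on the
  vertical mid-face lines and four veins on the vertical edges.  A site
  holds one tissue cell, permanent necrotic debris, or up to four
  endothelial cells.
* **Fields.** Each species obeys an explicit finite-difference
  reaction-diffusion update over the 26-neighbour stencil,
  `C ← C + D·(Δt/ΔS²)·Lap₂₆(C) − U + S [− W]`, with per-phenotype
  cellular uptake, transmural vessel sources `2πR·Pe·(ρ − C)` at perfused
  vessel sites, and (for VEGF) stress-dependent secretion by cancer cells
  plus first-order decay.  Macro steps (1 h) are split into sub-steps
  satisfying the stability bound `D·Δt/ΔS² ≤ 1/26`.
* **Subcellular scale.** Pluggable EGFR and TNF pathway surrogates turn
  local TGFα into PLCγ (arbitrating migrate-versus-proliferate) and local
  TNFα into an accumulating death signal, integrated with an adaptive ODE
  method each hour.
* **Decisions.** Ten state-variable policies contribute reward terms
  `RF_p(x) = tanh((x − threshold_p)/gradient_p)`; the per-cell reward is
  their mean.  Q values for every allowed action come from an ensemble of
  three support-vector regressors (RBF, polynomial, sigmoid) whose
  hyper-parameters `(C, ε, γ)` are chosen by NSGA-II maximising
  cross-validated recall, precision and F-measure, and which vote with
  F-measure weights.  Training samples `(state, action, Q)` with reward
  above a threshold slide through a FIFO window; the train phase samples
  actions proportionally to shifted Q modulated by the policy biases, the
  test phase greedily.
* **Validation.** Simulated growth curves are calibrated against the
  Gompertz law `n(t) = n0·exp[(α/β)(1 − e^{−βt})]`, a sigmoid
  vessel-growth law and an exponential branching law, with RMSE / MAD /
  MAPE error reporting and biological-range flags for the Gompertz α, β.

See `docs/methods.md` for assumptions, parameter defaults and their
rationale, and known limitations.

## Worked example

`examples/run_simulation.py` runs a small 12³ tissue block for 60 hourly
steps:

```text
 step  n_cancerous  n_necrotic  n_healthy  n_tip  n_stalk  perfused_segments
    0          104           0       1070      0       96                  0
   10          148           0       1085      0       96                  0
   20          193           0       1091    216      565                 12
   30          203           0       1091    534     1190                139
   40          203           0       1091    538     1194                140
   50          204           0       1091    538     1194                140
```

The cancer seed roughly doubles over the first 20 h while healthy
tissue, initialised homeostatic, holds its count; as the tumour outgrows
its oxygen supply its stressed cells secrete VEGF, the parent-vessel
stalk cells sprout (tip/stalk counts jump after step 10), perfused
segments appear where an arteriole path reaches the venous side, and
growth slows as the small 12³ block's free space fills.

`examples/qlearning_toy_mdp.py` validates the learning loop against
dynamic programming on a 3-state chain:

```text
state  action   learned Q   optimal Q*
  s0   advance     1.3115     1.3115
  s1   advance     1.6393     1.6393
  s2   advance     2.0492     2.0492
max |Q - Q*| = 0.0000
```

`examples/fit_growth_laws.py` recovers Gompertz parameters from a noisy
series (`fitted: n0=100.040 alpha=0.01066 beta=0.33962`, MAPE 0.67%);
`examples/diffusion_fields.py` and `examples/svr_ensemble.py` demonstrate
the field solver and the NSGA-II-tuned kernel ensemble.

The command line mirrors the library:

```bash
oncolattice simulate --config my_run.yaml --mode train --seed 1 --out runs/r1
oncolattice validate --trace runs/r1/trace.csv
oncolattice fitlaws --series counts.csv --law gompertz
```

Every run directory is self-describing (resolved config, seed, per-step
trace, snapshots, experience dataset) and reproduces bit-for-bit.

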