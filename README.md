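# flowfe

Targeted free-energy estimation between **non-overlapping metastable states**
via normalizing-flow maps to a common uniform reference.

## The problem

Molecular systems (conformers of a small molecule, wells of a rugged
landscape) often decompose into metastable states that share no
configurations.  The reduced free energy of state *i* is
*f*<sub>*i*</sub> = −ln ∫<sub>*i*</sub> e<sup>−*u*</sup> d**r** with
*u* = *U*/k<sub>B</sub>T, and the quantities of interest are the differences
Δ*f*<sub>*ij*</sub> = *f*<sub>*j*</sub> − *f*<sub>*i*</sub> and the
configurational entropy differences Δ*s*<sub>*ij*</sub> =
⟨*u*<sub>*j*</sub>⟩ − ⟨*u*<sub>*i*</sub>⟩ − Δ*f*<sub>*ij*</sub>.  Classical
free-energy perturbation needs configurational overlap, which disjoint
states do not have.

`flowfe` trains one invertible rational-quadratic spline coupling flow per
state, by maximum likelihood on that state's samples, mapping it onto a
shared uniform box.  The push-forward density
ln *q*(**r**) = −*D* ln *L* + ln |det *J*<sub>*r*→*z*</sub>| is exactly
normalized, so the **generalized work function**
φ<sub>*i*</sub>(**r**) = *u*<sub>*i*</sub>(**r**) + ln *q*<sub>*i*</sub>(**r**)
turns into absolute free-energy estimators:

| estimator | formula | samples used |
|---|---|---|
| AVMD / AVBG | ⟨φ⟩ | data / model |
| EXPMD | ln ⟨e<sup>+φ</sup>⟩<sub>p</sub> | data |
| EXPBG | −ln ⟨e<sup>−φ</sup>⟩<sub>q</sub> | model |
| BAR | mixture identity, solved self-consistently | data + model |
| MBAR | K-state joint solve on map-composed (remapped) potentials | all states' data |

State boundaries are enforced by a deterministic cluster rule and a 10²⁰
energy penalty outside the state (exact zero weight in every reweighting
path).  BAR/MBAR carry analytic (asymptotic) error bars; tracking those on
*validation* data, and the batch that maximizes AVMD on validation data, are
the package's overfitting diagnostics.

The package ships self-contained synthetic systems with exact ground truth:
a 3D toy potential of six narrow harmonic wells grouped into three 2-modal
states (truth by grid quadrature) and Gaussian-mixture systems with
closed-form free energies, entropies, and exact CDF maps.

## Worked example

Train a flow on one 2-modal state of the toy system and compare estimators
against quadrature truth:

```python
import numpy as np
from flowfe import (build_toy_system, sample_state, quadrature_free_energy,
                    SplineCouplingFlow, BaseUniform, TrainConfig,
                    train_state_model, RestrictedPotential, work_function,
                    estimate_AV, estimate_EXP, estimate_BAR, flow_sample)

system = build_toy_system()                      # six wells, three states
truth = quadrature_free_energy(system, 1, system.assigner, grid=128)

pool = sample_state(system, 1, system.assigner, 2000, seed=0)
train, val = pool[:1000], pool[1000:]            # 1000 T + 1000 V points

base = BaseUniform(3)
flow = SplineCouplingFlow(3, seed=11)
train_state_model(flow, base, train, val,
                  TrainConfig(n_batches=1000, eval_stride=1000, seed=1))

rp = RestrictedPotential(system, 1, system.assigner)
r_bg, lnq = flow_sample(flow, base, 2000, seed=5)
phi_v = work_function(flow, base, rp, val, "MD")
phi_bg = work_function(flow, base, rp, r_bg, "BG", log_q=lnq)

print(f"truth (quadrature) f_1 = {truth:.3f}")
bar = estimate_BAR(phi_v, phi_bg)
print(f"BAR_V   = {bar.value:.3f} +- {bar.stderr:.3f}")
exp = estimate_EXP(phi_bg)
print(f"EXPBG   = {exp.value:.3f} +- {exp.stderr:.3f}")
print(f"AVMD_V  = {estimate_AV(phi_v).value:.3f}")
```

Output:

```
truth (quadrature) f_1 = 3.701
BAR_V   = 3.706 +- 0.023
EXPBG   = 3.637 +- 0.113
AVMD_V  = 2.850
```

BAR on validation data lands on the quadrature truth within its analytic
error bar after 1000 training batches; EXPBG agrees within noise; the plain
work-function average AVMD is still far off because the map is imperfect —
exactly the behavior that makes AVMD a diagnostic rather than an estimator.

The full study — three states trained with the mid-training
train/validation swap-and-reset, all six estimators evaluated on both splits
and on fresh model samples every 50 batches, coverage against quadrature
truth, and the overfitting report — runs from the command line:

```
flowfe assess-toy --seed 42 --out results/toy
```

which writes `trace.csv` (one row per batch × estimator × split × target),
`summary.csv` (coverage, terminal bias and stderr per series) and
`report.json`/`report.txt`.  In this low-data regime the training-split
estimators drift far from the truth (terminal BAR_T bias ≈ +0.7 at stderr
0.022) while BAR_V and MBAR_V keep ≈ 90–97% of their post-burn-in estimates
within 2σ of the quadrature truth — the qualitative signature the package is
built to expose.  `flowfe sample`, `flowfe train`, `flowfe estimate` and
`flowfe report` expose the individual stages.

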