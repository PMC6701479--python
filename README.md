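# kapflex

Integrative analysis toolkit for flexible, natively asymmetric
multidomain protein dimers — built around the KAP1/TRIM28 archetype: an
antiparallel coiled-coil dimer whose two C-terminal PHD-bromodomain
modules hang from ~200-residue disordered linkers, one close to the
N-terminal RB1B2 modules and one far away.

The package couples four analysis layers that are usually scattered
across separate tools:

1. **Model-free SAXS** — Debye profile calculator for coarse-grained
   bead models, Guinier and rod ("cross-section") Guinier fits,
   dimensionless Kratky analysis, regularized indirect Fourier
   transform to P(r) with automatic Dmax selection, and closed-form
   χ² model-to-data comparison.
2. **Flexible fitting** — elastic-network normal modes in the
   rotations-translations-of-blocks (RTB) basis, nonlinear finite screw
   deformations that preserve rigid-domain geometry exactly, and a
   greedy χ²-minimizing fitting loop with bond-topology regularization
   (`flexfit`), plus ensemble drivers for hundreds of randomized
   starting models.
3. **Ensemble asymmetry readout** — per-protomer collective variables
   (dA, dB) = distance from each mobile-domain COM to the nearest
   terminal module COM, swap-symmetrized Gaussian-mixture clustering,
   Mahalanobis density levels and a 1-D two-Gaussian separation
   statistic.
4. **Binding kinetics and thermodynamics** — single-molecule TIRF trace
   analysis (event detection, dwell-time survival histograms,
   double-exponential dissociation and mono-exponential association
   fits, intensity-based dimer quantification) and one-set-of-sites ITC
   simulation and fitting with ΔG/ΔS bookkeeping.

A synthetic-data layer generates every input the pipeline consumes —
antiparallel dumbbell dimers with planted (dA*, dB*) ground truth,
noisy SAXS profiles, fluorescence time traces, ITC isotherms — so the
full analysis is testable end to end without any external data.
`docs/methods.md` documents the models, defaults and design choices.

## Worked example

Recover a planted asymmetric architecture from nothing but a noisy
synthetic scattering profile:

```python
import numpy as np
from kapflex.pipeline import PipelineConfig, run_asymmetry_pipeline

report = run_asymmetry_pipeline(PipelineConfig.desk(seed=1))
print("converged:", report["n_converged"], "/ 50")
print("cluster centers (dA, dB):")
print(np.round(report["cluster_centers"], 1))
print("1-D means:", np.round(report["one_d"].means, 1),
      "separation:", round(report["one_d"].separation, 1))
```

```
converged: 44 / 50
cluster centers (dA, dB):
[[ 63.8 125. ]
 [125.   63.8]]
1-D means: [ 63.7 124.8] separation: 5.5
```

The desk-scale run (50 randomized starts × 40 iterations × 60 modes on
a ~700-bead dimer) plants mobile-domain displacements of (60, 120) Å,
simulates a 1%-noise scattering profile, and flexibly refits randomized
starting models against it. 44 of the 50 starts converge to χ² ≤ 1.5;
their clustered collective variables return the planted asymmetry as a
mirror pair of centers within a few Å, and the pooled 1-D distance
distribution splits into two well-separated Gaussians — the signature
of a natively asymmetric dimer. The same machinery runs the full-scale
protocol (1,000 × 100) by changing the configuration only.

The kinetics and ITC layers round-trip their published parameter sets
the same way:

```python
import numpy as np
from kapflex import smtirf
from kapflex.synthetic_data import draw_bright_times

km = smtirf.KineticModel(tau_off_1=0.25, A1=87.0, tau_off_2=2.26,
                         A2=13.0, k_on=3.64e6, concentration=3e-9)
d = draw_bright_times(km, 5000, np.random.default_rng(42))
d = np.floor(d / 0.05) * 0.05          # 20 Hz camera discretization
curve = smtirf.SurvivalCurve.from_durations(d[d >= 0.05])
fit = smtirf.fit_dissociation(curve)
print(round(fit.tau_off_1, 3), round(fit.A1, 1),
      round(fit.tau_off_2, 2), round(fit.A2, 1))
```

```
0.244 87.6 2.22 12.4
```

i.e. the fast/slow residence times and amplitudes are recovered within
a few percent from 5,000 discretized dwells.

## Command line

`kapflex` exposes the stages as subcommands: `simulate`,
`saxs-analyze`, `flexfit`, `cluster`, `smtirf`, `itc`, and `replay`
(the end-to-end synthetic experiment). For example:

```bash
kapflex simulate --planted 60 120 --seed 2 --out sim/
kapflex saxs-analyze sim/profile.dat
kapflex replay --desk --seed 1 --out replay_out/
```

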