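# tirfquant

Quantification pipelines for in-vitro microtubule TIRF assays: dynamic
instability from kymographs, gamma lifetime statistics, polyglutamylation
linescan scoring, equilibrium binding, and rigid drift registration — plus
a synthetic-data generator with known ground truth so every stage can be
validated without real imaging data.

## Who this is for

Labs reconstituting microtubule dynamics on stabilized GMPCPP seeds and
imaging them by TIRF microscopy, and in particular anyone studying
microtubule polymerases such as the Elongator complex, whose Elp123
subcomplex binds microtubule tips while the Elp456 subcomplex delivers free
tubulin heterodimers — with a strong preference for polyglutamylated
tubulin. The package reimplements the quantification used in such studies
as tested, reusable code.

## What it computes

* **Kymograph dynamics** (`tirfquant.kymo`). Tips are traced per frame as
  the farthest half-maximum crossing of the intensity profile beyond the
  seed; growth events are segmented at catastrophes (a >3 px single-frame
  regression); speeds are ordinary least-squares slopes of position vs
  time (µm/min); polarity is assigned by speed (fast = plus end, slow =
  minus end).
* **Lifetime statistic** (`tirfquant.lifetime`). Growth-event lifetimes τ
  (onset to last frame before catastrophe) are fitted by gamma maximum
  likelihood: k̂ solves log k − ψ(k) = log x̄ − mean(log x), θ̂ = x̄/k̂. The
  summary statistic is the fitted gamma's median t₅₀ (the lifetime at half
  cumulative distribution), with error estimated as the interquartile
  range of t₅₀ over 10,000 bootstrap resamples.
* **Binding** (`tirfquant.binding`). The exact 1:1 quadratic-depletion
  equilibrium [RL] = ((R+L+K_d) − √((R+L+K_d)² − 4RL))/2, occupancy
  predictions between affinity variants, and nonlinear least-squares K_d
  fitting (log-space) of thermophoresis-style two-fold dilution series.
* **PTM linescans** (`tirfquant.ptm`). 2-px-wide linescans along traced
  microtubules, edge background subtraction, FOV averaging, and
  normalization to the seed channel:
  normalized = 100 × mean_MT(antibody) / mean_seed(488).
* **Registration** (`tirfquant.registration`). Per-frame drift by
  cross-correlation of successive frames with quadratic subpixel
  refinement, measured on one channel and applied to all.
* **Synthetic data** (`tirfquant.synthetic`). Seeded microtubules growing
  at constant speed per end with gamma-distributed catastrophe times,
  rendered kymographs and multichannel fields of view with Gaussian PSF
  and noise, rigid drift tracks, and quadratic-depletion titration curves.

## Worked example

```python
import numpy as np
from tirfquant.binding import percent_reduction, complex_concentration
from tirfquant.synthetic import DynamicsParams
from tirfquant.workflows import recover_growth_speeds, recover_lifetime_statistic

# Occupancy prediction: how much Elp123·Elp456 complex is lost when an
# interface mutation weakens Kd from 15.5 to 67.1 nM, at 50 nM Elp123
# and 100 nM Elp456 total?
print(complex_concentration(50e-9, 100e-9, 15.5e-9))   # 39.77 nM bound
print(complex_concentration(50e-9, 100e-9, 67.1e-9))   # 26.19 nM bound
print(percent_reduction(15.5e-9, 67.1e-9, 50e-9, 100e-9))  # 34.1 %

# Simulate 30 seeds at the buffer-control condition, render kymographs,
# and re-measure plus-end growth speeds with the full pipeline:
r = recover_growth_speeds(DynamicsParams(), n_seeds=30, duration_s=600.0,
                          rng_seed=0)
v = r["speeds"]["plus"]
print(v.mean(), v.std(ddof=1) / np.sqrt(v.size))
# 1.018 +/- 0.016 um/min (n=101) vs the generating 1.002 um/min

# Lifetime chain on 300 gamma lifetimes whose true median is 202.61 s:
fit = recover_lifetime_statistic(202.61, n_events=300, rng_seed=0,
                                 n_bootstrap=10_000)
print(fit.t50, fit.bootstrap_error)   # 199.91 +/- 9.93 s
```

The occupancy numbers say that at assay concentrations the mutant loses
about a third of its bound complex — enough to blunt, but not abolish, the
stabilizing activity. The recovery runs show the measurement pipelines are
unbiased: the recovered speed and lifetime agree with the generating
values within their standard errors.

## Command line

A thin CLI wraps the library:

```sh
tirfquant simulate events --config cfg.yaml --seed 1 --out out/
tirfquant register --channel seed --in movie.tif --out reg.tif --track track.csv
tirfquant kymo --in kymo.tif --seed-extent 51:79 --out out/
tirfquant lifetime --in lifetimes.csv --bootstrap 10000 --seed 1
tirfquant ptm --in fov.tif --traces traces.csv --seeds seeds.csv --out out/
tirfquant bind fit --in titration.csv
tirfquant bind occupancy --kd-a 15.5e-9 --kd-b 67.1e-9 --r-total 50e-9 --l-total 100e-9
```

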