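# stochexpr

Delayed stochastic simulation of a tet-inducible gene, Fano-factor noise
analysis, and single-cell fluorescence quantification.

## The problem

In *E. coli*, transcription initiation is not instantaneous: after RNA
polymerase binds a promoter it must form the closed and then the open
complex before elongation can begin, and the promoter is unavailable for
the next initiation while this happens.  If the duration of open-complex
formation varies strongly from one initiation to the next, it injects noise
into RNA — and hence protein — copy numbers, and that noise grows with
induction strength (when initiations are frequent enough for the
open-complex step to be limiting).  The experimental signature is a Fano
factor (variance/mean) of single-cell GFP levels that is flat at weak
induction but rises sharply at strong induction, far beyond Poisson
expectations.

This package provides the full computational side of that analysis, usable
by anyone studying promoter kinetics with single-cell fluorescence data:

* **`stochexpr.delayed_ssa`** — a general delayed stochastic simulation
  algorithm (SSA with a time-ordered waiting list for delayed products),
  with a numba-compiled kernel for population-scale runs and a plain-Python
  single-step reference.
* **`stochexpr.models`** — the two-variant gene expression model

  ```
  Pro --k1--> Pro(tau1) + RBS(tau2)     transcription  (promoter sequestered
  RBS --k2--> RBS + P(tau3)             translation     for tau1 while the
  RBS --k3--> 0                         RNA decay       open complex forms)
  P   --k4--> 0                         protein decay
  ```

  with k2 = 0.19 s⁻¹, k3 = 0.004 s⁻¹, k4 = 2·10⁻⁴ s⁻¹, τ2 = 2 s,
  τ3 = 420 s, and five induction conditions (aTc 0–2 ng/ml) encoded as
  k1 ∈ {1.5·10⁻⁴ … 2.8·10⁻²} s⁻¹.  Variant 1 uses a constant τ1 = 19 s;
  variant 2 draws τ1 from a gamma distribution with mean 19 s and SD 400 s
  (shape ≈ 2.3·10⁻³ — a very fat tail).  Closed-form stationary means
  (E[RNA] = (1/k1 + E[τ1])⁻¹/k3, E[P] = E[RNA]·k2/k4) serve as an
  independent oracle.
* **`stochexpr.stats`** — Fano factors, relative means, binned
  distributions, the fit distance D = Σᵢ (Fano(E)ᵢ − Fano(M)ᵢ)² over the
  five induction strengths, and a grid scan that fits the open-complex
  delay SD by minimising D.
* **`stochexpr.imaging`** — the microscopy quantification pipeline:
  2×2 median filtering, sum projection, permissive threshold + opening,
  solidity/eccentricity cluster detection with extended-maxima splitting,
  brightest-slice intensity extraction, top-2.5% and area outlier rules,
  linear autofluorescence subtraction, and MS2-GFP spot counting by
  intensity-distribution slicing.
* **`stochexpr.synthetic`** — a ground-truthed generator of population
  tables, confocal-like z-stacks of rod-shaped cells, and MS2-GFP spot
  images, so every stage is testable without real data.

## Worked example

```python
import numpy as np
from stochexpr import (ATC_CONDITIONS, MEASURED_GFP_SUMMARY, ModelParams,
                       simulate_population, steady_state_oracle,
                       calibration_factor, fano)

# One global fluorescence-per-protein factor reconciles the measured mean
# GFP levels with the closed-form model means at all five aTc conditions.
oracle = [steady_state_oracle(ModelParams(k1=k1))[1] for _, k1 in ATC_CONDITIONS]
phi = calibration_factor(MEASURED_GFP_SUMMARY["mean"], oracle)
print(f"fluorescence per protein phi = {phi:.1f} a.u./molecule")

for variant in (1, 2):
    pop = simulate_population(ModelParams(k1=2.8e-2, variant=variant),
                              n_cells=500, t_sample=25_000.0, master_seed=1)
    print(f"variant {variant}: mean P = {pop.protein.mean():7.1f} molecules, "
          f"Fano(phi*P) = {fano(phi * pop.protein):8.1f} a.u.")
```

prints

```
fluorescence per protein phi = 53.4 a.u./molecule
variant 1: mean P =  4309.4 molecules, Fano(phi*P) =   1757.8 a.u.
variant 2: mean P =  4381.2 molecules, Fano(phi*P) =  37657.7 a.u.
```

Both variants hit the same mean (they share k1 and the mean open-complex
duration), but the gamma-delay variant's fluorescence Fano factor at strong
induction is ~20× the constant-delay variant's — the mechanism by which
open-complex variability amplifies cell-to-cell diversity.

## Command line

```bash
stochexpr simulate --out runs/sim --n-cells 1000 --variant 2 --seed 1
stochexpr fit measured_summary.csv --out runs/fit --seed 1
stochexpr quantify stack.tif --mode protein --out runs/quant
stochexpr synth --out fixtures/ --seed 5    # ground-truthed test images
```

Every command writes a `manifest.json` (resolved configuration, seeds,
outputs) sufficient to reproduce its results bit-identically.

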