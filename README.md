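# rbale

Simulation and parameter estimation for **long-term repetitive-batch
adaptive laboratory evolution (rbALE)** in automated microbioreactors.

## The problem

In rbALE, a microbial culture grows in one well of a microtiter plate until
its backscatter signal (BS, an arbitrary-unit proxy for biomass) reaches a
trigger threshold; a small volume is then transferred into fresh medium in
the next well, and the cycle repeats. Emptying, washing and drying the used
well ("well recycling") removes the plate-size limit on consecutive
batches, so the number of cell generations an experiment can accumulate is
technically unlimited. Selection during the repeated batches enriches
faster-growing mutants — e.g. *Corynebacterium glutamicum* evolving
improved ethanol utilization at 428 mM ethanol.

This package is for scientists who design or analyse such experiments. It
provides:

* **core_models** — the process models:
  * linear calibration `X = (BS − b)/a` between backscatter and biomass;
  * piecewise-exponential rbALE growth, `X(t) = X_i · e^{μ_i (t − t_i)}`
    within batch *i*, with instantaneous dilution `X → X/f_dil` at each
    transfer (`f_dil = (800 + 50)/50 = 17` µL for the standard pipetting);
  * a WT/mutant competition variant whose apparent per-batch rate climbs
    from `μ_wt` toward `μ_evo` as the mutant takes over;
  * classical Monod batch kinetics,
    `dX/dt = μ_max S/(K_S + S) · X`, `dS/dt = −(1/Y_X/S) μ_max S/(K_S+S) · X`.
* **workflow_sim** — a discrete-event simulator of the scheduling logic:
  threshold triggering on the 15-min measurement grid, tempering delays,
  well recycling with wash/dry constraints, wrap-around reuse, fan-out
  (glucose-chain / ethanol-branch) layouts, and capacity arithmetic
  (generations per batch `log₂(BS_end/BS_start)`; a 48-well plate without
  recycling caps at `48 × 3 ≈ 144` generations).
* **synthetic_data** — generators for every input the pipeline consumes
  (noisy backscatter series, transfer-event logs, plate layouts, replicate
  bioreactor tables), always returning the ground truth alongside.
* **estimation** — multi-start least-squares fitting of per-batch growth
  rates, dilution factor and initial biomass to backscatter data; joint
  hierarchical Monod fitting over replicate bioreactors (global `μ_max`,
  `K_S`, `Y_X/S`; local `X_0`, `S_0`); residual-bootstrap confidence
  intervals; a log-linear slope oracle.
* **cli** — a `rbale` command tying the stages into a reproducible
  pipeline (`simulate-rbale`, `simulate-bioreactor`, `fit-rbale`,
  `fit-monod`, `capacity`, `report`).

## Worked example

Recover per-batch growth rates from a synthetic 16-batch wild-type glucose
run (true rate 0.41 h⁻¹, 2 % multiplicative measurement noise):

```python
from rbale import synthetic_data as sd
from rbale.estimation import fit_rbale, bootstrap_ci

ds = sd.gen_rbale_dataset(sd.glucose_validation(seed=7, cv=0.02))
fit = fit_rbale(ds.timeseries, ds.events)
fit = bootstrap_ci(fit, n_boot=100, seed=7)

mu = fit.estimates["mu"]
lo, hi = fit.ci["mu[1]"]
print(f"mean mu  = {mu.mean():.3f} 1/h  (truth 0.41)")
print(f"f_dil    = {fit.estimates['f_dil']:.2f}   (truth 17)")
print(f"batch 1: mu = {mu[0]:.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
```

prints

```
mean mu  = 0.410 1/h  (truth 0.41)
f_dil    = 17.06   (truth 17)
batch 1: mu = 0.404  95% CI [0.398, 0.411]
```

i.e. the estimator recovers the batch-wise specific growth rate to well
within the 0.41 ± 0.05 h⁻¹ band typical of glucose-grown *C. glutamicum*,
and the dilution factor matches the pipetting volumes. The same pipeline
runs from the shell:

```bash
rbale simulate-rbale --scenario constant --seed 7 --out run/
rbale fit-rbale --data run/ --out run/fit --bootstrap 100
rbale report --run run/
```

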