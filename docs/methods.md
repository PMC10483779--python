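# Methods

## Models

### rbALE growth model

Within one batch the culture grows exponentially with a
substrate-independent specific rate: `X(t) = X_start,i · exp(μ_i (t − s_i))`.
This is justified because, for the organisms and media emulated here,
substrate concentrations stay far above the affinity constants for
essentially the whole batch, so `μ ≈ μ_max` until the trigger fires.
Substrate is therefore not a state variable of the rbALE model; depletion
enters only through the trigger threshold (workflow layer) and through the
separate Monod model (bioreactor layer).

At a transfer event the biomass is divided instantaneously by the dilution
factor `f_dil`; for the standard 50 µL inoculum into 800 µL fresh medium,
`f_dil = 850/50 = 17`. The fresh medium is tempered for one 15-min
measurement cycle before inoculation; this is modelled as a lag during
which the diluted culture holds constant — the new batch's growth clock
starts one cycle after the transfer timestamp. The trajectory is
left-continuous at transfers (evaluating at the transfer time returns the
pre-dilution biomass, matching the last observation of the closing batch).

The piecewise solution is analytic. An adaptive ODE integration
(`rtol = atol = 1e−8`) of the same model is kept as an independent
cross-check and agrees with the analytic path to better than 1e−6 relative
error; the property suite exercises this on random parameter draws.

### Calibration and generations

Backscatter maps linearly to biomass, `X = (BS − b)/a`. Given only
backscatter data, `(a, b, X_0)` are jointly degenerate — any combination
with the same `a·X_0 + b` and scaling fits identically — so the default
fixes `a = 1, b = 0` and reports biomass in backscatter units. Joint
`(a, b)` estimation is an opt-in that requires pinning `X_0`.

Generations per batch are `log₂(BS_end/BS_start)` on blank-corrected
signal. Two accounting conventions coexist deliberately:

* **capacity arithmetic** uses the nominal ~3 generations per batch from
  the raw start ≈ 8 / threshold = 60 figures (`log₂ 7.5 = 2.91`), which is
  how plate capacity (144 generations without recycling, 288 achieved in a
  96-batch recycled run) is conventionally quoted;
* **trajectory accounting** uses the physical dilution factor 17, under
  which a steady-state batch spans `log₂ 17 = 4.09` doublings (each batch
  after the first starts at threshold/17 ≈ 3.5, not at 8).

Batch records carry the exact per-batch `log₂` ratios; `plan_capacity`
takes the nominal figure as an input.

### Competition model

Wild type and mutant grow as independent exponentials sharing every
dilution, so the mutant fraction follows
`odds_{k+1} = odds_k · exp((μ_evo − μ_wt) Δt_k)` and is unchanged by
transfers. The apparent batch rate `ln(X_tot,end/X_tot,start)/Δt` is
bounded by `[μ_wt, μ_evo]`, rises monotonically as the mutant takes over,
and converges to `μ_evo`. The default emergence scenario plants the mutant
at a biomass fraction of 1e−6 in batch 2, emulating a single-cell mutation
event early in the run.

### Monod batch model

Classical Monod kinetics with globals `(μ_max, K_S, Y_X/S)` shared across
replicate reactors and locals `(X_0, S_0)` free per reactor (each reactor
is started separately). The right-hand side clips `S` at zero; the
conserved quantity `X + Y_X/S · S` is preserved to ≤ 1e−6 relative at the
default tolerances (`rtol 1e−8`, `atol 1e−10`). During fitting the ODE
tolerance is relaxed to 1e−7 for speed; the conservation guarantee is
stated for the simulation path.

The substrate uptake rate at excess substrate follows from the yield
identity `q_S = μ_max/(Y_X/S · M) · 1000` (mmol g⁻¹ h⁻¹). For
`μ_max = 0.15 h⁻¹`, `Y_X/S = 0.45 g/g` and ethanol (M = 46.069 g/mol) this
gives **7.24 mmol g⁻¹ h⁻¹**. Reported experimental uptake rates for the
same kinetics can differ (e.g. 8.45 mmol g⁻¹ h⁻¹ has been reported for
cultures with these growth parameters, which would imply a lower effective
yield, maintenance consumption, or evaporation losses); the package
computes the identity and does not force agreement.

## Workflow simulation

Events snap to the 15-min measurement grid. The trigger fires at the first
grid point at or above the threshold (quantization ≤ one cycle); the
threshold is an absolute blank-corrected backscatter value supplied in
configuration (60 by default, i.e. 60 % of the expected final signal) and
is never inferred from data. When several groups trigger in the same
cycle, they are processed in group-label order so event logs are
deterministic.

Well recycling: after harvest a well is washed (2 × 900 µL) and needs a
minimum drying time (default 40 h) before reuse. Because a full wrap of an
8-well group takes ~50 h at typical rates, the default workflow never
violates this. Violations are warnings by default (residual liquid at the
observed magnitudes does not measurably perturb the next batch; any
surviving carryover cells are immediately outgrown) with a strict mode
available; scheduling a well that is still occupied is always a hard
error. Residual-volume biomass carryover is deliberately not modelled.

Fan-out topology: glucose rows run as ordinary chains; each glucose
trigger simultaneously inoculates the ethanol branch well in the same
column, so every ethanol batch descends from the concurrent glucose batch
and never from a previous ethanol batch.

Stop rules bound batches per group and/or wall time. A robot-failure pause
can be injected as an interval during which triggers are deferred and
growth saturates at a configurable stationary plateau.

## Synthetic data

The generator produces what the estimators consume, with known ground
truth: trigger/transfer times come from the noiseless schedule, each well
reports `blank + a·X(t) + b` between its inoculation and trigger plus one
pre-inoculation blank reading during tempering, and noise is applied to
the raw readings afterwards.

Defaults (chosen once as the study conditions): start backscatter 8,
threshold 60, per-well blank 2, `f_dil` 17, 16 batches; glucose scenario
μ = 0.41 h⁻¹; switching scenario stepping 0.085 → 0.16 (batch 5) → 0.21
(from batch 10); competition scenario μ_wt = 0.085, μ_evo = 0.21 h⁻¹;
bioreactor scenario 428 mM ethanol (19.72 g/L), μ_max = 0.15 h⁻¹,
K_S = 0.01 g/L, Y_X/S = 0.45 g/g, four reactors inoculated to OD 3.5,
sampled every 2 h for 20 h. Noise defaults: multiplicative Gaussian, CV 2 %
on backscatter and 3 % on offline CDW/ethanol — typical microbioreactor
and offline-assay repeatability. The OD→CDW factor defaults to
0.25 g L⁻¹ per OD unit and is configurable (it is instrument- and
strain-specific; users with their own correlation should set it).

What the generator does **not** emulate, and what passing recovery tests
therefore do not demonstrate for real data: lag and death phases,
evaporation drift, plate-position and optode effects, noise-coupled
trigger jitter (triggers are decided on the noiseless signal), residual
substrate carryover on medium switches, and biological batch-to-batch
variability beyond the configured rate schedule. An optional initial-lag
parameter can reproduce an anomalous slow first batch (e.g. after an
insufficient washing step during a carbon-source change); it is off by
default, and such batches are handled at the fitting stage by the explicit
exclusion mask — never by automatic outlier rejection.

## Estimation

Segmentation cuts the long-format series into per-batch slices
(inoculation to trigger), normalizing each by the destination well's last
pre-inoculation reading. Without an event log, transfers are detected
where the signal drops by more than 50 % between consecutive cycles; on
simulated data this recovers the logged windows to within one cycle.
Slices with fewer than 4 points are flagged and excluded with a warning.

The rbALE fit minimizes squared deviations between blank-corrected
measurements and the analytic trajectory over one rate per batch, the
shared dilution factor (one `f_dil` for the whole run) and `X_0`, using
multi-start trust-region least squares (default 10 starts; start 0 is the
undisturbed initial guess — per-batch log-linear slopes, `f_dil = 17` from
the pipetting volumes, `X_0` from the first observation — and subsequent
starts apply seeded log-normal jitter, SD 0.2). Optimizer tolerances are
1e−8 with at most 500 function evaluations per start. The number of rate
switches is not model-selected: one rate per batch is estimated, and
changepoint-count selection is out of scope.

The hierarchical Monod fit stacks all reactors into one weighted
least-squares problem; each observable is weighted by the reciprocal of
its overall data range, since CDW and substrate differ by an order of
magnitude in natural units. Approximate intervals come from the
Jacobian-based covariance at the optimum; a parameter whose interval spans
more than a factor of 10 is flagged weakly identifiable — with
`S_0 ≈ 19.7 g/L ≫ K_S`, `K_S` is always so flagged, which is the expected
behaviour, not a failure.

Uncertainty for reported rates uses a residual-resampling bootstrap
(percentile intervals, default 95 %, seeded): residuals are resampled
i.i.d. across observations and refits start from the point estimate. With
multiplicative noise the residuals are mildly heteroscedastic, so the
percentile intervals under-cover slightly; a 50-run calibration study at
CV 2 % (4-batch runs, 60 resamples — sizes chosen to keep the study
desk-scale) measures ~81 % coverage for the nominal 95 % intervals. Fewer
than half the replicates converging flags the intervals unreliable.

## Numerical conventions

Time in hours, biomass in g_CDW L⁻¹ (or backscatter units under the
identity calibration), substrate in g/L internally with mM conversion by
molar mass (ethanol 46.069, glucose 180.156 g/mol). Degenerate inputs
raise typed errors (`ConfigurationError`, `NegativeBiomassError`,
`IntegrationError` with solver diagnostics); constraint violations found
by the schedule validator are returned as data, not raised.

## Known limitations

* No oxygen transfer, pH dynamics, maintenance energy or product toxicity.
* The rbALE fit assumes the transfer times are known (from the event log)
  or detectable from clean drops; heavily corrupted series may need manual
  segmentation.
* Bootstrap intervals are percentile-based and mildly anti-conservative at
  small batch counts (see the coverage figure above).
* `K_S` is structurally near-unidentifiable from batch data where
  `S_0 ≫ K_S`; only its upper magnitude is constrained.
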