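"""Synthetic datasets emulating microbioreactor and bioreactor exports.

No public numeric dataset accompanies the experiments this package models,
so every pipeline input is generated here: noisy per-well backscatter time
series on the 15-minute measurement grid for repetitive-batch ALE runs
(constant-rate, stepwise-switching and mutant-competition scenarios),
replicate lab-scale bioreactor tables (cell dry weight and ethanol every
2 h), plate layouts and transfer-event logs. Trajectories come from the
scheduler and model layer and are then perturbed with configurable
measurement noise, and the ground truth is always returned alongside so
estimators can be scored against it.

Default study conditions: start backscatter ~8, trigger threshold 60,
dilution factor 17 (50 uL into 800 uL), wild-type glucose rate 0.41 1/h,
ethanol-evolution rates stepping 0.085 -> 0.16 -> 0.21 1/h over 16 batches,
and 428 mM ethanol bioreactor batches with mu_max 0.15 1/h, Y_X/S 0.45 g/g,
inoculated to OD 3.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import units
from .core_models import (
    Calibration,
    CompetitionParams,
    CompetitionTrajectory,
    MonodLocal,
    MonodParams,
    RbaleParams,
    competition_trajectory,
    rbale_trajectory,
    simulate_monod_batch,
)
from .errors import ConfigurationError
from .workflow_sim import (
    PlateLayout,
    ScheduleResult,
    StopRule,
    TriggerConfig,
    run_schedule,
)

__all__ = [
    "NoiseModel",
    "ScenarioConfig",
    "RbaleDataset",
    "BioreactorDataset",
    "ETOH_R3_MU_SCHEDULE",
    "glucose_validation",
    "ethanol_evolution_r3",
    "competition_takeover",
    "bioreactor_lab_scale",
    "gen_rbale_dataset",
    "gen_bioreactor_dataset",
    "write_fixtures",
    "read_rbale_fixtures",
    "read_bioreactor_fixtures",
]

#: Stepwise ground-truth rate schedule (h^-1) emulating the third ethanol
#: evolution run: ~0.085 in the first batches, reaching 0.16 by batch 5 and
#: plateauing at the final 0.21 from batch 10 on.
ETOH_R3_MU_SCHEDULE: tuple[float, ...] = (
    0.085, 0.085, 0.110, 0.135, 0.160,
    0.170, 0.180, 0.190, 0.200, 0.210,
    0.210, 0.210, 0.210, 0.210, 0.210, 0.210,
)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise law applied to generated observations.

    ``multiplicative-gaussian`` scales each value by ``1 + cv * z`` with
    standard-normal z (cv = coefficient of variation); ``additive-gaussian``
    adds ``sd * z``. Identical seeds give identical datasets.
    """

    kind: Literal["multiplicative-gaussian", "additive-gaussian"] = (
        "multiplicative-gaussian"
    )
    cv_or_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_or_sd < 0:
            raise ConfigurationError("cv_or_sd must be >= 0")
        if self.kind not in ("multiplicative-gaussian", "additive-gaussian"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.cv_or_sd == 0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative-gaussian":
            return values * (1.0 + self.cv_or_sd * z)
        return values + self.cv_or_sd * z


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic experiment: scenario, ground truth, size and noise."""

    scenario: Literal["constant", "switching", "competition", "bioreactor"]
    params: RbaleParams | CompetitionParams | MonodParams
    n_batches: int = 16
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    blank_bs: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_groups: int = 1
    filterset: str = "BS20"

    def __post_init__(self) -> None:
        if self.scenario == "bioreactor":
            if not isinstance(self.params, MonodParams):
                raise ConfigurationError("bioreactor scenario needs MonodParams")
        elif self.scenario == "competition":
            if not isinstance(self.params, CompetitionParams):
                raise ConfigurationError("competition scenario needs CompetitionParams")
        elif self.scenario in ("constant", "switching"):
            if not isinstance(self.params, RbaleParams):
                raise ConfigurationError(f"{self.scenario} scenario needs RbaleParams")
        else:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")


# ---------------------------------------------------------------------------
# Scenario factories (the study conditions)
# ---------------------------------------------------------------------------

def glucose_validation(seed: int = 0, cv: float = 0.02, n_batches: int = 16) -> ScenarioConfig:
    """Constant-rate wild-type glucose run: mu = 0.41 1/h, start BS 8."""
    return ScenarioConfig(
        scenario="constant",
        params=RbaleParams(mu=(0.41,), f_dil=17.0, X0=8.0),
        n_batches=n_batches,
        noise=NoiseModel(cv_or_sd=cv, seed=seed),
    )


def ethanol_evolution_r3(seed: int = 0, cv: float = 0.02) -> ScenarioConfig:
    """Stepwise-switching run emulating the third ethanol evolution replicate."""
    return ScenarioConfig(
        scenario="switching",
        params=RbaleParams(mu=ETOH_R3_MU_SCHEDULE, f_dil=17.0, X0=8.0),
        n_batches=len(ETOH_R3_MU_SCHEDULE),
        noise=NoiseModel(cv_or_sd=cv, seed=seed),
    )


def competition_takeover(
    seed: int = 0,
    cv: float = 0.02,
    n_batches: int = 16,
    initial_fraction: float = 1e-6,
) -> ScenarioConfig:
    """Mutant-takeover run: WT at 0.085 1/h, mutant at 0.21 1/h emerging in
    batch 2 at a vanishing biomass fraction."""
    return ScenarioConfig(
        scenario="competition",
        params=CompetitionParams(
            mu_wt=0.085,
            mu_evo=0.21,
            emergence_batch=2,
            initial_fraction=initial_fraction,
            f_dil=17.0,
            X0=8.0,
        ),
        n_batches=n_batches,
        noise=NoiseModel(cv_or_sd=cv, seed=seed),
    )


def bioreactor_lab_scale(
    seed: int = 0,
    cv: float = 0.03,
    n_reactors: int = 4,
    od_to_cdw: float = units.OD_TO_CDW_DEFAULT,
) -> ScenarioConfig:
    """Four replicate 428 mM ethanol batch reactors inoculated to OD 3.5,
    with the lab-scale kinetic globals mu_max 0.15 1/h, Y_X/S 0.45 g/g."""
    s0 = units.mm_to_gl(428.0, units.MOLAR_MASS_ETHANOL)
    x0 = 3.5 * od_to_cdw
    # deterministic per-reactor spread of the locals (separately started reactors)
    fx = (1.00, 0.97, 1.03, 1.05, 0.96, 1.02, 0.99, 1.04)
    fs = (1.00, 1.02, 0.98, 1.01, 1.03, 0.97, 1.00, 0.99)
    locs = tuple(
        MonodLocal(X0=x0 * fx[i % 8], S0=s0 * fs[i % 8]) for i in range(n_reactors)
    )
    return ScenarioConfig(
        scenario="bioreactor",
        params=MonodParams(mu_max=0.15, K_S=0.01, Y_XS=0.45, locals=locs),
        noise=NoiseModel(cv_or_sd=cv, seed=seed),
    )


# ---------------------------------------------------------------------------
# Dataset containers
# ---------------------------------------------------------------------------

@dataclass
class RbaleDataset:
    """Backscatter time series + event log + layout + ground truth."""

    timeseries: pd.DataFrame  # well, time_h, filterset, value
    events: pd.DataFrame
    layout: PlateLayout
    truth: dict
    schedule: ScheduleResult


@dataclass
class BioreactorDataset:
    """Offline bioreactor tables (reactor, time_h, cdw_gL, ethanol_mM) + truth."""

    tables: pd.DataFrame
    truth: dict


def _truth_dict(config: ScenarioConfig) -> dict:
    d = {
        "scenario": config.scenario,
        "params": dataclasses.asdict(config.params),
        "trigger": dataclasses.asdict(config.trigger),
        "blank_bs": config.blank_bs,
        "noise": dataclasses.asdict(config.noise),
        "n_batches": config.n_batches,
    }
    return d


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_rbale_dataset(config: ScenarioConfig) -> RbaleDataset:
    """Generate a noisy rbALE backscatter dataset plus its true event log.

    The scheduler decides trigger/transfer times from the noiseless
    trajectory; each well then reports raw backscatter
    ``blank + a*X(t) + b`` on the 15-min grid between its inoculation and
    trigger, preceded by one pre-inoculation blank reading taken during
    medium tempering. Noise is applied to the raw readings afterwards.
    """
    if config.scenario == "bioreactor":
        raise ConfigurationError("use gen_bioreactor_dataset for bioreactor scenarios")
    params = config.params
    trig = config.trigger
    layout = PlateLayout.default(n_groups=config.n_groups)
    sched = run_schedule(
        layout, trig, params, StopRule(max_batches=config.n_batches)
    )
    dt = trig.cycle_h
    lag = trig.temper_cycles * dt
    rng = np.random.default_rng(config.noise.seed)

    rows: list[tuple[str, float, str, float]] = []
    for group in layout.group_labels():
        recs = [b for b in sched.batches if b.group == group]
        transfer_times = [r.t_end for r in recs[:-1]]
        grid_parts, wells_parts = [], []
        for r in recs:
            n_cycles = int(round(r.duration_h / dt))
            t = r.t_start + dt * np.arange(n_cycles + 1)
            grid_parts.append(t)
            wells_parts.append([r.well] * len(t))
        grid = np.concatenate(grid_parts)
        if isinstance(params, CompetitionParams):
            traj: CompetitionTrajectory = competition_trajectory(
                params, transfer_times, grid, lag_h=lag, start_time=recs[0].t_start
            )
            bs = traj.backscatter
        else:
            _, bs = rbale_trajectory(
                params, transfer_times, grid, lag_h=lag, start_time=recs[0].t_start
            )
        wells = [w for part in wells_parts for w in part]
        # pre-inoculation blank reading of each destination well
        for r in recs:
            rows.append((r.well, r.t_start - lag, config.filterset, config.blank_bs))
        for w, t, v in zip(wells, grid, bs):
            rows.append((w, t, config.filterset, config.blank_bs + v))

    ts = pd.DataFrame(rows, columns=["well", "time_h", "filterset", "value"])
    ts = ts.sort_values(["time_h", "well"], kind="stable").reset_index(drop=True)
    ts["value"] = config.noise.apply(ts["value"].to_numpy(), rng)

    truth = _truth_dict(config)
    truth["batches"] = sched.batches_frame().to_dict(orient="list")
    return RbaleDataset(
        timeseries=ts,
        events=sched.events_frame(),
        layout=layout,
        truth=truth,
        schedule=sched,
    )


def gen_bioreactor_dataset(
    config: ScenarioConfig,
    n_reactors: int | None = None,
    sample_interval_h: float = 2.0,
    duration_h: float = 20.0,
) -> BioreactorDataset:
    """Generate replicate offline bioreactor tables from the Monod model.

    Each reactor shares the global kinetics and has its own initial
    conditions; CDW (g/L) and ethanol (mM) observations carry independent
    noise draws. The default 2-h sampling over 20 h spans growth, depletion
    and the stationary tail.
    """
    params = config.params
    if not isinstance(params, MonodParams):
        raise ConfigurationError("bioreactor generation needs MonodParams")
    n = n_reactors if n_reactors is not None else len(params.locals)
    if n > len(params.locals):
        raise ConfigurationError(f"only {len(params.locals)} local records for {n} reactors")
    rng = np.random.default_rng(config.noise.seed)
    grid = np.arange(0.0, duration_h + 1e-9, sample_interval_h)

    frames = []
    for r in range(n):
        x, s = simulate_monod_batch(params, replicate=r, grid=grid)
        cdw = config.noise.apply(x, rng)
        eth = config.noise.apply(
            units.gl_to_mm(s, units.MOLAR_MASS_ETHANOL), rng
        )
        frames.append(
            pd.DataFrame(
                {
                    "reactor": f"R{r + 1}",
                    "time_h": grid,
                    "cdw_gL": cdw,
                    "ethanol_mM": eth,
                }
            )
        )
    tables = pd.concat(frames, ignore_index=True)
    truth = _truth_dict(config)
    truth["n_reactors"] = n
    truth["sample_interval_h"] = sample_interval_h
    truth["duration_h"] = duration_h
    return BioreactorDataset(tables=tables, truth=truth)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixtures(dataset: RbaleDataset | BioreactorDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset to its on-disk CSV/JSON dialects; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if isinstance(dataset, RbaleDataset):
        paths["timeseries"] = directory / "timeseries.csv"
        dataset.timeseries.to_csv(paths["timeseries"], index=False)
        paths["events"] = directory / "events.csv"
        dataset.events.to_csv(paths["events"], index=False)
        paths["layout"] = directory / "layout.csv"
        dataset.layout.to_csv(paths["layout"])
    else:
        paths["bioreactor"] = directory / "bioreactor.csv"
        dataset.tables.to_csv(paths["bioreactor"], index=False)
    paths["truth"] = directory / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    return paths


def read_rbale_fixtures(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, PlateLayout, dict]:
    """Read back an rbALE fixture directory: (timeseries, events, layout, truth)."""
    directory = Path(directory)
    ts = pd.read_csv(directory / "timeseries.csv")
    events = pd.read_csv(
        directory / "events.csv", keep_default_na=False, dtype={"source": str, "dest": str}
    )
    layout = PlateLayout.from_csv(directory / "layout.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return ts, events, layout, truth


def read_bioreactor_fixtures(directory: str | Path) -> tuple[pd.DataFrame, dict]:
    directory = Path(directory)
    tables = pd.read_csv(directory / "bioreactor.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return tables, truth
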