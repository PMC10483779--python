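"""Discrete-event simulation of the long-term rbALE scheduling workflow.

Emulates the automated microbioreactor workflow on a 48-well FlowerPlate
(6 rows x 8 columns): backscatter is read every 15 minutes; when a well's
blank-corrected signal reaches the trigger threshold, fresh medium is
dispensed into the next well of the group and tempered for one cycle, the
triggering well is harvested, 50 uL of the harvest inoculates the fresh
medium, and the emptied well is washed and left to dry so it can host a
later batch. With well recycling the chain wraps around the group, so the
number of consecutive batches — and hence cell generations — is unbounded.

Two transfer topologies are supported: the plain linear chain with
wrap-around, and a chain-plus-branch fan-out where every trigger of a
(glucose) chain well additionally inoculates a dedicated (ethanol) branch
well, so each branch batch descends from the concurrent chain batch rather
than from a previous branch batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .core_models import CompetitionParams, RbaleParams, generations_between
from .errors import ConfigurationError

__all__ = [
    "PlateLayout",
    "TriggerConfig",
    "ScheduleEvent",
    "BatchRecord",
    "StopRule",
    "Violation",
    "CapacityReport",
    "ScheduleResult",
    "plan_capacity",
    "run_schedule",
    "validate_schedule",
]

ROWS = "ABCDEF"
N_COLS = 8

#: canonical processing order of events sharing a timestamp
_KIND_ORDER = {
    k: i
    for i, k in enumerate(
        [
            "measure",
            "trigger",
            "dispense_medium",
            "temper",
            "harvest",
            "inoculate",
            "wash",
            "dry_complete",
        ]
    )
}

GrowthParams = Union[RbaleParams, CompetitionParams]


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

@dataclass
class PlateLayout:
    """Well/group/medium assignment of one cultivation plate.

    ``topology`` per group: ``"linear-chain"`` (batches walk along the
    group's wells and wrap around) or ``"chain-plus-branch"`` (each chain
    trigger also inoculates the group's branch well in the same column).
    """

    wells: list[str]
    groups: dict[str, str]  # well -> group label
    media: dict[str, str]  # well -> medium label
    topology: dict[str, str] = field(default_factory=dict)  # group -> rule
    roles: dict[str, str] = field(default_factory=dict)  # well -> chain|branch

    def __post_init__(self) -> None:
        missing = [w for w in self.wells if w not in self.groups]
        if missing:
            raise ConfigurationError(f"wells without group assignment: {missing}")
        for g in set(self.groups.values()):
            self.topology.setdefault(g, "linear-chain")
        for w in self.wells:
            self.roles.setdefault(w, "chain")

    def group_wells(self, group: str, role: str = "chain") -> list[str]:
        return [
            w
            for w in self.wells
            if self.groups[w] == group and self.roles.get(w, "chain") == role
        ]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for w in self.wells:
            if self.groups[w] not in seen:
                seen.append(self.groups[w])
        return seen

    # -- factories ----------------------------------------------------------

    @classmethod
    def default(
        cls,
        n_groups: int = 6,
        wells_per_group: int = N_COLS,
        medium: str = "glucose_111mM",
    ) -> "PlateLayout":
        """Standard rbALE layout: one group per row, linear chains."""
        if n_groups < 1 or n_groups > len(ROWS) or wells_per_group < 1 or wells_per_group > N_COLS:
            raise ConfigurationError("layout exceeds the 6x8 FlowerPlate")
        wells, groups, media = [], {}, {}
        for r in ROWS[:n_groups]:
            for c in range(1, wells_per_group + 1):
                w = f"{r}{c}"
                wells.append(w)
                groups[w] = r
                media[w] = medium
        return cls(wells=wells, groups=groups, media=media)

    @classmethod
    def fanout(
        cls,
        chain_medium: str = "glucose_55mM",
        branch_medium: str = "ethanol_428mM",
    ) -> "PlateLayout":
        """Alternating fan-out layout: rows A, C, E carry glucose chains and
        rows B, D, F the ethanol branch wells inoculated from the chain."""
        wells, groups, media, roles, topo = [], {}, {}, {}, {}
        for chain_row, branch_row in (("A", "B"), ("C", "D"), ("E", "F")):
            g = chain_row
            topo[g] = "chain-plus-branch"
            for c in range(1, N_COLS + 1):
                cw, bw = f"{chain_row}{c}", f"{branch_row}{c}"
                wells += [cw, bw]
                groups[cw] = groups[bw] = g
                media[cw], media[bw] = chain_medium, branch_medium
                roles[cw], roles[bw] = "chain", "branch"
        return cls(wells=wells, groups=groups, media=media, topology=topo, roles=roles)

    # -- CSV round trip ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": self.wells,
                "group": [self.groups[w] for w in self.wells],
                "medium": [self.media[w] for w in self.wells],
                "role": [self.roles.get(w, "chain") for w in self.wells],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateLayout":
        df = pd.read_csv(path)
        layout = cls(
            wells=list(df["well"]),
            groups=dict(zip(df["well"], df["group"])),
            media=dict(zip(df["well"], df["medium"])),
            roles=dict(zip(df["well"], df.get("role", "chain"))),
        )
        for g in layout.group_labels():
            if layout.group_wells(g, "branch"):
                layout.topology[g] = "chain-plus-branch"
        return layout


@dataclass(frozen=True)
class TriggerConfig:
    """Threshold-trigger and liquid-handling configuration.

    The threshold is an absolute blank-corrected backscatter value fixed
    a priori (60 = 60% of the expected final signal); the simulator never
    infers it from data. ``drying_time_h`` is the minimum idle time before
    a washed well may be reused.
    """

    threshold_bs: float = 60.0
    cycle_min: float = 15.0
    temper_cycles: int = 1
    transfer_volume_ul: float = 50.0
    well_volume_ul: float = 800.0
    wash_steps: int = 2
    wash_volume_ul: float = 900.0
    drying_time_h: float = 40.0

    def __post_init__(self) -> None:
        if not (self.threshold_bs > 0):
            raise ConfigurationError("threshold_bs must be > 0")
        if min(self.transfer_volume_ul, self.well_volume_ul, self.wash_volume_ul) <= 0:
            raise ConfigurationError("all volumes must be > 0")
        if self.drying_time_h < 0 or self.cycle_min <= 0:
            raise ConfigurationError("drying_time_h >= 0 and cycle_min > 0 required")

    @property
    def cycle_h(self) -> float:
        return self.cycle_min / 60.0

    @property
    def f_dil(self) -> float:
        """Dilution factor implied by the transfer volumes: (V_well + V_transfer)/V_transfer."""
        return (self.well_volume_ul + self.transfer_volume_ul) / self.transfer_volume_ul


@dataclass(frozen=True)
class ScheduleEvent:
    time_h: float
    kind: str
    source: str | None
    dest: str | None
    batch: int
    group: str


@dataclass(frozen=True)
class BatchRecord:
    group: str
    batch: int  # 1-based
    well: str
    role: str
    t_start: float  # inoculation (h)
    t_end: float  # trigger (h)
    bs_start: float  # blank-corrected backscatter at inoculation
    bs_end: float  # blank-corrected backscatter at trigger
    mu_true: float  # ground-truth (or apparent) rate used in simulation

    @property
    def duration_h(self) -> float:
        return self.t_end - self.t_start

    @property
    def generations(self) -> float:
        return generations_between(self.bs_start, self.bs_end)


@dataclass(frozen=True)
class StopRule:
    """Finite stopping condition; at least one bound must be set.

    ``pause`` optionally injects a robot-failure interval
    ``(start_h, end_h, plateau_bs)`` during which no triggers are processed
    and growth saturates at the plateau backscatter.
    """

    max_batches: int | None = None
    max_time_h: float | None = None
    pause: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.max_batches is None and self.max_time_h is None:
            raise ConfigurationError("stop rule must bound batches or time")
        if self.max_batches is not None and self.max_batches < 1:
            raise ConfigurationError("max_batches must be >= 1")


@dataclass(frozen=True)
class Violation:
    kind: str  # occupancy | drying | provenance
    well: str
    time_h: float
    detail: str


@dataclass(frozen=True)
class CapacityReport:
    batches_per_run: float  # math.inf when recycling
    total_generations: float  # math.inf when recycling
    n_groups: int
    wells_per_group: int
    gens_per_batch: float
    recycle: bool

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.batches_per_run)


@dataclass
class ScheduleResult:
    events: list[ScheduleEvent]
    batches: list[BatchRecord]
    occupancy: dict[str, list[tuple[float, float]]]
    trigger: TriggerConfig
    layout: PlateLayout

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": [e.time_h for e in self.events],
                "kind": [e.kind for e in self.events],
                "source": [e.source or "" for e in self.events],
                "dest": [e.dest or "" for e in self.events],
                "batch": [e.batch for e in self.events],
                "group": [e.group for e in self.events],
            }
        )

    def batches_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [b.group for b in self.batches],
                "batch": [b.batch for b in self.batches],
                "well": [b.well for b in self.batches],
                "role": [b.role for b in self.batches],
                "t_start_h": [b.t_start for b in self.batches],
                "t_end_h": [b.t_end for b in self.batches],
                "bs_start": [b.bs_start for b in self.batches],
                "bs_end": [b.bs_end for b in self.batches],
                "duration_h": [b.duration_h for b in self.batches],
                "generations": [b.generations for b in self.batches],
                "mu_true": [b.mu_true for b in self.batches],
            }
        )

    def total_generations(self) -> float:
        return float(sum(b.generations for b in self.batches))


# ---------------------------------------------------------------------------
# Capacity arithmetic
# ---------------------------------------------------------------------------

def plan_capacity(
    wells_per_group: int,
    n_groups: int,
    recycle: bool,
    gens_per_batch: float,
) -> CapacityReport:
    """Batch and generation capacity of a plate.

    Without well recycling a group of n wells supports exactly n consecutive
    batches, so a 48-well plate at ~3 generations per batch caps at
    48 * 3 = 144 generations. With recycling both figures are unbounded.
    """
    if wells_per_group < 1 or n_groups < 1:
        raise ConfigurationError("need at least one well and one group")
    if wells_per_group * n_groups > len(ROWS) * N_COLS:
        raise ConfigurationError("layout exceeds the 48-well plate")
    if recycle:
        return CapacityReport(
            math.inf, math.inf, n_groups, wells_per_group, gens_per_batch, True
        )
    return CapacityReport(
        batches_per_run=float(wells_per_group),
        total_generations=wells_per_group * n_groups * gens_per_batch,
        n_groups=n_groups,
        wells_per_group=wells_per_group,
        gens_per_batch=gens_per_batch,
        recycle=False,
    )


# ---------------------------------------------------------------------------
# Scheduler
# ---------------------------------------------------------------------------

class _Culture:
    """Growth state of one lineage between transfers (single- or two-population)."""

    def __init__(self, params: GrowthParams, batch0: int = 1):
        self.params = params
        if isinstance(params, CompetitionParams):
            self.x_wt, self.x_evo = params.X0, 0.0
        else:
            self.x = params.X0
        self.batch = batch0  # 1-based index of the *next* batch to start

    def start_batch(self) -> float:
        """Biomass rate bookkeeping at batch start; returns current total X."""
        p = self.params
        if isinstance(p, CompetitionParams):
            if self.batch == p.emergence_batch:
                tot = self.x_wt + self.x_evo
                self.x_evo += p.initial_fraction / (1 - p.initial_fraction) * tot
            return self.x_wt + self.x_evo
        return self.x

    def total_at(self, dt: float) -> float:
        p = self.params
        if isinstance(p, CompetitionParams):
            return self.x_wt * math.exp(p.mu_wt * dt) + self.x_evo * math.exp(
                p.mu_evo * dt
            )
        return self.x * math.exp(p.mu_for_batch(self.batch - 1) * dt)

    def cycles_to_threshold(self, x_thr: float, dt_cycle: float, max_cycles: int) -> int:
        p = self.params
        if not isinstance(p, CompetitionParams):
            mu = p.mu_for_batch(self.batch - 1)
            if self.x >= x_thr:
                return 1
            if mu <= 0:
                raise ConfigurationError("zero growth rate: threshold never reached")
            k = math.ceil(math.log(x_thr / self.x) / (mu * dt_cycle) - 1e-12)
            return max(k, 1)
        for k in range(1, max_cycles + 1):
            if self.total_at(k * dt_cycle) >= x_thr * (1 - 1e-12):
                return k
        raise ConfigurationError("threshold not reached within max_cycles")

    def finish_batch(self, dt: float, f_dil: float, x_cap: float = math.inf) -> tuple[float, float]:
        """Advance to batch end (optionally capped at a stationary plateau),
        dilute; returns (X_end_total, apparent mu)."""
        p = self.params
        if isinstance(p, CompetitionParams):
            tot0 = self.x_wt + self.x_evo
            self.x_wt *= math.exp(p.mu_wt * dt)
            self.x_evo *= math.exp(p.mu_evo * dt)
            tot1 = self.x_wt + self.x_evo
            if tot1 > x_cap:  # stationary plateau: scale both populations
                s = x_cap / tot1
                self.x_wt *= s
                self.x_evo *= s
                tot1 = x_cap
            app = math.log(tot1 / tot0) / dt
            self.x_wt /= f_dil
            self.x_evo /= f_dil
        else:
            tot1 = self.x * math.exp(p.mu_for_batch(self.batch - 1) * dt)
            tot1 = min(tot1, x_cap)
            app = math.log(tot1 / self.x) / dt
            self.x = tot1 / f_dil
        self.batch += 1
        return tot1, app


def _as_growth_map(
    layout: PlateLayout, growth: GrowthParams | Mapping[str, GrowthParams]
) -> dict[str, GrowthParams]:
    labels = layout.group_labels()
    if isinstance(growth, (RbaleParams, CompetitionParams)):
        gm = {g: growth for g in labels}
        for g in labels:
            if layout.topology.get(g) == "chain-plus-branch":
                gm[f"{g}/branch"] = growth
        return gm
    gm = dict(growth)
    for g in labels:
        if g not in gm:
            raise ConfigurationError(f"no growth parameters for group {g!r}")
        if layout.topology.get(g) == "chain-plus-branch" and f"{g}/branch" not in gm:
            raise ConfigurationError(
                f"fan-out group {g!r} needs growth parameters under key '{g}/branch'"
            )
    return gm


def run_schedule(
    layout: PlateLayout,
    trigger: TriggerConfig,
    growth: GrowthParams | Mapping[str, GrowthParams],
    stop: StopRule,
    strict_drying: bool = False,
) -> ScheduleResult:
    """Simulate the full event-driven rbALE workflow.

    ``growth`` is one parameter record applied to every group, or a mapping
    from group label (and ``"<group>/branch"`` for fan-out layouts) to
    records. Biomass is tracked blank-free in calibrated units; the trigger
    fires at the first 15-min measurement cycle at or above the threshold.
    Dilution by ``trigger.f_dil`` happens at the trigger timestamp and the
    next batch's growth clock starts one tempering delay later.

    Groups are simulated independently; the merged event log is ordered by
    time, canonical kind order, then group label (deterministic tie-break).
    Drying-time violations warn by default (``strict_drying=True`` raises);
    scheduling an occupied well is always a hard error.
    """
    growth_map = _as_growth_map(layout, growth)
    dt = trigger.cycle_h
    lag = trigger.temper_cycles * dt
    events: list[ScheduleEvent] = []
    batches: list[BatchRecord] = []
    occupancy: dict[str, list[tuple[float, float]]] = {w: [] for w in layout.wells}
    last_wash: dict[str, float] = {}
    max_t = stop.max_time_h if stop.max_time_h is not None else math.inf
    max_cycles = int((max_t if math.isfinite(max_t) else 10000.0) / dt) + 10

    def check_well_free(well: str, t: float) -> None:
        for (a, b) in occupancy[well]:
            if a <= t < b:
                raise ConfigurationError(
                    f"well {well} scheduled at t={t:.2f} h while occupied [{a:.2f}, {b:.2f})"
                )
        if well in last_wash and t - last_wash[well] < trigger.drying_time_h:
            v = (
                f"well {well} reused {t - last_wash[well]:.2f} h after washing "
                f"(< drying time {trigger.drying_time_h} h)"
            )
            if strict_drying:
                raise ConfigurationError(v)
            warnings.warn(v, stacklevel=2)

    def occupy(well: str, a: float) -> None:
        occupancy[well].append((a, math.inf))

    def release(well: str, b: float) -> None:
        a, _ = occupancy[well][-1]
        occupancy[well][-1] = (a, b)

    x_thr = None  # computed per group from its calibration

    for group in layout.group_labels():
        gp = growth_map[group]
        chain = layout.group_wells(group, "chain")
        if not chain:
            raise ConfigurationError(f"group {group!r} has no chain wells")
        branch = layout.group_wells(group, "branch")
        fanout = layout.topology.get(group) == "chain-plus-branch"
        culture = _Culture(gp)
        # threshold is a blank-corrected backscatter value: X_thr = threshold / a
        x_thr = trigger.threshold_bs / gp.calib.a

        t_disp = 0.0
        b = 0
        prev_well: str | None = None
        while True:
            b += 1
            if stop.max_batches is not None and b > stop.max_batches:
                break
            if t_disp > max_t:
                break
            well = chain[(b - 1) % len(chain)]
            t_inoc = t_disp + lag
            check_well_free(well, t_disp)
            occupy(well, t_disp)
            events.append(ScheduleEvent(t_disp, "dispense_medium", None, well, b, group))
            events.append(ScheduleEvent(t_disp, "temper", None, well, b, group))
            events.append(ScheduleEvent(t_inoc, "inoculate", prev_well, well, b, group))

            x_start = culture.start_batch()
            k = culture.cycles_to_threshold(x_thr, dt, max_cycles)
            t_trig = t_inoc + k * dt
            x_cap = math.inf
            if stop.pause is not None:
                p0, p1, plateau_bs = stop.pause
                if p0 <= t_trig < p1:
                    # robot stopped: trigger deferred past the pause, growth
                    # saturates at the stationary plateau meanwhile
                    t_trig = t_inoc + math.ceil((p1 - t_inoc) / dt - 1e-9) * dt
                    x_cap = plateau_bs / gp.calib.a
            x_end, app_mu = culture.finish_batch(t_trig - t_inoc, trigger.f_dil, x_cap)
            events.append(ScheduleEvent(t_trig, "measure", well, None, b, group))
            events.append(ScheduleEvent(t_trig, "trigger", well, None, b, group))
            batches.append(
                BatchRecord(
                    group,
                    b,
                    well,
                    "chain",
                    t_inoc,
                    t_trig,
                    gp.calib.to_backscatter(x_start) - gp.calib.b,
                    gp.calib.to_backscatter(x_end) - gp.calib.b,
                    app_mu,
                )
            )

            if fanout:
                # concurrent branch batch inoculated from this chain trigger
                bp = growth_map[f"{group}/branch"]
                if isinstance(bp, CompetitionParams):
                    raise ConfigurationError("branch growth must be RbaleParams")
                bwell = branch[(b - 1) % len(branch)]
                branch_culture = _Culture(bp)
                branch_culture.x = x_end / trigger.f_dil  # inoculum from chain harvest
                check_well_free(bwell, t_trig)
                occupy(bwell, t_trig)
                events.append(
                    ScheduleEvent(t_trig, "dispense_medium", None, bwell, b, group)
                )
                events.append(ScheduleEvent(t_trig, "temper", None, bwell, b, group))
                tb_inoc = t_trig + lag
                events.append(ScheduleEvent(tb_inoc, "inoculate", well, bwell, b, group))
                xb0 = branch_culture.x
                kb = branch_culture.cycles_to_threshold(x_thr, dt, max_cycles)
                tb_trig = tb_inoc + kb * dt
                xb1, app_b = branch_culture.finish_batch(tb_trig - tb_inoc, trigger.f_dil)
                events.append(ScheduleEvent(tb_trig, "measure", bwell, None, b, group))
                events.append(ScheduleEvent(tb_trig, "trigger", bwell, None, b, group))
                th = tb_trig + lag
                events.append(ScheduleEvent(th, "harvest", bwell, None, b, group))
                for _ in range(trigger.wash_steps):
                    events.append(ScheduleEvent(th, "wash", None, bwell, b, group))
                events.append(
                    ScheduleEvent(th + trigger.drying_time_h, "dry_complete", None, bwell, b, group)
                )
                release(bwell, th)
                last_wash[bwell] = th
                batches.append(
                    BatchRecord(
                        group,
                        b,
                        bwell,
                        "branch",
                        tb_inoc,
                        tb_trig,
                        bp.calib.to_backscatter(xb0) - bp.calib.b,
                        bp.calib.to_backscatter(xb1) - bp.calib.b,
                        app_b,
                    )
                )

            last_batch = (
                stop.max_batches is not None and b == stop.max_batches
            ) or t_trig > max_t
            t_harvest = t_trig + lag
            events.append(ScheduleEvent(t_harvest, "harvest", well, None, b, group))
            if not last_batch:
                for _ in range(trigger.wash_steps):
                    events.append(ScheduleEvent(t_harvest, "wash", None, well, b, group))
                events.append(
                    ScheduleEvent(
                        t_harvest + trigger.drying_time_h, "dry_complete", None, well, b, group
                    )
                )
                last_wash[well] = t_harvest
            release(well, t_harvest)
            prev_well = well
            t_disp = t_trig  # fresh medium dispensed at the trigger timestamp
            if last_batch:
                break

    events.sort(key=lambda e: (e.time_h, _KIND_ORDER[e.kind], e.group, e.batch))
    batches.sort(key=lambda r: (r.t_start, r.group, r.role))
    return ScheduleResult(events, batches, occupancy, trigger, layout)


def validate_schedule(
    events: Sequence[ScheduleEvent] | pd.DataFrame, trigger: TriggerConfig
) -> list[Violation]:
    """Check an event log against the workflow's physical constraints.

    Returns an empty list iff (i) no well hosts overlapping batches
    (inoculate..harvest intervals), (ii) every well reuse respects the
    drying time after its last wash, and (iii) every inoculation was
    preceded by a medium dispense and tempering of the destination well.
    Violations are returned as data, never raised.
    """
    if isinstance(events, pd.DataFrame):
        events = [
            ScheduleEvent(
                float(r.time_h),
                str(r.kind),
                str(r.source) or None,
                str(r.dest) or None,
                int(r.batch),
                str(r.group),
            )
            for r in events.itertuples()
        ]
    out: list[Violation] = []
    intervals: dict[str, list[tuple[float, float]]] = {}
    open_at: dict[str, float] = {}
    washes: dict[str, list[float]] = {}
    dispensed: dict[str, list[float]] = {}

    for e in sorted(events, key=lambda e: (e.time_h, _KIND_ORDER[e.kind])):
        if e.kind == "dispense_medium" and e.dest:
            dispensed.setdefault(e.dest, []).append(e.time_h)
        elif e.kind == "inoculate" and e.dest:
            w = e.dest
            # (iii) provenance: dispense + temper delay before inoculation
            ds = [t for t in dispensed.get(w, []) if t <= e.time_h + 1e-9]
            need = trigger.temper_cycles * trigger.cycle_h
            if not ds or e.time_h - ds[-1] < need - 1e-9:
                out.append(
                    Violation(
                        "provenance",
                        w,
                        e.time_h,
                        "inoculation without prior medium dispense + tempering",
                    )
                )
            # (ii) drying
            ws = [t for t in washes.get(w, []) if t < e.time_h]
            if ws and e.time_h - ws[-1] < trigger.drying_time_h - 1e-9:
                out.append(
                    Violation(
                        "drying",
                        w,
                        e.time_h,
                        f"reused {e.time_h - ws[-1]:.2f} h after washing "
                        f"(min {trigger.drying_time_h} h)",
                    )
                )
            # (i) occupancy
            if w in open_at:
                out.append(
                    Violation(
                        "occupancy",
                        w,
                        e.time_h,
                        f"batch starts while batch from t={open_at[w]:.2f} h still open",
                    )
                )
            open_at[w] = e.time_h
        elif e.kind == "harvest" and e.source:
            if e.source in open_at:
                intervals.setdefault(e.source, []).append(
                    (open_at.pop(e.source), e.time_h)
                )
        elif e.kind == "wash" and e.dest:
            washes.setdefault(e.dest, []).append(e.time_h)
    return out
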