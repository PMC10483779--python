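"""Scheduler, capacity arithmetic and constraint validation."""

import math

import numpy as np
import pytest

from rbale.core_models import CompetitionParams, RbaleParams
from rbale.errors import ConfigurationError
from rbale.workflow_sim import (
    PlateLayout,
    ScheduleEvent,
    StopRule,
    TriggerConfig,
    plan_capacity,
    run_schedule,
    validate_schedule,
)

GLU = RbaleParams(mu=(0.41,), X0=8.0)
TC = TriggerConfig()


class TestCapacity:
    def test_full_plate_without_recycling(self):
        rep = plan_capacity(8, 6, recycle=False, gens_per_batch=3.0)
        assert rep.batches_per_run == 8
        assert rep.total_generations == 144
        assert not rep.unbounded

    def test_recycling_is_unbounded(self):
        rep = plan_capacity(8, 6, recycle=True, gens_per_batch=3.0)
        assert rep.unbounded
        assert math.isinf(rep.total_generations)

    def test_single_well(self):
        rep = plan_capacity(1, 1, recycle=False, gens_per_batch=2.9)
        assert rep.batches_per_run == 1
        assert rep.total_generations == pytest.approx(2.9)

    def test_zero_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            plan_capacity(8, 0, False, 3.0)


class TestRunSchedule:
    def test_six_groups_sixteen_batches(self):
        res = run_schedule(PlateLayout.default(), TC, GLU, StopRule(max_batches=16))
        assert len(res.batches) == 96
        assert validate_schedule(res.events, TC) == []

    def test_wraparound_reuses_first_well(self):
        res = run_schedule(
            PlateLayout.default(n_groups=1), TC, GLU, StopRule(max_batches=10)
        )
        by_batch = {b.batch: b.well for b in res.batches}
        assert by_batch[1] == "A1"
        assert by_batch[8] == "A8"
        assert by_batch[9] == "A1"  # wrap to the group's first well

    def test_first_batch_duration_on_grid(self):
        """Growth 8 -> 60 at 0.41 1/h snaps to 5.0 h on the 15-min grid."""
        res = run_schedule(
            PlateLayout.default(n_groups=1), TC, GLU, StopRule(max_batches=1)
        )
        expected = math.ceil(math.log(60 / 8) / 0.41 / 0.25) * 0.25
        assert res.batches[0].duration_h == pytest.approx(expected) == 5.0

    def test_trigger_fires_at_first_cycle_at_or_above_threshold(self):
        res = run_schedule(
            PlateLayout.default(n_groups=1), TC, GLU, StopRule(max_batches=5)
        )
        for b in res.batches:
            assert b.bs_end >= TC.threshold_bs - 1e-9
            # one cycle earlier the signal was still below threshold
            assert b.bs_end * math.exp(-b.mu_true * TC.cycle_h) < TC.threshold_bs

    def test_noiseless_cumulative_generations(self):
        """Sum of per-batch log2 fold-changes: first batch log2(60+/8), later
        batches ~log2(f_dil) since each starts at the previous trigger / 17."""
        res = run_schedule(
            PlateLayout.default(n_groups=1), TC, GLU, StopRule(max_batches=20)
        )
        total = res.total_generations()
        per_batch = [b.generations for b in res.batches]
        assert per_batch[0] == pytest.approx(
            math.log2(res.batches[0].bs_end / 8.0)
        )
        # steady-state batches each contribute ~log2(17) doublings
        assert np.mean(per_batch[1:]) == pytest.approx(math.log2(17), abs=0.2)
        assert total == pytest.approx(sum(per_batch))

    def test_event_log_time_ordered_and_complete(self):
        res = run_schedule(
            PlateLayout.default(n_groups=2), TC, GLU, StopRule(max_batches=4)
        )
        times = [e.time_h for e in res.events]
        assert times == sorted(times)
        kinds = {e.kind for e in res.events}
        assert {"dispense_medium", "temper", "inoculate", "trigger", "harvest", "wash"} <= kinds
        # exactly one trigger and one inoculate per batch record
        n_trig = sum(e.kind == "trigger" for e in res.events)
        n_inoc = sum(e.kind == "inoculate" for e in res.events)
        assert n_trig == n_inoc == len(res.batches)

    def test_competition_growth_supported(self):
        cp = CompetitionParams(
            mu_wt=0.085, mu_evo=0.21, emergence_batch=2, initial_fraction=1e-6, X0=8.0
        )
        res = run_schedule(
            PlateLayout.default(n_groups=1), TC, cp, StopRule(max_batches=16)
        )
        mus = np.array([b.mu_true for b in res.batches])
        assert np.all(np.diff(mus) >= -1e-9)
        assert mus[0] == pytest.approx(0.085, abs=1e-6)

    def test_missing_group_params_rejected(self):
        with pytest.raises(ConfigurationError):
            run_schedule(
                PlateLayout.default(n_groups=2), TC, {"A": GLU}, StopRule(max_batches=2)
            )

    def test_pause_defers_trigger_and_caps_growth(self):
        stop = StopRule(max_batches=3, pause=(4.0, 12.0, 80.0))
        res = run_schedule(PlateLayout.default(n_groups=1), TC, GLU, stop)
        b1 = res.batches[0]
        assert b1.t_end >= 12.0  # trigger deferred past the pause
        assert b1.bs_end <= 80.0  # growth saturated at the plateau


class TestFanout:
    def test_branch_batches_descend_from_concurrent_chain_batch(self):
        lay = PlateLayout.fanout()
        growth = {}
        for g in ("A", "C", "E"):
            growth[g] = RbaleParams(mu=(0.41,), X0=8.0)
            growth[f"{g}/branch"] = RbaleParams(mu=(0.19,), X0=8.0)
        res = run_schedule(lay, TC, growth, StopRule(max_batches=8))
        branch_inocs = [
            e
            for e in res.events
            if e.kind == "inoculate" and e.dest and e.dest[0] in "BDF"
        ]
        assert len(branch_inocs) == 24
        for e in branch_inocs:
            assert e.source[0] in "ACE"  # from the glucose chain, never B/D/F
            assert e.source[1:] == e.dest[1:]  # the well directly above
        assert validate_schedule(res.events, TC) == []

    def test_layout_csv_round_trip(self, tmp_path):
        lay = PlateLayout.fanout()
        p = tmp_path / "layout.csv"
        lay.to_csv(p)
        back = PlateLayout.from_csv(p)
        assert back.wells == lay.wells
        assert back.media == lay.media
        assert back.roles == lay.roles
        assert back.topology == lay.topology
        media_rows = {w[0] for w, m in back.media.items() if "ethanol" in m}
        assert media_rows == {"B", "D", "F"}


class TestValidateSchedule:
    def test_constructed_drying_violation(self):
        ev = [
            ScheduleEvent(0.0, "dispense_medium", None, "A1", 1, "A"),
            ScheduleEvent(0.0, "temper", None, "A1", 1, "A"),
            ScheduleEvent(0.25, "inoculate", None, "A1", 1, "A"),
            ScheduleEvent(5.0, "trigger", "A1", None, 1, "A"),
            ScheduleEvent(5.25, "harvest", "A1", None, 1, "A"),
            ScheduleEvent(5.25, "wash", None, "A1", 1, "A"),
            ScheduleEvent(6.0, "dispense_medium", None, "A1", 2, "A"),
            ScheduleEvent(6.0, "temper", None, "A1", 2, "A"),
            ScheduleEvent(6.25, "inoculate", None, "A1", 2, "A"),  # 1 h after wash
        ]
        v = validate_schedule(ev, TC)
        assert len(v) == 1 and v[0].kind == "drying" and v[0].well == "A1"

    def test_constructed_occupancy_violation(self):
        ev = [
            ScheduleEvent(0.0, "dispense_medium", None, "A3", 1, "A"),
            ScheduleEvent(0.25, "inoculate", None, "A3", 1, "A"),
            ScheduleEvent(1.0, "dispense_medium", None, "A3", 2, "A"),
            ScheduleEvent(1.25, "inoculate", None, "A3", 2, "A"),  # still occupied
        ]
        v = validate_schedule(ev, TC)
        assert any(x.kind == "occupancy" and x.well == "A3" for x in v)

    def test_inoculation_without_dispense_flagged(self):
        ev = [ScheduleEvent(1.0, "inoculate", None, "B2", 1, "B")]
        v = validate_schedule(ev, TC)
        assert any(x.kind == "provenance" for x in v)

    def test_strict_drying_mode_raises(self):
        tc_fast = TriggerConfig(drying_time_h=1000.0)
        with pytest.raises(ConfigurationError):
            run_schedule(
                PlateLayout.default(n_groups=1),
                tc_fast,
                GLU,
                StopRule(max_batches=10),
                strict_drying=True,
            )
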