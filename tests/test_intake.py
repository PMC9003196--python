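"""Intake logging: event semantics, device ingestion, daily statistics."""

from __future__ import annotations

import datetime

import pytest

from nutricontrol import intake
from nutricontrol.errors import ConflictError, DomainError, UnknownFoodError, ValidationError
from nutricontrol.model import IntakeLog, LogKind, NutrientVector
from nutricontrol.plan import meal_vector, plan_totals

T0 = datetime.datetime(2022, 3, 7, 8, 0)
KEY = "2022-03-07"


def ts(hour: int, minute: int = 0) -> datetime.datetime:
    return datetime.datetime(2022, 3, 7, hour, minute)


class TestConfirmAndPartial:
    def test_confirm_consumes_planned_meal(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "monday", "breakfast", T0)
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        expected = meal_vector(simple_plan.meal("monday", "breakfast"), food_table)
        assert stats.consumed == expected

    def test_double_confirmation_conflicts(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "monday", "breakfast", T0)
        with pytest.raises(ConflictError):
            intake.confirm_meal(log, simple_plan, "monday", "breakfast", ts(9))

    def test_confirm_and_partial_mutually_exclusive(self, simple_plan, food_table):
        log = IntakeLog()
        intake.log_partial(log, simple_plan, "monday", "lunch", 50.0, ts(13))
        with pytest.raises(ConflictError):
            intake.confirm_meal(log, simple_plan, "monday", "lunch", ts(14))
        log2 = IntakeLog()
        intake.confirm_meal(log2, simple_plan, "monday", "lunch", ts(13))
        with pytest.raises(ConflictError):
            intake.log_partial(log2, simple_plan, "monday", "lunch", 30.0, ts(14))

    def test_unknown_meal_rejected(self, simple_plan):
        with pytest.raises(ValidationError):
            intake.confirm_meal(IntakeLog(), simple_plan, "monday", "supper", T0)

    def test_two_of_three_meals_hand_sum(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "monday", "breakfast", T0)
        intake.confirm_meal(log, simple_plan, "monday", "lunch", ts(13))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        # bread 100 g (250) + milk 200 g (120) + chicken 150 g (247.5) + rice 200 g (260)
        assert stats.consumed.energy == pytest.approx(250 + 120 + 247.5 + 260)

    def test_full_percentage_equals_confirmation(self, simple_plan, food_table):
        log_a, log_b = IntakeLog(), IntakeLog()
        intake.confirm_meal(log_a, simple_plan, "monday", "lunch", ts(13))
        intake.log_partial(log_b, simple_plan, "monday", "lunch", 100.0, ts(13))
        sa = intake.daily_stats(log_a, simple_plan, "monday", KEY, food_table)
        sb = intake.daily_stats(log_b, simple_plan, "monday", KEY, food_table)
        assert sa.consumed == sb.consumed

    def test_half_meal_halves_energy(self, simple_plan, food_table):
        log = IntakeLog()
        intake.log_partial(log, simple_plan, "monday", "lunch", 50.0, ts(13))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        full = meal_vector(simple_plan.meal("monday", "lunch"), food_table)
        assert stats.consumed.energy == pytest.approx(full.energy / 2)

    @pytest.mark.parametrize("pct", [0.0, -5.0, 100.5])
    def test_percentage_bounds(self, simple_plan, pct):
        with pytest.raises(DomainError):
            intake.log_partial(IntakeLog(), simple_plan, "monday", "lunch", pct, ts(13))


class TestExtraAndSubstitution:
    def test_extra_food_adds_scaled_composition(self, simple_plan, food_table):
        log = IntakeLog()
        intake.log_extra_food(log, food_table, "snackbar", 30.0, ts(11))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.consumed.energy == pytest.approx(150.0)  # 500 kcal/100 g * 0.3

    def test_extra_food_unknown_id(self, food_table):
        with pytest.raises(UnknownFoodError, match="durian"):
            intake.log_extra_food(IntakeLog(), food_table, "durian", 100.0, ts(11))

    def test_identity_substitution_equals_plan(self, simple_plan, food_table):
        log = IntakeLog()
        intake.substitute_food(log, simple_plan, "monday", "lunch", "rice", "rice", 200.0, ts(13))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.consumed == meal_vector(simple_plan.meal("monday", "lunch"), food_table)

    def test_substitution_shifts_energy_by_difference(self, simple_plan, food_table):
        # swap 200 g rice (260 kcal) for 100 g bread (250 kcal): -10 kcal
        log = IntakeLog()
        intake.substitute_food(log, simple_plan, "monday", "lunch", "rice", "bread", 100.0, ts(13))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        full = meal_vector(simple_plan.meal("monday", "lunch"), food_table)
        assert stats.consumed.energy == pytest.approx(full.energy - 10.0)

    def test_substituting_absent_food_rejected(self, simple_plan):
        with pytest.raises(ValidationError):
            intake.substitute_food(IntakeLog(), simple_plan, "monday", "lunch",
                                   "milk", "bread", 100.0, ts(13))

    def test_removal_subtracts_item(self, simple_plan, food_table):
        log = IntakeLog()
        intake.remove_food(log, simple_plan, "monday", "lunch", "rice", ts(13))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        full = meal_vector(simple_plan.meal("monday", "lunch"), food_table)
        rice = food_table["rice"].portion(200.0)
        assert stats.consumed.energy == pytest.approx(full.energy - rice.energy)
        assert stats.consumed.protein == pytest.approx(full.protein - rice.protein)


class TestWaterAndActivity:
    def test_sips_accumulate(self, simple_plan, food_table):
        log = IntakeLog()
        for hour, vol in ((9, 200.0), (12, 150.0), (16, 250.0)):
            intake.log_water(log, vol, ts(hour))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.water_consumed_ml == pytest.approx(600.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(DomainError):
            intake.log_water(IntakeLog(), 0.0, ts(9))

    def test_activity_sums_into_pee(self, simple_plan, food_table):
        log = IntakeLog()
        intake.log_activity(log, 200.0, ts(10))
        intake.log_activity(log, 150.0, ts(18))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.pee_logged_kcal == pytest.approx(350.0)


class TestDeviceIngestion:
    def _write(self, path, rows):
        path.write_text("timestamp,value\n" + "".join(f"{t},{v}\n" for t, v in rows))
        return path

    def test_empty_file(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("timestamp,value\n")
        log, report = intake.ingest_device_csv(IntakeLog(), p, "water")
        assert (report.accepted, report.skipped_duplicates, report.rejected) == (0, 0, [])
        assert len(log) == 0

    def test_water_rows_total(self, tmp_path, simple_plan, food_table):
        rows = [(f"2022-03-07T{h:02d}:00:00", v) for h, v in
                ((8, 200), (10, 250), (12, 300), (15, 200), (18, 250))]
        p = self._write(tmp_path / "w.csv", rows)
        log, report = intake.ingest_device_csv(IntakeLog(), p, "water")
        assert report.accepted == 5
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.water_consumed_ml == pytest.approx(1200.0)

    def test_duplicate_timestamp_first_wins(self, tmp_path):
        p = self._write(tmp_path / "w.csv",
                        [("2022-03-07T08:00:00", 200), ("2022-03-07T08:00:00", 999)])
        log, report = intake.ingest_device_csv(IntakeLog(), p, "water")
        assert (report.accepted, report.skipped_duplicates) == (1, 1)
        assert log.entries[0].volume_ml == 200

    def test_reingestion_is_idempotent(self, tmp_path):
        p = self._write(tmp_path / "w.csv", [("2022-03-07T08:00:00", 200)])
        log, _ = intake.ingest_device_csv(IntakeLog(), p, "water")
        log, report = intake.ingest_device_csv(log, p, "water")
        assert report.accepted == 0 and report.skipped_duplicates == 1
        assert len(log) == 1

    def test_malformed_rows_rejected_with_line_numbers(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("timestamp,value\nnot-a-time,200\n2022-03-07T09:00:00,abc\n2022-03-07T10:00:00,150\n")
        log, report = intake.ingest_device_csv(IntakeLog(), p, "water")
        assert report.accepted == 1
        assert [line for line, _ in report.rejected] == [2, 3]

    def test_activity_kind_feeds_pee(self, tmp_path, simple_plan, food_table):
        p = self._write(tmp_path / "a.csv", [("2022-03-07T21:00:00", 350)])
        log, _ = intake.ingest_device_csv(IntakeLog(), p, "activity")
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)
        assert stats.pee_logged_kcal == pytest.approx(350.0)


class TestDailyStats:
    def test_empty_log_passes_targets_through(self, simple_plan, food_table):
        stats = intake.daily_stats(IntakeLog(), simple_plan, "monday", KEY, food_table)
        assert stats.consumed == NutrientVector.zero()
        assert stats.target.energy == simple_plan.targets.energy_kcal
        assert stats.water_target_ml == simple_plan.targets.water_ml

    def test_mixed_day_matches_brute_force(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "monday", "breakfast", T0)
        intake.confirm_meal(log, simple_plan, "monday", "dinner", ts(20))
        intake.log_extra_food(log, food_table, "apple", 150.0, ts(11))
        intake.log_water(log, 800.0, ts(12))
        intake.log_activity(log, 350.0, ts(21))
        stats = intake.daily_stats(log, simple_plan, "monday", KEY, food_table)

        acc: dict[str, float] = {k: 0.0 for k in NutrientVector.zero().as_dict()}
        for meal_type in ("breakfast", "dinner"):
            for fid, qty in simple_plan.meal("monday", meal_type).items:
                for k, v in food_table[fid].nutrients_per_100g.as_dict().items():
                    acc[k] += v * qty / 100.0
        for k, v in food_table["apple"].nutrients_per_100g.as_dict().items():
            acc[k] += v * 1.5
        assert stats.consumed.as_dict() == pytest.approx(acc)
        assert stats.water_consumed_ml == 800.0
        assert stats.pee_logged_kcal == 350.0

    def test_order_independence(self, simple_plan, food_table):
        events = [
            lambda lg: intake.confirm_meal(lg, simple_plan, "monday", "breakfast", T0),
            lambda lg: intake.substitute_food(lg, simple_plan, "monday", "lunch",
                                              "rice", "bread", 120.0, ts(13)),
            lambda lg: intake.log_extra_food(lg, food_table, "apple", 100.0, ts(11)),
            lambda lg: intake.log_water(lg, 500.0, ts(12)),
        ]
        import itertools
        baseline = None
        for perm in itertools.permutations(events):
            log = IntakeLog()
            for ev in perm:
                ev(log)
            consumed = intake.daily_stats(log, simple_plan, "monday", KEY, food_table).consumed
            if baseline is None:
                baseline = consumed
            assert consumed == baseline

    def test_removing_entry_lowers_consumed_by_its_vector(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "monday", "breakfast", T0)
        intake.log_extra_food(log, food_table, "apple", 100.0, ts(11))
        with_extra = intake.daily_stats(log, simple_plan, "monday", KEY, food_table).consumed
        log.entries = [e for e in log.entries if e.kind is not LogKind.EXTRA_FOOD]
        without = intake.daily_stats(log, simple_plan, "monday", KEY, food_table).consumed
        apple = food_table["apple"].nutrients_per_100g
        diff = {k: with_extra.as_dict()[k] - without.as_dict()[k] for k in apple.as_dict()}
        assert diff == pytest.approx(apple.as_dict())

    def test_fraction_of_target_unity_and_undefined(self, simple_plan, food_table):
        stats = intake.daily_stats(IntakeLog(), simple_plan, "monday", KEY, food_table)
        assert stats.fraction_of_target["energy"] == 0.0
        # sodium and magnesium have no target in the fixture plan
        assert stats.fraction_of_target["sodium"] is None

    def test_temperature_adjusts_water_target(self, simple_plan, food_table):
        stats = intake.daily_stats(IntakeLog(), simple_plan, "monday", KEY, food_table,
                                   temperature_c=27.0)
        assert stats.water_target_ml == pytest.approx(2300.0)
        stats_hot = intake.daily_stats(IntakeLog(), simple_plan, "monday", KEY, food_table,
                                       temperature_c=32.0)
        assert stats_hot.water_target_ml == pytest.approx(2800.0)

    def test_event_key_uses_event_variant(self, simple_plan, food_table):
        log = IntakeLog()
        intake.confirm_meal(log, simple_plan, "train", "event",
                            datetime.datetime(2022, 3, 9, 18, 0), key="train")
        stats = intake.daily_stats(log, simple_plan, "train", "train", food_table)
        assert stats.consumed.energy == pytest.approx(300.0)  # snackbar 60 g
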