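"""Reference protocols, counter selection and workflow composition."""
import pytest

from lapkit.errors import CapacityExceeded, InvalidComponent, MissingMeasurement
from lapkit.format_io import UserVariables
from lapkit.protocols import (
    Criterion,
    CounterSelectionCriteria,
    DEFAULT_PCR_PROFILE,
    TemperatureProfile,
    counter_select,
    make_broken_fixture_cvfs,
    make_fixture_cvf,
    make_measurements_fixture,
    protocol_consolidation,
    protocol_inoculation,
    protocol_pcr_mix,
    validate_cvf,
    write_temperature_profile,
)
from lapkit.vrobot import run_plan


def base_uv(**overrides):
    uv = UserVariables(
        pipR="p300_single", APINameTipR="tiprack_300ul_96",
        pipL="p20_single", APINameTipL="tiprack_20ul_96",
        number_samples=8, source_plate="plate_96_well",
        destination_plate="plate_96_well",
        reagent_rack="tuberack_24_falcon15")
    for key, value in overrides.items():
        setattr(uv, key, value)
    return uv


class TestInoculation:
    def test_wells_end_at_media_plus_inoculum(self, catalog):
        """8 samples x 2 media at 190+10 uL: every destination well ends
        at exactly 200 uL."""
        uv = base_uv(reagent_volumes={"media": 190.0, "inoculum": 10.0})
        uv.extras["media"] = ["LB", "M9"]
        plan, maps = protocol_inoculation(uv, catalog)
        state, _ = run_plan(plan, catalog)
        dest_slots = {slot for slot, _ in plan.sample_assignment.values()}
        filled = [v for (slot, _), v in state.well_volumes.items()
                  if slot in dest_slots]
        assert len(plan.sample_assignment) == 16
        for slot, well in plan.sample_assignment.values():
            assert state.volume_at(slot, well) == pytest.approx(200.0)
        assert maps and sum(len(m.names()) for m in maps) == 16

    def test_overfull_well_refused(self, catalog):
        uv = base_uv(reagent_volumes={"media": 250.0, "inoculum": 10.0})
        uv.extras["media"] = ["LB"]
        with pytest.raises(CapacityExceeded):
            protocol_inoculation(uv, catalog)

    def test_no_media_yields_empty_plan_with_warning(self, catalog):
        uv = base_uv(reagent_volumes={"media": 190.0, "inoculum": 10.0})
        uv.extras["media"] = []
        plan, maps = protocol_inoculation(uv, catalog)
        assert [s.kind for s in plan.steps] == ["comment"]
        assert "warning" in plan.steps[0].note
        assert maps == []

    def test_media_tubes_use_z_tracked_batches(self, catalog):
        uv = base_uv(reagent_volumes={"media": 150.0, "inoculum": 10.0})
        uv.extras["media"] = ["LB"]
        plan, _ = protocol_inoculation(uv, catalog)
        media_aspirates = [s for s in plan.steps
                           if s.kind == "aspirate" and "medium" in s.note]
        # 8 x 150 uL with a 300 uL pipette: 4 two-dispense batches
        assert [s.volume for s in media_aspirates] == [300.0] * 4


class TestConsolidation:
    def test_two_half_plates_fill_destination_exactly(self, catalog):
        uv = base_uv(number_samples=96,
                     reagent_volumes={"sample": 50.0})
        uv.extras["n_source_plates"] = 2
        plan, plate_map = protocol_consolidation(uv, catalog)
        state, _ = run_plan(plan, catalog)
        assert len(plate_map.names()) == 96  # no empty cells
        dest_slot = plate_map.slot
        for well in plate_map.assigned_wells():
            assert state.volume_at(dest_slot, well) == pytest.approx(50.0)

    def test_capacity_pigeonhole(self, catalog):
        uv = base_uv(number_samples=97, reagent_volumes={"sample": 50.0})
        uv.extras["n_source_plates"] = 2
        with pytest.raises(CapacityExceeded):
            protocol_consolidation(uv, catalog)

    def test_single_sample_lands_in_a1(self, catalog):
        uv = base_uv(number_samples=1, reagent_volumes={"sample": 30.0})
        plan, plate_map = protocol_consolidation(uv, catalog)
        assert plan.sample_assignment[0][1] == "A1"
        assert plate_map.assigned_wells() == {"A1": "P1_A1"}

    def test_map_names_trace_source_identity(self, catalog):
        uv = base_uv(number_samples=3, reagent_volumes={"sample": 30.0})
        _, plate_map = protocol_consolidation(
            uv, catalog, sample_names=["clone7", "clone9", "clone12"])
        assert plate_map.assigned_wells() == {
            "A1": "clone7", "B1": "clone9", "C1": "clone12"}


class TestPcrMix:
    def test_mix_total_and_tubes(self, catalog):
        """24 reactions x 20 uL components at 10% excess: 528 uL of
        master mix, one tube."""
        uv = base_uv(number_samples=24, extra_fraction=0.1,
                     reagent_volumes={"template": 2.0})
        uv.extras["components"] = ["buffer", "dntps", "polymerase"]
        uv.extras["volume_component"] = [10.0, 6.0, 4.0]
        plan, profile = protocol_pcr_mix(uv, catalog)
        req = plan.reagent_requirements["master_mix"]
        assert req.total_volume == pytest.approx(528.0)
        assert req.tube_count == 1
        state, _ = run_plan(plan, catalog)
        for slot, well in plan.sample_assignment.values():
            assert state.volume_at(slot, well) == pytest.approx(22.0)

    def test_identity_case_without_excess(self, catalog):
        uv = base_uv(number_samples=1, extra_fraction=0.0,
                     reagent_volumes={"template": 1.0})
        uv.extras["components"] = ["buffer", "dntps"]
        uv.extras["volume_component"] = [12.0, 8.0]
        plan, _ = protocol_pcr_mix(uv, catalog)
        assert plan.reagent_requirements["master_mix"].total_volume == \
            pytest.approx(20.0)

    def test_overfull_reaction_well_refused(self, catalog):
        uv = base_uv(number_samples=8, reagent_volumes={"template": 10.0})
        uv.extras["components"] = ["buffer"]
        uv.extras["volume_component"] = [195.0]
        with pytest.raises(CapacityExceeded):
            protocol_pcr_mix(uv, catalog)

    def test_profile_written_as_yaml_schedule(self, catalog, tmp_path):
        import yaml
        profile = TemperatureProfile.from_strings(["98:30:1", "60:20:35"])
        path = write_temperature_profile(profile, tmp_path / "profile.yaml")
        payload = yaml.safe_load(path.read_text())
        steps = payload["temperature_profile"]
        assert steps[1] == {"temperature_c": 60.0, "duration_s": 20.0,
                            "cycles": 35}
        assert profile.total_seconds() == pytest.approx(30 + 700)

    def test_default_profile_is_valid(self):
        assert all(s.duration_s > 0 and s.cycles >= 1
                   for s in DEFAULT_PCR_PROFILE.steps)


class TestCounterSelect:
    CRITERIA = CounterSelectionCriteria(
        Criterion("fluorescence", ">=", 10.0),
        Criterion("absorbance", "<=", 2.0))

    def test_conjunction_of_thresholds(self):
        rows = [("s1", "fluorescence", 12), ("s1", "absorbance", 1),
                ("s2", "fluorescence", 12), ("s2", "absorbance", 5),
                ("s3", "fluorescence", 4), ("s3", "absorbance", 1)]
        assert counter_select(rows, self.CRITERIA) == ["s1"]

    def test_impossible_conjunction_empty(self):
        rows = make_measurements_fixture([f"s{i}" for i in range(10)], seed=1)
        criteria = CounterSelectionCriteria(
            Criterion("fluorescence", ">=", 1e9),
            Criterion("absorbance", "<=", -1e9))
        assert counter_select(rows, criteria) == []

    def test_all_pass_in_id_order(self):
        ids = ["s10", "s2", "s1"]
        rows = make_measurements_fixture(ids, seed=2)
        criteria = CounterSelectionCriteria(
            Criterion("fluorescence", ">=", -1e9),
            Criterion("absorbance", "<=", 1e9))
        assert counter_select(rows, criteria) == sorted(ids)

    def test_missing_measurement(self):
        rows = [("s1", "fluorescence", 12)]
        with pytest.raises(MissingMeasurement):
            counter_select(rows, self.CRITERIA)

    def test_identical_measurements_rejected(self):
        with pytest.raises(InvalidComponent):
            CounterSelectionCriteria(Criterion("x", ">=", 1),
                                     Criterion("x", "<=", 2))


class TestFixtures:
    @pytest.mark.parametrize("protocol", ["inoculation", "consolidation",
                                          "pcr_mix", "counter_selection"])
    def test_valid_fixtures_validate(self, protocol, catalog):
        for seed in range(5):
            doc = make_fixture_cvf(protocol, seed)
            uv, report = validate_cvf(doc, protocol, catalog)
            assert report.ok, f"{protocol} seed {seed}: {report.summary()}"
            assert uv is not None

    @pytest.mark.parametrize("protocol", ["inoculation", "consolidation",
                                          "pcr_mix", "counter_selection"])
    def test_broken_fixtures_each_fail(self, protocol, catalog):
        for label, doc in make_broken_fixture_cvfs(protocol, seed=0).items():
            uv, report = validate_cvf(doc, protocol, catalog)
            assert uv is None, f"{protocol}/{label} unexpectedly validated"
            assert report.errors, label

    def test_fixture_generation_is_seeded(self):
        a = make_fixture_cvf("pcr_mix", seed=9)
        b = make_fixture_cvf("pcr_mix", seed=9)
        assert a.content_equal(b)


class TestWorkflowComposition:
    def test_counter_select_feeds_consolidation_feeds_pcr(self, catalog):
        """The screening -> cherry-picking -> PCR chain runs green end
        to end on one deck."""
        from lapkit.planning import concat_plans

        ids = [f"s{i:02d}" for i in range(48)]
        measurements = make_measurements_fixture(ids, seed=4)
        criteria = CounterSelectionCriteria(
            Criterion("fluorescence", ">=", 12.0),
            Criterion("absorbance", "<=", 0.7))
        selected = counter_select(measurements, criteria)
        assert 0 < len(selected) < len(ids)

        uv_cons = base_uv(number_samples=len(selected),
                          reagent_volumes={"sample": 30.0})
        cons_plan, cons_map = protocol_consolidation(
            uv_cons, catalog, sample_names=selected)
        assert sorted(cons_map.names()) == selected

        uv_pcr = base_uv(number_samples=len(selected),
                         extra_fraction=0.1,
                         reagent_volumes={"template": 2.0})
        uv_pcr.extras["components"] = ["buffer", "dntps", "polymerase"]
        uv_pcr.extras["volume_component"] = [10.0, 6.0, 4.0]
        pcr_plan, _ = protocol_pcr_mix(uv_pcr, catalog,
                                       occupied=cons_plan.deck_layout)

        # separately: run sequentially on a carried-over deck
        state_a, _ = run_plan(cons_plan, catalog)
        state_a, _ = run_plan(pcr_plan, catalog, state=state_a)
        # merged into one workflow plan
        merged = concat_plans(cons_plan, pcr_plan)
        state_b, log = run_plan(merged, catalog)
        assert state_b.digest() == state_a.digest()
        assert len(log.entries) == len(cons_plan.steps) + len(pcr_plan.steps)
        for held in state_b.pipette_held_volume.values():
            assert held == pytest.approx(0.0)
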