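"""Virtual-robot execution: tips, conservation, atomicity, z-tracking."""
import random

import pytest

from lapkit.errors import (
    DeckFull,
    InsufficientHeldVolume,
    InsufficientVolume,
    NoTipError,
    OverfillError,
    PlanExecutionError,
    SlotOccupied,
    UnsupportedLabware,
    VolumeOutOfRange,
)
from lapkit.labware import DeckState, height_from_volume, make_pipette
from lapkit.planning import ProtocolPlan, TransferStep
from lapkit.protocols import (
    make_fixture_cvf,
    protocol_consolidation,
    protocol_inoculation,
    protocol_pcr_mix,
    validate_cvf,
)
from lapkit.vrobot import (
    DEFAULT_BOTTOM_CLEARANCE,
    DEFAULT_SUBMERSION_OFFSET,
    aspirate,
    build_deck,
    check_tip_and_pick,
    dispense,
    distribute_z_tracking_falcon15ml,
    drop_tip,
    load_labware,
    run_plan,
)


def fresh_state(catalog, with_tips=True):
    state = DeckState()
    state.attach_pipette(make_pipette("right", "p300_single"))
    state.attach_pipette(make_pipette("left", "p20_single"))
    if with_tips:
        state = load_labware(state, 1, catalog.get("tiprack_300ul_96"))
        state = load_labware(state, 2, catalog.get("tiprack_20ul_96"))
    state = load_labware(state, 3, catalog.get("plate_96_well"),
                         {"A1": 180.0, "B1": 30.0})
    state = load_labware(state, 4, catalog.get("tuberack_24_falcon15"),
                         {"A1": 10_000.0, "B1": 5_000.0})
    return state


class TestLoadLabware:
    def test_tiprack_registers_capacity(self, catalog):
        state = DeckState()
        state = load_labware(state, 1, catalog.get("tiprack_300ul_96"))
        assert state.tips_available[1] == 96

    def test_occupied_slot(self, catalog):
        state = DeckState()
        state = load_labware(state, 1, catalog.get("plate_96_well"))
        with pytest.raises(SlotOccupied):
            load_labware(state, 1, catalog.get("plate_96_well"))

    def test_initial_overfill(self, catalog):
        state = DeckState()
        with pytest.raises(OverfillError):
            load_labware(state, 1, catalog.get("tuberack_24_falcon15"),
                         {"A1": 20_000.0})


class TestTipLogistics:
    def test_pick_decrements_rack(self, catalog):
        state = fresh_state(catalog)
        new = check_tip_and_pick(state, "right", catalog)
        assert new.tips_available[1] == 95
        assert new.pipette_has_tip["right"]
        assert not state.pipette_has_tip["right"]  # original untouched

    def test_no_op_when_tip_attached(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        again = check_tip_and_pick(state, "right", catalog)
        assert again.tips_available == state.tips_available
        assert again.digest() == state.digest()

    def test_auto_loads_fresh_rack_when_empty(self, catalog):
        state = fresh_state(catalog)
        state.tips_available[1] = 0
        new = check_tip_and_pick(state, "right", catalog)
        new_slot = next(s for s in new.slots if s not in state.slots)
        assert new.slots[new_slot].api_name == "tiprack_300ul_96"
        assert new.tips_available[new_slot] == 95
        assert new.pipette_has_tip["right"]

    def test_deck_full_when_no_slot_for_rack(self, catalog):
        state = fresh_state(catalog)
        state.tips_available[1] = 0
        for slot in state.free_slots():
            state = load_labware(state, slot, catalog.get("plate_96_well"))
        with pytest.raises(DeckFull):
            check_tip_and_pick(state, "right", catalog)

    def test_drop_tip(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        assert drop_tip(state, "right").pipette_has_tip["right"] is False


class TestAspirateDispense:
    def test_conservation_of_a_transfer(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        total = state.total_liquid()
        state, _ = aspirate(state, "right", (4, "A1"), 30)
        assert state.pipette_held_volume["right"] == 30
        state = dispense(state, "right", (3, "A2"), 30)
        assert state.total_liquid() == pytest.approx(total)
        assert state.pipette_held_volume["right"] == 0

    def test_aspirate_without_tip(self, catalog):
        state = fresh_state(catalog)
        with pytest.raises(NoTipError):
            aspirate(state, "right", (4, "A1"), 50)

    def test_cannot_empty_plate_well_below_zero(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        with pytest.raises(InsufficientVolume):
            aspirate(state, "right", (3, "B1"), 50)  # well holds 30

    def test_dispense_overfill_raises_before_mutation(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        state, _ = aspirate(state, "right", (4, "A1"), 30)
        before = state.digest()
        with pytest.raises(OverfillError):
            dispense(state, "right", (3, "A1"), 30)  # 180 + 30 > 200
        assert state.digest() == before
        assert state.volume_at(3, "A1") == 180

    def test_dispense_more_than_held(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "left", catalog)
        state, _ = aspirate(state, "left", (3, "B1"), 20)
        with pytest.raises(InsufficientHeldVolume):
            dispense(state, "left", (3, "A2"), 50)

    def test_volume_outside_pipette_range(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        with pytest.raises(VolumeOutOfRange):
            aspirate(state, "right", (4, "A1"), 10)  # below p300 minimum


class TestZTrackingDistribute:
    def test_dead_volume_breach(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        state.pipettes["right"] = make_pipette("right", "p1000_single")
        before = state.digest()
        with pytest.raises(InsufficientVolume):
            aspirate(state, "right", (4, "B1"), 4500)  # 5000-4500 < 1000
        assert state.digest() == before

    def test_50ml_tube_refused(self, catalog):
        state = fresh_state(catalog)
        state = load_labware(state, 5, catalog.get("tuberack_6_falcon50"),
                             {"A1": 20_000.0})
        state = check_tip_and_pick(state, "right", catalog)
        with pytest.raises(UnsupportedLabware):
            distribute_z_tracking_falcon15ml(
                state, "right", (5, "A1"), [((3, "A2"), 100.0)])

    def test_greedy_batching(self, catalog):
        """10 dispenses of 100 uL with a 20-300 pipette need 4
        aspirations (300+300+300+100)."""
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        wells = [f"{r}{c}" for c in (2, 3) for r in "ABCDE"]
        dispenses = [((3, w), 100.0) for w in wells]
        state, heights = distribute_z_tracking_falcon15ml(
            state, "right", (4, "A1"), dispenses)
        assert len(heights) == 4
        assert state.volume_at(4, "A1") == pytest.approx(9_000)
        assert all(state.volume_at(3, w) == 100 for w in wells)

    def test_heights_track_falling_surface(self, catalog):
        state = check_tip_and_pick(fresh_state(catalog), "right", catalog)
        geometry = catalog.get("tuberack_24_falcon15").tube_geometry
        expected, volume = [], 10_000.0
        for batch in (300, 300, 300, 100):
            h = height_from_volume(geometry, volume) - DEFAULT_SUBMERSION_OFFSET
            expected.append(max(h, DEFAULT_BOTTOM_CLEARANCE))
            volume -= batch
        dispenses = [((3, f"{r}{c}"), 100.0)
                     for c in (2, 3) for r in "ABCDE"]
        _, heights = distribute_z_tracking_falcon15ml(
            state, "right", (4, "A1"), dispenses)
        assert heights == pytest.approx(expected)
        assert all(b <= a for a, b in zip(heights, heights[1:]))


def _random_fixture_plan(seed, catalog):
    rng = random.Random(seed)
    protocol = rng.choice(("inoculation", "consolidation", "pcr_mix"))
    doc = make_fixture_cvf(protocol, seed)
    uv, report = validate_cvf(doc, protocol, catalog)
    assert report.ok, report.summary()
    if protocol == "inoculation":
        plan, _ = protocol_inoculation(uv, catalog)
    elif protocol == "consolidation":
        plan, _ = protocol_consolidation(uv, catalog)
    else:
        plan, _ = protocol_pcr_mix(uv, catalog)
    return plan


class TestRunPlan:
    def test_empty_plan_is_identity(self, catalog):
        state, log = run_plan(ProtocolPlan(), catalog)
        assert state.total_liquid() == 0
        assert log.entries == []

    def test_conservation_over_random_plans(self, catalog):
        """Liquid is neither created nor destroyed across 60 random
        protocol runs, and pipettes end empty."""
        for seed in range(60):
            plan = _random_fixture_plan(seed, catalog)
            state, log = run_plan(plan, catalog)
            initial = sum(plan.initial_volume_map().values())
            assert state.total_liquid() == pytest.approx(initial), f"seed {seed}"
            for held in state.pipette_held_volume.values():
                assert held == pytest.approx(0)
            assert len(log.entries) == len(plan.steps)

    def test_tip_accounting(self, catalog):
        plan = _random_fixture_plan(11, catalog)
        state, log = run_plan(plan, catalog)
        consumed = sum(
            d.tip_capacity - state.tips_available[s]
            for s, d in state.slots.items() if d.kind == "tiprack")
        assert consumed == log.pick_count()

    def test_failing_step_halts_with_state_and_log(self, catalog):
        plan = ProtocolPlan()
        plan.deck_layout = {1: "tiprack_300ul_96", 2: "plate_96_well",
                            3: "tuberack_24_falcon15"}
        plan.pipettes["right"] = make_pipette("right", "p300_single")
        plan.set_initial_volume(3, "A1", 5_000)
        plan.steps = [
            TransferStep("pick_tip", mount="right"),
            TransferStep("aspirate", mount="right", source=(3, "A1"),
                         volume=150.0),
            TransferStep("dispense", mount="right", destination=(2, "A1"),
                         volume=150.0),
            TransferStep("aspirate", mount="right", source=(3, "A1"),
                         volume=150.0),
            TransferStep("dispense", mount="right", destination=(2, "A1"),
                         volume=150.0),  # 150 + 150 > 200: overfill
        ]
        with pytest.raises(PlanExecutionError) as err:
            run_plan(plan, catalog)
        assert isinstance(err.value.cause, OverfillError)
        # log covers exactly the successful steps; state is their outcome
        assert len(err.value.log.entries) == 4
        state = err.value.state
        assert state.volume_at(2, "A1") == 150
        assert state.pipette_held_volume["right"] == 150

    def test_concatenation_equals_sequential_runs(self, catalog):
        from lapkit.planning import concat_plans
        doc = make_fixture_cvf("consolidation", seed=5)
        uv, _ = validate_cvf(doc, "consolidation", catalog)
        plan, _ = protocol_consolidation(uv, catalog)
        half = len(plan.steps) // 2
        # split so we do not cut an aspirate/dispense pair apart
        while plan.steps[half].kind != "pick_tip":
            half += 1
        p1 = ProtocolPlan(steps=plan.steps[:half],
                          deck_layout=plan.deck_layout,
                          pipettes=plan.pipettes,
                          initial_volumes=plan.initial_volumes)
        p2 = ProtocolPlan(steps=plan.steps[half:],
                          deck_layout=plan.deck_layout,
                          pipettes=plan.pipettes)
        state_seq, _ = run_plan(p1, catalog)
        state_seq, _ = run_plan(p2, catalog, state=state_seq)
        merged = concat_plans(
            ProtocolPlan(deck_layout=plan.deck_layout, pipettes=plan.pipettes,
                         initial_volumes=plan.initial_volumes,
                         steps=plan.steps[:half]),
            ProtocolPlan(steps=plan.steps[half:]))
        state_one, _ = run_plan(merged, catalog)
        assert state_one.digest() == state_seq.digest()
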