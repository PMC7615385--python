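"""Virtual liquid-handling robot.

Executes a :class:`~lapkit.planning.ProtocolPlan` against a
:class:`~lapkit.labware.DeckState` with strict accounting:

* volume conservation — liquid only moves, it is never created or lost;
* tip logistics — a pipette must carry a tip to touch liquid; racks are
  decremented per pick and a fresh rack is auto-loaded when every rack
  of the right type runs dry;
* bounds — a dispense that would overfill a well, or an aspiration that
  would empty a tube below its dead volume, fails *before* any state
  changes (failed steps are atomic no-ops);
* liquid-level (z) tracking — aspirations from conical tubes happen at
  ``height_from_volume(current volume) - submersion offset``, clamped
  to a bottom clearance, so the tip stays just below the surface.

Every executed step is recorded in an :class:`ActionLog` with pre/post
state digests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    DeckFull,
    InsufficientHeldVolume,
    InsufficientVolume,
    InvalidComponent,
    NoTipError,
    OverfillError,
    PlanExecutionError,
    SlotOccupied,
    UnsupportedLabware,
    VolumeOutOfRange,
)
from .labware import (
    DeckState,
    LabwareCatalog,
    LabwareDefinition,
    height_from_volume,
    parse_well_id,
    well_iterator,
)
from .planning import ProtocolPlan, TransferStep

#: How far (mm) below the liquid surface the tip aspirates.
DEFAULT_SUBMERSION_OFFSET = 10.0
#: Minimum tip height (mm) above the tube apex.
DEFAULT_BOTTOM_CLEARANCE = 1.0

#: Nominal capacity (uL) of the only tube type the z-tracked distribute
#: supports.
ZTRACK_SUPPORTED_CAPACITY = 15_000.0


@dataclass(frozen=True)
class LogEntry:
    step_index: int
    step: TransferStep
    pre_digest: str
    post_digest: str
    aspiration_height: float | None = None  # mm, tube-source aspirates only


@dataclass
class ActionLog:
    entries: list[LogEntry] = field(default_factory=list)
    error: str | None = None

    def pick_count(self) -> int:
        return sum(1 for e in self.entries if e.step.kind == "pick_tip"
                   and e.pre_digest != e.post_digest)

    def to_jsonl(self) -> str:
        lines = []
        for e in self.entries:
            d = {"i": e.step_index, "step": e.step.to_dict(),
                 "pre": e.pre_digest, "post": e.post_digest}
            if e.aspiration_height is not None:
                d["aspiration_height_mm"] = round(e.aspiration_height, 4)
            lines.append(json.dumps(d))
        if self.error:
            lines.append(json.dumps({"error": self.error}))
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        lines = []
        for e in self.entries:
            s = e.step
            bits = [f"#{e.step_index:04d}", s.kind]
            if s.mount:
                bits.append(f"[{s.mount}]")
            if s.volume is not None:
                bits.append(f"{s.volume:g} uL")
            if s.source:
                bits.append(f"from {s.source[0]}:{s.source[1]}")
            if s.destination:
                bits.append(f"to {s.destination[0]}:{s.destination[1]}")
            if e.aspiration_height is not None:
                bits.append(f"@ z={e.aspiration_height:.2f} mm")
            if s.note:
                bits.append(f"({s.note})")
            lines.append(" ".join(bits))
        if self.error:
            lines.append(f"ERROR: {self.error}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path, fmt: str = "jsonl") -> Path:
        path = Path(path)
        path.write_text(self.to_jsonl() if fmt == "jsonl" else self.to_text(),
                        encoding="utf-8")
        return path


# ---------------------------------------------------------------------------
# primitive state transitions — validate first, then mutate a copy
# ---------------------------------------------------------------------------

def _well_capacity(state: DeckState, slot: int, well_id: str) -> float:
    definition = state.slots[slot]
    parse_well_id(definition, well_id)  # raises BadWellId outside grid
    return definition.max_volume_of_well()


def load_labware(state: DeckState, slot: int, definition: LabwareDefinition,
                 initial_volumes: dict[str, float] | None = None) -> DeckState:
    """Place labware in a free slot; returns the new state."""
    if slot in state.slots:
        raise SlotOccupied(
            f"slot {slot} already holds {state.slots[slot].api_name}")
    if slot not in state.slot_numbers:
        raise InvalidComponent(f"slot {slot} does not exist on this deck")
    if initial_volumes:
        if definition.kind == "tiprack":
            raise InvalidComponent("tipracks do not hold liquid")
        cap = definition.max_volume_of_well()
        for well, vol in initial_volumes.items():
            parse_well_id(definition, well)
            if vol < 0:
                raise InvalidComponent(f"negative initial volume in {well}")
            if vol > cap + 1e-9:
                raise OverfillError(
                    f"initial volume {vol:g} uL in {well} exceeds maximum "
                    f"{cap:g} uL of {definition.api_name}")
    new = state.copy()
    new.slots[slot] = definition
    if definition.kind == "tiprack":
        new.tips_available[slot] = definition.tip_capacity
    for well, vol in (initial_volumes or {}).items():
        new.well_volumes[(slot, well)] = vol
    return new


def check_tip_and_pick(state: DeckState, mount: str,
                       catalog: LabwareCatalog) -> DeckState:
    """Ensure the pipette on ``mount`` carries a tip.

    A no-op when a tip is already attached.  Otherwise one tip is taken
    from the first rack (deck order) of the pipette's bound tip-rack
    type that still has tips; when all such racks are empty a fresh rack
    is auto-loaded into the lowest free slot first.
    """
    if mount not in state.pipettes:
        raise InvalidComponent(f"no pipette mounted on {mount}")
    if state.pipette_has_tip.get(mount, False):
        return state
    rack_name = state.pipettes[mount].tiprack_api_name
    rack_slots = [s for s in sorted(state.slots)
                  if state.slots[s].api_name == rack_name]
    source_slot = next((s for s in rack_slots if state.tips_available.get(s, 0) > 0),
                       None)
    if source_slot is None:
        free = state.lowest_free_slot()
        if free is None:
            raise DeckFull(
                f"all {rack_name} racks empty and no free slot for a fresh one")
        state = load_labware(state, free, catalog.get(rack_name))
        source_slot = free
    new = state.copy()
    new.tips_available[source_slot] -= 1
    new.pipette_has_tip[mount] = True
    return new


def drop_tip(state: DeckState, mount: str) -> DeckState:
    """Discard the current tip (to a virtual trash)."""
    if mount not in state.pipettes:
        raise InvalidComponent(f"no pipette mounted on {mount}")
    if state.pipette_held_volume.get(mount, 0.0) > 1e-9:
        raise InsufficientHeldVolume(
            "cannot drop a tip that still holds liquid")
    new = state.copy()
    new.pipette_has_tip[mount] = False
    return new


def aspirate(state: DeckState, mount: str, source: tuple[int, str],
             volume: float) -> tuple[DeckState, float | None]:
    """Draw ``volume`` uL from ``source``; returns (state, z-height).

    The returned height (mm, ``None`` for plate wells) is where the tip
    sat during aspiration: the liquid surface minus the submersion
    offset, never below the bottom clearance.
    """
    pip = state.pipettes.get(mount)
    if pip is None:
        raise InvalidComponent(f"no pipette mounted on {mount}")
    if not state.pipette_has_tip.get(mount, False):
        raise NoTipError(f"{mount} pipette has no tip attached")
    held = state.pipette_held_volume.get(mount, 0.0)
    if held > 1e-9:
        raise VolumeOutOfRange(
            f"{mount} pipette already holds {held:g} uL; dispense first")
    slot, well = source
    if slot not in state.slots:
        raise InvalidComponent(f"no labware in slot {slot}")
    definition = state.slots[slot]
    _well_capacity(state, slot, well)
    current = state.volume_at(slot, well)
    geometry = definition.tube_geometry
    floor = geometry.dead_volume if geometry is not None else 0.0
    # source sufficiency is diagnosed before pipette capability: the
    # user-facing problem is the liquid, not the hardware
    if current - volume < floor - 1e-9:
        kind = "dead volume" if geometry is not None else "zero"
        raise InsufficientVolume(
            f"aspirating {volume:g} uL from {current:g} uL in {slot}:{well} "
            f"would breach the {kind} floor ({floor:g} uL)")
    if not (pip.min_volume - 1e-9 <= volume <= pip.max_volume + 1e-9):
        raise VolumeOutOfRange(
            f"{volume:g} uL outside {pip.model} range "
            f"[{pip.min_volume:g}, {pip.max_volume:g}]")
    height = None
    if geometry is not None:
        surface = height_from_volume(geometry, current)
        height = max(surface - DEFAULT_SUBMERSION_OFFSET,
                     DEFAULT_BOTTOM_CLEARANCE)
    new = state.copy()
    new.well_volumes[(slot, well)] = current - volume
    new.pipette_held_volume[mount] = volume
    return new, height


def dispense(state: DeckState, mount: str, destination: tuple[int, str],
             volume: float) -> DeckState:
    """Expel ``volume`` uL into ``destination``."""
    pip = state.pipettes.get(mount)
    if pip is None:
        raise InvalidComponent(f"no pipette mounted on {mount}")
    if not state.pipette_has_tip.get(mount, False):
        raise NoTipError(f"{mount} pipette has no tip attached")
    held = state.pipette_held_volume.get(mount, 0.0)
    if volume > held + 1e-9:
        raise InsufficientHeldVolume(
            f"dispensing {volume:g} uL but only {held:g} uL held")
    slot, well = destination
    if slot not in state.slots:
        raise InvalidComponent(f"no labware in slot {slot}")
    cap = _well_capacity(state, slot, well)
    current = state.volume_at(slot, well)
    if current + volume > cap + 1e-9:
        raise OverfillError(
            f"dispensing {volume:g} uL into {slot}:{well} at {current:g} uL "
            f"would exceed its maximum {cap:g} uL")
    new = state.copy()
    new.well_volumes[(slot, well)] = current + volume
    remaining = held - volume
    new.pipette_held_volume[mount] = 0.0 if remaining < 1e-9 else remaining
    return new


def distribute_z_tracking_falcon15ml(
        state: DeckState, mount: str, source_tube: tuple[int, str],
        dispenses: list[tuple[tuple[int, str], float]],
) -> tuple[DeckState, list[float]]:
    """Distribute from one 15 mL conical tube to many wells, tracking the
    falling liquid level.

    Consecutive dispenses are batched greedily into single aspirations
    bounded by the pipette maximum.  Before each aspiration the tip
    height is computed from the tube's *current* volume, so the returned
    heights are non-increasing.  Only the 15 mL geometry is supported —
    a tube of any other nominal capacity (e.g. 50 mL) is refused, since
    the submersion calibration does not transfer.
    """
    pip = state.pipettes.get(mount)
    if pip is None:
        raise InvalidComponent(f"no pipette mounted on {mount}")
    slot, well = source_tube
    if slot not in state.slots:
        raise InvalidComponent(f"no labware in slot {slot}")
    geometry = state.slots[slot].tube_geometry
    if geometry is None:
        raise UnsupportedLabware(
            f"{state.slots[slot].api_name} is not a tube rack")
    if geometry.nominal_capacity != ZTRACK_SUPPORTED_CAPACITY:
        raise UnsupportedLabware(
            f"z-tracked distribution supports only "
            f"{ZTRACK_SUPPORTED_CAPACITY / 1000:g} mL tubes, got "
            f"{geometry.nominal_capacity / 1000:g} mL")
    # batch greedily, then replay through aspirate/dispense so every bound
    # (tip, dead volume, overfill) is enforced by the primitives
    batches: list[list[tuple[tuple[int, str], float]]] = []
    current: list[tuple[tuple[int, str], float]] = []
    total = 0.0
    for dest, vol in dispenses:
        if vol > pip.max_volume:
            raise VolumeOutOfRange(
                f"single dispense {vol:g} uL exceeds pipette max "
                f"{pip.max_volume:g} uL")
        if total + vol > pip.max_volume + 1e-9:
            batches.append(current)
            current, total = [], 0.0
        current.append((dest, vol))
        total += vol
    if current:
        batches.append(current)
    heights: list[float] = []
    for batch in batches:
        batch_volume = sum(v for _, v in batch)
        state, height = aspirate(state, mount, source_tube, batch_volume)
        assert height is not None
        heights.append(height)
        for dest, vol in batch:
            state = dispense(state, mount, dest, vol)
    return state, heights


# ---------------------------------------------------------------------------
# plan execution
# ---------------------------------------------------------------------------

def build_deck(plan: ProtocolPlan, catalog: LabwareCatalog,
               initial_volumes: dict[tuple[int, str], float] | None = None
               ) -> DeckState:
    """Materialize a plan's deck layout (plus its reagent fills) into a
    fresh :class:`DeckState`."""
    state = DeckState()
    for spec in plan.pipettes.values():
        state.attach_pipette(spec)
    fills: dict[tuple[int, str], float] = plan.initial_volume_map()
    if initial_volumes:
        fills.update(initial_volumes)
    for slot in sorted(plan.deck_layout):
        definition = catalog.get(plan.deck_layout[slot])
        per_well = {w: v for (s, w), v in fills.items() if s == slot}
        state = load_labware(state, slot, definition, per_well or None)
    return state


def run_plan(plan: ProtocolPlan, catalog: LabwareCatalog,
             initial_volumes: dict[tuple[int, str], float] | None = None,
             state: DeckState | None = None) -> tuple[DeckState, ActionLog]:
    """Execute a plan step by step.

    When ``state`` is given the plan runs on that carried-over deck
    (labware already present is kept), which is how sequentially merged
    plans compose into workflows.  On a step failure the error
    propagates after the log records all *successful* steps; the
    returned-state guarantee is that each failed step mutated nothing.
    """
    if state is None:
        state = build_deck(plan, catalog, initial_volumes)
    else:
        for spec in plan.pipettes.values():
            if spec.mount not in state.pipettes:
                state.attach_pipette(spec)
        for slot in sorted(plan.deck_layout):
            if slot not in state.slots:
                fills = {w: v for (s, w), v in plan.initial_volume_map().items()
                         if s == slot}
                state = load_labware(state, slot,
                                     catalog.get(plan.deck_layout[slot]),
                                     fills or None)
    log = ActionLog()
    for i, step in enumerate(plan.steps):
        pre = state.digest()
        height = None
        try:
            if step.kind == "comment":
                pass
            elif step.kind == "pick_tip":
                state = check_tip_and_pick(state, step.mount, catalog)
            elif step.kind == "drop_tip":
                state = drop_tip(state, step.mount)
            elif step.kind == "aspirate":
                state, height = aspirate(state, step.mount, step.source,
                                         step.volume)
            elif step.kind == "dispense":
                state = dispense(state, step.mount, step.destination,
                                 step.volume)
            elif step.kind == "load_labware":
                slot = step.destination[0]
                state = load_labware(state, slot, catalog.get(step.note))
        except Exception as exc:
            log.error = f"step {i} ({step.kind}): {exc}"
            raise PlanExecutionError(log.error, exc, state, log) from exc
        log.entries.append(LogEntry(i, step, pre, state.digest(), height))
    return state, log
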