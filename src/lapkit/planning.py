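"""Turn validated user variables into an executable protocol plan.

This is the parameter-setting layer: it computes reagent totals (sample
count x per-sample volume x excess fraction), allocates source tubes
with dead-volume headroom, assigns samples to destination wells, lays
labware out on the deck, and — per transfer — selects the pipette that
minimizes the number of liquid movements.

Pipette choice
--------------
A pipette with working range [min, max] can move a volume V in
k = ceil(V / max) aspirate/dispense cycles, provided k*min <= V (larger
k only raises the minimum-sum, so ceil(V/max) is the only candidate
count).  Among capable pipettes the one with the fewest movements wins;
ties prefer the pipette whose maximum is least oversized for the
per-movement volume, then the right mount.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    CapacityExceeded,
    DeckFull,
    InvalidComponent,
    InvalidGeometry,
    InvalidVolume,
    NoSuitablePipette,
    OverfillError,
)
from .format_io import UserVariables
from .labware import (
    LabwareCatalog,
    LabwareDefinition,
    PipetteSpec,
    TubeGeometry,
    well_iterator,
)

#: Never fill a tube beyond this fraction of its nominal capacity.
DEFAULT_MAX_FILL_FRACTION = 0.9

STEP_KINDS = ("aspirate", "dispense", "pick_tip", "drop_tip",
              "load_labware", "comment")


# ---------------------------------------------------------------------------
# steps and plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransferStep:
    """One executable atom of a protocol body."""

    kind: str
    mount: str | None = None               # "left" | "right"
    source: tuple[int, str] | None = None
    destination: tuple[int, str] | None = None
    volume: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise InvalidComponent(f"unknown step kind {self.kind!r}")
        needs_volume = self.kind in ("aspirate", "dispense")
        if needs_volume and (self.volume is None or self.volume <= 0):
            raise InvalidComponent(f"{self.kind} step needs volume > 0")
        if not needs_volume and self.volume is not None:
            raise InvalidComponent(f"{self.kind} step must not carry a volume")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.mount is not None:
            d["mount"] = self.mount
        if self.source is not None:
            d["source"] = [self.source[0], self.source[1]]
        if self.destination is not None:
            d["destination"] = [self.destination[0], self.destination[1]]
        if self.volume is not None:
            d["volume"] = self.volume
        if self.note:
            d["note"] = self.note
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransferStep":
        return cls(
            kind=d["kind"],
            mount=d.get("mount"),
            source=tuple(d["source"]) if "source" in d else None,
            destination=tuple(d["destination"]) if "destination" in d else None,
            volume=d.get("volume"),
            note=d.get("note", ""),
        )


@dataclass
class ReagentRequirement:
    """Total volume, tube count and per-tube fills for one reagent."""

    total_volume: float
    tube_count: int
    per_tube_fill: list[float]
    tubes: list[tuple[int, str]] = field(default_factory=list)  # (slot, well)

    def to_dict(self) -> dict:
        return {"total_volume": self.total_volume,
                "tube_count": self.tube_count,
                "per_tube_fill": list(self.per_tube_fill),
                "tubes": [[s, w] for s, w in self.tubes]}

    @classmethod
    def from_dict(cls, d: dict) -> "ReagentRequirement":
        return cls(total_volume=d["total_volume"], tube_count=d["tube_count"],
                   per_tube_fill=list(d["per_tube_fill"]),
                   tubes=[tuple(t) for t in d["tubes"]])


@dataclass
class ProtocolPlan:
    """An ordered, executable, serializable liquid-handling plan."""

    steps: list[TransferStep] = field(default_factory=list)
    deck_layout: dict[int, str] = field(default_factory=dict)  # slot -> api_name
    pipettes: dict[str, PipetteSpec] = field(default_factory=dict)  # mount -> spec
    reagent_requirements: dict[str, ReagentRequirement] = field(default_factory=dict)
    sample_assignment: dict[int, tuple[int, str]] = field(default_factory=dict)
    initial_volumes: dict[str, float] = field(default_factory=dict)  # "slot:well"
    sample_names: dict[int, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "deck_layout": {str(s): n for s, n in self.deck_layout.items()},
            "pipettes": {
                m: {"model": p.model, "min_volume": p.min_volume,
                    "max_volume": p.max_volume,
                    "tiprack_api_name": p.tiprack_api_name}
                for m, p in self.pipettes.items()},
            "reagent_requirements": {
                r: req.to_dict() for r, req in self.reagent_requirements.items()},
            "sample_assignment": {
                str(i): [s, w] for i, (s, w) in self.sample_assignment.items()},
            "sample_names": {str(i): n for i, n in self.sample_names.items()},
            "initial_volumes": dict(self.initial_volumes),
            "steps": [s.to_dict() for s in self.steps],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProtocolPlan":
        payload = json.loads(text)
        return cls(
            steps=[TransferStep.from_dict(d) for d in payload["steps"]],
            deck_layout={int(s): n for s, n in payload["deck_layout"].items()},
            pipettes={
                m: PipetteSpec(mount=m, model=d["model"],
                               min_volume=d["min_volume"],
                               max_volume=d["max_volume"],
                               tiprack_api_name=d["tiprack_api_name"])
                for m, d in payload["pipettes"].items()},
            reagent_requirements={
                r: ReagentRequirement.from_dict(d)
                for r, d in payload["reagent_requirements"].items()},
            sample_assignment={
                int(i): tuple(sw)
                for i, sw in payload["sample_assignment"].items()},
            sample_names={int(i): n
                          for i, n in payload.get("sample_names", {}).items()},
            initial_volumes=dict(payload.get("initial_volumes", {})),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProtocolPlan":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def initial_volume_map(self) -> dict[tuple[int, str], float]:
        out = {}
        for key, vol in self.initial_volumes.items():
            slot, well = key.split(":")
            out[(int(slot), well)] = vol
        return out

    def set_initial_volume(self, slot: int, well: str, volume: float) -> None:
        self.initial_volumes[f"{slot}:{well}"] = volume


def concat_plans(*plans: ProtocolPlan) -> ProtocolPlan:
    """Merge plans into one workflow: shared deck, concatenated steps.

    Labware layouts must agree wherever slots overlap — this is the
    modularity contract that lets separately authored plans run
    back-to-back on one deck.
    """
    merged = ProtocolPlan()
    for plan in plans:
        for slot, name in plan.deck_layout.items():
            if merged.deck_layout.get(slot, name) != name:
                raise InvalidComponent(
                    f"slot {slot} holds {merged.deck_layout[slot]!r} in one plan "
                    f"and {name!r} in another")
            merged.deck_layout[slot] = name
        for mount, spec in plan.pipettes.items():
            if merged.pipettes.get(mount, spec) != spec:
                raise InvalidComponent(f"conflicting pipette on {mount} mount")
            merged.pipettes[mount] = spec
        for key, vol in plan.initial_volumes.items():
            merged.initial_volumes[key] = merged.initial_volumes.get(key, 0.0) + vol
        merged.steps.extend(plan.steps)
        merged.reagent_requirements.update(plan.reagent_requirements)
        base = len(merged.sample_assignment)
        for i, sw in plan.sample_assignment.items():
            merged.sample_assignment[base + i] = sw
        for i, n in plan.sample_names.items():
            merged.sample_names[base + i] = n
    return merged


# ---------------------------------------------------------------------------
# pipette selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipetteChoice:
    mount: str
    movements: int
    per_movement_volumes: tuple[float, ...]


def plan_movements(volume: float, p: PipetteSpec) -> list[float]:
    """Minimal chunking of ``volume`` into transfers within [min, max].

    The movement count is ceil(volume / max).  Chunks are max-sized with
    the remainder last; a remainder below the pipette minimum is fixed
    by splitting the last two chunks evenly, falling back to an even
    split over all chunks when even that leaves the pair out of range.
    """
    if volume <= 0:
        raise InvalidVolume(f"volume must be positive, got {volume}")
    k = math.ceil(volume / p.max_volume - 1e-12)
    if volume < p.min_volume or k * p.min_volume > volume + 1e-9:
        raise NoSuitablePipette(
            f"{p.model} ({p.min_volume}-{p.max_volume} uL) cannot deliver "
            f"{volume} uL in valid chunks")
    if k == 1:
        return [volume]
    chunks = [p.max_volume] * (k - 1) + [volume - p.max_volume * (k - 1)]
    if chunks[-1] < p.min_volume - 1e-9:
        pair = chunks[-2] + chunks[-1]
        chunks[-2] = chunks[-1] = pair / 2.0
        if chunks[-1] < p.min_volume - 1e-9:
            chunks = [volume / k] * k
    assert abs(sum(chunks) - volume) < 1e-6
    return chunks


def give_me_optimal_pipette(volume: float, pipettes: list[PipetteSpec]
                            ) -> PipetteChoice:
    """Select the mounted pipette that moves ``volume`` in the fewest
    aspirate/dispense cycles.

    Ties prefer the pipette whose per-movement volume sits closest to
    its maximum (least oversized), then the right mount.
    """
    if volume <= 0:
        raise InvalidVolume(f"volume must be positive, got {volume}")
    if not pipettes:
        raise NoSuitablePipette("no pipettes mounted")
    candidates: list[tuple[tuple, PipetteChoice]] = []
    for p in pipettes:
        try:
            chunks = plan_movements(volume, p)
        except NoSuitablePipette:
            continue
        k = len(chunks)
        oversize = p.max_volume - volume / k
        mount_rank = 0 if p.mount == "right" else 1
        candidates.append(((k, oversize, mount_rank),
                           PipetteChoice(p.mount, k, tuple(chunks))))
    if not candidates:
        ranges = ", ".join(f"{p.model}[{p.min_volume}-{p.max_volume}]"
                           for p in pipettes)
        raise NoSuitablePipette(f"no pipette can deliver {volume} uL ({ranges})")
    candidates.sort(key=lambda c: c[0])
    return candidates[0][1]


# ---------------------------------------------------------------------------
# tube allocation and sample layout
# ---------------------------------------------------------------------------

def tubes_needed(total_volume: float, g: TubeGeometry,
                 max_fill_fraction: float = DEFAULT_MAX_FILL_FRACTION
                 ) -> tuple[int, list[float]]:
    """Minimal number of source tubes for ``total_volume`` uL of reagent.

    Each tube contributes ``nominal_capacity * max_fill_fraction -
    dead_volume`` of usable liquid.  Fills spread the requested total
    plus one dead volume per tube as evenly as possible.
    """
    if total_volume < 0:
        raise InvalidVolume(f"total volume must be >= 0, got {total_volume}")
    usable = g.nominal_capacity * max_fill_fraction - g.dead_volume
    if usable <= 0:
        raise InvalidGeometry(
            f"fill limit {g.nominal_capacity * max_fill_fraction:g} uL does not "
            f"exceed dead volume {g.dead_volume:g} uL")
    if total_volume == 0:
        return 0, []
    count = math.ceil(total_volume / usable - 1e-12)
    fills = [total_volume / count + g.dead_volume] * count
    return count, fills


def assign_samples_to_wells(n_samples: int, plate_def: LabwareDefinition,
                            n_plates: int = 1, order: str = "column-major",
                            slots: list[int] | None = None
                            ) -> dict[int, tuple[int, str]]:
    """Assign sample indices 0..n-1 to (plate-slot, well) pairs, filling
    plates in deck order and wells in the requested order."""
    capacity = n_plates * plate_def.n_wells
    if n_samples > capacity:
        raise CapacityExceeded(
            f"{n_samples} samples exceed {n_plates} x {plate_def.n_wells} wells")
    if slots is None:
        slots = list(range(1, n_plates + 1))
    if len(slots) != n_plates:
        raise InvalidComponent("slots list must match n_plates")
    assignment: dict[int, tuple[int, str]] = {}
    i = 0
    for plate_idx in range(n_plates):
        for well in well_iterator(plate_def, order):
            if i >= n_samples:
                return assignment
            assignment[i] = (slots[plate_idx], well)
            i += 1
    return assignment


# ---------------------------------------------------------------------------
# full parameter-setting
# ---------------------------------------------------------------------------

def _layout_deck(plan: ProtocolPlan, api_names: list[str],
                 slot_numbers=range(1, 12)) -> list[int]:
    """Place labware into the lowest free slots, in the given order."""
    taken = set(plan.deck_layout)
    assigned = []
    free = [s for s in slot_numbers if s not in taken]
    if len(free) < len(api_names):
        raise DeckFull(
            f"{len(api_names)} labware items but only {len(free)} free slots")
    for name, slot in zip(api_names, free):
        plan.deck_layout[slot] = name
        assigned.append(slot)
    return assigned


def ensure_tipracks(plan: ProtocolPlan, pipettes: list[PipetteSpec]) -> None:
    """Lay out one rack per tip type, reusing racks already on deck (so
    plans composed on a shared deck do not duplicate them)."""
    present = set(plan.deck_layout.values())
    wanted = []
    for p in pipettes:
        name = p.tiprack_api_name
        if name not in present and name not in wanted:
            wanted.append(name)
    if wanted:
        _layout_deck(plan, wanted)


def _transfer_steps(plan: ProtocolPlan, pipettes: list[PipetteSpec],
                    source: tuple[int, str], dest: tuple[int, str],
                    volume: float, note: str = "",
                    new_tip: bool = True) -> None:
    """Append pick-tip / chunked aspirate+dispense steps for one transfer."""
    choice = give_me_optimal_pipette(volume, pipettes)
    if new_tip:
        plan.steps.append(TransferStep("pick_tip", mount=choice.mount, note=note))
    for chunk in choice.per_movement_volumes:
        plan.steps.append(TransferStep("aspirate", mount=choice.mount,
                                       source=source, volume=chunk, note=note))
        plan.steps.append(TransferStep("dispense", mount=choice.mount,
                                       destination=dest, volume=chunk, note=note))


def plan_distribute(plan: ProtocolPlan, pipette: PipetteSpec,
                    source: tuple[int, str],
                    dispenses: list[tuple[tuple[int, str], float]],
                    note: str = "") -> None:
    """Greedy multi-dispense: consecutive dispenses are batched into one
    aspiration while their sum fits the pipette maximum (the step
    pattern of a z-tracked falcon distribution)."""
    batch: list[tuple[tuple[int, str], float]] = []
    batch_sum = 0.0

    def flush() -> None:
        nonlocal batch, batch_sum
        if not batch:
            return
        plan.steps.append(TransferStep("aspirate", mount=pipette.mount,
                                       source=source, volume=batch_sum,
                                       note=note or "distribute"))
        for dest, vol in batch:
            plan.steps.append(TransferStep("dispense", mount=pipette.mount,
                                           destination=dest, volume=vol,
                                           note=note or "distribute"))
        batch, batch_sum = [], 0.0

    for dest, vol in dispenses:
        if vol <= 0:
            raise InvalidVolume(f"dispense volume must be positive, got {vol}")
        if vol > pipette.max_volume:
            raise NoSuitablePipette(
                f"single dispense {vol} uL exceeds pipette max {pipette.max_volume}")
        if batch_sum + vol > pipette.max_volume + 1e-9:
            flush()
        batch.append((dest, vol))
        batch_sum += vol
    flush()


def set_parameters(uv: UserVariables, catalog: LabwareCatalog,
                   max_fill_fraction: float = DEFAULT_MAX_FILL_FRACTION
                   ) -> ProtocolPlan:
    """Compute a generic reagent-distribution plan from user variables.

    Deck layout (lowest free slots first): tip racks, reagent tube
    rack(s), source plate(s), destination plate(s).  Each reagent's
    requirement is ``number_samples * per-sample volume * (1 +
    extra_fraction)``; tubes are allocated with
    :func:`tubes_needed`, then every sample well receives each reagent
    using the movement-optimal pipette.
    """
    pipettes = uv.pipettes()
    if not pipettes:
        raise InvalidComponent("at least one pipette must be configured")
    if not uv.destination_plate:
        raise InvalidComponent("destination_plate is required")
    dest_def = catalog.get(uv.destination_plate)
    per_sample_total = sum(uv.reagent_volumes.values())
    if per_sample_total > dest_def.max_volume_of_well():
        raise CapacityExceeded(
            f"per-sample volume {per_sample_total:g} uL exceeds destination "
            f"well maximum {dest_def.max_volume_of_well():g} uL")

    plan = ProtocolPlan()
    for p in pipettes:
        plan.pipettes[p.mount] = p
        catalog.get(p.tiprack_api_name)  # raises UnknownLabware early
    _layout_deck(plan, [p.tiprack_api_name for p in pipettes])

    rack_name = uv.reagent_rack or "tuberack_24_falcon15"
    rack_def = catalog.get(rack_name)
    if rack_def.tube_geometry is None:
        raise InvalidComponent(f"reagent rack {rack_name!r} has no tube geometry")
    geometry = rack_def.tube_geometry

    # reagent totals and tube allocation
    reagents = {}
    tube_fills: list[tuple[str, float]] = []  # flattened (reagent, fill)
    for reagent, per_sample in uv.reagent_volumes.items():
        total = uv.number_samples * per_sample * (1.0 + uv.extra_fraction)
        count, fills = tubes_needed(total, geometry, max_fill_fraction)
        reagents[reagent] = ReagentRequirement(total, count, fills)
        tube_fills.extend((reagent, f) for f in fills)

    n_racks = max(1, math.ceil(len(tube_fills) / rack_def.n_wells))
    rack_slots = _layout_deck(plan, [rack_name] * n_racks)

    n_dest = max(1, math.ceil(uv.number_samples / dest_def.n_wells))
    dest_slots = _layout_deck(plan, [uv.destination_plate] * n_dest)

    # tube positions, column-major across racks
    tube_positions = [(slot, well) for slot in rack_slots
                      for well in well_iterator(rack_def, "column-major")]
    for (reagent, fill), pos in zip(tube_fills, tube_positions):
        reagents[reagent].tubes.append(pos)
        plan.set_initial_volume(pos[0], pos[1], fill)
    plan.reagent_requirements = reagents

    plan.sample_assignment = assign_samples_to_wells(
        uv.number_samples, dest_def, n_dest, slots=dest_slots)

    # one tip per reagent; refill from the next tube when one runs dry
    for reagent, req in reagents.items():
        per_sample = uv.reagent_volumes[reagent]
        usable_left = [f - geometry.dead_volume for f in req.per_tube_fill]
        tube_idx = 0
        dispenses: list[tuple[tuple[int, str], float]] = []
        choice = give_me_optimal_pipette(per_sample, pipettes)
        pip = plan.pipettes[choice.mount]
        plan.steps.append(TransferStep("pick_tip", mount=pip.mount, note=reagent))

        def flush_tube(idx: int, pending) -> None:
            if pending:
                plan_distribute(plan, pip, req.tubes[idx], pending, note=reagent)

        for i in range(uv.number_samples):
            dest = plan.sample_assignment[i]
            if usable_left[tube_idx] < per_sample - 1e-9:
                flush_tube(tube_idx, dispenses)
                dispenses = []
                tube_idx += 1
            usable_left[tube_idx] -= per_sample
            if per_sample <= pip.max_volume:
                dispenses.append((dest, per_sample))
            else:
                flush_tube(tube_idx, dispenses)
                dispenses = []
                for chunk in plan_movements(per_sample, pip):
                    plan.steps.append(TransferStep(
                        "aspirate", mount=pip.mount, source=req.tubes[tube_idx],
                        volume=chunk, note=reagent))
                    plan.steps.append(TransferStep(
                        "dispense", mount=pip.mount, destination=dest,
                        volume=chunk, note=reagent))
        flush_tube(tube_idx, dispenses)
        plan.steps.append(TransferStep("drop_tip", mount=pip.mount, note=reagent))
    return plan
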