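"""Reference protocol implementations and fixture generators.

Each protocol is a pure function from validated user variables (plus a
labware catalog) to an executable :class:`~lapkit.planning.ProtocolPlan`:

* **cell inoculation in different media** — fill destination wells with
  each growth medium from 15 mL conical tubes (z-tracked distribution),
  then add inoculum from the source plate well of each sample;
* **sample consolidation** — collect samples scattered over several
  source plates into a single 96-well plate, in column-major order;
* **PCR mix preparation** — pool the per-reaction components into a
  master mix (with a fractional excess), distribute the mix over the
  reaction wells, add template per well, and emit the thermocycling
  temperature profile as a schedule file;
* **two-criteria counter selection** — a screening rule, not a liquid
  step: keep the samples whose two measurements both pass their
  thresholds.  Its output is exactly the sample list consolidation
  takes, which is how the screening -> cherry-picking -> genotyping-PCR
  workflow chains together.

A seeded fixture generator produces valid variable files for every
protocol, plus deliberately broken variants (one violation each) to
exercise the validator.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import (
    CapacityExceeded,
    InvalidComponent,
    IOFailure,
    MissingMeasurement,
)
from .format_io import (
    CVFDocument,
    UserVariables,
    ValidationReport,
    VariableSchema,
    VariableSpec,
    validate_variables,
)
from .labware import LabwareCatalog, load_labware_catalog, well_iterator
from .planning import (
    ProtocolPlan,
    ReagentRequirement,
    TransferStep,
    give_me_optimal_pipette,
    plan_distribute,
    plan_movements,
    tubes_needed,
    ensure_tipracks,
    _layout_deck,
    _transfer_steps,
)
from .platemap import PlateMap, build_plate_map

PROTOCOLS = ("inoculation", "consolidation", "pcr_mix", "counter_selection")


# ---------------------------------------------------------------------------
# variable schemas
# ---------------------------------------------------------------------------

def _base_variables() -> list[VariableSpec]:
    return [
        VariableSpec("PipetteVariables", "pipR", "str", required=False),
        VariableSpec("PipetteVariables", "pipL", "str", required=False),
        VariableSpec("PipetteVariables", "APINameTipR", "str", required=False),
        VariableSpec("PipetteVariables", "APINameTipL", "str", required=False),
        VariableSpec("GeneralVariables", "number_samples", "int", minimum=1),
    ]


def schema_for(protocol: str, catalog: LabwareCatalog | None = None
               ) -> VariableSchema:
    """The declared variable schema of one reference protocol."""
    if catalog is None:
        catalog = load_labware_catalog()
    base = _base_variables()
    if protocol == "inoculation":
        extra = [
            VariableSpec("GeneralVariables", "source_plate", "str"),
            VariableSpec("GeneralVariables", "destination_plate", "str"),
            VariableSpec("GeneralVariables", "reagent_rack", "str",
                         required=False, default="tuberack_24_falcon15"),
            VariableSpec("MediaVariables", "media", "list_str"),
            VariableSpec("MediaVariables", "volume_media", "float", minimum=0),
            VariableSpec("MediaVariables", "volume_inoculum", "float", minimum=0),
        ]
    elif protocol == "consolidation":
        extra = [
            VariableSpec("GeneralVariables", "source_plate", "str"),
            VariableSpec("GeneralVariables", "destination_plate", "str"),
            VariableSpec("GeneralVariables", "n_source_plates", "int",
                         minimum=1, required=False, default=1),
            VariableSpec("SampleVariables", "volume_sample", "float", minimum=0),
            VariableSpec("SampleVariables", "sample_names", "list_str",
                         required=False),
        ]
    elif protocol == "pcr_mix":
        extra = [
            VariableSpec("GeneralVariables", "source_plate", "str"),
            VariableSpec("GeneralVariables", "destination_plate", "str"),
            VariableSpec("GeneralVariables", "reagent_rack", "str",
                         required=False, default="tuberack_24_falcon15"),
            VariableSpec("GeneralVariables", "extra_fraction", "float",
                         minimum=0, required=False, default=0.1),
            VariableSpec("ReagentVariables", "components", "list_str"),
            VariableSpec("ReagentVariables", "volume_component", "list_float"),
            VariableSpec("ReagentVariables", "volume_template", "float",
                         minimum=0),
            VariableSpec("ProfileVariables", "profile", "list_str",
                         required=False),
        ]
    elif protocol == "counter_selection":
        extra = [
            VariableSpec("SelectionVariables", "measurement_1", "str"),
            VariableSpec("SelectionVariables", "comparator_1", "str",
                         choices=(">=", "<=")),
            VariableSpec("SelectionVariables", "threshold_1", "float"),
            VariableSpec("SelectionVariables", "measurement_2", "str"),
            VariableSpec("SelectionVariables", "comparator_2", "str",
                         choices=(">=", "<=")),
            VariableSpec("SelectionVariables", "threshold_2", "float"),
        ]
    else:
        raise InvalidComponent(f"unknown protocol {protocol!r}; "
                               f"choose from {PROTOCOLS}")
    return VariableSchema(protocol=protocol, variables=base + extra,
                          catalog=catalog)


def validate_cvf(doc: CVFDocument, protocol: str,
                 catalog: LabwareCatalog | None = None
                 ) -> tuple[UserVariables | None, ValidationReport]:
    """Validate a raw CVF against one protocol's schema."""
    return validate_variables(doc, schema_for(protocol, catalog))


# ---------------------------------------------------------------------------
# cell inoculation in different media
# ---------------------------------------------------------------------------

def protocol_inoculation(uv: UserVariables, catalog: LabwareCatalog,
                         occupied: dict[int, str] | None = None
                         ) -> tuple[ProtocolPlan, list[PlateMap]]:
    """Inoculate ``number_samples`` cultures into each listed medium.

    Every (sample, medium) pair gets one destination well: first the
    medium volume is distributed from conical tubes with liquid-level
    tracking, then the inoculum is transferred from the sample's source
    well with a fresh tip per sample.
    """
    media: list[str] = list(uv.extras.get("media", []))
    if not media:
        plan = ProtocolPlan()
        plan.steps.append(TransferStep(
            "comment", note="warning: no media listed; nothing to inoculate"))
        return plan, []
    v_media = uv.reagent_volumes.get("media", 0.0)
    v_inoc = uv.reagent_volumes.get("inoculum", 0.0)
    dest_def = catalog.get(uv.destination_plate)
    well_max = dest_def.max_volume_of_well()
    if v_media + v_inoc > well_max:
        raise CapacityExceeded(
            f"final well volume {v_media + v_inoc:g} uL exceeds destination "
            f"well maximum {well_max:g} uL")
    n_wells_total = uv.number_samples * len(media)
    src_def = catalog.get(uv.source_plate)
    if uv.number_samples > src_def.n_wells:
        raise CapacityExceeded("more samples than source-plate wells")

    pipettes = uv.pipettes()
    plan = ProtocolPlan()
    plan.deck_layout.update(occupied or {})
    for p in pipettes:
        plan.pipettes[p.mount] = p
    ensure_tipracks(plan, pipettes)

    rack_name = uv.reagent_rack or "tuberack_24_falcon15"
    rack_def = catalog.get(rack_name)
    geometry = rack_def.tube_geometry
    if geometry is None:
        raise InvalidComponent(f"{rack_name!r} is not a tube rack")

    # one tube allocation per medium
    media_req: dict[str, ReagentRequirement] = {}
    tube_fills: list[tuple[str, float]] = []
    for medium in media:
        total = uv.number_samples * v_media * (1.0 + uv.extra_fraction)
        count, fills = tubes_needed(total, geometry)
        media_req[medium] = ReagentRequirement(total, count, fills)
        tube_fills.extend((medium, f) for f in fills)
    import math as _math
    n_racks = max(1, _math.ceil(len(tube_fills) / rack_def.n_wells))
    rack_slots = _layout_deck(plan, [rack_name] * n_racks)
    (src_slot,) = _layout_deck(plan, [uv.source_plate])
    n_dest = max(1, _math.ceil(n_wells_total / dest_def.n_wells))
    dest_slots = _layout_deck(plan, [uv.destination_plate] * n_dest)

    tube_positions = [(s, w) for s in rack_slots
                      for w in well_iterator(rack_def, "column-major")]
    for (medium, fill), pos in zip(tube_fills, tube_positions):
        media_req[medium].tubes.append(pos)
        plan.set_initial_volume(pos[0], pos[1], fill)
    plan.reagent_requirements = media_req

    # destination wells: media are consecutive blocks, column-major
    dest_wells = [(s, w) for s in dest_slots
                  for w in well_iterator(dest_def, "column-major")]
    source_wells = list(well_iterator(src_def, "column-major"))
    for i in range(uv.number_samples):
        plan.set_initial_volume(src_slot, source_wells[i], v_inoc * len(media))
    maps_assignment: dict[int, dict[str, str]] = {s: {} for s in dest_slots}

    # choose the pipette once per liquid class
    media_pip = plan.pipettes[give_me_optimal_pipette(v_media, pipettes).mount] \
        if v_media > 0 else None
    inoc_choice = give_me_optimal_pipette(v_inoc, pipettes) if v_inoc > 0 else None

    well_cursor = 0
    for m_idx, medium in enumerate(media):
        req = media_req[medium]
        block = dest_wells[well_cursor:well_cursor + uv.number_samples]
        for i, (slot, well) in enumerate(block):
            maps_assignment[slot][well] = f"s{i + 1}_{medium}"
        well_cursor += uv.number_samples
        if media_pip is None:
            continue
        plan.steps.append(TransferStep("pick_tip", mount=media_pip.mount,
                                       note=f"medium {medium}"))
        usable = [f - geometry.dead_volume for f in req.per_tube_fill]
        tube_idx, pending = 0, []
        for dest in block:
            if usable[tube_idx] < v_media - 1e-9:
                plan_distribute(plan, media_pip, req.tubes[tube_idx], pending,
                                note=f"medium {medium}")
                pending, tube_idx = [], tube_idx + 1
            usable[tube_idx] -= v_media
            pending.append((dest, v_media))
        if pending:
            plan_distribute(plan, media_pip, req.tubes[tube_idx], pending,
                            note=f"medium {medium}")
        plan.steps.append(TransferStep("drop_tip", mount=media_pip.mount,
                                       note=f"medium {medium}"))

    if inoc_choice is not None:
        for m_idx in range(len(media)):
            for i in range(uv.number_samples):
                dest = dest_wells[m_idx * uv.number_samples + i]
                _transfer_steps(plan, pipettes, (src_slot, source_wells[i]),
                                dest, v_inoc, note=f"inoculum s{i + 1}")
                plan.steps.append(TransferStep(
                    "drop_tip",
                    mount=give_me_optimal_pipette(v_inoc, pipettes).mount))

    plate_maps = [build_plate_map(dest_def, slot, maps_assignment[slot])
                  for slot in dest_slots]
    for i in range(n_wells_total):
        plan.sample_assignment[i] = dest_wells[i]
        m = media[i // uv.number_samples]
        plan.sample_names[i] = f"s{i % uv.number_samples + 1}_{m}"
    return plan, plate_maps


# ---------------------------------------------------------------------------
# sample consolidation into a single 96-well plate
# ---------------------------------------------------------------------------

def protocol_consolidation(uv: UserVariables, catalog: LabwareCatalog,
                           sample_names: list[str] | None = None,
                           occupied: dict[int, str] | None = None
                           ) -> tuple[ProtocolPlan, PlateMap]:
    """Collect scattered samples into one destination plate.

    Sample ``i`` lives on source plate ``i // wells-per-plate`` at the
    column-major well ``i %% wells-per-plate``; it moves to the next
    free destination well (column-major).  The plate map names each
    destination well after the sample's source identity.
    """
    dest_def = catalog.get(uv.destination_plate)
    if uv.number_samples > dest_def.n_wells:
        raise CapacityExceeded(
            f"{uv.number_samples} samples cannot consolidate into a single "
            f"{dest_def.n_wells}-well plate")
    src_def = catalog.get(uv.source_plate)
    n_src = int(uv.extras.get("n_source_plates", 1))
    if uv.number_samples > n_src * src_def.n_wells:
        raise CapacityExceeded("more samples than source wells")
    volume = uv.reagent_volumes.get("sample", 0.0)
    if volume <= 0:
        raise InvalidComponent("per-sample volume must be positive")
    if volume > dest_def.max_volume_of_well():
        raise CapacityExceeded(
            f"sample volume {volume:g} uL exceeds destination well maximum")
    if sample_names is None:
        raw = uv.extras.get("sample_names")
        sample_names = list(raw) if raw else None

    pipettes = uv.pipettes()
    plan = ProtocolPlan()
    plan.deck_layout.update(occupied or {})
    for p in pipettes:
        plan.pipettes[p.mount] = p
    ensure_tipracks(plan, pipettes)
    src_slots = _layout_deck(plan, [uv.source_plate] * n_src)
    (dest_slot,) = _layout_deck(plan, [uv.destination_plate])

    src_wells = list(well_iterator(src_def, "column-major"))
    dest_wells = list(well_iterator(dest_def, "column-major"))
    assignment: dict[str, str] = {}
    for i in range(uv.number_samples):
        plate_idx, well_idx = divmod(i, src_def.n_wells)
        source = (src_slots[plate_idx], src_wells[well_idx])
        dest = (dest_slot, dest_wells[i])
        plan.set_initial_volume(source[0], source[1], volume)
        name = (sample_names[i] if sample_names and i < len(sample_names)
                else f"P{plate_idx + 1}_{src_wells[well_idx]}")
        assignment[dest_wells[i]] = name
        plan.sample_assignment[i] = dest
        plan.sample_names[i] = name
        _transfer_steps(plan, pipettes, source, dest, volume, note=name)
        plan.steps.append(TransferStep(
            "drop_tip", mount=give_me_optimal_pipette(volume, pipettes).mount))
    plate_map = build_plate_map(dest_def, dest_slot, assignment)
    return plan, plate_map


# ---------------------------------------------------------------------------
# PCR master mix + temperature profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileStep:
    temperature_c: float
    duration_s: float
    cycles: int = 1

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidComponent("profile step duration must be positive")
        if self.cycles < 1:
            raise InvalidComponent("profile step cycles must be >= 1")


@dataclass
class TemperatureProfile:
    """An ordered thermocycling schedule (no device control — a plan
    document the thermocycler operator or driver consumes)."""

    steps: list[ProfileStep] = field(default_factory=list)

    @classmethod
    def from_strings(cls, specs: list[str]) -> "TemperatureProfile":
        """Parse ``"temperature:seconds[:cycles]"`` entries."""
        steps = []
        for spec in specs:
            parts = spec.split(":")
            if len(parts) not in (2, 3):
                raise InvalidComponent(
                    f"profile step {spec!r} is not temp:seconds[:cycles]")
            temp, dur = float(parts[0]), float(parts[1])
            cycles = int(parts[2]) if len(parts) == 3 else 1
            steps.append(ProfileStep(temp, dur, cycles))
        return cls(steps)

    def total_seconds(self) -> float:
        return sum(s.duration_s * s.cycles for s in self.steps)


#: A generic 30-cycle two-step PCR schedule used when the CVF gives none.
DEFAULT_PCR_PROFILE = TemperatureProfile([
    ProfileStep(98.0, 180.0, 1),   # initial denaturation
    ProfileStep(98.0, 10.0, 30),   # denature
    ProfileStep(55.0, 20.0, 30),   # anneal
    ProfileStep(72.0, 30.0, 30),   # extend
    ProfileStep(72.0, 300.0, 1),   # final extension
    ProfileStep(4.0, 60.0, 1),     # hold (finite for scheduling)
])


def write_temperature_profile(profile: TemperatureProfile,
                              path: str | Path) -> Path:
    payload = {"temperature_profile": [
        {"temperature_c": s.temperature_c, "duration_s": s.duration_s,
         "cycles": s.cycles} for s in profile.steps]}
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    except OSError as exc:
        raise IOFailure(f"cannot write profile {path}: {exc}") from exc
    return path


def protocol_pcr_mix(uv: UserVariables, catalog: LabwareCatalog,
                     occupied: dict[int, str] | None = None
                     ) -> tuple[ProtocolPlan, TemperatureProfile]:
    """Prepare a PCR master mix and set up the reaction plate.

    The mix totals ``sum(component volumes) x reactions x (1 +
    extra_fraction)`` and is assembled in 15 mL conical tube(s); each
    component arrives from its own stock tube.  The mix is then
    distributed over the reaction wells with liquid-level tracking and
    template is added per well from the source plate.
    """
    components: list[str] = list(uv.extras.get("components", []))
    comp_volumes_raw = uv.extras.get("volume_component", [])
    comp_volumes = [float(v) for v in comp_volumes_raw]
    if len(components) != len(comp_volumes):
        raise InvalidComponent(
            f"{len(components)} components but {len(comp_volumes)} volumes")
    v_template = uv.reagent_volumes.get("template", 0.0)
    n_rxn = uv.number_samples
    per_rxn_mix = sum(comp_volumes)
    dest_def = catalog.get(uv.destination_plate)
    if per_rxn_mix + v_template > dest_def.max_volume_of_well():
        raise CapacityExceeded(
            f"per-well volume {per_rxn_mix + v_template:g} uL exceeds "
            f"destination well maximum {dest_def.max_volume_of_well():g} uL")

    pipettes = uv.pipettes()
    plan = ProtocolPlan()
    plan.deck_layout.update(occupied or {})
    for p in pipettes:
        plan.pipettes[p.mount] = p
    ensure_tipracks(plan, pipettes)

    rack_name = uv.reagent_rack or "tuberack_24_falcon15"
    rack_def = catalog.get(rack_name)
    geometry = rack_def.tube_geometry
    if geometry is None:
        raise InvalidComponent(f"{rack_name!r} is not a tube rack")

    mix_total = per_rxn_mix * n_rxn * (1.0 + uv.extra_fraction)
    mix_count, mix_fills = tubes_needed(mix_total, geometry)
    mix_count = max(mix_count, 1)

    import math as _math
    n_tubes = mix_count + len(components)
    n_racks = max(1, _math.ceil(n_tubes / rack_def.n_wells))
    rack_slots = _layout_deck(plan, [rack_name] * n_racks)
    (src_slot,) = _layout_deck(plan, [uv.source_plate])
    n_dest = max(1, _math.ceil(n_rxn / dest_def.n_wells))
    dest_slots = _layout_deck(plan, [uv.destination_plate] * n_dest)

    positions = [(s, w) for s in rack_slots
                 for w in well_iterator(rack_def, "column-major")]
    mix_tubes = positions[:mix_count]
    comp_tubes = positions[mix_count:mix_count + len(components)]

    plan.reagent_requirements["master_mix"] = ReagentRequirement(
        mix_total, mix_count, mix_fills or [geometry.dead_volume],
        tubes=list(mix_tubes))
    # mix tubes start with only their dead-volume cushion; components fill them
    for pos in mix_tubes:
        plan.set_initial_volume(pos[0], pos[1], geometry.dead_volume)

    share = [f - geometry.dead_volume for f in mix_fills] or [0.0]
    for comp, v_comp, pos in zip(components, comp_volumes, comp_tubes):
        comp_total = v_comp * n_rxn * (1.0 + uv.extra_fraction)
        plan.set_initial_volume(pos[0], pos[1], comp_total + geometry.dead_volume)
        plan.reagent_requirements[comp] = ReagentRequirement(
            comp_total, 1, [comp_total + geometry.dead_volume], tubes=[pos])
        # split this component over the mix tubes pro rata
        for mix_pos, mix_share in zip(mix_tubes, share):
            part = comp_total * (mix_share / sum(share)) if sum(share) else 0.0
            if part <= 0:
                continue
            _transfer_steps(plan, pipettes, pos, mix_pos, part, note=comp)
            plan.steps.append(TransferStep(
                "drop_tip", mount=give_me_optimal_pipette(part, pipettes).mount))

    # distribute mix to reaction wells, one tip, z-tracked batching
    dest_wells = [(s, w) for s in dest_slots
                  for w in well_iterator(dest_def, "column-major")][:n_rxn]
    if per_rxn_mix > 0:
        pip = plan.pipettes[give_me_optimal_pipette(per_rxn_mix, pipettes).mount]
        plan.steps.append(TransferStep("pick_tip", mount=pip.mount,
                                       note="master mix"))
        usable = [f - geometry.dead_volume for f in
                  plan.reagent_requirements["master_mix"].per_tube_fill]
        tube_idx, pending = 0, []
        for dest in dest_wells:
            if usable[tube_idx] < per_rxn_mix - 1e-9:
                plan_distribute(plan, pip, mix_tubes[tube_idx], pending,
                                note="master mix")
                pending, tube_idx = [], tube_idx + 1
            usable[tube_idx] -= per_rxn_mix
            pending.append((dest, per_rxn_mix))
        if pending:
            plan_distribute(plan, pip, mix_tubes[tube_idx], pending,
                            note="master mix")
        plan.steps.append(TransferStep("drop_tip", mount=pip.mount,
                                       note="master mix"))

    # template per reaction, fresh tip each
    src_wells = list(well_iterator(catalog.get(uv.source_plate), "column-major"))
    if v_template > 0:
        for i, dest in enumerate(dest_wells):
            source = (src_slot, src_wells[i % len(src_wells)])
            plan.set_initial_volume(source[0], source[1], v_template)
            _transfer_steps(plan, pipettes, source, dest, v_template,
                            note=f"template rxn{i + 1}")
            plan.steps.append(TransferStep(
                "drop_tip",
                mount=give_me_optimal_pipette(v_template, pipettes).mount))
    for i, dest in enumerate(dest_wells):
        plan.sample_assignment[i] = dest
        plan.sample_names[i] = f"rxn{i + 1}"

    raw_profile = uv.extras.get("profile")
    profile = (TemperatureProfile.from_strings(list(raw_profile))
               if raw_profile else DEFAULT_PCR_PROFILE)
    return plan, profile


# ---------------------------------------------------------------------------
# two-criteria counter selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Criterion:
    measurement: str
    comparator: str  # ">=" | "<="
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in (">=", "<="):
            raise InvalidComponent(f"comparator must be >= or <=, "
                                   f"got {self.comparator!r}")

    def passes(self, value: float) -> bool:
        return value >= self.threshold if self.comparator == ">=" \
            else value <= self.threshold


@dataclass(frozen=True)
class CounterSelectionCriteria:
    """Two measurement thresholds combined by conjunction: a sample is
    kept only when it passes both."""

    criterion1: Criterion
    criterion2: Criterion

    def __post_init__(self) -> None:
        if self.criterion1.measurement == self.criterion2.measurement:
            raise InvalidComponent(
                "the two criteria must use distinct measurements")


def counter_select(measurements: pd.DataFrame | list[tuple[str, str, float]],
                   criteria: CounterSelectionCriteria) -> list[str]:
    """Select the sample ids passing both criteria, in sorted id order.

    ``measurements`` is long-form: (sample-id, measurement-name, value)
    rows, as a DataFrame with those three columns or a list of tuples.
    Every sample must carry both measurements.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements.iloc[:, :3].copy()
        df.columns = ["sample_id", "measurement", "value"]
    else:
        df = pd.DataFrame(measurements,
                          columns=["sample_id", "measurement", "value"])
    wide = df.pivot_table(index="sample_id", columns="measurement",
                          values="value", aggfunc="first")
    selected = []
    for crit in (criteria.criterion1, criteria.criterion2):
        if crit.measurement not in wide.columns:
            raise MissingMeasurement(
                f"no sample carries measurement {crit.measurement!r}")
    for sample_id, row in wide.iterrows():
        values = {}
        for crit in (criteria.criterion1, criteria.criterion2):
            v = row.get(crit.measurement)
            if v is None or pd.isna(v):
                raise MissingMeasurement(
                    f"sample {sample_id!r} lacks {crit.measurement!r}")
            values[crit.measurement] = float(v)
        if criteria.criterion1.passes(values[criteria.criterion1.measurement]) \
                and criteria.criterion2.passes(
                    values[criteria.criterion2.measurement]):
            selected.append(str(sample_id))
    return sorted(selected)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-form per-well measurement table
    (sample_id, measurement, value)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def make_fixture_cvf(protocol: str, seed: int | None = None) -> CVFDocument:
    """A valid, randomized (but seeded) variable file for ``protocol``."""
    rng = random.Random(seed)
    pip_section = [
        ("pipR", "p300_single"),
        ("pipL", "p20_single"),
        ("APINameTipR", "tiprack_300ul_96"),
        ("APINameTipL", "tiprack_20ul_96"),
    ]
    if protocol == "inoculation":
        n = rng.randint(4, 16)
        media = rng.sample(["LB", "M9", "TB", "SOC", "YPD"], rng.randint(1, 3))
        v_media = float(rng.randint(100, 180))
        sections = {
            "PipetteVariables": pip_section,
            "GeneralVariables": [
                ("number_samples", str(n)),
                ("source_plate", "plate_96_well"),
                ("destination_plate", "plate_96_well"),
                ("reagent_rack", "tuberack_24_falcon15"),
            ],
            "MediaVariables": [
                ("media", media if len(media) > 1 else media[0]),
                ("volume_media", str(v_media)),
                ("volume_inoculum", str(float(rng.randint(5, 15)))),
            ],
        }
    elif protocol == "consolidation":
        n = rng.randint(8, 96)
        sections = {
            "PipetteVariables": pip_section,
            "GeneralVariables": [
                ("number_samples", str(n)),
                ("source_plate", "plate_96_well"),
                ("destination_plate", "plate_96_well"),
                ("n_source_plates", str(max(1, -(-n // 48)))),
            ],
            "SampleVariables": [
                ("volume_sample", str(float(rng.randint(20, 150)))),
            ],
        }
    elif protocol == "pcr_mix":
        comps = ["buffer", "dntps", "polymerase", "primers"]
        vols = [float(rng.randint(2, 10)) for _ in comps]
        sections = {
            "PipetteVariables": pip_section,
            "GeneralVariables": [
                ("number_samples", str(rng.randint(8, 48))),
                ("source_plate", "plate_96_well"),
                ("destination_plate", "plate_96_well"),
                ("reagent_rack", "tuberack_24_falcon15"),
                ("extra_fraction", "0.1"),
            ],
            "ReagentVariables": [
                ("components", comps),
                ("volume_component", [str(v) for v in vols]),
                ("volume_template", str(float(rng.randint(1, 5)))),
            ],
            "ProfileVariables": [
                ("profile", ["98:180:1", "98:10:30", "55:20:30",
                             "72:30:30", "72:300:1"]),
            ],
        }
    elif protocol == "counter_selection":
        sections = {
            "PipetteVariables": pip_section,
            "GeneralVariables": [("number_samples", str(rng.randint(8, 96)))],
            "SelectionVariables": [
                ("measurement_1", "fluorescence"),
                ("comparator_1", ">="),
                ("threshold_1", str(float(rng.randint(5, 20)))),
                ("measurement_2", "absorbance"),
                ("comparator_2", "<="),
                ("threshold_2", str(round(rng.uniform(0.2, 0.8), 2))),
            ],
        }
    else:
        raise InvalidComponent(f"unknown protocol {protocol!r}")
    return CVFDocument(sections=sections, source_dialect="memory")


def make_broken_fixture_cvfs(protocol: str, seed: int | None = None
                             ) -> dict[str, CVFDocument]:
    """Deliberately invalid variants, one violation each, keyed by what
    is wrong — food for the validator tests."""
    broken: dict[str, CVFDocument] = {}

    def fresh() -> CVFDocument:
        return make_fixture_cvf(protocol, seed)

    def mutate(label: str, section: str, name: str, value) -> None:
        doc = fresh()
        pairs = doc.sections[section]
        if value is None:
            doc.sections[section] = [(k, v) for k, v in pairs if k != name]
        else:
            replaced = False
            for i, (k, _) in enumerate(pairs):
                if k == name:
                    pairs[i] = (k, value)
                    replaced = True
            if not replaced:
                pairs.append((name, value))
        broken[label] = doc

    mutate("missing_tiprack_right", "PipetteVariables", "APINameTipR", "")
    mutate("unknown_pipette_model", "PipetteVariables", "pipR", "p5000_single")
    mutate("non_numeric_samples", "GeneralVariables", "number_samples", "many")
    mutate("zero_samples", "GeneralVariables", "number_samples", "0")
    no_pips = fresh()
    no_pips.sections["PipetteVariables"] = [
        ("pipR", ""), ("pipL", ""), ("APINameTipR", ""), ("APINameTipL", "")]
    broken["no_pipettes"] = no_pips
    if protocol == "inoculation":
        mutate("overfilled_well", "MediaVariables", "volume_media", "300")
        mutate("unknown_labware", "GeneralVariables", "destination_plate",
               "plate_384_well")
    elif protocol == "consolidation":
        mutate("unknown_labware", "GeneralVariables", "source_plate",
               "mystery_plate")
        mutate("negative_volume", "SampleVariables", "volume_sample", "-5")
    elif protocol == "pcr_mix":
        mutate("negative_volume", "ReagentVariables", "volume_template", "-1")
        mutate("overfilled_well", "ReagentVariables", "volume_component",
               ["150", "80", "50", "40"])
    elif protocol == "counter_selection":
        mutate("bad_comparator", "SelectionVariables", "comparator_1", "!=")
        mutate("non_numeric_threshold", "SelectionVariables", "threshold_1",
               "high")
    return broken


def make_measurements_fixture(sample_ids: list[str], seed: int = 0,
                              measurement_names: tuple[str, str] =
                              ("fluorescence", "absorbance")) -> pd.DataFrame:
    """A seeded long-form measurement table for counter-selection tests."""
    rng = random.Random(seed)
    rows = []
    for sid in sample_ids:
        rows.append((sid, measurement_names[0], round(rng.uniform(0, 30), 3)))
        rows.append((sid, measurement_names[1], round(rng.uniform(0, 1.2), 3)))
    return pd.DataFrame(rows, columns=["sample_id", "measurement", "value"])
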