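"""Labware model: plates, tip racks, tube racks, reservoirs and the deck.

The central piece of science here is the volume <-> liquid-height
mathematics for conical-bottom (falcon-style) centrifuge tubes, used by
the virtual robot to aspirate just below the liquid surface instead of
plunging the tip to the bottom.  A tube is modeled as an inverted cone
(apex at the bottom) of height ``cone_height`` joined to a cylinder of
height ``cylinder_height``; both share the radius ``junction_radius`` at
the junction.  With the mm^3 == uL identity,

    V(h) = (pi/3) * (r*h/h_cone)^2 * h            for h <= h_cone
    V(h) = V(h_cone) + pi * r^2 * (h - h_cone)    above the junction

which is strictly increasing and continuous, so it inverts in closed
form on each branch.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import (
    InvalidComponent,
    OutOfRange,
    UnknownLabware,
    UnreadableFile,
)

#: 1 cubic millimetre of water is exactly 1 microlitre.
MM3_PER_UL = 1.0

LabwareKind = str  # one of {"plate", "tiprack", "tuberack", "reservoir"}
Mount = str        # one of {"left", "right"}

#: Deck slots available on the simulated platform, lowest first.
DEFAULT_SLOTS = tuple(range(1, 12))


# ---------------------------------------------------------------------------
# tube geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeGeometry:
    """Cone-plus-cylinder tube model.

    Parameters
    ----------
    junction_radius : float
        Inner radius (mm) of the cylinder, equal to the cone radius at
        the cone/cylinder junction.
    cone_height : float
        Height (mm) of the conical bottom section.
    cylinder_height : float
        Height (mm) of the cylindrical section above the cone.
    nominal_capacity : float
        Marketed capacity in uL (15 mL tube -> 15000).
    dead_volume : float
        Liquid (uL) that can never be reliably recovered; aspiration
        below this level is refused.
    """

    junction_radius: float
    cone_height: float
    cylinder_height: float
    nominal_capacity: float
    dead_volume: float

    def __post_init__(self) -> None:
        for name in ("junction_radius", "cone_height", "cylinder_height",
                     "nominal_capacity", "dead_volume"):
            if getattr(self, name) <= 0:
                raise InvalidComponent(f"TubeGeometry.{name} must be positive")
        if self.dead_volume >= self.nominal_capacity:
            raise InvalidComponent("dead_volume must be below nominal capacity")
        if self.physical_capacity < self.nominal_capacity:
            raise InvalidComponent(
                "geometry cannot hold its own nominal capacity "
                f"({self.physical_capacity:.0f} < {self.nominal_capacity:.0f} uL)")

    @property
    def total_height(self) -> float:
        return self.cone_height + self.cylinder_height

    @property
    def cone_volume(self) -> float:
        r = self.junction_radius
        return (math.pi / 3.0) * r * r * self.cone_height * MM3_PER_UL

    @property
    def physical_capacity(self) -> float:
        """Volume at the brim, in uL."""
        r = self.junction_radius
        return self.cone_volume + math.pi * r * r * self.cylinder_height * MM3_PER_UL


def volume_from_height(g: TubeGeometry, h: float) -> float:
    """Liquid volume (uL) when the surface sits at height ``h`` mm."""
    if h < 0 or h > g.total_height + 1e-9:
        raise OutOfRange(f"height {h} mm outside [0, {g.total_height}] mm")
    if h <= g.cone_height:
        r_at_h = g.junction_radius * h / g.cone_height
        return (math.pi / 3.0) * r_at_h * r_at_h * h * MM3_PER_UL
    r = g.junction_radius
    return g.cone_volume + math.pi * r * r * (h - g.cone_height) * MM3_PER_UL


def height_from_volume(g: TubeGeometry, v: float) -> float:
    """Surface height (mm) for a liquid volume ``v`` uL; inverse of
    :func:`volume_from_height` on both branches."""
    if v < 0 or v > g.physical_capacity * (1 + 1e-12):
        raise OutOfRange(f"volume {v} uL outside [0, {g.physical_capacity:.1f}] uL")
    if v <= g.cone_volume:
        r = g.junction_radius
        return (3.0 * v * g.cone_height ** 2 / (math.pi * r * r)) ** (1.0 / 3.0)
    r = g.junction_radius
    return g.cone_height + (v - g.cone_volume) / (math.pi * r * r)


# ---------------------------------------------------------------------------
# labware definitions and catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabwareDefinition:
    api_name: str
    kind: LabwareKind
    rows: int
    cols: int
    well_max_volume: float | None = None       # plates / reservoirs
    tube_geometry: TubeGeometry | None = None  # tuberacks

    def __post_init__(self) -> None:
        if self.kind not in ("plate", "tiprack", "tuberack", "reservoir"):
            raise InvalidComponent(f"unknown labware kind {self.kind!r}")
        if self.rows < 1 or self.cols < 1:
            raise InvalidComponent("grid must be at least 1x1")
        if self.kind in ("plate", "reservoir"):
            if not self.well_max_volume or self.well_max_volume <= 0:
                raise InvalidComponent(f"{self.kind} needs well_max_volume > 0")
            if self.tube_geometry is not None:
                raise InvalidComponent(f"{self.kind} must not carry tube geometry")
        elif self.kind == "tuberack":
            if self.tube_geometry is None:
                raise InvalidComponent("tuberack needs tube_geometry")
            if self.well_max_volume is not None:
                raise InvalidComponent("tuberack capacity comes from its geometry")
        elif self.kind == "tiprack":
            if self.well_max_volume is not None or self.tube_geometry is not None:
                raise InvalidComponent("tiprack holds tips, not liquid")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    @property
    def tip_capacity(self) -> int:
        if self.kind != "tiprack":
            raise InvalidComponent(f"{self.api_name} is not a tiprack")
        return self.n_wells

    def max_volume_of_well(self) -> float:
        """Per-well liquid maximum in uL (physical brim for tubes)."""
        if self.kind in ("plate", "reservoir"):
            assert self.well_max_volume is not None
            return self.well_max_volume
        if self.kind == "tuberack":
            assert self.tube_geometry is not None
            return self.tube_geometry.physical_capacity
        raise InvalidComponent(f"{self.api_name} does not hold liquid")


def well_iterator(definition: LabwareDefinition, order: str = "column-major"):
    """Yield well ids over the grid: letter row (A at top) + 1-based column.

    ``column-major`` (the robot's tip-pickup order) yields A1, B1, ...,
    then A2, ...; ``row-major`` yields A1, A2, ... then B1, ...
    """
    if order not in ("column-major", "row-major"):
        raise InvalidComponent(f"unknown well order {order!r}")
    rows = range(definition.rows)
    cols = range(definition.cols)
    if order == "column-major":
        for c in cols:
            for r in rows:
                yield f"{_row_letter(r)}{c + 1}"
    else:
        for r in rows:
            for c in cols:
                yield f"{_row_letter(r)}{c + 1}"


def _row_letter(index: int) -> str:
    # A..Z then AA.. for oversized labware
    letters = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def parse_well_id(definition: LabwareDefinition, well_id: str) -> tuple[int, int]:
    """Return 0-based (row, col) for ``well_id`` or raise ``BadWellId``."""
    from .errors import BadWellId
    i = 0
    while i < len(well_id) and well_id[i].isalpha():
        i += 1
    letters, digits = well_id[:i], well_id[i:]
    if not letters or not digits or not digits.isdigit():
        raise BadWellId(f"malformed well id {well_id!r}")
    row = 0
    for ch in letters.upper():
        row = row * 26 + (ord(ch) - ord("A") + 1)
    row -= 1
    col = int(digits) - 1
    if not (0 <= row < definition.rows and 0 <= col < definition.cols):
        raise BadWellId(
            f"{well_id!r} outside {definition.rows}x{definition.cols} grid of "
            f"{definition.api_name}")
    return row, col


# Nominal 15 mL conical geometry used by the z-tracked distribute; values
# are documented defaults of this toolkit, not vendor-certified dimensions.
FALCON_15ML = TubeGeometry(
    junction_radius=7.5,
    cone_height=22.0,
    cylinder_height=95.0,
    nominal_capacity=15_000.0,
    dead_volume=1_000.0,
)

# 50 mL counterpart, present so the 15 mL-only operations have something
# realistic to refuse.
FALCON_50ML = TubeGeometry(
    junction_radius=13.5,
    cone_height=15.0,
    cylinder_height=100.0,
    nominal_capacity=50_000.0,
    dead_volume=3_000.0,
)

_BUILTIN_DEFS = (
    LabwareDefinition("plate_96_well", "plate", 8, 12, well_max_volume=200.0),
    LabwareDefinition("deepwell_96_plate", "plate", 8, 12, well_max_volume=2000.0),
    LabwareDefinition("reservoir_12_channel", "reservoir", 1, 12,
                      well_max_volume=22_000.0),
    LabwareDefinition("tuberack_24_falcon15", "tuberack", 4, 6,
                      tube_geometry=FALCON_15ML),
    LabwareDefinition("tuberack_6_falcon50", "tuberack", 2, 3,
                      tube_geometry=FALCON_50ML),
    LabwareDefinition("tiprack_20ul_96", "tiprack", 8, 12),
    LabwareDefinition("tiprack_300ul_96", "tiprack", 8, 12),
    LabwareDefinition("tiprack_1000ul_96", "tiprack", 8, 12),
)


class LabwareCatalog:
    """api_name -> LabwareDefinition lookup with JSON (de)serialization."""

    def __init__(self, definitions: dict[str, LabwareDefinition]):
        self._defs = dict(definitions)

    def __contains__(self, api_name: str) -> bool:
        return api_name in self._defs

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabwareCatalog) and self._defs == other._defs

    def get(self, api_name: str) -> LabwareDefinition:
        try:
            return self._defs[api_name]
        except KeyError:
            raise UnknownLabware(f"labware {api_name!r} not in catalog") from None

    def names(self) -> list[str]:
        return sorted(self._defs)

    def to_json(self) -> str:
        payload = {}
        for name in sorted(self._defs):
            d = asdict(self._defs[name])
            d.pop("api_name")
            if d["tube_geometry"] is None:
                d.pop("tube_geometry")
            if d["well_max_volume"] is None:
                d.pop("well_max_volume")
            payload[name] = d
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def load_labware_catalog(source: str | Path = "builtin") -> LabwareCatalog:
    """Load a labware catalog from a JSON file, or the built-in one.

    The built-in catalog covers the standard SBS 96-well plate (8x12),
    a 24-position rack of 15 mL conical tubes, a 6-position 50 mL rack,
    a 12-channel reservoir and 96-tip racks for each supported pipette.
    """
    if source == "builtin":
        return LabwareCatalog({d.api_name: d for d in _BUILTIN_DEFS})
    path = Path(source)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise UnreadableFile(f"cannot read labware catalog {path}: {exc}") from exc
    defs: dict[str, LabwareDefinition] = {}
    for api_name, d in payload.items():
        geo = d.get("tube_geometry")
        defs[api_name] = LabwareDefinition(
            api_name=api_name,
            kind=d["kind"],
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            well_max_volume=d.get("well_max_volume"),
            tube_geometry=TubeGeometry(**geo) if geo else None,
        )
    return LabwareCatalog(defs)


# ---------------------------------------------------------------------------
# pipettes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipetteSpec:
    """A mounted single-channel pipette and its tip-rack binding."""

    mount: Mount
    model: str
    min_volume: float
    max_volume: float
    tiprack_api_name: str

    def __post_init__(self) -> None:
        if self.mount not in ("left", "right"):
            raise InvalidComponent(f"mount must be left/right, got {self.mount!r}")
        if not (0 < self.min_volume <= self.max_volume):
            raise InvalidComponent(
                f"need 0 < min <= max, got [{self.min_volume}, {self.max_volume}]")


#: Supported pipette models: working volume range (uL) and default tip rack.
PIPETTE_MODELS: dict[str, dict] = {
    "p20_single": {"min_volume": 1.0, "max_volume": 20.0,
                   "tiprack": "tiprack_20ul_96"},
    "p300_single": {"min_volume": 20.0, "max_volume": 300.0,
                    "tiprack": "tiprack_300ul_96"},
    "p1000_single": {"min_volume": 100.0, "max_volume": 1000.0,
                     "tiprack": "tiprack_1000ul_96"},
}


def make_pipette(mount: Mount, model: str,
                 tiprack_api_name: str | None = None) -> PipetteSpec:
    """Build a :class:`PipetteSpec` from a known model name."""
    if model not in PIPETTE_MODELS:
        raise UnknownLabware(f"unknown pipette model {model!r}")
    spec = PIPETTE_MODELS[model]
    return PipetteSpec(
        mount=mount,
        model=model,
        min_volume=spec["min_volume"],
        max_volume=spec["max_volume"],
        tiprack_api_name=tiprack_api_name or spec["tiprack"],
    )


# ---------------------------------------------------------------------------
# deck state
# ---------------------------------------------------------------------------

@dataclass
class DeckState:
    """Live state of the simulated deck.

    Volumes are per (slot, well-id); tip racks are tracked by remaining
    tip count per slot; each mount carries a has-tip flag and the volume
    currently held in the tip.
    """

    slots: dict[int, LabwareDefinition] = field(default_factory=dict)
    well_volumes: dict[tuple[int, str], float] = field(default_factory=dict)
    tips_available: dict[int, int] = field(default_factory=dict)
    pipette_has_tip: dict[Mount, bool] = field(default_factory=dict)
    pipette_held_volume: dict[Mount, float] = field(default_factory=dict)
    pipettes: dict[Mount, PipetteSpec] = field(default_factory=dict)
    slot_numbers: tuple[int, ...] = DEFAULT_SLOTS

    def copy(self) -> "DeckState":
        return DeckState(
            slots=dict(self.slots),
            well_volumes=dict(self.well_volumes),
            tips_available=dict(self.tips_available),
            pipette_has_tip=dict(self.pipette_has_tip),
            pipette_held_volume=dict(self.pipette_held_volume),
            pipettes=dict(self.pipettes),
            slot_numbers=self.slot_numbers,
        )

    def attach_pipette(self, spec: PipetteSpec) -> None:
        self.pipettes[spec.mount] = spec
        self.pipette_has_tip.setdefault(spec.mount, False)
        self.pipette_held_volume.setdefault(spec.mount, 0.0)

    def free_slots(self) -> list[int]:
        return [s for s in self.slot_numbers if s not in self.slots]

    def lowest_free_slot(self) -> int | None:
        free = self.free_slots()
        return free[0] if free else None

    def total_liquid(self) -> float:
        return sum(self.well_volumes.values())

    def volume_at(self, slot: int, well_id: str) -> float:
        return self.well_volumes.get((slot, well_id), 0.0)

    def digest(self) -> str:
        """Order-stable hash of the liquid + tip + pipette state."""
        import hashlib
        items = sorted(
            (str(slot), well, f"{vol:.6f}")
            for (slot, well), vol in self.well_volumes.items())
        items += sorted(
            ("tips", str(slot), str(n)) for slot, n in self.tips_available.items())
        items += sorted(
            ("pip", m, str(self.pipette_has_tip.get(m, False)),
             f"{self.pipette_held_volume.get(m, 0.0):.6f}")
            for m in self.pipettes)
        h = hashlib.sha256(repr(items).encode())
        return h.hexdigest()[:16]
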