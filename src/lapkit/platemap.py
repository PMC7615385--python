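"""Labeled plate maps for sample traceability.

A plate map is a grid the shape of its labware, each cell optionally
carrying a sample name, exported to CSV so the bench scientist (or a
downstream instrument) can see which sample sits in which well.  The
CSV layout is a spreadsheet-like grid: the header row holds the column
numbers, the first cell of each row its letter; empty wells are empty
fields.  Files use RFC-4180 quoting, UTF-8 and LF line endings, so
names containing commas, quotes or unicode survive the round trip.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import BadWellId, InvalidComponent, IOFailure, UnreadableFile
from .labware import LabwareDefinition, parse_well_id, _row_letter


@dataclass
class PlateMap:
    """Sample names arranged on a labware grid."""

    labware_api_name: str
    slot: int
    grid: list[list[str | None]]  # rows x cols, None = empty well

    def __post_init__(self) -> None:
        if not self.grid or any(len(r) != len(self.grid[0]) for r in self.grid):
            raise InvalidComponent("grid must be rectangular and non-empty")

    @property
    def rows(self) -> int:
        return len(self.grid)

    @property
    def cols(self) -> int:
        return len(self.grid[0])

    def names(self) -> list[str]:
        return [c for row in self.grid for c in row if c is not None]

    def assigned_wells(self) -> dict[str, str]:
        """well-id -> sample-name for every non-empty cell."""
        out = {}
        for r, row in enumerate(self.grid):
            for c, name in enumerate(row):
                if name is not None:
                    out[f"{_row_letter(r)}{c + 1}"] = name
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """The grid as a pandas DataFrame (row letters x column numbers)."""
        return pd.DataFrame(
            self.grid,
            index=[_row_letter(r) for r in range(self.rows)],
            columns=[str(c + 1) for c in range(self.cols)],
        )

    def default_filename(self) -> str:
        return f"{self.labware_api_name}_slot{self.slot}_map.csv"


def build_plate_map(definition: LabwareDefinition, slot: int,
                    assignment: dict[str, str]) -> PlateMap:
    """Place ``assignment`` (well-id -> sample name) onto the labware grid.

    Duplicate sample names are allowed but the caller sees them via
    ``names()``; unknown well ids raise :class:`BadWellId`.
    """
    grid: list[list[str | None]] = [
        [None] * definition.cols for _ in range(definition.rows)]
    for well_id, name in assignment.items():
        r, c = parse_well_id(definition, well_id)
        grid[r][c] = name
    return PlateMap(definition.api_name, slot, grid)


def export_plate_map_csv(m: PlateMap, path: str | Path) -> Path:
    """Write the map as a spreadsheet-style CSV grid."""
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow([""] + [str(c + 1) for c in range(m.cols)])
            for r, row in enumerate(m.grid):
                writer.writerow([_row_letter(r)]
                                + [cell if cell is not None else "" for cell in row])
    except OSError as exc:
        raise IOFailure(f"cannot write plate map {path}: {exc}") from exc
    return path


def import_plate_map_csv(path: str | Path, labware_api_name: str = "",
                         slot: int = 0) -> PlateMap:
    """Read a CSV written by :func:`export_plate_map_csv`."""
    path = Path(path)
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    except OSError as exc:
        raise UnreadableFile(f"cannot read plate map {path}: {exc}") from exc
    if not rows or not rows[0] or rows[0][0] != "":
        raise UnreadableFile(f"{path} is not a plate-map CSV (bad header)")
    n_cols = len(rows[0]) - 1
    grid: list[list[str | None]] = []
    for raw in rows[1:]:
        if not raw:
            continue
        cells = raw[1:] + [""] * (n_cols - len(raw) + 1)
        grid.append([c if c != "" else None for c in cells[:n_cols]])
    if not labware_api_name:
        labware_api_name, slot = _parse_map_filename(path.name)
    return PlateMap(labware_api_name, slot, grid)


def _parse_map_filename(name: str) -> tuple[str, int]:
    stem = name[:-4] if name.endswith(".csv") else name
    if stem.endswith("_map") and "_slot" in stem:
        api, _, tail = stem[:-4].rpartition("_slot")
        if tail.isdigit():
            return api, int(tail)
    return stem, 0
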