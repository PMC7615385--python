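"""Reading, writing and validating the protocol format's inputs.

Three concerns live here:

* the hyphenated protocol **name grammar**
  (``LAP-<Description>-<Platform>-<major.minor.patch>``) and the
  three-part script structure (Classes / Functions / Body) every
  standardized automation script must declare;
* the **Customizable Variable File** (CVF) — the user-editable
  parameter file, readable from an xlsx workbook (one sheet per
  section), a directory of CSVs, JSON, or XML, all carrying the same
  section -> (variable, value) model;
* **validation**: a declarative per-variable schema plus cross-variable
  rules, producing a report of every problem found rather than failing
  on the first.
"""
from __future__ import annotations

import csv
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import (
    DuplicateVariable,
    InvalidComponent,
    IOFailure,
    MalformedName,
    UnknownDialect,
    UnreadableFile,
)
from .labware import LabwareCatalog, PIPETTE_MODELS

#: The mandatory sections of a standardized automation script, in order.
LAP_SECTIONS: tuple[str, ...] = ("Classes", "Functions", "Body")


# ---------------------------------------------------------------------------
# protocol names
# ---------------------------------------------------------------------------

_VERSION_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)$")
_CAMEL_RE = re.compile(r"^[A-Za-z0-9]+$")

# file extensions silently stripped from a name's tail before parsing
_KNOWN_EXTENSIONS = (".py", ".xlsx", ".csv", ".json", ".xml", ".yaml",
                     ".yml", ".txt", ".zip")


@dataclass(frozen=True)
class LAPName:
    """A protocol identifier: repository token, CamelCase description,
    platform tag and semantic version, joined by hyphens."""

    repository: str
    description: str
    platform: str
    version: str

    def __post_init__(self) -> None:
        for f in ("repository", "description", "platform", "version"):
            value = getattr(self, f)
            if not value:
                raise InvalidComponent(f"LAPName.{f} must not be empty")
            if "-" in value:
                raise InvalidComponent(
                    f"LAPName.{f} must not contain the '-' delimiter")
        if self.repository != "LAP":
            raise InvalidComponent(
                f"repository token must be 'LAP', got {self.repository!r}")
        if not _CAMEL_RE.match(self.description):
            raise InvalidComponent(
                f"description must be alphanumeric CamelCase, got {self.description!r}")
        if not _VERSION_RE.match(self.version):
            raise InvalidComponent(
                f"version must be major.minor.patch integers, got {self.version!r}")

    @property
    def version_tuple(self) -> tuple[int, int, int]:
        m = _VERSION_RE.match(self.version)
        assert m is not None
        return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


def parse_lap_name(name: str) -> LAPName:
    """Parse ``LAP-<Description>-<Platform>-<x.y.z>[.ext]``."""
    stripped = name.strip()
    for ext in _KNOWN_EXTENSIONS:
        if stripped.lower().endswith(ext):
            stripped = stripped[: -len(ext)]
            break
    parts = stripped.split("-")
    if len(parts) != 4:
        raise MalformedName(
            f"expected 4 hyphen-separated fields, got {len(parts)} in {name!r}")
    repository, description, platform, version = parts
    if repository != "LAP":
        raise MalformedName(f"name must start with 'LAP', got {repository!r}")
    if not _VERSION_RE.match(version):
        raise MalformedName(f"bad version field {version!r} (want d.d.d)")
    try:
        return LAPName(repository, description, platform, version)
    except InvalidComponent as exc:
        raise MalformedName(str(exc)) from exc


def format_lap_name(n: LAPName) -> str:
    """Serialize back to the hyphenated form; inverse of :func:`parse_lap_name`."""
    return "-".join((n.repository, n.description, n.platform, n.version))


def validate_lap_structure(sections: list[str] | tuple[str, ...]) -> "ValidationReport":
    """Check that a script declares exactly the mandatory sections, in order.

    ``sections`` is the ordered list of top-level section names a script
    declares; a conforming script has exactly ``LAP_SECTIONS``.
    """
    issues: list[Issue] = []
    expected = list(LAP_SECTIONS)
    if list(sections) != expected:
        missing = [s for s in expected if s not in sections]
        extra = [s for s in sections if s not in expected]
        for s in missing:
            issues.append(Issue("error", "structure", s, "mandatory section missing"))
        for s in extra:
            issues.append(Issue("error", "structure", s, "unknown section"))
        if not missing and not extra:
            issues.append(Issue("error", "structure", "",
                                f"sections out of order: {list(sections)}"))
    return ValidationReport(issues=issues)


# ---------------------------------------------------------------------------
# CVF document model
# ---------------------------------------------------------------------------

RawValue = str | list[str]

DIALECTS = ("xlsx", "csv-bundle", "json", "xml")


@dataclass
class CVFDocument:
    """A raw, untyped Customizable Variable File.

    ``sections`` maps section name -> ordered list of (variable, raw
    value) pairs.  Values are strings (or lists of strings for
    multi-valued variables); typing happens at validation.
    """

    sections: dict[str, list[tuple[str, RawValue]]]
    source_dialect: str = "memory"

    def __post_init__(self) -> None:
        for section, pairs in self.sections.items():
            names = [name for name, _ in pairs]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                raise DuplicateVariable(
                    f"variable(s) {sorted(dupes)} duplicated in section {section!r}")

    def get(self, section: str, variable: str, default: RawValue | None = None
            ) -> RawValue | None:
        for name, value in self.sections.get(section, []):
            if name == variable:
                return value
        return default

    def content_equal(self, other: "CVFDocument") -> bool:
        """Equality of the logical content, ignoring the source dialect."""
        return self.sections == other.sections


def _normalize_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value).strip()


def read_cvf(path: str | Path, dialect: str | None = None) -> CVFDocument:
    """Read a Customizable Variable File in any supported dialect.

    The dialect is inferred from the file extension when not given:
    ``.xlsx``, ``.json``, ``.xml``, or a directory of per-section CSVs.
    """
    path = Path(path)
    if dialect is None:
        if path.is_dir():
            dialect = "csv-bundle"
        else:
            dialect = {".xlsx": "xlsx", ".json": "json",
                       ".xml": "xml"}.get(path.suffix.lower())
        if dialect is None:
            raise UnknownDialect(f"cannot infer CVF dialect from {path.name!r}")
    if dialect not in DIALECTS:
        raise UnknownDialect(f"unsupported CVF dialect {dialect!r}")
    if not path.exists():
        raise UnreadableFile(f"no such file: {path}")
    reader = {"xlsx": _read_xlsx, "csv-bundle": _read_csv_bundle,
              "json": _read_json, "xml": _read_xml}[dialect]
    sections = reader(path)
    return CVFDocument(sections=sections, source_dialect=dialect)


def write_cvf(doc: CVFDocument, path: str | Path, dialect: str | None = None) -> Path:
    """Write ``doc`` in the requested dialect (inferred from extension)."""
    path = Path(path)
    if dialect is None:
        dialect = {".xlsx": "xlsx", ".json": "json", ".xml": "xml"}.get(
            path.suffix.lower(), "csv-bundle" if not path.suffix else None)
        if dialect is None:
            raise UnknownDialect(f"cannot infer CVF dialect from {path.name!r}")
    if dialect not in DIALECTS:
        raise UnknownDialect(f"unsupported CVF dialect {dialect!r}")
    writer = {"xlsx": _write_xlsx, "csv-bundle": _write_csv_bundle,
              "json": _write_json, "xml": _write_xml}[dialect]
    writer(doc, path)
    return path


# --- xlsx: one sheet per section, columns Variable, Value[, Value 2 ...] ---

def _read_xlsx(path: Path) -> dict[str, list[tuple[str, RawValue]]]:
    import openpyxl
    try:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:
        raise UnreadableFile(f"cannot open workbook {path}: {exc}") from exc
    sections: dict[str, list[tuple[str, RawValue]]] = {}
    for ws in wb.worksheets:
        pairs: list[tuple[str, RawValue]] = []
        rows = ws.iter_rows(values_only=True)
        header = next(rows, None)
        if header is None:
            sections[ws.title] = pairs
            continue
        for row in rows:
            if row is None or all(c is None for c in row):
                continue
            name = _normalize_cell(row[0])
            if not name:
                continue
            values = [_normalize_cell(c) for c in row[1:]]
            while values and values[-1] == "":
                values.pop()
            pairs.append((name, values[0] if len(values) == 1 else list(values)))
        sections[ws.title] = pairs
    wb.close()
    _check_dupes(sections)
    return sections


def _write_xlsx(doc: CVFDocument, path: Path) -> None:
    import openpyxl
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for section, pairs in doc.sections.items():
        ws = wb.create_sheet(title=section[:31])
        width = max([1] + [len(v) if isinstance(v, list) else 1 for _, v in pairs])
        ws.append(["Variable", "Value"] + [f"Value {i}" for i in range(2, width + 1)])
        for name, value in pairs:
            cells = value if isinstance(value, list) else [value]
            ws.append([name] + list(cells))
    try:
        wb.save(path)
    except OSError as exc:
        raise IOFailure(f"cannot write workbook {path}: {exc}") from exc


# --- csv bundle: a directory, one <Section>.csv per section ---------------

def _read_csv_bundle(path: Path) -> dict[str, list[tuple[str, RawValue]]]:
    if not path.is_dir():
        raise UnreadableFile(f"csv-bundle dialect expects a directory: {path}")
    sections: dict[str, list[tuple[str, RawValue]]] = {}
    for csv_path in sorted(path.glob("*.csv")):
        pairs: list[tuple[str, RawValue]] = []
        with open(csv_path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            next(reader, None)  # header
            for row in reader:
                if not row or not row[0].strip():
                    continue
                values = [c.strip() for c in row[1:]]
                while values and values[-1] == "":
                    values.pop()
                pairs.append((row[0].strip(),
                              values[0] if len(values) == 1 else list(values)))
        sections[csv_path.stem] = pairs
    _check_dupes(sections)
    return sections


def _write_csv_bundle(doc: CVFDocument, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for section, pairs in doc.sections.items():
        width = max([1] + [len(v) if isinstance(v, list) else 1 for _, v in pairs])
        with open(path / f"{section}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["Variable", "Value"]
                            + [f"Value {i}" for i in range(2, width + 1)])
            for name, value in pairs:
                cells = value if isinstance(value, list) else [value]
                writer.writerow([name] + list(cells))


# --- json: {section: {variable: value-or-list}} ----------------------------

def _read_json(path: Path) -> dict[str, list[tuple[str, RawValue]]]:
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise UnreadableFile(f"cannot read JSON CVF {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise UnreadableFile(f"JSON CVF must be an object of sections: {path}")
    sections: dict[str, list[tuple[str, RawValue]]] = {}
    for section, variables in payload.items():
        pairs: list[tuple[str, RawValue]] = []
        for name, value in variables.items():
            if isinstance(value, list):
                pairs.append((name, [_normalize_cell(v) for v in value]))
            else:
                pairs.append((name, _normalize_cell(value)))
        sections[section] = pairs
    _check_dupes(sections)
    return sections


def _write_json(doc: CVFDocument, path: Path) -> None:
    payload = {section: {name: value for name, value in pairs}
               for section, pairs in doc.sections.items()}
    try:
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    except OSError as exc:
        raise IOFailure(f"cannot write JSON CVF {path}: {exc}") from exc


# --- xml: <cvf><section name=..><variable name=..>value ... -----------------

def _read_xml(path: Path) -> dict[str, list[tuple[str, RawValue]]]:
    try:
        tree = ET.parse(path)
    except (OSError, ET.ParseError) as exc:
        raise UnreadableFile(f"cannot read XML CVF {path}: {exc}") from exc
    root = tree.getroot()
    sections: dict[str, list[tuple[str, RawValue]]] = {}
    for sec_el in root.findall("section"):
        name = sec_el.get("name", "")
        pairs: list[tuple[str, RawValue]] = []
        for var_el in sec_el.findall("variable"):
            vname = var_el.get("name", "")
            value_els = var_el.findall("value")
            if value_els:
                values = [(v.text or "") for v in value_els]
                pairs.append((vname, values))
            else:
                pairs.append((vname, var_el.text or ""))
        sections[name] = pairs
    _check_dupes(sections)
    return sections


def _write_xml(doc: CVFDocument, path: Path) -> None:
    root = ET.Element("cvf")
    for section, pairs in doc.sections.items():
        sec_el = ET.SubElement(root, "section", name=section)
        for name, value in pairs:
            var_el = ET.SubElement(sec_el, "variable", name=name)
            if isinstance(value, list):
                for v in value:
                    ET.SubElement(var_el, "value").text = v
            else:
                var_el.text = value
    ET.indent(root)
    try:
        ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)
    except OSError as exc:
        raise IOFailure(f"cannot write XML CVF {path}: {exc}") from exc


def _check_dupes(sections: dict[str, list[tuple[str, RawValue]]]) -> None:
    for section, pairs in sections.items():
        names = [n for n, _ in pairs]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateVariable(
                f"variable(s) {sorted(dupes)} duplicated in section {section!r}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    section: str
    variable: str
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def add(self, severity: str, section: str, variable: str, message: str) -> None:
        self.issues.append(Issue(severity, section, variable, message))

    def summary(self) -> str:
        if self.ok and not self.issues:
            return "OK: no issues"
        lines = [f"[{i.severity}] {i.section}/{i.variable}: {i.message}"
                 for i in self.issues]
        return "\n".join(lines)


@dataclass(frozen=True)
class VariableSpec:
    """One schema entry: where a variable lives and how to type it."""

    section: str
    name: str
    vtype: str               # str | int | float | bool | list_str | list_float
    required: bool = True
    minimum: float | None = None
    maximum: float | None = None
    choices: tuple[str, ...] | None = None
    default: object = None


@dataclass
class VariableSchema:
    """A protocol's declared variables plus the labware catalog used for
    name resolution and well-capacity cross checks."""

    protocol: str
    variables: list[VariableSpec]
    catalog: LabwareCatalog | None = None


@dataclass
class UserVariables:
    """Validated, typed experiment parameters.

    The conventional names are stable across protocols: the right and
    left mounted pipettes are ``pipR``/``pipL`` and their tip racks
    ``APINameTipR``/``APINameTipL``.
    """

    pipR: str | None = None
    pipL: str | None = None
    APINameTipR: str | None = None
    APINameTipL: str | None = None
    number_samples: int = 1
    source_plate: str | None = None
    destination_plate: str | None = None
    reagent_rack: str | None = None
    reagent_volumes: dict[str, float] = field(default_factory=dict)
    extra_fraction: float = 0.0
    extras: dict[str, object] = field(default_factory=dict)

    def pipettes(self) -> list:
        """Mounted :class:`~lapkit.labware.PipetteSpec` objects."""
        from .labware import make_pipette
        out = []
        if self.pipR:
            out.append(make_pipette("right", self.pipR, self.APINameTipR))
        if self.pipL:
            out.append(make_pipette("left", self.pipL, self.APINameTipL))
        return out


_TRUE = {"true", "yes", "1"}
_FALSE = {"false", "no", "0"}


def _parse_typed(raw: RawValue, vtype: str):
    """Parse one raw value; raises ValueError with a user-facing message."""
    if vtype in ("list_str", "list_float"):
        items = raw if isinstance(raw, list) else ([raw] if raw != "" else [])
        if vtype == "list_str":
            return [str(x) for x in items]
        return [_parse_number(x) for x in items]
    if isinstance(raw, list):
        raise ValueError(f"expected a single value, got {len(raw)} values")
    raw = raw.strip()
    if vtype == "str":
        return raw
    if vtype == "bool":
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"expected True/False, got {raw!r}")
    if vtype == "int":
        num = _parse_number(raw)
        if num != int(num):
            raise ValueError(f"expected an integer, got {raw!r}")
        return int(num)
    if vtype == "float":
        return _parse_number(raw)
    raise ValueError(f"unknown type {vtype!r}")


def _parse_number(raw: str) -> float:
    raw = raw.strip()
    if "," in raw:
        raise ValueError(f"thousands separators are not accepted: {raw!r}")
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"not a number: {raw!r}") from None


def validate_variables(doc: CVFDocument, schema: VariableSchema
                       ) -> tuple[UserVariables | None, ValidationReport]:
    """Validate a raw CVF against a protocol schema.

    Two phases: each declared variable is located, typed and
    bounds-checked; then cross-variable rules run (a mounted pipette
    requires its tip rack, per-well dispense volumes must fit the
    destination wells).  All problems are collected; ``UserVariables``
    is only returned when the report is clean.
    """
    report = ValidationReport()
    typed: dict[str, object] = {}

    for spec in schema.variables:
        raw = doc.get(spec.section, spec.name)
        present = raw is not None and raw != "" and raw != []
        if not present:
            if spec.required:
                report.add("error", spec.section, spec.name,
                           "required variable is missing or blank")
            elif spec.default is not None:
                typed[spec.name] = spec.default
            continue
        try:
            value = _parse_typed(raw, spec.vtype)
        except ValueError as exc:
            report.add("error", spec.section, spec.name, str(exc))
            continue
        if spec.choices is not None and value not in spec.choices:
            report.add("error", spec.section, spec.name,
                       f"{value!r} not one of {sorted(spec.choices)}")
            continue
        for bound, op, word in ((spec.minimum, lambda a, b: a < b, "below minimum"),
                                (spec.maximum, lambda a, b: a > b, "above maximum")):
            if bound is None or not isinstance(value, (int, float)) \
                    or isinstance(value, bool):
                continue
            if op(value, bound):
                report.add("error", spec.section, spec.name,
                           f"value {value} {word} {bound}")
                break
        else:
            typed[spec.name] = value
            continue
    # unknown variables are surfaced as warnings, never errors
    declared = {(s.section, s.name) for s in schema.variables}
    for section, pairs in doc.sections.items():
        for name, _ in pairs:
            if (section, name) not in declared:
                report.add("warning", section, name,
                           "variable not declared by this protocol; ignored")

    _cross_checks(typed, schema, report)
    if not report.ok:
        return None, report
    return _build_user_variables(typed), report


def _cross_checks(typed: dict[str, object], schema: VariableSchema,
                  report: ValidationReport) -> None:
    catalog = schema.catalog
    pip_r, pip_l = typed.get("pipR"), typed.get("pipL")
    if not pip_r and not pip_l:
        report.add("error", "PipetteVariables", "pipR",
                   "at least one pipette (pipR or pipL) must be set")
    for pip, tip, label in (("pipR", "APINameTipR", "right"),
                            ("pipL", "APINameTipL", "left")):
        if typed.get(pip) and not typed.get(tip):
            report.add("error", "PipetteVariables", tip,
                       f"missing tip rack for {label} pipette")
        model = typed.get(pip)
        if model and model not in PIPETTE_MODELS:
            report.add("error", "PipetteVariables", pip,
                       f"unknown pipette model {model!r}")
    if catalog is not None:
        for var in ("APINameTipR", "APINameTipL", "source_plate",
                    "destination_plate", "reagent_rack"):
            name = typed.get(var)
            if name and name not in catalog:
                report.add("error", "GeneralVariables", var,
                           f"labware {name!r} not in catalog")
    # per-well volume must fit the destination well
    dest = typed.get("destination_plate")
    if catalog is not None and dest and dest in catalog:
        dest_def = catalog.get(dest)
        if dest_def.kind in ("plate", "reservoir"):
            well_max = dest_def.max_volume_of_well()
            per_well = 0.0
            for key, value in typed.items():
                if not key.startswith("volume_"):
                    continue
                if isinstance(value, (int, float)) and not isinstance(value, bool):
                    per_well += float(value)
                elif isinstance(value, list):
                    per_well += sum(v for v in value
                                    if isinstance(v, (int, float)))
            if per_well > well_max:
                report.add("error", "ReagentVariables", "volume",
                           f"per-well volume {per_well:g} uL exceeds well maximum "
                           f"{well_max:g} uL of {dest}")


def _build_user_variables(typed: dict[str, object]) -> UserVariables:
    core = {"pipR", "pipL", "APINameTipR", "APINameTipL", "number_samples",
            "source_plate", "destination_plate", "reagent_rack",
            "extra_fraction"}
    uv = UserVariables(
        pipR=typed.get("pipR") or None,
        pipL=typed.get("pipL") or None,
        APINameTipR=typed.get("APINameTipR") or None,
        APINameTipL=typed.get("APINameTipL") or None,
        number_samples=int(typed.get("number_samples", 1)),
        source_plate=typed.get("source_plate") or None,
        destination_plate=typed.get("destination_plate") or None,
        reagent_rack=typed.get("reagent_rack") or None,
        extra_fraction=float(typed.get("extra_fraction", 0.0)),
    )
    for key, value in typed.items():
        if key in core:
            continue
        if key.startswith("volume_") and isinstance(value, (int, float)):
            uv.reagent_volumes[key[len("volume_"):]] = float(value)
        else:
            uv.extras[key] = value
    return uv


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

@dataclass
class ProtocolMetadata:
    """The YAML metadata sheet shipped next to each protocol script."""

    lap_name: LAPName
    description: str
    platform: str
    code_version: str
    requirements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lap_name.version != self.code_version:
            raise InvalidComponent(
                f"metadata code_version {self.code_version!r} differs from "
                f"name version {self.lap_name.version!r}")


def write_metadata_yaml(meta: ProtocolMetadata, path: str | Path) -> Path:
    """Write protocol metadata as YAML with stable key order."""
    payload = {
        "lap_name": format_lap_name(meta.lap_name),
        "description": meta.description,
        "platform": meta.platform,
        "code_version": meta.code_version,
        "requirements": list(meta.requirements),
    }
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)
    except OSError as exc:
        raise IOFailure(f"cannot write metadata {path}: {exc}") from exc
    return path


def read_metadata_yaml(path: str | Path) -> ProtocolMetadata:
    try:
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        raise UnreadableFile(f"cannot read metadata {path}: {exc}") from exc
    return ProtocolMetadata(
        lap_name=parse_lap_name(payload["lap_name"]),
        description=payload.get("description", ""),
        platform=payload.get("platform", ""),
        code_version=payload.get("code_version", ""),
        requirements=list(payload.get("requirements", [])),
    )
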