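"""Reading and writing acquisition settings, scan jobs, coordinate lists, templates.

The engine's whole workflow is file-driven: the first- and second-scan
acquisition parameters live in two independent settings files, detection
results travel as a coordinate CSV (the macro contract), and a template ties
the pieces together so an experiment can be reloaded with one click.  The
settings dialect here is a versioned JSON document — a vendor-neutral stand-in
for the proprietary, machine-editable metadata files a microscope's native
software produces and reloads.

Serialization is canonical and deterministic: keys are sorted, floats are
formatted via ``repr`` after rounding to 9 significant digits, output is UTF-8
with LF endings.  Identical objects therefore produce byte-identical files,
and read/write are exact inverses on canonical documents.

Coordinate CSV contract (bit-exact, for external macros)::

    object_id,x_um,y_um,bbox_w_um,bbox_h_um,label,score

µm units, period decimal separator, UTF-8, LF line endings.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence, TextIO, Union

from .scan_planner import PlanItem, Rect, SingleField, TileGrid
from .stage_geometry import ObjectiveProfile, StagePoint

import numpy as np

__all__ = [
    "SCHEMA_VERSION",
    "COORD_HEADER",
    "ValidationError",
    "VersionError",
    "CoordinateParseError",
    "TemplateResolutionError",
    "AcquisitionSettings",
    "ScanJob",
    "CoordinateRecord",
    "SampleLayout",
    "Template",
    "read_settings",
    "write_settings",
    "read_coordinates",
    "write_coordinates",
    "read_job",
    "write_job",
    "save_template",
    "load_template",
    "validate_job",
    "canonical_dumps",
]

SCHEMA_VERSION = 1
COORD_HEADER = ["object_id", "x_um", "y_um", "bbox_w_um", "bbox_h_um", "label", "score"]


class ValidationError(ValueError):
    """A document violates the settings schema; the message names the field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class VersionError(ValueError):
    """Unknown schema_version."""


class CoordinateParseError(ValueError):
    """Malformed coordinate CSV row; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class TemplateResolutionError(FileNotFoundError):
    """A template references a settings file that does not resolve."""


# ---------------------------------------------------------------------------
# Canonical JSON
# ---------------------------------------------------------------------------

def _canon(value: Any) -> Any:
    if isinstance(value, float):
        return float(repr(float(f"{value:.9g}"))) if value == value else value
    if isinstance(value, dict):
        return {k: _canon(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_canon(v) for v in value]
    return value


def canonical_dumps(doc: dict) -> str:
    """Serialize a document deterministically: sorted keys, 9-significant-digit floats."""
    return json.dumps(_canon(doc), sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def _write_text(text: str, sink: Union[str, Path, TextIO]) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8", newline="\n")


def _read_text(source: Union[str, Path, TextIO]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text(encoding="utf-8")


# ---------------------------------------------------------------------------
# Schema helpers — small, flat documents, so validation is explicit
# ---------------------------------------------------------------------------

def _require(doc: dict, field_name: str, types) -> Any:
    key = field_name.split(".")[-1]
    if not isinstance(doc, dict) or key not in doc:
        raise ValidationError(field_name, "missing required field")
    val = doc[key]
    type_tuple = types if isinstance(types, tuple) else (types,)
    if isinstance(val, bool) and bool not in type_tuple:
        raise ValidationError(field_name, f"expected {types}, got bool")
    if not isinstance(val, type_tuple):
        raise ValidationError(field_name, f"expected {types}, got {type(val).__name__}")
    return val


def _num(doc: dict, field_name: str, minimum=None, strict=False) -> float:
    val = _require(doc, field_name, (int, float))
    if minimum is not None and (val <= minimum if strict else val < minimum):
        op = ">" if strict else ">="
        raise ValidationError(field_name, f"must be {op} {minimum}, got {val}")
    return float(val)


def _int(doc: dict, field_name: str, minimum=None) -> int:
    val = _require(doc, field_name, int)
    if minimum is not None and val < minimum:
        raise ValidationError(field_name, f"must be >= {minimum}, got {val}")
    return int(val)


def _check_version(doc: dict, kind: str) -> None:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise VersionError(f"unknown schema_version {version!r} (supported: {SCHEMA_VERSION})")
    actual = doc.get("kind")
    if actual != kind:
        raise ValidationError("kind", f"expected {kind!r}, got {actual!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionSettings:
    """Imaging parameters for one scan: objective, zoom, frame size, channels, z/t.

    The effective field of view is ``objective.fov / zoom``; pixel size follows
    as effective FOV over image size.  ``channels`` is a list of
    (name, exposure-or-gain) pairs; ``z_stack``/``time_lapse`` metadata is
    carried through into plans even where a renderer only produces single
    planes.
    """

    id: str
    objective: ObjectiveProfile
    zoom: float = 1.0
    image_width: int = 512
    image_height: int = 512
    channels: list[tuple[str, float]] = field(default_factory=lambda: [("ch0", 1.0)])
    z_stack: tuple[int, float] = (1, 0.0)        # (n_slices, step µm)
    time_lapse: tuple[int, float] = (1, 0.0)     # (n_frames, interval s)

    def __post_init__(self) -> None:
        if self.zoom < 1.0:
            raise ValidationError("zoom", f"must be >= 1, got {self.zoom}")
        if self.image_width < 1 or self.image_height < 1:
            raise ValidationError("image_width", "image size must be >= 1 pixel")
        if self.z_stack[0] < 1 or self.z_stack[1] < 0:
            raise ValidationError("z_stack", f"invalid {self.z_stack}")
        if self.time_lapse[0] < 1 or self.time_lapse[1] < 0:
            raise ValidationError("time_lapse", f"invalid {self.time_lapse}")
        if not self.channels:
            raise ValidationError("channels", "at least one channel is required")

    @property
    def fov(self) -> tuple[float, float]:
        """Effective field of view (w, h) in µm at this zoom."""
        return self.objective.fov_width / self.zoom, self.objective.fov_height / self.zoom

    @property
    def pixel_size(self) -> tuple[float, float]:
        """µm per pixel (x, y)."""
        w, h = self.fov
        return w / self.image_width, h / self.image_height

    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels]


@dataclass
class CoordinateRecord:
    """One detected-object row of the coordinate-list macro contract."""

    object_id: str
    x: float
    y: float
    bbox_w: float = 0.0
    bbox_h: float = 0.0
    label: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.bbox_w < 0 or self.bbox_h < 0:
            raise ValidationError("bbox_w_um", f"bbox must be >= 0, got {self.bbox_w}x{self.bbox_h}")


@dataclass
class SampleLayout:
    """Physical sample slots on the stage: up to five slides, a plate, or a dish."""

    slots: list[tuple[str, StagePoint, float, float]]  # (slot_id, origin, w µm, h µm)
    adapter_kind: str = "slides"

    def __post_init__(self) -> None:
        if not 1 <= len(self.slots) <= 5:
            raise ValidationError("slots", f"1-5 sample slots supported, got {len(self.slots)}")
        for i, (sid_a, oa, wa, ha) in enumerate(self.slots):
            if wa <= 0 or ha <= 0:
                raise ValidationError("slots", f"slot {sid_a!r} must have positive size")
            for sid_b, ob, wb, hb in self.slots[i + 1:]:
                if (oa.x < ob.x + wb and ob.x < oa.x + wa
                        and oa.y < ob.y + hb and ob.y < oa.y + ha):
                    raise ValidationError("slots", f"slots {sid_a!r} and {sid_b!r} overlap")

    def slot_rect(self, slot_id: str) -> Rect:
        for sid, origin, w, h in self.slots:
            if sid == slot_id:
                return Rect(origin.x, origin.y, w, h)
        raise KeyError(f"no slot {slot_id!r} in layout")


@dataclass
class ScanJob:
    """A settings file plus the concrete positions/grids to acquire on one sample."""

    settings: AcquisitionSettings
    items: list[tuple[str, PlanItem]]  # (object_id or tile id, item)
    sample_id: str = "sample0"


@dataclass
class Template:
    """A reloadable experiment definition: both scan settings plus detection/NoIR knobs.

    ``first_scan_settings``/``second_scan_settings`` are paths (relative to the
    template file) of the two independent settings documents; they must resolve
    when the template is loaded.
    """

    first_scan_settings: str
    second_scan_settings: str
    detection_params: "DetectionParams"
    layout: SampleLayout
    noir_enabled: bool = True
    noir_margin: float = 0.0
    macro: str = "tissue"                      # builtin macro: "tissue" | "rare_event"
    marker_rules: list["MarkerRule"] = field(default_factory=list)
    search_overlap: float = 0.0
    acquisition_margin: float = 0.0            # context margin around objects, µm


# ---------------------------------------------------------------------------
# Settings documents
# ---------------------------------------------------------------------------

def _objective_to_doc(obj: ObjectiveProfile) -> dict:
    return {
        "name": obj.name,
        "magnification": float(obj.magnification),
        "fov_width": float(obj.fov_width),
        "fov_height": float(obj.fov_height),
        "paracentricity_dx": float(obj.paracentricity_dx),
        "paracentricity_dy": float(obj.paracentricity_dy),
    }


def _objective_from_doc(doc: dict) -> ObjectiveProfile:
    _require(doc, "objective.name", str)
    try:
        return ObjectiveProfile(
            name=doc["name"],
            magnification=_num(doc, "objective.magnification", 0, strict=True),
            fov_width=_num(doc, "objective.fov_width", 0, strict=True),
            fov_height=_num(doc, "objective.fov_height", 0, strict=True),
            paracentricity_dx=_num(doc, "objective.paracentricity_dx"),
            paracentricity_dy=_num(doc, "objective.paracentricity_dy"),
        )
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ValidationError("objective", str(exc)) from exc


def settings_to_doc(settings: AcquisitionSettings) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "acquisition_settings",
        "id": settings.id,
        "objective": _objective_to_doc(settings.objective),
        "zoom": float(settings.zoom),
        "image_width": int(settings.image_width),
        "image_height": int(settings.image_height),
        "channels": [{"name": n, "exposure": float(e)} for n, e in settings.channels],
        "z_stack": {"n_slices": int(settings.z_stack[0]), "step_um": float(settings.z_stack[1])},
        "time_lapse": {"n_frames": int(settings.time_lapse[0]),
                       "interval_s": float(settings.time_lapse[1])},
    }


def settings_from_doc(doc: dict) -> AcquisitionSettings:
    _check_version(doc, "acquisition_settings")
    objective = _objective_from_doc(_require(doc, "objective", dict))
    channels_doc = _require(doc, "channels", list)
    channels = []
    for i, ch in enumerate(channels_doc):
        if not isinstance(ch, dict):
            raise ValidationError(f"channels[{i}]", "expected an object")
        channels.append((_require(ch, f"channels[{i}].name", str),
                         _num(ch, f"channels[{i}].exposure", 0)))
    z_doc = _require(doc, "z_stack", dict)
    t_doc = _require(doc, "time_lapse", dict)
    return AcquisitionSettings(
        id=_require(doc, "id", str),
        objective=objective,
        zoom=_num(doc, "zoom", 1),
        image_width=_int(doc, "image_width", 1),
        image_height=_int(doc, "image_height", 1),
        channels=channels,
        z_stack=(_int(z_doc, "z_stack.n_slices", 1), _num(z_doc, "z_stack.step_um", 0)),
        time_lapse=(_int(t_doc, "time_lapse.n_frames", 1), _num(t_doc, "time_lapse.interval_s", 0)),
    )


def read_settings(source: Union[str, Path, TextIO]) -> AcquisitionSettings:
    return settings_from_doc(json.loads(_read_text(source)))


def write_settings(settings: AcquisitionSettings, sink: Union[str, Path, TextIO]) -> None:
    _write_text(canonical_dumps(settings_to_doc(settings)), sink)


# ---------------------------------------------------------------------------
# Scan jobs
# ---------------------------------------------------------------------------

def _item_to_doc(item: PlanItem) -> dict:
    if isinstance(item, SingleField):
        return {"type": "single_field",
                "center": [float(item.center.x), float(item.center.y)],
                "width": float(item.width), "height": float(item.height)}
    return {
        "type": "tile_grid",
        "origin": [float(item.origin.x), float(item.origin.y)],
        "rows": int(item.rows), "cols": int(item.cols),
        "tile_w": float(item.tile_w), "tile_h": float(item.tile_h),
        "overlap": float(item.overlap),
        "last_col_shift": float(item.last_col_shift),
        "last_row_shift": float(item.last_row_shift),
        "enabled": [[bool(v) for v in row] for row in item.enabled],
    }


def _item_from_doc(doc: dict, where: str) -> PlanItem:
    kind = _require(doc, f"{where}.type", str)
    if kind == "single_field":
        cx, cy = _require(doc, f"{where}.center", list)
        return SingleField(center=StagePoint(float(cx), float(cy)),
                           width=_num(doc, f"{where}.width", 0, strict=True),
                           height=_num(doc, f"{where}.height", 0, strict=True))
    if kind == "tile_grid":
        ox, oy = _require(doc, f"{where}.origin", list)
        return TileGrid(
            origin=StagePoint(float(ox), float(oy)),
            rows=_int(doc, f"{where}.rows", 1),
            cols=_int(doc, f"{where}.cols", 1),
            tile_w=_num(doc, f"{where}.tile_w", 0, strict=True),
            tile_h=_num(doc, f"{where}.tile_h", 0, strict=True),
            overlap=_num(doc, f"{where}.overlap", 0),
            enabled=np.array(_require(doc, f"{where}.enabled", list), dtype=bool),
            last_col_shift=_num(doc, f"{where}.last_col_shift"),
            last_row_shift=_num(doc, f"{where}.last_row_shift"),
        )
    raise ValidationError(f"{where}.type", f"unknown item type {kind!r}")


def job_to_doc(job: ScanJob) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "scan_job",
        "sample_id": job.sample_id,
        "settings": settings_to_doc(job.settings),
        "items": [{"id": item_id, **_item_to_doc(item)} for item_id, item in job.items],
    }


def job_from_doc(doc: dict) -> ScanJob:
    _check_version(doc, "scan_job")
    settings = settings_from_doc(_require(doc, "settings", dict))
    items = []
    for i, item_doc in enumerate(_require(doc, "items", list)):
        items.append((_require(item_doc, f"items[{i}].id", str),
                      _item_from_doc(item_doc, f"items[{i}]")))
    return ScanJob(settings=settings, items=items, sample_id=_require(doc, "sample_id", str))


def read_job(source: Union[str, Path, TextIO]) -> ScanJob:
    return job_from_doc(json.loads(_read_text(source)))


def write_job(job: ScanJob, sink: Union[str, Path, TextIO]) -> None:
    _write_text(canonical_dumps(job_to_doc(job)), sink)


# ---------------------------------------------------------------------------
# Coordinate CSV — the macro contract
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    return repr(float(f"{float(x):.9g}"))


def write_coordinates(records: Sequence[CoordinateRecord],
                      sink: Union[str, Path, TextIO]) -> None:
    """Write the coordinate list as the fixed-header CSV of the macro contract."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(COORD_HEADER)
    for rec in records:
        writer.writerow([rec.object_id, _fmt_float(rec.x), _fmt_float(rec.y),
                         _fmt_float(rec.bbox_w), _fmt_float(rec.bbox_h),
                         rec.label, _fmt_float(rec.score)])
    _write_text(buf.getvalue(), sink)


def read_coordinates(source: Union[str, Path, TextIO]) -> list[CoordinateRecord]:
    """Parse a coordinate CSV; a malformed row raises with its 1-based line number."""
    text = _read_text(source)
    rows = list(csv.reader(io.StringIO(text)))
    if not rows:
        raise CoordinateParseError(1, "empty file (header required)")
    if rows[0] != COORD_HEADER:
        raise CoordinateParseError(1, f"bad header {rows[0]!r}, expected {COORD_HEADER!r}")
    records = []
    for line_no, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(COORD_HEADER):
            raise CoordinateParseError(line_no, f"expected {len(COORD_HEADER)} fields, got {len(row)}")
        try:
            records.append(CoordinateRecord(
                object_id=row[0], x=float(row[1]), y=float(row[2]),
                bbox_w=float(row[3]), bbox_h=float(row[4]),
                label=row[5], score=float(row[6]),
            ))
        except ValueError as exc:
            raise CoordinateParseError(line_no, str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def _layout_to_doc(layout: SampleLayout) -> dict:
    return {
        "adapter_kind": layout.adapter_kind,
        "slots": [{"slot_id": sid, "origin": [float(o.x), float(o.y)],
                   "width": float(w), "height": float(h)}
                  for sid, o, w, h in layout.slots],
    }


def _layout_from_doc(doc: dict) -> SampleLayout:
    slots = []
    for i, s in enumerate(_require(doc, "layout.slots", list)):
        ox, oy = _require(s, f"layout.slots[{i}].origin", list)
        slots.append((_require(s, f"layout.slots[{i}].slot_id", str),
                      StagePoint(float(ox), float(oy)),
                      _num(s, f"layout.slots[{i}].width", 0, strict=True),
                      _num(s, f"layout.slots[{i}].height", 0, strict=True)))
    return SampleLayout(slots=slots, adapter_kind=_require(doc, "layout.adapter_kind", str))


def template_to_doc(template: Template) -> dict:
    from .detection import detection_params_to_doc, marker_rule_to_doc

    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "template",
        "first_scan_settings": template.first_scan_settings,
        "second_scan_settings": template.second_scan_settings,
        "detection_params": detection_params_to_doc(template.detection_params),
        "layout": _layout_to_doc(template.layout),
        "noir_enabled": bool(template.noir_enabled),
        "noir_margin_um": float(template.noir_margin),
        "macro": template.macro,
        "marker_rules": [marker_rule_to_doc(r) for r in template.marker_rules],
        "search_overlap": float(template.search_overlap),
        "acquisition_margin_um": float(template.acquisition_margin),
    }


def template_from_doc(doc: dict) -> Template:
    from .detection import detection_params_from_doc, marker_rule_from_doc

    _check_version(doc, "template")
    return Template(
        first_scan_settings=_require(doc, "first_scan_settings", str),
        second_scan_settings=_require(doc, "second_scan_settings", str),
        detection_params=detection_params_from_doc(_require(doc, "detection_params", dict)),
        layout=_layout_from_doc(_require(doc, "layout", dict)),
        noir_enabled=bool(_require(doc, "noir_enabled", bool)),
        noir_margin=_num(doc, "noir_margin_um", 0),
        macro=_require(doc, "macro", str),
        marker_rules=[marker_rule_from_doc(r) for r in _require(doc, "marker_rules", list)],
        search_overlap=_num(doc, "search_overlap", 0),
        acquisition_margin=_num(doc, "acquisition_margin_um", 0),
    )


def save_template(template: Template, sink: Union[str, Path]) -> None:
    _write_text(canonical_dumps(template_to_doc(template)), sink)


def load_template(source: Union[str, Path], resolve: bool = True) -> Template:
    """Load a template; with ``resolve``, check both referenced settings files load."""
    source = Path(source)
    template = template_from_doc(json.loads(source.read_text(encoding="utf-8")))
    if resolve:
        base = source.parent
        for ref in (template.first_scan_settings, template.second_scan_settings):
            path = Path(ref)
            if not path.is_absolute():
                path = base / path
            if not path.is_file():
                raise TemplateResolutionError(f"template references missing settings file {ref!r}")
            read_settings(path)  # re-validate on load
    return template


# ---------------------------------------------------------------------------
# Job validation
# ---------------------------------------------------------------------------

def validate_job(job: ScanJob, layout: SampleLayout) -> list[str]:
    """Check that every field/tile centre of the job lies inside its sample slot.

    Returns a list of human-readable violations; an empty list means the job is
    geometrically valid for the layout.  An item is acceptable when its centre
    falls inside *any* slot (jobs may span multiple slides).
    """
    violations = []
    rects = [Rect(o.x, o.y, w, h) for _, o, w, h in layout.slots]

    def inside(p: StagePoint) -> bool:
        return any(r.x <= p.x <= r.x1 and r.y <= p.y <= r.y1 for r in rects)

    for item_id, item in job.items:
        if isinstance(item, SingleField):
            if not inside(item.center):
                violations.append(f"item {item_id!r}: field centre ({item.center.x}, "
                                  f"{item.center.y}) outside every sample slot")
        else:
            for r, c, rect in item.iter_tiles(enabled_only=True):
                if not inside(rect.center):
                    violations.append(f"item {item_id!r}: tile ({r}, {c}) centre outside "
                                      f"every sample slot")
    return violations
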