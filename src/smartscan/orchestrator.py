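"""The three-step screening workflow: first scan -> analysis -> second scan.

Every step is file-driven so the workflow can run fully automatically ("play")
or step by step, with the user free to inspect — or edit — the coordinate CSV
between analysis and the second scan.  All artifacts live in one run directory:

``first_scan_job.json``   the search-mosaic job (settings + tile grid)
``mosaic.tif``            the stitched search mosaic (float32, C x H x W)
``mosaic_frame.json``     pixel-to-stage frame and channel order of the mosaic
``labels.tif``            label image of detected objects (row i of the CSV
                          corresponds to label value i + 1)
``coordinates.csv``       the detected-object list (the macro contract)
``second_scan_job.json``  the generated second-scan job — the file a
                          microscope's own software would reload and execute
``objects/``              the re-acquired high-resolution images
``manifest.json``         per-step status, artifact paths, counts, timings

Stitching uses nominal stage positions only (the virtual stage is exact and the
search mosaic is a locator, not a quantitative image); overlap strips are
blended by unweighted averaging, so pixel-level tests are exact.  Running the
three steps individually is byte-identical to one automatic run: each step
reads its inputs back from the run directory, never from process state.
"""

from __future__ import annotations

import json
import logging
import time
import uuid
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from . import detection as det
from .acquisition_io import (
    AcquisitionSettings,
    ScanJob,
    Template,
    canonical_dumps,
    load_template,
    read_coordinates,
    read_settings,
    write_coordinates,
    write_job,
)
from .scan_planner import (
    Rect,
    SecondScanPlan,
    SingleField,
    TileGrid,
    apply_noir,
    estimate_savings,
    plan_object_acquisition,
    plan_search_mosaic,
)
from .stage_geometry import MosaicFrame, StagePoint
from .virtual_microscope import (
    SyntheticSampleSpec,
    VirtualSlide,
    acquire,
    generate_slide,
    spec_from_doc,
    spec_to_doc,
)

__all__ = [
    "RunManifest",
    "WorkflowError",
    "run_first_scan",
    "run_analysis",
    "run_second_scan",
    "run_all",
    "stitch_tiles",
    "write_demo_experiment",
]

log = logging.getLogger("smartscan")

STEPS = ("first_scan", "analysis", "second_scan")


class WorkflowError(RuntimeError):
    """A step was launched out of order or with missing artifacts."""


@dataclass
class RunManifest:
    """Status and artifact index of one screening run."""

    out_dir: Path
    run_id: str = ""
    template_path: str = ""
    seed: Optional[int] = None
    status: dict = field(default_factory=lambda: {s: "pending" for s in STEPS})
    artifacts: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    savings: Optional[float] = None
    timings: dict = field(default_factory=dict)
    slot: Optional[list] = None          # [x, y, w, h] of the scanned sample slot

    def path(self, name: str) -> Path:
        return self.out_dir / self.artifacts[name]

    def save(self) -> None:
        doc = {
            "run_id": self.run_id,
            "template_path": self.template_path,
            "seed": self.seed,
            "status": self.status,
            "artifacts": self.artifacts,
            "counts": self.counts,
            "savings": self.savings,
            "timings": self.timings,
            "slot": self.slot,
        }
        (self.out_dir / "manifest.json").write_text(canonical_dumps(doc), encoding="utf-8")

    @classmethod
    def load(cls, out_dir: Union[str, Path]) -> "RunManifest":
        out_dir = Path(out_dir)
        doc = json.loads((out_dir / "manifest.json").read_text(encoding="utf-8"))
        return cls(out_dir=out_dir, run_id=doc["run_id"], template_path=doc["template_path"],
                   seed=doc["seed"], status=doc["status"], artifacts=doc["artifacts"],
                   counts=doc["counts"], savings=doc["savings"], timings=doc["timings"],
                   slot=doc.get("slot"))

    def _require_done(self, step: str) -> None:
        if self.status.get(step) != "done":
            raise WorkflowError(f"step {step!r} must be done first (status: {self.status})")


# ---------------------------------------------------------------------------
# Template/settings resolution
# ---------------------------------------------------------------------------

def _load_bundle(template_path: Union[str, Path]
                 ) -> tuple[Template, AcquisitionSettings, AcquisitionSettings]:
    template_path = Path(template_path)
    template = load_template(template_path)
    base = template_path.parent

    def resolve(ref: str) -> Path:
        p = Path(ref)
        return p if p.is_absolute() else base / p

    return (template,
            read_settings(resolve(template.first_scan_settings)),
            read_settings(resolve(template.second_scan_settings)))


def _load_slide(manifest: RunManifest) -> Optional[VirtualSlide]:
    if "slide_spec" not in manifest.artifacts:
        return None
    doc = json.loads(manifest.path("slide_spec").read_text(encoding="utf-8"))
    return generate_slide(spec_from_doc(doc))


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch_tiles(tiles: list[tuple[dict[str, np.ndarray], MosaicFrame]],
                 channels: list[str]) -> tuple[dict[str, np.ndarray], MosaicFrame]:
    """Stitch acquired tiles by nominal stage position, averaging overlaps."""
    if not tiles:
        raise ValueError("no tiles to stitch")
    ps = tiles[0][1].pixel_size
    for _, frame in tiles:
        if abs(frame.pixel_size - ps) > 1e-9 * ps or frame.y_axis_sign != 1:
            raise ValueError("all tiles must share pixel size and y-axis orientation")

    x_min = min(f.origin.x for _, f in tiles)
    y_min = min(f.origin.y for _, f in tiles)
    x_max = max(f.origin.x + img[channels[0]].shape[1] * ps for img, f in tiles)
    y_max = max(f.origin.y + img[channels[0]].shape[0] * ps for img, f in tiles)
    width = int(round((x_max - x_min) / ps))
    height = int(round((y_max - y_min) / ps))

    out = {ch: np.zeros((height, width), dtype=np.float64) for ch in channels}
    count = np.zeros((height, width), dtype=np.int32)
    for images, frame in tiles:
        h, w = images[channels[0]].shape
        c0 = int(round((frame.origin.x - x_min) / ps))
        r0 = int(round((frame.origin.y - y_min) / ps))
        for ch in channels:
            out[ch][r0:r0 + h, c0:c0 + w] += images[ch]
        count[r0:r0 + h, c0:c0 + w] += 1
    filled = np.maximum(count, 1)
    for ch in channels:
        out[ch] /= filled
    frame = MosaicFrame(origin=StagePoint(x_min, y_min), pixel_size=ps, y_axis_sign=1)
    return out, frame


def _write_mosaic(manifest: RunManifest, images: dict[str, np.ndarray],
                  frame: MosaicFrame, channels: list[str]) -> None:
    stack = np.stack([images[ch] for ch in channels]).astype(np.float32)
    tifffile.imwrite(manifest.out_dir / "mosaic.tif", stack, photometric="minisblack")
    h, w = stack.shape[1:]
    (manifest.out_dir / "mosaic_frame.json").write_text(canonical_dumps({
        "origin": [frame.origin.x, frame.origin.y],
        "pixel_size": frame.pixel_size,
        "y_axis_sign": frame.y_axis_sign,
        "channels": channels,
        "height": h, "width": w,
    }), encoding="utf-8")
    manifest.artifacts["mosaic"] = "mosaic.tif"
    manifest.artifacts["mosaic_frame"] = "mosaic_frame.json"


def _read_mosaic(manifest: RunManifest) -> tuple[dict[str, np.ndarray], MosaicFrame, list[str]]:
    doc = json.loads(manifest.path("mosaic_frame").read_text(encoding="utf-8"))
    stack = tifffile.imread(manifest.path("mosaic"))
    if stack.ndim == 2:
        stack = stack[None]
    channels = doc["channels"]
    images = {ch: stack[i].astype(np.float64) for i, ch in enumerate(channels)}
    frame = MosaicFrame(origin=StagePoint(*doc["origin"]), pixel_size=doc["pixel_size"],
                        y_axis_sign=doc["y_axis_sign"])
    return images, frame, channels


def _ingest_tile_dir(tile_dir: Path) -> tuple[list[tuple[dict, MosaicFrame]], list[str]]:
    """Load pre-acquired tiles: a manifest JSON naming TIFFs and stage origins."""
    doc = json.loads((tile_dir / "tiles.json").read_text(encoding="utf-8"))
    channels = doc["channels"]
    ps = float(doc["pixel_size"])
    missing = [t["id"] for t in doc["tiles"] if not (tile_dir / t["path"]).is_file()]
    if missing:
        raise WorkflowError(f"missing tiles: {', '.join(missing)}")
    tiles = []
    for t in doc["tiles"]:
        stack = tifffile.imread(tile_dir / t["path"])
        if stack.ndim == 2:
            stack = stack[None]
        images = {ch: stack[i].astype(np.float64) for i, ch in enumerate(channels)}
        frame = MosaicFrame(origin=StagePoint(*t["origin"]), pixel_size=ps, y_axis_sign=1)
        tiles.append((images, frame))
    return tiles, channels


# ---------------------------------------------------------------------------
# Step 1: first scan
# ---------------------------------------------------------------------------

def run_first_scan(template_path: Union[str, Path],
                   source: Union[VirtualSlide, SyntheticSampleSpec, str, Path],
                   out_dir: Union[str, Path],
                   seed: Optional[int] = None,
                   slot_id: Optional[str] = None,
                   run_id: Optional[str] = None) -> RunManifest:
    """Capture and stitch the low-resolution search mosaic over one sample slot.

    ``source`` is a virtual slide (or its spec, regenerated deterministically —
    ``seed`` overrides the spec's seed), or a directory of pre-acquired tiles
    with a ``tiles.json`` position manifest.
    """
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template, first_settings, _ = _load_bundle(template_path)

    manifest = RunManifest(out_dir=out_dir, run_id=run_id or uuid.uuid4().hex[:12],
                           template_path=str(template_path), seed=seed)

    slot = template.layout.slot_rect(slot_id) if slot_id \
        else template.layout.slot_rect(template.layout.slots[0][0])
    manifest.slot = [slot.x, slot.y, slot.w, slot.h]

    grid = plan_search_mosaic(slot, first_settings.fov, template.search_overlap)
    write_job(ScanJob(settings=first_settings, items=[("search", grid)],
                      sample_id=slot_id or template.layout.slots[0][0]),
              out_dir / "first_scan_job.json")
    manifest.artifacts["first_scan_job"] = "first_scan_job.json"

    if isinstance(source, (str, Path)) and Path(source).is_dir():
        tiles, channels = _ingest_tile_dir(Path(source))
    else:
        if isinstance(source, (str, Path)):
            spec = spec_from_doc(json.loads(Path(source).read_text(encoding="utf-8")))
            source = None if spec is None else generate_slide(
                replace(spec, seed=seed) if seed is not None else spec)
        elif isinstance(source, SyntheticSampleSpec):
            source = generate_slide(replace(source, seed=seed) if seed is not None else source)
        slide: VirtualSlide = source
        (out_dir / "slide_spec.json").write_text(canonical_dumps(spec_to_doc(slide.spec)),
                                                 encoding="utf-8")
        manifest.artifacts["slide_spec"] = "slide_spec.json"
        channels = first_settings.channel_names()
        tiles = []
        for r, c, _rect in grid.iter_tiles():
            images, frame = acquire(slide, first_settings, (grid, r, c),
                                    item_id=f"scan1_r{r}c{c}")
            tiles.append((images, frame))

    mosaic, frame = stitch_tiles(tiles, channels)
    _write_mosaic(manifest, mosaic, frame, channels)

    manifest.counts["search_tiles"] = len(tiles)
    manifest.status["first_scan"] = "done"
    manifest.timings["first_scan_s"] = round(time.perf_counter() - t0, 3)
    manifest.save()
    h, w = mosaic[channels[0]].shape
    log.info("first_scan: %d tiles stitched into %dx%d px mosaic", len(tiles), w, h)
    return manifest


# ---------------------------------------------------------------------------
# Step 2: analysis
# ---------------------------------------------------------------------------

def _detect(template: Template, images: dict, frame: MosaicFrame,
            macro: Optional[str], manifest: RunManifest) -> list[det.DetectedObject]:
    choice = macro or template.macro
    if choice == "tissue":
        return det.detect_tissue(images, frame, template.detection_params)
    if choice == "rare_event":
        return det.detect_rare_events(images, frame, template.detection_params,
                                      template.marker_rules)
    if choice.startswith("external:"):
        shape = next(iter(images.values())).shape
        records, rejected = det.run_external_macro(
            choice[len("external:"):], manifest.path("mosaic"), frame, shape)
        for line in rejected:
            log.warning("analysis: rejected %s", line)
        manifest.counts["rejected_records"] = len(rejected)
        return det.import_manual_selection(records, frame)
    if choice.startswith("manual:"):
        records = read_coordinates(choice[len("manual:"):])
        return det.import_manual_selection(records, frame)
    raise WorkflowError(f"unknown macro choice {choice!r}")


def run_analysis(manifest: RunManifest, macro: Optional[str] = None) -> RunManifest:
    """Run the image-analysis routine on the stitched mosaic, emit the coordinate CSV.

    ``macro`` overrides the template's choice: ``"tissue"``, ``"rare_event"``,
    ``"external:<command>"`` or ``"manual:<csv path>"``.
    """
    t0 = time.perf_counter()
    manifest._require_done("first_scan")
    template, _, _ = _load_bundle(manifest.template_path)
    images, frame, _channels = _read_mosaic(manifest)

    try:
        objects = _detect(template, images, frame, macro, manifest)
    except Exception:
        manifest.status["analysis"] = "failed"
        manifest.save()
        raise

    # label image: CSV row i <-> label value i + 1, so masks survive the
    # round trip through the run directory (and manual CSV edits)
    h, w = next(iter(images.values())).shape
    labels = np.zeros((h, w), dtype=np.uint32)
    for i, obj in enumerate(objects):
        if obj.mask is None:
            continue
        col0, row0 = det._frame_offset(frame, obj.mask_frame)
        mh, mw = obj.mask.shape
        r0, c0 = max(0, row0), max(0, col0)
        r1, c1 = min(h, row0 + mh), min(w, col0 + mw)
        sub = obj.mask[r0 - row0:r1 - row0, c0 - col0:c1 - col0]
        labels[r0:r1, c0:c1][sub] = i + 1
    tifffile.imwrite(manifest.out_dir / "labels.tif", labels)
    manifest.artifacts["labels"] = "labels.tif"

    write_coordinates(det.objects_to_records(objects), manifest.out_dir / "coordinates.csv")
    manifest.artifacts["coordinates"] = "coordinates.csv"
    manifest.counts["objects"] = len(objects)
    manifest.status["analysis"] = "done"
    manifest.timings["analysis_s"] = round(time.perf_counter() - t0, 3)
    manifest.save()
    log.info("analysis: %d objects of interest", len(objects))
    return manifest


# ---------------------------------------------------------------------------
# Step 3: second scan
# ---------------------------------------------------------------------------

def _rebuild_objects(manifest: RunManifest) -> list[det.DetectedObject]:
    """Reload detected objects from the coordinate CSV plus the label image."""
    records = read_coordinates(manifest.path("coordinates"))
    _, frame, _ = _read_mosaic(manifest)
    labels = tifffile.imread(manifest.path("labels")) if "labels" in manifest.artifacts \
        else None
    objects = []
    for i, rec in enumerate(records):
        mask_full = labels == i + 1 if labels is not None else None
        if mask_full is None or not mask_full.any():
            objects.extend(det.import_manual_selection([rec], frame))
            continue
        rows = np.any(mask_full, axis=1).nonzero()[0]
        cols = np.any(mask_full, axis=0).nonzero()[0]
        minr, maxr = int(rows[0]), int(rows[-1]) + 1
        minc, maxc = int(cols[0]), int(cols[-1]) + 1
        crop = mask_full[minr:maxr, minc:maxc]
        objects.append(det.DetectedObject(
            object_id=rec.object_id,
            centroid=StagePoint(rec.x, rec.y),
            bbox=det._bbox_to_stage(frame, minr, minc, maxr, maxc),
            label=rec.label, score=rec.score,
            area=float(crop.sum()) * frame.pixel_size ** 2,
            mask=crop, mask_frame=det._crop_frame(frame, minr, minc),
        ))
    return objects


def _shift_item(item, dx: float, dy: float):
    if isinstance(item, SingleField):
        return replace(item, center=StagePoint(item.center.x + dx, item.center.y + dy))
    return replace(item, origin=StagePoint(item.origin.x + dx, item.origin.y + dy),
                   enabled=item.enabled.copy())


def run_second_scan(manifest: RunManifest, noir: Optional[bool] = None) -> RunManifest:
    """Plan and acquire the high-resolution second scan of every detected object.

    Small objects become single fields centred on their centroids; large ones
    become tile grids, NoIR-pruned against their pixel masks when enabled.  The
    objective change applies the predefined paracentricity correction, and the
    generated job file plus the acquisition-savings fraction are recorded.
    """
    t0 = time.perf_counter()
    manifest._require_done("analysis")
    template, first_settings, second_settings = _load_bundle(manifest.template_path)
    use_noir = template.noir_enabled if noir is None else noir

    objects = _rebuild_objects(manifest)
    fov2 = second_settings.fov
    entries = []
    for obj in objects:
        item = plan_object_acquisition(obj, fov2, overlap=template.search_overlap,
                                       margin=template.acquisition_margin)
        if use_noir and isinstance(item, TileGrid) and obj.mask is not None:
            item = apply_noir(item, obj.mask, obj.mask_frame, margin=template.noir_margin)
        entries.append((obj.object_id, item))
    plan = SecondScanPlan(entries=entries, settings_id=second_settings.id,
                          fov_w=fov2[0], fov_h=fov2[1], overlap=template.search_overlap)

    slot = Rect(*manifest.slot)
    manifest.savings = estimate_savings(plan, slot)

    # paracentricity: coordinates were measured under the first-scan objective
    dx = second_settings.objective.paracentricity_dx - first_settings.objective.paracentricity_dx
    dy = second_settings.objective.paracentricity_dy - first_settings.objective.paracentricity_dy
    job_items = [(oid, _shift_item(item, dx, dy)) for oid, item in entries]
    job = ScanJob(settings=second_settings, items=job_items,
                  sample_id=template.layout.slots[0][0])
    write_job(job, manifest.out_dir / "second_scan_job.json")
    manifest.artifacts["second_scan_job"] = "second_scan_job.json"

    if not objects:
        warnings.warn("no objects of interest: second scan skipped", stacklevel=2)

    n_fields = 0
    slide = _load_slide(manifest)
    if slide is not None and objects:
        obj_dir = manifest.out_dir / "objects"
        obj_dir.mkdir(exist_ok=True)
        for oid, item in job_items:
            if isinstance(item, SingleField):
                captures = [(oid, item)]
            else:
                captures = [(f"{oid}_r{r}c{c}", (item, r, c))
                            for r, c, _ in item.iter_tiles()]
            for cap_id, cap in captures:
                images, _frame = acquire(slide, second_settings, cap, item_id=cap_id)
                stack = np.stack([images[ch] for ch in second_settings.channel_names()])
                tifffile.imwrite(obj_dir / f"{cap_id}.tif", stack.astype(np.float32),
                                 photometric="minisblack")
                n_fields += 1
        manifest.artifacts["objects_dir"] = "objects"

    manifest.counts["second_scan_fields"] = n_fields if slide is not None else plan.n_fields
    manifest.status["second_scan"] = "done"
    manifest.timings["second_scan_s"] = round(time.perf_counter() - t0, 3)
    manifest.save()
    log.info("second_scan: %d objects, %d fields, savings %.3f (NoIR %s)",
             len(objects), manifest.counts["second_scan_fields"],
             manifest.savings, "on" if use_noir else "off")
    return manifest


# ---------------------------------------------------------------------------
# "Play": the whole workflow in one click
# ---------------------------------------------------------------------------

def run_all(template_path: Union[str, Path],
            source: Union[VirtualSlide, SyntheticSampleSpec, str, Path],
            out_dir: Union[str, Path],
            seed: Optional[int] = None,
            noir: Optional[bool] = None,
            macro: Optional[str] = None,
            run_id: Optional[str] = None) -> RunManifest:
    """Run first scan, analysis and second scan back to back.

    Equivalent, artifact for artifact, to launching the three steps manually
    with the same inputs; a failure in any step halts the chain with the
    manifest recording the failed step.
    """
    manifest = run_first_scan(template_path, source, out_dir, seed=seed, run_id=run_id)
    manifest = run_analysis(manifest, macro=macro)
    manifest = run_second_scan(manifest, noir=noir)
    return manifest


# ---------------------------------------------------------------------------
# Demo experiment writer (used by the CLI and the examples)
# ---------------------------------------------------------------------------

def write_demo_experiment(out_dir: Union[str, Path], kind: str = "ctc",
                          seed: int = 0) -> tuple[Path, Path]:
    """Write a ready-to-run template, settings pair and slide spec for one scenario.

    Returns ``(template_path, slide_spec_path)``.  The two scenarios mirror the
    classic screening applications: ``"tma"`` (77 tissue pieces, detect and
    recapture each one) and ``"ctc"`` (10,000 cells, 0.25% rare events defined
    as DNA+, CK+, CD45-).
    """
    from .acquisition_io import SampleLayout, save_template, write_settings
    from .detection import DetectionParams, MarkerRule
    from .stage_geometry import ObjectiveProfile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSampleSpec(kind=kind, seed=seed)

    if kind == "tma":
        first = AcquisitionSettings(
            id="tma_search_5x",
            objective=ObjectiveProfile("5x", 5, 3000.0, 3000.0, 0.0, 0.0),
            image_width=300, image_height=300, channels=[("DAPI", 1.0)])
        second = AcquisitionSettings(
            id="tma_capture_20x",
            objective=ObjectiveProfile("20x", 20, 750.0, 750.0, 12.0, -9.0),
            image_width=512, image_height=512, channels=[("DAPI", 1.0)],
            z_stack=(5, 2.0))
        params = DetectionParams(channel="DAPI", threshold_mode="fixed",
                                 threshold_value=80.0, smoothing_sigma=1.0,
                                 min_area=5000.0)
        rules, macro = [], "tissue"
    elif kind == "ctc":
        first = AcquisitionSettings(
            id="ctc_search_10x",
            objective=ObjectiveProfile("10x", 10, 1500.0, 1500.0, 0.0, 0.0),
            image_width=750, image_height=750,
            channels=[("DNA", 1.0), ("CK", 1.0), ("CD45", 1.0)])
        second = AcquisitionSettings(
            id="ctc_capture_40x",
            objective=ObjectiveProfile("40x", 40, 375.0, 375.0, 5.0, 7.0),
            image_width=512, image_height=512,
            channels=[("DNA", 1.0), ("CK", 1.0), ("CD45", 1.0)],
            z_stack=(9, 0.5))
        params = DetectionParams(channel="DNA", threshold_mode="fixed",
                                 threshold_value=80.0, smoothing_sigma=1.0,
                                 min_area=20.0, max_area=2000.0)
        rules = [MarkerRule("CK", "positive", 50.0),
                 MarkerRule("CD45", "negative", 50.0)]
        macro = "rare_event"
    else:
        raise ValueError(f"unknown demo kind {kind!r}")

    write_settings(first, out_dir / "first_scan_settings.json")
    write_settings(second, out_dir / "second_scan_settings.json")
    layout = SampleLayout(slots=[("slot0", StagePoint(0.0, 0.0),
                                  spec.extent[0], spec.extent[1])])
    template = Template(
        first_scan_settings="first_scan_settings.json",
        second_scan_settings="second_scan_settings.json",
        detection_params=params, layout=layout, noir_enabled=True,
        noir_margin=0.0, macro=macro, marker_rules=rules,
        search_overlap=0.0, acquisition_margin=0.0)
    template_path = out_dir / "template.json"
    save_template(template, template_path)
    spec_path = out_dir / "slide_spec.json"
    spec_path.write_text(canonical_dumps(spec_to_doc(spec)), encoding="utf-8")
    return template_path, spec_path
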