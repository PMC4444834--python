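"""Built-in image-analysis macros: tissue pieces and rare multi-marker events.

Two detectors cover the common screening applications:

``detect_tissue``
    Finds bright connected regions in a single channel of the search mosaic —
    the tissue-microarray use case, where every piece of tissue on the slide
    must be located and re-captured at high resolution.  The pipeline is
    deliberately simple (the three knobs a user tunes are threshold, smoothing
    and a size filter): optional Gaussian smoothing, a global threshold (fixed
    value or Otsu), hole filling, a 1 px morphological closing, 8-connected
    component labelling, and an area filter in µm².

``detect_rare_events``
    The circulating-tumour-cell style assay: segment nuclei on the nuclear
    counterstain channel, then measure each candidate's mean intensity per
    marker channel on the nucleus mask dilated by 2 px (the dilation picks up
    the cytoplasmic rim, where cytokeratin lives), and keep only candidates
    satisfying every marker rule — e.g. CK-positive AND CD45-negative, which
    separates tumour cells from leukocytes.  Positive rules use ``mean >=
    threshold``; negative rules use strict ``mean < threshold``.

Any external image-analysis routine can stand in for the built-ins through the
macro contract: it receives the stitched mosaic TIFF and a frame JSON, and must
write the fixed-header coordinate CSV of :mod:`smartscan.acquisition_io`.
Objects can equally be picked by hand from the search mosaic
(:func:`import_manual_selection`).

Objects touching the mosaic border are kept (a rare event at the border must
not be lost) and flagged with ``border=True``.
"""

from __future__ import annotations

import math
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .acquisition_io import (
    CoordinateRecord,
    ValidationError,
    read_coordinates,
)
from .stage_geometry import MosaicFrame, StagePoint, pixel_to_stage

__all__ = [
    "DetectionParams",
    "MarkerRule",
    "DetectedObject",
    "ConfigurationError",
    "MacroContractError",
    "detect_tissue",
    "detect_rare_events",
    "run_external_macro",
    "import_manual_selection",
    "objects_to_records",
    "detection_params_to_doc",
    "detection_params_from_doc",
    "marker_rule_to_doc",
    "marker_rule_from_doc",
]


class ConfigurationError(ValueError):
    """Detection is configured against a channel the mosaic does not have."""


class MacroContractError(RuntimeError):
    """An external macro violated the contract (exit status, missing/invalid CSV)."""


@dataclass
class DetectionParams:
    """The user-facing segmentation knobs: threshold, smoothing, size filter."""

    channel: str = "ch0"
    threshold_mode: str = "otsu"          # "fixed" | "otsu"
    threshold_value: float = 0.0          # used when mode == "fixed"
    smoothing_sigma: float = 0.0          # Gaussian sigma, pixels; 0 disables
    min_area: float = 0.0                 # µm²
    max_area: Optional[float] = None      # µm²; None = unbounded

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "otsu"):
            raise ValidationError("threshold_mode",
                                  f"must be 'fixed' or 'otsu', got {self.threshold_mode!r}")
        if self.smoothing_sigma < 0:
            raise ValidationError("smoothing_sigma", f"must be >= 0, got {self.smoothing_sigma}")
        if self.min_area < 0:
            raise ValidationError("min_area", f"must be >= 0, got {self.min_area}")
        if self.max_area is not None and self.max_area < self.min_area:
            raise ValidationError("max_area",
                                  f"max_area {self.max_area} < min_area {self.min_area}")


@dataclass
class MarkerRule:
    """One marker-channel classification rule.

    ``polarity="positive"``: candidate mean over the (dilated) mask must be
    >= ``threshold``.  ``polarity="negative"``: mean must be strictly below it.
    """

    channel: str
    polarity: str          # "positive" | "negative"
    threshold: float

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValidationError("polarity",
                                  f"must be 'positive' or 'negative', got {self.polarity!r}")
        if self.threshold < 0:
            raise ValidationError("threshold", f"must be >= 0, got {self.threshold}")

    def accepts(self, mean: float) -> bool:
        return mean >= self.threshold if self.polarity == "positive" else mean < self.threshold


@dataclass
class DetectedObject:
    """One object of interest, located in stage space.

    ``bbox`` is (x, y, w, h) in µm (min corner plus size); ``mask`` is the
    object's binary pixel mask cropped to its bounding box, with ``mask_frame``
    mapping that crop back to stage coordinates (so NoIR pruning can reuse it).
    ``area`` is the mask area in µm².
    """

    object_id: str
    centroid: StagePoint
    bbox: tuple[float, float, float, float]
    label: str = ""
    score: float = 0.0
    area: float = 0.0
    channel_stats: dict[str, float] = field(default_factory=dict)
    mask: Optional[np.ndarray] = None
    mask_frame: Optional[MosaicFrame] = None
    border: bool = False

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w < 0 or h < 0:
            raise ValueError(f"bbox size must be >= 0, got {w}x{h}")
        tol = 1e-6 * max(1.0, abs(w), abs(h))
        if not (x - tol <= self.centroid.x <= x + w + tol
                and y - tol <= self.centroid.y <= y + h + tol):
            raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")


# ---------------------------------------------------------------------------
# Segmentation pipeline
# ---------------------------------------------------------------------------

def _select_channel(mosaic, channel: str) -> np.ndarray:
    if isinstance(mosaic, dict):
        if channel not in mosaic:
            raise ConfigurationError(
                f"channel {channel!r} not in mosaic (have {sorted(mosaic)})")
        return np.asarray(mosaic[channel], dtype=float)
    return np.asarray(mosaic, dtype=float)


def _segment(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Smoothing -> global threshold -> fill holes -> closing; returns bool mask."""
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    smoothed = image
    if params.smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(image, sigma=params.smoothing_sigma)
    if params.threshold_mode == "fixed":
        binary = smoothed >= params.threshold_value
    else:
        if smoothed.min() == smoothed.max():
            return np.zeros_like(smoothed, dtype=bool)
        binary = smoothed > filters.threshold_otsu(smoothed)
    if not binary.any():
        return binary
    binary = ndimage.binary_fill_holes(binary)
    binary = morphology.closing(binary, morphology.disk(1))
    return binary


def _bbox_to_stage(frame: MosaicFrame, minr: int, minc: int, maxr: int, maxc: int
                   ) -> tuple[float, float, float, float]:
    """Stage-space (x, y, w, h) of a half-open pixel bbox, using pixel squares."""
    ps = frame.pixel_size
    x0 = frame.origin.x + (minc - 0.5) * ps
    x1 = frame.origin.x + (maxc - 0.5) * ps
    ya = frame.origin.y + frame.y_axis_sign * (minr - 0.5) * ps
    yb = frame.origin.y + frame.y_axis_sign * (maxr - 0.5) * ps
    y0, y1 = min(ya, yb), max(ya, yb)
    return x0, y0, x1 - x0, y1 - y0


def _crop_frame(frame: MosaicFrame, minr: int, minc: int) -> MosaicFrame:
    return MosaicFrame(origin=pixel_to_stage(frame, minc, minr),
                       pixel_size=frame.pixel_size, y_axis_sign=frame.y_axis_sign)


def detect_tissue(mosaic, frame: MosaicFrame, params: DetectionParams,
                  label: str = "tissue") -> list[DetectedObject]:
    """Detect bright connected regions in one channel of the search mosaic.

    Returns objects sorted by descending mask area (ties broken by stage
    position), with centroids converted to stage µm.  An all-background image
    yields an empty list.
    """
    image = _select_channel(mosaic, params.channel)
    binary = _segment(image, params)
    if not binary.any():
        return []
    labels = measure.label(binary, connectivity=2)  # 8-connectivity
    ps2 = frame.pixel_size ** 2
    h, w = image.shape

    regions = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * ps2
        if area_um2 < params.min_area:
            continue
        if params.max_area is not None and area_um2 > params.max_area:
            continue
        regions.append((area_um2, region))
    regions.sort(key=lambda t: (-t[0], t[1].bbox))

    stats_channels = sorted(mosaic) if isinstance(mosaic, dict) else [params.channel]
    objects = []
    for i, (area_um2, region) in enumerate(regions):
        minr, minc, maxr, maxc = region.bbox
        crow, ccol = region.centroid
        crop = labels[minr:maxr, minc:maxc] == region.label
        stats = {}
        for ch in stats_channels:
            img = _select_channel(mosaic, ch)
            stats[ch] = float(img[minr:maxr, minc:maxc][crop].mean())
        objects.append(DetectedObject(
            object_id=f"obj_{i:04d}",
            centroid=pixel_to_stage(frame, ccol, crow),
            bbox=_bbox_to_stage(frame, minr, minc, maxr, maxc),
            label=label,
            score=float(area_um2),
            area=float(area_um2),
            channel_stats=stats,
            mask=crop,
            mask_frame=_crop_frame(frame, minr, minc),
            border=(minr == 0 or minc == 0 or maxr == h or maxc == w),
        ))
    return objects


def detect_rare_events(mosaic: dict[str, np.ndarray], frame: MosaicFrame,
                       nucleus: DetectionParams,
                       rules: Sequence[MarkerRule]) -> list[DetectedObject]:
    """Detect rare marker-defined events (e.g. CTCs: nucleated, CK+, CD45-).

    Nuclei are segmented on ``nucleus.channel`` with the standard pipeline;
    each candidate's mean intensity per marker channel is measured on its
    nucleus mask dilated by 2 px, and the candidate is an event iff every
    positive rule's mean is >= its threshold and every negative rule's mean is
    strictly below its threshold.  Only events are returned.
    """
    if not isinstance(mosaic, dict):
        raise ConfigurationError("rare-event detection needs a named multichannel mosaic")
    for rule in rules:
        if rule.channel not in mosaic:
            raise ConfigurationError(
                f"channel {rule.channel!r} not in mosaic (have {sorted(mosaic)})")
    candidates = detect_tissue(mosaic, frame, nucleus, label="nucleus")
    if not candidates:
        return []

    h, w = next(iter(mosaic.values())).shape
    ps = frame.pixel_size
    footprint = morphology.disk(2)
    events = []
    for obj in candidates:
        # pixel window of the nucleus crop, padded by 2 px for the dilation
        col0, row0 = _frame_offset(frame, obj.mask_frame)
        mh, mw = obj.mask.shape
        r0, c0 = max(0, row0 - 2), max(0, col0 - 2)
        r1, c1 = min(h, row0 + mh + 2), min(w, col0 + mw + 2)
        padded = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        padded[row0 - r0:row0 - r0 + mh, col0 - c0:col0 - c0 + mw] = obj.mask
        dilated = morphology.dilation(padded, footprint)

        means = dict(obj.channel_stats)
        margins = []
        is_event = True
        for rule in rules:
            img = np.asarray(mosaic[rule.channel], dtype=float)
            mean = float(img[r0:r1, c0:c1][dilated].mean())
            means[rule.channel] = mean
            if not rule.accepts(mean):
                is_event = False
            margins.append(mean - rule.threshold if rule.polarity == "positive"
                           else rule.threshold - mean)
        if not is_event:
            continue
        events.append(DetectedObject(
            object_id=f"event_{len(events):04d}",
            centroid=obj.centroid,
            bbox=obj.bbox,
            label="event",
            score=float(min(margins)) if margins else 0.0,
            area=obj.area,
            channel_stats=means,
            mask=obj.mask,
            mask_frame=obj.mask_frame,
            border=obj.border,
        ))
    return events


def _frame_offset(parent: MosaicFrame, crop: MosaicFrame) -> tuple[int, int]:
    """Integer pixel offset (col, row) of a crop frame inside its parent frame."""
    col = (crop.origin.x - parent.origin.x) / parent.pixel_size
    row = (crop.origin.y - parent.origin.y) / (parent.y_axis_sign * parent.pixel_size)
    return int(round(col)), int(round(row))


# ---------------------------------------------------------------------------
# External macros and manual selection
# ---------------------------------------------------------------------------

def mosaic_stage_bounds(frame: MosaicFrame, shape: tuple[int, int]
                        ) -> tuple[float, float, float, float]:
    """Stage-space (x0, x1, y0, y1) covered by a mosaic raster of ``shape``."""
    h, w = shape
    ps = frame.pixel_size
    x0 = frame.origin.x - ps / 2.0
    x1 = frame.origin.x + (w - 0.5) * ps
    ya = frame.origin.y - frame.y_axis_sign * ps / 2.0
    yb = frame.origin.y + frame.y_axis_sign * (h - 0.5) * ps
    return x0, x1, min(ya, yb), max(ya, yb)


def run_external_macro(command: Union[str, Sequence[str]], mosaic_path: Union[str, Path],
                       frame: MosaicFrame, shape: tuple[int, int],
                       out_csv: Union[str, Path, None] = None,
                       timeout: float = 300.0) -> tuple[list[CoordinateRecord], list[str]]:
    """Run an external image-analysis routine under the macro contract.

    The routine is invoked as ``command <mosaic_tiff> <frame_json> <out_csv>``
    and must exit 0 after writing the coordinate CSV.  Returned records are
    validated against the mosaic's stage bounds; out-of-bounds records are
    dropped and reported.  Returns ``(accepted_records, rejection_report)``.
    """
    import json

    mosaic_path = Path(mosaic_path)
    out_csv = Path(out_csv) if out_csv else mosaic_path.with_suffix(".macro_coords.csv")
    frame_json = mosaic_path.with_suffix(".frame.json")
    frame_json.write_text(json.dumps({
        "origin": [frame.origin.x, frame.origin.y],
        "pixel_size": frame.pixel_size,
        "y_axis_sign": frame.y_axis_sign,
        "height": shape[0], "width": shape[1],
    }, sort_keys=True), encoding="utf-8")

    argv = shlex.split(command) if isinstance(command, str) else list(command)
    argv += [str(mosaic_path), str(frame_json), str(out_csv)]
    try:
        proc = subprocess.run(argv, capture_output=True, text=True, timeout=timeout)
    except (OSError, subprocess.TimeoutExpired) as exc:
        raise MacroContractError(f"macro failed to run: {exc}") from exc
    if proc.returncode != 0:
        raise MacroContractError(
            f"macro exited with status {proc.returncode}; stderr: {proc.stderr[-2000:]}")
    if not out_csv.is_file():
        raise MacroContractError(f"macro did not write the coordinate CSV {out_csv}")
    try:
        records = read_coordinates(out_csv)
    except ValueError as exc:
        raise MacroContractError(f"macro wrote an invalid coordinate CSV: {exc}") from exc

    x0, x1, y0, y1 = mosaic_stage_bounds(frame, shape)
    accepted, report = [], []
    for rec in records:
        if x0 <= rec.x <= x1 and y0 <= rec.y <= y1:
            accepted.append(rec)
        else:
            report.append(f"record {rec.object_id!r} at ({rec.x}, {rec.y}) is outside "
                          f"the mosaic bounds x[{x0}, {x1}] y[{y0}, {y1}]")
    return accepted, report


def import_manual_selection(records: Sequence[CoordinateRecord],
                            frame: MosaicFrame) -> list[DetectedObject]:
    """Turn user-picked coordinates into detected objects with rectangular masks."""
    objects = []
    ps = frame.pixel_size
    for rec in records:
        w = max(rec.bbox_w, 0.0)
        h = max(rec.bbox_h, 0.0)
        bbox = (rec.x - w / 2.0, rec.y - h / 2.0, w, h)
        # rectangular pixel mask covering the bbox (>= 1 px)
        n_cols = max(1, int(math.ceil(w / ps)))
        n_rows = max(1, int(math.ceil(h / ps)))
        ccol, crow = _stage_to_pixel_idx(frame, rec.x, rec.y)
        col0 = ccol - (n_cols - 1) // 2
        row0 = crow - (n_rows - 1) // 2
        objects.append(DetectedObject(
            object_id=rec.object_id,
            centroid=StagePoint(rec.x, rec.y),
            bbox=bbox,
            label="manual",
            score=rec.score,
            area=w * h,
            mask=np.ones((n_rows, n_cols), dtype=bool),
            mask_frame=_crop_frame(frame, int(row0), int(col0)),
        ))
    return objects


def _stage_to_pixel_idx(frame: MosaicFrame, x: float, y: float) -> tuple[int, int]:
    col = (x - frame.origin.x) / frame.pixel_size
    row = (y - frame.origin.y) / (frame.y_axis_sign * frame.pixel_size)
    return int(round(col)), int(round(row))


def objects_to_records(objects: Sequence[DetectedObject]) -> list[CoordinateRecord]:
    """Export detected objects as coordinate-list records (the macro contract)."""
    return [CoordinateRecord(
        object_id=o.object_id, x=o.centroid.x, y=o.centroid.y,
        bbox_w=o.bbox[2], bbox_h=o.bbox[3], label=o.label, score=o.score,
    ) for o in objects]


# ---------------------------------------------------------------------------
# Serialization of detection parameters (used by templates)
# ---------------------------------------------------------------------------

def detection_params_to_doc(params: DetectionParams) -> dict:
    return {
        "channel": params.channel,
        "threshold_mode": params.threshold_mode,
        "threshold_value": float(params.threshold_value),
        "smoothing_sigma": float(params.smoothing_sigma),
        "min_area_um2": float(params.min_area),
        "max_area_um2": None if params.max_area is None else float(params.max_area),
    }


def detection_params_from_doc(doc: dict) -> DetectionParams:
    return DetectionParams(
        channel=doc.get("channel", "ch0"),
        threshold_mode=doc.get("threshold_mode", "otsu"),
        threshold_value=float(doc.get("threshold_value", 0.0)),
        smoothing_sigma=float(doc.get("smoothing_sigma", 0.0)),
        min_area=float(doc.get("min_area_um2", 0.0)),
        max_area=None if doc.get("max_area_um2") is None else float(doc["max_area_um2"]),
    )


def marker_rule_to_doc(rule: MarkerRule) -> dict:
    return {"channel": rule.channel, "polarity": rule.polarity,
            "threshold": float(rule.threshold)}


def marker_rule_from_doc(doc: dict) -> MarkerRule:
    return MarkerRule(channel=doc["channel"], polarity=doc["polarity"],
                      threshold=float(doc["threshold"]))
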