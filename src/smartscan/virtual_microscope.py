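"""Synthetic slides and a virtual microscope that renders them on demand.

This module stands in for the physical instrument so the whole screening
workflow can run (and be scored against ground truth) with no hardware.  A
:class:`VirtualSlide` is an *analytic* scene — each placed object contributes a
smooth intensity profile over stage space — rather than a stored raster, so any
field of view, objective or zoom can be rendered consistently: the second scan
genuinely sees more detail than the first, just as on a real stage.

Two scene kinds are built in:

``tma``
    A tissue-microarray slide: dozens of differently sized, differently bright
    tissue pieces (ellipses or lobed blobs) scattered without overlap on a
    single channel plus a nuclear counterstain naming convention.

``ctc``
    A rare-event cell field: ``n_cells`` nucleated cells on three channels
    (nuclear stain ``DNA``, cytokeratin ``CK``, leukocyte marker ``CD45``).
    Exactly ``round(n_cells * event_fraction)`` cells are tumour-like events
    (CK bright, CD45 dim); the rest are leukocyte-like (CK dim, CD45 bright).
    The default event fraction of 0.25% mirrors the spiked-sample designs used
    to validate rare-cell assays, where tumour cells occur at under 1 in 400.

Noise is additive Gaussian read noise on top of a flat background; the
signal-to-noise ratio of an object is ``(object amplitude) / noise_sd``.  The
per-field noise stream is seeded by ``(slide seed, item id, channel)``, so
re-acquiring the same field reproduces the same image bit for bit.

Objectives with a nonzero paracentricity offset image the region centred at
``commanded position - offset``; returned frames are expressed in *commanded*
stage coordinates, matching what a real stage reports.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .acquisition_io import AcquisitionSettings, ValidationError
from .scan_planner import Rect, SingleField, TileGrid
from .stage_geometry import MosaicFrame, StagePoint

__all__ = [
    "SyntheticSampleSpec",
    "PlacedObject",
    "VirtualSlide",
    "PlacementError",
    "OutOfBoundsError",
    "generate_slide",
    "acquire",
    "render_region",
    "spec_to_doc",
    "spec_from_doc",
]

CTC_CHANNELS = ("DNA", "CK", "CD45")
TMA_CHANNELS = ("DAPI",)


class PlacementError(RuntimeError):
    """The slide extent is too small to place all requested objects."""


class OutOfBoundsError(ValueError):
    """A requested field does not touch the slide extent at all."""


@dataclass
class SyntheticSampleSpec:
    """Everything needed to build a slide reproducibly from a seed.

    Sizes in µm, intensities in arbitrary camera units above ``background``.
    ``noise_sd`` is the Gaussian read-noise standard deviation; with the
    defaults the weakest signal of interest (a marker at amplitude 120) still
    has SNR >= 5 even at ``noise_sd`` up to 24.
    """

    kind: str = "ctc"                       # "tma" | "ctc"
    extent: Optional[tuple[float, float]] = None   # default: 4 mm² (ctc), 2 cm² (tma)
    seed: int = 0
    background: float = 20.0
    noise_sd: float = 8.0
    # --- tma ---
    n_pieces: int = 77
    piece_size_range: tuple[float, float] = (150.0, 900.0)   # diameters, µm
    piece_intensity_range: tuple[float, float] = (120.0, 220.0)
    shape_family: str = "blob"              # "ellipse" | "blob"
    # --- ctc ---
    n_cells: int = 10_000
    event_fraction: float = 0.0025
    nucleus_radius: float = 6.0             # µm, mean; +/-15% cell-to-cell
    nucleus_amp: tuple[float, float] = (150.0, 15.0)         # (mean, sd)
    ck_event_amp: tuple[float, float] = (120.0, 12.0)
    ck_other_amp: tuple[float, float] = (8.0, 3.0)
    cd45_event_amp: tuple[float, float] = (6.0, 3.0)
    cd45_other_amp: tuple[float, float] = (120.0, 12.0)
    min_cell_gap: float = 10.0              # µm between nucleus envelopes

    def __post_init__(self) -> None:
        if self.kind not in ("tma", "ctc"):
            raise ValidationError("kind", f"must be 'tma' or 'ctc', got {self.kind!r}")
        if self.extent is None:
            self.extent = (20000.0, 20000.0) if self.kind == "tma" else (4000.0, 4000.0)
        if not (0.0 <= self.event_fraction <= 1.0):
            raise ValidationError("event_fraction",
                                  f"must be in [0, 1], got {self.event_fraction}")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValidationError("extent", f"must be positive, got {self.extent}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", f"must be >= 0, got {self.noise_sd}")

    @property
    def channels(self) -> tuple[str, ...]:
        return TMA_CHANNELS if self.kind == "tma" else CTC_CHANNELS


@dataclass
class PlacedObject:
    """One ground-truth object: a smooth lobed-ellipse intensity profile.

    The boundary radius at polar angle phi (in the object's own frame) is
    ``r(phi) = base_radius * (1 + sum_k lobes[k] * cos((k+2) phi + phases[k]))``;
    an ellipse is the special case with no lobes and ``aspect != 1``.  The
    profile falls from 1 inside to 0 outside over ``edge_width`` µm.
    ``amplitudes`` maps channel name to peak intensity above background.
    """

    object_id: str
    kind: str                               # "tissue" | "event" | "leukocyte"
    center: StagePoint
    base_radius: float
    aspect: float
    angle: float
    lobes: tuple[float, ...]
    phases: tuple[float, ...]
    edge_width: float
    amplitudes: dict[str, float]

    @property
    def max_radius(self) -> float:
        return self.base_radius * max(1.0, self.aspect) * (1.0 + sum(abs(a) for a in self.lobes))

    def profile(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Evaluate the 0..1 shape profile at stage coords (broadcastable)."""
        dx = xs - self.center.x
        dy = ys - self.center.y
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        u = dx * ca + dy * sa
        v = (-dx * sa + dy * ca) / self.aspect
        r = np.hypot(u, v)
        boundary = np.full_like(r, self.base_radius)
        if self.lobes:
            phi = np.arctan2(v, u)
            for k, (amp, ph) in enumerate(zip(self.lobes, self.phases)):
                boundary = boundary + self.base_radius * amp * np.cos((k + 2) * phi + ph)
        # signed distance (µm, approx) outside the boundary, smoothed into [0, 1]
        t = (r - boundary) / self.edge_width
        return 1.0 / (1.0 + np.exp(np.clip(t, -60.0, 60.0)))

    def true_mask_predicate(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Boolean ground-truth membership (profile above half maximum)."""
        return self.profile(xs, ys) >= 0.5


@dataclass
class VirtualSlide:
    """A generated scene: spec, ground truth, and analytic per-channel intensity."""

    spec: SyntheticSampleSpec
    ground_truth: list[PlacedObject] = field(default_factory=list)

    @property
    def extent_rect(self) -> Rect:
        return Rect(0.0, 0.0, self.spec.extent[0], self.spec.extent[1])

    def events(self) -> list[PlacedObject]:
        return [o for o in self.ground_truth if o.kind == "event"]


# ---------------------------------------------------------------------------
# Slide generation
# ---------------------------------------------------------------------------

def _place_non_overlapping(rng: np.random.Generator, extent: tuple[float, float],
                           radii: Sequence[float], gap: float) -> list[tuple[float, float]]:
    """Rejection-sample centres so circles of the given radii never overlap.

    A uniform spatial hash keeps the pairwise test local; each object gets at
    most 1000 attempts before a :class:`PlacementError`.
    """
    w, h = extent
    max_r = max(radii)
    cell = max(2 * max_r + gap, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    centers: list[tuple[float, float]] = []

    for i, r in enumerate(radii):
        if 2 * r >= min(w, h):
            raise PlacementError(f"object {i} (radius {r} µm) larger than the slide extent")
        for _ in range(1000):
            x = rng.uniform(r, w - r)
            y = rng.uniform(r, h - r)
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for nx in (gx - 1, gx, gx + 1):
                for ny in (gy - 1, gy, gy + 1):
                    for j in grid.get((nx, ny), ()):
                        cx, cy = centers[j]
                        if math.hypot(x - cx, y - cy) < r + radii[j] + gap:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                centers.append((x, y))
                grid.setdefault((gx, gy), []).append(i)
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{len(radii)} after 1000 attempts; "
                f"extent {w}x{h} µm is too crowded")
    return centers


def _sample_amp(rng: np.random.Generator, mean_sd: tuple[float, float]) -> float:
    mean, sd = mean_sd
    return float(max(0.0, rng.normal(mean, sd)))


def generate_slide(spec: SyntheticSampleSpec) -> VirtualSlide:
    """Build the ground-truth scene for a spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    objects: list[PlacedObject] = []

    if spec.kind == "tma":
        lo, hi = spec.piece_size_range
        diameters = rng.uniform(lo, hi, size=spec.n_pieces)
        aspects = rng.uniform(1.0, 1.6, size=spec.n_pieces)
        angles = rng.uniform(0.0, math.pi, size=spec.n_pieces)
        amps = rng.uniform(*spec.piece_intensity_range, size=spec.n_pieces)
        n_lobes = 3 if spec.shape_family == "blob" else 0
        lobes = rng.uniform(0.02, 0.10, size=(spec.n_pieces, n_lobes))
        phases = rng.uniform(0.0, 2 * math.pi, size=(spec.n_pieces, n_lobes))
        base_radii = diameters / 2.0 / np.maximum(1.0, aspects)
        env = base_radii * np.maximum(1.0, aspects) * (1.0 + lobes.sum(axis=1)) if n_lobes \
            else base_radii * np.maximum(1.0, aspects)
        # generous spacing so the pieces read as distinct cores
        centers = _place_non_overlapping(rng, spec.extent, list(env), gap=150.0)
        for i in range(spec.n_pieces):
            objects.append(PlacedObject(
                object_id=f"piece_{i:03d}", kind="tissue",
                center=StagePoint(*centers[i]),
                base_radius=float(base_radii[i]), aspect=float(aspects[i]),
                angle=float(angles[i]),
                lobes=tuple(float(a) for a in lobes[i]),
                phases=tuple(float(p) for p in phases[i]),
                edge_width=5.0,
                amplitudes={"DAPI": float(amps[i])},
            ))
    else:
        n_events = int(round(spec.n_cells * spec.event_fraction))
        radii = spec.nucleus_radius * rng.uniform(0.85, 1.15, size=spec.n_cells)
        centers = _place_non_overlapping(rng, spec.extent, list(radii),
                                         gap=spec.min_cell_gap)
        # which cells are events is itself randomized, then counts are exact
        event_idx = set(rng.choice(spec.n_cells, size=n_events, replace=False).tolist()) \
            if n_events else set()
        for i in range(spec.n_cells):
            is_event = i in event_idx
            kind = "event" if is_event else "leukocyte"
            objects.append(PlacedObject(
                object_id=f"cell_{i:05d}", kind=kind,
                center=StagePoint(*centers[i]),
                base_radius=float(radii[i]), aspect=1.0, angle=0.0,
                lobes=(), phases=(), edge_width=1.5,
                amplitudes={
                    "DNA": _sample_amp(rng, spec.nucleus_amp),
                    "CK": _sample_amp(rng, spec.ck_event_amp if is_event
                                      else spec.ck_other_amp),
                    "CD45": _sample_amp(rng, spec.cd45_event_amp if is_event
                                        else spec.cd45_other_amp),
                },
            ))
    return VirtualSlide(spec=spec, ground_truth=objects)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_region(slide: VirtualSlide, channel: str, region: Rect,
                  shape: tuple[int, int]) -> np.ndarray:
    """Sample the analytic intensity of one channel over a stage-space region.

    Pixel (0, 0) is the top-left; its centre sits at
    ``(region.x + ps/2, region.y + ps/2)`` and row index increases with stage Y
    (the virtual camera's convention).  Noise-free.
    """
    if channel not in slide.spec.channels:
        raise ValidationError("channel", f"slide has channels {slide.spec.channels}, "
                                         f"got {channel!r}")
    h, w = shape
    ps_x = region.w / w
    ps_y = region.h / h
    xs = region.x + (np.arange(w) + 0.5) * ps_x
    ys = region.y + (np.arange(h) + 0.5) * ps_y
    out = np.full((h, w), slide.spec.background, dtype=np.float64)
    for obj in slide.ground_truth:
        amp = obj.amplitudes.get(channel, 0.0)
        if amp == 0.0:
            continue
        # window where the profile is non-negligible (tail < ~1e-6 of amp)
        reach = obj.max_radius + 14.0 * obj.edge_width
        c0 = np.searchsorted(xs, obj.center.x - reach)
        c1 = np.searchsorted(xs, obj.center.x + reach)
        r0 = np.searchsorted(ys, obj.center.y - reach)
        r1 = np.searchsorted(ys, obj.center.y + reach)
        if c0 >= c1 or r0 >= r1:
            continue
        out[r0:r1, c0:c1] += amp * obj.profile(xs[None, c0:c1], ys[r0:r1, None])
    return out


def _noise_rng(slide: VirtualSlide, item_id: str, channel: str) -> np.random.Generator:
    tag = zlib.crc32(f"{item_id}|{channel}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([slide.spec.seed & 0x7FFFFFFF, tag]))


def _item_rect(item, settings: AcquisitionSettings) -> Rect:
    if isinstance(item, SingleField):
        return item.rect()
    if isinstance(item, Rect):
        return item
    if isinstance(item, tuple) and len(item) == 3 and isinstance(item[0], TileGrid):
        grid, r, c = item
        return grid.tile_rect(r, c)
    raise TypeError(f"cannot acquire item of type {type(item).__name__}")


def acquire(slide: VirtualSlide, settings: AcquisitionSettings, item,
            item_id: str = "field") -> tuple[dict[str, np.ndarray], MosaicFrame]:
    """Simulate capturing one field: render, add read noise, return image + frame.

    ``item`` is a :class:`~smartscan.scan_planner.SingleField`, a
    :class:`~smartscan.scan_planner.Rect`, or a ``(TileGrid, row, col)`` tile,
    positioned in *commanded* stage coordinates.  The objective's
    paracentricity offset displaces the imaged scene region
    (scene = commanded - offset); the returned frame is in commanded
    coordinates.  Z-stack and time-lapse settings are carried in the plan but a
    single 2-D plane is rendered.

    Noise is seeded by ``(slide seed, item_id, channel)`` so re-acquisition is
    reproducible.  Raises :class:`OutOfBoundsError` if the imaged region does
    not intersect the slide extent.
    """
    rect = _item_rect(item, settings)
    fov_w, fov_h = settings.fov
    ps_x = fov_w / settings.image_width
    ps_y = fov_h / settings.image_height
    if abs(ps_x - ps_y) > 1e-9 * max(ps_x, ps_y):
        raise ValidationError("image_width",
                              f"anisotropic pixels ({ps_x} x {ps_y} µm) are not supported")
    if abs(rect.w - fov_w) > 1e-6 * fov_w or abs(rect.h - fov_h) > 1e-6 * fov_h:
        raise ValidationError("items", f"item size {rect.w}x{rect.h} µm does not match the "
                                       f"effective FOV {fov_w}x{fov_h} µm")

    dx = settings.objective.paracentricity_dx
    dy = settings.objective.paracentricity_dy
    scene = Rect(rect.x - dx, rect.y - dy, rect.w, rect.h)
    ext = slide.extent_rect
    if scene.x1 < ext.x or scene.x > ext.x1 or scene.y1 < ext.y or scene.y > ext.y1:
        raise OutOfBoundsError(f"field at ({rect.x}, {rect.y}) images region outside the "
                               f"slide extent {slide.spec.extent}")

    shape = (settings.image_height, settings.image_width)
    images = {}
    for name, exposure in settings.channels:
        img = render_region(slide, name, scene, shape)
        if slide.spec.noise_sd > 0:
            rng = _noise_rng(slide, item_id, name)
            img = img + rng.normal(0.0, slide.spec.noise_sd, size=shape)
        images[name] = img * exposure
    frame = MosaicFrame(origin=StagePoint(rect.x + ps_x / 2.0, rect.y + ps_y / 2.0),
                        pixel_size=ps_x, y_axis_sign=1)
    return images, frame


# ---------------------------------------------------------------------------
# Spec (de)serialization — slides persist as their spec and regenerate on load
# ---------------------------------------------------------------------------

def spec_to_doc(spec: SyntheticSampleSpec) -> dict:
    return {
        "schema_version": 1,
        "kind_doc": "synthetic_sample_spec",
        "kind": spec.kind,
        "extent": list(spec.extent),
        "seed": spec.seed,
        "background": spec.background,
        "noise_sd": spec.noise_sd,
        "n_pieces": spec.n_pieces,
        "piece_size_range": list(spec.piece_size_range),
        "piece_intensity_range": list(spec.piece_intensity_range),
        "shape_family": spec.shape_family,
        "n_cells": spec.n_cells,
        "event_fraction": spec.event_fraction,
        "nucleus_radius": spec.nucleus_radius,
        "nucleus_amp": list(spec.nucleus_amp),
        "ck_event_amp": list(spec.ck_event_amp),
        "ck_other_amp": list(spec.ck_other_amp),
        "cd45_event_amp": list(spec.cd45_event_amp),
        "cd45_other_amp": list(spec.cd45_other_amp),
        "min_cell_gap": spec.min_cell_gap,
    }


def spec_from_doc(doc: dict) -> SyntheticSampleSpec:
    def pair(key):
        a, b = doc[key]
        return float(a), float(b)

    return SyntheticSampleSpec(
        kind=doc["kind"],
        extent=pair("extent"),
        seed=int(doc["seed"]),
        background=float(doc["background"]),
        noise_sd=float(doc["noise_sd"]),
        n_pieces=int(doc["n_pieces"]),
        piece_size_range=pair("piece_size_range"),
        piece_intensity_range=pair("piece_intensity_range"),
        shape_family=doc["shape_family"],
        n_cells=int(doc["n_cells"]),
        event_fraction=float(doc["event_fraction"]),
        nucleus_radius=float(doc["nucleus_radius"]),
        nucleus_amp=pair("nucleus_amp"),
        ck_event_amp=pair("ck_event_amp"),
        ck_other_amp=pair("ck_other_amp"),
        cd45_event_amp=pair("cd45_event_amp"),
        cd45_other_amp=pair("cd45_other_amp"),
        min_cell_gap=float(doc["min_cell_gap"]),
    )
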