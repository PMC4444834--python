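"""Tile-grid planning: search mosaic, per-object second-scan plans, NoIR pruning.

The first (search) scan is a grid of juxtaposed low-resolution fields covering
the whole sample.  After detection, each object of interest gets its own
second-scan plan: an object whose padded bounding box fits inside one
high-resolution field of view becomes a :class:`SingleField` centred on its
centroid; a larger object is covered by a :class:`TileGrid` of high-resolution
fields.  The NoIR step ("non-informative regions") then disables every grid
tile that does not touch the object's pixel mask (optionally dilated by a
margin), so irregular objects are acquired without wasting fields on empty
corners.

Geometry conventions
--------------------
* Tiles are axis-aligned closed rectangles in stage space (µm); a mask pixel
  occupies the closed square of side ``pixel_size`` centred on its pixel
  centre.  Grazing contact counts as intersection — the pruning is
  conservative and never drops an object pixel.
* Grid step is ``tile_size * (1 - overlap)``.  The first tile is centred at
  ``bounds.min + fov/2``; the last row/column is shifted inward so the grid
  never overhangs the bounds by more than half a field.
* Tiles are acquired in row-major serpentine order (row 0 left-to-right,
  row 1 right-to-left, ...), which keeps simulated stage travel short and the
  downstream stitch deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Sequence, Union

import numpy as np

from .stage_geometry import MosaicFrame, StagePoint

__all__ = [
    "Rect",
    "TileGrid",
    "SingleField",
    "SecondScanPlan",
    "plan_search_mosaic",
    "plan_object_acquisition",
    "apply_noir",
    "merge_nearby_objects",
    "estimate_savings",
    "EmptyMaskWarning",
]

_EPS = 1e-9  # µm-scale float guard for ceil/tie arithmetic


class EmptyMaskWarning(UserWarning):
    """Signalled when NoIR pruning receives a mask with no object pixels."""


class Rect(NamedTuple):
    """Axis-aligned stage-space rectangle: min corner plus size, in µm."""

    x: float
    y: float
    w: float
    h: float

    @property
    def x1(self) -> float:
        return self.x + self.w

    @property
    def y1(self) -> float:
        return self.y + self.h

    @property
    def center(self) -> StagePoint:
        return StagePoint(self.x + self.w / 2.0, self.y + self.h / 2.0)


@dataclass
class SingleField:
    """One high-resolution field: a single acquisition centred on an object."""

    center: StagePoint
    width: float
    height: float

    def rect(self) -> Rect:
        return Rect(self.center.x - self.width / 2.0, self.center.y - self.height / 2.0,
                    self.width, self.height)


@dataclass
class TileGrid:
    """Overlap-aware field grid with a per-tile enabled mask.

    ``origin`` is the stage position of the *centre* of tile (row 0, col 0).
    ``last_col_shift``/``last_row_shift`` (µm, <= 0) move the centres of the
    last column/row inward so the grid hugs the planned bounds; all other
    tiles sit on the regular ``step = tile_size * (1 - overlap)`` lattice.
    """

    origin: StagePoint
    rows: int
    cols: int
    tile_w: float
    tile_h: float
    overlap: float
    enabled: np.ndarray = field(default=None)  # (rows, cols) bool
    last_col_shift: float = 0.0
    last_row_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"grid must have >= 1 row and column, got {self.rows}x{self.cols}")
        if not (0.0 <= self.overlap <= 0.9):
            raise ValueError(f"overlap must be in [0, 0.9], got {self.overlap}")
        if self.tile_w <= 0 or self.tile_h <= 0:
            raise ValueError(f"tile size must be positive, got {self.tile_w}x{self.tile_h}")
        if self.enabled is None:
            self.enabled = np.ones((self.rows, self.cols), dtype=bool)
        else:
            self.enabled = np.asarray(self.enabled, dtype=bool)
            if self.enabled.shape != (self.rows, self.cols):
                raise ValueError(
                    f"enabled mask shape {self.enabled.shape} != grid {self.rows}x{self.cols}"
                )

    @property
    def step_w(self) -> float:
        return self.tile_w * (1.0 - self.overlap)

    @property
    def step_h(self) -> float:
        return self.tile_h * (1.0 - self.overlap)

    @property
    def n_enabled(self) -> int:
        return int(self.enabled.sum())

    def tile_center(self, row: int, col: int) -> StagePoint:
        x = self.origin.x + col * self.step_w
        y = self.origin.y + row * self.step_h
        if col == self.cols - 1:
            x += self.last_col_shift
        if row == self.rows - 1:
            y += self.last_row_shift
        return StagePoint(x, y)

    def tile_rect(self, row: int, col: int) -> Rect:
        c = self.tile_center(row, col)
        return Rect(c.x - self.tile_w / 2.0, c.y - self.tile_h / 2.0, self.tile_w, self.tile_h)

    def extent(self) -> Rect:
        """Bounding rectangle of the union of all tiles (enabled or not)."""
        first = self.tile_rect(0, 0)
        last = self.tile_rect(self.rows - 1, self.cols - 1)
        return Rect(first.x, first.y, last.x1 - first.x, last.y1 - first.y)

    def iter_tiles(self, enabled_only: bool = True) -> Iterator[tuple[int, int, Rect]]:
        """Yield (row, col, rect) in row-major serpentine acquisition order."""
        for r in range(self.rows):
            cols = range(self.cols) if r % 2 == 0 else range(self.cols - 1, -1, -1)
            for c in cols:
                if enabled_only and not self.enabled[r, c]:
                    continue
                yield r, c, self.tile_rect(r, c)


PlanItem = Union[SingleField, TileGrid]


@dataclass
class SecondScanPlan:
    """Per-object acquisition plan for the high-resolution second scan.

    ``entries`` maps each detected object id to the item that re-acquires it.
    ``fov_w``/``fov_h``/``overlap`` record the effective second-scan field of
    view and overlap the plan was built with, so savings against a baseline
    full mosaic can be recomputed from the plan alone.
    """

    entries: list[tuple[str, PlanItem]]
    settings_id: str
    fov_w: float
    fov_h: float
    overlap: float = 0.0

    @property
    def n_fields(self) -> int:
        n = 0
        for _, item in self.entries:
            n += 1 if isinstance(item, SingleField) else item.n_enabled
        return n


# ---------------------------------------------------------------------------
# Grid construction
# ---------------------------------------------------------------------------

def _axis_layout(length: float, fov: float, step: float, lo: float) -> tuple[int, float, float]:
    """Tile count, first-tile centre and last-tile inward shift along one axis."""
    if length <= fov + _EPS:
        return 1, lo + length / 2.0, 0.0
    n = int(math.ceil((length - fov) / step - _EPS)) + 1
    first = lo + fov / 2.0
    nominal_last = first + (n - 1) * step
    clamped_last = lo + length - fov / 2.0
    shift = min(0.0, clamped_last - nominal_last)
    return n, first, shift


def plan_search_mosaic(bounds: Rect, fov: tuple[float, float], overlap: float) -> TileGrid:
    """Lay out the first-scan search mosaic: juxtaposed fields covering ``bounds``.

    ``cols = ceil((bounds.w - fov_w) / step_w) + 1`` (1 if the bounds fit in a
    single field), rows analogous; every point of ``bounds`` is covered by at
    least one tile, and all tiles start enabled.
    """
    fov_w, fov_h = fov
    if fov_w <= 0 or fov_h <= 0:
        raise ValueError(f"field of view must be positive, got {fov_w}x{fov_h}")
    if bounds.w <= 0 or bounds.h <= 0:
        raise ValueError(f"bounds must have positive size, got {bounds.w}x{bounds.h}")
    if not (0.0 <= overlap <= 0.9):
        raise ValueError(f"overlap must be in [0, 0.9], got {overlap}")

    step_w = fov_w * (1.0 - overlap)
    step_h = fov_h * (1.0 - overlap)
    cols, cx0, col_shift = _axis_layout(bounds.w, fov_w, step_w, bounds.x)
    rows, cy0, row_shift = _axis_layout(bounds.h, fov_h, step_h, bounds.y)
    return TileGrid(
        origin=StagePoint(cx0, cy0),
        rows=rows,
        cols=cols,
        tile_w=fov_w,
        tile_h=fov_h,
        overlap=overlap,
        last_col_shift=col_shift,
        last_row_shift=row_shift,
    )


def plan_object_acquisition(obj, fov2: tuple[float, float], overlap: float = 0.0,
                            margin: float = 0.0) -> PlanItem:
    """Choose the second-scan plan for one detected object.

    If the object's bounding box padded by ``margin`` on every side fits within
    the second-scan field of view in both axes, the object is captured as one
    :class:`SingleField` centred on its centroid (a padded box exactly equal to
    the field resolves to the cheaper single field).  Otherwise a fully enabled
    :class:`TileGrid` covering the padded box is returned, laid out exactly as
    :func:`plan_search_mosaic` would.

    ``obj`` needs ``centroid`` (:class:`~smartscan.stage_geometry.StagePoint`)
    and ``bbox`` (x, y, w, h in µm) attributes.
    """
    fov_w, fov_h = fov2
    if fov_w <= 0 or fov_h <= 0:
        raise ValueError(f"field of view must be positive, got {fov_w}x{fov_h}")
    bx, by, bw, bh = obj.bbox
    padded = Rect(bx - margin, by - margin, bw + 2.0 * margin, bh + 2.0 * margin)
    # fit is judged around the centroid (the field is centred there), so a
    # single field always covers the whole padded box it replaces
    need_w = 2.0 * max(obj.centroid.x - padded.x, padded.x1 - obj.centroid.x)
    need_h = 2.0 * max(obj.centroid.y - padded.y, padded.y1 - obj.centroid.y)
    if need_w <= fov_w + _EPS and need_h <= fov_h + _EPS:
        return SingleField(center=obj.centroid, width=fov_w, height=fov_h)
    return plan_search_mosaic(padded, fov2, overlap)


# ---------------------------------------------------------------------------
# NoIR pruning
# ---------------------------------------------------------------------------

def _mask_pixel_bounds(frame: MosaicFrame, mask_shape: tuple[int, int]) -> tuple[float, float, float, float]:
    """Stage-space bounding box (x0, x1, y0, y1) of the whole mask raster."""
    ps = frame.pixel_size
    n_rows, n_cols = mask_shape
    x0 = frame.origin.x - ps / 2.0
    x1 = frame.origin.x + (n_cols - 0.5) * ps
    ya = frame.origin.y - frame.y_axis_sign * ps / 2.0
    yb = frame.origin.y + frame.y_axis_sign * (n_rows - 0.5) * ps
    return x0, x1, min(ya, yb), max(ya, yb)


def apply_noir(grid: TileGrid, mask: np.ndarray, frame: MosaicFrame,
               margin: float = 0.0) -> TileGrid:
    """Disable every grid tile that does not touch the object mask.

    A tile stays enabled iff it was enabled in the input grid *and* its closed
    stage-space rectangle lies within ``margin`` µm (Euclidean) of the union of
    the mask's pixel squares — i.e. it intersects the mask dilated by
    ``margin``.  The result's enabled set is therefore always a subset of the
    input's.  An empty mask disables every tile and signals
    :class:`EmptyMaskWarning`.
    """
    mask = np.asarray(mask, dtype=bool)
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    new_enabled = np.zeros_like(grid.enabled)
    if not mask.any():
        warnings.warn("NoIR mask contains no object pixels; all tiles disabled",
                      EmptyMaskWarning, stacklevel=2)
        return replace(grid, enabled=new_enabled)

    ps = frame.pixel_size
    sign = frame.y_axis_sign
    ox, oy = frame.origin.x, frame.origin.y
    m2 = margin * margin
    n_rows, n_cols = mask.shape

    def col_window(x_lo: float, x_hi: float) -> tuple[int, int]:
        # columns whose pixel square can lie within `margin` of [x_lo, x_hi]
        c0 = int(math.floor((x_lo - margin - ox) / ps - 0.5)) - 1
        c1 = int(math.ceil((x_hi + margin - ox) / ps + 0.5)) + 2
        return max(0, c0), min(n_cols, c1)

    def row_window(y_lo: float, y_hi: float) -> tuple[int, int]:
        # row centre stage y = oy + sign*r*ps; invert for both bounds
        r_at_lo = (y_lo - margin - oy) / (sign * ps)
        r_at_hi = (y_hi + margin - oy) / (sign * ps)
        lo, hi = sorted((r_at_lo, r_at_hi))
        r0 = int(math.floor(lo - 0.5)) - 1
        r1 = int(math.ceil(hi + 0.5)) + 2
        return max(0, r0), min(n_rows, r1)

    for r in range(grid.rows):
        for c in range(grid.cols):
            if not grid.enabled[r, c]:
                continue
            t = grid.tile_rect(r, c)
            c0, c1 = col_window(t.x, t.x1)
            r0, r1 = row_window(t.y, t.y1)
            if c0 >= c1 or r0 >= r1:
                continue
            sub_rows, sub_cols = np.nonzero(mask[r0:r1, c0:c1])
            if sub_rows.size == 0:
                continue
            nz_rows = sub_rows + r0
            nz_cols = sub_cols + c0
            # stage-space edges of each candidate pixel square (centre +/- ps/2)
            px_lo = ox + (nz_cols - 0.5) * ps
            px_hi = ox + (nz_cols + 0.5) * ps
            py_a = oy + sign * (nz_rows - 0.5) * ps
            py_b = oy + sign * (nz_rows + 0.5) * ps
            py_lo = np.minimum(py_a, py_b)
            py_hi = np.maximum(py_a, py_b)
            dx = np.maximum(0.0, np.maximum(t.x - px_hi, px_lo - t.x1))
            dy = np.maximum(0.0, np.maximum(t.y - py_hi, py_lo - t.y1))
            if margin == 0.0:
                hit = bool(np.any((dx == 0.0) & (dy == 0.0)))
            else:
                hit = bool(np.any(dx * dx + dy * dy <= m2))
            new_enabled[r, c] = hit
    return replace(grid, enabled=new_enabled)


# ---------------------------------------------------------------------------
# Object merging and savings accounting
# ---------------------------------------------------------------------------

def _rect_gap(a: tuple[float, float, float, float],
              b: tuple[float, float, float, float]) -> float:
    """Euclidean distance between two (x, y, w, h) boxes; 0 if they touch."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    dx = max(0.0, max(bx - (ax + aw), ax - (bx + bw)))
    dy = max(0.0, max(by - (ay + ah), ay - (by + bh)))
    return math.hypot(dx, dy)


def merge_nearby_objects(records: Sequence, min_separation: float) -> list:
    """Merge detected objects whose bounding boxes lie within ``min_separation``.

    Groups are formed by the transitive closure of the pairwise "boxes within
    ``min_separation`` µm" relation, and merging is repeated on the merged
    boxes until nothing changes, so the operation is idempotent.  A merged
    object takes the union bounding box, the area-weighted centroid of its
    members, a combined id, and the maximum score.

    Prevents overlapping second-scan plans for objects that would be acquired
    together anyway.
    """
    from .detection import DetectedObject  # runtime import: avoids a module cycle

    objs = list(records)
    while True:
        n = len(objs)
        if n <= 1:
            return objs
        # union-find over the pairwise proximity relation
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _rect_gap(objs[i].bbox, objs[j].bbox) <= min_separation:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        groups: dict[int, list] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(objs[i])
        if len(groups) == n:
            return objs
        merged = []
        for members in groups.values():
            if len(members) == 1:
                merged.append(members[0])
                continue
            members = sorted(members, key=lambda o: o.object_id)
            x0 = min(o.bbox[0] for o in members)
            y0 = min(o.bbox[1] for o in members)
            x1 = max(o.bbox[0] + o.bbox[2] for o in members)
            y1 = max(o.bbox[1] + o.bbox[3] for o in members)
            areas = np.array([max(o.area, _EPS) for o in members])
            cx = float(np.average([o.centroid.x for o in members], weights=areas))
            cy = float(np.average([o.centroid.y for o in members], weights=areas))
            merged.append(DetectedObject(
                object_id="+".join(o.object_id for o in members),
                centroid=StagePoint(cx, cy),
                bbox=(x0, y0, x1 - x0, y1 - y0),
                label=members[0].label,
                score=max(o.score for o in members),
                area=float(areas.sum()),
            ))
        objs = merged


def estimate_savings(plan: SecondScanPlan, baseline_bounds: Rect) -> float:
    """Fraction of fields skipped relative to a full mosaic over the baseline.

    ``1 - (enabled fields in plan) / (fields of a full mosaic over
    baseline_bounds at the plan's FOV and overlap)``, clipped to [0, 1].  This
    is the efficiency gain of object-directed acquisition over blanket
    mosaicking of the whole sample.
    """
    baseline = plan_search_mosaic(baseline_bounds, (plan.fov_w, plan.fov_h), plan.overlap)
    total = baseline.rows * baseline.cols
    return float(min(1.0, max(0.0, 1.0 - plan.n_fields / total)))
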