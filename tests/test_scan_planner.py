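"""Grid planning, NoIR pruning (vs a rasterized oracle), merging, savings."""

import math

import numpy as np
import pytest

from smartscan.detection import DetectedObject
from smartscan.scan_planner import (
    EmptyMaskWarning,
    Rect,
    SecondScanPlan,
    SingleField,
    TileGrid,
    apply_noir,
    estimate_savings,
    merge_nearby_objects,
    plan_object_acquisition,
    plan_search_mosaic,
)
from smartscan.stage_geometry import MosaicFrame, StagePoint


# ---------------------------------------------------------------------------
# Search-mosaic layout
# ---------------------------------------------------------------------------

class TestPlanSearchMosaic:
    @pytest.mark.parametrize("bounds,fov,overlap,expect", [
        (Rect(0, 0, 1000, 500), (250, 250), 0.0, (2, 4)),    # ceil arithmetic
        (Rect(0, 0, 1000, 500), (250, 250), 0.1, (3, 5)),    # step 225
        (Rect(0, 0, 100, 100), (250, 250), 0.0, (1, 1)),     # sample < FOV
    ])
    def test_grid_shape_follows_ceil_rule(self, bounds, fov, overlap, expect):
        grid = plan_search_mosaic(bounds, fov, overlap)
        assert (grid.rows, grid.cols) == expect
        assert grid.enabled.all()

    def test_overlap_of_one_or_more_rejected(self):
        with pytest.raises(ValueError):
            plan_search_mosaic(Rect(0, 0, 100, 100), (50, 50), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_every_point_of_bounds_is_covered(self, seed):
        r = np.random.default_rng(seed)
        bounds = Rect(r.uniform(-500, 500), r.uniform(-500, 500),
                      r.uniform(30, 400), r.uniform(30, 400))
        fov = (r.uniform(20, 150), r.uniform(20, 150))
        overlap = r.uniform(0, 0.6)
        grid = plan_search_mosaic(bounds, fov, overlap)
        assert _uncovered_fraction(grid, bounds) == 0.0

    def test_grid_overhang_is_at_most_half_a_field(self):
        grid = plan_search_mosaic(Rect(0, 0, 1000, 500), (250, 250), 0.1)
        ext = grid.extent()
        assert ext.x >= -125 - 1e-9 and ext.x1 <= 1000 + 125 + 1e-9
        assert ext.y >= -125 - 1e-9 and ext.y1 <= 500 + 125 + 1e-9


def _uncovered_fraction(grid: TileGrid, bounds: Rect) -> float:
    """Sample bounds at 1 µm pitch; fraction of points in no tile."""
    xs = np.arange(bounds.x, bounds.x1 + 1e-9, 1.0)
    ys = np.arange(bounds.y, bounds.y1 + 1e-9, 1.0)
    covered = np.zeros((ys.size, xs.size), dtype=bool)
    for _r, _c, rect in grid.iter_tiles(enabled_only=True):
        cx = (xs >= rect.x - 1e-9) & (xs <= rect.x1 + 1e-9)
        cy = (ys >= rect.y - 1e-9) & (ys <= rect.y1 + 1e-9)
        covered |= cy[:, None] & cx[None, :]
    return 1.0 - covered.mean()


# ---------------------------------------------------------------------------
# Per-object planning
# ---------------------------------------------------------------------------

def _obj(bbox, centroid=None):
    x, y, w, h = bbox
    c = centroid or (x + w / 2, y + h / 2)
    return DetectedObject(object_id="o", centroid=StagePoint(*c), bbox=bbox, area=w * h)


class TestPlanObjectAcquisition:
    def test_small_object_becomes_single_field_at_centroid(self):
        item = plan_object_acquisition(_obj((0, 0, 100, 80)), (150, 150))
        assert isinstance(item, SingleField)
        assert (item.center.x, item.center.y) == (50.0, 40.0)
        assert (item.width, item.height) == (150, 150)

    def test_wide_object_becomes_tile_grid(self):
        item = plan_object_acquisition(_obj((0, 0, 400, 100)), (150, 150), overlap=0.0)
        assert isinstance(item, TileGrid)
        assert (item.rows, item.cols) == (1, 3)

    def test_bbox_exactly_equal_to_fov_is_a_single_field(self):
        item = plan_object_acquisition(_obj((0, 0, 150, 150)), (150, 150))
        assert isinstance(item, SingleField)

    def test_margin_pushes_object_over_the_field_size(self):
        item = plan_object_acquisition(_obj((0, 0, 140, 140)), (150, 150), margin=20)
        assert isinstance(item, TileGrid)

    def test_grid_covers_padded_bbox(self):
        obj = _obj((10, -30, 700, 320))
        item = plan_object_acquisition(obj, (150, 150), overlap=0.1, margin=25)
        padded = Rect(10 - 25, -30 - 25, 750, 370)
        assert _uncovered_fraction(item, padded) == 0.0


# ---------------------------------------------------------------------------
# NoIR pruning vs the brute-force rasterization oracle
# ---------------------------------------------------------------------------

def noir_oracle(grid: TileGrid, mask: np.ndarray, frame: MosaicFrame,
                margin: float) -> np.ndarray:
    """Brute-force NoIR oracle on the mask's own raster.

    Builds every mask pixel square as an explicit rectangle (at 1 µm pixel
    size the raster *is* the 1 µm rasterization of the object) and asks a
    computational-geometry library whether each tile rectangle lies within
    ``margin`` of any of them — the closed "grazing contact counts" convention,
    computed by an independent route.
    """
    import shapely
    from shapely.strtree import STRtree

    nz_rows, nz_cols = np.nonzero(mask)
    ps = frame.pixel_size
    ox, oy = frame.origin.x, frame.origin.y
    sign = frame.y_axis_sign
    px = ox + nz_cols * ps
    py = oy + sign * nz_rows * ps
    squares = shapely.box(px - ps / 2, py - ps / 2, px + ps / 2, py + ps / 2)
    tree = STRtree(squares)
    enabled = np.zeros_like(grid.enabled)
    for r in range(grid.rows):
        for c in range(grid.cols):
            if not grid.enabled[r, c]:
                continue
            t = grid.tile_rect(r, c)
            tile_box = shapely.box(t.x, t.y, t.x1, t.y1)
            if margin == 0.0:
                hits = tree.query(tile_box, predicate="intersects")
            else:
                hits = tree.query(tile_box, predicate="dwithin", distance=margin)
            enabled[r, c] = hits.size > 0
    return enabled


def random_noir_case(rng, max_grid=16):
    """Integer-lattice grid + random blob mask sharing the same stage frame."""
    rows = int(rng.integers(1, max_grid + 1))
    cols = int(rng.integers(1, max_grid + 1))
    tile = float(rng.integers(3, 9) * 2)          # even integer tile size
    grid = TileGrid(origin=StagePoint(tile / 2, tile / 2), rows=rows, cols=cols,
                    tile_w=tile, tile_h=tile, overlap=0.0)
    h = int(rows * tile)
    w = int(cols * tile)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        rad = rng.uniform(1, max(2.0, min(w, h) / 3))
        mask |= (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= rad ** 2
    frame = MosaicFrame(StagePoint(0.5, 0.5), 1.0, 1)
    margin = float(rng.choice([0.0, 0.0, rng.integers(0, 12)]))
    return grid, mask, frame, margin


class TestApplyNoir:
    def test_centered_disk_disables_exactly_the_corner_tiles(self):
        yy, xx = np.mgrid[0:1000, 0:1000]
        mask = (xx + 0.5 - 500) ** 2 + (yy + 0.5 - 500) ** 2 <= 500 ** 2
        frame = MosaicFrame(StagePoint(0.5, 0.5), 1.0, 1)
        grid = plan_search_mosaic(Rect(0, 0, 1000, 1000), (125, 125), 0.0)
        pruned = apply_noir(grid, mask, frame, 0.0)
        assert pruned.n_enabled == 60
        corners = [(0, 0), (0, 7), (7, 0), (7, 7)]
        assert all(not pruned.enabled[r, c] for r, c in corners)
        assert (pruned.enabled == noir_oracle(grid, mask, frame, 0.0)).all()

    def test_mask_filling_the_grid_disables_nothing(self):
        grid = plan_search_mosaic(Rect(0, 0, 64, 64), (16, 16), 0.0)
        mask = np.ones((64, 64), dtype=bool)
        frame = MosaicFrame(StagePoint(0.5, 0.5), 1.0, 1)
        assert apply_noir(grid, mask, frame, 0.0).enabled.all()

    def test_margin_larger_than_grid_diagonal_disables_nothing(self):
        grid = plan_search_mosaic(Rect(0, 0, 64, 64), (16, 16), 0.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 32] = True
        frame = MosaicFrame(StagePoint(0.5, 0.5), 1.0, 1)
        assert apply_noir(grid, mask, frame, 200.0).enabled.all()

    def test_empty_mask_disables_everything_with_warning(self):
        grid = plan_search_mosaic(Rect(0, 0, 64, 64), (16, 16), 0.0)
        frame = MosaicFrame(StagePoint(0.5, 0.5), 1.0, 1)
        with pytest.warns(EmptyMaskWarning):
            pruned = apply_noir(grid, np.zeros((64, 64), dtype=bool), frame, 0.0)
        assert pruned.n_enabled == 0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_rasterization_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        grid, mask, frame, margin = random_noir_case(rng, max_grid=10)
        pruned = apply_noir(grid, mask, frame, margin)
        assert (pruned.enabled == noir_oracle(grid, mask, frame, margin)).all()
        # result is a subset of the input enabled set
        assert not (pruned.enabled & ~grid.enabled).any()

    def test_enabled_count_monotone_in_margin(self):
        rng = np.random.default_rng(7)
        grid, mask, frame, _ = random_noir_case(rng, max_grid=12)
        counts = [apply_noir(grid, mask, frame, m).n_enabled
                  for m in (0.0, 2.0, 5.0, 11.0, 23.0)]
        assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_oracle(objs, min_separation):
    """O(n^3)-ish reference: repeatedly merge any close pair until stable."""
    def gap(a, b):
        ax, ay, aw, ah = a.bbox
        bx, by, bw, bh = b.bbox
        dx = max(0.0, max(bx - (ax + aw), ax - (bx + bw)))
        dy = max(0.0, max(by - (ay + ah), ay - (by + bh)))
        return math.hypot(dx, dy)

    objs = list(objs)
    changed = True
    while changed:
        changed = False
        for i in range(len(objs)):
            for j in range(i + 1, len(objs)):
                if gap(objs[i], objs[j]) <= min_separation:
                    a, b = objs[i], objs[j]
                    x0 = min(a.bbox[0], b.bbox[0])
                    y0 = min(a.bbox[1], b.bbox[1])
                    x1 = max(a.bbox[0] + a.bbox[2], b.bbox[0] + b.bbox[2])
                    y1 = max(a.bbox[1] + a.bbox[3], b.bbox[1] + b.bbox[3])
                    objs = [o for k, o in enumerate(objs) if k not in (i, j)]
                    objs.append(DetectedObject(
                        object_id="m", centroid=StagePoint((x0 + x1) / 2, (y0 + y1) / 2),
                        bbox=(x0, y0, x1 - x0, y1 - y0), area=a.area + b.area))
                    changed = True
                    break
            if changed:
                break
    return objs


class TestMergeNearbyObjects:
    def test_distant_objects_unchanged(self):
        objs = [_obj((0, 0, 10, 10)), _obj((1000, 0, 10, 10))]
        assert merge_nearby_objects(objs, 10.0) == objs

    def test_abutting_boxes_merge_to_union(self):
        a = DetectedObject("a", StagePoint(5, 5), (0, 0, 10, 10), area=100)
        b = DetectedObject("b", StagePoint(15, 5), (10, 0, 10, 10), area=100)
        merged = merge_nearby_objects([a, b], 10.0)
        assert len(merged) == 1
        assert merged[0].bbox == (0, 0, 20, 10)
        assert merged[0].centroid.x == pytest.approx(10.0)  # equal-area weighting

    def test_area_weighted_centroid(self):
        a = DetectedObject("a", StagePoint(0, 0), (-1, -1, 2, 2), area=300)
        b = DetectedObject("b", StagePoint(3, 0), (2, -1, 2, 2), area=100)
        merged = merge_nearby_objects([a, b], 10.0)
        assert merged[0].centroid.x == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_fixpoint_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        objs = []
        for i in range(n):
            x, y = rng.uniform(0, 200, size=2)
            w, h = rng.uniform(1, 40, size=2)
            objs.append(DetectedObject(f"o{i}", StagePoint(x + w / 2, y + h / 2),
                                       (x, y, w, h), area=w * h))
        sep = float(rng.uniform(0, 30))
        got = merge_nearby_objects(objs, sep)
        want = merge_oracle(objs, sep)
        got_boxes = sorted(tuple(round(v, 6) for v in o.bbox) for o in got)
        want_boxes = sorted(tuple(round(v, 6) for v in o.bbox) for o in want)
        assert got_boxes == want_boxes
        # idempotence
        again = merge_nearby_objects(got, sep)
        assert sorted(o.bbox for o in again) == sorted(o.bbox for o in got)


# ---------------------------------------------------------------------------
# Savings
# ---------------------------------------------------------------------------

def _disk_savings(n: int) -> float:
    """NoIR savings of a centred inscribed disk on an n x n grid over its square."""
    extent = 2048.0
    ps = extent / 1024
    yy, xx = np.mgrid[0:1024, 0:1024]
    mask = ((xx + 0.5) * ps - extent / 2) ** 2 + ((yy + 0.5) * ps - extent / 2) ** 2 \
        <= (extent / 2) ** 2
    frame = MosaicFrame(StagePoint(ps / 2, ps / 2), ps, 1)
    grid = plan_search_mosaic(Rect(0, 0, extent, extent), (extent / n, extent / n), 0.0)
    pruned = apply_noir(grid, mask, frame, 0.0)
    plan = SecondScanPlan(entries=[("disk", pruned)], settings_id="s",
                          fov_w=extent / n, fov_h=extent / n)
    return estimate_savings(plan, Rect(0, 0, extent, extent))


class TestEstimateSavings:
    def test_full_mosaic_saves_nothing(self):
        grid = plan_search_mosaic(Rect(0, 0, 1000, 1000), (100, 100), 0.0)
        plan = SecondScanPlan(entries=[("all", grid)], settings_id="s",
                              fov_w=100, fov_h=100)
        assert estimate_savings(plan, Rect(0, 0, 1000, 1000)) == 0.0

    def test_single_tile_of_a_10x10_baseline_saves_99_percent(self):
        plan = SecondScanPlan(entries=[("one", SingleField(StagePoint(50, 50), 100, 100))],
                              settings_id="s", fov_w=100, fov_h=100)
        assert estimate_savings(plan, Rect(0, 0, 1000, 1000)) == pytest.approx(0.99)

    def test_disk_savings_grow_toward_the_analytic_limit(self):
        # tile counting keeps every boundary tile, so finite-n savings sit below
        # 1 - pi/4 and increase toward it as the grid is refined
        values = [_disk_savings(n) for n in (8, 16, 32, 64)]
        assert values == sorted(values)
        limit = 1 - math.pi / 4
        assert all(v < limit for v in values)
        # at n=64 the boundary-tile deficit is ~2 pi / n ~ 0.1 relative
        assert values[-1] == pytest.approx(limit, abs=0.05)
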