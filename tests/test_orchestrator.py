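"""The three-step workflow engine: stitching, step chaining, NoIR, savings, CLI."""

import json

import numpy as np
import pytest
import tifffile

from smartscan.acquisition_io import (
    AcquisitionSettings,
    read_coordinates,
    read_job,
)
from smartscan.orchestrator import (
    RunManifest,
    WorkflowError,
    run_all,
    run_analysis,
    run_first_scan,
    run_second_scan,
)
from smartscan.scan_planner import Rect, SingleField, plan_search_mosaic
from smartscan.stage_geometry import ObjectiveProfile
from smartscan.virtual_microscope import (
    SyntheticSampleSpec,
    acquire,
    generate_slide,
    render_region,
)

from conftest import (
    CTC_PARAMS,
    CTC_RULES,
    make_experiment,
    mask_coverage_violations as _mask_coverage_violations,
    small_ctc_experiment,
    small_tma_experiment,
)


def _ctc_settings(fov, px, offset=(0.0, 0.0), sid="s"):
    return AcquisitionSettings(
        id=sid, objective=ObjectiveProfile("o", 10.0, fov, fov, *offset),
        image_width=px, image_height=px,
        channels=[("DNA", 1.0), ("CK", 1.0), ("CD45", 1.0)])


class TestFirstScanAndStitching:
    def test_single_tile_sample_mosaic_equals_the_tile(self, tmp_path):
        spec = SyntheticSampleSpec(kind="ctc", n_cells=30, extent=(500.0, 500.0), seed=2)
        template, spec_path = make_experiment(
            tmp_path, spec=spec, first=_ctc_settings(750.0, 250, sid="first"),
            second=_ctc_settings(250.0, 128, sid="second"),
            params=CTC_PARAMS, rules=CTC_RULES, macro="rare_event")
        manifest = run_first_scan(template, spec_path, tmp_path / "run")
        assert manifest.counts["search_tiles"] == 1
        stack = tifffile.imread(manifest.path("mosaic"))
        slide = generate_slide(spec)
        grid = plan_search_mosaic(Rect(0, 0, 500, 500), (750.0, 750.0), 0.0)
        images, _ = acquire(slide, _ctc_settings(750.0, 250, sid="first"),
                            (grid, 0, 0), item_id="scan1_r0c0")
        assert np.array_equal(stack[0], images["DNA"].astype(np.float32))

    def test_juxtaposed_grid_stitches_to_the_sum_of_tile_sizes(self, tmp_path):
        # 3000 x 1500 µm slot, 750 µm FOV at 375 px -> 4 x 2 tiles, 1500 x 750 px
        spec = SyntheticSampleSpec(kind="ctc", n_cells=50, extent=(3000.0, 1500.0), seed=3)
        template, spec_path = make_experiment(
            tmp_path, spec=spec, first=_ctc_settings(750.0, 375, sid="first"),
            second=_ctc_settings(250.0, 128, sid="second"),
            params=CTC_PARAMS, rules=CTC_RULES, macro="rare_event")
        manifest = run_first_scan(template, spec_path, tmp_path / "run")
        assert manifest.counts["search_tiles"] == 8
        stack = tifffile.imread(manifest.path("mosaic"))
        assert stack.shape == (3, 750, 1500)

    def test_overlapping_stitch_matches_direct_render_within_noise(self, tmp_path):
        spec = SyntheticSampleSpec(kind="ctc", n_cells=120, extent=(1500.0, 1500.0),
                                   seed=4)
        template, spec_path = make_experiment(
            tmp_path, spec=spec, first=_ctc_settings(750.0, 375, sid="first"),
            second=_ctc_settings(250.0, 128, sid="second"),
            params=CTC_PARAMS, rules=CTC_RULES, macro="rare_event", overlap=0.2)
        manifest = run_first_scan(template, spec_path, tmp_path / "run")
        stack = tifffile.imread(manifest.path("mosaic"))
        doc = json.loads(manifest.path("mosaic_frame").read_text())
        h, w = doc["height"], doc["width"]
        ps = doc["pixel_size"]
        ox, oy = doc["origin"]
        slide = generate_slide(spec)
        clean = render_region(slide, "DNA", Rect(ox - ps / 2, oy - ps / 2, w * ps, h * ps),
                              (h, w))
        resid = stack[0] - clean
        sd = spec.noise_sd
        assert np.abs(resid).mean() < 1.2 * sd
        assert np.abs(resid).max() < 6.5 * sd

    def test_missing_ingested_tiles_are_listed(self, tmp_path):
        tile_dir = tmp_path / "tiles"
        tile_dir.mkdir()
        (tile_dir / "tiles.json").write_text(json.dumps({
            "channels": ["DNA"], "pixel_size": 2.0,
            "tiles": [{"id": "t0", "path": "t0.tif", "origin": [0, 0]},
                      {"id": "t1", "path": "t1.tif", "origin": [100, 0]}]}))
        spec = SyntheticSampleSpec(kind="ctc", n_cells=10, extent=(500.0, 500.0), seed=1)
        template, _ = make_experiment(
            tmp_path, spec=spec, first=_ctc_settings(750.0, 250, sid="f"),
            second=_ctc_settings(250.0, 128, sid="s2"),
            params=CTC_PARAMS, rules=CTC_RULES, macro="rare_event")
        with pytest.raises(WorkflowError, match="t0.*t1"):
            run_first_scan(template, tile_dir, tmp_path / "run")


class TestWorkflowChain:
    def test_steps_cannot_run_out_of_order(self, tmp_path):
        template, spec_path = small_ctc_experiment(tmp_path, n_cells=30, extent=800.0)
        manifest = run_first_scan(template, spec_path, tmp_path / "run")
        fresh = RunManifest(out_dir=tmp_path / "run")
        with pytest.raises(WorkflowError):
            run_analysis(fresh)
        with pytest.raises(WorkflowError):
            run_second_scan(manifest)  # analysis not done yet

    def test_auto_play_equals_stepwise_runs_byte_for_byte(self, tmp_path):
        template, spec_path = small_ctc_experiment(tmp_path, seed=11)
        auto = run_all(template, spec_path, tmp_path / "auto", run_id="r")
        manual = run_first_scan(template, spec_path, tmp_path / "manual", run_id="r")
        manual = run_analysis(manual)
        manual = run_second_scan(manual)
        for artifact in ("mosaic", "labels", "coordinates", "second_scan_job"):
            assert auto.path(artifact).read_bytes() == manual.path(artifact).read_bytes()

    def test_empty_object_list_warns_and_skips_acquisition(self, tmp_path):
        template, spec_path = small_ctc_experiment(tmp_path, seed=5, n_cells=50,
                                                   extent=900.0)
        # no events at all on this slide
        doc = json.loads(spec_path.read_text())
        doc["event_fraction"] = 0.0
        spec_path.write_text(json.dumps(doc))
        manifest = run_first_scan(template, spec_path, tmp_path / "run")
        manifest = run_analysis(manifest)
        assert manifest.counts["objects"] == 0
        with pytest.warns(UserWarning, match="no objects"):
            manifest = run_second_scan(manifest)
        assert manifest.counts["second_scan_fields"] == 0
        assert read_job(manifest.path("second_scan_job")).items == []

    def test_failed_analysis_halts_the_chain(self, tmp_path):
        template, spec_path = small_ctc_experiment(tmp_path, seed=6, n_cells=30,
                                                   extent=800.0)
        with pytest.raises(WorkflowError, match="unknown macro"):
            run_all(template, spec_path, tmp_path / "run", macro="nonsense")
        manifest = RunManifest.load(tmp_path / "run")
        assert manifest.status["analysis"] == "failed"
        assert manifest.status["second_scan"] == "pending"


class TestSecondScan:
    def test_small_objects_become_centered_single_fields_with_paracentricity(self, tmp_path):
        template, spec_path = small_ctc_experiment(tmp_path, seed=12)
        manifest = run_all(template, spec_path, tmp_path / "run")
        records = read_coordinates(manifest.path("coordinates"))
        job = read_job(manifest.path("second_scan_job"))
        assert len(job.items) == len(records) > 0
        # second objective offset (5, 7), first (0, 0)
        for rec, (oid, item) in zip(records, job.items):
            assert oid == rec.object_id
            assert isinstance(item, SingleField)
            assert item.center.x == pytest.approx(rec.x + 5.0, abs=1e-9)
            assert item.center.y == pytest.approx(rec.y + 7.0, abs=1e-9)
        # one image captured per object at second-scan settings
        tifs = sorted((manifest.out_dir / "objects").glob("*.tif"))
        assert len(tifs) == len(records)
        assert tifffile.imread(tifs[0]).shape == (3, 128, 128)

    def test_captured_field_recentres_the_object_despite_paracentricity(self, tmp_path):
        """End to end: the re-acquired image of a detected cell has its nucleus
        in the image centre even though the commanded stage position is offset."""
        template, spec_path = small_ctc_experiment(tmp_path, seed=13)
        manifest = run_all(template, spec_path, tmp_path / "run")
        records = read_coordinates(manifest.path("coordinates"))
        assert records
        img = tifffile.imread(manifest.out_dir / "objects" /
                              f"{records[0].object_id}.tif")[0]  # DNA channel
        h, w = img.shape
        centre = img[h // 2 - 2:h // 2 + 2, w // 2 - 2:w // 2 + 2].mean()
        # the nucleus (amplitude ~150 over background 20) sits under the centre;
        # an off-centre capture would read background (~20) here
        assert centre > 100.0

    def test_noir_prunes_fields_but_never_uncovers_the_object(self, tmp_path):
        template_on, spec_path = small_tma_experiment(tmp_path / "on", seed=21)
        template_off, _ = small_tma_experiment(tmp_path / "off", seed=21, noir=False)

        on = run_all(template_on, spec_path, tmp_path / "run_on")
        off = run_all(template_off, (tmp_path / "off" / "slide_spec.json"),
                      tmp_path / "run_off")
        assert on.counts["objects"] == off.counts["objects"] > 0
        assert on.counts["second_scan_fields"] <= off.counts["second_scan_fields"]
        assert on.savings >= off.savings
        for manifest in (on, off):
            assert _mask_coverage_violations(manifest) == 0

    def test_reported_savings_match_a_recount_from_the_emitted_job(self, tmp_path):
        template, spec_path = small_tma_experiment(tmp_path, seed=22)
        manifest = run_all(template, spec_path, tmp_path / "run")
        job = read_job(manifest.path("second_scan_job"))
        n_fields = sum(1 if isinstance(item, SingleField) else item.n_enabled
                       for _, item in job.items)
        fov = job.settings.fov
        baseline = plan_search_mosaic(Rect(*manifest.slot), fov, 0.0)
        expected = 1.0 - n_fields / (baseline.rows * baseline.cols)
        assert manifest.savings == pytest.approx(max(0.0, min(1.0, expected)), abs=1e-12)


class TestCLI:
    def test_stepwise_and_play_verbs(self, tmp_path):
        from click.testing import CliRunner
        from smartscan.cli import main

        template, spec_path = small_ctc_experiment(tmp_path, seed=31)
        runner = CliRunner()
        res = runner.invoke(main, ["plan", "--template", str(template)])
        assert res.exit_code == 0 and "tiles" in res.output

        run_dir = tmp_path / "run"
        for args in (["scan1", "--template", str(template), "--slide", str(spec_path),
                      "--out", str(run_dir)],
                     ["analyze", "--out", str(run_dir)],
                     ["scan2", "--out", str(run_dir), "--noir"]):
            res = runner.invoke(main, args)
            assert res.exit_code == 0, res.output

        res = runner.invoke(main, ["play", "--template", str(template), "--slide",
                                   str(spec_path), "--out", str(tmp_path / "run2")])
        assert res.exit_code == 0, res.output
        assert "savings" in res.output
        assert (tmp_path / "run2" / "coordinates.csv").read_bytes() == \
            (run_dir / "coordinates.csv").read_bytes()

    def test_simulate_writes_a_loadable_bundle(self, tmp_path):
        from click.testing import CliRunner
        from smartscan.cli import main
        from smartscan.acquisition_io import load_template

        res = CliRunner().invoke(main, ["simulate", "--kind", "tma", "--seed", "7",
                                        "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        template = load_template(tmp_path / "template.json")
        assert template.macro == "tissue"
        doc = json.loads((tmp_path / "slide_spec.json").read_text())
        assert doc["n_pieces"] == 77 and doc["seed"] == 7
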