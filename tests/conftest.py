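"""Shared fixtures: small, fast experiment bundles built with the library API."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from smartscan import (
    AcquisitionSettings,
    DetectionParams,
    MarkerRule,
    ObjectiveProfile,
    SampleLayout,
    StagePoint,
    SyntheticSampleSpec,
    Template,
)
from smartscan.acquisition_io import save_template, write_settings
from smartscan.orchestrator import canonical_dumps
from smartscan.virtual_microscope import spec_to_doc

# study-condition parameters for the rare-event assay, shared by tests
CTC_PARAMS = DetectionParams(channel="DNA", threshold_mode="fixed", threshold_value=80.0,
                             smoothing_sigma=1.0, min_area=20.0, max_area=2000.0)
CTC_RULES = [MarkerRule("CK", "positive", 50.0), MarkerRule("CD45", "negative", 50.0)]


def make_experiment(out_dir: Path, *, spec: SyntheticSampleSpec,
                    first: AcquisitionSettings, second: AcquisitionSettings,
                    params: DetectionParams, rules=(), macro: str = "tissue",
                    noir: bool = True, noir_margin: float = 0.0,
                    overlap: float = 0.0, margin: float = 0.0) -> tuple[Path, Path]:
    """Write a template + settings + slide spec bundle; returns (template, spec) paths."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_settings(first, out_dir / "first.json")
    write_settings(second, out_dir / "second.json")
    layout = SampleLayout(slots=[("slot0", StagePoint(0.0, 0.0),
                                  spec.extent[0], spec.extent[1])])
    template = Template(first_scan_settings="first.json", second_scan_settings="second.json",
                        detection_params=params, layout=layout, noir_enabled=noir,
                        noir_margin=noir_margin, macro=macro, marker_rules=list(rules),
                        search_overlap=overlap, acquisition_margin=margin)
    save_template(template, out_dir / "template.json")
    (out_dir / "slide_spec.json").write_text(canonical_dumps(spec_to_doc(spec)),
                                             encoding="utf-8")
    return out_dir / "template.json", out_dir / "slide_spec.json"


def small_ctc_experiment(out_dir: Path, seed: int = 1, n_cells: int = 400,
                         extent: float = 1500.0, **kwargs) -> tuple[Path, Path]:
    """A reduced rare-event experiment that runs end to end in a few seconds."""
    spec = SyntheticSampleSpec(kind="ctc", n_cells=n_cells, extent=(extent, extent),
                               seed=seed)
    first = AcquisitionSettings(
        id="search", objective=ObjectiveProfile("10x", 10, 750.0, 750.0),
        image_width=375, image_height=375,
        channels=[("DNA", 1.0), ("CK", 1.0), ("CD45", 1.0)])
    second = AcquisitionSettings(
        id="capture", objective=ObjectiveProfile("40x", 40, 375.0, 375.0, 5.0, 7.0),
        image_width=128, image_height=128,
        channels=[("DNA", 1.0), ("CK", 1.0), ("CD45", 1.0)])
    kwargs.setdefault("macro", "rare_event")
    kwargs.setdefault("rules", CTC_RULES)
    return make_experiment(out_dir, spec=spec, first=first, second=second,
                           params=CTC_PARAMS, **kwargs)


def small_tma_experiment(out_dir: Path, seed: int = 1, n_pieces: int = 8,
                         extent: float = 7000.0, **kwargs) -> tuple[Path, Path]:
    """A reduced tissue-screen experiment: a handful of pieces on a small slide."""
    spec = SyntheticSampleSpec(kind="tma", n_pieces=n_pieces, extent=(extent, extent),
                               piece_size_range=(200.0, 900.0), seed=seed)
    first = AcquisitionSettings(
        id="search", objective=ObjectiveProfile("5x", 5, 3500.0, 3500.0),
        image_width=350, image_height=350, channels=[("DAPI", 1.0)])
    second = AcquisitionSettings(
        id="capture", objective=ObjectiveProfile("20x", 20, 600.0, 600.0, 12.0, -9.0),
        image_width=256, image_height=256, channels=[("DAPI", 1.0)])
    params = DetectionParams(channel="DAPI", threshold_mode="fixed", threshold_value=80.0,
                             smoothing_sigma=1.0, min_area=5000.0)
    return make_experiment(out_dir, spec=spec, first=first, second=second,
                           params=params, **kwargs)


def mask_coverage_violations(manifest) -> int:
    """Count object mask pixels (stage centres) not covered by the object's plan entry
    in the emitted second-scan job (paracentricity shift undone)."""
    import json

    import tifffile

    from smartscan.acquisition_io import load_template, read_job, read_settings
    from smartscan.scan_planner import SingleField

    labels = tifffile.imread(manifest.path("labels"))
    doc = json.loads(manifest.path("mosaic_frame").read_text())
    ps = doc["pixel_size"]
    ox, oy = doc["origin"]
    job = read_job(manifest.path("second_scan_job"))
    template = load_template(Path(manifest.template_path))
    first = read_settings(Path(manifest.template_path).parent / template.first_scan_settings)
    dx = job.settings.objective.paracentricity_dx - first.objective.paracentricity_dx
    dy = job.settings.objective.paracentricity_dy - first.objective.paracentricity_dy

    bad = 0
    for i, (_oid, item) in enumerate(job.items):
        rows, cols = np.nonzero(labels == i + 1)
        xs = ox + cols * ps
        ys = oy + rows * ps
        covered = np.zeros(xs.shape, dtype=bool)
        rects = ([item.rect()] if isinstance(item, SingleField)
                 else [rect for _, _, rect in item.iter_tiles()])
        for rect in rects:
            covered |= ((xs >= rect.x - dx) & (xs <= rect.x1 - dx)
                        & (ys >= rect.y - dy) & (ys <= rect.y1 - dy))
        bad += int((~covered).sum())
    return bad


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
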