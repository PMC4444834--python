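# smartscan

**smartscan** turns the plain "tile-scan everything at high resolution" workflow
of an automated microscope into an *intelligent screen*: a fast low-resolution
**search mosaic** over the whole sample, an image-analysis step that reduces the
mosaic to a **list of object coordinates**, and a targeted high-resolution
**second scan** that acquires only those objects. For rare targets — a handful
of circulating tumour cells among tens of thousands of leukocytes, or a few
dozen tissue pieces scattered over a slide — this saves the overwhelming
majority of acquisition time and storage while losing nothing of interest.

It is written for microscopy core facilities and image-analysis developers who
want the *logic* of intelligent screening (planning, detection, pruning,
coordinate bookkeeping) as a vendor-neutral, fully testable library: the
acquisition-settings files are a documented JSON dialect rather than any
vendor's proprietary metadata, and a built-in **virtual microscope** renders
synthetic slides so every part of the workflow runs — and is scored against
ground truth — without hardware.

## The method

1. **First scan.** A grid of juxtaposed fields (optionally overlapping by a
   fraction `o`, step = FOV·(1−o)) covering the sample bounds:
   `cols = ceil((W − fov_w)/step_w) + 1` and analogously for rows, with the last
   row/column shifted inward so the grid hugs the bounds. Tiles are stitched by
   nominal stage position into the search mosaic, with pixel↔stage mapping
   `x = x₀ + col·s`, `y = y₀ ± row·s` (`s` = pixel size in µm).

2. **Analysis.** A detection "macro" turns the mosaic into coordinates. Two are
   built in: *tissue detection* (smooth → threshold → fill holes → close →
   8-connected components → area filter) and *rare-event detection* (segment
   nuclei on the counterstain channel, measure each candidate's mean marker
   intensity on its mask dilated by 2 px, keep candidates that are positive for
   every positive marker and below threshold on every negative one — e.g.
   nucleated, CK⁺, CD45⁻). Any external program can substitute via the macro
   contract (read mosaic TIFF + frame JSON, write the coordinate CSV), and
   objects can be picked manually.

3. **Second scan.** Each object whose padded bounding box fits in the
   high-resolution field of view becomes a single field centred on its
   centroid; larger objects get a tile grid. With **NoIR** (non-informative
   region pruning) enabled, grid tiles that do not touch the object's pixel
   mask (dilated by a configurable margin) are disabled — irregular objects are
   captured snugly instead of as full rectangles. Switching objectives applies
   the predefined per-objective **paracentricity correction** (a stage-space
   translation), so objects stay centred across the magnification change. The
   result is a scan-job file the acquisition software would reload, plus a
   savings report: `1 − enabled fields / fields of a full mosaic`.

## Worked example

Simulate a tissue-microarray slide with 77 differently sized pieces and screen
it with a single command:

```bash
$ smartscan simulate --kind tma --seed 1 --out demo/
$ smartscan plan --template demo/template.json
search mosaic: 7 x 7 tiles of 3000 x 3000 µm (overlap 0)

$ smartscan play --template demo/template.json --slide demo/slide_spec.json --out demo/run
objects: 77
second-scan fields: 101
savings vs full mosaic: 0.861
```

The 5× first scan tiles a 2 × 2 cm slide with 49 fields; the detector finds all
77 tissue pieces; the 20× second scan needs only 101 fields (small pieces as
single fields, large ones as NoIR-pruned grids) instead of the 729 fields a
blanket 20× mosaic of the slide would take — 86.1% of the acquisition is
skipped. The run directory holds the stitched mosaic, the coordinate CSV
(editable before `scan2` in stepwise mode), the label image, the generated
second-scan job and every captured object image.

The same flow with `--kind ctc` screens a 10,000-cell rare-event slide
(0.25% spiked events, i.e. 25 cells): the classifier returns exactly the 25
DNA⁺ CK⁺ CD45⁻ cells as single 40× fields.

The CLI verbs `scan1`, `analyze`, `scan2` run the same three steps one at a
time; `play` chains them and is byte-identical to the stepwise run.

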