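# Methods

## Model of the instrument and workflow

smartscan models an automated microscope as a stage that can be commanded to a
position `(x, y)` in µm and a camera that captures an axis-aligned rectangular
field of view (FOV) centred there. The screening workflow is the classic
three-step feedback loop: (1) a low-magnification *search mosaic* covering the
sample, (2) image analysis of that mosaic yielding object coordinates, and
(3) a high-magnification *second scan* restricted to those objects. All state
between steps lives in files (settings JSON, coordinate CSV, scan-job JSON), so
the loop can run automatically or be interrupted for human curation between any
two steps; re-running a step reads only the run directory, which is what makes
automatic and stepwise execution byte-identical.

### Coordinate frames

A mosaic image is linked to the stage by an affine frame: the stage position of
the centre of pixel (0, 0), an isotropic pixel size (µm/px), and a sign for the
Y axis (vendors disagree on whether row index grows with stage Y). Pixel
indices are 0-based, a pixel coordinate refers to the pixel *centre*, and a
pixel occupies the closed square of one pixel size centred there; tile and
field rectangles are closed sets. All planning geometry follows from these
conventions.

Changing objectives shifts the optical axis by a fixed translation per
objective (*paracentricity*). Each objective carries its offset relative to one
declared reference objective; correcting a target from objective A to B adds
`offset(B) − offset(A)`. Translation-only is the minimal model consistent with
a "predefined correction" per lens pair; no rotation or scale term is fitted
(a rotational component, if present on a real stand, is not representable —
declared limitation). The virtual microscope makes the convention concrete: an
objective with offset `d` commanded to `p` images the scene centred at
`p − d`, and all returned frames are in commanded coordinates, which is what a
real stage reports. Because coordinates are detected under the first-scan
objective and corrected when the job is built, objects land centred in the
second-scan fields end to end.

## Planning

**Search mosaic.** For bounds of width `W` and FOV width `f` at overlap
fraction `o` (step `s = f(1−o)`), the column count is 1 if `W ≤ f` and
`ceil((W−f)/s) + 1` otherwise (rows analogous). The first tile is centred at
`min + f/2`; the last row/column is shifted inward so the grid never overhangs
the bounds by more than half a field. This layout is deterministic, symmetric
in its overhang, and covers every point of the bounds (proved by construction
and checked by 1 µm grid sampling in the tests). Tiles are acquired in
row-major serpentine order to keep stage travel short and stitching
deterministic.

**Per-object plans.** An object is captured as a single field when a field
centred on its *centroid* covers its margin-padded bounding box, i.e. when
`2·max(c − x₀, x₁ − c) ≤ fov` on both axes; equality resolves to the cheaper
single field. The naive test "padded box fits in the FOV" is not sufficient:
for an asymmetric object the centroid sits off the box centre and a
centroid-centred field would clip the box edge, violating the guarantee that a
plan covers its object. Objects failing the test get a tile grid laid out over
the padded box exactly as the search mosaic is.

**NoIR pruning.** A grid tile stays enabled iff its closed rectangle intersects
the object's pixel mask — the union of the mask's pixel squares — dilated by a
Euclidean margin (default 0 µm; a template parameter, since no canonical value
exists). Grazing contact counts as intersection: the rule is deliberately
conservative and can be shown never to drop a mask pixel from coverage (every
mask pixel lies in some tile of the covering grid, and that tile, touching the
mask, stays enabled). An empty mask disables all tiles and signals a warning.
The implementation computes exact rectangle-to-pixel-square distances inside a
per-tile candidate window; the tests check it, tile for tile, against an
independent computational-geometry oracle (shapely rectangle `dwithin`
queries) on hundreds of random masks.

A consequence of conservative pruning worth knowing: the enabled-tile count
*over*-counts the object area by the boundary-tile ring, a relative excess of
order `1/n` on an `n×n` grid. For a disk inscribed in a square the skipped
fraction therefore approaches `1 − π/4 ≈ 0.215` from below as the grid is
refined — measured 0.063, 0.125, 0.164, 0.183 at n = 8, 16, 32, 64 — and is
still about 0.03 short of the limit at n = 64. The savings estimate itself is
simply `1 − enabled fields / fields of a full mosaic over the baseline bounds`,
clipped to [0, 1].

**Merging.** Optionally, objects whose bounding boxes lie within a separation
threshold are merged (union box, area-weighted centroid) before planning.
Merging groups by transitive closure of the pairwise relation and repeats until
stable: a single closure pass is not idempotent, because a merged union box can
come within the threshold of a group the first pass kept separate. The
orchestrator does not merge by default.

## Detection

**Tissue pieces** (single channel): optional Gaussian smoothing (sigma in
pixels), a global threshold (fixed value, or Otsu when no calibration is
available), binary hole filling, a closing of radius 1 px, 8-connected
labelling, then an area filter in µm². The three knobs a user actually tunes
are threshold, smoothing and the size filter. Objects touching the mosaic
border are kept and flagged rather than dropped — a rare target at a tile seam
must not be lost.

**Rare events** (multichannel): nuclei are segmented on the counterstain
channel with the same pipeline; each candidate's mean intensity per marker
channel is measured on its nucleus mask dilated by 2 px, which captures the
cytoplasmic rim where cytokeratin lives (the nucleus mask alone would
under-read a cytoplasmic marker). A candidate is an event iff every
positive-polarity rule has mean ≥ threshold and every negative-polarity rule
has mean strictly below threshold; the asymmetric bounds (≥ vs <) fix the
boundary behaviour. The canonical configuration is the circulating-tumour-cell
assay: nucleated, CK-positive, CD45-negative, which excludes leukocytes.

External routines participate through the macro contract (mosaic TIFF + frame
JSON in, coordinate CSV out, exit status 0); records outside the mosaic bounds
are rejected with a report. Manual selections become rectangular-mask objects
labelled `manual`.

## The virtual microscope

The simulator is analytic, not raster-based: each placed object contributes a
smooth radial profile `1/(1 + exp((r − R(φ))/w))` (a lobed ellipse boundary
`R(φ)` with edge width `w`), so any FOV, zoom or pixel size samples the same
underlying scene — the second scan genuinely sees more detail than the first,
as on real hardware. Noise is additive Gaussian read noise on a flat
background, seeded per `(slide seed, field id, channel)` so re-acquisition is
bit-reproducible; Poisson noise is deliberately omitted so that the
signal-to-noise ratio, defined as object amplitude over noise sd, is exact.
Objects are placed by rejection sampling (≤ 1000 attempts each, spatial-hash
accelerated) with a minimum gap so ground-truth objects never overlap.

Two scenes are built in, with defaults chosen as the study conditions:

* **tma** — 77 tissue pieces (ellipses or lobed blobs), diameters 150–900 µm,
  amplitudes 120–220 over background 20, on a 2 × 2 cm slide with a 150 µm
  minimum gap so pieces read as distinct cores.
* **ctc** — 10,000 cells on a 4 × 4 mm region, event fraction 0.25%
  (exactly `round(n · f)` events), nucleus radius 6 µm ± 15%, nuclear amplitude
  150 ± 15, event CK 120 ± 12 vs 8 ± 3 in non-events, CD45 reversed, 10 µm
  minimum inter-cell gap (so adjacent nuclei do not fuse under a 1 px closing
  at the 2 µm/px search resolution). The default read noise sd of 30 puts the
  nuclear SNR at 5 — the detection task is noise-limited, not trivial.

The demo detection parameters (fixed nuclear threshold at background + 60,
smoothing 1 px, min area 20 µm², marker cutoffs at background + 30) give every
decision a margin of several standard deviations under these conditions, which
is why recall and precision of 1.0 over 20 seeded slides is an expected —
and verified — outcome rather than luck. What the synthetic scenes do *not*
model: optical PSF and defocus, uneven illumination, Poisson statistics,
stage positioning error, autofocus failures, staining variability beyond
Gaussian amplitude spread. Perfect recovery here validates the engine's logic,
not the difficulty of real-world CTC imaging.

Z-stack and time-lapse settings are carried through plans and job files
untouched, but the renderer produces a single 2-D plane (declared limitation).

## File formats and determinism

Settings, jobs, templates and slide specs are versioned JSON written
canonically: sorted keys, floats normalised to 9 significant digits, UTF-8, LF.
The coordinate CSV has a fixed seven-column header, µm units, period decimals.
Canonical writing makes "same inputs → byte-identical artifacts" a testable
contract rather than an aspiration; the determinism check runs the whole
workflow twice and compares files byte for byte. Stitching uses nominal stage
positions with unweighted averaging in overlap strips — the virtual stage is
exact and the search mosaic is a locator, not a quantitative image — so
stitched pixels are exactly reproducible too.

## Problem sizes used in the checks

The verification suite uses: 200 random masks on grids up to 16×16 for pruning
agreement; a 1024² mask at 2 µm/px for the inscribed-disk savings; 100 random
bounds/FOV/overlap combinations sampled at 1 µm for coverage; 100 random
documents per format for round-trips; 20 slides × 10,000 cells for rare-event
recovery; and the full 77-piece TMA screen end to end. These sizes keep a full
run in the single-digit minutes on one CPU while leaving each measurement at
the scale its claim is about.

## Known limitations

* Paracentricity is translation-only; parfocality (z) is out of scope.
* Stitching performs no cross-correlation registration; it trusts stage
  coordinates, which is exact only on the virtual stage.
* The settings dialect is a stand-in: no parser for any vendor's native
  metadata is included.
* Acquisition order optimisation is limited to serpentine ordering; no
  travelling-salesman path planning.
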