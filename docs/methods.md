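# Methods

## Scope and model

`gutmorph` quantifies secretory-vesicle load and apico-basal polarization
in columnar epithelial cells from 3D instance label volumes (cells,
nuclei, vesicles, lumen), as produced by volume-EM segmentation. The
pipeline has five stages — scene simulation, optional intensity
segmentation, label morphometrics, polarity scoring, phenotype
classification — each usable on its own through the library API or the
`gutmorph` CLI.

### Coordinate contract

All grids share axis order (slice, row, column) with spacing in nm in the
same order; the default (50, 15, 15) nm reflects block-face acquisition:
50 nm slice thickness, 15 nm in-plane pixels. World coordinates are
voxel-centre nm with 0-based indices, `world = (index + 0.5) * spacing`.
TIFF stacks carry spacing in a JSON sidecar (`<name>.tif.meta.json`);
NRRD output embeds it in the header (a minimal built-in codec supporting
3D raw/gzip little-endian data). Connectivity (6 or 26) is defined in
index space and deliberately ignores anisotropy, matching the convention
of voxel-grid tooling.

## Morphometrics

`object_census` measures every positive label: voxel count, physical
volume `V = count × s0·s1·s2`, voxel-centre centroid in nm, and
equivalent spherical diameter `(6V/π)^(1/3)`. Vesicle ownership is the
cell with maximal voxel overlap (ties to the smaller cell id); vesicles
overlapping no cell are reported unassigned and excluded from per-cell
statistics. A centroid-containment rule is available as a config
alternative. Vesicles split into two size classes at an equivalent
diameter of 600 nm — midway between twice the small mode (~300 nm) and
the large mode (~1 µm); the boundary value itself is classed `large`.
The cutoff is configurable. Per-cell counts and all polarity statistics
use the secretory class only by default: the large electron-dense
vesicles occur in every midgut cell and carry no phenotype signal, so
including them (switchable) would only dilute the contrast.

## Polarity

The apico-basal axis of each cell is estimated from its surface
contacts: the apical anchor is the centroid of cell voxels 6-adjacent to
the lumen mask, the basal anchor the centroid of cell voxels 6-adjacent
to background lying within 60° of the apical-anchor→cell-centroid
direction (the cone excludes lateral background contacts of edge cells).
Cells without lumen contact fall back to a configured global axis, or
raise an error naming the cell.

"Base of the nucleus" is read as the nucleus's **apical-most** extent
along the axis, making the apical compartment the supranuclear cytoplasm
between nucleus and apical membrane. This is one of three defensible
readings (apical-most point, basal-most point, centroid); the
`percentile` parameter (100 = apical-most, 0 = basal-most, 50 = median)
exposes the alternatives rather than hard-coding one, and also softens
the extreme against segmentation noise. A vesicle is apical iff the axis
coordinate of its **centroid** strictly exceeds the nucleus-base
coordinate — centroid position is the simplest rule consistent with a
per-vesicle binary classification; a majority-volume alternative can be
selected in config. A centroid exactly at the boundary counts as basal.
Zero-vesicle cells report a missing fraction, never a division error.

## Phenotype calls

Two criteria with the published comparisons applied verbatim
(`≥` for the count ratio, strict `>`/`<` for the fractions):

* high-vesicle: count ≥ 3 × baseline;
* among high-vesicle cells: apical fraction > 0.75 → exocrine-like,
  < 0.50 → differentiating, in the gap → **indeterminate** (the two
  published bounds do not tile [0, 1]; forcing a side would fabricate a
  rule). All other cells → stomach.

The baseline ("a typical main-stomach cell") is not operationally defined
in the source material, so two modes exist: supervised (median count over
caller-given reference stomach cells) and unsupervised (median of the
cells at or below the overall median count — a robust proxy for the
low-vesicle population). The unsupervised default is what the pipeline
and acceptance runs use.

## Synthetic scenes

The generator emulates what the analysis needs and nothing more: a flat
monolayer slab of jittered-rectangle columnar cells, apical faces against
a full-width lumen slab at +axis0, a basal background margin below, one
ellipsoidal nucleus per cell seated in the basal half, and spherical
vesicles planted by rejection sampling — non-overlapping (with one voxel
of clearance so distinct vesicles never become 6-face-adjacent), fully
inside their owner cell, never intersecting the nucleus. Secretory
vesicle counts are Poisson; each vesicle goes supranuclear with
probability `apical_bias`, otherwise basal/paranuclear; diameters are
normal truncated at ±3 SD. The planting rule uses the *rasterized*
nucleus's apical extent with a 150 nm guard margin on either side, so
planted apical flags are exactly recoverable by the measurement rule and
small axis-estimation tilts cannot flip a label. One root seed; each cell
draws from its own deterministic substream (`SeedSequence(seed,
spawn_key=(cell_id,))`), so adding or editing one cell never perturbs
another's draws. Placement failure after 1,000 attempts per vesicle is an
error naming the cell, not a silent truncation.

Default study conditions: 20 cells (4 × 5) — 7 exocrine (Poisson mean
100 secretory vesicles, bias 0.9), 2 differentiating (100, 0.4), 11
stomach (25, 0.5); secretory diameters N(300, 30) nm, large dense
vesicles 1–3 per cell at N(1000, 100) nm; spacing (50, 15, 15) nm.
Stomach-cell count statistics and the stomach-cell number are not
reported for the real tissue and are realistic inventions (flagged as
such); the 4× exocrine/stomach mean ratio comfortably clears the 3×
criterion without sitting on it. Cell geometry is likewise invented:
1.8 µm footprint, 10 µm height, nucleus semiaxes (800, 500, 500) nm
centred 3.4 µm above the base — columnar-epithelium proportions chosen
so that the densest planted compartment stays well below the
random-sequential-adsorption jamming density (placement converges in a
handful of attempts).

The optional grayscale render assigns per-compartment 8-bit means
(cytoplasm 128, secretory vesicles 220 — electron-lucent, large vesicles
40 — electron-dense, nuclei 90, 1-voxel darkened cell-boundary seams 60,
lumen/background 150) plus clipped additive Gaussian noise (SD 10
default).

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: EM texture and membranes, curved
gut geometry, touching or non-spherical vesicles, segmentation errors in
the cell/nucleus masks, partial cells at the volume border, and any
organelles beyond those quantified. Tests on synthetic scenes validate
the measurement and classification logic, not robustness to real-world
segmentation quality.

## Segmentation stage

`threshold_components` labels the 6-connected components of a band
threshold (masked to cell interiors in the pipeline), drops components
below `min_size_voxels`, and orders labels by descending size with the
first C-order voxel as tie-break — deterministic and idempotent.
`magic_wand` is seeded region growing: the connected region within an
absolute intensity tolerance of the *seed voxel's* value (not a running
mean), 26-connected by default, implemented with
`skimage.segmentation.flood` and verified in tests against an
independent breadth-first-search oracle. Default thresholds (200–255,
min size 8) are tuned to the synthetic render's contrast; real volumes
need their own settings. Instance splitting of touching vesicles
(watershed) and cell/nucleus segmentation from intensity are out of
scope — cell and nucleus masks are inputs.

## Numerical choices and degenerate inputs

* Size-class boundary at exactly 600 nm → `large`; vesicle centroid
  exactly at the nucleus base → basal; count exactly 3 × baseline →
  high-vesicle. All three tie rules are documented comparisons, not
  accidents of floating point.
* Baseline 0 (all lower-half cells empty) is replaced by the smallest
  positive count; an all-zero scene is an error in unsupervised mode.
* Labels are stored as unsigned 16-bit on disk; a scene or segmentation
  with more than 65,535 objects is an error at write time (int32 in
  memory).
* Ownership ties and greedy IoU matching break ties by smaller id, so
  outputs are reproducible across runs and platforms.

## Problem sizes

The default scene is ~61 M voxels (210 × 480 × 600) and builds in ~1.5 s;
a full label-route pipeline run takes ~10 s on one CPU. The test suite
runs the default study at 20 seeds plus a 50-cell polarity-recovery
scene; the acceptance script repeats the 20-scene study from scratch.
Sphere-measurement accuracy is validated at nominal diameters of 300 nm
and 1000 nm (within 10% at the default anisotropic spacing, with
rasterization error decreasing monotonically as isotropic spacing shrinks
50 → 25 → 10 nm).

## Known limitations

* Axis estimation assumes a roughly prismatic cell with identifiable
  lumen and basal contacts; strongly curved or wedge-shaped cells would
  need the global-axis fallback or a different estimator.
* The unsupervised baseline assumes low-vesicle cells are the majority
  class; in a field of view dominated by exocrine cells, supervised
  reference ids should be used.
* Anisotropy-blind connectivity slightly favours in-plane merging at
  50 nm slice spacing; at the default contrast this has no measurable
  effect on recovery.
* The indeterminate band [0.50, 0.75] is reported, not resolved; cells
  landing there need more context than the two published bounds provide.
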