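# Methods

## The measurement problem

A myxospermous seed sown on a toluidine-blue-O agarose gel releases its
soluble seed-coat mucilage over ~24 h; the dye stains the pectic mucilage
purple-pink, producing a concentric halo around the dark seed on a
light-blue background. The quantities of interest per seed are the
projected seed area *AreaS*, the halo area *AreaM* (defined as every pixel
inside the halo outline, **including** the pixels under the seed, since the
mucilage extends beneath it), and the **adjusted mucilage content**
*AreaM/AreaS*, which normalises the halo by the size of the seed that
produced it. Seed shape itself is characterised by the standard descriptor
set (perimeter, circularity, Feret diameters, solidity, …).

The approach is deliberately supervised global thresholding, not learned
segmentation: stained plates are high-contrast, three-class scenes (gel /
halo / seed) where fixed HSV bands, refined once per imaging setup, are
transparent, fast and auditable.

## Pipeline model and assumptions

* **Calibration.** A single isotropic scalar (px/mm), from two marked
  points spanning the plate at a known distance, or from the plate width.
  Square pixels are assumed; anisotropic sensors are out of scope. Cropping
  to a window inside the plate removes dish edges and does not change the
  calibration.
* **Colour model.** 8-bit HSV planes, all three scaled to 0–255
  (hue = angle·255/360, truncated; achromatic pixels get h = s = 0). This
  matches how the threshold presets are quoted in the plant-phenotyping
  literature. The inverse transform dequantises hue and saturation at the
  midpoint of the truncation cell; round-tripping is then exact to ±1
  intensity level for moderately saturated colours (chroma ≲ 85), which
  covers the stained-plate palette — fully saturated hues quantise more
  coarsely, a limitation inherent to 8-bit hue.
* **Band semantics.** Each preset quotes one number per channel; it is the
  non-trivial bound of an inclusive band whose other end is the channel
  extreme: mucilage 172/24/85 → H ∈ [172,255], S ∈ [24,255], V ∈ [85,255];
  seed 255/255/70 → V ∈ [0,70] with H and S passing everything (seed
  segmentation rests on brightness alone).
* **Hole filling.** Background is flood-filled from the border with
  4-connectivity against 8-connected foreground (the standard dual pairing
  that avoids topological paradoxes). Halos therefore come out simply
  connected and *AreaM* includes the seed's pixels; specular glints inside
  seeds are closed the same way.
* **Labeling.** 8-connected components, numbered by raster order of each
  component's topmost-then-leftmost pixel — "line by line from the top".
  8-connectivity keeps anti-aliased blob boundaries whole.
* **Area filter.** Halos outside [18, 315] mm² are deleted: below, dust and
  staining specks; above, two or more halos fused on the gel (they are
  deleted, not split — fused halos have no well-defined per-seed area).
  Seed masks get their own filter, default [0.5, 50] mm² for flax-sized
  seeds. Border-touching objects are flagged, and deleted only on request;
  cropping inside the plate is the primary defence.
* **Matching.** Rank matching (seed *k* ↔ halo *k*) is the default and is
  exact when sowing is diagonal, so both numbering passes visit objects in
  the same order. Its documented failure mode — one missing or fused halo
  shifts every later rank — is why count mismatches raise loud warnings and
  why a containment mode (seed centroid inside halo region) is offered for
  arbitrary layouts. The matched table is written automatically; pairing is
  always a partial injection.

## Shape descriptors and numerical choices

Per object: area, perimeter, circularity, max Feret, min Feret, Feret
angle, solidity, convex area, aspect ratio, centroid x, centroid y — the
package's canonical 11-descriptor set, all in mm-based units.

* **Area** is the pixel count divided by (px/mm)² — never a fitted-circle
  idealisation.
* **Perimeter** is the Freeman chain code of the Moore-traced outer
  boundary (axis steps 1, diagonal steps √2) multiplied by the classical
  **0.948 isotropy correction**. Raw chain codes systematically
  overestimate smooth contours — measured +5.0 to +5.3% on digital disks of
  radius 20–100 px, which would depress a disk's circularity to ≈ 0.91.
  With the correction the disk perimeter error is −0.5% to −0.2% and
  circularity clips to exactly 1.0. The uncorrected length remains
  available (`chain_code_length`, `region_perimeter(..., corrected=False)`);
  on a 10×10 pixel square it is exactly 36 (the 4·(n−1) pixel-center
  polygon), while the corrected default reads 34.13.
* **Circularity** = 4π·A/P², clipped at 1.0 (digitisation can push raw
  values slightly above 1; the descriptor's range is 0.0–1.0). A
  single-pixel object (zero-length boundary polygon) is defined as
  circularity 1.0.
* **Feret.** Max Feret is the largest pairwise distance between pixel
  centers, computed on convex-hull vertices (provably equal to the O(n²)
  exhaustive search, which the tests run as oracle); min Feret is the
  minimal caliper width over hull edges; the angle of the max chord is
  measured counter-clockwise from the image x-axis in [0°, 180°).
  Collinear components degrade gracefully (min Feret 0).
* **Solidity / convex area.** Convex area is the shoelace area of the
  convex hull of the **pixel squares** (centers ± 0.5 px), which guarantees
  convex_area ≥ pixel-count area, makes solidity exactly 1.0 for convex
  digital shapes like rectangles, and gives the 3×3 plus-sign the
  octagonal hull of area 7 (solidity 5/7). The convention has a known
  consequence: a digital disk of radius r scores ≈ (r/(r+0.5))² — 0.957 at
  r = 20, 0.990 at r = 100 — because the hull covers the half-pixel rim
  that pixel counting does not. Aspect ratio is max/min Feret (1.0 for
  degenerate minima).
* **IsoData thresholding** iterates T ← round((mean ≤ T + mean > T)/2)
  from the histogram's mass bisector, ties rounding half up, until stable
  (a 2-cycle guard returns the current iterate; none was observed in
  randomized testing against the exhaustive 256-candidate fixed-point
  search). Histograms with fewer than two populated bins raise a
  degenerate-histogram error; the band suggester then falls back to the
  shipped defaults with a warning. Suggested mucilage bands keep the upper
  class (low = T+1); the seed V band keeps the dark class (high = T). The
  suggester is advisory: the pipeline applies presets unless
  `--auto-threshold` is passed, mirroring the supervised workflow.

## The synthetic plate generator

`seedhalo.synthetic` renders what the pipeline is built to measure: a
light-blue gel (190, 215, 235), dark elliptical seeds (60, 40, 30) and
concentric halo disks with a radial colour gradient (200, 120, 180) →
(215, 150, 200) chosen to sit inside the flax mucilage bands — renderer
constants, not measurements. Defaults model flax: seed semi-axes 2.0–2.6 ×
1.0–1.3 mm, halo radii 3.5–6.0 mm (halo areas ≈ 38–113 mm², inside the
18–315 mm² window), 8 px/mm. Per-channel Gaussian sensor noise is optional.
Diagonal sowing places centers strictly monotonically in row and column
(the layout under which rank matching is provably exact), so the plate side
grows with the seed count; jittered mode scatters seeds on a shuffled grid
for containment-matching tests. Scenario plates cover merged halos (two
7.5 mm-radius halos 14 mm apart, union ≈ 338 mm² > 315), border-touching
halos, mucilage-free seeds and four small-seeded species.

Ground truth is analytic: ellipse area πab, Ramanujan's perimeter
approximation (relative error < 10⁻⁴ at these axis ratios), Feret 2a,
solidity 1; halo area πR². Everything is drawn from one seeded generator,
so plates are byte-reproducible.

**What the generator does not emulate** — and what passing tests therefore
do not show about real plates: uneven illumination and vignetting, dye
gradients that cross the threshold bands, partially released or asymmetric
halos, touching seeds, JPEG artefacts, and lens distortion. Real deployments
should validate thresholds on the overlay triptych before trusting the
tables.

## Problem sizes

The quantitative recovery suite runs 20 plates of 5–30 seeds (alternating
clean and Gaussian noise σ ∈ [1, 5]) at 8 px/mm and asserts AreaS/AreaM
within 3% of truth, adjusted ratio within 4%, and exact rank pairing; the
descriptor oracles use disks of radius 20–100 px and 100 random blobs of up
to 500 px. These sizes make the whole suite run in about a minute on one
core while keeping rasterization error well below the asserted tolerances.

## Known limitations

* Thresholds are global; strongly uneven lighting requires cropping or
  recalibration, not a local threshold.
* Fused halos are deleted, not split; watershed-style separation is out of
  scope, as are CNN segmenters.
* Only the flax preset is calibrated. **Recalibrating presets:** run
  `seedhalo analyze --auto-threshold` on a representative plate, inspect
  the overlay, round the suggested bands to taste and store them in a copy
  of `presets.ini` (loadable via `seedhalo.load_presets(path)`), together
  with area filters bracketing the species' seed and halo sizes.
* Circularity/solidity are digitisation-limited for objects below ~15 px
  diameter; choose the imaging scale so seeds span at least ~20 px.
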