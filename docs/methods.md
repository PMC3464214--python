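# Methods

## Scope and model

`tubecount` quantifies tube-formation efficiency from phase-contrast
micrographs in two stages — fully automated foreground segmentation, then
semi-automatic measurement of operator-identified tubes — and provides the
companion assay quantifications (scratch-wound closure, single-cell shape,
comparative ΔCT). The segmentation model assumes exactly two image
properties: cell/tube pixels are darker than the surrounding background,
and cell boundaries are sharp. No learned components, texture descriptors
or watershed instance separation are used.

All internal arithmetic is float64; images are quantised back to 8/16-bit
(round-half-to-even) only when written to disk. Coordinates are (row, col),
0-based, origin top-left. Components and holes use 8-connectivity for
foreground and 4-connectivity for background. Every stage is deterministic;
the only randomness in the package lives in the synthetic generators and is
fully determined by their seed.

## Stage 1 — enhancement

Order: median denoising → homomorphic filtering → contrast stretching.
Impulse noise is removed before the frequency-domain filter so single hot
pixels do not leak into the spectrum; the stretch comes last so the
thresholding stage sees the full dynamic range.

- **Median filter** — window 3 px (default), edge-replicated borders.
  Output never leaves the input's [min, max].
- **Homomorphic filter** — log-transform (`log1p`), FFT, Gaussian
  high-emphasis transfer function
  `H(f) = g_lo + (g_hi − g_lo)(1 − exp(−f²/2f_c²))` with defaults
  g_lo = 0.5, g_hi = 1.5 and cutoff f_c = 0.05 × image diagonal (DFT index
  units), inverse FFT, `expm1`, rescale to the input range. The image is
  mirror-padded by half its size before the transform: the DFT is cyclic,
  and without padding an illumination gradient wraps across the border and
  rings back as spurious dark/bright bands wide enough to survive
  small-object removal. With g_lo = g_hi = 1 the operator reproduces its
  input to ~1e−15 relative error.
- **Contrast stretch** — percentiles (1, 99) map linearly onto [0, 255]
  with clipping; a constant image is returned unchanged with a warning
  (the stretch is undefined). Order-preserving inside the band.

All enhancement defaults (window sizes, gains, percentiles) are exposed in
`EnhanceConfig`; they were chosen once as standard textbook values for
~1 Mpx phase-contrast fields and are not tuned per image.

## Stage 1 — segmentation

Two independent cues on the enhanced image, intersected:

1. **Multi-scale local-mean thresholding.** A pixel is dark iff its value
   is strictly below the mean of its w×w neighbourhood (edge-replicated)
   minus an offset, for *every* w in the window set (default {15, 31, 63}
   px, chosen to span sub-tube to super-tube scales; `scaled_windows()`
   rescales the set for other image sizes). Offset default 0 — the literal
   darker-than-average rule. A relative tie tolerance of 1e−9 keeps exact
   floating-point ties (e.g. constant images) out of the mask. Increasing
   the offset can only shrink the mask, and the multi-scale mask is
   contained in every single-window mask by construction.
2. **Edge objects.** Sobel gradient magnitude (standard 3×3 kernels,
   edge-replicated) thresholded at
   `max(75th percentile, 3 × median magnitude)`. The percentile alone would
   mark the top quantile of *any* gradient field, including pure sensor
   noise; real cell boundaries sit far above the median while a noise-only
   (Rayleigh-like) magnitude field has essentially no mass above 3× its
   median, so the floor makes edge evidence mean something. Zero-gradient
   pixels are never edges, so constant images give empty masks. Edges are
   then closed with a disk (radius 3), holes filled, and 8-connected
   components under 64 px dropped. The closing pads by the disk radius
   first so it behaves as on an infinite background plane — library border
   conventions either clip foreground at the frame (cropped erosion) or
   invent it (reflect padding).

The final mask is the pixelwise AND of the two cues followed by another
small-object removal; it is contained in both parents. The mask operators
are local, hence shift-equivariant away from a border margin; the
homomorphic enhancement is a global frequency-domain operator, so exact
equivariance of the full pipeline is not claimed (the tests check the mask
operators).

On the default synthetic conditions (below), 20 seeded fixtures give mean
IoU ≈ 0.97 against ground truth; the thresholding cue alone covers ≥ 96%
of true tube pixels.

## Stage 2 — tube measurement

The operator supplies (start, end) pixel pairs per tube; clicks rarely land
on the mask, so each endpoint snaps to the nearest foreground pixel within
`snap_radius` (default 10 px, row-major tie-break). Endpoints in different
foreground components are reported as untraceable and the tube is skipped
(counted in the QC columns), never silently dropped.

- **Tracing.** Minimum-cost 8-connected path through the foreground with
  step cost `step_length × (1 + 1/d)`, d the Euclidean distance transform
  (EDT) at the entered pixel — a centerline-seeking geodesic that follows
  the tube axis instead of hugging the mask boundary.
- **Length.** Euclidean chord length of the traced path subsampled every
  5 vertices. Raw 8-connected chain length overestimates oblique straight
  segments by up to ~8% (worst at 30°/60°); the chord sum removes that
  bias, keeping recovered lengths within ~0.5% on straight tubes at any
  angle, and within 5% under rotation as required.
- **Width.** 2 × EDT along the path, with the EDT evaluated on a 2×
  upsampled mask (pixel spacing 0.5, best of each vertex's four
  subpixels). On the integer grid the medial axis of an even-width tube
  falls between pixel rows and 2×EDT−1 is one pixel short; the half-pixel
  grid measures rectangles of any width exactly. Vertices within one
  median width of the tube ends are trimmed from the average (there the
  EDT sees the end cap, not the sides), provided the path is at least 4×
  longer than the trim.
- **Area.** Foreground pixels whose nearest path vertex lies within
  `mean_width/2 + 1` px, kept as an explicit pixel set; the per-image total
  is the union over tubes, so crossing tubes are not double-counted.
- **Graph.** Endpoints within `merge_eps` (default 10 px) merge by
  single-linkage transitive closure into nodes at their centroid; tubes
  are edges of a multigraph. Branching points are nodes of degree ≥ 3 —
  taken from the annotated topology, not from a skeleton of the mask.
- **Statistics.** total length, average length (total/n), area-weighted
  mean width, tube count, branching points, union area. `pixel_size`
  (µm/px) scales lengths/widths linearly and areas quadratically. An empty
  annotation yields all-zero statistics, not an error.

On the 20 default fixtures, recovered totals are within 1% (length),
8% (width) and 4% (area) of generator truth; tube and branching-point
counts are exact on noise-free fixtures.

## Companion measurements

- **Wound closure.** `open_wound_fraction` = 100 × background/total pixels;
  `wound_recovery_series` relates each time point to t = 0 and refuses a
  series whose wound is already closed at t = 0. Cell-occupied masks for
  image input come from `wound_cell_mask`: occupancy of a confluent
  monolayer is a *texture* property (the sheet is full of cell-boundary
  edges, the scratch is optically flat), so the mask is built from the
  Sobel edge cue alone, consolidated with a generous closing (radius 10)
  and hole fill. The intensity cue used for tubes is deliberately not
  intersected in — it marks dark cell bodies and structurally under-counts
  the occupied sheet. On synthetic series the estimated open fraction
  carries a ~2–4 pp positive bias from the half-covered wound margin;
  recovery percentages remain monotone and ordering-faithful.
- **Cell shape.** Area = pixel count; perimeter by marching-squares contour
  at the 0.5 level, chord-subsampled every 5 vertices — the raw contour
  staircases along smooth boundaries (+5% on disks) while naive
  boundary-pixel counting biases circularity by tens of percent; the
  chord-subsampled estimator is within ~0.5% on disks, rectangles and
  ellipses at 100 px scale. Circularity = P²/(4πA): exactly 1 for an ideal
  disk, 4/π for a square, rising with elongation. The mask must contain
  exactly one 8-connected component.
- **Comparative ΔCT.** ΔCT = CT_target − CT_reference per sample (replicate
  wells of one gene are averaged first); fold = 2^−(ΔCT − mean ΔCT_control)
  per sample, then mean ± SD per condition. Per-sample CT shifts cancel
  exactly. No amplification-efficiency correction is applied.

## Synthetic data

The generators exist so that every stage is testable without microscopy
data; they are deterministic functions of their spec (identical inputs ⇒
bit-identical outputs), rendered with 4× supersampling and majority-vote
downsampling so mask truth is well defined.

- **Tube networks** (`TubeNetworkSpec` defaults): 256×256 px, 8 straight
  tubes of width 4–8 px and length ≥ 50 px, tube intensity 80 on background
  200 (8-bit scale), multiplicative left-to-right illumination ramp
  0.8–1.2, additive Gaussian noise at 2% of range, branch probability 0.3
  (a branch starts exactly at an existing endpoint, so truth branching
  points are unambiguous), distinct junctions kept ≥ 30 px apart. Truth:
  exact mask, per-tube analytic lengths/widths, endpoint annotation, and
  the six statistics.
- **Wound series**: a confluent monolayer rendered as a Voronoi-like
  tessellation of dark polygonal cells (mean diameter 15 px, centers on a
  jittered grid so neighbouring nuclei cannot coincide) separated by thin
  bright seams, with a centred cell-free vertical band per time point;
  truth open fraction = band width / image width.
- **Cell shapes**: disk, ellipse, rectangle, star silhouettes with analytic
  area/perimeter truth (ellipse perimeter via the complete elliptic
  integral).

What the generators do **not** emulate: phase-contrast halo artefacts,
cell bodies between tubes, partial confluency gradients, focus drift,
uneven Matrigel thickness. Passing the recovery tests therefore shows the
pipeline implements its model faithfully under its stated assumptions, not
that it matches human annotation on arbitrary real micrographs.

## Problem sizes and numerical choices

The test and acceptance fixtures use 20 seeded 256×256 networks — large
enough for the default window set and geodesics to behave as on full-size
micrographs while keeping the whole suite under a minute of compute. Brute
-force oracle comparisons (local means, Sobel magnitudes, morphological
closing, Dijkstra geodesics) run on ≤ 32×32 instances, 100 seeded cases
each. Ties: row-major for endpoint snapping, first-minimum for argmin;
degenerate inputs (constant images, empty masks, empty annotations) return
the documented neutral results rather than raising wherever a neutral
result exists.

## Known limitations

- Tube identification is manual by design; there is no annotation-free
  mode, and statistics inherit any operator bias in endpoint placement.
- Width is a medial-axis estimate; on tubes narrower than ~3 px it
  quantises visibly.
- The wound open-fraction estimate is biased a few percentage points high
  at wound margins (half-covered boundary cells).
- The ΔCT layer reports folds and dispersion only; significance testing is
  out of scope.
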