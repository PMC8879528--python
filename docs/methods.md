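# Methods

This note records the model, the parameter choices, and the design
decisions behind `layermark`, in the spirit of a package methods section:
what is computed, under which assumptions, and what the synthetic tests do
and do not establish about physical prints.

## Watermark model

A watermark is an `n_rows x n_cols` binary matrix placed on one flat face
of an oblong tablet. Each cell spans one **encoding layer pair** and one
**bit column**:

- Vertically, the pair of layers `(k, k+1)` prints at thicknesses
  `h(1-a), h(1+a)` for a 0 and `h(1+a), h(1-a)` for a 1. The sum is `2h`
  exactly, so the modulation is invisible to total height, layer count,
  and print time. Implementation-wise only the *lower* layer's top z is
  shifted by `±a*h`; the upper layer keeps its nominal top z and
  compensates implicitly. Modulating both layers would touch the outer
  surface twice for no informational gain.
- Horizontally, cells are `bit_cell_width` wide; the z-shift holds a
  plateau inside the cell and fades linearly over a `ramp` length at cell
  boundaries (so transitions between opposite bits span `2*ramp`).
  Extrusion of every modified wall segment is rescaled by
  `local thickness / h` (volume = width x thickness x length, the same
  flow model slicers use), so deposited volume follows the geometry and
  the pair's total extrusion is conserved.

Rows are separated by `s` unmodulated **separating layers** and the patch
keeps physical margins to the bed and the tablet top. Only the straight
part of the long faces is usable; the rounded ends are excluded
(`flat extent = length - 2 * corner_radius`).

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `layer_height` h | 0.2 | mm | standard FDM layer height for this scheme; 0.1 supported to double row capacity at the cost of pitch (and decode margin) halving |
| `amplitude` a | 0.25 | — | `a*h = 0.05 mm ≈ 2.36 px` at 1200 dpi: comfortably above the tracer's sub-pixel noise floor, small against h so flow stays in the printable regime |
| `separating_layers` s | 2 | layers | minimum distance that keeps adjacent rows' modulated boundaries from interacting |
| `margin_bottom/top` | 0.8 | mm | bed adhesion and top-surface imprecision make the outer layers unreliable; 0.8 mm = 4 layers at h = 0.2 |
| `bit_cell_width` | 1.6 | mm | 4 extrusion widths; the largest round value that places 9 columns on a 15 mm flat extent |
| `ramp` | 0.4 | mm | one extrusion width; shorter ramps approach a step the nozzle cannot render |
| `extrusion_width` | 0.4 | mm | standard 0.4 mm nozzle |

Margins are **physical lengths**, not layer counts: this is the reading
under which halving h doubles the usable rows (3 rows at h = 0.2 vs
6 rows at h = 0.1 on a 4 mm tall tablet), which is the point of supporting
the finer layer height. Row capacity solves
`ceil(mb/h) + 2n + s(n-1) + ceil(mt/h) <= height/h` for the largest
integer n. Rows pack bottom-up from the minimum margin (no vertical
centering — placement lower in the tablet prints earlier and more
reliably); columns pack contiguously, centered in the flat extent, with
ties broken toward −X on a 0.1 µm grid.

## Parity code

The code is a classical 2-D even-parity product code over the
`(n_rows-1) x (n_cols-1)` data block: row parities in the last column,
column parities in the last row, corner = parity of parities. The corner
is checked against *both* readings (row-parity XOR and column-parity
XOR); disagreement counts as a corner failure. Correction flips the
unique single-cell explanation of the syndrome — data cell (one failing
row + one failing column, corner clean), row-parity cell (one failing
row + corner), column-parity cell (one failing column + corner), or the
corner alone — then re-verifies; any other syndrome, or a repair that
does not verify clean, is reported as `failed` rather than guessed at.
Minimum distance is 4: all single errors are corrected, all double errors
detected; triple and heavier corruption can in principle alias onto a
valid or singly-corrupted matrix, which is the usual product-code
limitation and the reason decode failure is a status, not an exception.

## G-code handling

The parser accepts the Marlin/Prusa subset: G0/G1 in absolute XYZ (G90),
absolute or relative extrusion (M82/M83, G92 E resets), `;` comments, and
PrusaSlicer `;LAYER_CHANGE` markers. Without markers, layers are split at
extruding-move z increases; z-hop travels do not open layers. Arc moves
(G2/G3) and relative XYZ (G91) are rejected as unsupported dialects.
Unmodified lines round-trip verbatim; synthesized lines are formatted to
5 decimals (0.01 µm, far below printer resolution). In absolute-E
documents the rescaled segments are followed by a `G92 E` resync so
downstream unmodified commands still extrude their original amounts.

Face detection selects, per layer, the longest run of extruding moves
within 5° of the X axis whose endpoints sit within 1.5 extrusion widths
of the layer's y-extreme on the chosen side, subject to a 2 mm minimum
length (a curved wall always has a short near-tangent stretch at its
extreme; the minimum rejects it). The reported extent is clipped to the
flat region.

The module also generates single-perimeter oblong-tablet G-code (stadium
or rounded-rectangle loops, fixed seam on the left end cap, 1.75 mm
filament volume model). This is the fixture source for all embedding
tests — the scheme needs nothing from a print but its outer wall, so a
single-perimeter document exercises every invariant (infill and inner
walls would pass through untouched).

## Synthetic scans

The renderer draws what a flatbed scanner sees of the tablet's flat side
in the parallel-to-scan-light orientation: a bright background, a darker
tablet silhouette, and Gaussian-profile dark grooves at every layer
boundary (sharp on the flat extent, faded on the rounded caps, strong at
the bed/top silhouette edges). Modulated grooves are displaced by the
same piecewise-linear shift profile the embedder writes into G-code, so
renderer and embedder share one geometric source of truth.

Artifacts, applied in physical order (roughness → grooves →
bubbles/speculars → illumination gradient → transparency → blur → sensor
noise):

- **roughness**: per-boundary random displacement, correlated along x
  over 0.8 mm, plus a proportional fine speckle texture (scattered
  light). Displacement noise at the modulation amplitude `a*h` makes bit
  signs unreliable and is the modeled mechanism behind undetectable
  rough-surface prints.
- **transparency**: blends the object toward the background *before*
  blur and noise — a washed-out object cannot be recovered by contrast
  normalization afterwards, which is why transparent/reflective prints
  fail while the same geometry with an opacifying colorant decodes.
- **bubbles**: bright elliptical blobs alpha-blended over the surface
  (overheated prints); at high density they erase the groove pattern.
- **perpendicular orientation**: groove contrast reduced to 35 % and
  bright specular blobs inside the patch — bits glint to the eye but the
  layer pattern the detector needs is degraded.

Material presets bundle these into named regimes (`smooth_opaque`,
`colored_opaque` decodable; `transparent_reflective`, `rough`, `bubbly`
not). The preset numbers are **calibration choices** tuned once so the
qualitative decodable/undecodable split is reproduced; no quantitative
roughness or reflectivity measurements exist to validate them against,
and they should not be read as material constants.

What the renderer does *not* model: physically based optics (BRDF,
subsurface scattering), printing dynamics (melt viscosity, solidification,
stringing), scanner MTF beyond a Gaussian blur, or geometric distortion
and tilt of the tablet on the glass. Passing round-trip tests therefore
demonstrate the pipeline's internal consistency and its noise margins
under these artifact models — not decoding performance on physical scans.

## Decoder

1. **Locate**: vertical high-pass energy per image column finds the
   x-range with layer banding (the flat extent); autocorrelation of the
   banding profile must peak within ±20 % of the expected pitch
   `h*dpi/25.4`, else the scan is rejected as aperiodic. The bed and top
   silhouette grooves anchor layer indexing; if their span disagrees with
   the expected layer count by more than 20 % the expected pitch is used.
   Bit-column strips are mapped from the plan's mm intervals, *trimmed by
   the ramp length* so only the plateau of each cell is sampled (the
   ramps carry a reduced shift and would dilute the measurement).
2. **Trace**: per strip, grooves are valleys of the column-averaged,
   detrended darkness profile (peak distance 0.55 pitch, quadratic
   sub-pixel refinement). The reference lattice `y(j) = phase - j*pitch`
   is least-squares fitted to separating-layer grooves only — they are
   unmodulated by construction, so the payload cannot bias its own
   reference.
3. **Extract**: per cell, the groove nearest the expected modulated
   boundary (within 0.45 pitch) gives displacement = reference − measured
   y; positive (toward the tablet top) reads 1, negative 0; confidence is
   `|displacement| / (a*h)` clipped to [0, 1]. A missing groove yields
   confidence 0.
4. **Correct**: the recovered matrix passes through the parity corrector;
   the decode status is `ok`, `corrected`, or `failed`, with diagnostic
   flags (`aperiodic`, `low_contrast`, `roughness`) carried alongside.

The decoder sees only layout information (rows, columns, cell width, h,
a, separation, margins) before the parity step — it is blind to the
payload. Grooves are assumed dark against the body (true for the
modeled parallel-orientation scans); scans with inverted polarity would
need inverting upstream.

## Numerical choices and degenerate inputs

- Layer divisibility: heights not a multiple of h floor the layer count
  with a warning rather than failing.
- `amplitude = 0` is legal and renders/decodes to zero confidence — the
  degenerate no-information case.
- Sub-pixel refinement falls back to integer positions at profile edges
  or flat curvature.
- All randomness (renderer artifacts, test payloads) flows through
  seeded `numpy` generators; identical seeds give bit-identical rasters.
- The capacity formula uses a 1e-6 mm tolerance for divisibility and
  snapping, so 0.1/0.2 mm grids survive binary floating point.

## Problem sizes used in the test suite

Round-trip and robustness tests run at the two reference geometries
(12 x 4 x 4 mm with the 3x3 code; 23 x 8 x 6 mm with the 5x5 code),
1200 dpi rendering, 50 random payloads for the headline round trip, 20
trials for failure-mode rates, and 20 payloads per level for the 5-point
artifact sweeps. Exhaustive correction checks cover every single-cell
flip of the 3x3 (all 16 payloads), 5x5, and 5x9 codes and every
double-flip cell pair of the 5x5.

## Known limitations

- Single error correction per matrix, by design; heavy corruption can
  alias (see parity section). Confidence-weighted soft decoding could
  repair more but is not implemented.
- Decoding assumes a known dpi and an upright, untilted tablet; there is
  no rotation/scale registration, no multi-tablet segmentation, and no
  smartphone-photo support.
- Embedding modifies outer-perimeter walls only; prints whose outermost
  wall on the marked face is not in the G-code's extruding moves (e.g.
  vase mode oddities, arc-fitted perimeters) are rejected rather than
  guessed at.
- The 0.1 mm layer height halves the pixel pitch and the displacement
  signal; it decodes in clean renders but with reduced margin, matching
  its status as a supported-but-discouraged setting.
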