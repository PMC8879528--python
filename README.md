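# layermark

Blind layer-thickness watermarking for FDM 3D-printed tablets.

Personalized medicines printed on demand in pharmacies and hospitals ship
without serialized anti-counterfeit packaging, so batch traceability has to
live **on the dosage form itself**. `layermark` implements a
steganographic scheme for fused-deposition-modelling (FDM) prints of
oblong tablets: traceability bits are encoded as local layer-thickness
modulations on a flat tablet side, printed with no extra equipment, and
read back with an ordinary paper scanner. The package is for
pharmaceutical-manufacturing and 3D-printing researchers who want to
embed, plan, simulate, and decode such watermarks without a printer in the
loop.

## The scheme

A code is an `n_rows x n_cols` binary matrix. Each bit cell occupies a
pair of adjacent printed layers within a 1.6 mm wide column on the flat
face: to encode a **0** the lower layer prints thin and the upper layer
compensates, `h(1-a)` then `h(1+a)`; to encode a **1** the order flips,
`h(1+a)` then `h(1-a)`. The pair always sums to `2h`, so object height,
layer count, print time, weight, and seam position are unchanged — the
mark is invisible bookkeeping in the G-code. Rows are separated by `s >= 2`
unmodulated layers and kept `>= 0.8 mm` away from the bed and the tablet
top, where print precision is poorest.

Error handling uses a 2-D even-parity product code: the last column holds
one parity bit per row, the last row one per column, and the corner
protects the parities themselves. Any single wrong cell produces a unique
(row, column) syndrome and is flipped back; multi-bit corruption is
detected and reported as a failure.

Decoding is *blind*: the detector knows the layout (rows, columns, layer
height `h`, amplitude `a`) but not the payload. In a flat-side scan at
1200 dpi the layer boundaries form dark grooves at a pitch of
`h * dpi / 25.4` (9.45 px at `h = 0.2 mm`). The decoder fits the reference
grid to the unmodulated separating-layer grooves only, then reads each bit
from the sign of the modulated groove's sub-pixel displacement
(`a*h = 2.36 px` at defaults), with `|displacement| / (a*h)` as a
per-cell confidence.

Because no public scan corpus of watermarked tablets exists, the `synth`
module renders side-view scans from a code matrix and placement plan —
including the material failure modes seen in practice (surface roughness,
transparency/reflection, gas bubbles, perpendicular scan-light
orientation) — so the whole embed → scan → decode loop is testable on a
desk.

## Worked example

Encode a 4-bit payload `0111` into the minimal 3x3 code (2x2 data +
5 parity cells):

```text
$ layermark encode --payload 0111 --rows 3 --cols 3
0 1 1
1 1 0
1 0 1
```

The last column is the row parities (0^1=1, 1^1=0), the last row the
column parities (0^1=1, 1^1=0), and the corner 1^0=1 checks the checks.

Capacity of the largest swallowable oblong (23 x 8 x 6 mm, 4 mm corner
radius) at the default 0.2 mm layer height:

```text
$ layermark capacity --config cfg.yaml
{
  "rows": 6,
  "cols": 9,
  "total_cells": 54,
  "data_bits": 40,
  "flat_extent_mm": 15
}
```

Nine 1.6 mm columns fit the 15 mm flat extent — 9 bits per line; the
printed reference code uses 5 of the 6 possible rows, i.e. 32 data bits
and 13 parity bits, which is ~4.3 billion distinct payloads.

Full round trip — generate tablet G-code, embed a random payload, render
a synthetic scan, decode, compare:

```text
$ layermark verify --seed 1
{"status": "ok", "payload_recovered": true, "mean_confidence": 0.968926015391254}
```

`status: ok` means the parity syndrome was already clean; `corrected`
would mean one cell was repaired. Mean confidence near 1 says the groove
displacements measured at essentially the full `a*h` amplitude.

Other subcommands: `embed` (watermark real slicer G-code), `render`
(synthetic scan PNG + ground truth JSON), `decode` (matrix/payload/
confidence JSON from a scan image). Python API mirrors the CLI; see
module docstrings and `docs/methods.md`.

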