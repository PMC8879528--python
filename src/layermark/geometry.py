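"""Tablet geometry, watermark parameters, and bit-patch placement.

An oblong (stadium-shaped) tablet offers two flat faces along its long
axis; only the flat extent ``length - 2*corner_radius`` can carry bit
columns.  Vertically, each bit row occupies a pair of adjacent layers whose
thicknesses are modulated to ``h(1-a)/h(1+a)`` (bit 0) or ``h(1+a)/h(1-a)``
(bit 1); rows are separated by unmodulated layers, and protective margins
are kept clear above the print bed and below the tablet top because those
layers print least precisely.

Margins are physical lengths in millimetres (default 0.8 mm, i.e. four
layers at the 0.2 mm default layer height), so halving the layer height
doubles the number of rows that fit in a given tablet height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "TabletGeometry",
    "WatermarkParams",
    "PatchPlan",
    "CapacityError",
    "SeamError",
    "layer_count",
    "row_capacity",
    "column_capacity",
    "plan_patch",
]

_EPS = 1e-6  # mm tolerance for layer divisibility


class CapacityError(ValueError):
    """Requested code does not fit the tablet under the given parameters."""


class SeamError(ValueError):
    """The layer seam would fall inside the watermark patch."""


@dataclass(frozen=True)
class TabletGeometry:
    """Oblong tablet dimensions in mm.

    ``length`` is the X extent, ``width`` the Y extent, ``height`` the Z
    (build) extent.  ``corner_radius`` rounds the two ends; the watermarkable
    flat extent on each long face is ``length - 2*corner_radius``.
    """

    length: float
    width: float
    height: float
    corner_radius: float = 2.0

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("all tablet dimensions must be positive")
        if self.corner_radius < 0:
            raise ValueError("corner_radius must be non-negative")
        if 2 * self.corner_radius > min(self.length, self.width) + _EPS:
            raise ValueError("corner_radius too large for the tablet footprint")

    @property
    def flat_extent(self) -> float:
        """Usable straight length of a long face, in mm."""
        return self.length - 2 * self.corner_radius

    @property
    def flat_x_range(self) -> tuple[float, float]:
        """X interval of the flat face region (tablet origin at x=0)."""
        return (self.corner_radius, self.length - self.corner_radius)


@dataclass(frozen=True)
class WatermarkParams:
    """Embedding parameters.

    layer_height : nominal layer height h in mm (0.2 default; 0.1 supported).
    amplitude : modulation fraction a of h; the encoding pair prints at
        thicknesses h(1-a) and h(1+a).
    separating_layers : unmodulated layers between vertically adjacent rows.
    margin_bottom, margin_top : keep-clear heights in mm at bed and tablet top.
    bit_cell_width : horizontal extent of one bit cell in mm.
    ramp : horizontal transition length at cell boundaries in mm (one
        extrusion width by default) over which the surface shift fades in/out.
    extrusion_width : nominal track width in mm.
    """

    layer_height: float = 0.2
    amplitude: float = 0.25
    separating_layers: int = 2
    margin_bottom: float = 0.8
    margin_top: float = 0.8
    bit_cell_width: float = 1.6
    ramp: float = 0.4
    extrusion_width: float = 0.4

    def __post_init__(self) -> None:
        if self.layer_height <= 0:
            raise ValueError("layer_height must be positive")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.separating_layers < 2:
            raise ValueError("at least two separating layers are required")
        if self.margin_bottom < 0 or self.margin_top < 0:
            raise ValueError("margins must be non-negative")
        if self.bit_cell_width <= 2 * self.ramp:
            raise ValueError("bit_cell_width must exceed twice the ramp length")

    @property
    def delta_z(self) -> float:
        """Absolute surface shift a*h of a modulated boundary, in mm."""
        return self.amplitude * self.layer_height


@dataclass(frozen=True)
class PatchPlan:
    """Placement of a code matrix on one tablet face.

    ``rows`` lists the encoding layer pairs (k, k+1), 1-based from the first
    printed layer, ordered bottom-up.  ``columns`` lists the x-intervals in
    mm, left-to-right.  ``row_order`` maps matrix row 0 to the ``"top"``
    (default, matching how codes are read off a scan) or ``"bottom"``
    physical row.
    """

    face: str
    columns: tuple[tuple[float, float], ...]
    rows: tuple[tuple[int, int], ...]
    row_order: str = "top"
    seam_x: float = 0.0

    def __post_init__(self) -> None:
        if self.face not in ("+y", "-y"):
            raise ValueError("face must be '+y' or '-y'")
        if self.row_order not in ("top", "bottom"):
            raise ValueError("row_order must be 'top' or 'bottom'")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    @property
    def x_range(self) -> tuple[float, float]:
        return (self.columns[0][0], self.columns[-1][1])

    def matrix_row_for_physical(self, i: int) -> int:
        """Matrix row index for bottom-up physical row ``i``."""
        return self.n_rows - 1 - i if self.row_order == "top" else i

    def modulated_boundary_layer(self, i: int) -> int:
        """Layer index k of the displaced boundary (top of the lower
        encoding layer) for bottom-up physical row ``i``."""
        return self.rows[i][0]


def layer_count(geometry: TabletGeometry, h: float) -> int:
    """Number of printed layers for the tablet height at layer height h."""
    if h <= 0:
        raise ValueError("layer height must be positive")
    ratio = geometry.height / h
    n = int(round(ratio))
    if abs(ratio - n) > _EPS * max(1.0, ratio):
        warnings.warn(
            f"height {geometry.height} mm is not a multiple of h={h} mm; "
            f"flooring to {math.floor(ratio)} layers",
            stacklevel=2,
        )
        n = math.floor(ratio)
    return n


def _margin_layers(margin_mm: float, h: float) -> int:
    return math.ceil(margin_mm / h - _EPS)


def row_capacity(geometry: TabletGeometry, params: WatermarkParams) -> int:
    """Maximum number of bit rows that fit in the tablet height.

    Solves ceil(margin_bottom/h) + 2n + s(n-1) + ceil(margin_top/h)
    <= layer_count for the largest integer n >= 0.
    """
    h = params.layer_height
    total = layer_count(geometry, h)
    mb = _margin_layers(params.margin_bottom, h)
    mt = _margin_layers(params.margin_top, h)
    s = params.separating_layers
    n = (total - mb - mt + s) // (2 + s)
    return max(0, n)


def column_capacity(geometry: TabletGeometry, params: WatermarkParams) -> int:
    """Maximum number of bit columns across the flat extent."""
    if geometry.flat_extent <= 0:
        return 0
    return int(geometry.flat_extent / params.bit_cell_width + _EPS)


def plan_patch(
    geometry: TabletGeometry,
    params: WatermarkParams,
    n_rows: int,
    n_cols: int,
    face: str = "-y",
    seam_x: float = 0.0,
    row_order: str = "top",
) -> PatchPlan:
    """Place an ``n_rows x n_cols`` code on ``face``.

    Rows are packed greedily from the bottom margin upward; columns are
    packed contiguously and centred in the flat extent (tie-break toward -X
    when a half-cell offset would be needed).  Raises :class:`CapacityError`
    when the code does not fit and :class:`SeamError` when the perimeter
    seam would land inside the patch.
    """
    max_rows = row_capacity(geometry, params)
    if n_rows > max_rows:
        raise CapacityError(
            f"{n_rows} rows requested but only {max_rows} fit: "
            f"height {geometry.height} mm at h={params.layer_height} mm with "
            f"margins {params.margin_bottom}/{params.margin_top} mm and "
            f"{params.separating_layers} separating layers"
        )
    max_cols = column_capacity(geometry, params)
    if n_cols > max_cols:
        raise CapacityError(
            f"{n_cols} columns requested but only {max_cols} fit: flat extent "
            f"{geometry.flat_extent:.3f} mm at cell width {params.bit_cell_width} mm"
        )
    if n_rows < 1 or n_cols < 1:
        raise CapacityError("the patch needs at least one row and one column")

    h = params.layer_height
    m = _margin_layers(params.margin_bottom, h)
    s = params.separating_layers
    rows = tuple((m + 1 + i * (2 + s), m + 2 + i * (2 + s)) for i in range(n_rows))

    patch_width = n_cols * params.bit_cell_width
    x0 = geometry.length / 2 - patch_width / 2
    # Snap toward -X so interval endpoints stay on a clean 0.1 um grid,
    # then clamp to the flat extent (the snap can undershoot by one grid
    # step when the patch fills the extent exactly).
    x0 = max(math.floor(x0 * 1e4) / 1e4, geometry.flat_x_range[0])
    columns = tuple(
        (x0 + c * params.bit_cell_width, x0 + (c + 1) * params.bit_cell_width)
        for c in range(n_cols)
    )
    flat_lo, flat_hi = geometry.flat_x_range
    if columns[0][0] < flat_lo - _EPS or columns[-1][1] > flat_hi + _EPS:
        raise CapacityError("columns fall outside the flat extent")

    if columns[0][0] - params.ramp <= seam_x <= columns[-1][1] + params.ramp:
        raise SeamError(
            f"layer seam at x={seam_x} mm lies inside the patch "
            f"[{columns[0][0]}, {columns[-1][1]}] mm; relocate the seam"
        )

    return PatchPlan(face=face, columns=columns, rows=rows, row_order=row_order, seam_x=seam_x)
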