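"""Decode the bit matrix from a grayscale scan of the tablet's flat side.

In a parallel-orientation scan, every layer boundary shows as a dark groove
at a pitch of one layer height (9.45 px at 0.2 mm / 1200 dpi).  Inside a
bit cell the groove between the two encoding layers is displaced by
``±a*h`` from the regular grid — toward the tablet top for a 1 (lower
layer thicker), toward the bed for a 0.  The decoder is blind to the
payload but knows the layout (rows, columns, cell width, layer height,
amplitude): it locates the patch from the periodic banding, traces the
grooves per bit-column strip with sub-pixel valley detection, fits the
reference grid to the unmodulated separating-layer boundaries only, and
reads each bit from the sign of the local displacement.  The recovered
matrix then passes through the 2-D parity corrector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from . import codec
from .codec import BitMatrix, DecodeStatus
from .geometry import PatchPlan, TabletGeometry, WatermarkParams

__all__ = [
    "ScanImage",
    "LocatedPatch",
    "BoundaryTrace",
    "DecodeResult",
    "AperiodicError",
    "load_scan",
    "locate_patch",
    "trace_boundaries",
    "extract_bits",
    "decode_image",
]

MM_PER_INCH = 25.4


class AperiodicError(ValueError):
    """No periodic layer banding at the expected pitch was found."""


@dataclass
class ScanImage:
    """Calibrated grayscale raster; row 0 is the image top (tablet top)."""

    image: np.ndarray  # float in [0, 1]
    dpi: float = 1200.0
    roi: tuple[int, int, int, int] | None = None  # (x0, y0, x1, y1)
    orientation: str = "parallel"

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("scan image must be 2-D grayscale")
        self.image = img
        if self.roi is not None:
            x0, y0, x1, y1 = self.roi
            h, w = img.shape
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError("ROI outside raster")

    @property
    def px_per_mm(self) -> float:
        return self.dpi / MM_PER_INCH


def load_scan(path, dpi: float = 1200.0, orientation: str = "parallel") -> ScanImage:
    """Read a PNG/TIFF scan; color is collapsed by luminance."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return ScanImage(arr, dpi=dpi, orientation=orientation)


@dataclass
class LocatedPatch:
    """Patch rectangle plus the coordinate maps the tracer needs."""

    box: tuple[int, int, int, int]  # (x0, y0, x1, y1) pixels
    strips: tuple[tuple[int, int], ...]  # per-column x ranges
    x_center_px: float  # image x of the tablet length midpoint
    y_bed: float  # image y of z = 0
    y_top: float  # image y of z = height
    pitch: float  # px per layer


@dataclass
class BoundaryTrace:
    """Detected layer-boundary grooves in one bit-column strip."""

    positions: np.ndarray  # sub-pixel y, strictly increasing
    scores: np.ndarray  # per-boundary contrast (prominence)
    phase: float  # reference grid: y(j) = phase - j * pitch
    pitch: float
    matched: dict[int, float]  # boundary layer-index -> measured y


@dataclass
class DecodeResult:
    matrix: BitMatrix | None
    payload: codec.Payload | None
    status: DecodeStatus
    confidence: np.ndarray
    flags: tuple[str, ...] = ()
    corrected_positions: tuple[tuple[int, int], ...] = field(default_factory=tuple)


def _normalize(img: np.ndarray) -> np.ndarray:
    """Linear rescale to full dynamic range (scanner gain is upstream)."""
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-9:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _crop(scan: ScanImage) -> tuple[np.ndarray, int, int]:
    if scan.roi is None:
        return scan.image, 0, 0
    x0, y0, x1, y1 = scan.roi
    return scan.image[y0:y1, x0:x1], x0, y0


def locate_patch(
    scan: ScanImage,
    plan: PatchPlan,
    geometry: TabletGeometry,
    params: WatermarkParams,
) -> LocatedPatch:
    """Find the patch rectangle and bit-column strips.

    The flat extent is found from the x-range with strong high-frequency
    vertical structure (the layer grooves); periodicity at the expected
    pitch is verified by autocorrelation; the bed and top silhouette lines
    anchor the layer indexing.  Raises :class:`AperiodicError` when no
    banding at the expected pitch exists.
    """
    img, ox, oy = _crop(scan)
    ppm = scan.px_per_mm
    pitch0 = params.layer_height * ppm
    dark = 1.0 - _normalize(img)

    # columns with groove energy = flat extent of the face
    hp = dark - gaussian_filter1d(dark, sigma=1.5 * pitch0, axis=0)
    energy = gaussian_filter1d(hp.std(axis=0), sigma=0.5 * ppm)
    if energy.max() < 0.02:
        raise AperiodicError("no layer banding found (uniform image?)")
    above = np.nonzero(energy > 0.5 * energy.max())[0]
    xl, xr = int(above[0]), int(above[-1])
    if xr - xl < 2:
        raise AperiodicError("banding region is degenerate")

    profile = dark[:, xl : xr + 1].mean(axis=1)
    prof_hp = profile - gaussian_filter1d(profile, sigma=1.5 * pitch0)
    # periodicity check at the expected pitch (+/- 20 %)
    ac = np.correlate(prof_hp, prof_hp, mode="full")[len(prof_hp) - 1 :]
    if ac[0] <= 0:
        raise AperiodicError("flat intensity profile")
    ac = ac / ac[0]
    lo_lag = max(2, int(0.8 * pitch0))
    hi_lag = min(len(ac) - 1, int(np.ceil(1.2 * pitch0)))
    if hi_lag <= lo_lag or ac[lo_lag : hi_lag + 1].max() < 0.15:
        raise AperiodicError(
            f"no periodicity at expected pitch {pitch0:.2f} px (+/- 20 %)"
        )

    valleys, props = find_peaks(prof_hp, distance=max(2, 0.6 * pitch0), prominence=0.0)
    if len(valleys) < 3:
        raise AperiodicError("fewer than three grooves detected")
    prom = props["prominences"]
    strong = valleys[prom > 0.25 * np.median(prom[np.argsort(prom)[-10:]])]
    y_top = float(strong[0])
    y_bed = float(strong[-1])
    n_layers = int(round(geometry.height / params.layer_height))
    pitch = (y_bed - y_top) / n_layers
    if not 0.8 * pitch0 <= pitch <= 1.2 * pitch0:
        # silhouette edges unusable; fall back to the expected pitch
        pitch = pitch0
        y_bed = y_top + pitch * n_layers

    x_center = 0.5 * (xl + xr)
    mm_mid = geometry.length / 2.0

    def x_px(x_mm: float) -> float:
        return x_center + (x_mm - mm_mid) * ppm

    # sample only the plateau of each cell: the ramps at the cell edges
    # carry a reduced shift and would dilute the measured displacement
    strips = tuple(
        (int(round(x_px(x0m + params.ramp))), int(round(x_px(x1m - params.ramp))))
        for x0m, x1m in plan.columns
    )
    k_lo = plan.rows[0][0] - 1  # bottom of lowest encoding pair
    k_hi = plan.rows[-1][1]  # top of highest encoding pair
    box = (
        int(round(x_px(plan.x_range[0]))) + ox,
        int(np.floor(y_bed - k_hi * pitch)) + oy,
        int(round(x_px(plan.x_range[1]))) + ox,
        int(np.ceil(y_bed - k_lo * pitch)) + oy,
    )
    if scan.roi is not None:
        box = scan.roi
    return LocatedPatch(
        box=box,
        strips=tuple((s0 + ox, s1 + ox) for s0, s1 in strips),
        x_center_px=x_center + ox,
        y_bed=y_bed + oy,
        y_top=y_top + oy,
        pitch=pitch,
    )


def _subpixel(prof: np.ndarray, idx: int) -> float:
    """Quadratic sub-pixel refinement of a peak position."""
    if idx <= 0 or idx >= len(prof) - 1:
        return float(idx)
    y0, y1, y2 = prof[idx - 1], prof[idx], prof[idx + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def trace_boundaries(
    scan: ScanImage,
    located: LocatedPatch,
    strip: tuple[int, int],
    plan: PatchPlan,
    params: WatermarkParams,
) -> BoundaryTrace:
    """Trace groove positions in one strip and fit the reference grid.

    Valleys of the column-averaged darkness profile are refined to
    sub-pixel accuracy; the reference lattice ``y(j) = phase - j*pitch`` is
    fitted ONLY to separating-layer boundaries, which are unmodulated by
    construction, so the modulated grooves cannot bias it.
    """
    img = scan.image
    x0, x1 = strip
    x0 = max(0, x0)
    x1 = min(img.shape[1], x1)
    dark = 1.0 - _normalize(img[:, x0:x1])
    profile = dark.mean(axis=1)
    prof_hp = profile - gaussian_filter1d(profile, sigma=1.5 * located.pitch)
    prof_sm = gaussian_filter1d(prof_hp, sigma=max(0.08 * located.pitch, 0.6))

    idx, props = find_peaks(
        prof_sm, distance=max(2, 0.55 * located.pitch), prominence=0.0
    )
    positions = np.array([_subpixel(prof_sm, i) for i in idx])
    scores = props["prominences"]

    modulated = {plan.modulated_boundary_layer(i) for i in range(plan.n_rows)}
    k_lo = plan.rows[0][0] - params.separating_layers - 1
    k_hi = plan.rows[-1][1] + params.separating_layers + 1
    n_layers = int(round((located.y_bed - located.y_top) / located.pitch))
    k_lo = max(0, k_lo)
    k_hi = min(n_layers, k_hi)

    js, ys = [], []
    for j in range(k_lo, k_hi + 1):
        if j in modulated:
            continue
        y_exp = located.y_bed - j * located.pitch
        if len(positions) == 0:
            continue
        d = np.abs(positions - y_exp)
        m = int(np.argmin(d))
        if d[m] <= 0.35 * located.pitch:
            js.append(j)
            ys.append(positions[m])
    if len(js) >= 2:
        slope, intercept = np.polyfit(js, ys, 1)
        pitch_fit, phase = -float(slope), float(intercept)
        if not 0.8 * located.pitch <= pitch_fit <= 1.2 * located.pitch:
            pitch_fit, phase = located.pitch, located.y_bed
    else:
        pitch_fit, phase = located.pitch, located.y_bed

    matched = {j: float(y) for j, y in zip(js, ys)}
    return BoundaryTrace(
        positions=positions,
        scores=np.asarray(scores, dtype=float),
        phase=phase,
        pitch=pitch_fit,
        matched=matched,
    )


def extract_bits(
    traces: list[BoundaryTrace],
    plan: PatchPlan,
    params: WatermarkParams,
    scan: ScanImage | None = None,
) -> tuple[BitMatrix, np.ndarray]:
    """Read one bit per cell from the modulated-boundary displacement.

    Displacement of the measured groove from the reference grid toward the
    tablet top (smaller image y) means the lower encoding layer is thicker:
    bit 1.  Confidence is ``|displacement| / (a*h)`` clipped to [0, 1].  A
    cell whose groove is missing gets confidence 0 and its bit from the
    darkness-centroid sign in the expected window.
    """
    n_rows, n_cols = plan.n_rows, plan.n_cols
    cells = np.zeros((n_rows, n_cols), dtype=np.uint8)
    conf = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        j = plan.modulated_boundary_layer(i)
        mrow = plan.matrix_row_for_physical(i)
        for c in range(n_cols):
            tr = traces[c]
            y_ref = tr.phase - j * tr.pitch
            full_shift = params.amplitude * params.layer_height * (tr.pitch / params.layer_height)
            disp = None
            if len(tr.positions):
                d = np.abs(tr.positions - y_ref)
                m = int(np.argmin(d))
                if d[m] <= 0.45 * tr.pitch:
                    disp = y_ref - float(tr.positions[m])
            if disp is None:
                conf[mrow, c] = 0.0
                cells[mrow, c] = 0
                continue
            cells[mrow, c] = 1 if disp > 0 else 0
            conf[mrow, c] = min(abs(disp) / full_shift, 1.0) if full_shift > 0 else 0.0
    return BitMatrix(cells), conf


def decode_image(
    scan: ScanImage,
    plan: PatchPlan,
    geometry: TabletGeometry,
    params: WatermarkParams,
) -> DecodeResult:
    """Full pipeline: locate -> trace -> extract -> parity-correct."""
    shape = (plan.n_rows, plan.n_cols)
    try:
        located = locate_patch(scan, plan, geometry, params)
    except AperiodicError:
        return DecodeResult(
            matrix=None,
            payload=None,
            status=DecodeStatus.FAILED,
            confidence=np.zeros(shape),
            flags=("aperiodic",),
        )

    traces = [
        trace_boundaries(scan, located, strip, plan, params)
        for strip in located.strips
    ]
    flags: list[str] = []
    expected = plan.n_rows + (plan.n_rows - 1) * params.separating_layers
    if any(len(t.positions) < expected for t in traces):
        flags.append("low_contrast")
    resid = _grid_residual(traces)
    if resid > 0.12 * located.pitch:
        flags.append("roughness")

    matrix, conf = extract_bits(traces, plan, params, scan)
    result = codec.correct(matrix)
    return DecodeResult(
        matrix=result.matrix if result.status != DecodeStatus.FAILED else matrix,
        payload=result.payload,
        status=result.status,
        confidence=conf,
        flags=tuple(flags),
        corrected_positions=result.corrected_positions,
    )


def _grid_residual(traces: list[BoundaryTrace]) -> float:
    """RMS residual of separating boundaries about the fitted grids, px."""
    res = []
    for tr in traces:
        for j, y in tr.matched.items():
            res.append(y - (tr.phase - j * tr.pitch))
    if not res:
        return float("inf")
    return float(np.sqrt(np.mean(np.square(res))))
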