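"""Synthetic flat-side scan rendering with material-artifact presets.

No public dataset of watermarked-tablet scans exists, so embedding and
decoding are exercised against rendered side views: horizontal dark
grooves at every layer boundary (pitch = layer height), the groove between
each cell's encoding layers displaced by ``±a*h`` with ramped transitions,
and material artifacts layered on top — surface-roughness jitter and
speckle, gas-bubble blobs, specular reflections (perpendicular scan
orientation), an illumination gradient, optical blur, sensor noise, and a
transparency factor that washes out contrast.  Presets map the qualitative
print-material outcomes (opaque PLA-like prints decodable; transparent,
rough, or bubbly prints not) onto parameter bundles; the numeric values
are calibration choices of this package, not measured material constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .codec import BitMatrix
from .gcode import shift_profile
from .geometry import PatchPlan, TabletGeometry, WatermarkParams
from .imaging import ScanImage

__all__ = [
    "SynthParams",
    "MaterialPreset",
    "RenderTruth",
    "render_scan",
    "material_preset",
    "PRESET_NAMES",
]

BORDER_MM = 1.0  # white margin around the tablet silhouette
_BG = 0.92  # scanner background level
_BODY = 0.78  # tablet body level


@dataclass(frozen=True)
class SynthParams:
    """Renderer knobs; all artifact strengths are non-negative.

    dpi : scan resolution (1200 default).
    groove_contrast : darkness of a layer groove, fraction of range.
    groove_width_px : Gaussian sigma of the groove line profile.
    noise_sigma : additive Gaussian noise, fraction of dynamic range.
    blur_px : Gaussian optical blur sigma.
    illumination_gradient : relative brightness change across the image.
    roughness_sigma_mm : random boundary displacement from surface
        roughness (correlated along x over ``roughness_corr_mm``); also
        drives a proportional surface-speckle texture.
    specular_density : bright reflection blobs per mm^2 (perpendicular
        orientation artifact).
    bubble_density : bright gas-bubble blobs per mm^2.
    transparency : global contrast washout toward the background, 0-1.
    orientation : "parallel" (canonical) or "perpendicular".
    """

    dpi: float = 1200.0
    groove_contrast: float = 0.35
    groove_width_px: float = 2.0
    noise_sigma: float = 0.05
    blur_px: float = 1.0
    illumination_gradient: float = 0.0
    roughness_sigma_mm: float = 0.003
    roughness_corr_mm: float = 0.8
    specular_density: float = 0.0
    bubble_density: float = 0.0
    transparency: float = 0.0
    orientation: str = "parallel"

    def __post_init__(self) -> None:
        if self.orientation not in ("parallel", "perpendicular"):
            raise ValueError("orientation must be 'parallel' or 'perpendicular'")
        for name in (
            "groove_contrast",
            "noise_sigma",
            "blur_px",
            "roughness_sigma_mm",
            "specular_density",
            "bubble_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.transparency <= 1:
            raise ValueError("transparency must lie in [0, 1]")
        if not 0 <= self.groove_contrast <= 1:
            raise ValueError("groove_contrast must lie in [0, 1]")


@dataclass(frozen=True)
class MaterialPreset:
    name: str
    synth: SynthParams
    decodable: bool
    note: str


@dataclass
class RenderTruth:
    """Ground truth the renderer records for validation."""

    ppm: float
    patch_box: tuple[int, int, int, int]  # (x0, y0, x1, y1) px
    grid_y: np.ndarray  # nominal y of boundary j = index, px
    modulated_y: dict[tuple[int, int], float]  # (physical row, col) -> displaced y px
    flat_x_px: tuple[float, float]


def render_scan(
    matrix: BitMatrix,
    plan: PatchPlan,
    geometry: TabletGeometry,
    params: WatermarkParams,
    synth: SynthParams | None = None,
    seed: int = 0,
) -> tuple[ScanImage, RenderTruth]:
    """Render a side-view scan of the watermarked tablet.

    Deterministic for a fixed seed.  Artifacts are applied in physical
    order: roughness jitter -> grooves -> bubbles/specular -> illumination
    -> blur -> noise -> transparency.
    """
    if (matrix.n_rows, matrix.n_cols) != (plan.n_rows, plan.n_cols):
        raise ValueError(
            f"matrix {matrix.n_rows}x{matrix.n_cols} does not match plan "
            f"{plan.n_rows}x{plan.n_cols}"
        )
    synth = synth or SynthParams()
    rng = np.random.default_rng(seed)
    ppm = synth.dpi / 25.4
    h = params.layer_height
    L, H = geometry.length, geometry.height
    W_px = int(round((L + 2 * BORDER_MM) * ppm))
    H_px = int(round((H + 2 * BORDER_MM) * ppm))
    n_layers = int(round(H / h))

    def x_px(x_mm: float) -> float:
        return (BORDER_MM + x_mm) * ppm

    def y_px(z_mm: float) -> float:
        return (BORDER_MM + H - z_mm) * ppm

    img = np.full((H_px, W_px), _BG)
    ox0, ox1 = int(round(x_px(0.0))), int(round(x_px(L)))
    oy0, oy1 = int(round(y_px(H))), int(round(y_px(0.0)))
    img[oy0:oy1, ox0:ox1] = _BODY

    flat_lo, flat_hi = geometry.flat_x_range
    xs_mm = np.arange(W_px) / ppm - BORDER_MM
    on_object = (xs_mm >= 0) & (xs_mm <= L)
    on_flat = (xs_mm >= flat_lo) & (xs_mm <= flat_hi)

    # boundary z as a function of x, for j = 0 .. n_layers
    boundary_z = np.tile((np.arange(n_layers + 1) * h)[:, None], (1, W_px))
    modulated = {}
    for i in range(plan.n_rows):
        j = plan.modulated_boundary_layer(i)
        mrow = plan.matrix_row_for_physical(i)
        nodes_x, nodes_d = shift_profile(matrix.cells[mrow], plan, params)
        boundary_z[j] += np.interp(xs_mm, nodes_x, nodes_d, left=0.0, right=0.0)
        modulated[i] = j

    # surface roughness: smooth random displacement per boundary, plus a
    # proportional speckle texture that mimics scattered light
    if synth.roughness_sigma_mm > 0:
        corr_px = max(synth.roughness_corr_mm * ppm, 1.0)
        for j in range(1, n_layers):  # silhouette edges stay straight
            noise = rng.standard_normal(W_px)
            noise = gaussian_filter1d(noise, sigma=corr_px)
            sd = noise.std()
            if sd > 0:
                boundary_z[j] += noise / sd * synth.roughness_sigma_mm
        speckle_amp = min(1.5 * synth.roughness_sigma_mm / h, 0.6)
        speckle = rng.standard_normal((H_px, W_px))
        speckle = gaussian_filter(speckle, sigma=(0.05 * ppm, 0.1 * ppm))
        sd = speckle.std()
        if sd > 0:
            img[oy0:oy1, ox0:ox1] += (speckle_amp * speckle / sd * 0.2)[
                oy0:oy1, ox0:ox1
            ]

    # grooves: Gaussian-profile dark lines; weaker on the rounded caps,
    # weaker everywhere in perpendicular orientation
    contrast_x = np.where(on_flat, synth.groove_contrast, 0.3 * synth.groove_contrast)
    contrast_x = contrast_x * on_object
    if synth.orientation == "perpendicular":
        contrast_x = contrast_x * 0.35
    yy = np.arange(H_px)[:, None]
    sig = synth.groove_width_px
    for j in range(n_layers + 1):
        yb = y_px(0) - boundary_z[j] * ppm  # y decreases as z grows
        cx = contrast_x.copy()
        if j in (0, n_layers):
            cx = np.where(on_object, 0.55, 0.0)  # silhouette edges
        img -= cx[None, :] * np.exp(-0.5 * ((yy - yb[None, :]) / sig) ** 2)

    # bright blobs: gas bubbles anywhere on the body, speculars in the patch
    def blobs(count_area_mm2: float, density: float, x_range, z_range, amp=0.85):
        n = rng.poisson(density * count_area_mm2)
        for _ in range(n):
            bx = rng.uniform(*x_range)
            bz = rng.uniform(*z_range)
            ax = rng.uniform(0.1, 0.45) * ppm
            az = rng.uniform(0.08, 0.3) * ppm
            cxp, cyp = x_px(bx), y_px(bz)
            x_lo = max(0, int(cxp - 4 * ax))
            x_hi = min(W_px, int(cxp + 4 * ax) + 1)
            y_lo = max(0, int(cyp - 4 * az))
            y_hi = min(H_px, int(cyp + 4 * az) + 1)
            if x_hi <= x_lo or y_hi <= y_lo:
                continue
            gx = np.arange(x_lo, x_hi)
            gy = np.arange(y_lo, y_hi)[:, None]
            m = np.exp(-0.5 * (((gx - cxp) / ax) ** 2 + ((gy - cyp) / az) ** 2))
            region = img[y_lo:y_hi, x_lo:x_hi]
            img[y_lo:y_hi, x_lo:x_hi] = region * (1 - m) + amp * m

    if synth.bubble_density > 0:
        blobs(L * H, synth.bubble_density, (0, L), (0, H), amp=0.9)
    if synth.orientation == "perpendicular" and synth.specular_density > 0:
        px0, px1 = plan.x_range
        z_lo = (plan.rows[0][0] - 1) * h
        z_hi = plan.rows[-1][1] * h
        blobs(
            (px1 - px0) * (z_hi - z_lo),
            synth.specular_density,
            (px0, px1),
            (z_lo, z_hi),
            amp=0.98,
        )

    if synth.illumination_gradient > 0:
        ramp = 1.0 + synth.illumination_gradient * (
            np.linspace(0, 1, W_px) - 0.5
        )
        img = img * ramp[None, :]

    # transparency washes out the *object's* contrast; optical blur and
    # sensor noise act afterwards, so a washed-out scan cannot be rescued
    # by contrast normalization
    if synth.transparency > 0:
        img = img * (1 - synth.transparency) + _BG * synth.transparency
    if synth.blur_px > 0:
        img = gaussian_filter(img, sigma=synth.blur_px)
    if synth.noise_sigma > 0:
        img = img + rng.normal(0.0, synth.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    # ground truth
    grid_y = np.array([y_px(j * h) for j in range(n_layers + 1)])
    modulated_y = {}
    for i, j in modulated.items():
        for c, (cx0, cx1) in enumerate(plan.columns):
            xc = 0.5 * (cx0 + cx1)
            zc = float(np.interp(xc, xs_mm, boundary_z[j]))
            modulated_y[(i, c)] = y_px(zc)
    k_lo, k_hi = plan.rows[0][0] - 1, plan.rows[-1][1]
    truth = RenderTruth(
        ppm=ppm,
        patch_box=(
            int(x_px(plan.x_range[0])),
            int(y_px(k_hi * h)),
            int(np.ceil(x_px(plan.x_range[1]))),
            int(np.ceil(y_px(k_lo * h))),
        ),
        grid_y=grid_y,
        modulated_y=modulated_y,
        flat_x_px=(x_px(flat_lo), x_px(flat_hi)),
    )
    return ScanImage(img, dpi=synth.dpi, orientation=synth.orientation), truth


# ---------------------------------------------------------------------------
# material presets: qualitative print-material outcomes -> parameter bundles

_PRESETS: dict[str, MaterialPreset] = {
    "smooth_opaque": MaterialPreset(
        "smooth_opaque",
        SynthParams(),
        decodable=True,
        note="opaque, smooth print (PLA- or EC-like); grooves crisp",
    ),
    "colored_opaque": MaterialPreset(
        "colored_opaque",
        SynthParams(groove_contrast=0.30, noise_sigma=0.06),
        decodable=True,
        note="opaque colored print (colorant-loaded PVA-like)",
    ),
    "transparent_reflective": MaterialPreset(
        "transparent_reflective",
        SynthParams(transparency=0.92, noise_sigma=0.06),
        decodable=False,
        note="translucent, reflective print (pure PVA-like); contrast washed out",
    ),
    "rough": MaterialPreset(
        "rough",
        SynthParams(roughness_sigma_mm=0.075),
        decodable=False,
        note="rough extrudate surface (ERL-like); boundaries jittered beyond a*h",
    ),
    "bubbly": MaterialPreset(
        "bubbly",
        SynthParams(bubble_density=5.0, noise_sigma=0.06),
        decodable=False,
        note="overheated print with gas bubbles obscuring the layer pattern",
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def material_preset(name: str) -> MaterialPreset:
    """Look up a material preset by name.

    Presets span both regimes: ``smooth_opaque`` and ``colored_opaque``
    decode; ``transparent_reflective``, ``rough``, and ``bubbly`` do not.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {', '.join(_PRESETS)}"
        ) from None


def preset_with(name: str, **overrides) -> SynthParams:
    """Preset parameters with selected fields replaced."""
    return replace(material_preset(name).synth, **overrides)
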