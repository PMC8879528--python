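"""Marlin/Prusa G-code parsing, watermark embedding, and serialization.

The embedder modulates the printed layer thickness locally: inside each bit
cell on the chosen flat face, the *lower* layer of the cell's encoding pair
has its top surface shifted by ``+a*h`` (bit 1) or ``-a*h`` (bit 0), while
the upper layer keeps its nominal top z.  The pair's thicknesses are then
``h(1+a)/h(1-a)`` or ``h(1-a)/h(1+a)`` and always sum to ``2h``, so the
object height, the layer count, the seam position, and the print time are
unchanged.  Extrusion is rescaled linearly with local thickness so the
deposited volume follows the modulated geometry.

Only G0/G1 motion in absolute XYZ (G90) is supported; extrusion may be
absolute (M82) or relative (M83) and is normalized to per-move amounts.
Unknown commands pass through verbatim.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .codec import BitMatrix
from .geometry import PatchPlan, TabletGeometry, WatermarkParams

__all__ = [
    "GcodeCommand",
    "GcodeLayer",
    "GcodeDocument",
    "WallSegment",
    "UnsupportedDialectError",
    "EmptyDocumentError",
    "EmbeddingError",
    "FaceDetectionError",
    "parse_gcode",
    "write_gcode",
    "find_face_segments",
    "embed_watermark",
    "shift_profile",
    "generate_oblong_gcode",
    "total_extrusion",
    "total_path_length",
]

_E_TOL = 1e-9
_WORD_RE = re.compile(r"([A-Za-z])\s*(-?\d+\.?\d*)")


class UnsupportedDialectError(ValueError):
    """G-code uses a dialect outside the supported Marlin subset."""


class EmptyDocumentError(ValueError):
    """No extruding moves found — nothing is printed."""


class EmbeddingError(ValueError):
    """Document and plan are inconsistent for embedding."""


class FaceDetectionError(ValueError):
    """The requested flat face was not found on one or more layers."""


@dataclass(eq=False)
class GcodeCommand:
    """One G-code line with parsed motion state.

    ``raw`` holds the original text for verbatim round-trip; synthesized
    commands have ``raw=None`` and are formatted on write.  Positions are
    absolute mm *after* the move; ``e_rel`` is the filament length extruded
    by this move (negative = retraction).
    """

    raw: str | None
    verb: str = ""
    px: float = 0.0
    py: float = 0.0
    pz: float = 0.0
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    e_rel: float = 0.0
    e_abs: float | None = None  # absolute E after move, if M82 mode
    f: float | None = None
    has_xy: bool = False
    has_f: bool = False
    emit_z: bool = False  # synthesized commands: write explicit Z

    @property
    def is_motion(self) -> bool:
        return self.verb in ("G0", "G1")

    @property
    def is_extruding(self) -> bool:
        return self.is_motion and self.e_rel > _E_TOL and self.has_xy


@dataclass
class GcodeLayer:
    """Commands of one printed layer with its top-surface z."""

    z_top: float
    thickness: float
    commands: list[GcodeCommand] = field(default_factory=list)


@dataclass
class GcodeDocument:
    preamble: list[GcodeCommand] = field(default_factory=list)
    layers: list[GcodeLayer] = field(default_factory=list)
    postamble: list[GcodeCommand] = field(default_factory=list)
    extrusion_absolute: bool = False
    has_layer_markers: bool = False

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def max_z(self) -> float:
        return self.layers[-1].z_top if self.layers else 0.0

    def all_commands(self):
        yield from self.preamble
        for layer in self.layers:
            yield from layer.commands
        yield from self.postamble


@dataclass(frozen=True)
class WallSegment:
    """A maximal straight outer-wall run on one face of one layer.

    ``x_extent`` is clipped to the geometry's flat region: the wall just
    beyond the roundings starts at a near-tangent angle and can pass the
    straightness test, but it is not watermarkable surface.
    """

    layer_index: int  # 1-based
    face: str
    command_indices: tuple[int, ...]  # indices into the layer's command list
    points: tuple[tuple[float, float], ...]
    x_extent: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------
# parsing

def parse_gcode(text: str) -> GcodeDocument:
    """Parse Marlin-flavor G-code into a layered document.

    Layers are detected from PrusaSlicer ``;LAYER_CHANGE`` markers when
    present, otherwise from Z increases on extruding moves (z-hop travels
    are ignored).  Raises :class:`UnsupportedDialectError` on G91 or arc
    moves and :class:`EmptyDocumentError` when nothing is extruded.
    """
    commands: list[GcodeCommand] = []
    marker_indices: list[int] = []
    x = y = z = 0.0
    e_abs = 0.0
    e_mode_abs = True  # Marlin default is absolute E
    any_abs_e = False
    feed: float | None = None

    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith(";") and "LAYER_CHANGE" in stripped:
            marker_indices.append(len(commands))
        code = stripped.split(";", 1)[0].strip()
        words = _WORD_RE.findall(code) if code else []
        if not words:
            commands.append(GcodeCommand(raw=line, verb=""))
            continue
        verb = words[0][0].upper() + str(int(float(words[0][1])))
        params = {k.upper(): float(v) for k, v in words[1:]}

        if verb in ("G2", "G3"):
            raise UnsupportedDialectError("arc moves (G2/G3) are not supported")
        if verb == "G91":
            raise UnsupportedDialectError(
                "relative XYZ positioning (G91) is not supported"
            )

        cmd = GcodeCommand(raw=line, verb=verb)
        if verb in ("G0", "G1"):
            cmd.px, cmd.py, cmd.pz = x, y, z
            x = params.get("X", x)
            y = params.get("Y", y)
            z = params.get("Z", z)
            if "F" in params:
                feed = params["F"]
                cmd.has_f = True
            cmd.x, cmd.y, cmd.z = x, y, z
            cmd.f = feed
            cmd.has_xy = "X" in params or "Y" in params
            if "E" in params:
                if e_mode_abs:
                    cmd.e_rel = params["E"] - e_abs
                    e_abs = params["E"]
                    cmd.e_abs = e_abs
                    any_abs_e = True
                else:
                    cmd.e_rel = params["E"]
        elif verb == "G92":
            if "E" in params:
                e_abs = params["E"]
                cmd.e_abs = e_abs
            x = params.get("X", x)
            y = params.get("Y", y)
            z = params.get("Z", z)
        elif verb == "M82":
            e_mode_abs = True
        elif verb == "M83":
            e_mode_abs = False
        # G90 and everything else: passthrough
        commands.append(cmd)

    ext_indices = [i for i, c in enumerate(commands) if c.is_extruding]
    if not ext_indices:
        raise EmptyDocumentError("no extruding moves in document")
    last_ext = ext_indices[-1]

    doc = GcodeDocument(
        extrusion_absolute=any_abs_e,
        has_layer_markers=bool(marker_indices),
    )
    doc.postamble = commands[last_ext + 1 :]

    if marker_indices:
        doc.preamble = commands[: marker_indices[0]]
        bounds = marker_indices + [last_ext + 1]
        spans = [
            (bounds[i], min(bounds[i + 1], last_ext + 1))
            for i in range(len(marker_indices))
            if bounds[i] <= last_ext
        ]
    else:
        spans = _layer_spans(commands, ext_indices)
        doc.preamble = commands[: spans[0][0]]

    prev_z = 0.0
    for start, stop in spans:
        group = commands[start:stop]
        ext = [c for c in group if c.is_extruding]
        if not ext:
            continue
        z_top = max(c.z for c in ext)
        if z_top <= prev_z + 1e-9:
            raise UnsupportedDialectError(
                f"layer z {z_top} does not increase past {prev_z} (non-planar?)"
            )
        doc.layers.append(
            GcodeLayer(z_top=z_top, thickness=z_top - prev_z, commands=group)
        )
        prev_z = z_top
    return doc


def _layer_spans(commands, ext_indices):
    """Index spans (start, stop) of each layer, split at extruding-z jumps."""
    layer_z: list[float] = []
    last_in_layer: list[int] = []
    for i in ext_indices:
        zi = commands[i].z
        if not layer_z or zi > layer_z[-1] + 1e-9:
            layer_z.append(zi)
            last_in_layer.append(i)
        else:
            last_in_layer[-1] = i

    # layer 1 begins at the first motion command that sets Z or XY
    first = next(
        i
        for i, c in enumerate(commands)
        if c.is_motion and (c.has_xy or c.z != c.pz or c.z > 0)
    )
    spans = []
    start = first
    for stop in last_in_layer:
        spans.append((start, stop + 1))
        start = stop + 1
    return spans


# ---------------------------------------------------------------------------
# serialization

def _fmt(value: float, decimals: int = 5) -> str:
    s = f"{value:.{decimals}f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def write_gcode(doc: GcodeDocument) -> str:
    """Serialize the document; unmodified lines are emitted verbatim."""
    out: list[str] = []
    e_emit = 0.0  # running absolute E actually emitted (M82 documents)
    for cmd in doc.all_commands():
        if cmd.raw is not None:
            if cmd.e_abs is not None:
                e_emit = cmd.e_abs
            out.append(cmd.raw)
            continue
        if cmd.verb == "G92":
            e_emit = cmd.e_abs or 0.0
            out.append(f"G92 E{_fmt(e_emit)}")
            continue
        parts = [cmd.verb, f"X{_fmt(cmd.x)}", f"Y{_fmt(cmd.y)}"]
        if cmd.emit_z:
            parts.append(f"Z{_fmt(cmd.z)}")
        if abs(cmd.e_rel) > _E_TOL:
            if doc.extrusion_absolute:
                e_emit += cmd.e_rel
                parts.append(f"E{_fmt(e_emit)}")
            else:
                parts.append(f"E{_fmt(cmd.e_rel)}")
        if cmd.has_f and cmd.f is not None:
            parts.append(f"F{_fmt(cmd.f)}")
        out.append(" ".join(parts))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# face detection

def find_face_segments(
    doc: GcodeDocument,
    geometry: TabletGeometry,
    face: str = "-y",
    extrusion_width: float = 0.4,
    layer_indices: list[int] | None = None,
    min_length: float = 2.0,
) -> dict[int, WallSegment]:
    """Locate the straight outer-wall run on ``face`` for each layer.

    A wall move belongs to the face when its direction is within 5 degrees
    of the X axis and both endpoints lie within ``1.5 * extrusion_width``
    of the layer's y extreme on that side.  Runs shorter than
    ``min_length`` mm are rejected (a curved wall always has a short
    near-horizontal stretch at its extreme).  Returns the longest maximal
    run per layer, keyed by 1-based layer index; raises
    :class:`FaceDetectionError` listing layers where no run exists.
    """
    if face not in ("+y", "-y"):
        raise ValueError("face must be '+y' or '-y'")
    sign = -1.0 if face == "-y" else 1.0
    want = layer_indices or list(range(1, doc.n_layers + 1))
    tan_tol = math.tan(math.radians(5.0))
    band = 1.5 * extrusion_width
    segments: dict[int, WallSegment] = {}
    missing: list[int] = []

    for li in want:
        layer = doc.layers[li - 1]
        ys: list[float] = []
        for c in layer.commands:
            if c.is_extruding:
                ys += [c.y, c.py]
        if not ys:
            missing.append(li)
            continue
        y_extreme = min(ys) if sign < 0 else max(ys)

        def on_face(cmd: GcodeCommand) -> bool:
            if not cmd.is_extruding:
                return False
            dx, dy = cmd.x - cmd.px, cmd.y - cmd.py
            if abs(dx) < 1e-9:
                return False
            return (
                abs(dy) <= abs(dx) * tan_tol
                and abs(cmd.y - y_extreme) <= band
                and abs(cmd.py - y_extreme) <= band
            )

        best: list[int] = []
        run: list[int] = []
        for idx, cmd in enumerate(layer.commands):
            if on_face(cmd):
                run.append(idx)
            else:
                if len(run) > len(best):
                    best = run
                run = []
        if len(run) > len(best):
            best = run
        if best:
            x_lo = min(layer.commands[best[0]].px, layer.commands[best[-1]].x)
            x_hi = max(layer.commands[best[0]].px, layer.commands[best[-1]].x)
            if x_hi - x_lo < min_length:
                best = []
        if not best:
            missing.append(li)
            continue
        first_cmd = layer.commands[best[0]]
        pts = [(first_cmd.px, first_cmd.py)]
        pts += [(layer.commands[i].x, layer.commands[i].y) for i in best]
        xs = [p[0] for p in pts]
        flat_lo, flat_hi = geometry.flat_x_range
        extent = (max(min(xs), flat_lo), min(max(xs), flat_hi))
        segments[li] = WallSegment(li, face, tuple(best), tuple(pts), extent)

    if missing:
        raise FaceDetectionError(f"no straight {face} wall run found on layers {missing}")
    return segments


# ---------------------------------------------------------------------------
# surface-shift profile shared by the embedder and the synthetic renderer

def shift_profile(
    bits_row: np.ndarray,
    plan: PatchPlan,
    params: WatermarkParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear boundary displacement (mm) along x for one bit row.

    Returns node arrays ``(xs, dz)`` for ``numpy.interp``: each cell holds a
    plateau at ``+a*h`` (bit 1) or ``-a*h`` (bit 0) trimmed by the ramp
    length at both edges, with linear transitions between cells and down to
    zero at the patch edges.  Outside the patch the shift is zero.
    """
    dz_mag = params.delta_z
    xs = [plan.columns[0][0]]
    ds = [0.0]
    for c, (x0, x1) in enumerate(plan.columns):
        d = dz_mag if bits_row[c] else -dz_mag
        xs += [x0 + params.ramp, x1 - params.ramp]
        ds += [d, d]
    xs.append(plan.columns[-1][1])
    ds.append(0.0)
    return np.asarray(xs), np.asarray(ds)


# ---------------------------------------------------------------------------
# embedding

def embed_watermark(
    doc: GcodeDocument,
    matrix: BitMatrix,
    plan: PatchPlan,
    params: WatermarkParams,
    geometry: TabletGeometry | None = None,
) -> GcodeDocument:
    """Embed the code matrix into the document (returns a modified copy).

    For every bit cell, wall moves of the lower encoding layer inside the
    cell's x-interval are split at the shift-profile breakpoints and their
    top z displaced by the local shift; the upper encoding layer keeps its
    nominal z.  Extrusion of both layers is rescaled by local thickness / h,
    so deposited volume tracks the modulated geometry and the pair's total
    is conserved.
    """
    if (matrix.n_rows, matrix.n_cols) != (plan.n_rows, plan.n_cols):
        raise EmbeddingError(
            f"matrix is {matrix.n_rows}x{matrix.n_cols} but plan is "
            f"{plan.n_rows}x{plan.n_cols}"
        )
    h = params.layer_height
    needed = sorted({k for pair in plan.rows for k in pair})
    if needed[-1] > doc.n_layers:
        raise EmbeddingError("plan requires more layers than the document has")
    for k in needed:
        if abs(doc.layers[k - 1].thickness - h) > 1e-4:
            raise EmbeddingError(
                f"layer {k} has thickness {doc.layers[k - 1].thickness:.4f} mm, "
                f"expected {h} mm"
            )

    out = GcodeDocument(
        preamble=list(doc.preamble),
        layers=[GcodeLayer(l.z_top, l.thickness, list(l.commands)) for l in doc.layers],
        postamble=list(doc.postamble),
        extrusion_absolute=doc.extrusion_absolute,
        has_layer_markers=doc.has_layer_markers,
    )
    geom = geometry or TabletGeometry(1e6, 1e6, doc.max_z + 1.0, 0.0)
    segments = find_face_segments(
        doc, geom, plan.face, params.extrusion_width, layer_indices=needed
    )

    for i in range(plan.n_rows):
        mrow = plan.matrix_row_for_physical(i)
        xs, ds = shift_profile(matrix.cells[mrow], plan, params)
        k_lower, k_upper = plan.rows[i]
        _modulate_layer(out.layers[k_lower - 1], segments[k_lower], xs, ds, params, lower=True)
        _modulate_layer(out.layers[k_upper - 1], segments[k_upper], xs, ds, params, lower=False)
    return out


def _modulate_layer(layer, segment, xs, ds, params, lower: bool):
    """Split & rewrite the face wall moves of one encoding layer."""
    h = params.layer_height
    replacements: dict[int, list[GcodeCommand]] = {}
    for idx in segment.command_indices:
        cmd = layer.commands[idx]
        xa, xb = cmd.px, cmd.x
        lo, hi = min(xa, xb), max(xa, xb)
        if hi <= xs[0] + 1e-9 or lo >= xs[-1] - 1e-9:
            continue  # move entirely outside the patch
        cuts = sorted(
            (x for x in xs if lo + 1e-9 < x < hi - 1e-9), reverse=xa > xb
        )
        breaks = [xa] + list(cuts) + [xb]
        length = abs(xb - xa)
        total_scale = _profile_scale(xa, xb, xs, ds, h, lower)
        pieces: list[GcodeCommand] = []
        e_done = 0.0
        for j in range(len(breaks) - 1):
            x0, x1 = breaks[j], breaks[j + 1]
            frac = abs(x1 - x0) / length
            t1 = (x1 - xa) / (xb - xa)
            yj = cmd.py + (cmd.y - cmd.py) * t1
            d0 = float(np.interp(x0, xs, ds))
            d1 = float(np.interp(x1, xs, ds))
            scale = (h + 0.5 * (d0 + d1)) / h if lower else (h - 0.5 * (d0 + d1)) / h
            if j < len(breaks) - 2:
                e_piece = cmd.e_rel * frac * scale
                e_done += e_piece
            else:
                # last piece absorbs rounding so the move total is exact
                e_piece = cmd.e_rel * total_scale - e_done
            pieces.append(
                GcodeCommand(
                    raw=None,
                    verb="G1",
                    px=breaks[j],
                    py=cmd.py + (cmd.y - cmd.py) * ((breaks[j] - xa) / (xb - xa)),
                    pz=cmd.pz,
                    x=x1,
                    y=yj,
                    z=cmd.z + d1 if lower else cmd.z,
                    e_rel=e_piece,
                    f=cmd.f,
                    has_xy=True,
                    has_f=cmd.has_f and j == 0,
                    emit_z=lower,
                )
            )
        if cmd.e_abs is not None:
            pieces.append(GcodeCommand(raw=None, verb="G92", e_abs=cmd.e_abs))
        replacements[idx] = pieces

    if not replacements:
        return
    new_commands: list[GcodeCommand] = []
    for idx, cmd in enumerate(layer.commands):
        new_commands.extend(replacements.get(idx, [cmd]))
    layer.commands = new_commands


def _profile_scale(xa, xb, xs, ds, h, lower: bool) -> float:
    """Exact mean thickness scale of a move under the piecewise-linear shift."""
    lo, hi = min(xa, xb), max(xa, xb)
    nodes = [lo] + [x for x in xs if lo < x < hi] + [hi]
    total = 0.0
    for j in range(len(nodes) - 1):
        d0 = float(np.interp(nodes[j], xs, ds))
        d1 = float(np.interp(nodes[j + 1], xs, ds))
        total += (nodes[j + 1] - nodes[j]) * 0.5 * (d0 + d1)
    mean_d = total / (hi - lo)
    return (h + mean_d) / h if lower else (h - mean_d) / h


# ---------------------------------------------------------------------------
# bookkeeping helpers

def total_extrusion(doc: GcodeDocument) -> float:
    """Total filament length extruded, mm."""
    return sum(c.e_rel for c in doc.all_commands() if c.is_motion and c.e_rel > 0)


def total_path_length(doc: GcodeDocument) -> float:
    """Total XY travel of motion commands, mm (a print-time proxy at
    constant feedrate)."""
    return sum(
        math.hypot(c.x - c.px, c.y - c.py) for c in doc.all_commands() if c.is_motion
    )


# ---------------------------------------------------------------------------
# synthetic G-code generation (test fixture source; no slicer required)

def generate_oblong_gcode(
    geometry: TabletGeometry,
    params: WatermarkParams,
    layer_markers: bool = True,
    relative_e: bool = True,
    cap_segments: int = 12,
    feedrate: float = 600.0,
) -> str:
    """Generate single-perimeter G-code for an oblong tablet.

    Each layer is one closed outer-perimeter loop of a rounded rectangle
    (a stadium when ``corner_radius = width/2``), always started at the same
    seam point on the left end cap so the seam never enters the patch.
    Extrusion uses a 1.75 mm filament volume model, relative (M83) by
    default.
    """
    h = params.layer_height
    ew = params.extrusion_width
    n_layers = int(round(geometry.height / h))
    inset = ew / 2.0
    r = max(geometry.corner_radius - inset, 0.0)
    cx0, cx1 = geometry.corner_radius, geometry.length - geometry.corner_radius
    cy0, cy1 = geometry.corner_radius, geometry.width - geometry.corner_radius
    filament_area = math.pi * (1.75 / 2.0) ** 2

    def arc(cx, cy, a0, a1):
        return [
            (cx + r * math.cos(t), cy + r * math.sin(t))
            for t in np.linspace(a0, a1, cap_segments + 1)
        ]

    # counterclockwise loop; seam at the leftmost edge, x = inset
    loop: list[tuple[float, float]] = []
    loop += arc(cx0, cy0, math.pi, 1.5 * math.pi)  # left-bottom corner
    loop.append((cx1, inset))  # -y face
    loop += arc(cx1, cy0, 1.5 * math.pi, 2.0 * math.pi)
    loop.append((geometry.length - inset, cy1))  # right side
    loop += arc(cx1, cy1, 0.0, 0.5 * math.pi)
    loop.append((cx0, geometry.width - inset))  # +y face
    loop += arc(cx0, cy1, 0.5 * math.pi, math.pi)
    loop.append((inset, cy0))  # close the left side
    clean = [loop[0]]
    for p in loop[1:]:
        if math.hypot(p[0] - clean[-1][0], p[1] - clean[-1][1]) > 1e-9:
            clean.append(p)
    if math.hypot(clean[0][0] - clean[-1][0], clean[0][1] - clean[-1][1]) > 1e-9:
        clean.append(clean[0])

    lines = [
        "; synthetic oblong tablet (layermark fixture generator)",
        "G90",
        "M83" if relative_e else "M82",
        "G28 ; home",
    ]
    e_abs = 0.0
    for k in range(1, n_layers + 1):
        z = k * h
        if layer_markers:
            lines.append(";LAYER_CHANGE")
            lines.append(f";Z:{_fmt(z)}")
        lines.append(f"G1 Z{_fmt(z)} F{_fmt(feedrate)}")
        x0, y0 = clean[0]
        lines.append(f"G0 X{_fmt(x0)} Y{_fmt(y0)}")
        for (xa, ya), (xb, yb) in zip(clean[:-1], clean[1:]):
            dist = math.hypot(xb - xa, yb - ya)
            e = dist * ew * h / filament_area
            if relative_e:
                lines.append(f"G1 X{_fmt(xb)} Y{_fmt(yb)} E{_fmt(e)}")
            else:
                e_abs += e
                lines.append(f"G1 X{_fmt(xb)} Y{_fmt(yb)} E{_fmt(e_abs)}")
    lines += ["M104 S0", "M140 S0", "M84"]
    return "\n".join(lines) + "\n"
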