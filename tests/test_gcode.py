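"""G-code parsing, embedding invariants, and serialization round trips."""

import numpy as np
import pytest

from layermark import codec
from layermark.gcode import (
    EmbeddingError,
    EmptyDocumentError,
    FaceDetectionError,
    UnsupportedDialectError,
    embed_watermark,
    find_face_segments,
    generate_oblong_gcode,
    parse_gcode,
    shift_profile,
    total_extrusion,
    total_path_length,
    write_gcode,
)
from layermark.geometry import TabletGeometry, WatermarkParams, plan_patch

TWO_LAYER_SNIPPET = """\
G90
M83
G1 Z0.2 F600
G0 X1 Y1
G1 X9 Y1 E0.5
G1 X9 Y9 E0.5
G1 X1 Y9 E0.5
G1 X1 Y1 E0.5
G1 Z0.4
G0 X1 Y1
G1 X9 Y1 E0.5
G1 X9 Y9 E0.5
G1 X1 Y9 E0.5
G1 X1 Y1 E0.5
M84
"""


class TestParse:
    def test_two_layer_snippet(self):
        doc = parse_gcode(TWO_LAYER_SNIPPET)
        assert doc.n_layers == 2
        assert [l.thickness for l in doc.layers] == pytest.approx([0.2, 0.2])
        assert doc.max_z == pytest.approx(0.4)
        assert doc.postamble[-1].raw == "M84"

    def test_marker_and_heuristic_agree(self, small_tablet, default_params):
        """Layer structure is identical with and without ;LAYER_CHANGE."""
        with_markers = parse_gcode(
            generate_oblong_gcode(small_tablet, default_params, layer_markers=True)
        )
        without = parse_gcode(
            generate_oblong_gcode(small_tablet, default_params, layer_markers=False)
        )
        assert with_markers.n_layers == without.n_layers == 20
        for a, b in zip(with_markers.layers, without.layers):
            assert a.z_top == pytest.approx(b.z_top)
            assert a.thickness == pytest.approx(b.thickness)
            ea = sum(c.e_rel for c in a.commands if c.is_extruding)
            eb = sum(c.e_rel for c in b.commands if c.is_extruding)
            assert ea == pytest.approx(eb)

    def test_g91_rejected(self):
        with pytest.raises(UnsupportedDialectError):
            parse_gcode("G91\nG1 X5 E1\n")

    def test_arc_rejected(self):
        with pytest.raises(UnsupportedDialectError):
            parse_gcode("G90\nG2 X5 Y5 I2 J0 E1\n")

    def test_no_extrusion_rejected(self):
        with pytest.raises(EmptyDocumentError):
            parse_gcode("G90\nG0 X5 Y5\nG0 Z1\n")

    def test_zhop_is_not_a_layer(self):
        text = TWO_LAYER_SNIPPET.replace(
            "G1 X9 Y9 E0.5\nG1 X1 Y9 E0.5\nG1 X1 Y1 E0.5\nG1 Z0.4",
            "G1 X9 Y9 E0.5\nG1 Z0.6\nG0 X5 Y5\nG1 Z0.2\n"
            "G1 X1 Y9 E0.5\nG1 X1 Y1 E0.5\nG1 Z0.4",
            1,
        )
        doc = parse_gcode(text)
        assert doc.n_layers == 2

    def test_absolute_extrusion_normalized(self):
        text = TWO_LAYER_SNIPPET.replace("M83", "M82")
        lines = []
        e = 0.0
        for line in text.splitlines():
            if "E0.5" in line:
                e += 0.5
                line = line.replace("E0.5", f"E{e}")
            lines.append(line)
        doc = parse_gcode("\n".join(lines))
        assert doc.extrusion_absolute
        assert total_extrusion(doc) == pytest.approx(4.0)


class TestFaceSegments:
    def test_small_oblong_minus_y_extent(self, small_tablet, default_params):
        doc = parse_gcode(generate_oblong_gcode(small_tablet, default_params))
        segs = find_face_segments(doc, small_tablet, "-y", layer_indices=[5])
        x0, x1 = segs[5].x_extent
        assert x0 == pytest.approx(2.0, abs=0.3)
        assert x1 == pytest.approx(10.0, abs=0.3)

    def test_large_oblong_flat_length(self, large_tablet, default_params):
        doc = parse_gcode(generate_oblong_gcode(large_tablet, default_params))
        segs = find_face_segments(doc, large_tablet, "-y", layer_indices=[10])
        x0, x1 = segs[10].x_extent
        assert x1 - x0 == pytest.approx(15.0, abs=0.5)

    def test_cylinder_has_no_flat_face(self, default_params):
        round_geo = TabletGeometry(8.0, 8.0, 4.0, 4.0)
        doc = parse_gcode(generate_oblong_gcode(round_geo, default_params))
        with pytest.raises(FaceDetectionError):
            find_face_segments(doc, round_geo, "-y", layer_indices=[5])


@pytest.fixture(scope="module")
def embedded_pair(request):
    """Original and embedded document for a checkerboard 3x3 code."""
    geo = TabletGeometry(12.0, 4.0, 4.0, 2.0)
    params = WatermarkParams()
    plan = plan_patch(geo, params, 3, 3)
    matrix = codec.encode([0, 1, 1, 0], 3, 3)
    doc = parse_gcode(generate_oblong_gcode(geo, params))
    embedded = embed_watermark(doc, matrix, plan, params, geo)
    return geo, params, plan, matrix, doc, embedded


class TestEmbed:
    def test_height_exactly_conserved(self, embedded_pair):
        *_, doc, embedded = embedded_pair
        assert embedded.max_z == doc.max_z

    def test_layer_count_unchanged(self, embedded_pair):
        *_, doc, embedded = embedded_pair
        assert embedded.n_layers == doc.n_layers

    def test_modulated_z_matches_bits(self, embedded_pair):
        """At each cell center the lower layer's wall z is shifted by
        exactly +a*h (bit 1) or -a*h (bit 0); the upper layer stays
        nominal, so the pair's thicknesses sum to 2h."""
        geo, params, plan, matrix, doc, embedded = embedded_pair
        reparsed = parse_gcode(write_gcode(embedded))
        h, a = params.layer_height, params.amplitude
        for i in range(plan.n_rows):
            k_lo, k_up = plan.rows[i]
            mrow = plan.matrix_row_for_physical(i)
            for c, (x0, x1) in enumerate(plan.columns):
                xc = 0.5 * (x0 + x1)
                expected = h * a if matrix.cells[mrow, c] else -h * a
                z_lo = _wall_z_at(reparsed.layers[k_lo - 1], xc)
                z_up = _wall_z_at(reparsed.layers[k_up - 1], xc)
                assert z_lo - k_lo * h == pytest.approx(expected, abs=1e-4)
                assert z_up == pytest.approx(k_up * h, abs=1e-4)
                thick_lo = z_lo - (k_lo - 1) * h
                thick_up = k_up * h - z_lo
                assert thick_lo + thick_up == pytest.approx(2 * h, abs=1e-4)

    def test_extrusion_conserved(self, embedded_pair):
        geo, params, plan, matrix, doc, embedded = embedded_pair
        e0 = total_extrusion(doc)
        assert abs(total_extrusion(embedded) - e0) / e0 < 0.005
        all_one = codec.BitMatrix(np.ones((3, 3), dtype=np.uint8) * 0 + 1)
        all_zero = codec.BitMatrix(np.zeros((3, 3), dtype=np.uint8))
        e_one = total_extrusion(embed_watermark(doc, all_one, plan, params, geo))
        e_zero = total_extrusion(embed_watermark(doc, all_zero, plan, params, geo))
        assert abs(e_one - e_zero) / e0 < 0.005
        assert abs(e_one - e0) / e0 < 0.005

    def test_path_length_and_command_count(self, embedded_pair):
        *_, doc, embedded = embedded_pair
        p0 = total_path_length(doc)
        assert abs(total_path_length(embedded) - p0) / p0 < 0.01
        n0 = sum(1 for _ in doc.all_commands())
        n1 = sum(1 for _ in embedded.all_commands())
        assert abs(n1 - n0) / n0 < 0.2  # split moves only, no new travel

    def test_seam_unchanged(self, embedded_pair):
        """Every layer's perimeter still starts at the same point."""
        *_, doc, embedded = embedded_pair
        for la, lb in zip(doc.layers, embedded.layers):
            fa = next(c for c in la.commands if c.is_extruding)
            fb = next(c for c in lb.commands if c.is_extruding)
            assert (fa.px, fa.py) == (fb.px, fb.py)

    def test_round_trip_preserves_modulation(self, embedded_pair):
        *_, embedded = embedded_pair
        reparsed = parse_gcode(write_gcode(embedded))
        again = parse_gcode(write_gcode(reparsed))
        za = [c.z for l in reparsed.layers for c in l.commands if c.is_extruding]
        zb = [c.z for l in again.layers for c in l.commands if c.is_extruding]
        assert za == pytest.approx(zb, abs=1e-4)

    def test_matrix_plan_size_mismatch(self, embedded_pair):
        geo, params, plan, *_ , doc, _ = embedded_pair
        wrong = codec.encode(list(np.zeros(16, dtype=int)), 5, 5)
        with pytest.raises(EmbeddingError):
            embed_watermark(doc, wrong, plan, params, geo)

    def test_wrong_layer_height_rejected(self, embedded_pair):
        geo, params, plan, matrix, doc, _ = embedded_pair
        thin = WatermarkParams(layer_height=0.1)
        with pytest.raises(EmbeddingError):
            embed_watermark(doc, matrix, plan, thin, geo)

    def test_absolute_e_document_resynced(self, small_tablet, default_params):
        """Embedding an M82 document keeps downstream E targets valid."""
        text = generate_oblong_gcode(small_tablet, default_params, relative_e=False)
        doc = parse_gcode(text)
        plan = plan_patch(small_tablet, default_params, 3, 3)
        matrix = codec.encode([1, 0, 0, 1], 3, 3)
        embedded = embed_watermark(doc, matrix, plan, default_params, small_tablet)
        reparsed = parse_gcode(write_gcode(embedded))
        e0 = total_extrusion(doc)
        assert abs(total_extrusion(reparsed) - e0) / e0 < 0.005


class TestShiftProfile:
    def test_plateau_and_ramp(self, small_plan, default_params):
        bits = np.array([1, 0, 1])
        xs, ds = shift_profile(bits, small_plan, default_params)
        dz = default_params.delta_z
        x0, x1 = small_plan.columns[0]
        assert np.interp(0.5 * (x0 + x1), xs, ds) == pytest.approx(dz)
        assert np.interp(x0, xs, ds) == pytest.approx(0.0)
        xm0, xm1 = small_plan.columns[1]
        assert np.interp(0.5 * (xm0 + xm1), xs, ds) == pytest.approx(-dz)
        # transition midpoint between cells crosses zero
        assert np.interp(xm0, xs, ds) == pytest.approx(0.0, abs=1e-9)

    def test_zero_outside_patch(self, small_plan, default_params):
        xs, ds = shift_profile(np.array([1, 1, 1]), small_plan, default_params)
        assert np.interp(small_plan.columns[0][0] - 1.0, xs, ds, left=0.0) == 0.0


def _wall_z_at(layer, x_mm):
    """z of the -y outer wall at x, from the move covering that x."""
    best = None
    y_min = min(c.y for c in layer.commands if c.is_extruding)
    for c in layer.commands:
        if not c.is_extruding or abs(c.y - y_min) > 0.6:
            continue
        lo, hi = min(c.px, c.x), max(c.px, c.x)
        if lo - 1e-9 <= x_mm <= hi + 1e-9:
            best = c
    assert best is not None
    return best.z


class TestWriteGcode:
    def test_two_layer_round_trip(self):
        doc = parse_gcode(TWO_LAYER_SNIPPET)
        again = parse_gcode(write_gcode(doc))
        assert again.n_layers == doc.n_layers
        assert [l.z_top for l in again.layers] == [l.z_top for l in doc.layers]

    def test_unmodified_document_is_verbatim(self):
        assert write_gcode(parse_gcode(TWO_LAYER_SNIPPET)) == TWO_LAYER_SNIPPET

    def test_postamble_preserved(self, small_tablet, default_params):
        text = generate_oblong_gcode(small_tablet, default_params)
        out = write_gcode(parse_gcode(text))
        assert out.rstrip().splitlines()[-3:] == ["M104 S0", "M140 S0", "M84"]
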