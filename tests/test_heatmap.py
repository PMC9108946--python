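import xml.etree.ElementTree as ET

import pytest

from ecoconverge import (
    DEFAULT_RAMP,
    HeatmapStyle,
    arrow_glyph,
    build_matrix,
    color_for,
    render_heatmap,
)
from ecoconverge.heatmap import DEFAULT_STYLE, render_svg, srgb_lightness

from conftest import make_score


def one_cell_matrix(ns=1, cp=-1):
    return build_matrix(
        [make_score("NS", "A", "coral", "past", ns)],
        [make_score("CP", "A", "coral", "past", cp)],
    )


class TestColorFor:
    def test_centre_is_lightest(self):
        centre = color_for(0)
        assert all(
            srgb_lightness(centre) >= srgb_lightness(color_for(d))
            for d in range(-4, 5)
        )

    def test_extremes_are_ramp_ends(self):
        assert color_for(-4) == DEFAULT_RAMP[0]
        assert color_for(4) == DEFAULT_RAMP[-1]

    def test_lightness_non_increasing_outward(self):
        for k in range(0, 4):
            assert srgb_lightness(color_for(k)) >= srgb_lightness(color_for(k + 1))
            assert srgb_lightness(color_for(-k)) >= srgb_lightness(color_for(-k - 1))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            color_for(5)


class TestStyleValidation:
    def test_ramp_must_have_nine_colours(self):
        with pytest.raises(ValueError, match="9"):
            HeatmapStyle(ramp=("#ffffff",) * 5)

    def test_ramp_lightness_must_peak_at_centre(self):
        bad = list(DEFAULT_RAMP)
        bad[4] = "#000000"  # darkest at the centre
        with pytest.raises(ValueError, match="lightness"):
            HeatmapStyle(ramp=tuple(bad))


class TestArrowGlyph:
    @pytest.mark.parametrize(
        "score, glyph",
        [(2, "steep-up"), (1, "up-slant"), (0, "flat"),
         (-1, "down-slant"), (-2, "steep-down")],
    )
    def test_five_glyphs(self, score, glyph):
        assert arrow_glyph(score) == glyph

    def test_odd_symmetry_of_names(self):
        assert arrow_glyph(-2) == arrow_glyph(2).replace("up", "down")
        assert arrow_glyph(-1) == arrow_glyph(1).replace("up", "down")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            arrow_glyph(3)


class TestRenderSvg:
    def test_one_cell_has_two_arrows_with_distinct_colours(self):
        svg = render_svg(one_cell_matrix())
        root = ET.fromstring(svg)  # well-formed XML
        arrows = [
            g for g in root.iter("{http://www.w3.org/2000/svg}g")
            if "arrow" in g.get("class", "") and "legend" not in g.get("class", "")
        ]
        assert len(arrows) == 2
        colors = set()
        for g in arrows:
            line = g.find("{http://www.w3.org/2000/svg}line")
            colors.add(line.get("stroke"))
        assert colors == {DEFAULT_STYLE.ns_color, DEFAULT_STYLE.cp_color}

    def test_all_zero_matrix_shares_lightest_fill(self):
        ns = [make_score("NS", s, "coral", "past", 0) for s in "ABC"]
        cp = [make_score("CP", s, "coral", "past", 0) for s in "ABC"]
        svg = render_svg(build_matrix(ns, cp))
        root = ET.fromstring(svg)
        fills = {
            r.get("fill")
            for g in root.iter("{http://www.w3.org/2000/svg}g")
            if g.get("class", "").startswith("cell")
            for r in g.iter("{http://www.w3.org/2000/svg}rect")
        }
        assert fills == {DEFAULT_RAMP[4]}

    def test_twelve_cell_fixture_structure(self, matrix12):
        matrix, _, _ = matrix12
        svg = render_svg(matrix)
        root = ET.fromstring(svg)
        cells = [
            g for g in root.iter("{http://www.w3.org/2000/svg}g")
            if g.get("class", "").startswith("cell")
        ]
        assert len(cells) == 12
        # two arrows inside each complete cell
        for g in cells:
            arrows = [
                c for c in g
                if "arrow" in c.get("class", "")
            ]
            assert len(arrows) == 2
        # one header icon per habitat column (2 habitats x 2 directions)
        icons = [
            g for g in root.iter("{http://www.w3.org/2000/svg}g")
            if g.get("class", "").startswith("icon icon-")
        ]
        assert len(icons) == 4

    def test_missing_cells_have_no_arrows(self):
        m = build_matrix([make_score("NS", "A", "seagrass", "past", 0)], [])
        svg = render_svg(m)
        root = ET.fromstring(svg)
        cell = next(
            g for g in root.iter("{http://www.w3.org/2000/svg}g")
            if g.get("class") == "cell missing"
        )
        assert not [c for c in cell if "arrow" in c.get("class", "")]
        assert svg.count('class="arrow arrow-ns') == 1  # legend only

    def test_basic_mode_drops_arrows_and_icons(self, matrix12):
        matrix, _, _ = matrix12
        style = HeatmapStyle(show_arrows=False, show_icons=False)
        svg = render_svg(matrix, style)
        assert "arrow" not in svg and "icon" not in svg

    def test_empty_matrix_rejected(self):
        from ecoconverge.convergence import ConvergenceMatrix

        with pytest.raises(ValueError):
            render_svg(ConvergenceMatrix(sites=(), columns=(), cells=()))


class TestRenderFiles:
    def test_svg_is_byte_stable(self, matrix12, tmp_path):
        matrix, _, _ = matrix12
        p1 = render_heatmap(matrix, DEFAULT_STYLE, tmp_path / "a.svg")
        p2 = render_heatmap(matrix, DEFAULT_STYLE, tmp_path / "b.svg")
        assert p1.read_bytes() == p2.read_bytes()

    def test_png_output(self, matrix12, tmp_path):
        from PIL import Image

        matrix, _, _ = matrix12
        style = HeatmapStyle(output_format="png")
        path = render_heatmap(matrix, style, tmp_path / "m.png")
        img = Image.open(path)
        assert img.size[0] > 100 and img.size[1] > 100
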