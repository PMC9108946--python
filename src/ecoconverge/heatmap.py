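"""Figure-style heat map of NS-CP convergence.

Cells are coloured by the divergence score d on a 9-step diverging ramp
(lightest at d = 0, darkening toward both extremes), and each complete
cell overlays two trend arrows — red for the natural-science score, blue
for the community-perception score — whose steepness encodes the 5-point
trend (+-60 deg strong, +-30 deg mild, flat for 0). Column headers carry a
habitat icon and the time direction; a legend explains ramp and arrows.
Icons and arrows keep the figure readable independent of language and
literacy; a "basic" mode (no arrows/icons) is available via the style.

Rendering goes through a small list of drawing primitives emitted either
as SVG text (byte-stable: no timestamps, no generated ids) or rasterized
to PNG with Pillow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .convergence import ConvergenceMatrix

__all__ = [
    "HeatmapStyle",
    "DEFAULT_RAMP",
    "color_for",
    "arrow_glyph",
    "srgb_lightness",
    "render_heatmap",
    "render_svg",
]

#: 9-step diverging ramp (ColorBrewer RdBu), index = d + 4; centre is the
#: lightest colour so full convergence reads as near-white.
DEFAULT_RAMP = (
    "#b2182b",  # d = -4
    "#d6604d",
    "#f4a582",
    "#fddbc7",
    "#f7f7f7",  # d = 0
    "#d1e5f0",
    "#92c5de",
    "#4393c4",
    "#2166ac",  # d = +4
)

#: Built-in habitat icon glyphs; aquaculture is drawn as shellfish.
DEFAULT_ICONS = {
    "fisheries": "fish",
    "aquaculture": "shellfish",
    "mangrove": "mangrove",
    "coral": "coral",
    "seagrass": "seagrass",
}

ARROW_GLYPHS = {
    -2: "steep-down",
    -1: "down-slant",
    0: "flat",
    1: "up-slant",
    2: "steep-up",
}

#: Arrow slope per score: +-60 deg strong, +-30 deg mild, 0 flat.
ARROW_ANGLES = {-2: -60.0, -1: -30.0, 0: 0.0, 1: 30.0, 2: 60.0}


def _hex_to_rgb(color: str) -> tuple:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))


def srgb_lightness(color: str) -> float:
    """CIE L* (0..100) of a '#rrggbb' colour, via linear sRGB and D65 Y."""
    def linearize(u: float) -> float:
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (linearize(v / 255.0) for v in _hex_to_rgb(color))
    y = 0.2126 * r + 0.7152 * g + 0.0722 * b  # relative luminance, D65
    f = y ** (1.0 / 3.0) if y > (6 / 29) ** 3 else y / (3 * (6 / 29) ** 2) + 4 / 29
    return 116.0 * f - 16.0


@dataclass(frozen=True)
class HeatmapStyle:
    """Display attributes for the convergence heat map."""

    ramp: tuple = DEFAULT_RAMP
    ns_color: str = "#d62728"  # red: natural-science arrow
    cp_color: str = "#1f77b4"  # blue: community-perception arrow
    icons: dict = field(default_factory=lambda: dict(DEFAULT_ICONS))
    missing_fill: str = "#e8e8e8"
    output_format: str = "svg"
    cell_size: float = 64.0
    show_arrows: bool = True
    show_icons: bool = True
    show_legend: bool = True

    def __post_init__(self) -> None:
        if len(self.ramp) != 9:
            raise ValueError(f"ramp must have exactly 9 colours, got {len(self.ramp)}")
        if self.output_format not in ("svg", "png"):
            raise ValueError(
                f"output_format must be 'svg' or 'png', got {self.output_format!r}"
            )
        mid = srgb_lightness(self.ramp[4])
        for k in range(4):
            lo = srgb_lightness(self.ramp[4 - k - 1])
            hi = srgb_lightness(self.ramp[4 + k + 1])
            prev_lo = srgb_lightness(self.ramp[4 - k])
            prev_hi = srgb_lightness(self.ramp[4 + k])
            if lo > prev_lo or hi > prev_hi or lo > mid or hi > mid:
                raise ValueError(
                    "ramp lightness must peak at the centre (d=0) and be "
                    "non-increasing toward both ends"
                )


DEFAULT_STYLE = HeatmapStyle()


def color_for(d: int, style: HeatmapStyle = DEFAULT_STYLE) -> str:
    """Ramp colour for a divergence score; d=0 gets the lightest colour."""
    if d not in range(-4, 5):
        raise ValueError(f"divergence score must be an integer in -4..4, got {d!r}")
    return style.ramp[d + 4]


def arrow_glyph(score: int) -> str:
    """Glyph id for a 5-point trend score (steep-up .. steep-down)."""
    try:
        return ARROW_GLYPHS[score]
    except KeyError:
        raise ValueError(f"score must be an integer in -2..2, got {score!r}") from None


# ---------------------------------------------------------------------------
# drawing primitives: ("rect", x, y, w, h, fill, stroke, css_class)
#                     ("line", x1, y1, x2, y2, color, width, css_class)
#                     ("polygon", points, fill, css_class)
#                     ("text", x, y, s, size, color, anchor)
#                     ("group", css_class, [primitives])

def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return "0" if s == "-0" else s


def _arrow_primitives(
    score: int, cx: float, cy: float, length: float, color: str, css_class: str
) -> tuple:
    """An arrow (shaft + head) centred on (cx, cy), sloped by the score."""
    angle = math.radians(ARROW_ANGLES[score])
    dx = math.cos(angle) * length / 2.0
    dy = -math.sin(angle) * length / 2.0  # screen y grows downward
    x1, y1, x2, y2 = cx - dx, cy - dy, cx + dx, cy + dy
    head = length * 0.3
    spread = math.radians(25.0)
    theta = math.atan2(y2 - y1, x2 - x1)
    hx1 = x2 - head * math.cos(theta - spread)
    hy1 = y2 - head * math.sin(theta - spread)
    hx2 = x2 - head * math.cos(theta + spread)
    hy2 = y2 - head * math.sin(theta + spread)
    return (
        "group",
        css_class,
        [
            ("line", x1, y1, x2, y2, color, 2.2, "shaft"),
            ("polygon", [(x2, y2), (hx1, hy1), (hx2, hy2)], color, "head"),
        ],
    )


def _icon_primitives(glyph: str, cx: float, cy: float, s: float) -> tuple:
    """Small built-in habitat glyph drawn inside a box of half-width s."""
    dark = "#333333"
    if glyph == "fish":
        body = [
            (cx - s, cy), (cx - s * 0.3, cy - s * 0.5), (cx + s * 0.4, cy - s * 0.35),
            (cx + s * 0.8, cy), (cx + s * 0.4, cy + s * 0.35), (cx - s * 0.3, cy + s * 0.5),
        ]
        tail = [(cx - s, cy), (cx - s * 1.4, cy - s * 0.4), (cx - s * 1.4, cy + s * 0.4)]
        prims = [("polygon", body, dark, "body"), ("polygon", tail, dark, "tail")]
    elif glyph == "shellfish":
        shell = [
            (cx, cy + s * 0.6), (cx - s * 0.9, cy - s * 0.2), (cx - s * 0.45, cy - s * 0.6),
            (cx, cy - s * 0.7), (cx + s * 0.45, cy - s * 0.6), (cx + s * 0.9, cy - s * 0.2),
        ]
        prims = [("polygon", shell, dark, "shell")] + [
            ("line", cx, cy + s * 0.6, cx + f * s * 0.55, cy - s * 0.55, dark, 1.0, "rib")
            for f in (-1.0, -0.4, 0.4, 1.0)
        ]
    elif glyph == "mangrove":
        canopy = [
            (cx, cy - s), (cx - s * 0.9, cy - s * 0.1), (cx + s * 0.9, cy - s * 0.1),
        ]
        prims = [
            ("polygon", canopy, dark, "canopy"),
            ("line", cx, cy - s * 0.1, cx, cy + s * 0.4, dark, 2.0, "trunk"),
            ("line", cx, cy + s * 0.4, cx - s * 0.6, cy + s, dark, 1.4, "root"),
            ("line", cx, cy + s * 0.4, cx, cy + s, dark, 1.4, "root"),
            ("line", cx, cy + s * 0.4, cx + s * 0.6, cy + s, dark, 1.4, "root"),
        ]
    elif glyph == "coral":
        prims = [
            ("line", cx, cy + s, cx, cy - s * 0.2, dark, 2.0, "stem"),
            ("line", cx, cy + s * 0.2, cx - s * 0.7, cy - s * 0.7, dark, 1.6, "branch"),
            ("line", cx, cy + s * 0.2, cx + s * 0.7, cy - s * 0.7, dark, 1.6, "branch"),
            ("line", cx - s * 0.35, cy - s * 0.25, cx - s * 0.8, cy - s * 0.1, dark, 1.2, "twig"),
            ("line", cx + s * 0.35, cy - s * 0.25, cx + s * 0.8, cy - s * 0.1, dark, 1.2, "twig"),
        ]
    elif glyph == "seagrass":
        prims = [
            ("line", cx + f * s * 0.5, cy + s, cx + f * s * 0.8, cy - s, dark, 1.6, "blade")
            for f in (-1.0, -0.33, 0.33, 1.0)
        ]
    else:
        prims = [("rect", cx - s, cy - s, 2 * s, 2 * s, "none", dark, "placeholder")]
    return ("group", f"icon icon-{glyph}", prims)


def _build_primitives(matrix: ConvergenceMatrix, style: HeatmapStyle) -> tuple:
    """Lay out the full figure; returns (width, height, primitives)."""
    cs = style.cell_size
    left = 110.0  # row-label gutter
    top = 64.0 if style.show_icons else 40.0
    ncols, nrows = len(matrix.columns), len(matrix.sites)
    grid_w, grid_h = ncols * cs, nrows * cs
    legend_h = 120.0 if style.show_legend else 10.0
    width = left + grid_w + 20.0
    height = top + grid_h + legend_h

    prims: list = [
        ("rect", 0, 0, width, height, "#ffffff", "none", "background")
    ]

    # column headers: habitat icon + direction label
    for j, (habitat, direction) in enumerate(matrix.columns):
        x = left + j * cs + cs / 2.0
        if style.show_icons:
            glyph = style.icons.get(habitat, habitat)
            if isinstance(glyph, str) and not glyph.endswith((".png", ".svg")):
                prims.append(_icon_primitives(glyph, x, 22.0, 12.0))
            prims.append(("text", x, 48.0, direction, 10.0, "#333333", "middle"))
        else:
            prims.append(("text", x, 18.0, habitat, 10.0, "#333333", "middle"))
            prims.append(("text", x, 32.0, direction, 10.0, "#333333", "middle"))

    # row labels
    for i, site in enumerate(matrix.sites):
        y = top + i * cs + cs / 2.0 + 4.0
        prims.append(("text", left - 8.0, y, site, 11.0, "#333333", "end"))

    # cells
    for i, site in enumerate(matrix.sites):
        for j, (habitat, direction) in enumerate(matrix.columns):
            x, y = left + j * cs, top + i * cs
            cell = matrix.cell(site, habitat, direction)
            if cell is None or cell.missing:
                prims.append(
                    ("group", "cell missing", [
                        ("rect", x, y, cs, cs, style.missing_fill, "#bbbbbb", "fill"),
                    ])
                )
                continue
            body = [("rect", x, y, cs, cs, color_for(cell.d, style), "#bbbbbb", "fill")]
            if style.show_arrows:
                body.append(_arrow_primitives(
                    cell.ns_score, x + cs * 0.32, y + cs / 2.0, cs * 0.42,
                    style.ns_color, "arrow arrow-ns",
                ))
                body.append(_arrow_primitives(
                    cell.cp_score, x + cs * 0.68, y + cs / 2.0, cs * 0.42,
                    style.cp_color, "arrow arrow-cp",
                ))
            prims.append(("group", f"cell d{cell.d:+d}", body))

    if style.show_legend:
        ly = top + grid_h + 28.0
        prims.append(("text", left, ly - 10.0,
                      "divergence d = NS score - CP score", 10.0, "#333333", "start"))
        sw = 26.0
        for k, d in enumerate(range(-4, 5)):
            x = left + k * (sw + 4.0)
            prims.append(("group", f"legend-swatch d{d:+d}", [
                ("rect", x, ly, sw, 18.0, style.ramp[d + 4], "#bbbbbb", "fill"),
            ]))
            prims.append(("text", x + sw / 2.0, ly + 32.0, f"{d:+d}" if d else "0",
                          9.0, "#333333", "middle"))
        if style.show_arrows:
            ay = ly + 58.0
            prims.append(_arrow_primitives(1, left + 10.0, ay, 22.0,
                                           style.ns_color, "arrow arrow-ns legend"))
            prims.append(("text", left + 28.0, ay + 4.0,
                          "natural-science trend", 9.0, "#333333", "start"))
            prims.append(_arrow_primitives(1, left + 180.0, ay, 22.0,
                                           style.cp_color, "arrow arrow-cp legend"))
            prims.append(("text", left + 198.0, ay + 4.0,
                          "community-perception trend", 9.0, "#333333", "start"))
    return width, height, prims


# ---------------------------------------------------------------------------
# SVG backend

def _svg_of(p) -> str:
    kind = p[0]
    if kind == "group":
        _, cls, children = p
        inner = "".join(_svg_of(c) for c in children)
        return f'<g class="{cls}">{inner}</g>'
    if kind == "rect":
        _, x, y, w, h, fill, stroke, cls = p
        return (
            f'<rect class="{cls}" x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
            f'height="{_fmt(h)}" fill="{fill}" stroke="{stroke}"/>'
        )
    if kind == "line":
        _, x1, y1, x2, y2, color, w, cls = p
        return (
            f'<line class="{cls}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" '
            f'y2="{_fmt(y2)}" stroke="{color}" stroke-width="{_fmt(w)}" '
            f'stroke-linecap="round"/>'
        )
    if kind == "polygon":
        _, points, fill, cls = p
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        return f'<polygon class="{cls}" points="{pts}" fill="{fill}"/>'
    if kind == "text":
        _, x, y, s, size, color, anchor = p
        return (
            f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-size="{_fmt(size)}" '
            f'font-family="sans-serif" fill="{color}" text-anchor="{anchor}">{s}</text>'
        )
    raise ValueError(f"unknown primitive {kind!r}")


def render_svg(matrix: ConvergenceMatrix, style: HeatmapStyle = DEFAULT_STYLE) -> str:
    """Render the heat map as a deterministic SVG string."""
    if not matrix.cells:
        raise ValueError("cannot render an empty matrix")
    width, height, prims = _build_primitives(matrix, style)
    body = "\n".join(_svg_of(p) for p in prims)
    return (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"{body}\n</svg>\n"
    )


# ---------------------------------------------------------------------------
# PNG backend (same primitives, rasterized with Pillow)

def _draw_png(p, draw, scale: float) -> None:
    from PIL import ImageFont

    kind = p[0]
    if kind == "group":
        for c in p[2]:
            _draw_png(c, draw, scale)
    elif kind == "rect":
        _, x, y, w, h, fill, stroke, _cls = p
        draw.rectangle(
            [x * scale, y * scale, (x + w) * scale, (y + h) * scale],
            fill=None if fill == "none" else fill,
            outline=None if stroke == "none" else stroke,
        )
    elif kind == "line":
        _, x1, y1, x2, y2, color, w, _cls = p
        draw.line(
            [x1 * scale, y1 * scale, x2 * scale, y2 * scale],
            fill=color, width=max(1, round(w * scale)),
        )
    elif kind == "polygon":
        _, points, fill, _cls = p
        draw.polygon([(x * scale, y * scale) for x, y in points], fill=fill)
    elif kind == "text":
        _, x, y, s, size, color, anchor = p
        font = ImageFont.load_default()
        px = x * scale
        if anchor in ("middle", "end"):
            tw = draw.textlength(s, font=font)
            px -= tw if anchor == "end" else tw / 2.0
        draw.text((px, (y - size) * scale), s, fill=color, font=font)


def render_heatmap(
    matrix: ConvergenceMatrix,
    style: HeatmapStyle = DEFAULT_STYLE,
    path: str | Path = "heatmap.svg",
) -> Path:
    """Write the heat map to ``path`` (format from the style tag).

    SVG output is byte-stable for fixed inputs; PNG is rasterized at 2x
    from the same drawing primitives.
    """
    path = Path(path)
    if style.output_format == "svg":
        path.write_text(render_svg(matrix, style), encoding="utf-8")
        return path
    from PIL import Image, ImageDraw

    if not matrix.cells:
        raise ValueError("cannot render an empty matrix")
    scale = 2.0
    width, height, prims = _build_primitives(matrix, style)
    img = Image.new("RGB", (round(width * scale), round(height * scale)), "#ffffff")
    draw = ImageDraw.Draw(img)
    for p in prims:
        _draw_png(p, draw, scale)
    img.save(path, format="PNG")
    return path
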