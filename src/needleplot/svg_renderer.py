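"""Compose the diagram into a deterministic, standalone SVG document.

Layer order, bottom to top: backbone bar, structural motif regions,
domain boxes with their adaptive labels, the data-driven axis, lollipop
stems, lollipop heads, and optional per-variant text labels.  Each head
carries a native SVG ``<title>`` element so hovering in a browser shows
the change text — interactivity with no script dependency.

Determinism contract: identical inputs produce byte-identical output.
All coordinates are rounded to two decimals before formatting, element
emission order is fixed (variants sorted by position then input order),
and the document embeds no timestamps or external references, so the
SVGs are safe golden-file and pipeline artifacts.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Sequence

from . import layout_engine as le
from .layout_engine import DrawConfig
from .pfam_client import ProteinArchitecture
from .variant_parser import Variant

_SVG_NS = "http://www.w3.org/2000/svg"
_FONT_FAMILY = "'DejaVu Sans',sans-serif"


@dataclass(frozen=True)
class SVGDocument:
    """A complete SVG diagram as XML text."""

    content: str

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.content)


def _fmt(value: float) -> str:
    """Format a coordinate with a fixed two-decimal contract."""
    return f"{value + 0.0:.2f}"


def render_svg(
    architecture: ProteinArchitecture,
    variants: Sequence[Variant],
    config: DrawConfig | None = None,
) -> SVGDocument:
    """Render *architecture* and *variants* into an :class:`SVGDocument`.

    Motifs are skipped under ``hide_motifs``; disorder regions are drawn
    only when ``show_disordered`` is set (they are numerous and often
    clutter).  The axis is omitted under ``hide_axis``.  Layout errors
    (variant beyond the protein, stagger overflow) propagate; no partial
    document is ever produced.
    """
    config = config or DrawConfig()
    length = architecture.length

    radii = le.scale_radii(variants, config)
    layout = le.stagger_lollipops(variants, radii, length, config)
    ticks = le.select_ticks(architecture, variants, config)

    height = config.lollipop_zone_height + config.backbone_height + config.axis_height
    backbone_top = config.lollipop_zone_height

    root = ET.Element(
        "svg",
        {
            "xmlns": _SVG_NS,
            "width": _fmt(config.plot_width),
            "height": _fmt(height),
            "viewBox": f"0 0 {_fmt(config.plot_width)} {_fmt(height)}",
        },
    )

    # backbone bar
    usable = config.plot_width - 2 * config.pad
    ET.SubElement(
        root,
        "rect",
        {
            "class": "backbone",
            "x": _fmt(config.pad),
            "y": _fmt(backbone_top),
            "width": _fmt(usable),
            "height": _fmt(config.backbone_height),
            "fill": config.backbone_color,
        },
    )

    # structural motifs, drawn as overlays on the backbone band
    if not config.hide_motifs:
        for motif in architecture.motifs:
            if motif.kind == "disorder" and not config.show_disordered:
                continue
            left, width = le.residue_span_px(motif.start, motif.end, length, config)
            color = config.motif_colors.get(motif.kind, config.backbone_color)
            ET.SubElement(
                root,
                "rect",
                {
                    "class": f"motif motif-{motif.kind}",
                    "x": _fmt(left),
                    "y": _fmt(backbone_top),
                    "width": _fmt(width),
                    "height": _fmt(config.backbone_height),
                    "fill": color,
                },
            )

    # domain boxes with adaptive labels
    domain_pad = 4.0
    for domain in architecture.domains:
        left, width = le.residue_span_px(domain.start, domain.end, length, config)
        group = ET.SubElement(root, "g", {"class": "domain"})
        rect = ET.SubElement(
            group,
            "rect",
            {
                "x": _fmt(left),
                "y": _fmt(backbone_top - domain_pad),
                "width": _fmt(width),
                "height": _fmt(config.backbone_height + 2 * domain_pad),
                "rx": "3.00",
                "fill": domain.color,
            },
        )
        title = ET.SubElement(rect, "title")
        title.text = f"{domain.short_name}: {domain.description}"
        label = le.choose_domain_label(domain, architecture.domains, width, config)
        if label.mode != "hidden":
            text = ET.SubElement(
                group,
                "text",
                {
                    "x": _fmt(left + width / 2),
                    "y": _fmt(backbone_top + config.backbone_height / 2
                              + 0.35 * config.font_size),
                    "text-anchor": "middle",
                    "font-family": _FONT_FAMILY,
                    "font-size": _fmt(config.font_size),
                    "fill": config.domain_text_color,
                },
            )
            text.text = label.text

    # data-driven axis
    if not config.hide_axis:
        axis_top = backbone_top + config.backbone_height
        for tick in ticks.ticks:
            x = le.aa_to_px(tick.position, length, config)
            ET.SubElement(
                root,
                "line",
                {
                    "class": "tick",
                    "x1": _fmt(x),
                    "y1": _fmt(axis_top),
                    "x2": _fmt(x),
                    "y2": _fmt(axis_top + 4),
                    "stroke": config.axis_color,
                    "stroke-width": "1.00",
                },
            )
            text = ET.SubElement(
                root,
                "text",
                {
                    "class": "tick-label",
                    "x": _fmt(x),
                    "y": _fmt(axis_top + 4 + config.font_size),
                    "text-anchor": "middle",
                    "font-family": _FONT_FAMILY,
                    "font-size": _fmt(config.font_size),
                    "fill": config.axis_color,
                },
            )
            text.text = str(tick.position)

    # lollipops: stems first, then every head above them
    order = sorted(range(len(variants)), key=lambda i: (variants[i].position, i))
    for i in order:
        head_y = backbone_top - layout.stem_top[i]
        ET.SubElement(
            root,
            "line",
            {
                "class": "stem",
                "x1": _fmt(layout.x[i]),
                "y1": _fmt(backbone_top),
                "x2": _fmt(layout.x[i]),
                "y2": _fmt(head_y),
                "stroke": config.backbone_color,
                "stroke-width": "2.00",
            },
        )
    for i in order:
        head_y = backbone_top - layout.stem_top[i]
        circle = ET.SubElement(
            root,
            "circle",
            {
                "class": "head",
                "cx": _fmt(layout.x[i]),
                "cy": _fmt(head_y),
                "r": _fmt(layout.radius[i]),
                "fill": variants[i].color or config.lollipop_color,
            },
        )
        title = ET.SubElement(circle, "title")
        title.text = variants[i].change
        if config.show_labels:
            text = ET.SubElement(
                root,
                "text",
                {
                    "class": "variant-label",
                    "x": _fmt(layout.x[i]),
                    "y": _fmt(head_y - layout.radius[i] - 3),
                    "text-anchor": "middle",
                    "font-family": _FONT_FAMILY,
                    "font-size": _fmt(0.9 * config.font_size),
                    "fill": config.axis_color,
                },
            )
            text.text = variants[i].change

    body = ET.tostring(root, encoding="unicode")
    content = '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"
    return SVGDocument(content=content)
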