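"""Minimal deterministic SVG document builder.

Byte-identical output for identical input is a design requirement (plots are
diffed in tests and pipelines), so there are no timestamps, element order is
insertion order, and geometry floats are formatted at a fixed 3 decimals.
Data attributes that must round-trip numerically (``data-y`` etc.) use a
12-significant-digit format instead.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

SVG_NS = "http://www.w3.org/2000/svg"


def fmt(v: float) -> str:
    """Geometry coordinate format: fixed 3 decimals."""
    return f"{float(v):.3f}"


def fmt_data(v: float) -> str:
    """High-precision format for data-* attributes (round-trips to <1e-9)."""
    return f"{float(v):.12g}"


class SVGDocument:
    """An SVG 1.1 document assembled from ordered drawing primitives."""

    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self.root = ET.Element(
            "svg",
            {
                "xmlns": SVG_NS,
                "version": "1.1",
                "width": fmt(width),
                "height": fmt(height),
                "viewBox": f"0 0 {fmt(width)} {fmt(height)}",
            },
        )

    def group(self, id: str, parent: ET.Element | None = None, **attrs) -> ET.Element:
        g = ET.SubElement(parent if parent is not None else self.root, "g", {"id": id})
        for k, v in attrs.items():
            g.set(k.replace("_", "-"), str(v))
        return g

    def _el(self, tag: str, parent: ET.Element | None, attrs: dict) -> ET.Element:
        clean = {k.replace("_", "-"): str(v) for k, v in attrs.items() if v is not None}
        return ET.SubElement(parent if parent is not None else self.root, tag, clean)

    def rect(self, x, y, w, h, parent=None, **attrs) -> ET.Element:
        return self._el(
            "rect",
            parent,
            {"x": fmt(x), "y": fmt(y), "width": fmt(w), "height": fmt(h), **attrs},
        )

    def line(self, x1, y1, x2, y2, parent=None, **attrs) -> ET.Element:
        return self._el(
            "line",
            parent,
            {"x1": fmt(x1), "y1": fmt(y1), "x2": fmt(x2), "y2": fmt(y2), **attrs},
        )

    def circle(self, cx, cy, r, parent=None, **attrs) -> ET.Element:
        return self._el(
            "circle", parent, {"cx": fmt(cx), "cy": fmt(cy), "r": fmt(r), **attrs}
        )

    def path(self, d: str, parent=None, **attrs) -> ET.Element:
        return self._el("path", parent, {"d": d, **attrs})

    def text(self, x, y, content: str, parent=None, **attrs) -> ET.Element:
        el = self._el("text", parent, {"x": fmt(x), "y": fmt(y), **attrs})
        el.text = content
        return el

    def tostring(self) -> str:
        body = ET.tostring(self.root, encoding="unicode")
        return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.tostring())


# Fixed default palette; categories are assigned colors by sorted label order.
PALETTE = [
    "#4e79a7",
    "#f28e2b",
    "#59a14f",
    "#e15759",
    "#b07aa1",
    "#76b7b2",
    "#edc948",
    "#9c755f",
    "#bab0ac",
    "#ff9da7",
]


def color_map(labels) -> dict[str, str]:
    """Deterministic category -> color assignment (sorted label order)."""
    return {
        lab: PALETTE[i % len(PALETTE)] for i, lab in enumerate(sorted(set(labels)))
    }
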