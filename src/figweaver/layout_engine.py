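"""Place sanitized assets on a canvas.

Each panel is one plot with a rectangle on the canvas, a stacking rank ``z``
(larger z = nearer the viewer), an opacity in [0, 1] and a zoom/pan window
into the asset's own coordinate system.  Stacking is realized through painter
order: panels are emitted in ascending-z document order, so later elements
occlude earlier ones.  A panel becomes a nested ``<svg>`` viewport whose
``viewBox`` is the asset viewBox shifted by the pan offset and shrunk by the
zoom factor::

    window = (vb.x + dx, vb.y + dy, vb.w / zoom, vb.h / zoom)

Aspect ratio is always preserved with centered uniform scaling (``meet``):
plots are never silently distorted; fill-crop effects are achieved by
adjusting zoom/pan instead.  Canvas units are user units (CSS pixels); print
resolution is the renderer's concern since vector output is
resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from lxml import etree

from .errors import ValidationError
from .svg_model import NSMAP, SVG_NS, ViewBox


class Rect(NamedTuple):
    x: float
    y: float
    w: float
    h: float


@dataclass
class Canvas:
    """The target drawing surface, in user units (CSS px)."""

    width: float
    height: float
    background: str | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"canvas dimensions must be positive, got {self.width}x{self.height}"
            )


@dataclass
class Panel:
    """One placed asset: geometry, stacking, opacity, zoom/pan and flags."""

    asset_ref: str
    rect: Rect
    z: int = 0
    opacity: float = 1.0
    zoom: float = 1.0
    pan: tuple[float, float] = (0.0, 0.0)
    title: str | None = None  # markdown-lite source; parsed at compose time
    strip_background: bool = False

    def __post_init__(self) -> None:
        self.rect = Rect(*self.rect)
        self.pan = tuple(self.pan)
        if self.rect.w <= 0 or self.rect.h <= 0:
            raise ValidationError(f"panel {self.asset_ref!r}: rect w/h must be positive")
        if not 0.0 <= self.opacity <= 1.0:
            raise ValidationError(
                f"panel {self.asset_ref!r}: opacity {self.opacity} outside [0, 1]"
            )
        if self.zoom <= 0:
            raise ValidationError(f"panel {self.asset_ref!r}: zoom must be > 0")


def order_panels(panels: list[Panel]) -> list[Panel]:
    """Stable-sort panels ascending by z into painter order.

    Ties keep their original relative order; the returned list is the order in
    which panels must be emitted so that higher-z panels draw on top.
    """
    return sorted(panels, key=lambda p: p.z)


def zoom_pan_window(view_box: ViewBox, zoom: float,
                    pan: tuple[float, float]) -> ViewBox:
    """Source window of a zoomed/panned panel (see module docstring)."""
    if zoom <= 0:
        raise ValidationError(f"zoom must be > 0, got {zoom}")
    dx, dy = pan
    return ViewBox(view_box.min_x + dx, view_box.min_y + dy,
                   view_box.width / zoom, view_box.height / zoom)


def fmt_num(x: float) -> str:
    """Deterministic compact number formatting for SVG attributes."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def panel_viewport(panel: Panel,
                   asset_geometry: tuple[float, float, ViewBox | None]
                   ) -> etree._Element:
    """Build the nested ``<svg>`` viewport for one panel.

    The element is positioned at ``rect.x, rect.y`` with ``rect.w x rect.h``
    and shows the zoom/pan window of the asset with centered uniform scaling.
    The asset's content is appended by the composer.
    """
    w, h, vb = asset_geometry
    if vb is None:
        vb = ViewBox(0.0, 0.0, w, h)
    window = zoom_pan_window(vb, panel.zoom, panel.pan)
    el = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
    el.set("x", fmt_num(panel.rect.x))
    el.set("y", fmt_num(panel.rect.y))
    el.set("width", fmt_num(panel.rect.w))
    el.set("height", fmt_num(panel.rect.h))
    el.set("viewBox", " ".join(fmt_num(v) for v in window))
    el.set("preserveAspectRatio", "xMidYMid meet")
    return el


def apply_opacity(placed: etree._Element, opacity: float) -> etree._Element:
    """Set group-level opacity on a panel wrapper; 1.0 emits no attribute."""
    if not 0.0 <= opacity <= 1.0:
        raise ValidationError(f"opacity {opacity} outside [0, 1]")
    if opacity == 1.0:
        if "opacity" in placed.attrib:
            del placed.attrib["opacity"]
        return placed
    placed.set("opacity", fmt_num(opacity))
    return placed
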