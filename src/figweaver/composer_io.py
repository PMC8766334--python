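"""Assemble a session into outputs and round-trip it through files.

A :class:`Session` is the complete unit of work: the canvas, an ordered asset
table (SVG text and raster payloads stored inline), the panels placed on the
canvas and any free text blocks.  :func:`compose` runs the full sanitation
pipeline per panel — parse (rasters are wrapped as SVG first), cascade
inlining, optional white-background stripping, id namespacing with the
panel's 1-based session position as the running inject number — then places
panels in painter order inside nested viewports, applies per-panel opacity
and draws titles and text blocks on top.  The composite contains no
stylesheet elements and no duplicate ids, so it can be inlined anywhere.

:func:`write_html` produces a single self-contained HTML file: the composite
inline, a minimal embedded click-to-enlarge behavior, and the full session as
an embedded JSON block so the file doubles as a session file —
:func:`load_session` restores the identical session from it (or from a bare
session JSON file).
"""

from __future__ import annotations

import base64
import json
import re
from dataclasses import dataclass, field

from lxml import etree

from .errors import CapabilityError, FigweaverError, SessionLoadError, ValidationError
from .layout_engine import Canvas, Panel, Rect, apply_opacity, fmt_num, panel_viewport
from .richtext import apply_text_patterns, render_text_svg
from .style_scoper import cascade_inline, namespace_ids, strip_white_background
from .svg_model import (NSMAP, SVG_NS, RasterAsset, SvgDocument, ViewBox,
                        parse_svg, serialize_svg, wrap_raster)

SCHEMA_VERSION = "1.0"
SESSION_BLOCK_ID = "figweaver-session"

#: base font size (user units) for titles and text blocks
TEXT_BASE_SIZE = 16.0
#: inset of rendered text from its anchor rectangle
TEXT_INSET = 4.0


@dataclass
class Asset:
    """One uploaded image: ``format`` is "svg", "png", "jpeg" or "gif";
    ``content`` is SVG text for vector assets and raw bytes for rasters."""

    format: str
    content: str | bytes

    def __post_init__(self) -> None:
        if self.format not in ("svg", "png", "jpeg", "gif"):
            raise ValidationError(f"unknown asset format {self.format!r}")
        if self.format == "svg" and not isinstance(self.content, str):
            raise ValidationError("svg asset content must be text")
        if self.format != "svg" and not isinstance(self.content, bytes):
            raise ValidationError("raster asset content must be bytes")


@dataclass
class TextBlock:
    rect: Rect
    text: str

    def __post_init__(self) -> None:
        self.rect = Rect(*self.rect)


@dataclass
class Session:
    """Canvas + assets + panels + text blocks; the unit of save/load."""

    canvas: Canvas
    assets: dict[str, Asset] = field(default_factory=dict)
    panels: list[Panel] = field(default_factory=list)
    text_blocks: list[TextBlock] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.panels:
            raise ValidationError("session has no panels; nothing to compose")
        for i, panel in enumerate(self.panels, 1):
            if panel.asset_ref not in self.assets:
                raise ValidationError(
                    f"panel {i} references unknown asset {panel.asset_ref!r}"
                )

    # -- canonical dict form (the serialized schema) -----------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "canvas": {
                "width": self.canvas.width,
                "height": self.canvas.height,
                "background": self.canvas.background,
            },
            "assets": {
                asset_id: {
                    "format": a.format,
                    "content": (a.content if a.format == "svg"
                                else base64.b64encode(a.content).decode("ascii")),
                }
                for asset_id, a in self.assets.items()
            },
            "panels": [
                {
                    "asset": p.asset_ref,
                    "x": p.rect.x, "y": p.rect.y, "w": p.rect.w, "h": p.rect.h,
                    "z": p.z,
                    "opacity": p.opacity,
                    "zoom": p.zoom,
                    "pan": [p.pan[0], p.pan[1]],
                    "title": p.title,
                    "strip_background": p.strip_background,
                }
                for p in self.panels
            ],
            "text_blocks": [
                {"x": t.rect.x, "y": t.rect.y, "w": t.rect.w, "h": t.rect.h,
                 "text": t.text}
                for t in self.text_blocks
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Session":
        try:
            version = data["schema_version"]
            if version != SCHEMA_VERSION:
                raise SessionLoadError(
                    f"unknown session schema_version {version!r}; this build "
                    f"reads version {SCHEMA_VERSION!r}"
                )
            canvas = Canvas(width=data["canvas"]["width"],
                            height=data["canvas"]["height"],
                            background=data["canvas"].get("background"))
            assets = {}
            for asset_id, a in data["assets"].items():
                content = (a["content"] if a["format"] == "svg"
                           else base64.b64decode(a["content"]))
                assets[asset_id] = Asset(format=a["format"], content=content)
            panels = [
                Panel(asset_ref=p["asset"],
                      rect=Rect(p["x"], p["y"], p["w"], p["h"]),
                      z=p["z"], opacity=p["opacity"], zoom=p["zoom"],
                      pan=(p["pan"][0], p["pan"][1]),
                      title=p.get("title"),
                      strip_background=p.get("strip_background", False))
                for p in data["panels"]
            ]
            text_blocks = [
                TextBlock(rect=Rect(t["x"], t["y"], t["w"], t["h"]), text=t["text"])
                for t in data.get("text_blocks", [])
            ]
        except SessionLoadError:
            raise
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise SessionLoadError(f"corrupt session data: {exc}") from exc
        return cls(canvas=canvas, assets=assets, panels=panels,
                   text_blocks=text_blocks, schema_version=version)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        return self.to_dict() == other.to_dict()


# ---------------------------------------------------------------------------
# composition

def _parse_asset(asset_id: str, asset: Asset) -> SvgDocument:
    try:
        if asset.format == "svg":
            return parse_svg(asset.content)
        return wrap_raster(RasterAsset.from_bytes(asset.content))
    except FigweaverError as exc:
        raise type(exc)(f"asset {asset_id!r}: {exc}") from exc


def compose(session: Session) -> SvgDocument:
    """Compose the session into one conflict-free multi-panel SVG.

    Panels are numbered 1..N in session order; panel i's ids carry the suffix
    ``--inject-i``.  Painter order follows ascending z (stable), and titles
    and text blocks are drawn on top of all panels.
    """
    session.validate()
    canvas = session.canvas
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
    root.set("width", fmt_num(canvas.width))
    root.set("height", fmt_num(canvas.height))
    root.set("viewBox", f"0 0 {fmt_num(canvas.width)} {fmt_num(canvas.height)}")
    if canvas.background:
        bg = etree.SubElement(root, f"{{{SVG_NS}}}rect")
        bg.set("width", fmt_num(canvas.width))
        bg.set("height", fmt_num(canvas.height))
        bg.set("fill", canvas.background)

    # sanitize each panel's asset with its 1-based session position
    placed: list[tuple[Panel, int, etree._Element]] = []
    for index, panel in enumerate(session.panels, 1):
        doc = _parse_asset(panel.asset_ref, session.assets[panel.asset_ref])
        cascade_inline(doc)
        if panel.strip_background:
            strip_white_background(doc)
        scoped = namespace_ids(doc, index)
        viewport = panel_viewport(
            panel, (doc.intrinsic_width, doc.intrinsic_height, doc.view_box))
        # carry inheritable root attributes (fonts, namespaced ids) onto the
        # viewport; geometry attributes are owned by the viewport itself
        for attr, value in scoped.doc.root.items():
            name = attr.rsplit("}", 1)[-1]
            if name not in ("width", "height", "viewBox", "x", "y",
                            "preserveAspectRatio", "version"):
                viewport.set(attr, value)
        for child in list(scoped.doc.root):
            viewport.append(child)
        wrapper = etree.Element(f"{{{SVG_NS}}}g", nsmap=NSMAP)
        wrapper.set("id", f"figweaver-panel-{index}")
        wrapper.set("class", "figweaver-panel")
        wrapper.append(viewport)
        apply_opacity(wrapper, panel.opacity)
        placed.append((panel, index, wrapper))

    # painter order: stable ascending z
    for _panel, _index, wrapper in sorted(placed, key=lambda t: t[0].z):
        root.append(wrapper)

    # titles and text blocks draw above every panel
    for panel, index, _wrapper in placed:
        if panel.title:
            g = render_text_svg(apply_text_patterns(panel.title),
                                (panel.rect.x + TEXT_INSET,
                                 panel.rect.y + TEXT_INSET),
                                TEXT_BASE_SIZE)
            g.set("id", f"figweaver-title-{index}")
            root.append(g)
    for j, block in enumerate(session.text_blocks, 1):
        g = render_text_svg(apply_text_patterns(block.text),
                            (block.rect.x + TEXT_INSET, block.rect.y + TEXT_INSET),
                            TEXT_BASE_SIZE)
        g.set("id", f"figweaver-text-{j}")
        root.append(g)

    return SvgDocument(root=root, intrinsic_width=canvas.width,
                       intrinsic_height=canvas.height,
                       view_box=ViewBox(0, 0, canvas.width, canvas.height))


# ---------------------------------------------------------------------------
# session serialization

def save_session(session: Session) -> str:
    """Canonical session JSON (sorted keys, ASCII-escaped)."""
    return json.dumps(session.to_dict(), sort_keys=True, ensure_ascii=True,
                      separators=(",", ": "), indent=1)


_SESSION_BLOCK_RE = re.compile(
    r'<script type="application/json" id="%s">\s*(.*?)\s*</script>'
    % SESSION_BLOCK_ID,
    re.S,
)

_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8"/>
<title>figweaver figure</title>
<style>
body {{ margin: 0; background: #f4f4f4; font-family: sans-serif; }}
.figweaver-canvas {{ margin: 1em auto; width: {width}px; background: white;
                     box-shadow: 0 1px 4px rgba(0,0,0,0.3); }}
.figweaver-panel {{ cursor: zoom-in; }}
#figweaver-overlay {{ display: none; position: fixed; inset: 0;
                      background: rgba(0,0,0,0.75); z-index: 10;
                      cursor: zoom-out; overflow: auto; }}
#figweaver-overlay svg {{ background: white; margin: 2em auto; display: block; }}
</style>
</head>
<body>
<div class="figweaver-canvas">
{composite}
</div>
<div id="figweaver-overlay"></div>
<script type="application/json" id="{block_id}">
{session_json}
</script>
<script>
(function () {{
  "use strict";
  var overlay = document.getElementById("figweaver-overlay");
  var panels = document.querySelectorAll(".figweaver-panel");
  panels.forEach(function (panel) {{
    panel.addEventListener("click", function () {{
      var clone = panel.querySelector("svg").cloneNode(true);
      clone.removeAttribute("x");
      clone.removeAttribute("y");
      clone.setAttribute("width", "90%");
      clone.setAttribute("height", "90%");
      overlay.replaceChildren(clone);
      overlay.style.display = "block";
    }});
  }});
  overlay.addEventListener("click", function () {{
    overlay.style.display = "none";
  }});
}})();
</script>
</body>
</html>
"""


def write_html(session: Session, composite: SvgDocument) -> str:
    """Self-contained interactive HTML that doubles as a session file.

    The composite is inlined (links inside assets stay clickable), panel
    wrappers carry stable ``figweaver-panel-N`` ids with a minimal embedded
    click-to-enlarge behavior, and the full session is embedded as JSON so
    :func:`load_session` restores it exactly.  No external references.
    """
    session_json = save_session(session).replace("<", "\\u003c")
    return _HTML_TEMPLATE.format(
        width=fmt_num(session.canvas.width),
        composite=serialize_svg(composite),
        block_id=SESSION_BLOCK_ID,
        session_json=session_json,
    )


def load_session(source: str) -> Session:
    """Restore a :class:`Session` from HTML output or bare session JSON."""
    looks_like_html = re.search(r"<(!DOCTYPE|html)", source[:512], re.I) is not None
    m = _SESSION_BLOCK_RE.search(source)
    if m is not None:
        # the JSON is embedded verbatim; '<' is unicode-escaped inside strings
        payload = m.group(1)
    elif looks_like_html:
        raise SessionLoadError(
            "no session block found in HTML input; the file may be truncated "
            "or was not produced by figweaver"
        )
    else:
        payload = source
    try:
        data = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise SessionLoadError(f"session block is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SessionLoadError("session block must be a JSON object")
    return Session.from_dict(data)


# ---------------------------------------------------------------------------
# PDF export

def export_pdf(composite: SvgDocument, path: str) -> None:
    """Render the composite to a single-page PDF via an SVG renderer.

    A thin adapter: the correctness surface is the SVG itself.  The page box
    matches the canvas dimensions.  When no renderer is installed a
    :class:`CapabilityError` explains the print-to-PDF fallback.
    """
    try:
        import cairosvg  # optional; not part of the core install
    except ImportError as exc:
        raise CapabilityError(
            "no vector renderer available for PDF export; open the HTML "
            "output in a browser and print to PDF instead"
        ) from exc
    cairosvg.svg2pdf(
        bytestring=serialize_svg(composite).encode("utf-8"),
        write_to=path,
        output_width=composite.intrinsic_width,
        output_height=composite.intrinsic_height,
    )
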