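"""Parse, interrogate and serialize SVG documents; wrap rasters as SVG.

The in-memory representation is a thin :class:`SvgDocument` wrapper around an
``lxml`` element tree plus the resolved intrinsic geometry.  Coordinates follow
the SVG/CSS convention throughout the package: origin at the top-left, y grows
downward, one user unit equals one CSS pixel (96 per inch).

Raster plots (PNG/JPEG/GIF) are adapted into single-``<image>`` SVG documents
with the payload embedded as a base64 data URI, so every downstream stage of
the pipeline only ever deals with vector documents.
"""

from __future__ import annotations

import base64
import io
import re
from dataclasses import dataclass, field
from typing import NamedTuple

from lxml import etree
from PIL import Image

from .errors import GeometryError, SvgFormatError, SvgParseError

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"
NSMAP = {None: SVG_NS, "xlink": XLINK_NS}

#: user units per physical unit at the 96 units/inch convention
UNIT_FACTORS = {
    "": 1.0,
    "px": 1.0,
    "pt": 96.0 / 72.0,
    "pc": 16.0,
    "mm": 96.0 / 25.4,
    "cm": 96.0 / 2.54,
    "in": 96.0,
}

#: fallback geometry when neither width/height nor viewBox is declared
DEFAULT_WIDTH = 300.0
DEFAULT_HEIGHT = 150.0

_LENGTH_RE = re.compile(r"^\s*([+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\s*([a-z%]*)\s*$")

_RASTER_MAGIC = {
    "png": b"\x89PNG\r\n\x1a\n",
    "gif": (b"GIF87a", b"GIF89a"),
    "jpeg": b"\xff\xd8\xff",
}


class ViewBox(NamedTuple):
    """The ``viewBox`` rectangle: the window of user space shown by a viewport."""

    min_x: float
    min_y: float
    width: float
    height: float


@dataclass
class SvgDocument:
    """One parsed vector asset.

    Parameters
    ----------
    root
        The ``<svg>`` element tree (lxml).
    intrinsic_width, intrinsic_height
        Resolved size in user units (CSS px).
    view_box
        The declared ``viewBox`` or ``None``.
    """

    root: etree._Element
    intrinsic_width: float = field(default=DEFAULT_WIDTH)
    intrinsic_height: float = field(default=DEFAULT_HEIGHT)
    view_box: ViewBox | None = None

    def __post_init__(self) -> None:
        if localname(self.root) != "svg":
            raise SvgFormatError(
                f"root element is <{localname(self.root)}>, expected <svg>"
            )
        if self.view_box is not None and (
            self.view_box.width <= 0 or self.view_box.height <= 0
        ):
            raise GeometryError("viewBox width and height must be positive")

    @property
    def effective_view_box(self) -> ViewBox:
        """The declared viewBox, or ``(0, 0, width, height)`` when absent."""
        if self.view_box is not None:
            return self.view_box
        return ViewBox(0.0, 0.0, self.intrinsic_width, self.intrinsic_height)

    def copy(self) -> "SvgDocument":
        import copy as _copy

        return SvgDocument(
            root=_copy.deepcopy(self.root),
            intrinsic_width=self.intrinsic_width,
            intrinsic_height=self.intrinsic_height,
            view_box=self.view_box,
        )


@dataclass(frozen=True)
class RasterAsset:
    """A PNG/JPEG/GIF payload with verified type and pixel dimensions."""

    payload: bytes
    media_type: str  # "png" | "jpeg" | "gif"
    pixel_width: int
    pixel_height: int

    def __post_init__(self) -> None:
        if self.media_type not in _RASTER_MAGIC:
            raise SvgFormatError(
                f"unsupported media type {self.media_type!r}; convert TIFF/PDF and "
                "other formats to SVG (preferred) or PNG with an external tool "
                "such as Inkscape or pdf2svg"
            )
        if sniff_media_type(self.payload) != self.media_type:
            raise SvgFormatError(
                f"payload magic bytes do not match declared type {self.media_type!r}"
            )
        if self.pixel_width <= 0 or self.pixel_height <= 0:
            raise SvgFormatError("raster pixel dimensions must be positive")

    @classmethod
    def from_bytes(cls, payload: bytes) -> "RasterAsset":
        """Sniff the format from magic bytes and read pixel dimensions."""
        media_type = sniff_media_type(payload)
        if media_type is None:
            raise SvgFormatError(
                "unrecognized raster payload; accepted formats are png, jpeg and "
                "gif — convert other formats (tiff, pdf, ...) externally, "
                "preferably to SVG"
            )
        with Image.open(io.BytesIO(payload)) as im:
            width, height = im.size
        return cls(payload=payload, media_type=media_type,
                   pixel_width=width, pixel_height=height)


def sniff_media_type(payload: bytes) -> str | None:
    """Return "png"/"jpeg"/"gif" from magic bytes, or None."""
    if payload.startswith(_RASTER_MAGIC["png"]):
        return "png"
    if payload.startswith(_RASTER_MAGIC["gif"]):
        return "gif"
    if payload.startswith(_RASTER_MAGIC["jpeg"]):
        return "jpeg"
    return None


def localname(el: etree._Element) -> str:
    """Tag name without namespace; empty string for comments/PIs."""
    tag = el.tag
    if not isinstance(tag, str):
        return ""
    return tag.rsplit("}", 1)[-1]


def parse_svg(text: str | bytes) -> SvgDocument:
    """Parse SVG text into an :class:`SvgDocument`.

    Namespaces, comments and processing instructions are preserved; a DOCTYPE,
    if present, is accepted on input and dropped on serialization (it would
    interfere with inline embedding in HTML).

    Raises
    ------
    SvgParseError
        On malformed XML, with the offending line/column.
    SvgFormatError
        When the root element is not ``<svg>``.
    """
    parser = etree.XMLParser(resolve_entities=False, no_network=True,
                             remove_comments=False, remove_pis=False)
    data = text.encode("utf-8") if isinstance(text, str) else text
    try:
        root = etree.fromstring(data, parser=parser)
    except etree.XMLSyntaxError as exc:
        line, column = (exc.position or (None, None))
        raise SvgParseError(f"malformed XML: {exc.msg}", line=line, column=column) from exc
    if localname(root) != "svg":
        raise SvgFormatError(
            f"root element is <{localname(root)}>, expected <svg>"
        )
    doc = SvgDocument(root=root)
    width, height, view_box = resolve_geometry(doc)
    doc.intrinsic_width = width
    doc.intrinsic_height = height
    doc.view_box = view_box
    return doc


def parse_length(value: str, reference: float | None = None) -> float:
    """Convert an SVG length to user units (96/inch convention).

    ``reference`` is the axis length a percentage refers to; percentages with
    no reference raise :class:`GeometryError`, as do font-relative units.
    """
    m = _LENGTH_RE.match(value)
    if not m:
        raise GeometryError(f"cannot parse length {value!r}")
    number, unit = float(m.group(1)), m.group(2)
    if unit == "%":
        if reference is None:
            raise GeometryError(
                f"percentage length {value!r} requires a viewBox to resolve against"
            )
        return number / 100.0 * reference
    if unit not in UNIT_FACTORS:
        raise GeometryError(
            f"unsupported length unit {unit!r} in {value!r}; supported units are "
            "unitless, px, pt, pc, mm, cm, in"
        )
    return number * UNIT_FACTORS[unit]


def parse_view_box(value: str) -> ViewBox:
    parts = re.split(r"[\s,]+", value.strip())
    if len(parts) != 4:
        raise GeometryError(f"viewBox must have 4 numbers, got {value!r}")
    try:
        nums = [float(p) for p in parts]
    except ValueError as exc:
        raise GeometryError(f"non-numeric viewBox {value!r}") from exc
    vb = ViewBox(*nums)
    if vb.width <= 0 or vb.height <= 0:
        raise GeometryError(f"viewBox width/height must be positive, got {value!r}")
    return vb


def resolve_geometry(doc: SvgDocument) -> tuple[float, float, ViewBox | None]:
    """Resolve intrinsic width/height (user units) and viewBox of a document.

    Resolution order: explicit ``width``/``height`` attributes (lengths
    converted to user units; percentages resolved against the viewBox), else
    the viewBox dimensions, else the 300x150 renderer default.
    """
    root = doc.root
    vb_attr = root.get("viewBox")
    view_box = parse_view_box(vb_attr) if vb_attr is not None else None

    def axis(attr: str, vb_len: float | None, default: float) -> float:
        raw = root.get(attr)
        if raw is None or raw.strip() == "auto":
            return vb_len if vb_len is not None else default
        length = parse_length(raw, reference=vb_len)
        if length <= 0:
            raise GeometryError(f"{attr} must be positive, got {raw!r}")
        return length

    width = axis("width", view_box.width if view_box else None, DEFAULT_WIDTH)
    height = axis("height", view_box.height if view_box else None, DEFAULT_HEIGHT)
    return width, height, view_box


def serialize_svg(doc: SvgDocument) -> str:
    """Serialize to standalone SVG text.

    Output is deterministic for identical trees; namespace declarations are
    emitted by lxml at the root; no XML declaration or DOCTYPE is written so
    the text can be inlined into HTML verbatim.
    """
    return etree.tostring(doc.root, encoding="unicode")


def canonical_svg(doc: SvgDocument) -> str:
    """Canonical (C14N) form used to compare trees up to attribute order."""
    return etree.canonicalize(etree.tostring(doc.root, encoding="unicode"))


def wrap_raster(asset: RasterAsset) -> SvgDocument:
    """Embed a raster image in a minimal SVG of matching pixel geometry.

    The result has ``viewBox=(0, 0, pixel_width, pixel_height)`` and a single
    ``<image>`` whose ``xlink:href`` is an RFC 2397 base64 data URI; the
    payload round-trips byte-exactly through base64.
    """
    w, h = asset.pixel_width, asset.pixel_height
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
    root.set("width", str(w))
    root.set("height", str(h))
    root.set("viewBox", f"0 0 {w} {h}")
    image = etree.SubElement(root, f"{{{SVG_NS}}}image")
    image.set("x", "0")
    image.set("y", "0")
    image.set("width", str(w))
    image.set("height", str(h))
    image.set("preserveAspectRatio", "xMidYMid meet")
    uri = "data:image/{};base64,{}".format(
        asset.media_type, base64.b64encode(asset.payload).decode("ascii")
    )
    image.set(f"{{{XLINK_NS}}}href", uri)
    return SvgDocument(root=root, intrinsic_width=float(w),
                       intrinsic_height=float(h), view_box=ViewBox(0, 0, w, h))
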