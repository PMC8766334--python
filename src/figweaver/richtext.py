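"""Markdown-lite text patterns and vector text rendering.

Panel titles and free text blocks accept a deliberately tiny grammar of
eleven patterns, applied line by line:

* ``*text*`` -> italic, ``**text**`` -> bold (longest delimiter wins, so
  ``**`` is tried before ``*``; unmatched delimiters stay literal)
* a line starting with ``#`` .. ``######`` followed by a space -> heading
  levels 1-6
* a line starting with ``1. `` -> ordered list item; ``* `` or ``- `` ->
  unordered list item; consecutive items group into one list

Everything else is plain text; the grammar is total and never fails.
Formatted text is rendered to SVG ``<text>``/``<tspan>`` elements by
:func:`render_text_svg`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from lxml import etree

from .svg_model import NSMAP, SVG_NS

# heading font-size multipliers relative to the base size; headings are bold
HEADING_SCALE = {1: 2.0, 2: 1.5, 3: 1.3, 4: 1.15, 5: 1.0, 6: 0.85}

#: vertical advance between lines, in multiples of the line's font size
LINE_SPACING = 1.4


@dataclass
class Plain:
    text: str


@dataclass
class Italic:
    children: list


@dataclass
class Bold:
    children: list


@dataclass
class Line:
    children: list


@dataclass
class Heading:
    level: int
    children: list

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 6:
            raise ValueError(f"heading level {self.level} outside [1, 6]")


@dataclass
class ListItem:
    children: list


@dataclass
class OrderedList:
    items: list


@dataclass
class UnorderedList:
    items: list


@dataclass
class RichText:
    """A parsed block of formatted text: a list of lines, headings and lists."""

    blocks: list = field(default_factory=list)


_HEADING_RE = re.compile(r"^(#{1,6}) (.*)$")
_ORDERED_RE = re.compile(r"^\d+\. (.*)$")
_UNORDERED_RE = re.compile(r"^[*-] (.*)$")


def _find_single_star(s: str, start: int) -> int:
    """Next lone '*' at or after `start`; '**' pairs are stepped over so a
    bold span can sit inside an italic one."""
    i = start
    n = len(s)
    while i < n:
        if s[i] == "*":
            if i + 1 < n and s[i + 1] == "*":
                i += 2
                continue
            return i
        i += 1
    return -1


def _parse_inline(s: str) -> list:
    """Left-to-right first-match emphasis parsing; ** before *; unmatched or
    empty delimiters remain literal text."""
    nodes: list = []
    buf: list[str] = []

    def flush() -> None:
        if buf:
            nodes.append(Plain("".join(buf)))
            buf.clear()

    i = 0
    n = len(s)
    while i < n:
        if s.startswith("**", i):
            j = s.find("**", i + 2)
            if j > i + 2:  # non-empty bold span
                flush()
                nodes.append(Bold(_parse_inline(s[i + 2:j])))
                i = j + 2
                continue
        if s[i] == "*":
            j = _find_single_star(s, i + 1)
            if j > i + 1:  # non-empty italic span
                flush()
                nodes.append(Italic(_parse_inline(s[i + 1:j])))
                i = j + 1
                continue
        buf.append(s[i])
        i += 1
    flush()
    return nodes


def apply_text_patterns(text: str) -> RichText:
    """Parse markdown-lite source into a :class:`RichText` tree."""
    blocks: list = []
    for raw_line in text.split("\n"):
        m = _HEADING_RE.match(raw_line)
        if m:
            blocks.append(Heading(len(m.group(1)), _parse_inline(m.group(2))))
            continue
        m = _ORDERED_RE.match(raw_line)
        if m:
            item = ListItem(_parse_inline(m.group(1)))
            if blocks and isinstance(blocks[-1], OrderedList):
                blocks[-1].items.append(item)
            else:
                blocks.append(OrderedList([item]))
            continue
        m = _UNORDERED_RE.match(raw_line)
        if m:
            item = ListItem(_parse_inline(m.group(1)))
            if blocks and isinstance(blocks[-1], UnorderedList):
                blocks[-1].items.append(item)
            else:
                blocks.append(UnorderedList([item]))
            continue
        blocks.append(Line(_parse_inline(raw_line)))
    return RichText(blocks)


def to_plain_text(rt: RichText) -> str:
    """The source text with only the consumed delimiter characters removed."""

    def inline(nodes: list) -> str:
        out = []
        for node in nodes:
            if isinstance(node, Plain):
                out.append(node.text)
            else:
                out.append(inline(node.children))
        return "".join(out)

    lines: list[str] = []
    for block in rt.blocks:
        if isinstance(block, (Line, Heading)):
            lines.append(inline(block.children))
        elif isinstance(block, (OrderedList, UnorderedList)):
            lines.extend(inline(item.children) for item in block.items)
    return "\n".join(lines)


def _render_inline(parent: etree._Element, nodes: list,
                   italic: bool = False, bold: bool = False) -> None:
    for node in nodes:
        if isinstance(node, Plain):
            span = etree.SubElement(parent, f"{{{SVG_NS}}}tspan")
            if italic:
                span.set("font-style", "italic")
            if bold:
                span.set("font-weight", "bold")
            span.text = node.text
        elif isinstance(node, Italic):
            _render_inline(parent, node.children, italic=True, bold=bold)
        elif isinstance(node, Bold):
            _render_inline(parent, node.children, italic=italic, bold=True)


def render_text_svg(rt: RichText, origin: tuple[float, float],
                    base_font_size: float) -> etree._Element:
    """Render formatted text into an SVG ``<g>`` of ``<text>`` lines.

    Each visual line becomes one ``<text>`` element whose baseline advances by
    ``LINE_SPACING`` times that line's font size; headings are bold and scaled
    per :data:`HEADING_SCALE`; list items are prefixed ``N. `` or a bullet.
    """
    from .layout_engine import fmt_num  # avoid import cycle at module load

    x0, y0 = origin
    g = etree.Element(f"{{{SVG_NS}}}g", nsmap=NSMAP)
    y = y0

    def emit_line(nodes: list, size: float, bold: bool = False,
                  prefix: str | None = None) -> None:
        nonlocal y
        y += size  # baseline of this line
        text_el = etree.SubElement(g, f"{{{SVG_NS}}}text")
        text_el.set("x", fmt_num(x0))
        text_el.set("y", fmt_num(y))
        text_el.set("font-size", fmt_num(size))
        if bold:
            text_el.set("font-weight", "bold")
        if prefix is not None:
            span = etree.SubElement(text_el, f"{{{SVG_NS}}}tspan")
            span.text = prefix
        _render_inline(text_el, nodes)
        y += (LINE_SPACING - 1.0) * size

    for block in rt.blocks:
        if isinstance(block, Heading):
            emit_line(block.children, base_font_size * HEADING_SCALE[block.level],
                      bold=True)
        elif isinstance(block, OrderedList):
            for i, item in enumerate(block.items, 1):
                emit_line(item.children, base_font_size, prefix=f"{i}. ")
        elif isinstance(block, UnorderedList):
            for item in block.items:
                emit_line(item.children, base_font_size, prefix="• ")
        elif isinstance(block, Line):
            emit_line(block.children, base_font_size)
    return g
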