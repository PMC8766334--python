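"""Make each SVG asset self-contained and collision-free.

When several inline SVGs share one HTML parse tree, their ``<style>`` sheets
apply globally and their element ids share a single namespace, so two plots
that both define ``.edge { stroke: ... }`` or an id ``grad1`` silently restyle
each other.  This module removes both failure modes:

* :func:`cascade_inline` resolves the stylesheet cascade (importance,
  specificity, source order — with a pre-existing ``style`` attribute
  outranking all non-important rules) and writes the winning declaration of
  every property into each element's ``style`` attribute, then deletes the
  ``<style>`` elements.
* :func:`namespace_ids` renames every id with the suffix ``--inject-X`` (X a
  running number per added image) and rewrites all internal references —
  fragment links and functional ``url(#...)`` values — consistently, leaving
  external links untouched.
* :func:`strip_white_background` optionally removes a full-canvas white
  backdrop so panels can be overlaid transparently.

The selector engine supports the subset that plotting tools and pathway
exporters emit: universal, type, class, id, attribute presence/equality,
descendant and child combinators, and comma grouping.  Pseudo-classes,
pseudo-elements, sibling combinators and media queries are skipped with a
:class:`~figweaver.errors.ScopingWarning`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from lxml import etree

from .errors import ScopingWarning, UnsupportedSelectorError
from .svg_model import SvgDocument, localname

_COMMENT_RE = re.compile(r"/\*.*?\*/", re.S)
_URL_REF_RE = re.compile(r"""url\(\s*(['"]?)#([^)'"\s]+)\1\s*\)""")

ID_SUFFIX_TEMPLATE = "--inject-{}"

# attributes that may carry a bare fragment reference ("#id")
_FRAGMENT_ATTRS = {"href"}


# ---------------------------------------------------------------------------
# selector model

@dataclass(frozen=True)
class SimpleSelector:
    kind: str  # "universal" | "type" | "class" | "id" | "attr"
    name: str = ""
    value: str | None = None  # for [attr=value]


@dataclass(frozen=True)
class CompoundSelector:
    """A sequence of simple selectors applying to one element (e.g. g.node)."""

    simples: tuple[SimpleSelector, ...]

    def matches(self, el: etree._Element) -> bool:
        return all(_matches_simple(el, s) for s in self.simples)


@dataclass(frozen=True)
class ComplexSelector:
    """Compounds joined by combinators; combinator[i] joins compound i-1 to i.

    combinators[0] is always None; " " is descendant, ">" is child.
    """

    compounds: tuple[CompoundSelector, ...]
    combinators: tuple[str | None, ...]

    def matches(self, el: etree._Element) -> bool:
        return _matches_complex(el, self.compounds, self.combinators,
                                len(self.compounds) - 1)


def _matches_simple(el: etree._Element, s: SimpleSelector) -> bool:
    if s.kind == "universal":
        return True
    if s.kind == "type":
        return localname(el) == s.name
    if s.kind == "class":
        classes = (el.get("class") or "").split()
        return s.name in classes
    if s.kind == "id":
        return el.get("id") == s.name
    if s.kind == "attr":
        actual = el.get(s.name)
        if actual is None:
            return False
        return s.value is None or actual == s.value
    raise AssertionError(f"unknown simple selector kind {s.kind}")


def _matches_complex(el, compounds, combinators, i) -> bool:
    if not compounds[i].matches(el):
        return False
    if i == 0:
        return True
    comb = combinators[i]
    parent = el.getparent()
    if comb == ">":
        return parent is not None and _matches_complex(parent, compounds,
                                                       combinators, i - 1)
    # descendant: any ancestor may match the preceding compound
    while parent is not None:
        if _matches_complex(parent, compounds, combinators, i - 1):
            return True
        parent = parent.getparent()
    return False


_SELECTOR_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s*>\s*|\s+)               # combinator (child or descendant)
  | \*                                 # universal
  | (?P<id>\#[-\w]+)
  | (?P<class>\.[-\w]+)
  | (?P<attr>\[\s*[-\w]+\s*(?:=\s*(?:"[^"]*"|'[^']*'|[-\w]+)\s*)?\])
  | (?P<type>[-\w]+)
    """,
    re.X,
)

_UNSUPPORTED_CHARS_RE = re.compile(r"[:+~|]|::")


def parse_selector(selector: str) -> ComplexSelector:
    """Parse one complex selector of the supported subset.

    Raises :class:`UnsupportedSelectorError` on pseudo-classes/elements,
    sibling combinators or anything else outside the subset.
    """
    selector = selector.strip()
    if not selector:
        raise UnsupportedSelectorError("empty selector")
    if _UNSUPPORTED_CHARS_RE.search(selector):
        raise UnsupportedSelectorError(
            f"selector {selector!r} uses an unsupported feature "
            "(pseudo-class/element or sibling combinator)"
        )
    compounds: list[CompoundSelector] = []
    combinators: list[str | None] = []
    current: list[SimpleSelector] = []
    pending_comb: str | None = None
    pos = 0
    while pos < len(selector):
        m = _SELECTOR_TOKEN_RE.match(selector, pos)
        if m is None:
            raise UnsupportedSelectorError(
                f"cannot parse selector {selector!r} at position {pos}"
            )
        token = m.group(0)
        if m.group("ws") is not None:
            if current:
                compounds.append(CompoundSelector(tuple(current)))
                combinators.append(pending_comb)
                current = []
                pending_comb = ">" if ">" in token else " "
            elif ">" in token:
                raise UnsupportedSelectorError(
                    f"selector {selector!r} has a dangling combinator"
                )
        elif token == "*":
            current.append(SimpleSelector("universal"))
        elif m.group("id"):
            current.append(SimpleSelector("id", token[1:]))
        elif m.group("class"):
            current.append(SimpleSelector("class", token[1:]))
        elif m.group("attr"):
            inner = token[1:-1].strip()
            if "=" in inner:
                name, _, value = inner.partition("=")
                value = value.strip().strip("\"'")
                current.append(SimpleSelector("attr", name.strip(), value))
            else:
                current.append(SimpleSelector("attr", inner))
        else:  # type
            current.append(SimpleSelector("type", token))
        pos = m.end()
    if not current:
        raise UnsupportedSelectorError(f"selector {selector!r} ends with a combinator")
    compounds.append(CompoundSelector(tuple(current)))
    combinators.append(pending_comb)
    # first combinator slot must be None by construction
    combinators[0] = None
    return ComplexSelector(tuple(compounds), tuple(combinators))


def compute_specificity(selector: str) -> tuple[int, int, int]:
    """Specificity triple (ids, classes+attributes, types) of one selector.

    The universal selector contributes nothing.  Unsupported selectors raise
    :class:`UnsupportedSelectorError`.
    """
    parsed = parse_selector(selector)
    a = b = c = 0
    for compound in parsed.compounds:
        for s in compound.simples:
            if s.kind == "id":
                a += 1
            elif s.kind in ("class", "attr"):
                b += 1
            elif s.kind == "type":
                c += 1
    return (a, b, c)


# ---------------------------------------------------------------------------
# stylesheet rules

@dataclass
class StyleRule:
    """One cascade participant: a single (non-grouped) selector with its
    declaration block, specificity and global source order."""

    selector: str
    declarations: dict[str, tuple[str, bool]]  # property -> (value, important)
    specificity: tuple[int, int, int]
    source_order: int
    parsed: ComplexSelector = field(repr=False, compare=False, default=None)

    def sort_key_for(self, prop: str) -> tuple[bool, tuple[int, int, int], int]:
        important = self.declarations[prop][1]
        return (important, self.specificity, self.source_order)


_IMPORTANT_RE = re.compile(r"!\s*important\s*$", re.I)


def parse_declarations(block: str) -> dict[str, tuple[str, bool]]:
    """Parse ``prop: value [!important]; ...`` into an ordered mapping.

    Malformed declarations are skipped with a warning; never fatal.
    """
    decls: dict[str, tuple[str, bool]] = {}
    for part in block.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            warnings.warn(f"skipping malformed declaration {part!r}", ScopingWarning,
                          stacklevel=2)
            continue
        prop, _, value = part.partition(":")
        prop = prop.strip().lower()
        value = value.strip()
        if not prop or not value:
            warnings.warn(f"skipping malformed declaration {part!r}", ScopingWarning,
                          stacklevel=2)
            continue
        important = bool(_IMPORTANT_RE.search(value))
        if important:
            value = _IMPORTANT_RE.sub("", value).strip()
        decls[prop] = (value, important)
    return decls


def _iter_css_rules(css: str):
    """Yield (selector_group, declaration_block) pairs; skip at-rules."""
    css = _COMMENT_RE.sub("", css)
    pos = 0
    n = len(css)
    while pos < n:
        while pos < n and css[pos] in " \t\r\n":
            pos += 1
        if pos >= n:
            break
        if css[pos] == "@":
            # skip the whole at-rule: to ';' or through a balanced {...} block
            brace = css.find("{", pos)
            semi = css.find(";", pos)
            if brace != -1 and (semi == -1 or brace < semi):
                depth = 0
                i = brace
                while i < n:
                    if css[i] == "{":
                        depth += 1
                    elif css[i] == "}":
                        depth -= 1
                        if depth == 0:
                            break
                    i += 1
                warnings.warn(
                    f"skipping at-rule {css[pos:brace].strip()!r}", ScopingWarning,
                    stacklevel=3)
                pos = i + 1
            else:
                pos = (semi + 1) if semi != -1 else n
            continue
        brace = css.find("{", pos)
        if brace == -1:
            break
        close = css.find("}", brace)
        if close == -1:
            warnings.warn("unterminated rule block at end of stylesheet",
                          ScopingWarning, stacklevel=3)
            break
        yield css[pos:brace].strip(), css[brace + 1:close]
        pos = close + 1


def collect_rules(doc: SvgDocument) -> list[StyleRule]:
    """Collect every rule from every ``<style>`` element, in document order.

    Comma-grouped selectors are split into one :class:`StyleRule` per member,
    each with its own specificity; ``source_order`` increases across members
    and across ``<style>`` elements.  Unsupported selectors are excluded with
    a warning.
    """
    rules: list[StyleRule] = []
    order = 0
    for style_el in doc.root.iter():
        if localname(style_el) != "style":
            continue
        css = "".join(style_el.itertext())
        for selector_group, block in _iter_css_rules(css):
            decls = parse_declarations(block)
            if not decls:
                continue
            for selector in selector_group.split(","):
                selector = selector.strip()
                if not selector:
                    continue
                try:
                    parsed = parse_selector(selector)
                    spec = compute_specificity(selector)
                except UnsupportedSelectorError as exc:
                    warnings.warn(f"skipping unsupported selector: {exc}",
                                  ScopingWarning, stacklevel=2)
                    continue
                rules.append(StyleRule(selector=selector,
                                       declarations=dict(decls),
                                       specificity=spec,
                                       source_order=order,
                                       parsed=parsed))
                order += 1
    return rules


# ---------------------------------------------------------------------------
# cascade inlining

def parse_style_attribute(style: str) -> dict[str, str]:
    """Parse an inline ``style`` attribute into an ordered property map."""
    out: dict[str, str] = {}
    for part in style.split(";"):
        part = part.strip()
        if not part or ":" not in part:
            continue
        prop, _, value = part.partition(":")
        out[prop.strip().lower()] = value.strip()
    return out


def serialize_style_attribute(style: dict[str, str]) -> str:
    return "; ".join(f"{p}: {v}" for p, v in style.items())


def cascade_inline(doc: SvgDocument) -> SvgDocument:
    """Resolve the stylesheet cascade into per-element ``style`` attributes.

    For every element and property, the winning declaration among matching
    rules is chosen by ``(important, specificity, source_order)``; a
    pre-existing inline style outranks every non-important rule but loses to
    ``!important`` declarations.  All ``<style>`` elements are removed.
    Elements matched by no rule are left byte-identical.  The operation
    mutates ``doc`` in place and returns it; it is idempotent.
    """
    rules = collect_rules(doc)
    for el in doc.root.iter():
        if not isinstance(el.tag, str) or localname(el) == "style":
            continue
        matching = [r for r in rules if r.parsed.matches(el)]
        if not matching:
            continue
        inline = parse_style_attribute(el.get("style") or "")
        # winner per property among rules
        winners: dict[str, tuple[str, tuple]] = {}
        for rule in matching:
            for prop in rule.declarations:
                key = rule.sort_key_for(prop)
                if prop not in winners or key >= winners[prop][1]:
                    winners[prop] = (rule.declarations[prop][0], key)
        merged = dict(inline)
        for prop, (value, key) in winners.items():
            important = key[0]
            if prop in inline and not important:
                continue  # inline style beats non-important rules
            merged[prop] = value
        el.set("style", serialize_style_attribute(merged))
    for style_el in [e for e in doc.root.iter() if localname(e) == "style"]:
        style_el.getparent().remove(style_el)
    return doc


# ---------------------------------------------------------------------------
# id namespacing

@dataclass
class ScopedAsset:
    """A sanitized asset: no stylesheets, ids namespaced with ``--inject-X``."""

    doc: SvgDocument
    inject_index: int
    id_map: dict[str, str]


def _rewrite_value(value: str, id_map: dict[str, str],
                   missing: set[str]) -> str:
    def repl(m: re.Match) -> str:
        target = m.group(2)
        if target in id_map:
            return f"url(#{id_map[target]})"
        missing.add(target)
        return m.group(0)

    return _URL_REF_RE.sub(repl, value)


def namespace_ids(doc: SvgDocument, inject_index: int) -> ScopedAsset:
    """Append ``--inject-X`` (X = ``inject_index``) to every id and rewrite
    all internal references consistently.

    Fragment-only link attributes (``href``/``xlink:href`` of the form
    ``#id``) and functional ``url(#id)`` references in any attribute or inline
    style are rewritten; external URLs are preserved verbatim.  References to
    nonexistent ids are left as-is with a warning.  Mutates in place.
    """
    if inject_index < 1:
        raise ValueError(f"inject_index must be >= 1, got {inject_index}")
    suffix = ID_SUFFIX_TEMPLATE.format(inject_index)
    id_map = {
        old: old + suffix
        for el in doc.root.iter()
        if isinstance(el.tag, str) and (old := el.get("id")) is not None
    }
    missing: set[str] = set()
    for el in doc.root.iter():
        if not isinstance(el.tag, str):
            continue
        for attr, value in list(el.items()):
            name = attr.rsplit("}", 1)[-1]
            if name == "id":
                el.set(attr, id_map[value])
                continue
            if name in _FRAGMENT_ATTRS and value.startswith("#"):
                target = value[1:]
                if target in id_map:
                    el.set(attr, "#" + id_map[target])
                else:
                    missing.add(target)
                continue
            if "url(" in value:
                el.set(attr, _rewrite_value(value, id_map, missing))
    for target in sorted(missing):
        warnings.warn(f"reference to nonexistent id {target!r} left unchanged",
                      ScopingWarning, stacklevel=2)
    return ScopedAsset(doc=doc, inject_index=inject_index, id_map=id_map)


# ---------------------------------------------------------------------------
# white-background removal

_WHITE_RE = re.compile(
    r"^\s*(#fff|#ffffff|white|rgb\(\s*255\s*,\s*255\s*,\s*255\s*\))\s*$", re.I
)
_NONE_RE = re.compile(r"^\s*none\s*$", re.I)

#: fraction of the viewBox a white shape must cover to count as background
BACKGROUND_COVERAGE_THRESHOLD = 0.98


def _presentation_value(el: etree._Element, prop: str) -> str | None:
    style = parse_style_attribute(el.get("style") or "")
    if prop in style:
        return style[prop]
    return el.get(prop)


def _shape_bbox(el: etree._Element, vb) -> tuple[float, float, float, float] | None:
    """Axis-aligned bbox of simple shapes; percentages resolve against vb."""

    def num(attr: str, default: float, ref: float) -> float:
        raw = el.get(attr)
        if raw is None:
            return default
        raw = raw.strip()
        try:
            if raw.endswith("%"):
                return float(raw[:-1]) / 100.0 * ref
            return float(raw)
        except ValueError:
            return default

    tag = localname(el)
    if tag == "rect":
        x = num("x", 0.0, vb.width)
        y = num("y", 0.0, vb.height)
        w = num("width", 0.0, vb.width)
        h = num("height", 0.0, vb.height)
        return (x, y, w, h)
    if tag == "circle":
        cx, cy = num("cx", 0.0, vb.width), num("cy", 0.0, vb.height)
        r = num("r", 0.0, vb.width)
        return (cx - r, cy - r, 2 * r, 2 * r)
    if tag == "ellipse":
        cx, cy = num("cx", 0.0, vb.width), num("cy", 0.0, vb.height)
        rx, ry = num("rx", 0.0, vb.width), num("ry", 0.0, vb.height)
        return (cx - rx, cy - ry, 2 * rx, 2 * ry)
    return None


def strip_white_background(doc: SvgDocument) -> SvgDocument:
    """Remove background paint so the document becomes transparent.

    Removes any root-level ``background``/``background-color`` declaration and
    every unstroked shape with exactly-white fill whose bounding box covers at
    least :data:`BACKGROUND_COVERAGE_THRESHOLD` of the viewBox.  Small white
    glyphs are preserved.  Idempotent; mutates in place.
    """
    vb = doc.effective_view_box
    vb_area = vb.width * vb.height
    root_style = parse_style_attribute(doc.root.get("style") or "")
    for prop in ("background", "background-color"):
        root_style.pop(prop, None)
    if doc.root.get("style") is not None:
        if root_style:
            doc.root.set("style", serialize_style_attribute(root_style))
        else:
            del doc.root.attrib["style"]

    to_remove = []
    for el in doc.root.iter():
        if not isinstance(el.tag, str):
            continue
        fill = _presentation_value(el, "fill")
        if fill is None or not _WHITE_RE.match(fill):
            continue
        stroke = _presentation_value(el, "stroke")
        if stroke is not None and not _NONE_RE.match(stroke):
            continue
        bbox = _shape_bbox(el, vb)
        if bbox is None:
            continue
        x, y, w, h = bbox
        ix = max(x, vb.min_x)
        iy = max(y, vb.min_y)
        ix2 = min(x + w, vb.min_x + vb.width)
        iy2 = min(y + h, vb.min_y + vb.height)
        inter = max(0.0, ix2 - ix) * max(0.0, iy2 - iy)
        if vb_area > 0 and inter / vb_area >= BACKGROUND_COVERAGE_THRESHOLD:
            to_remove.append(el)
    for el in to_remove:
        parent = el.getparent()
        if parent is not None:
            parent.remove(el)
    return doc
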