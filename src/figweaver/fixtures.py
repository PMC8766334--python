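"""Deterministic generators for adversarial inputs.

Real-world trouble cases for figure composition are plots from different
tools that share stylesheet selectors (``.edge``, ``circle``, ...) bound to
different paints, reuse the same element ids (``node1``, ``grad1``), carry
gradient definitions referenced through ``url(#...)``, embed link-outs to
external databases, and sit on an opaque white background.  This module
manufactures exactly those documents — plus whole random sessions — from a
seed, so every other module can be tested without downloading anything.
All outputs are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

from lxml import etree
from PIL import Image

from .composer_io import Asset, Session, TextBlock
from .layout_engine import Canvas, Panel, Rect
from .svg_model import NSMAP, SVG_NS, XLINK_NS, SvgDocument, ViewBox, parse_svg

_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5", "#393b79", "#637939", "#8c6d31", "#843c39",
    "#7b4173", "#3182bd", "#e6550d", "#31a354", "#756bb1", "#636363",
]

#: sample title exercising emphasis and unicode, used by gen_session
_TITLE_SAMPLES = [
    "**Panel** α: *expression*",
    "Pathway ♥ overview",
    "*UMAP* of 10× data — **clusters**",
    "Δ log₂ fold-change",
    "plain title",
]

#: one text block touching every markdown-lite pattern
ALL_PATTERN_TEXT = (
    "# Results\n## Subsection\n### Detail\n#### Minor\n##### Fine\n"
    "###### caption\n*ital* and **bold** mixed\n"
    "1. first\n2. second\n* star item\n- dash item"
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a batch of mutually conflicting SVG assets."""

    seed: int
    n_assets: int = 2
    conflict_selectors: tuple[str, ...] = (".edge", "circle", "#n1")
    shared_ids: tuple[str, ...] = ("node1", "grad1")
    include_gradients: bool = False
    include_links: bool = False
    include_white_background: bool = False

    def __post_init__(self) -> None:
        if self.n_assets < 1:
            raise ValueError("n_assets must be >= 1")


def _el(parent, tag, **attrs):
    el = etree.SubElement(parent, f"{{{SVG_NS}}}{tag}")
    for k, v in attrs.items():
        el.set(k.replace("_", "-"), str(v))
    return el


def _selector_element(parent, selector: str, rng: random.Random) -> etree._Element:
    """Create an element guaranteed to match `selector` and nothing else in
    the conflict set."""
    if selector.startswith("."):
        return _el(parent, "rect", x=rng.randint(0, 100), y=rng.randint(0, 100),
                   width=30, height=18, **{"class": selector[1:]})
    if selector.startswith("#"):
        return _el(parent, "rect", x=rng.randint(0, 100), y=rng.randint(100, 160),
                   width=24, height=24, id=selector[1:])
    # a type selector
    if selector == "circle":
        return _el(parent, "circle", cx=rng.randint(20, 180),
                   cy=rng.randint(20, 180), r=rng.randint(5, 15))
    return _el(parent, selector)


def gen_conflicting_svgs(spec: FixtureSpec
                         ) -> tuple[list[SvgDocument], list[dict[str, str]]]:
    """Generate ``n_assets`` documents that would clash if inlined together.

    Every asset binds each ``conflict_selector`` to its own paint (paints
    differ across assets per selector) and defines every ``shared_id`` once.
    Returns ``(docs, truth)`` where ``truth[i][selector]`` is the paint the
    sanitized asset *i* must show for elements matched by ``selector``.
    """
    rng = random.Random(spec.seed)
    # distinct paints per selector across assets
    paints = {
        sel: rng.sample(_PALETTE, spec.n_assets)
        for sel in spec.conflict_selectors
    }
    docs: list[SvgDocument] = []
    truth: list[dict[str, str]] = []
    for i in range(spec.n_assets):
        root = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
        root.set("width", "200")
        root.set("height", "200")
        root.set("viewBox", "0 0 200 200")
        if spec.include_white_background:
            _el(root, "rect", x=0, y=0, width=200, height=200, fill="#ffffff")
        css_lines = [f"{sel} {{ fill: {paints[sel][i]}; }}"
                     for sel in spec.conflict_selectors]
        style = etree.SubElement(root, f"{{{SVG_NS}}}style")
        style.text = "\n".join(css_lines)
        for sel in spec.conflict_selectors:
            _selector_element(root, sel, rng)
        for shared_id in spec.shared_ids:
            if spec.include_gradients and shared_id.startswith("grad"):
                continue  # defined below inside <defs>
            g = _el(root, "g", id=shared_id)
            _el(g, "rect", x=rng.randint(0, 150), y=rng.randint(0, 150),
                width=10, height=10, fill=rng.choice(_PALETTE))
        if spec.include_gradients:
            defs = etree.SubElement(root, f"{{{SVG_NS}}}defs")
            grad_ids = [s for s in spec.shared_ids if s.startswith("grad")] or ["grad1"]
            for grad_id in grad_ids:
                grad = _el(defs, "linearGradient", id=grad_id,
                           x1=0, y1=0, x2=1, y2=0)
                _el(grad, "stop", offset="0", stop_color=rng.choice(_PALETTE))
                _el(grad, "stop", offset="1", stop_color=rng.choice(_PALETTE))
                _el(root, "rect", x=40, y=40, width=60, height=20,
                    fill=f"url(#{grad_id})")
        if spec.include_links:
            a = etree.SubElement(root, f"{{{SVG_NS}}}a")
            a.set(f"{{{XLINK_NS}}}href", "https://www.uniprot.org/uniprot/Q9NWZ3")
            label = _el(a, "text", x=10, y=190, font_size=10)
            label.text = "IRAK4"
        # tiny white glyph that must survive background stripping; a bare
        # rect so no conflict selector can restyle it
        _el(root, "rect", x=166, y=26, width=8, height=8, fill="white")
        docs.append(parse_svg(etree.tostring(root, encoding="unicode")))
        truth.append({sel: paints[sel][i] for sel in spec.conflict_selectors})
    return docs, truth


def gen_reference_svg(seed: int) -> SvgDocument:
    """One pathway-like document with a stylesheet, gradient, link-out and
    white background — the single-asset fixture for round-trip and
    sanitation-fidelity tests."""
    docs, _ = gen_conflicting_svgs(FixtureSpec(
        seed=seed, n_assets=1, include_gradients=True, include_links=True,
        include_white_background=True))
    return docs[0]


_RULE_PROPS = ["fill", "stroke", "opacity", "stroke-width"]


def gen_random_styled_svg(seed: int) -> SvgDocument:
    """A randomized document for cascade-equivalence testing.

    Random shallow tree of ``g``/``rect``/``circle`` elements with random
    classes and ids, a stylesheet with randomly chosen selectors (type,
    class, id, descendant, grouped), occasional ``!important`` flags and
    pre-existing inline styles.
    """
    rng = random.Random(seed)
    classes = ["a", "b", "node", "edge"]
    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap=NSMAP)
    root.set("viewBox", "0 0 100 100")
    n_groups = rng.randint(1, 3)
    uid = 0
    for _ in range(n_groups):
        g = _el(root, "g")
        if rng.random() < 0.5:
            g.set("class", rng.choice(classes))
        for _ in range(rng.randint(1, 4)):
            tag = rng.choice(["rect", "circle"])
            child = _el(g, tag)
            if tag == "rect":
                child.set("width", "10")
                child.set("height", "10")
            else:
                child.set("r", "5")
            if rng.random() < 0.6:
                child.set("class", " ".join(
                    rng.sample(classes, rng.randint(1, 2))))
            if rng.random() < 0.3:
                uid += 1
                child.set("id", f"e{uid}")
            if rng.random() < 0.25:
                child.set("style", f"fill: {rng.choice(_PALETTE)}")
    selectors = ["rect", "circle", "g", "*"] + \
        [f".{c}" for c in classes] + \
        [f"g.{rng.choice(classes)} rect", "g > circle"] + \
        [f"#e{i}" for i in range(1, uid + 1)]
    css_lines = []
    for _ in range(rng.randint(2, 8)):
        sel = rng.choice(selectors)
        if rng.random() < 0.2:
            sel = sel + ", " + rng.choice(selectors)
        prop = rng.choice(_RULE_PROPS)
        value = (rng.choice(_PALETTE) if prop in ("fill", "stroke")
                 else str(rng.choice([0.25, 0.5, 1, 2])))
        bang = " !important" if rng.random() < 0.15 else ""
        css_lines.append(f"{sel} {{ {prop}: {value}{bang}; }}")
    style = etree.SubElement(root, f"{{{SVG_NS}}}style")
    style.text = "\n".join(css_lines)
    return parse_svg(etree.tostring(root, encoding="unicode"))


def _gen_raster_bytes(rng: random.Random, fmt: str) -> bytes:
    im = Image.new("RGB", (rng.randint(4, 16), rng.randint(4, 16)),
                   tuple(rng.randint(0, 255) for _ in range(3)))
    buf = io.BytesIO()
    im.save(buf, format=fmt.upper())
    return buf.getvalue()


def gen_session(seed: int, n_panels: int) -> Session:
    """A full random session: mixed SVG + raster assets, random rects inside
    the canvas, a random z permutation, opacities in [0, 1], zooms in
    [0.25, 4], unicode titles and a text block using all eleven patterns."""
    if n_panels < 1:
        raise ValueError("n_panels must be >= 1")
    rng = random.Random(seed)
    canvas = Canvas(width=float(rng.randint(600, 1200)),
                    height=float(rng.randint(400, 900)),
                    background=rng.choice([None, "white", "#f8f8f8"]))
    docs, _ = gen_conflicting_svgs(FixtureSpec(
        seed=rng.randrange(2**31), n_assets=n_panels,
        include_gradients=True, include_links=True,
        include_white_background=True))
    assets: dict[str, Asset] = {}
    panels: list[Panel] = []
    zs = list(range(n_panels))
    rng.shuffle(zs)
    for i, doc in enumerate(docs):
        if i % 4 == 3:  # every fourth asset is a raster
            fmt = rng.choice(["png", "jpeg", "gif"])
            asset_id = f"raster{i}.{fmt}"
            assets[asset_id] = Asset(format=fmt,
                                     content=_gen_raster_bytes(rng, fmt))
        else:
            asset_id = f"plot{i}.svg"
            assets[asset_id] = Asset(
                format="svg",
                content=etree.tostring(doc.root, encoding="unicode"))
        w = float(rng.randint(80, max(81, int(canvas.width) // 2)))
        h = float(rng.randint(80, max(81, int(canvas.height) // 2)))
        x = float(rng.randint(0, max(1, int(canvas.width - w))))
        y = float(rng.randint(0, max(1, int(canvas.height - h))))
        panels.append(Panel(
            asset_ref=asset_id,
            rect=Rect(x, y, w, h),
            z=zs[i],
            opacity=round(rng.uniform(0.0, 1.0), 3),
            zoom=round(rng.uniform(0.25, 4.0), 3),
            pan=(float(rng.randint(-20, 20)), float(rng.randint(-20, 20))),
            title=rng.choice(_TITLE_SAMPLES) if rng.random() < 0.8 else None,
            strip_background=rng.random() < 0.5,
        ))
    text_blocks = []
    if rng.random() < 0.7:
        text_blocks.append(TextBlock(
            rect=Rect(10.0, 10.0, 300.0, 200.0), text=ALL_PATTERN_TEXT))
    return Session(canvas=canvas, assets=assets, panels=panels,
                   text_blocks=text_blocks)
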