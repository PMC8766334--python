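"""Minimal deterministic SVG rasterizer for fidelity tests.

Renders the restricted element subset the fixtures use — ``rect``,
``circle``, ``g`` (with group opacity), nested ``svg`` viewports with
``viewBox`` + centered "meet" scaling, ``linearGradient`` fills referenced
via ``url(#...)``, ``<a>`` wrappers — onto a numpy RGBA buffer with hard
(center-sampled) edges and source-over compositing.  Stylesheets are
resolved through the brute-force cascade oracle, so original documents
(global ``<style>``) and sanitized documents (inline styles) go through the
same pipeline and can be compared pixel for pixel.

Text is not rendered; fidelity checks rely on identical text nodes on both
sides of a comparison.
"""

from __future__ import annotations

import re

import numpy as np

from _cascade_oracle import _parse_inline, oracle_effective_styles

_NAMED_COLORS = {
    "white": (255, 255, 255), "black": (0, 0, 0), "red": (255, 0, 0),
    "green": (0, 128, 0), "blue": (0, 0, 255), "none": None,
    "transparent": None,
}

_URL_RE = re.compile(r"""url\(\s*['"]?#([^)'"\s]+)['"]?\s*\)""")


def _local(el):
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _parse_color(value):
    """-> (r, g, b) floats in [0,1] or None for no paint."""
    value = value.strip().lower()
    if value in _NAMED_COLORS:
        rgb = _NAMED_COLORS[value]
        return None if rgb is None else tuple(c / 255.0 for c in rgb)
    m = re.match(r"^#([0-9a-f]{3})$", value)
    if m:
        return tuple(int(c * 2, 16) / 255.0 for c in m.group(1))
    m = re.match(r"^#([0-9a-f]{6})$", value)
    if m:
        h = m.group(1)
        return tuple(int(h[i:i + 2], 16) / 255.0 for i in (0, 2, 4))
    m = re.match(r"^rgb\(\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)$", value)
    if m:
        return tuple(int(g) / 255.0 for g in m.groups())
    raise ValueError(f"mini-rasterizer: unsupported color {value!r}")


class _Ctx:
    """Uniform device transform (device = s*user + t) plus a clip rect."""

    def __init__(self, s, tx, ty, clip):
        self.s, self.tx, self.ty = s, tx, ty
        self.clip = clip  # (x0, y0, x1, y1) device coords


def _style_lookup(el, prop, styles):
    cur = el
    while cur is not None:
        eff = styles.get(cur, {})
        if prop in eff:
            return eff[prop], cur
        inline = _parse_inline(cur.get("style") or "")
        if prop in inline:
            return inline[prop], cur
        attr = cur.get(prop)
        if attr is not None:
            return attr, cur
        cur = cur.getparent()  # fill/stroke inherit
    return None, None


def _source_over(dst, src_rgb, src_a, mask):
    a_s = np.zeros(dst.shape[:2])
    a_s[mask] = src_a if np.isscalar(src_a) else src_a[mask]
    a_d = dst[..., 3]
    a_out = a_s + a_d * (1 - a_s)
    safe = a_out > 0
    for ch in range(3):
        c_s = np.zeros(dst.shape[:2])
        if isinstance(src_rgb, tuple):
            c_s[mask] = src_rgb[ch]
        else:
            c_s[mask] = src_rgb[..., ch][mask]
        num = c_s * a_s + dst[..., ch] * a_d * (1 - a_s)
        dst[..., ch] = np.where(safe, np.divide(num, a_out,
                                                out=np.zeros_like(num),
                                                where=safe), 0.0)
    dst[..., 3] = a_out


def _composite_layer(dst, layer, opacity):
    a_s = layer[..., 3] * opacity
    a_d = dst[..., 3]
    a_out = a_s + a_d * (1 - a_s)
    safe = a_out > 0
    for ch in range(3):
        num = layer[..., ch] * a_s + dst[..., ch] * a_d * (1 - a_s)
        dst[..., ch] = np.where(safe, np.divide(num, a_out,
                                                out=np.zeros_like(num),
                                                where=safe), 0.0)
    dst[..., 3] = a_out


class MiniRasterizer:
    def __init__(self, doc, scale=2.0):
        self.scale = scale
        self.width = int(round(doc.intrinsic_width * scale))
        self.height = int(round(doc.intrinsic_height * scale))
        self.root = doc.root
        self.styles = oracle_effective_styles(self.root)
        self.ids = {el.get("id"): el for el in self.root.iter()
                    if isinstance(el.tag, str) and el.get("id")}
        xs = (np.arange(self.width) + 0.5)
        ys = (np.arange(self.height) + 0.5)
        self.X, self.Y = np.meshgrid(xs, ys)
        vb = doc.effective_view_box
        s = min(self.width / vb.width, self.height / vb.height)
        tx = (self.width - vb.width * s) / 2.0 - vb.min_x * s
        ty = (self.height - vb.height * s) / 2.0 - vb.min_y * s
        self.root_ctx = _Ctx(s, tx, ty, (0.0, 0.0, float(self.width),
                                         float(self.height)))

    def render(self):
        buf = np.zeros((self.height, self.width, 4))
        for child in self.root:
            self._render_el(child, self.root_ctx, buf)
        return buf

    # -- element dispatch ------------------------------------------------

    def _render_el(self, el, ctx, buf):
        tag = _local(el)
        if tag in ("style", "defs", "linearGradient", "radialGradient",
                   "text", "image", "title", "desc", "") or tag is None:
            return
        opacity_raw, owner = _style_lookup(el, "opacity", self.styles)
        opacity = 1.0
        if opacity_raw is not None and owner is el:  # opacity does not inherit
            opacity = float(opacity_raw)
        target = buf
        layer = None
        if opacity < 1.0:
            layer = np.zeros_like(buf)
            target = layer
        if tag == "svg" and el is not self.root:
            self._render_nested_svg(el, ctx, target)
        elif tag in ("g", "a"):
            for child in el:
                self._render_el(child, ctx, target)
        elif tag == "rect":
            self._render_rect(el, ctx, target)
        elif tag == "circle":
            self._render_circle(el, ctx, target)
        else:
            raise ValueError(f"mini-rasterizer: unsupported element <{tag}>")
        if layer is not None:
            _composite_layer(buf, layer, opacity)

    def _render_nested_svg(self, el, ctx, buf):
        x = float(el.get("x", 0)) * ctx.s + ctx.tx
        y = float(el.get("y", 0)) * ctx.s + ctx.ty
        w = float(el.get("width")) * ctx.s
        h = float(el.get("height")) * ctx.s
        vb_raw = el.get("viewBox")
        if vb_raw:
            mx, my, vw, vh = (float(v) for v in re.split(r"[\s,]+", vb_raw.strip()))
        else:
            mx, my, vw, vh = 0.0, 0.0, w / ctx.s, h / ctx.s
        s = min(w / vw, h / vh)
        tx = x + (w - vw * s) / 2.0 - mx * s
        ty = y + (h - vh * s) / 2.0 - my * s
        clip = (max(ctx.clip[0], x), max(ctx.clip[1], y),
                min(ctx.clip[2], x + w), min(ctx.clip[3], y + h))
        inner = _Ctx(s, tx, ty, clip)
        for child in el:
            self._render_el(child, inner, buf)

    # -- shapes ----------------------------------------------------------

    def _clip_mask(self, ctx):
        x0, y0, x1, y1 = ctx.clip
        return (self.X >= x0) & (self.X < x1) & (self.Y >= y0) & (self.Y < y1)

    def _paint(self, el, ctx, buf, mask):
        fill_raw, _ = _style_lookup(el, "fill", self.styles)
        if fill_raw is None:
            fill_raw = "black"  # SVG initial fill
        fill_raw = fill_raw.strip()
        fill_opacity_raw, owner = _style_lookup(el, "fill-opacity", self.styles)
        fill_a = float(fill_opacity_raw) if fill_opacity_raw is not None else 1.0
        mask = mask & self._clip_mask(ctx)
        if not mask.any():
            return
        m = _URL_RE.match(fill_raw)
        if m:
            rgb_img = self._gradient_image(el, ctx, m.group(1))
            _source_over(buf, rgb_img, fill_a, mask)
            return
        rgb = _parse_color(fill_raw)
        if rgb is None:
            return
        _source_over(buf, rgb, fill_a, mask)

    def _user_bbox(self, el):
        tag = _local(el)
        if tag == "rect":
            x, y = float(el.get("x", 0)), float(el.get("y", 0))
            return x, y, float(el.get("width")), float(el.get("height"))
        cx, cy, r = (float(el.get(k, 0)) for k in ("cx", "cy", "r"))
        return cx - r, cy - r, 2 * r, 2 * r

    def _gradient_image(self, el, ctx, grad_id):
        grad = self.ids.get(grad_id)
        if grad is None or _local(grad) != "linearGradient":
            raise ValueError(f"mini-rasterizer: unresolved gradient #{grad_id}")
        x1 = float(grad.get("x1", 0)); y1 = float(grad.get("y1", 0))
        x2 = float(grad.get("x2", 1)); y2 = float(grad.get("y2", 0))
        stops = []
        for stop in grad:
            if _local(stop) != "stop":
                continue
            off = float(stop.get("offset", 0))
            color_raw, _ = _style_lookup(stop, "stop-color", self.styles)
            stops.append((off, _parse_color(color_raw or "black")))
        stops.sort(key=lambda t: t[0])
        bx, by, bw, bh = self._user_bbox(el)
        ux = (self.X - ctx.tx) / ctx.s
        uy = (self.Y - ctx.ty) / ctx.s
        px = (ux - bx) / bw
        py = (uy - by) / bh
        dx, dy = x2 - x1, y2 - y1
        denom = dx * dx + dy * dy or 1.0
        t = np.clip(((px - x1) * dx + (py - y1) * dy) / denom, 0.0, 1.0)
        offs = [s[0] for s in stops]
        img = np.zeros(self.X.shape + (3,))
        for ch in range(3):
            img[..., ch] = np.interp(t, offs, [s[1][ch] for s in stops])
        return img

    def _render_rect(self, el, ctx, buf):
        x, y, w, h = self._user_bbox(el)
        x0, y0 = x * ctx.s + ctx.tx, y * ctx.s + ctx.ty
        x1, y1 = x0 + w * ctx.s, y0 + h * ctx.s
        mask = (self.X >= x0) & (self.X < x1) & (self.Y >= y0) & (self.Y < y1)
        self._paint(el, ctx, buf, mask)

    def _render_circle(self, el, ctx, buf):
        cx = float(el.get("cx", 0)) * ctx.s + ctx.tx
        cy = float(el.get("cy", 0)) * ctx.s + ctx.ty
        r = float(el.get("r", 0)) * ctx.s
        mask = (self.X - cx) ** 2 + (self.Y - cy) ** 2 <= r * r
        self._paint(el, ctx, buf, mask)


def rasterize(doc, scale=2.0) -> np.ndarray:
    """Render `doc` to an RGBA float array at `scale` device px per user unit."""
    return MiniRasterizer(doc, scale=scale).render()


def to_rgb_on_white(buf: np.ndarray) -> np.ndarray:
    """Flatten RGBA over a white page, 8-bit — convenient for comparisons."""
    a = buf[..., 3:4]
    rgb = buf[..., :3] * a + (1 - a)
    return np.round(rgb * 255).astype(np.uint8)
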