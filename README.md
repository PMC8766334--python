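# figweaver

Headless composition of multi-panel scientific figures from vector (SVG) and
raster (PNG/JPEG/GIF) plots.

## The problem

Bioinformatics tools — pathway databases, heatmap packages, ggplot2/D3
pipelines — emit publication-quality plots as SVG. Assembling several of them
into one composite figure by inlining them into a single document breaks in
two characteristic ways:

1. **Stylesheet cross-talk.** `<style>` rules in SVG are globally scoped.
   When two plots both define `.edge { stroke: ... }` or `circle { fill: ... }`
   with different values, they share one parse tree after merging and the
   cascade picks a single winner — one plot silently restyles the other.
2. **Id collisions.** Both plots defining `id="grad1"` leaves `url(#grad1)`
   references ambiguous; gradients, clip paths and links break.

figweaver sanitizes every asset before placement:

* **Cascade inlining** — for every element and property, the winning
  declaration is chosen by the standard cascade order
  *(importance, specificity, source order)*, with specificity the triple
  *(id count, class+attribute count, type count)* and a pre-existing inline
  `style` attribute outranking all non-`!important` rules. The winner is
  written into the element's `style` attribute and all `<style>` elements are
  removed, so the document carries its styling with it.
* **Id namespacing** — panel *X* (1-based session position) gets every id
  renamed `id` → `id--inject-X`, with every internal reference (`url(#id)`
  in attributes or styles, fragment-only `href="#id"`) rewritten
  consistently. External links (e.g. UniProt link-outs) are preserved
  verbatim and stay clickable in the output.

Panels are then placed on a canvas as nested SVG viewports. A panel with
viewBox *vb*, zoom *z* and pan *(dx, dy)* shows the source window

```
window = (vb.x + dx, vb.y + dy, vb.w / z, vb.h / z)
```

with centered uniform scaling (`xMidYMid meet`, never distorting). Stacking
uses painter order: panels are emitted in ascending z, so larger z draws on
top; per-panel group opacity and optional white-background stripping let
plots overlay (e.g. spatial clustering over histology). Titles and text
blocks use an 11-pattern markdown-lite grammar (`*i*`, `**b**`, `#`–`######`
headings, `1. `/`* `/`- ` lists).

Output is a standalone composite SVG and/or a **self-contained interactive
HTML** file — composite inline, click-to-enlarge panels, no external
references — which embeds the full session as JSON and can be reloaded to
continue editing.

## Worked example

```sh
figweaver fixtures --seed 1 --n-assets 2 --out assets
cat > figure.yaml <<'EOF'
canvas: {width: 500, height: 280, background: white}
panels:
  - {asset: assets/asset0.svg, x: 20,  y: 20, w: 220, h: 220, z: 1,
     title: "**A** pathway", strip_background: true}
  - {asset: assets/asset1.svg, x: 200, y: 40, w: 220, h: 220, z: 2,
     opacity: 0.6, zoom: 2, pan: [10, 10], title: "**B** *overlay*"}
text_blocks:
  - {x: 20, y: 248, w: 460, h: 30, text: "###### Panels generated by figweaver fixtures"}
EOF
figweaver compose figure.yaml --out-svg figure.svg --out-html figure.html
```

prints

```
figweaver: INFO: wrote 2 assets to assets
figweaver: INFO: wrote figure.svg
figweaver: INFO: wrote figure.html
```

The two fixture assets deliberately share the ids `node1`/`grad1` and the
selectors `.edge`, `circle`, `#n1` with clashing paints; in `figure.svg` the
ids appear exactly once each as `node1--inject-1` and `node1--inject-2`, the
stylesheets are gone, and each plot keeps its own colors. Panel B sits on
top at 60 % opacity showing a 2× zoom window shifted by (10, 10). Opening
`figure.html` in a browser gives click-to-enlarge panels;
`figweaver reload figure.html --out-manifest recovered.yaml` restores the
manifest and asset files for further editing, and the recovered manifest
composes to byte-identical output.

The same pipeline is available as a library:

```python
from figweaver import Session, Canvas, Panel, Rect, Asset, compose, write_html
```

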