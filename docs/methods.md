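# Methods

This note documents the models and procedures figweaver implements, the
parameters that matter, what the generated test inputs do and do not
emulate, and the design decisions taken where the problem left room.

## Coordinate model

One coordinate convention is used throughout: origin top-left, y increasing
downward, one user unit = one CSS pixel (96 per inch). Canvas units are user
units; print resolution is left to the renderer since vector output is
resolution-independent.

Intrinsic document geometry resolves in this order: explicit
`width`/`height` attributes (units `px`, `pt`, `pc`, `mm`, `cm`, `in`
converted at 96 units/inch; percentages resolved against the viewBox, an
error without one), else the viewBox dimensions, else 300×150 — the common
renderer default, chosen as a deterministic fallback. Font-relative units
(`em`/`ex`) are rejected with a clear error: plotting-tool outputs
essentially never size the root element in font units, and guessing a font
context would make geometry nondeterministic.

XML comments and processing instructions are preserved through
parse/serialize; a DOCTYPE is dropped on output because it interferes with
inlining the document into HTML. Serialization is deterministic for
identical trees; tree equality in tests is judged on the C14N canonical
form, i.e. up to attribute-order normalization.

## The cascade inliner

### Supported selector subset

Universal (`*`), type, class, id, attribute presence/equality, descendant
and child combinators, and comma grouping. Pseudo-classes/elements, sibling
combinators and at-rules (media queries) are skipped with a warning rather
than an error: a skipped decorative rule degrades styling gracefully,
whereas aborting would reject the whole asset. This subset covers what
plotting libraries and pathway exporters actually emit.

### Resolution order

For each element and property the winning declaration is the maximum under
the key *(important, specificity, source order)* where specificity is
*(ids, classes+attributes, types)* and source order is the global rule index
across all `<style>` elements (comma groups split into one rule per member,
each with its own specificity and order). Two deliberate placements follow
standard cascade semantics so that the scoped output renders exactly as a
browser rendered the original:

* a pre-existing inline `style` attribute outranks every non-important rule;
* `!important` declarations outrank the inline style.

Ties in specificity are broken by source order (later wins). Inheritance is
**not** materialized: only matched declarations are inlined, and inheritable
properties keep propagating naturally through the tree. Materializing
computed styles would bloat the output and, worse, change the semantics of
descendant overrides. Presentation attributes (`fill="..."`) are left in
place and outranked by the merged `style` attribute per standard precedence.

Malformed declarations and unsupported selectors produce warnings and are
skipped; rule collection is never fatal. The operation is idempotent: after
the `<style>` elements are removed, a second pass finds no rules and leaves
every element untouched.

### Verification strategy

The inliner is checked against an independent brute-force oracle
(`tests/_cascade_oracle.py`) that tests every rule against every element
with no indexing — descendant matching enumerates entire ancestor chains —
and sorts the full candidate list per property. Randomized documents
(random trees, random selectors including grouped and combinator forms,
random `!important` flags and inline styles) must agree on every
(element, property) pair.

## Id namespacing

Every `id` value `v` becomes `v--inject-X`, X the panel's 1-based position
in the session (a running number incremented per added image). Rewritten
reference forms: functional `url(#v)` anywhere in attribute values
(including inline styles), and fragment-only `href`/`xlink:href="#v"`.
URLs with a host or path are left verbatim, which keeps database link-outs
active in the composite. A reference to a nonexistent id is left as-is with
a warning — the input was already broken and rewriting a dangling reference
could only mask that.

## White-background removal

"Background" is defined operationally: a shape with exactly-white fill
(`#fff`, `#ffffff`, `white`, `rgb(255,255,255)`, case-insensitive), no
stroke (absent or `none`), whose bounding box covers at least **0.98** of
the viewBox area; plus any root-level `background`/`background-color`
declaration. The exact-white + near-full-coverage rule avoids eating white
diagram glyphs (small markers, knockout text) while catching the canvas
rects that plotting tools emit. Bounding boxes are computed for `rect`,
`circle` and `ellipse`; percentages resolve against the viewBox. The
operation is idempotent and is applied only to panels that request it.

## Layout

Larger z means nearer the viewer; panels are emitted in ascending-z painter
order with a stable sort, so equal z preserves session order. The zoom/pan
window is `(vb.x+dx, vb.y+dy, vb.w/zoom, vb.h/zoom)`; zoom must be
positive, making the mapping invertible, and window area scales as 1/zoom².
Aspect ratio is always preserved with centered fit-inside scaling
(`xMidYMid meet`) — a panel that wants fill-crop behavior expresses it
through zoom/pan rather than by letting the composer distort the plot.
Opacity 1.0 emits no attribute (canonical form), so default panels
serialize identically whether or not opacity was specified.

## Text

The grammar implements exactly eleven patterns: `*...*` italic, `**...**`
bold (longest delimiter tried first), line-leading `#`–`######` headings
1–6, `1. ` ordered-list lines (any `N. ` prefix is accepted), and `* `/`- `
unordered-list lines; consecutive list lines group into one list. Unmatched
or empty delimiters stay literal, making the grammar total. Emphasis
resolves left-to-right first-match; the search for a closing `*` steps over
`**` pairs so bold can nest inside italic deterministically.

Rendering: one `<text>` element per visual line; baselines advance by 1.4×
the line's font size; heading sizes are {h1: 2.0, h2: 1.5, h3: 1.3,
h4: 1.15, h5: 1.0, h6: 0.85} × the 16 px base, all bold — mirroring common
user-agent defaults, since no standard exists for SVG text. List items are
prefixed `N. ` or `• `. Richer editor features (font families, colors) are
out of grammar; per-node overrides pass through the session untouched.

## Session schema and HTML output

The session is a versioned JSON document (`schema_version: "1.0"`) with all
assets inline — SVG as text, rasters base64 — because self-containment is
the essential property of a sharable session file. Titles and text blocks
are stored as their markdown-lite *source* strings; the parsed tree is
derived data recomputed at compose time, which keeps round-trip equality a
plain structural comparison. Reload restores the pre-sanitization session
and compose re-runs the full pipeline, so sanitation never accumulates.

The HTML output embeds the composite inline, the session JSON in a
`<script type="application/json">` block (`<` unicode-escaped so no HTML
parsing hazard exists), and a small self-contained script providing
click-to-enlarge on the stable `figweaver-panel-N` wrappers. There are no
external references of any kind; asset hyperlinks inside the composite are
the only URLs and remain clickable. Serialization is canonical (sorted
keys), so identical sessions produce byte-identical SVG and HTML — verified
by re-running the whole pipeline twice.

PDF export is a thin adapter over an SVG renderer (`cairosvg` when
installed); the page box equals the canvas. Without a renderer it raises a
capability error pointing to the browser print-to-PDF route, since the
correctness surface is the SVG itself.

## Synthetic inputs: what they cover and what they do not

The fixture generator manufactures the adversarial conditions the tool
exists for: assets sharing selectors bound to distinct paints (with a
ground-truth table for oracle tests), shared ids, gradients referenced via
`url(#...)`, absolute link-outs, full-canvas white backgrounds, plus whole
random sessions (random rects inside the canvas, z permutations, opacities
in [0, 1], zooms in [0.25, 4], unicode titles, text exercising every
pattern). Everything is byte-deterministic per seed.

Real exports differ in ways the fixtures do not emulate: deeply nested
transform stacks, `<use>` indirection, fonts and text-on-path, filters,
CSS variables, and multi-megabyte pathway diagrams. Passing tests therefore
demonstrate correctness of the cascade/namespacing/layout machinery on the
supported subset, not coverage of every SVG feature in the wild; unsupported
selector features degrade with warnings by design.

## Rendering fidelity checks

Fidelity of sanitation ("inlining + namespacing changes no pixel") is
checked with a deterministic reference rasterizer shipped with the test
suite: center-sampled hard-edge rendering of the fixture element subset
(rects, circles, linear gradients, nested viewports, group opacity) onto a
numpy RGBA buffer at 2× resolution, with stylesheets resolved through the
independent brute-force cascade oracle. Because original and sanitized
documents go through the identical pipeline, any semantic change surfaces
as a pixel difference at tolerance 0. When `cairosvg` is importable the
same comparison is additionally cross-checked under it. The same rasterizer
verifies painter order (only the top opaque panel survives an overlap) and
opacity compositing (zero-opacity panels contribute nothing; two
half-transparent layers both remain visible).

## Problem sizes

Default verification sizes: ~200 randomized documents for cascade
equivalence, composites of up to 25 clashing assets for id safety, 100
random sessions for round-trip identity, 2× resolution for pixel checks.
These sizes exercise every code path and interaction while keeping the full
suite in the low seconds on one CPU.
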