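"""style_scoper: cascade inlining, id namespacing, background stripping."""

import re
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from figweaver.errors import ScopingWarning, UnsupportedSelectorError
from figweaver.fixtures import (FixtureSpec, gen_conflicting_svgs,
                                gen_random_styled_svg)
from figweaver.style_scoper import (cascade_inline, collect_rules,
                                    compute_specificity, namespace_ids,
                                    parse_style_attribute,
                                    strip_white_background)
from figweaver.svg_model import canonical_svg, localname, parse_svg, serialize_svg

from _cascade_oracle import oracle_effective_styles, oracle_specificity

SVG = '<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 100 100">{}</svg>'


def elements(doc):
    return [el for el in doc.root.iter() if isinstance(el.tag, str)]


def inlined(el):
    return parse_style_attribute(el.get("style") or "")


# ---------------------------------------------------------------------------
# specificity

# hand-computed per the cascade definition: (ids, classes+attrs, types)
SPECIFICITY_TABLE = [
    ("*", (0, 0, 0)),
    ("rect", (0, 0, 1)),
    (".c", (0, 1, 0)),
    ("#i", (1, 0, 0)),
    ("g.node rect", (0, 1, 2)),
    ("#a .b", (1, 1, 0)),
    ("#legend .key", (1, 1, 0)),
    ("g > circle", (0, 0, 2)),
    ("g rect.a", (0, 1, 2)),
    ("[fill]", (0, 1, 0)),
    ("[fill=red]", (0, 1, 0)),
    ("rect[width='10']", (0, 1, 1)),
    (".a.b", (0, 2, 0)),
    ("#x#y", (2, 0, 0)),
    ("* rect", (0, 0, 1)),
    ("g g g", (0, 0, 3)),
    ("#a g.node > rect.leaf", (1, 2, 2)),
    ("svg .axis text", (0, 1, 2)),
    (".edge", (0, 1, 0)),
    ("circle", (0, 0, 1)),
]


@pytest.mark.parametrize("selector,expected", SPECIFICITY_TABLE)
def test_specificity_matches_hand_computation(selector, expected):
    assert compute_specificity(selector) == expected
    assert oracle_specificity(selector) == expected


@pytest.mark.parametrize("selector", ["a:hover", "rect::before", "p + q", "a ~ b"])
def test_unsupported_selector_features_signalled(selector):
    with pytest.raises(UnsupportedSelectorError):
        compute_specificity(selector)


# ---------------------------------------------------------------------------
# rule collection

def test_collect_single_class_rule():
    doc = parse_svg(SVG.format("<style>.a{fill:red}</style>"))
    rules = collect_rules(doc)
    assert len(rules) == 1
    rule = rules[0]
    assert rule.selector == ".a"
    assert rule.declarations == {"fill": ("red", False)}
    assert rule.specificity == (0, 1, 0)
    assert rule.source_order == 0


def test_no_style_elements_gives_empty_list():
    doc = parse_svg(SVG.format("<rect/>"))
    assert collect_rules(doc) == []


def test_comma_group_splits_into_member_rules():
    doc = parse_svg(SVG.format("<style>#x,.y{stroke:blue}</style>"))
    rules = collect_rules(doc)
    assert [(r.selector, r.specificity, r.source_order) for r in rules] == [
        ("#x", (1, 0, 0), 0), (".y", (0, 1, 0), 1)]


def test_unsupported_selector_skipped_with_warning():
    doc = parse_svg(SVG.format("<style>a:hover{fill:red}.ok{fill:blue}</style>"))
    with pytest.warns(ScopingWarning, match="unsupported selector"):
        rules = collect_rules(doc)
    assert [r.selector for r in rules] == [".ok"]


def test_malformed_declaration_skipped_not_fatal():
    doc = parse_svg(SVG.format("<style>.a{fill red; stroke: blue}</style>"))
    with pytest.warns(ScopingWarning, match="malformed"):
        rules = collect_rules(doc)
    assert rules[0].declarations == {"stroke": ("blue", False)}


def test_important_flag_parsed():
    doc = parse_svg(SVG.format("<style>.a{fill:red !important}</style>"))
    assert collect_rules(doc)[0].declarations == {"fill": ("red", True)}


# ---------------------------------------------------------------------------
# cascade inlining

def test_class_beats_type():
    doc = parse_svg(SVG.format(
        "<style>circle{fill:blue}.a{fill:red}</style><circle class='a'/>"))
    cascade_inline(doc)
    circle = next(el for el in elements(doc) if localname(el) == "circle")
    assert inlined(circle) == {"fill": "red"}


def test_source_order_breaks_specificity_ties():
    doc = parse_svg(SVG.format(
        "<style>.a{fill:red}.b{fill:blue}</style><rect class='a b'/>"))
    cascade_inline(doc)
    rect = next(el for el in elements(doc) if localname(el) == "rect")
    assert inlined(rect)["fill"] == "blue"


def test_inline_style_beats_non_important_rules():
    doc = parse_svg(SVG.format(
        "<style>rect{fill:red}</style><rect style='fill:green'/>"))
    cascade_inline(doc)
    rect = next(el for el in elements(doc) if localname(el) == "rect")
    assert inlined(rect)["fill"] == "green"


def test_important_rule_beats_inline_style():
    doc = parse_svg(SVG.format(
        "<style>rect{fill:red !important}</style><rect style='fill:green'/>"))
    cascade_inline(doc)
    rect = next(el for el in elements(doc) if localname(el) == "rect")
    assert inlined(rect)["fill"] == "red"


def test_no_style_elements_output_byte_identical():
    text = SVG.format('<rect style="fill:red" width="10" height="10"/>')
    doc = parse_svg(text)
    before = serialize_svg(doc)
    cascade_inline(doc)
    assert serialize_svg(doc) == before


def test_style_elements_removed():
    doc = parse_svg(SVG.format("<style>.a{fill:red}</style><rect class='a'/>"))
    cascade_inline(doc)
    assert not any(localname(el) == "style" for el in elements(doc))


def test_cascade_inline_idempotent(reference_doc):
    doc = reference_doc
    cascade_inline(doc)
    once = serialize_svg(doc)
    cascade_inline(doc)
    assert serialize_svg(doc) == once


@pytest.mark.parametrize("seed", range(40))
def test_cascade_equals_brute_force_oracle(seed):
    """Every (element, property) matches an exhaustive independent cascade."""
    doc = gen_random_styled_svg(seed)
    expected = oracle_effective_styles(doc.root)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ScopingWarning)
        cascade_inline(doc)
    for el, want in expected.items():
        assert inlined(el) == want


def test_conflicting_assets_keep_their_own_paints(conflicting_pair):
    """Two plots with clashing global rules stay styled independently."""
    docs, truth = conflicting_pair
    for doc, paints in zip(docs, truth):
        cascade_inline(doc)
        for el in elements(doc):
            if "edge" in (el.get("class") or "").split():
                assert inlined(el)["fill"] == paints[".edge"]
            if localname(el) == "circle":
                assert inlined(el)["fill"] == paints["circle"]
            if el.get("id") == "n1":
                assert inlined(el)["fill"] == paints["#n1"]
    for selector in truth[0]:
        assert truth[0][selector] != truth[1][selector]


# ---------------------------------------------------------------------------
# id namespacing

def test_suffix_form_and_url_rewrite():
    doc = parse_svg(SVG.format(
        '<defs><linearGradient id="grad1"/></defs>'
        '<rect fill="url(#grad1)"/>'))
    scoped = namespace_ids(doc, 2)
    grad = next(el for el in elements(doc) if el.get("id"))
    assert grad.get("id") == "grad1--inject-2"
    rect = next(el for el in elements(doc) if localname(el) == "rect")
    assert rect.get("fill") == "url(#grad1--inject-2)"
    assert scoped.id_map == {"grad1": "grad1--inject-2"}


def test_fragment_href_rewritten_external_preserved():
    doc = parse_svg(SVG.format(
        '<circle id="n1"/>'
        '<a xmlns:xlink="http://www.w3.org/1999/xlink" '
        'xlink:href="#n1"><text>in</text></a>'
        '<a xmlns:xlink="http://www.w3.org/1999/xlink" '
        'xlink:href="https://www.uniprot.org/uniprot/Q9NWZ3"><text>out</text></a>'))
    namespace_ids(doc, 3)
    hrefs = [el.get("{http://www.w3.org/1999/xlink}href")
             for el in elements(doc) if localname(el) == "a"]
    assert hrefs == ["#n1--inject-3", "https://www.uniprot.org/uniprot/Q9NWZ3"]


def test_document_without_ids_is_noop():
    text = SVG.format('<rect width="10" height="10"/>')
    doc = parse_svg(text)
    scoped = namespace_ids(doc, 1)
    assert scoped.id_map == {}
    assert serialize_svg(doc) == text


def test_dangling_reference_warned_and_left():
    doc = parse_svg(SVG.format('<rect fill="url(#missing)"/>'))
    with pytest.warns(ScopingWarning, match="missing"):
        namespace_ids(doc, 1)
    rect = next(el for el in elements(doc) if localname(el) == "rect")
    assert rect.get("fill") == "url(#missing)"


def test_inject_index_must_be_positive():
    doc = parse_svg("<svg/>")
    with pytest.raises(ValueError):
        namespace_ids(doc, 0)


@given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=10))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_referential_integrity_property(inject_index, seed):
    """After namespacing, referenced fragments are a subset of defined ids."""
    docs, _ = gen_conflicting_svgs(FixtureSpec(
        seed=seed, n_assets=1, include_gradients=True, include_links=True))
    doc = docs[0]
    cascade_inline(doc)
    namespace_ids(doc, inject_index)
    defined = {el.get("id") for el in elements(doc) if el.get("id")}
    assert all(i.endswith(f"--inject-{inject_index}") for i in defined)
    referenced = set()
    for el in elements(doc):
        for attr, value in el.attrib.items():
            if attr.rsplit("}", 1)[-1] == "href" and value.startswith("#"):
                referenced.add(value[1:])
            for m in re.finditer(r"url\(#([^)]+)\)", value):
                referenced.add(m.group(1))
    assert referenced <= defined


# ---------------------------------------------------------------------------
# white-background stripping

def test_full_canvas_white_rect_removed():
    doc = parse_svg(SVG.format(
        '<rect x="0" y="0" width="100" height="100" fill="#ffffff"/>'
        '<rect x="10" y="10" width="20" height="20" fill="red"/>'))
    strip_white_background(doc)
    rects = [el for el in elements(doc) if localname(el) == "rect"]
    assert len(rects) == 1
    assert rects[0].get("fill") == "red"


@pytest.mark.parametrize("white", ["#fff", "#FFFFFF", "white", "WHITE",
                                   "rgb(255, 255, 255)"])
def test_all_white_spellings_detected(white):
    doc = parse_svg(SVG.format(
        f'<rect width="100%" height="100%" fill="{white}"/>'))
    strip_white_background(doc)
    assert not any(localname(el) == "rect" for el in elements(doc))


def test_small_white_glyph_preserved():
    doc = parse_svg(SVG.format('<circle cx="50" cy="50" r="4" fill="white"/>'))
    strip_white_background(doc)
    assert any(localname(el) == "circle" for el in elements(doc))


def test_stroked_white_rect_preserved():
    doc = parse_svg(SVG.format(
        '<rect width="100" height="100" fill="white" stroke="black"/>'))
    strip_white_background(doc)
    assert any(localname(el) == "rect" for el in elements(doc))


def test_near_full_coverage_threshold():
    # 97% coverage is below the 0.98 threshold: preserved
    doc = parse_svg(SVG.format(
        '<rect width="97" height="100" fill="white"/>'))
    strip_white_background(doc)
    assert any(localname(el) == "rect" for el in elements(doc))


def test_strip_is_idempotent(reference_doc):
    doc = reference_doc
    strip_white_background(doc)
    once = serialize_svg(doc)
    strip_white_background(doc)
    assert serialize_svg(doc) == once


def test_root_background_declaration_removed():
    doc = parse_svg('<svg viewBox="0 0 10 10" '
                    'style="background: white; font-size: 10px"/>')
    strip_white_background(doc)
    assert "background" not in (doc.root.get("style") or "")
    assert "font-size" in doc.root.get("style")
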