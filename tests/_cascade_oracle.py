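"""Independent brute-force cascade oracle.

A deliberately naive, exhaustive re-implementation of stylesheet resolution
used only to check `figweaver.style_scoper`: every rule is tested against
every element with no indexing; descendant matching enumerates complete
ancestor chains; winners are chosen by sorting the full candidate list by
(important, specificity, source order).  Kept structurally different from the
package implementation on purpose.
"""

from __future__ import annotations

import re


def _local(el):
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


_TOKEN = re.compile(r"#[-\w]+|\.[-\w]+|\[[^\]]+\]|\*|[-\w]+")


def oracle_specificity(selector: str) -> tuple[int, int, int]:
    """Count id / class+attr / type tokens straight off the selector text."""
    a = b = c = 0
    for token in _TOKEN.findall(selector.replace(">", " ")):
        if token.startswith("#"):
            a += 1
        elif token.startswith(".") or token.startswith("["):
            b += 1
        elif token != "*":
            c += 1
    return (a, b, c)


def _compound_matches(el, compound: str) -> bool:
    for token in _TOKEN.findall(compound):
        if token == "*":
            continue
        if token.startswith("#"):
            if el.get("id") != token[1:]:
                return False
        elif token.startswith("."):
            if token[1:] not in (el.get("class") or "").split():
                return False
        elif token.startswith("["):
            inner = token[1:-1]
            if "=" in inner:
                name, _, value = inner.partition("=")
                if el.get(name.strip()) != value.strip().strip("'\""):
                    return False
            elif el.get(inner.strip()) is None:
                return False
        else:
            if _local(el) != token:
                return False
    return True


def _split_complex(selector: str) -> list[tuple[str | None, str]]:
    """-> [(combinator_to_previous, compound), ...]; combinator ' ' or '>'."""
    parts = re.split(r"\s*(>)\s*|\s+", selector.strip())
    out: list[tuple[str | None, str]] = []
    pending = None
    for part in parts:
        if part is None or part == "":
            continue
        if part == ">":
            pending = ">"
            continue
        out.append((pending if out else None, part))
        pending = None
    return out


def oracle_matches(el, selector: str) -> bool:
    """Exhaustive match: try every strictly-increasing assignment of the
    selector's compounds to the element's ancestor chain."""
    chain = [el]
    p = el.getparent()
    while p is not None:
        chain.append(p)
        p = p.getparent()
    seq = _split_complex(selector)

    def attempt(seq_i: int, chain_i: int) -> bool:
        comb, compound = seq[seq_i]
        if not _compound_matches(chain[chain_i], compound):
            return False
        if seq_i == 0:
            return True
        prev_comb = seq[seq_i][0]
        if prev_comb == ">":
            candidates = [chain_i + 1] if chain_i + 1 < len(chain) else []
        else:
            candidates = range(chain_i + 1, len(chain))
        return any(attempt(seq_i - 1, j) for j in candidates)

    return attempt(len(seq) - 1, 0)


def _parse_inline(style: str) -> dict[str, str]:
    out = {}
    for chunk in style.split(";"):
        if ":" in chunk:
            k, _, v = chunk.partition(":")
            out[k.strip().lower()] = v.strip()
    return out


def oracle_collect_rules(root) -> list[dict]:
    """All supported rules from every <style>, flattened over comma groups."""
    rules = []
    order = 0
    for el in root.iter():
        if _local(el) != "style":
            continue
        css = re.sub(r"/\*.*?\*/", "", "".join(el.itertext()), flags=re.S)
        for m in re.finditer(r"([^{}@]+)\{([^{}]*)\}", css):
            group, block = m.group(1).strip(), m.group(2)
            decls = {}
            for chunk in block.split(";"):
                if ":" not in chunk:
                    continue
                prop, _, value = chunk.partition(":")
                prop, value = prop.strip().lower(), value.strip()
                if not prop or not value:
                    continue
                important = bool(re.search(r"!\s*important\s*$", value, re.I))
                if important:
                    value = re.sub(r"!\s*important\s*$", "", value, flags=re.I).strip()
                decls[prop] = (value, important)
            for selector in group.split(","):
                selector = selector.strip()
                if not selector or re.search(r"[:+~]", selector):
                    continue
                rules.append({"selector": selector, "decls": decls,
                              "spec": oracle_specificity(selector),
                              "order": order})
                order += 1
    return rules


def oracle_effective_styles(root) -> dict:
    """element -> {property: winning value} after the full cascade,
    including pre-existing inline styles (which beat non-important rules)."""
    rules = oracle_collect_rules(root)
    result = {}
    for el in root.iter():
        if not isinstance(el.tag, str) or _local(el) == "style":
            continue
        candidates = []  # (rank, spec, order, prop, value)
        for rule in rules:
            if oracle_matches(el, rule["selector"]):
                for prop, (value, important) in rule["decls"].items():
                    rank = 2 if important else 0
                    candidates.append((rank, rule["spec"], rule["order"],
                                       prop, value))
        for prop, value in _parse_inline(el.get("style") or "").items():
            candidates.append((1, (9, 9, 9), 10 ** 9, prop, value))
        winners = {}
        for rank, spec, order, prop, value in sorted(
                candidates, key=lambda t: (t[0], t[1], t[2])):
            winners[prop] = value  # later (stronger) entries overwrite
        if candidates:
            result[el] = winners
    return result
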