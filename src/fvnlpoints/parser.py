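"""Ingredient-list parsing.

Canadian labelling regulations require ingredients to be listed in descending
order of their proportion by weight, so the *position* of an ingredient is the
only quantitative signal a label without quantitative ingredient declarations
(QUIDs) carries.  This module turns the free-text declaration into an ordered
tree of :class:`IngredientNode` objects: top-level ingredients split on commas
or semicolons outside brackets, with bracketed groups attached as ordered
sub-ingredients of the name immediately preceding them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IngredientNode",
    "IngredientList",
    "ParseError",
    "EmptyInputError",
    "NormalizationError",
    "parse_ingredient_list",
    "normalize_name",
]


class ParseError(ValueError):
    """Raised for malformed ingredient text (e.g. unbalanced brackets)."""


class EmptyInputError(ParseError):
    """Raised when the ingredient text is empty after trimming."""


class NormalizationError(ValueError):
    """Raised when a name normalizes to the empty string."""


_OPEN = {"(": ")", "[": "]"}
_CLOSE = {")", "]"}

# trailing percentage declarations like "strawberries 25%" or "(10 %)"
_PCT_RE = re.compile(r"\b\d+(?:[.,]\d+)?\s*%")
_WS_RE = re.compile(r"\s+")


def normalize_name(text: str) -> str:
    """Normalize an ingredient name for lexicon lookup.

    Lowercases, strips surrounding whitespace/punctuation and footnote
    asterisks/daggers, drops trailing percentage tokens, and collapses
    internal whitespace.  Idempotent.
    """
    if not text or not text.strip():
        raise NormalizationError("empty ingredient name")
    s = text.lower()
    s = s.replace("*", " ").replace("†", " ").replace("‡", " ")
    s = _PCT_RE.sub(" ", s)
    s = s.strip(" \t\n\r.,;:!?\"'`·-")
    s = _WS_RE.sub(" ", s).strip()
    if not s:
        raise NormalizationError(f"name {text!r} is empty after normalization")
    return s


@dataclass
class IngredientNode:
    """One ingredient slot: its printed text, normalized name, 1-based rank
    among its siblings and any bracketed sub-ingredients in label order."""

    raw_text: str
    name: str
    position: int
    sub_ingredients: list["IngredientNode"] = field(default_factory=list)

    @property
    def has_sub_ingredients(self) -> bool:
        return bool(self.sub_ingredients)

    def __repr__(self) -> str:  # compact, test-friendly
        subs = f", subs={self.sub_ingredients!r}" if self.sub_ingredients else ""
        return f"IngredientNode({self.name!r}@{self.position}{subs})"


@dataclass
class IngredientList:
    """Ordered top-level ingredient nodes plus the source text they came from."""

    nodes: list[IngredientNode]
    source_text: str

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, i):
        return self.nodes[i]


def _check_brackets(text: str) -> None:
    stack: list[tuple[str, int]] = []
    for i, ch in enumerate(text):
        if ch in _OPEN:
            stack.append((ch, i))
        elif ch in _CLOSE:
            if not stack or _OPEN[stack[-1][0]] != ch:
                raise ParseError(f"unbalanced closing bracket {ch!r} at position {i}")
            stack.pop()
    if stack:
        ch, i = stack[-1]
        raise ParseError(f"unclosed bracket {ch!r} at position {i}")


def _split_top_level(text: str) -> list[str]:
    """Split on commas/semicolons at bracket depth zero; a period at depth
    zero terminates the list (Canadian labels end the declaration there)."""
    parts: list[str] = []
    depth = 0
    buf: list[str] = []
    for ch in text:
        if ch in _OPEN:
            depth += 1
            buf.append(ch)
        elif ch in _CLOSE:
            depth -= 1
            buf.append(ch)
        elif depth == 0 and ch in ",;":
            parts.append("".join(buf))
            buf = []
        elif depth == 0 and ch == ".":
            break  # the declaration ends at a top-level period
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return [p for p in (p.strip() for p in parts) if p]


# leading name up to the first bracket group
_SEGMENT_RE = re.compile(r"([\(\[])")


def _parse_segment(segment: str, position: int) -> IngredientNode:
    """Parse one top-level (or sub-level) segment: a name optionally followed
    by one bracketed sub-ingredient group, e.g. ``peanut butter (peanuts,
    vegetable oil, salt)``."""
    m = _SEGMENT_RE.search(segment)
    if m is None:
        return IngredientNode(
            raw_text=segment, name=normalize_name(segment), position=position
        )
    head = segment[: m.start()].strip()
    open_ch = m.group(1)
    close_ch = _OPEN[open_ch]
    depth = 0
    inner_start = m.start() + 1
    inner_end = None
    for i in range(m.start(), len(segment)):
        ch = segment[i]
        if ch in _OPEN:
            depth += 1
        elif ch in _CLOSE:
            depth -= 1
            if depth == 0:
                inner_end = i
                break
    assert inner_end is not None, "bracket balance checked upstream"
    inner = segment[inner_start:inner_end]
    tail = segment[inner_end + 1 :].strip(" .")
    # stray brackets with no preceding name: fail soft with a synthetic parent
    name_src = head if head else "(unnamed group)"
    name = normalize_name(name_src) if head else "unnamed group"
    subs = [
        _parse_segment(part, k + 1)
        for k, part in enumerate(_split_top_level(inner))
    ]
    raw = segment if not tail else segment
    node = IngredientNode(
        raw_text=raw, name=name, position=position, sub_ingredients=subs
    )
    if tail:
        # trailing text after the bracket group (rare; e.g. "oil (refined) blend")
        node.name = normalize_name(f"{name_src} {tail}")
    return node


def parse_ingredient_list(text: str) -> IngredientList:
    """Parse a free-text ingredient declaration into an :class:`IngredientList`.

    Top-level ingredients are separated by commas or semicolons outside
    brackets; round and square brackets both introduce sub-ingredient groups,
    nested to arbitrary depth.  "and/or"-joined alternatives stay a single
    node.  Raises :class:`EmptyInputError` on blank input and
    :class:`ParseError` on unbalanced brackets (with position).
    """
    if text is None or not text.strip():
        raise EmptyInputError("ingredient list text is empty")
    _check_brackets(text)
    segments = _split_top_level(text.strip())
    if not segments:
        raise EmptyInputError("ingredient list contains no ingredients")
    nodes = [_parse_segment(seg, i + 1) for i, seg in enumerate(segments)]
    return IngredientList(nodes=nodes, source_text=text)
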