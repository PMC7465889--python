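"""Ingredient classification lexicon.

The scoring rules need to know, for each normalized ingredient name, whether
it is FVNL under each nutrient-profile model (eligibility differs: tubers,
seeds, spices and capers count under FSANZ NPSC/HSR only; rapeseed, walnut
and olive oils under the Nutri-Score only), whether it is concentrated
(juice concentrate, paste, dried fruit), whether it is a minimal-weight
additive, an added sugar/sweetener, a dense "substantial" ingredient, or
water.  The lexicon is data, not code: a default bank ships with the package
and users can load their own.

Matching is deterministic: patterns are matched on stemmed word boundaries
as contiguous token runs, the longest match wins, and there is no fuzzy
matching.  Unknown names classify as non-FVNL and non-minimal, with an
"unknown" note carried into the rationale trace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .models import Model
from .parser import IngredientNode, normalize_name

__all__ = [
    "CLASS_TAGS",
    "LexiconEntry",
    "IngredientClassification",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "classify_ingredient",
    "is_concentrated",
    "effective_fvnl",
]

# closed set of classification tags a lexicon entry may carry
CLASS_TAGS = frozenset(
    {
        "fvnl_fruit",
        "fvnl_vegetable",
        "fvnl_nut",
        "fvnl_legume",
        "tuber",
        "eligible_oil",
        "seed_fsanz_only",
        "spice_fsanz_only",
        "concentrated_marker",
        "minimal_weight",
        "added_sugar",
        "dense_substantial",
        "water",
    }
)

_FVNL_CORE = {"fvnl_fruit", "fvnl_vegetable", "fvnl_nut", "fvnl_legume"}
_FVNL_FSANZ_EXTRA = {"tuber", "seed_fsanz_only", "spice_fsanz_only"}

_ANDOR_RE = re.compile(r"\band/or\b")
_TOKEN_RE = re.compile(r"[^\s\-–—/]+")


class LexiconError(ValueError):
    """Raised for an invalid lexicon file (unknown tags, duplicates...)."""


def _stem(token: str) -> str:
    """Light plural stemming so "tomatoes" matches "tomato"."""
    t = token
    if len(t) > 3:
        if t.endswith(("ches", "shes", "xes", "zes", "oes", "ses")):
            return t[:-2]
        if t.endswith("ies"):
            return t[:-3] + "y"
        if t.endswith("s") and not t.endswith("ss"):
            return t[:-1]
    return t


def _stem_tokens(text: str) -> tuple[str, ...]:
    return tuple(_stem(t) for t in _TOKEN_RE.findall(text))


@dataclass(frozen=True)
class LexiconEntry:
    """One pattern and the classification tags it carries."""

    pattern: str
    classes: frozenset[str]
    notes: str = ""

    def __post_init__(self):
        if not self.pattern or not self.pattern.strip():
            raise LexiconError("lexicon pattern must be non-empty")
        if not self.classes:
            raise LexiconError(f"entry {self.pattern!r} has no classes")
        bad = self.classes - CLASS_TAGS
        if bad:
            raise LexiconError(
                f"entry {self.pattern!r} uses unknown class tag(s): {sorted(bad)}"
            )
        heavy = self.classes & {"dense_substantial", "added_sugar"}
        if "minimal_weight" in self.classes and heavy:
            raise LexiconError(
                f"entry {self.pattern!r} cannot be both minimal-weight and "
                f"substantial ({sorted(heavy)})"
            )


@dataclass
class IngredientClassification:
    """Resolved classification of one normalized ingredient name."""

    name: str
    fvnl_by_model: dict[Model, bool]
    concentrated: bool = False
    minimal_weight: bool = False
    added_sugar: bool = False
    dense_substantial: bool = False
    is_water: bool = False
    unknown: bool = False
    matched: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    def fvnl(self, model: Model) -> bool:
        return self.fvnl_by_model[Model(model)]


def _classes_to_fvnl(classes: frozenset[str]) -> dict[Model, bool]:
    core = bool(classes & _FVNL_CORE)
    fsanz = core or bool(classes & _FVNL_FSANZ_EXTRA)
    nutri = core or ("eligible_oil" in classes)
    return {
        Model.FSANZ_NPSC: fsanz,
        Model.HSR: fsanz,
        Model.NUTRI_SCORE: nutri,
        Model.OFCOM: core,
    }


class Lexicon:
    """A validated ingredient lexicon with deterministic longest-match lookup."""

    def __init__(
        self, entries: list[LexiconEntry], neutral: list[str] | None = None
    ):
        self.entries = list(entries)
        self.neutral = [normalize_name(p) for p in (neutral or [])]
        self._validate()
        # compiled: stemmed token tuple -> (classes or None for neutral, pattern)
        self._patterns: list[tuple[tuple[str, ...], frozenset[str] | None, str]] = []
        for e in self.entries:
            self._patterns.append((_stem_tokens(e.pattern), e.classes, e.pattern))
        for p in self.neutral:
            self._patterns.append((_stem_tokens(p), None, p))
        self._cache: dict[str, IngredientClassification] = {}

    def _validate(self) -> None:
        seen: dict[str, frozenset[str]] = {}
        dupes: list[str] = []
        for e in self.entries:
            key = normalize_name(e.pattern)
            if key in seen and seen[key] != e.classes:
                dupes.append(key)
            seen[key] = e.classes
        for p in self.neutral:
            if p in seen:
                dupes.append(p)
        if dupes:
            raise LexiconError(
                f"duplicate conflicting patterns in lexicon: {sorted(set(dupes))}"
            )

    # -- matching ----------------------------------------------------------

    def _matches(self, tokens: tuple[str, ...]):
        """All (pattern_tokens, classes, pattern) occurring as a contiguous
        token run within ``tokens``."""
        out = []
        n = len(tokens)
        for ptoks, classes, pat in self._patterns:
            k = len(ptoks)
            if k == 0 or k > n:
                continue
            for i in range(n - k + 1):
                if tokens[i : i + k] == ptoks:
                    out.append((ptoks, classes, pat))
                    break
        return out

    def _resolve_alternative(self, alt: str):
        """Winner-take-all classes for one and/or alternative; returns
        (classes, matched patterns, known?)."""
        tokens = _stem_tokens(alt)
        matches = self._matches(tokens)
        # pure concentration markers ("concentrated", "paste") are modifiers:
        # they flag concentration but never decide what the ingredient *is*,
        # so they do not compete in the winner-take-all selection
        identity = [
            m for m in matches if m[1] is None or m[1] - {"concentrated_marker"}
        ]
        if matches and not identity:
            return frozenset(), tuple(sorted(m[2] for m in matches)), True
        matches = identity
        if not matches:
            return frozenset(), (), False
        best_key = max((len(pt), sum(len(t) for t in pt)) for pt, _, _ in matches)
        classes: set[str] = set()
        pats: list[str] = []
        for pt, cls, pat in matches:
            if (len(pt), sum(len(t) for t in pt)) == best_key:
                pats.append(pat)
                if cls is not None:
                    classes.update(cls)
        return frozenset(classes), tuple(sorted(pats)), True

    def classify(self, name: str) -> IngredientClassification:
        """Classify a normalized ingredient name.

        "and/or"-joined alternatives occupy one slot in the label's weight
        ordering; the classification is the logical OR of the alternatives.
        """
        name = normalize_name(name)
        if name in self._cache:
            return self._cache[name]
        alts = [a for a in (s.strip() for s in _ANDOR_RE.split(name)) if a]
        merged: set[str] = set()
        matched: list[str] = []
        any_known = False
        for alt in alts or [name]:
            classes, pats, known = self._resolve_alternative(alt)
            merged.update(classes)
            matched.extend(pats)
            any_known = any_known or known
        # a name may carry a concentration marker anywhere, not only in the
        # winning match ("concentrated apple juice" matches "apple juice")
        concentrated = self._marker_match(name)
        heavy = bool(merged & {"dense_substantial", "added_sugar"})
        minimal = "minimal_weight" in merged and not heavy
        notes: list[str] = []
        if not any_known:
            notes.append("unknown ingredient: treated as non-FVNL, non-minimal")
        cls = IngredientClassification(
            name=name,
            fvnl_by_model=_classes_to_fvnl(frozenset(merged)),
            concentrated=concentrated,
            minimal_weight=minimal,
            added_sugar="added_sugar" in merged,
            dense_substantial=heavy,
            is_water="water" in merged,
            unknown=not any_known,
            matched=tuple(matched),
            notes=tuple(notes),
        )
        self._cache[name] = cls
        return cls

    def _marker_match(self, name: str) -> bool:
        tokens = _stem_tokens(name)
        for ptoks, classes, _ in self._patterns:
            if classes and "concentrated_marker" in classes:
                k = len(ptoks)
                for i in range(len(tokens) - k + 1):
                    if tokens[i : i + k] == ptoks:
                        return True
        return False

    def is_concentrated(self, name: str) -> bool:
        return self.classify(name).concentrated


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a YAML lexicon file.

    Raises :class:`LexiconError` on unknown class tags or duplicate patterns
    with conflicting classes.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "entries" not in raw:
        raise LexiconError(f"lexicon file {path} must contain an 'entries' list")
    entries = []
    for item in raw["entries"]:
        try:
            entries.append(
                LexiconEntry(
                    pattern=str(item["pattern"]),
                    classes=frozenset(item.get("classes", [])),
                    notes=str(item.get("notes", "") or ""),
                )
            )
        except KeyError as exc:
            raise LexiconError(f"lexicon entry missing field: {exc}") from exc
    return Lexicon(entries, raw.get("neutral") or [])


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The lexicon bank shipped with the package."""
    ref = resources.files("fvnlpoints.data").joinpath("default_lexicon.yml")
    with resources.as_file(ref) as p:
        return load_lexicon(p)


# -- module-level conveniences over the default lexicon ---------------------


def classify_ingredient(
    name: str, model: Model | str | None = None, lexicon: Lexicon | None = None
) -> IngredientClassification:
    """Classify a normalized name (``model`` is accepted for symmetry; the
    returned object carries the FVNL flag for every supported model)."""
    lex = lexicon or default_lexicon()
    return lex.classify(name)


def is_concentrated(name: str, lexicon: Lexicon | None = None) -> bool:
    lex = lexicon or default_lexicon()
    return lex.is_concentrated(name)


def effective_fvnl(
    node: IngredientNode, model: Model | str, lexicon: Lexicon | None = None
) -> bool:
    """FVNL status of an ingredient slot, applying the sub-ingredient rule.

    A composite ingredient ("peanut butter (peanuts, vegetable oil, salt)")
    counts as FVNL if one of its first two sub-ingredients is FVNL, applied
    recursively; a leaf ingredient uses its own classification.
    """
    lex = lexicon or default_lexicon()
    model = Model(model)
    if node.sub_ingredients:
        return any(
            effective_fvnl(sub, model, lex) for sub in node.sub_ingredients[:2]
        )
    return lex.classify(node.name).fvnl(model)
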