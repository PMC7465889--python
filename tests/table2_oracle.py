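"""Independent brute-force oracle for the published scoring criteria.

A direct transcription of the criteria prose, coded on a tiny hand-labelled
vocabulary with no use of the package's parser, lexicon or scorer.  The
equivalence test scores every short ingredient list over this vocabulary
through both routes and compares levels.
"""

from __future__ import annotations

# 12-word vocabulary spanning every classification the rules consume.
# fvnl: the set of model codes under which the word counts as FVNL.
_ALL = {"FSANZ", "HSR", "NUTRI", "OFCOM"}
VOCAB: dict[str, dict] = {
    "cherries": {"fvnl": _ALL, "conc": False, "kind": "food"},
    "almonds": {"fvnl": _ALL, "conc": False, "kind": "food"},
    "chickpeas": {"fvnl": _ALL, "conc": False, "kind": "food"},
    "raisins": {"fvnl": _ALL, "conc": True, "kind": "food"},
    "tomato paste": {"fvnl": _ALL, "conc": True, "kind": "food"},
    "olive oil": {"fvnl": {"NUTRI"}, "conc": False, "kind": "neutral"},
    "sunflower oil": {"fvnl": set(), "conc": False, "kind": "neutral"},
    "water": {"fvnl": set(), "conc": False, "kind": "water"},
    "sugar": {"fvnl": set(), "conc": False, "kind": "dense"},
    "cheese": {"fvnl": set(), "conc": False, "kind": "dense"},
    "salt": {"fvnl": set(), "conc": False, "kind": "salt"},
    "citric acid": {"fvnl": set(), "conc": False, "kind": "additive"},
}

OPTION1_CATS = {"J", "K", "O", "P", "V"}
WATER_MINIMAL = {"V", "P"}
WATER_NONSUB = {"J", "K", "O"}
SALT_SEASONING = {"O", "S"}

_POINTS = {
    ("FSANZ", False): {"L0": 0, "L1": 1, "L2": 2, "L5": 5, "L8": 8},
    ("HSR", False): {"L0": 0, "L1": 1, "L2": 2, "L5": 5, "L8": 8},
    ("NUTRI", False): {"L0": 0, "L1": 1, "L2": 2, "L5": 5, "L8": 5},
    ("NUTRI", True): {"L0": 0, "L1": 2, "L2": 4, "L5": 10, "L8": 10},
    ("OFCOM", False): {"L0": 0, "L1": 1, "L2": 2, "L5": 5, "L8": 5},
}
_POINTS[("FSANZ", True)] = _POINTS[("FSANZ", False)]
_POINTS[("HSR", True)] = _POINTS[("HSR", False)]
_POINTS[("OFCOM", True)] = _POINTS[("OFCOM", False)]


def _is_fvnl(word: str, model: str) -> bool:
    return model in VOCAB[word]["fvnl"]


def _weights(words: list[str], model: str, category: str) -> list[str | None]:
    """Contribution class per slot: None=FVNL, else minimal/nonsub/substantial."""
    fvnl = [_is_fvnl(w, model) for w in words]
    first_fvnl = fvnl.index(True) if True in fvnl else None
    minimal = []
    for w in words:
        kind = VOCAB[w]["kind"]
        if kind == "additive":
            minimal.append(True)
        elif kind == "salt":
            minimal.append(category not in SALT_SEASONING)
        else:
            minimal.append(False)
    first_min = minimal.index(True) if True in minimal else None
    out: list[str | None] = []
    for i, w in enumerate(words):
        if fvnl[i]:
            out.append(None)
            continue
        if first_fvnl is not None and i < first_fvnl:
            out.append("substantial")
            continue
        if minimal[i]:
            out.append("minimal")
            continue
        if first_min is not None and i > first_min:
            out.append("minimal")
            continue
        kind = VOCAB[w]["kind"]
        if kind == "water":
            if category in WATER_MINIMAL:
                out.append("minimal")
            elif category in WATER_NONSUB:
                out.append("nonsubstantial")
            else:
                out.append("substantial")
        elif kind == "dense":
            out.append("substantial")
        else:  # neutral oils, seasoning salt
            out.append("nonsubstantial")
    return out


def _upper(words: list[str], model: str, category: str) -> str:
    non_fvnl = [c for c in _weights(words, model, category) if c is not None]
    if all(c == "minimal" for c in non_fvnl):
        return "L8"
    if any(c == "substantial" for c in non_fvnl):
        return "L2"
    return "L5"


def oracle_level(words: list[str], model: str, category: str) -> str:
    """Criteria level per the published prose, on hand-labelled words."""
    head3 = words[:3]
    fvnl3 = [w for w in head3 if _is_fvnl(w, model)]
    conc3 = [w for w in fvnl3 if VOCAB[w]["conc"]]
    option1 = (
        model != "OFCOM"
        and category in OPTION1_CATS
        and bool(fvnl3)
        and 2 * len(conc3) > len(fvnl3)
    )
    if option1:
        pos = None
        for i, w in enumerate(head3):
            if _is_fvnl(w, model) and VOCAB[w]["conc"]:
                pos = i + 1
                break
        if pos is None:
            return "L0"
        if pos == 3:
            return "L1"
        return _upper(words, model, category)
    # non-concentrated criteria
    head2 = words[:2]
    flags = [_is_fvnl(w, model) for w in head2]
    if not any(flags):
        return "L0"
    if not flags[0]:
        return "L1"
    return _upper(words, model, category)


def oracle_points(
    words: list[str], model: str, category: str, beverage: bool = False
) -> int:
    return _POINTS[(model, beverage)][oracle_level(words, model, category)]
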