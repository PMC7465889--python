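"""Nutrient-profile models and their FVNL point scales.

Four models credit fruit/vegetable/nut/legume (FVNL) content from the
ingredient list: the FSANZ Nutrient Profiling Scoring Criterion, the Health
Star Rating system, the Nutri-Score (separate food and beverage scales, and
additionally crediting rapeseed, walnut and olive oils) and, optionally, the
UK Ofcom model.  Without quantitative ingredient declarations only five rungs
of each scale are attainable; the rung is decided by the position-based
criteria in :mod:`fvnlpoints.scorer` and mapped to points here.
"""

from __future__ import annotations

from enum import Enum

__all__ = [
    "Model",
    "CriteriaLevel",
    "map_level_to_points",
    "valid_points",
    "average_multi_component",
]


class Model(str, Enum):
    FSANZ_NPSC = "FSANZ_NPSC"
    HSR = "HSR"
    NUTRI_SCORE = "NUTRI_SCORE"
    OFCOM = "OFCOM"

    @classmethod
    def parse(cls, text: str) -> "Model":
        key = text.strip().upper().replace("-", "_").replace(" ", "_")
        aliases = {
            "FSANZ": cls.FSANZ_NPSC,
            "NPSC": cls.FSANZ_NPSC,
            "FSANZ_NPSC": cls.FSANZ_NPSC,
            "HSR": cls.HSR,
            "HEALTH_STAR_RATING": cls.HSR,
            "NUTRI": cls.NUTRI_SCORE,
            "NUTRISCORE": cls.NUTRI_SCORE,
            "NUTRI_SCORE": cls.NUTRI_SCORE,
            "OFCOM": cls.OFCOM,
        }
        if key not in aliases:
            raise ValueError(f"unknown nutrient-profile model {text!r}")
        return aliases[key]


class CriteriaLevel(str, Enum):
    """The five attainable criteria rungs (named for the FSANZ/HSR points)."""

    L0 = "L0"
    L1 = "L1"
    L2 = "L2"
    L5 = "L5"
    L8 = "L8"


# level -> points, per model; the Nutri-Score beverage scale keeps its own
# intermediate rungs (>40% -> 2, >60% -> 4, >80% -> 10)
_SCALES: dict[tuple[Model, bool], dict[CriteriaLevel, int]] = {
    (Model.FSANZ_NPSC, False): {
        CriteriaLevel.L0: 0,
        CriteriaLevel.L1: 1,
        CriteriaLevel.L2: 2,
        CriteriaLevel.L5: 5,
        CriteriaLevel.L8: 8,
    },
    (Model.NUTRI_SCORE, False): {
        CriteriaLevel.L0: 0,
        CriteriaLevel.L1: 1,
        CriteriaLevel.L2: 2,
        CriteriaLevel.L5: 5,
        CriteriaLevel.L8: 5,
    },
    (Model.NUTRI_SCORE, True): {
        CriteriaLevel.L0: 0,
        CriteriaLevel.L1: 2,
        CriteriaLevel.L2: 4,
        CriteriaLevel.L5: 10,
        CriteriaLevel.L8: 10,
    },
    (Model.OFCOM, False): {
        CriteriaLevel.L0: 0,
        CriteriaLevel.L1: 1,
        CriteriaLevel.L2: 2,
        CriteriaLevel.L5: 5,
        CriteriaLevel.L8: 5,
    },
}
_SCALES[(Model.HSR, False)] = _SCALES[(Model.FSANZ_NPSC, False)]
_SCALES[(Model.FSANZ_NPSC, True)] = _SCALES[(Model.FSANZ_NPSC, False)]
_SCALES[(Model.HSR, True)] = _SCALES[(Model.HSR, False)]
_SCALES[(Model.OFCOM, True)] = _SCALES[(Model.OFCOM, False)]


def map_level_to_points(
    level: CriteriaLevel, model: Model, beverage: bool = False
) -> int:
    """Map a criteria rung to points on the model's scale.

    ``beverage`` selects the Nutri-Score beverage scale and is ignored by the
    other models (which do not distinguish foods from beverages).
    """
    key = (Model(model), bool(beverage))
    if key not in _SCALES:
        raise ValueError(f"unsupported model {model!r}")
    return _SCALES[key][CriteriaLevel(level)]


def valid_points(model: Model, beverage: bool = False) -> tuple[int, ...]:
    """The attainable point values for a model, ascending."""
    scale = _SCALES[(Model(model), bool(beverage))]
    return tuple(sorted(set(scale.values())))


def average_multi_component(
    points: list[int], model: Model, beverage: bool = False
) -> int:
    """Average component points and snap to the nearest attainable point.

    Multi-part products (salad + dressing packet, cracker + dip kits) are
    scored per component and averaged; the mean is snapped to the model's
    attainable point set, ties snapping downward (the conservative choice).
    """
    if not points:
        raise ValueError("cannot average an empty list of component points")
    valid = valid_points(model, beverage)
    for p in points:
        if p not in valid:
            raise ValueError(f"component points {p} not in valid set {valid}")
    mean = sum(points) / len(points)
    # ties snap to the lower point: iterate ascending with strict improvement
    best = valid[0]
    best_d = abs(mean - best)
    for v in valid[1:]:
        d = abs(mean - v)
        if d < best_d:
            best, best_d = v, d
    return best
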