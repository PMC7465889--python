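"""Position-based FVNL point estimation.

Without quantitative ingredient declarations, the only quantitative signal on
a label is ingredient order (descending proportion by weight under Canadian
regulations).  The scorer walks a decision tree:

1. No ingredient list -> 0 points unless the product *name* makes its FVNL
   nature evident (garden salad, fruit/vegetable tray prepared in-store).
2. Multi-part products (salad + dressing packet, snack kits) -> each
   component is scored under the non-concentrated criteria and the component
   points are averaged, snapped to the model's attainable point set.
3. A fruit/vegetable-category product whose FVNL ingredients among the first
   three are all (or mainly) concentrated -> Option 1 (concentrated
   criteria: a concentrated FVNL must be one of the first *three*
   ingredients).
4. Everything else -> Option 2 (non-concentrated criteria: an FVNL must be
   one of the first *two* ingredients).

Within an option, the rung above the 0/1 position rungs is decided by how
much the non-FVNL ingredients appear to contribute to product weight:
2 points when a substantial non-FVNL ingredient is present (added sugars or
sweeteners, butter, cheeses, starches, cereal-based ingredients, meats, and
water outside the category exceptions), 8 points when every non-FVNL
ingredient contributes only minimal weight (salt as a preservative, colour,
vitamins, minerals, flavour extracts, antioxidants, food additives), and
5 points in between.  Every fired rule is recorded in a rationale trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .categories import TRA_CATEGORIES, CategoryError, validate_category
from .lexicon import Lexicon, default_lexicon, effective_fvnl
from .models import (
    CriteriaLevel,
    Model,
    average_multi_component,
    map_level_to_points,
)
from .parser import IngredientList, IngredientNode, parse_ingredient_list

__all__ = [
    "ProductRecord",
    "ScoreResult",
    "ScoringConfig",
    "FvnlScorer",
    "select_option",
    "score_option1",
    "score_option2",
    "score_product",
]


@dataclass
class ProductRecord:
    """One product: identity, TRA category, raw ingredient text(s), flags."""

    id: str
    name: str
    tra_category: str
    ingredient_texts: list[str] = field(default_factory=list)
    has_ingredient_list: bool = True
    nutriscore_beverage: bool = False

    def __post_init__(self):
        self.tra_category = validate_category(self.tra_category)
        self.ingredient_texts = [
            t for t in self.ingredient_texts if t and str(t).strip()
        ]
        if not self.ingredient_texts:
            self.has_ingredient_list = False


@dataclass
class ScoreResult:
    """Outcome of scoring one product under one model, with the rule trace."""

    model: Model
    option_used: str  # option1 | option2 | no_list | name_override | multi_component
    level: CriteriaLevel | None
    points: int
    trace: list[str] = field(default_factory=list)


@dataclass
class ScoringConfig:
    """Category-conditional scoring policy.

    All defaults encode the published criteria plus their documented
    interpretations (see docs/methods.md); every field is overridable.
    """

    # categories whose concentrated products are assessed under Option 1
    option1_categories: frozenset[str] = frozenset({"J", "K", "O", "P", "V"})
    # FVNL-based categories scored generously (water/oil/salt-only lists may
    # reach the 5- or 8-point rungs)
    generous_categories: frozenset[str] = frozenset({"J", "K", "O", "P", "V"})
    # water contribution per category: canned produce water is drained before
    # consumption (minimal); juice categories allow 5 but not 8; elsewhere
    # water contributes substantially
    water_minimal_categories: frozenset[str] = frozenset({"V", "P"})
    water_nonsubstantial_categories: frozenset[str] = frozenset({"J", "K", "O"})
    # categories where salt is a seasoning on the food itself (salted nuts,
    # chips) rather than a preservative, so it blocks the 8-point rung
    salt_seasoning_categories: frozenset[str] = frozenset({"O", "S"})
    # dense ingredients matching these tokens, sitting directly before the
    # additive tail of a generous-category list, are dusting/coating agents
    coating_patterns: tuple[str, ...] = ("starch",)
    # product-name keywords that assign points to list-less products
    name_override_keywords: tuple[str, ...] = (
        "salad",
        "fruit tray",
        "vegetable tray",
        "veggie tray",
        "fruit platter",
        "vegetable platter",
        "crudite",
    )
    name_override_level: CriteriaLevel = CriteriaLevel.L8

    @classmethod
    def from_dict(cls, data: dict) -> "ScoringConfig":
        kwargs = {}
        for key in (
            "option1_categories",
            "generous_categories",
            "water_minimal_categories",
            "water_nonsubstantial_categories",
            "salt_seasoning_categories",
        ):
            if key in data:
                kwargs[key] = frozenset(str(c).upper() for c in data[key])
        if "coating_patterns" in data:
            kwargs["coating_patterns"] = tuple(data["coating_patterns"])
        if "name_override_keywords" in data:
            kwargs["name_override_keywords"] = tuple(data["name_override_keywords"])
        if "name_override_level" in data:
            kwargs["name_override_level"] = CriteriaLevel(data["name_override_level"])
        return cls(**kwargs)


# weight-contribution classes for a single non-FVNL ingredient slot
_MINIMAL = "minimal"
_NONSUBSTANTIAL = "nonsubstantial"
_SUBSTANTIAL = "substantial"


class FvnlScorer:
    """Scores :class:`ProductRecord` objects against one lexicon + config."""

    def __init__(
        self, lexicon: Lexicon | None = None, config: ScoringConfig | None = None
    ):
        self.lexicon = lexicon or default_lexicon()
        self.config = config or ScoringConfig()

    # -- helpers ------------------------------------------------------------

    def _fvnl(self, node: IngredientNode, model: Model) -> bool:
        return effective_fvnl(node, model, self.lexicon)

    def _is_salt_seasoning(self, node: IngredientNode, category: str) -> bool:
        if category not in self.config.salt_seasoning_categories:
            return False
        return "salt" in {t for t in node.name.split()}

    def _weight_classes(
        self,
        nodes: list[IngredientNode],
        model: Model,
        category: str,
        trace: list[str],
    ) -> list[str | None]:
        """Per-slot contribution class; ``None`` marks effective-FVNL slots."""
        cfg = self.config
        fvnl_flags = [self._fvnl(n, model) for n in nodes]
        first_fvnl = next((i for i, f in enumerate(fvnl_flags) if f), None)

        # base classifications; salt-as-seasoning demotion applies first so a
        # seasoning salt does not open the "after salt/preservative" tail
        base: list = [self.lexicon.classify(n.name) for n in nodes]
        is_minimal = []
        for i, (node, cls) in enumerate(zip(nodes, base)):
            m = cls.minimal_weight
            if m and self._is_salt_seasoning(node, category):
                m = False
                trace.append(
                    f"'{node.name}' treated as seasoning, not preservative, "
                    f"in category {category}"
                )
            is_minimal.append(m)
        first_minimal = next((i for i, m in enumerate(is_minimal) if m), None)

        out: list[str | None] = []
        for i, (node, cls) in enumerate(zip(nodes, base)):
            if fvnl_flags[i]:
                out.append(None)
                continue
            if cls.unknown:
                trace.append(f"'{node.name}': {cls.notes[0]}")
            # a non-FVNL ingredient listed before the first FVNL outweighs it
            if first_fvnl is not None and i < first_fvnl:
                out.append(_SUBSTANTIAL)
                trace.append(
                    f"'{node.name}' precedes the first FVNL ingredient: "
                    "substantial by weight order"
                )
                continue
            if is_minimal[i]:
                out.append(_MINIMAL)
                continue
            # ingredients after salt/preservatives contribute only a small amount
            if first_minimal is not None and i > first_minimal:
                out.append(_MINIMAL)
                trace.append(
                    f"'{node.name}' appears after salt/preservatives: "
                    "contributes only a small amount"
                )
                continue
            if cls.is_water:
                if category in cfg.water_minimal_categories:
                    out.append(_MINIMAL)
                    trace.append(
                        f"water in category {category} is typically drained: minimal"
                    )
                elif category in cfg.water_nonsubstantial_categories:
                    out.append(_NONSUBSTANTIAL)
                else:
                    out.append(_SUBSTANTIAL)
                continue
            if cls.dense_substantial:
                if (
                    category in cfg.generous_categories
                    and any(p in node.name for p in cfg.coating_patterns)
                    and all(is_minimal[j] for j in range(i + 1, len(nodes)))
                ):
                    out.append(_MINIMAL)
                    trace.append(
                        f"'{node.name}' sits before the additive tail in "
                        f"FVNL-based category {category}: treated as coating"
                    )
                else:
                    out.append(_SUBSTANTIAL)
                continue
            out.append(_NONSUBSTANTIAL)
        return out

    def _upper_rung(
        self,
        nodes: list[IngredientNode],
        model: Model,
        category: str,
        trace: list[str],
    ) -> CriteriaLevel:
        """Decide 2 vs 5 vs 8 once the FVNL position criterion is met."""
        classes = self._weight_classes(nodes, model, category, trace)
        non_fvnl = [c for c in classes if c is not None]
        if all(c == _MINIMAL for c in non_fvnl):
            trace.append(
                "all non-FVNL ingredients contribute only minimal weight: 8-point rung"
            )
            return CriteriaLevel.L8
        if any(c == _SUBSTANTIAL for c in non_fvnl):
            trace.append(
                "a non-FVNL ingredient contributes substantially: 2-point rung"
            )
            return CriteriaLevel.L2
        trace.append(
            "non-FVNL ingredients present but none substantial: 5-point rung"
        )
        return CriteriaLevel.L5

    # -- option selection ----------------------------------------------------

    def select_option(
        self,
        record: ProductRecord,
        parsed: list[IngredientList],
        model: Model,
        trace: list[str] | None = None,
    ) -> str:
        """Pick the assessment path for a record (see module docstring)."""
        trace = trace if trace is not None else []
        model = Model(model)
        if not record.has_ingredient_list or not parsed:
            trace.append("no ingredient list")
            return "no_list"
        if len(parsed) > 1:
            trace.append(
                f"{len(parsed)} components: averaged under the "
                "non-concentrated criteria"
            )
            return "multi_component"
        if model is Model.OFCOM:
            # the Ofcom scale does not distinguish concentrated products
            trace.append("Ofcom model: non-concentrated criteria only")
            return "option2"
        if record.tra_category not in self.config.option1_categories:
            trace.append(
                f"category {record.tra_category} is not a fruit/vegetable "
                "category: Option 2"
            )
            return "option2"
        head = parsed[0].nodes[:3]
        fvnl_nodes = [n for n in head if self._fvnl(n, model)]
        conc = [n for n in fvnl_nodes if self.lexicon.is_concentrated(n.name)]
        if fvnl_nodes and 2 * len(conc) > len(fvnl_nodes):
            trace.append(
                f"{len(conc)}/{len(fvnl_nodes)} FVNL ingredients among the "
                "first three are concentrated: Option 1"
            )
            return "option1"
        trace.append(
            "FVNL ingredients among the first three are not mainly "
            "concentrated: Option 2"
        )
        return "option2"

    # -- the two criteria sets ------------------------------------------------

    def score_option1(
        self,
        parsed: IngredientList,
        model: Model,
        category: str,
        trace: list[str] | None = None,
    ) -> CriteriaLevel:
        """Concentrated criteria: a concentrated FVNL component must be one
        of the first three ingredients."""
        trace = trace if trace is not None else []
        model = Model(model)
        conc_pos = None
        for node in parsed.nodes[:3]:
            if self._fvnl(node, model) and self.lexicon.is_concentrated(node.name):
                conc_pos = node.position
                break
        if conc_pos is None:
            trace.append(
                "no concentrated FVNL among the first three ingredients: 0 points"
            )
            return CriteriaLevel.L0
        if conc_pos == 3:
            trace.append("concentrated FVNL is the third ingredient: 1-point rung")
            return CriteriaLevel.L1
        trace.append(
            f"concentrated FVNL is ingredient {conc_pos}: examining remaining "
            "ingredients"
        )
        return self._upper_rung(parsed.nodes, model, category, trace)

    def score_option2(
        self,
        parsed: IngredientList,
        model: Model,
        category: str,
        trace: list[str] | None = None,
    ) -> CriteriaLevel:
        """Non-concentrated criteria: an FVNL must be one of the first two
        ingredients (composites use the first-two-sub-ingredients rule)."""
        trace = trace if trace is not None else []
        model = Model(model)
        head = parsed.nodes[:2]
        flags = [self._fvnl(n, model) for n in head]
        for n, f in zip(head, flags):
            if n.sub_ingredients:
                trace.append(
                    f"'{n.name}' is composite: FVNL via first two "
                    f"sub-ingredients = {f}"
                )
        if not any(flags):
            trace.append("FVNL is not one of the first two ingredients: 0 points")
            return CriteriaLevel.L0
        if not flags[0]:
            trace.append("FVNL is the second ingredient: 1-point rung")
            return CriteriaLevel.L1
        trace.append("FVNL is the first ingredient: examining remaining ingredients")
        return self._upper_rung(parsed.nodes, model, category, trace)

    # -- orchestration ---------------------------------------------------------

    def _name_override(self, record: ProductRecord, trace: list[str]) -> bool:
        name = record.name.lower()
        for kw in self.config.name_override_keywords:
            if kw in name:
                trace.append(
                    f"product name contains {kw!r}: FVNL nature evident from name"
                )
                return True
        return False

    def score_product(self, record: ProductRecord, model: Model) -> ScoreResult:
        """Run the full decision tree for one product under one model."""
        model = Model(model)
        if record.tra_category not in TRA_CATEGORIES:
            raise CategoryError(f"unknown TRA category {record.tra_category!r}")
        beverage = record.nutriscore_beverage
        trace: list[str] = [
            f"model={model.value} category={record.tra_category} "
            f"beverage={beverage}"
        ]
        parsed = [parse_ingredient_list(t) for t in record.ingredient_texts]
        option = self.select_option(record, parsed, model, trace)

        if option == "no_list":
            if self._name_override(record, trace):
                level = self.config.name_override_level
                pts = map_level_to_points(level, model, beverage)
                trace.append(f"name override level {level.value}: {pts} points")
                return ScoreResult(model, "name_override", level, pts, trace)
            trace.append("no ingredient list and no name override: 0 points")
            return ScoreResult(model, "no_list", CriteriaLevel.L0, 0, trace)

        if option == "multi_component":
            comp_points: list[int] = []
            for k, comp in enumerate(parsed, start=1):
                sub_trace: list[str] = []
                level = self.score_option2(
                    comp, model, record.tra_category, sub_trace
                )
                pts = map_level_to_points(level, model, beverage)
                comp_points.append(pts)
                trace.append(f"component {k}: level {level.value}, {pts} points")
                trace.extend(f"  component {k}: {line}" for line in sub_trace)
            pts = average_multi_component(comp_points, model, beverage)
            trace.append(
                f"average of {comp_points} snapped to nearest attainable "
                f"point: {pts}"
            )
            return ScoreResult(model, "multi_component", None, pts, trace)

        scorer = self.score_option1 if option == "option1" else self.score_option2
        level = scorer(parsed[0], model, record.tra_category, trace)
        pts = map_level_to_points(level, model, beverage)
        trace.append(f"level {level.value} -> {pts} points on the {model.value} scale")
        return ScoreResult(model, option, level, pts, trace)


# -- module-level conveniences over a default scorer -------------------------

_DEFAULT: FvnlScorer | None = None


def _default_scorer() -> FvnlScorer:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FvnlScorer()
    return _DEFAULT


def select_option(
    record: ProductRecord, parsed: list[IngredientList], model: Model
) -> str:
    return _default_scorer().select_option(record, parsed, model)


def score_option1(parsed: IngredientList, model: Model, category: str) -> CriteriaLevel:
    return _default_scorer().score_option1(parsed, model, validate_category(category))


def score_option2(parsed: IngredientList, model: Model, category: str) -> CriteriaLevel:
    return _default_scorer().score_option2(parsed, model, validate_category(category))


def score_product(record: ProductRecord, model: Model) -> ScoreResult:
    return _default_scorer().score_product(record, model)
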