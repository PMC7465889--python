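"""Synthetic product fixtures with known ground-truth FVNL points.

The reference food-label database behind the published category
distributions is proprietary, so testing rests on generated products whose
true criteria rung is fixed *by construction*: each template encodes an
ingredient pattern transcribed from the published criteria exemplars and
category examples, and its truth rung was assigned by hand against the
criteria prose when the template was written — independent of the scoring
engine.  Scoring every generated product and comparing against the embedded
truth is the headline regression suite.

Template slots (``{fruit}``, ``{oil}`` ...) are filled from pools drawn only
from the default lexicon, so a recovery failure implicates the rules, not
the vocabulary; every pool member preserves the template's classification
pattern.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .models import CriteriaLevel, Model, map_level_to_points
from .scorer import ProductRecord

__all__ = ["FixtureTemplate", "TEMPLATE_BANK", "generate_products"]

L0, L1, L2, L5, L8 = (
    CriteriaLevel.L0,
    CriteriaLevel.L1,
    CriteriaLevel.L2,
    CriteriaLevel.L5,
    CriteriaLevel.L8,
)
_ALL_MODELS = (Model.FSANZ_NPSC, Model.HSR, Model.NUTRI_SCORE, Model.OFCOM)

# slot pools; members are interchangeable within a template's truth pattern
POOLS: dict[str, tuple[str, ...]] = {
    "fruit": ("cherries", "strawberries", "blueberries", "peaches", "mango", "apples"),
    "fruit2": ("pears", "raspberries", "apricots", "pineapple"),
    "vegetable": ("tomatoes", "carrots", "spinach", "beets", "broccoli", "kale"),
    "vegetable2": ("onions", "celery", "zucchini", "cauliflower"),
    "nut": ("almonds", "peanuts", "walnuts", "cashews"),
    "legume": ("chickpeas", "lentils", "black beans", "soybeans"),
    "conc_fruit": ("concentrated apple juice", "apple juice concentrate", "raisins", "dates"),
    "minimal": ("citric acid", "ascorbic acid", "natural flavour", "potassium sorbate"),
    "sugar": ("sugar", "honey", "corn syrup", "brown sugar"),
    "dense": ("wheat flour", "rice", "cheese", "pasta"),
    "oil": ("sunflower oil", "vegetable oil", "safflower oil"),
}


def _levels(default: CriteriaLevel, **overrides: CriteriaLevel) -> dict[Model, CriteriaLevel]:
    out = {m: default for m in _ALL_MODELS}
    for key, lvl in overrides.items():
        out[Model[key]] = lvl
    return out


@dataclass(frozen=True)
class FixtureTemplate:
    """One product pattern with its hand-assigned truth rung per model."""

    key: str
    tra_category: str
    product_name: str
    components: tuple[str, ...]  # slot patterns; empty tuple = no list
    truth_levels: dict[Model, CriteriaLevel] | None = None
    truth_points_override: dict[Model, int] | None = None  # multi-component
    beverage: bool = False

    def truth_points(self) -> dict[Model, int]:
        if self.truth_points_override is not None:
            return dict(self.truth_points_override)
        assert self.truth_levels is not None
        return {
            m: map_level_to_points(lvl, m, self.beverage)
            for m, lvl in self.truth_levels.items()
        }


TEMPLATE_BANK: tuple[FixtureTemplate, ...] = (
    # --- nuts and seeds (O) -------------------------------------------------
    FixtureTemplate("o_plain_nuts", "O", "Plain roasted {nut}", ("{nut}",), _levels(L8)),
    FixtureTemplate(
        "o_salted_nuts", "O", "Salted {nut}", ("{nut}, {oil}, salt",), _levels(L5)
    ),
    FixtureTemplate(
        "o_sugar_coated", "O", "Candied {nut}", ("{nut}, {sugar}",), _levels(L2)
    ),
    FixtureTemplate(
        "o_starch_dusted",
        "O",
        "Dusted {nut} snack",
        ("{nut}, wheat starch, citric acid",),
        _levels(L8),
    ),
    FixtureTemplate(
        "o_nut_second", "O", "{nut} candy dough", ("{dense}, {nut}, {sugar}",), _levels(L1)
    ),
    FixtureTemplate(
        "o_no_fvnl", "O", "Seasoned crouton mix", ("{dense}, {oil}, {nut}",), _levels(L0)
    ),
    FixtureTemplate(
        "o_composite_butter",
        "O",
        "Chocolate {nut} butter cup",
        ("peanut butter (peanuts, {oil}, salt), {sugar}",),
        _levels(L2),
    ),
    FixtureTemplate(
        "o_composite_spread",
        "O",
        "Sweetened nut-style spread",
        ("peanut spread (palm oil, {sugar}, peanuts), {oil}",),
        _levels(L0),
    ),
    # --- vegetables (V) -----------------------------------------------------
    FixtureTemplate(
        "v_canned_water", "V", "Canned {vegetable}", ("{vegetable}, water, salt",), _levels(L8)
    ),
    FixtureTemplate(
        "v_pickled_sweet",
        "V",
        "Sweet pickled {vegetable}",
        ("{vegetable}, water, {sugar}, salt",),
        _levels(L2),
    ),
    FixtureTemplate(
        "v_marinated",
        "V",
        "Marinated {vegetable}",
        ("{vegetable}, {vegetable2}, {oil}",),
        _levels(L5),
    ),
    FixtureTemplate(
        "v_juice_second", "V", "{vegetable} drink", ("water, {vegetable}",), _levels(L1)
    ),
    # --- fruit and fruit juices (J) ------------------------------------------
    FixtureTemplate(
        "j_fruit_in_syrup", "J", "{fruit} in syrup", ("{fruit}, water, {sugar}",), _levels(L2)
    ),
    FixtureTemplate(
        "j_fruit_in_water", "J", "{fruit} in water", ("{fruit}, water",), _levels(L5)
    ),
    FixtureTemplate(
        "j_plain_fruit", "J", "Frozen {fruit}", ("{fruit}, {fruit2}",), _levels(L8)
    ),
    FixtureTemplate(
        "j_conc_sweetened",
        "J",
        "{fruit} fruit spread from concentrate",
        ("{conc_fruit}, water, {sugar}",),
        _levels(L2),
    ),
    FixtureTemplate(
        "j_drink_conc_third",
        "J",
        "Fruit drink from concentrate",
        ("filtered water, {sugar}, apple juice concentrate",),
        # Ofcom has no concentrated path, so the third-position rung is 0
        _levels(L1, OFCOM=L0),
    ),
    FixtureTemplate(
        "j_pure_concentrate",
        "J",
        "Frozen juice concentrate",
        ("apple juice concentrate, {minimal}",),
        _levels(L8),
    ),
    FixtureTemplate(
        "j_raisins_oil", "J", "Oiled raisins", ("raisins, sunflower oil",), _levels(L5)
    ),
    FixtureTemplate(
        "j_andor_concentrates",
        "J",
        "Mixed juice concentrate blend",
        (
            "apple and/or pear concentrate, apple and/or grape and/or pear "
            "juice concentrate, citrus pectin, elderberry juice concentrate, "
            "natural flavour, lemon juice concentrate",
        ),
        _levels(L8),
    ),
    # --- legumes (K) ----------------------------------------------------------
    FixtureTemplate(
        "k_canned", "K", "Canned {legume}", ("{legume}, water, salt",), _levels(L5)
    ),
    FixtureTemplate("k_dried", "K", "Dry {legume}", ("{legume}",), _levels(L8)),
    FixtureTemplate(
        "k_soup_mix", "K", "{legume} soup mix", ("{legume}, water, barley",), _levels(L2)
    ),
    # --- soups (T) -------------------------------------------------------------
    FixtureTemplate(
        "t_broth_based", "T", "{vegetable} broth soup", ("water, {vegetable}, salt",), _levels(L1)
    ),
    FixtureTemplate(
        "t_veg_first", "T", "Cream-style {vegetable} soup", ("{vegetable}, water, salt",), _levels(L2)
    ),
    FixtureTemplate(
        "t_chunky",
        "T",
        "Chunky {vegetable} soup",
        ("{vegetable}, {vegetable2}, {oil}, salt",),
        _levels(L5),
    ),
    # --- bakery (A) ------------------------------------------------------------
    FixtureTemplate(
        "a_fruit_second",
        "A",
        "Fruit and grain bar",
        ("{dense}, raisins, {sugar}",),
        _levels(L1),
    ),
    FixtureTemplate(
        "a_fruit_first", "A", "Fruit-first cereal bar", ("raisins, {dense}, {sugar}",), _levels(L2)
    ),
    FixtureTemplate(
        "a_composite_granola",
        "A",
        "Granola fruit bar",
        ("granola (oats, honey), raisins, {sugar}",),
        _levels(L1),
    ),
    FixtureTemplate(
        "a_no_list_bread",
        "A",
        "In-store baked multigrain loaf",
        (),
        _levels(L0),
    ),
    # --- potatoes, sweet potatoes and yams (P) ---------------------------------
    FixtureTemplate(
        "p_fries",
        "P",
        "Oven fries",
        ("potatoes, {oil}, salt",),
        _levels(L5, NUTRI_SCORE=L0, OFCOM=L0),
    ),
    FixtureTemplate(
        "p_canned",
        "P",
        "Canned potatoes",
        ("potatoes, water, salt",),
        _levels(L8, NUTRI_SCORE=L0, OFCOM=L0),
    ),
    # --- cereals (C) ------------------------------------------------------------
    FixtureTemplate(
        "c_plain_seeds",
        "C",
        "Plain chia seeds",
        ("chia seeds",),
        _levels(L8, NUTRI_SCORE=L0, OFCOM=L0),
    ),
    FixtureTemplate(
        "c_dried_fruit_second",
        "C",
        "Breakfast cereal with fruit",
        ("{dense}, raisins, {sugar}, salt",),
        _levels(L1),
    ),
    # --- fats and oils (H) --------------------------------------------------------
    FixtureTemplate(
        "h_olive_oil",
        "H",
        "Extra virgin olive oil",
        ("olive oil",),
        _levels(L0, NUTRI_SCORE=L8),
    ),
    FixtureTemplate(
        "h_oil_blend",
        "H",
        "Oil blend",
        ("vegetable oil, olive oil",),
        _levels(L0, NUTRI_SCORE=L1),
    ),
    # --- beverages (B; Nutri-Score beverage scale) --------------------------------
    FixtureTemplate(
        "b_fruit_drink",
        "B",
        "Fruit punch from concentrate",
        ("water, concentrated apple juice",),
        _levels(L1),
        beverage=True,
    ),
    FixtureTemplate(
        "b_coconut_water",
        "B",
        "Pure coconut water",
        ("coconut water",),
        _levels(L8),
        beverage=True,
    ),
    FixtureTemplate(
        "b_coconut_sweet",
        "B",
        "Sweetened coconut water",
        ("coconut water, {sugar}",),
        _levels(L2),
        beverage=True,
    ),
    FixtureTemplate(
        "b_soda",
        "B",
        "Cola soft drink",
        ("water, {sugar}, natural flavour",),
        _levels(L0),
        beverage=True,
    ),
    # --- dairy (D) -----------------------------------------------------------------
    FixtureTemplate(
        "d_fruit_yogurt", "D", "{fruit} yogurt", ("milk, {fruit}, {sugar}",), _levels(L1)
    ),
    FixtureTemplate(
        "d_plain_dessert", "D", "Vanilla dairy dessert", ("milk, {sugar}, {dense}",), _levels(L0)
    ),
    # --- sugars and sweets (U) -------------------------------------------------------
    FixtureTemplate(
        "u_jam", "U", "{fruit} jam", ("{fruit}, {sugar}, pectin",), _levels(L2)
    ),
    FixtureTemplate(
        "u_fruit_leather", "U", "{fruit} leather", ("{fruit}, {oil}",), _levels(L5)
    ),
    FixtureTemplate(
        "u_pure_fruit_spread", "U", "Pure {fruit} spread", ("{fruit}, {fruit2}",), _levels(L8)
    ),
    # --- sauces and condiments (R) -----------------------------------------------------
    FixtureTemplate(
        "r_pasta_sauce",
        "R",
        "Rustic pasta sauce",
        ("tomatoes, {oil}, salt, spices",),
        _levels(L5),
    ),
    FixtureTemplate(
        "r_hummus",
        "R",
        "Classic hummus",
        ("chickpeas, tahini, {oil}, salt",),
        _levels(L5),
    ),
    FixtureTemplate(
        "r_veg_second", "R", "Simmering sauce", ("water, {vegetable}, {sugar}, salt",), _levels(L1)
    ),
    # --- snacks (S) ----------------------------------------------------------------------
    FixtureTemplate(
        "s_potato_chips",
        "S",
        "Kettle potato chips",
        ("potatoes, {oil}, salt",),
        _levels(L5, NUTRI_SCORE=L0, OFCOM=L0),
    ),
    FixtureTemplate(
        "s_sweet_nuts", "S", "Honey-roasted {nut}", ("{nut}, {sugar}",), _levels(L2)
    ),
    # --- miscellaneous (M) -----------------------------------------------------------------
    FixtureTemplate(
        "m_seasoning",
        "M",
        "Vegetable seasoning blend",
        ("dehydrated onions, paprika",),
        _levels(L8, NUTRI_SCORE=L5, OFCOM=L5),
    ),
    # --- no ingredient list, name override (Q) ------------------------------------------------
    FixtureTemplate("q_garden_salad", "Q", "Garden salad", (), _levels(L8)),
    # --- multi-component kits ------------------------------------------------------------------
    FixtureTemplate(
        "n_veg_cheese_kit",
        "N",
        "Vegetable and cheese snack kit",
        ("carrots, water, {minimal}", "cheese, water"),
        truth_points_override={
            Model.FSANZ_NPSC: 1,
            Model.HSR: 1,
            Model.NUTRI_SCORE: 1,
            Model.OFCOM: 1,
        },
    ),
    FixtureTemplate(
        "q_salad_kit",
        "Q",
        "Salad kit with crouton packet",
        ("lettuce, carrots", "wheat flour, water, salt"),
        truth_points_override={
            Model.FSANZ_NPSC: 5,
            Model.HSR: 5,
            Model.NUTRI_SCORE: 2,
            Model.OFCOM: 2,
        },
    ),
)

_BY_CATEGORY: dict[str, list[FixtureTemplate]] = {}
for _t in TEMPLATE_BANK:
    _BY_CATEGORY.setdefault(_t.tra_category, []).append(_t)


def _fill(pattern: str, rng: random.Random) -> tuple[str, dict[str, str]]:
    chosen: dict[str, str] = {}
    out = pattern
    for slot, pool in POOLS.items():
        token = "{" + slot + "}"
        while token in out:
            if slot not in chosen:
                chosen[slot] = rng.choice(pool)
            out = out.replace(token, chosen[slot], 1)
    return out, chosen


def generate_products(
    n: int,
    seed: int,
    category_mix: dict[str, float] | None = None,
) -> list[tuple[ProductRecord, dict]]:
    """Generate ``n`` products with embedded truth, deterministically.

    ``category_mix`` optionally weights TRA categories; templates within a
    category are sampled uniformly.  Each returned truth dict carries the
    template key, the truth rung per model (where defined) and the truth
    points per model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    if category_mix is not None:
        cats = sorted(category_mix)
        weights = [float(category_mix[c]) for c in cats]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("category weights must be non-negative, not all zero")
        for c in cats:
            if category_mix[c] > 0 and c not in _BY_CATEGORY:
                raise ValueError(f"no fixture templates for category {c!r}")
    out: list[tuple[ProductRecord, dict]] = []
    for i in range(n):
        if category_mix is None:
            template = TEMPLATE_BANK[rng.randrange(len(TEMPLATE_BANK))]
        else:
            cat = rng.choices(cats, weights=weights, k=1)[0]
            bank = _BY_CATEGORY[cat]
            template = bank[rng.randrange(len(bank))]
        chosen_all: dict[str, str] = {}
        texts = []
        for comp in template.components:
            # slot choices are shared across components of one product
            filled, chosen = _fill(comp, rng)
            chosen_all.update(chosen)
            texts.append(filled)
        name = template.product_name
        for slot, value in chosen_all.items():
            name = name.replace("{" + slot + "}", value)
        if "{" in name:  # name-only slots not used in any component
            name, _ = _fill(name, rng)
        record = ProductRecord(
            id=f"FX{i:05d}",
            name=name,
            tra_category=template.tra_category,
            ingredient_texts=texts,
            nutriscore_beverage=template.beverage,
        )
        truth = {
            "template": template.key,
            "levels": (
                {m.value: lvl.value for m, lvl in template.truth_levels.items()}
                if template.truth_levels is not None
                else None
            ),
            "points": {m.value: p for m, p in template.truth_points().items()},
        }
        out.append((record, truth))
    return out
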