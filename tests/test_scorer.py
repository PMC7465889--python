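"""Decision-tree scoring: worked examples, point scales, averaging,
no-list handling, and the scorer's structural invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fvnlpoints import (
    CategoryError,
    CriteriaLevel,
    Model,
    ProductRecord,
    average_multi_component,
    map_level_to_points,
    parse_ingredient_list,
    valid_points,
)
from conftest import make_product

F, H, N, O = Model.FSANZ_NPSC, Model.HSR, Model.NUTRI_SCORE, Model.OFCOM
LEVEL_ORDER = {lvl: i for i, lvl in enumerate(
    [CriteriaLevel.L0, CriteriaLevel.L1, CriteriaLevel.L2,
     CriteriaLevel.L5, CriteriaLevel.L8])}


class TestWorkedExamples:
    """Every printed single-product exemplar, under the FSANZ/HSR scale."""

    CASES = [
        ("peanut butter (peanuts, vegetable oil, salt), sugar", "O", "option2", 2),
        ("peanut spread (palm oil, sugar, peanuts), water", "O", "option2", 0),
        ("Filtered water, sugar, concentrated fruit juice", "J", "option1", 1),
        ("Concentrated apple juice, water, sugar", "J", "option1", 2),
        ("Thompson raisins, sunflower oil", "J", "option1", 5),
        (
            "Apple and/or pear concentrate, apple and/or grape and/or pear "
            "juice concentrate, citrus pectin, elderberry juice concentrate, "
            "natural flavour, lemon juice concentrate",
            "J",
            "option1",
            8,
        ),
        ("Cherries, water, sugar", "J", "option2", 2),
        ("Cherries, safflower oil, vinegar", "J", "option2", 5),
        ("Almonds, wheat starch, citric acid", "O", "option2", 8),
        ("Beets, water, salt", "V", "option2", 8),
    ]

    @pytest.mark.parametrize("text, cat, option, points", CASES)
    @pytest.mark.parametrize("model", [F, H])
    def test_fsanz_hsr_points(self, scorer, text, cat, option, points, model):
        res = scorer.score_product(make_product(text, cat), model)
        assert res.option_used == option
        assert res.points == points
        assert res.trace  # rationale is always recorded

    def test_soup_with_tomato_paste_is_not_concentrated(self, scorer):
        # concentrated FVNL in a non-produce category stays on Option 2
        res = scorer.score_product(
            make_product("tomato paste, water, salt", "T"), F
        )
        assert res.option_used == "option2"

    def test_granola_bar_with_dried_fruit_uses_option2(self, scorer):
        res = scorer.score_product(
            make_product("wheat flour, raisins, sugar", "A"), F
        )
        assert res.option_used == "option2"
        assert res.points == 1

    def test_pure_concentrate_with_only_ascorbic_acid_scores_top(self, scorer):
        res = scorer.score_product(
            make_product("apple juice concentrate, ascorbic acid", "J"), F
        )
        assert res.points == 8

    def test_canned_legumes_water_blocks_top_rung(self, scorer):
        res = scorer.score_product(make_product("lentils, water, salt", "K"), F)
        assert res.points == 5

    def test_salted_nuts_score_five_not_eight(self, scorer):
        # salt on nuts is a seasoning on the food, not a preservative
        res = scorer.score_product(make_product("almonds, salt", "O"), F)
        assert res.points == 5


class TestLevelToPoints:
    @pytest.mark.parametrize(
        "level, model, beverage, expected",
        [
            (CriteriaLevel.L8, F, False, 8),
            (CriteriaLevel.L8, H, False, 8),
            (CriteriaLevel.L8, N, False, 5),
            (CriteriaLevel.L8, N, True, 10),
            (CriteriaLevel.L5, N, False, 5),
            (CriteriaLevel.L5, N, True, 10),
            (CriteriaLevel.L2, N, True, 4),
            (CriteriaLevel.L1, N, True, 2),
            (CriteriaLevel.L1, F, False, 1),
            (CriteriaLevel.L8, O, False, 5),
            (CriteriaLevel.L0, F, False, 0),
            (CriteriaLevel.L0, N, True, 0),
            (CriteriaLevel.L0, O, False, 0),
        ],
    )
    def test_scale_mapping(self, level, model, beverage, expected):
        assert map_level_to_points(level, model, beverage) == expected

    def test_valid_sets(self):
        assert valid_points(F) == (0, 1, 2, 5, 8)
        assert valid_points(N) == (0, 1, 2, 5)
        assert valid_points(N, beverage=True) == (0, 2, 4, 10)
        assert valid_points(O) == (0, 1, 2, 5)


class TestAveraging:
    @pytest.mark.parametrize(
        "points, model, expected",
        [
            ([2, 2], F, 2),
            ([8, 0], F, 5),   # mean 4: |4-5| < |4-2|
            ([5, 1], F, 2),   # mean 3: |3-2| < |3-5|
            ([8, 8, 0], F, 5),  # mean 16/3: closer to 5 than 8
            ([5, 0], N, 2),   # mean 2.5 ties between 2 and... snaps down
            ([2, 4], N, 2),   # Nutri beverage points average on its own set
        ],
    )
    def test_snap_to_valid_set(self, points, model, expected):
        beverage = model is N and set(points) <= {0, 2, 4, 10} and 4 in points
        assert average_multi_component(points, model, beverage) == expected

    def test_tie_snaps_downward(self):
        # mean 1.5 is equidistant from 1 and 2 on the FSANZ scale
        assert average_multi_component([1, 2], F) == 1

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            average_multi_component([], F)

    def test_invalid_member_raises(self):
        with pytest.raises(ValueError):
            average_multi_component([3], F)


class TestDecisionTreeOrchestration:
    def test_no_list_scores_zero(self, scorer):
        rec = ProductRecord(
            id="x", name="in-store baked bread", tra_category="A",
            ingredient_texts=[],
        )
        for model in (F, N):
            res = scorer.score_product(rec, model)
            assert res.option_used == "no_list"
            assert res.points == 0

    def test_no_list_name_override(self, scorer):
        rec = ProductRecord(
            id="x", name="Fresh fruit tray", tra_category="J",
            ingredient_texts=[],
        )
        assert scorer.score_product(rec, F).points == 8
        assert scorer.score_product(rec, F).option_used == "name_override"
        assert scorer.score_product(rec, N).points == 5

    def test_multi_component_averages_and_snaps(self, scorer):
        rec = make_product(["lettuce, carrots", "wheat flour, water, salt"], "Q")
        res = scorer.score_product(rec, F)
        assert res.option_used == "multi_component"
        assert res.points == 5  # components 8 and 0, mean 4, nearest is 5
        assert scorer.score_product(rec, N).points == 2

    def test_invalid_category_raises(self):
        with pytest.raises(CategoryError):
            make_product("cherries", "Z9")

    def test_nutriscore_beverage_scale(self, scorer):
        rec = make_product("coconut water", "B", beverage=True)
        assert scorer.score_product(rec, N).points == 10
        assert scorer.score_product(rec, F).points == 8

    def test_ofcom_has_no_concentrated_path(self, scorer):
        rec = make_product("filtered water, sugar, apple juice concentrate", "J")
        assert scorer.score_product(rec, F).points == 1
        assert scorer.score_product(rec, O).points == 0

    def test_determinism_byte_identical_trace(self, scorer):
        rec = make_product("Cherries, water, sugar", "J")
        a = scorer.score_product(rec, F)
        b = scorer.score_product(rec, F)
        assert a.trace == b.trace and a.points == b.points


# -- randomized structural invariants ---------------------------------------

VOCAB = [
    "cherries", "almonds", "chickpeas", "raisins", "tomato paste",
    "olive oil", "sunflower oil", "water", "sugar", "cheese", "salt",
    "citric acid",
]
CATEGORIES = ["A", "B", "J", "K", "N", "O", "S", "T", "V"]

lists_st = st.lists(st.sampled_from(VOCAB), min_size=1, max_size=6)


@given(
    words=lists_st,
    category=st.sampled_from(CATEGORIES),
    model=st.sampled_from([F, H, N, O]),
    beverage=st.booleans(),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_points_always_in_valid_set(scorer, words, category, model, beverage):
    rec = make_product(", ".join(words), category, beverage=beverage)
    res = scorer.score_product(rec, model)
    assert res.points in valid_points(model, beverage)


@given(
    words=lists_st,
    category=st.sampled_from(CATEGORIES),
    model=st.sampled_from([F, H, N]),
    heavy=st.sampled_from(["cheese", "sugar"]),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_prepending_substantial_never_raises_level(
    scorer, words, category, model, heavy
):
    base = scorer.score_product(make_product(", ".join(words), category), model)
    worse = scorer.score_product(
        make_product(", ".join([heavy] + words), category), model
    )
    if base.level is not None and worse.level is not None:
        assert LEVEL_ORDER[worse.level] <= LEVEL_ORDER[base.level]


def test_deleting_non_fvnl_bulk_from_fvnl_led_list_gives_top_rung(scorer):
    """Stripping every non-FVNL, non-additive ingredient from an FVNL-led
    list leaves a 'pure state' product on the 8-point rung."""
    rng = random.Random(20260928)
    fvnl_words = ["cherries", "almonds", "chickpeas"]
    others = ["sunflower oil", "water", "sugar", "cheese"]
    additives = ["citric acid"]
    for _ in range(100):
        tail = rng.sample(others, k=rng.randint(1, 3)) + rng.sample(
            additives, k=rng.randint(0, 1)
        )
        rng.shuffle(tail)
        words = [rng.choice(fvnl_words)] + tail
        category = rng.choice(CATEGORIES)
        stripped = [w for w in words if w not in others]
        res = scorer.score_product(
            make_product(", ".join(stripped), category), F
        )
        assert res.level == CriteriaLevel.L8, (words, category)


@given(words=lists_st, category=st.sampled_from(CATEGORIES))
@settings(max_examples=300, deadline=None, derandomize=True)
def test_nutri_food_points_bounded_by_fsanz_without_eligible_oils(
    scorer, words, category
):
    """With no rapeseed/walnut/olive oil present, the Nutri-Score food scale
    can never exceed FSANZ points (its top rung is capped at 5)."""
    if "olive oil" in words:
        words = [w for w in words if w != "olive oil"]
    if not words:
        return
    rec = make_product(", ".join(words), category)
    assert (
        scorer.score_product(rec, N).points <= scorer.score_product(rec, F).points
    )
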