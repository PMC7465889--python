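"""Health Canada Table of Reference Amounts (TRA) major food categories.

Products are conditioned on one of the 24 major TRA categories (letter codes
A-X).  The scoring rules use the category to decide concentrated-product
eligibility, the water rule for canned produce, and the generosity rules for
FVNL-based categories.
"""

from __future__ import annotations

__all__ = ["TRA_CATEGORIES", "validate_category", "CategoryError"]


class CategoryError(ValueError):
    """Raised for a category code outside the closed TRA set."""


TRA_CATEGORIES: dict[str, str] = {
    "A": "Bakery products",
    "B": "Beverages",
    "C": "Cereals and other grain products",
    "D": "Dairy products",
    "E": "Desserts",
    "F": "Dessert toppings and fillings",
    "G": "Eggs and egg substitutes",
    "H": "Fats and oils",
    "I": "Marine and fresh water animals",
    "J": "Fruit and fruit juices",
    "K": "Legumes",
    "L": "Meat, poultry, their products and substitutes",
    "M": "Miscellaneous",
    "N": "Combination dishes",
    "O": "Nuts and seeds",
    "P": "Potatoes, sweet potatoes and yams",
    "Q": "Salads",
    "R": "Sauces, dips, gravies and condiments",
    "S": "Snacks",
    "T": "Soups",
    "U": "Sugars and sweets",
    "V": "Vegetables",
    # The two remaining major categories hold products typically excluded
    # from FVNL analyses (see docs/methods.md); the codes are still accepted.
    "W": "Meal replacements and nutritional supplements",
    "X": "Foods intended solely for children under 4 years of age",
}

_BY_NAME = {name.lower(): code for code, name in TRA_CATEGORIES.items()}


def validate_category(value: str) -> str:
    """Return the canonical single-letter code for a category code or name.

    Accepts ``"J"``, ``"j."``, or the full category name (case-insensitive).
    Raises :class:`CategoryError` otherwise.
    """
    if value is None:
        raise CategoryError("missing TRA category")
    s = str(value).strip().rstrip(".")
    if not s:
        raise CategoryError("missing TRA category")
    if len(s) == 1 and s.upper() in TRA_CATEGORIES:
        return s.upper()
    if s.lower() in _BY_NAME:
        return _BY_NAME[s.lower()]
    raise CategoryError(f"unknown TRA category {value!r}")
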