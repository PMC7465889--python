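import pytest

from fvnlpoints import FvnlScorer, ProductRecord, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def scorer():
    return FvnlScorer()


def make_product(ingredients, category, beverage=False, name="product", pid="p1"):
    texts = [ingredients] if isinstance(ingredients, str) else list(ingredients)
    return ProductRecord(
        id=pid,
        name=name,
        tra_category=category,
        ingredient_texts=texts,
        nutriscore_beverage=beverage,
    )
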