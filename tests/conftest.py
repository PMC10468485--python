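import pytest

from upfscan.additives import default_lexicon
from upfscan.catalog import Basis, NutritionFacts, ProductRecord


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_record(
    product_id="P1",
    subgroup="Sweet cookies",
    nova_group=4,
    ingredients="farinha de trigo, acucar, sal",
    energy_kcal=400.0,
    basis=Basis.per_100g,
    **facts,
):
    """Build a valid record with sensible defaults; keyword args override panel fields."""
    return ProductRecord(
        product_id=product_id,
        name=f"test {product_id}",
        subgroup=subgroup,
        nova_group=nova_group,
        facts=NutritionFacts(basis=basis, energy_kcal=energy_kcal, **facts),
        ingredients_text=ingredients,
    )


@pytest.fixture
def record_factory():
    return make_record
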