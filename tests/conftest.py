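"""Shared fixtures: module catalog, construct recipes, synthetic DNA."""

import pytest

from gdtandem.assembly import AssemblyRecipe, build_catalog, construct_recipes
from gdtandem.fixtures import make_insert, make_vector


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def recipes():
    return construct_recipes()


@pytest.fixture(scope="session")
def w4_recipe(recipes):
    return recipes["W4"]


@pytest.fixture(scope="session")
def w8_recipe(recipes):
    return AssemblyRecipe("W8", recipes["W4"].items * 2)


@pytest.fixture(scope="session")
def bam_vector():
    """Synthetic 600 bp circular vector with a unique BamHI site."""
    return make_vector(600, ("BamHI",), seed=11)


@pytest.fixture(scope="session")
def bgl_bam_insert():
    """Synthetic insert carrying BglII/BamHI sticky ends, no internal sites."""
    return make_insert(48, "BglII", "BamHI", seed=12)
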