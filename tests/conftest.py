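"""Shared fixtures: small toy networks and synthetic profile sets."""
import pytest

from metaniche.classes import ORGANIC_CLASSES
from metaniche.simulate import ToyNetworkSpec, make_toy_model, toy_class_map


@pytest.fixture
def glucose_spec():
    """One carbohydrate-like substrate, yield 0.5, uptake 10 → max growth 5."""
    return ToyNetworkSpec(
        classes=("carbohydrates",),
        biomass_yields={"carbohydrates__s0": 0.5},
        uptake_bound=10.0,
    )


@pytest.fixture
def glucose_model(glucose_spec):
    return make_toy_model(glucose_spec)


@pytest.fixture
def limited_spec():
    """Four classes, carboxylic acids fully growth-limiting."""
    return ToyNetworkSpec(
        classes=ORGANIC_CLASSES[:4],
        limiting_classes=frozenset({"carboxylic_acids"}),
    )


@pytest.fixture
def limited_model(limited_spec):
    return make_toy_model(limited_spec)


@pytest.fixture
def limited_class_map(limited_spec):
    return toy_class_map(limited_spec)


@pytest.fixture
def generalist_spec():
    """All 11 classes interchangeable, growth capped below total supply."""
    return ToyNetworkSpec(classes=ORGANIC_CLASSES, biomass_cap=20.0)
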