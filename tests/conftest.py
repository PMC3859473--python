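import pytest

from zoonet.datamodel import (
    ChecklistOrder,
    Holding,
    IUCNCategory,
    SpeciesTaxon,
    Zoo,
    validate_dataset,
)


@pytest.fixture
def toy_dataset():
    """Small consistent dataset: 3 zoos, 2 orders, 5 species."""
    zoos = [Zoo("Z1", 51.5, -0.1), Zoo("Z2", 48.9, 2.3), Zoo("Z3", 40.7, -74.0)]
    species = [
        SpeciesTaxon("sp1", "Mammalia", "Carnivora", IUCNCategory.EN),
        SpeciesTaxon("sp2", "Mammalia", "Carnivora", IUCNCategory.LC),
        SpeciesTaxon("sp3", "Mammalia", "Rodentia", IUCNCategory.VU),
        SpeciesTaxon("sp4", "Mammalia", "Rodentia", IUCNCategory.LC),
        SpeciesTaxon("sp5", "Mammalia", "Rodentia", IUCNCategory.NT),
    ]
    holdings = [
        Holding("Z1", "sp1", 12),
        Holding("Z2", "sp1", 3),
        Holding("Z1", "sp2", 30),
        Holding("Z3", "sp3", 7),
        Holding("Z2", "sp4", 5),
    ]
    checklist = [
        ChecklistOrder("Mammalia", "Carnivora", 10, 4),
        ChecklistOrder("Mammalia", "Rodentia", 20, 6),
    ]
    return validate_dataset(zoos, species, holdings, checklist)


@pytest.fixture
def four_zoo_toy():
    """Three zoos within ~60 km each holding 20 of one threatened species,
    plus one zoo ~5,000 km away holding none of it."""
    zoos = [
        Zoo("A", 0.0, 0.0),
        Zoo("B", 0.5, 0.0),
        Zoo("C", 0.0, 0.5),
        Zoo("D", 45.0, 0.0),
    ]
    species = [
        SpeciesTaxon("sp1", "Reptilia", "Testudines", IUCNCategory.VU),
        SpeciesTaxon("sp2", "Reptilia", "Testudines", IUCNCategory.LC),
    ]
    holdings = [
        Holding("A", "sp1", 20),
        Holding("B", "sp1", 20),
        Holding("C", "sp1", 20),
        Holding("D", "sp2", 5),
    ]
    checklist = [ChecklistOrder("Reptilia", "Testudines", 40, 10)]
    return validate_dataset(zoos, species, holdings, checklist)
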