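import pytest

from herbcat import Backbone, BackboneEntry, GeneratorConfig, generate


@pytest.fixture(scope="session")
def toy_backbone() -> Backbone:
    """Small hand-built backbone with accepted names, a synonym and a
    near-neighbour pair for ambiguity tests."""
    return Backbone(
        [
            BackboneEntry(name="Aus bus", group="angiosperm", family="Ausaceae",
                          life_forms=frozenset({"tree"}),
                          vegetation_types=frozenset({"floresta ombrofila densa"})),
            BackboneEntry(name="Aus cus", status="synonym", accepted_name="Aus bus",
                          group="angiosperm", family="Ausaceae"),
            BackboneEntry(name="Dus ena", group="lycophyte_fern", family="Dusaceae",
                          life_forms=frozenset({"herb"})),
            BackboneEntry(name="Dus enu", group="lycophyte_fern", family="Dusaceae"),
            BackboneEntry(name="Gymnos solo", group="gymnosperm", family="Gymnosaceae",
                          origin="non_native", endemic_to_country=False,
                          life_forms=frozenset({"tree"})),
        ]
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        seed=7,
        n_species={"angiosperm": 40, "gymnosperm": 3, "lycophyte_fern": 10},
        n_families={"angiosperm": 8, "gymnosperm": 2, "lycophyte_fern": 3},
        n_genera={"angiosperm": 15, "gymnosperm": 3, "lycophyte_fern": 5},
        mean_records_per_species=4.0,
        n_priority_species=3,
        n_collectors=10,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("synthetic_small")
    paths, truth = generate(small_config, out)
    return paths, truth
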