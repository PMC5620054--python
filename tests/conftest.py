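import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from holomem.pipeline import PipelineConfig, run
from holomem.records import SpeciesInfo
from holomem.synthetic import SimulationConfig, default_patterns, generate_bundle


def small_species() -> list[SpeciesInfo]:
    return [
        SpeciesInfo("out_a", "outgroup"),
        SpeciesInfo("out_b", "outgroup"),
        SpeciesInfo("met_hum", "metazoan-vertebrate", is_human_proxy=True),
        SpeciesInfo("met_x", "metazoan-invertebrate"),
        SpeciesInfo("met_y", "metazoan-invertebrate"),
        SpeciesInfo("met_z", "metazoan-invertebrate"),
    ]


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(seed=11, species=small_species(),
                    patterns=default_patterns(6, 3, 2), spurious_rate=0.0)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 6-species, 11-family zero-noise bundle plus its pipeline run."""
    root = tmp_path_factory.mktemp("small_bundle")
    paths, truth = generate_bundle(small_config(), root)
    result = run(PipelineConfig.for_bundle(root), root / "run")
    return paths, truth, result


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The full study-condition bundle: 24 species, 60 planted families,
    seed 1, with spurious cross-family hits at the default rate."""
    root = tmp_path_factory.mktemp("default_bundle")
    paths, truth = generate_bundle(SimulationConfig(seed=1), root)
    result = run(PipelineConfig.for_bundle(root), root / "run")
    return paths, truth, result


@pytest.fixture(scope="session")
def zero_noise_bundle(tmp_path_factory):
    """Default-size bundle with spurious_rate 0 (exact-recovery variant)."""
    root = tmp_path_factory.mktemp("zero_noise_bundle")
    config = SimulationConfig(seed=1, spurious_rate=0.0)
    paths, truth = generate_bundle(config, root)
    result = run(PipelineConfig.for_bundle(root), root / "run")
    return paths, truth, result


def level1_assignment(result) -> dict[str, str]:
    return {p: c.cluster_id for c in result.level1 for p in c.members}
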