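import numpy as np
import pytest

from fourc.fragends import GenomeSequence, RestrictionScheme, build_fragend_library
from fourc.profiles import Viewpoint
from fourc.simulate import SimulationConfig, simulate_genome


def small_sim_config(**overrides) -> SimulationConfig:
    """A scaled-down scenario for fast unit tests: 60 kb cis + 20 kb trans,
    2,000 cis / 200 trans reads."""
    defaults = dict(
        seed=0,
        chrom_lengths={"chrV": 60_000, "chrT": 20_000},
        viewpoint=Viewpoint(
            name="vp", chrom="chrV", position=30_000,
            reading_primer="GTCCCAAGGGCACACTGATC",
        ),
        n_reads_cis=2_000,
        n_reads_trans=200,
        effect_regions=[],
        anchor_centers=[("chrV", 10_000), ("chrV", 20_000), ("chrV", 45_000)],
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The package's default scenario (the full study design)."""
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_library(default_config):
    genome = simulate_genome(default_config)
    return build_fragend_library(genome, default_config.scheme)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_genome):
    return build_fragend_library(small_genome, small_config.scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_genome():
    """Hand-written two-chromosome genome with known GATC/GTAC layout."""
    return [
        GenomeSequence("chr1", "AAAA" + "GATC" + "TTGTACTT" + "GATC" + "CCCC"),
        GenomeSequence("chr2", "GGGG" + "GATC" + "AAAAAAAA"),
    ]


@pytest.fixture()
def toy_scheme():
    return RestrictionScheme(extract_len=6)
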