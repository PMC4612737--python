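import pytest

from methylcompare.io import GenomeSpec
from methylcompare.latent import LatentClassParams
from methylcompare.simulate import (
    TruthConfig,
    generate_genome_fixture,
    generate_latent,
    generate_probe_manifest,
)

# the default operating point used across tests: array test (1) vs capture
# test (2) at a mid-threshold, type-1-chemistry regime
STUDY_PARAMS = LatentClassParams(
    se1=0.743, se2=0.525, sp1=0.868, sp2=0.938, pi=0.515, covp=0.02, covn=0.005
)


@pytest.fixture(scope="session")
def genome_fixture():
    return generate_genome_fixture(seed=11)


@pytest.fixture(scope="session")
def genome(genome_fixture):
    return genome_fixture[0]


@pytest.fixture(scope="session")
def small_genome():
    return GenomeSpec(lengths={"chr1": 100_000})


@pytest.fixture(scope="session")
def manifest(genome):
    return generate_probe_manifest(genome, 400, seed=12)


@pytest.fixture(scope="session")
def latent_small(manifest):
    cfg = TruthConfig(n_loci=len(manifest), n_samples=8, pi=0.515, seed=13)
    return cfg, generate_latent(cfg)
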