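import pytest

from genefamscan.io_formats import PipelineConfig
from genefamscan.synthetic_data import GeneratorProfile, generate_family_genome

SIGNATURE_DEFS = {
    "ATP_binding": "[IL]GXGXFGVA",
    "active_site": "[VI]CHRDLKLENTLL",
}


@pytest.fixture(scope="session")
def family42():
    """Default-profile synthetic family, seed 42 (shared, read-only)."""
    return generate_family_genome(GeneratorProfile(rng_seed=42))


@pytest.fixture(scope="session")
def small_family():
    """A 6-member family with few decoys, for fast end-to-end tests."""
    profile = GeneratorProfile(
        family_size=6, n_kinase_decoys=3, n_nonkinase_decoys=3, rng_seed=7
    )
    return generate_family_genome(profile)


@pytest.fixture()
def config():
    return PipelineConfig()
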