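import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from buscosynteny.synthetic import SimConfig, simulate_pair  # noqa: E402

# small, fast study pair reused across test modules: turtle-like contrast of
# an ancestral karyotype vs a descendant carrying two fusions
SMALL_CFG = SimConfig(
    n_ancestral_chroms=6, n_orthologs=120,
    chrom_length_range=(30_000, 60_000),
    events=(("fusion", None), ("fusion", None)), seed=7)


@pytest.fixture(scope="session")
def fused_pair():
    return simulate_pair(SMALL_CFG)


@pytest.fixture(scope="session")
def null_pair():
    cfg = SimConfig(n_ancestral_chroms=4, n_orthologs=40,
                    chrom_length_range=(20_000, 40_000), seed=11)
    return simulate_pair(cfg)
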