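import pytest
from hypothesis import HealthCheck, settings

import acetyldiff as ad

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """A compact two-condition dataset shared by the slower tests."""
    config, annotation = ad.make_study(
        seed=7, genome_length=500_000, n_chromosomes=2, n_genes=100,
        n_regions=25)
    tags = ad.simulate_study(config)
    return config, annotation, tags


@pytest.fixture(scope="session")
def small_regions(small_study):
    config, _, tags = small_study
    return ad.call_enriched_regions(
        tags[("control", "chip")], tags[("control", "input")],
        ad.CallerParams(), config.chrom_sizes())
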