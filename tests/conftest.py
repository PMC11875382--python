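import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture
def marker_config():
    from fawkit.refseqs import DEFAULT_MARKER_CONFIG

    return DEFAULT_MARKER_CONFIG


@pytest.fixture
def small_population():
    """50-specimen mixed collection with ground truth, no heterozygotes."""
    from fawkit.synthetic import PopulationSpec, gen_population_sequences

    spec = PopulationSpec(
        collection_id="Hi11",
        n=50,
        csh_freqs={"CSh1": 0.2, "CSh2": 0.6, "CSh4": 0.2},
        tpi_hap_freqs={"AfrCa1c": 0.5, "AfrCa2c": 0.3, "AfrCa1a": 0.2},
        heterozygosity_rate=0.0,
        seed=11,
    )
    return spec, gen_population_sequences(spec)
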