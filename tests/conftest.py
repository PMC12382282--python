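import pytest
from hypothesis import HealthCheck, settings

import umicall as uc

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def mixed_pipeline():
    """Small simulated run with medium/low/zero-VAF sites, fully analysed."""
    cfg = uc.SimConfig(n_targets=5, reference_length=12_000,
                       input_genome_equivalents=2_000, rng_seed=123,
                       variant_specs=((0, 0.05), (1, 0.01)))
    return uc.run_simulated_pipeline(uc.PipelineParams(sim=cfg))


@pytest.fixture(scope="session")
def wildtype_pipeline():
    """Small variant-free run (every monitored site truly wild-type)."""
    cfg = uc.SimConfig(n_targets=10, reference_length=15_000,
                       input_genome_equivalents=800, rng_seed=7)
    return uc.run_simulated_pipeline(uc.PipelineParams(sim=cfg))
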