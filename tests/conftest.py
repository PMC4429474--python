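import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from cytcensus import SyntheticSpec, generate_proteome, run_census


@pytest.fixture(scope="session")
def world():
    """The default synthetic census world (5 species, ~200 proteins, seed 1)."""
    spec = SyntheticSpec(rng_seed=1)
    ps, truth = generate_proteome(spec)
    return spec, ps, truth


@pytest.fixture(scope="session")
def census(world):
    """The census report over the default synthetic world (computed once)."""
    _, ps, _ = world
    return run_census(ps)
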