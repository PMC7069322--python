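import pytest
from hypothesis import settings

from depthratio import simulate as sim

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_params():
    """3 autosomes + 1 Z scaffold of 100 kb at ~30x with one planted
    comparison-side duplication (2 vs 4 copies)."""
    return sim.SimParams(
        n_autosomes=3,
        n_z_scaffolds=1,
        scaffold_length=100_000,
        cnv_segments=[sim.CNVSpec("autosome_1", 20_000, 40_000, 2, 4)],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return sim.make_truth(small_params)


@pytest.fixture(scope="session")
def small_tracks(small_params, small_truth):
    male = sim.simulate_coverage(small_params, small_truth, "male")
    female = sim.simulate_coverage(small_params, small_truth, "female")
    return male, female
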