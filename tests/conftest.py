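import numpy as np
import pytest

from cohesion.entropy import DensityVarianceParams


@pytest.fixture(scope="session")
def dv_params() -> DensityVarianceParams:
    """Default density-variance parameters, calibrated once per session."""
    return DensityVarianceParams().calibrated()


@pytest.fixture(scope="session")
def scaled_sweep():
    """The scaled-down Daisyworld luminosity sweep (0.45-1.45 step 0.05,
    10 replicates, 200 ticks, 29x29) at master seed 0, shared by every
    test that reads the tipping-point structure."""
    from cohesion.daisyworld import DaisyworldConfig, luminosity_sweep

    return luminosity_sweep(
        DaisyworldConfig(steps=200),
        l_min=0.45,
        l_max=1.45,
        l_step=0.05,
        replicates=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def two_scenario_samples():
    """Factory for five replicate samples falling into two well-separated
    unimodal scenarios: two from N(0,1), three from N(10,1)."""
    from cohesion.ensemble import Sample

    def make(seed: int, n_obs: int = 200):
        rng = np.random.default_rng(seed)
        samples = [
            Sample(id=f"s{i}", observations=tuple(rng.normal(0.0, 1.0, n_obs)))
            for i in range(2)
        ] + [
            Sample(id=f"s{i}", observations=tuple(rng.normal(10.0, 1.0, n_obs)))
            for i in range(2, 5)
        ]
        return tuple(samples)

    return make
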