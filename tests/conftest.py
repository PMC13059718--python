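import numpy as np
import pytest

from ferrodyn import (
    CANONICAL_PARAMS,
    ModelState,
    NoiseParams,
    Scenario,
    generate,
    generate_dataset,
)


@pytest.fixture(scope="session")
def canonical():
    return CANONICAL_PARAMS


@pytest.fixture(scope="session")
def rsl3_params(canonical):
    """GPX4 inhibition: death threshold lowered to 40% of control."""
    return canonical.with_(r0=canonical.r0 * 0.4)


@pytest.fixture(scope="session")
def md_scenario():
    """Medium-density control condition; informative for all four default free parameters."""
    return Scenario(name="MD", seeding="MD", initial_confluence=0.44, replicates=3, seed=0)


@pytest.fixture(scope="session")
def noiseless_md():
    sc = Scenario(
        name="MD", seeding="MD", initial_confluence=0.44,
        noise=NoiseParams.none(), replicates=1, seed=0,
    )
    return generate(sc)


@pytest.fixture(scope="session")
def noisy_md(md_scenario):
    return generate(md_scenario)


@pytest.fixture(scope="session")
def joint_control_rsl3():
    """Paired control / GPX4-inhibited datasets sharing every parameter but r0."""
    ctrl = Scenario(name="control", seeding="MD", initial_confluence=0.44, replicates=3, seed=11)
    rsl3 = Scenario(
        name="RSL3", seeding="MD", initial_confluence=0.44,
        r0_multiplier=0.4, replicates=3, seed=11,
    )
    return generate_dataset({"control": ctrl, "RSL3": rsl3})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def ld_state():
    return ModelState(n=0.20, r=0.0)
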