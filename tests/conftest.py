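import numpy as np
import pytest

import saoslo as s
from saoslo import presets


@pytest.fixture(scope="session")
def default_system():
    """The 128-px benchmark simulator with the fixed seeded sample."""
    return s.default_system()


@pytest.fixture(scope="session")
def default_basis(default_system):
    return default_system.make_basis(range(4, 29))


@pytest.fixture(scope="session")
def small_system():
    """64-px simulator used where full resolution is not the point."""
    return presets.scaled_down_system()


@pytest.fixture(scope="session")
def small_basis(small_system):
    return small_system.make_basis(range(4, 29))


@pytest.fixture(scope="session")
def trained_scaled_agent():
    """The desk-scale training run: N=3 modes, 64-px sample, 3,000 episodes,
    10 noise profiles per episode, fixed seed.  Shared across the tests that
    probe what training achieved (several minutes of CPU)."""
    system = presets.scaled_down_system()
    env = presets.scaled_down_env(system)
    schedule = presets.scaled_down_schedule()
    checkpoint, trace = s.train(env, schedule)
    return {"system": system, "env": env, "schedule": schedule,
            "checkpoint": checkpoint, "trace": trace}


@pytest.fixture(scope="session")
def transferred(trained_scaled_agent):
    """Fine-tune of the trained agent on a perturbed simulator (fiber 3->4
    Airy-disk diameters plus a fixed 0.03-um astigmatism offset): a
    surrogate for adapting simulation-trained weights to a real bench."""
    ckpt = trained_scaled_agent["checkpoint"]
    system_p = presets.scaled_down_system(fiber_diameter=4.0)
    env_p = presets.scaled_down_env(system_p, config="C",
                                    extra_aberration=np.array([0.0, 0.0, 0.03]))
    ckpt_t, trace = s.transfer_learn(ckpt, env_p, np.random.default_rng(42))
    return {"env_p": env_p, "before": ckpt, "after": ckpt_t, "trace": trace}
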