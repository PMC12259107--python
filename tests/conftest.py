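import numpy as np
import pytest

from lnpkmc import (Environment, Formulation, InitPopulationSpec,
                    InteractionParams)
from lnpkmc.initializer import build_initial_population, derive_system_volume


@pytest.fixture
def env():
    return Environment()


@pytest.fixture
def form():
    return Formulation()


@pytest.fixture
def ip():
    return InteractionParams()


@pytest.fixture
def small_population(form, env):
    """120-particle default-formulation population, fixed seed."""
    spec = InitPopulationSpec(n0=120, r0=9.0)
    pop = build_initial_population(spec, form, env, seed=7)
    return pop, spec


@pytest.fixture
def small_v_system(form):
    return derive_system_volume(InitPopulationSpec(n0=120, r0=9.0), form)


def run_default(n0, r0, seed, form=None, env=None, ip=None, schedule="dialysis",
                t_end=64800.0, **kwargs):
    """One full-protocol run (dialysis at 1 h, 18 h endpoint) at given size."""
    import lnpkmc as L

    form = form or Formulation()
    env = env or Environment()
    ip = ip or InteractionParams()
    if schedule == "dialysis":
        schedule = L.EnvironmentSchedule.dialysis()
    spec = InitPopulationSpec(n0=n0, r0=r0)
    rng = np.random.default_rng(seed)
    pop = build_initial_population(spec, form, env, rng)
    v_system = derive_system_volume(spec, form)
    return L.simulate(pop, form, env, ip, v_system, schedule=schedule,
                      t_end=t_end, seed=rng, **kwargs)
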