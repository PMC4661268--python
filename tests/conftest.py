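import numpy as np
import pytest

from porepmf.synthetic.surfaces import ModelSurfaceSpec
from porepmf.synthetic.sampler import SamplerConfig
from porepmf import umbrella, wham


@pytest.fixture(scope="session")
def diagonal_plan():
    return umbrella.plan_windows(mode="diagonal")


@pytest.fixture(scope="session")
def flat_surface():
    return ModelSurfaceSpec.flat()


@pytest.fixture(scope="session")
def opening_surface():
    """Plateau surface with constructed opening free energy 5.3 kcal/mol."""
    return ModelSurfaceSpec.opening_profile(5.3)


@pytest.fixture(scope="session")
def harmonic_well():
    return ModelSurfaceSpec("harmonic_well", {"k": 3.0, "center": (9.5, 9.5)})


def run_diagonal_wham(surface, n_steps, seed, proposal="walk", step_size=0.5):
    """Sample 12 diagonal windows on a surface and unbias them with WHAM."""
    plan = umbrella.plan_windows(mode="diagonal")
    cfg = SamplerConfig(
        n_steps=n_steps, seed=seed, proposal=proposal, step_size=step_size
    )
    windows = umbrella.run_umbrella_set(plan, surface, cfg)
    stripped = [umbrella.strip_burn_in(w) for w in windows]
    hists = wham.histogram_windows(stripped)
    return wham.wham_solve(hists, [w.bias for w in windows])
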