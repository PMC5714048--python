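import numpy as np
import pytest

import autoimrt as ai


@pytest.fixture(scope="session")
def hn_template():
    return ai.bundled_template("hn6")


@pytest.fixture(scope="session")
def small_grid():
    # coarse lattice keeps the unit suite fast; the acceptance suite runs
    # the default 2 mm grid
    return ai.Grid(shape=(64, 64, 48), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    return ai.make_hn_phantom(ai.PhantomSpec(grid=small_grid, seed=1))


@pytest.fixture(scope="session")
def small_derived(small_phantom, hn_template):
    return ai.derive_structures(small_phantom, hn_template.recipes)


@pytest.fixture(scope="session")
def small_beams(small_derived, hn_template):
    return ai.build_beams(hn_template.beams, small_derived["TPTV"])


@pytest.fixture(scope="session")
def small_influence(small_beams, small_derived, hn_template):
    return ai.compute_influence(
        small_beams, small_derived.grid, small_derived["external"],
        model=hn_template.dose_model,
    )


@pytest.fixture(scope="session")
def small_initial(small_influence, small_derived, hn_template):
    return ai.optimize_fluence(
        small_influence, small_derived, hn_template.initial_objectives,
        hn_template.initial_opt,
    )


def random_mask(grid, rng, name="m", density=0.3):
    return ai.Mask(name, grid, rng.random(grid.shape) < density)
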