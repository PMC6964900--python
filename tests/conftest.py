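import numpy as np
import pandas as pd
import pytest

from heatdown import GridSpec, SceneRecipe, UrbanCenter


@pytest.fixture
def fine_spec():
    # 36 x 36 fine grid, 12:1 nested in a 3 x 3 coarse grid
    return GridSpec(west=-91.0, north=39.0, dx=0.125 / 12, dy=0.125 / 12,
                    nrows=36, ncols=36)


@pytest.fixture
def coarse_spec():
    return GridSpec(west=-91.0, north=39.0, dx=0.125, dy=0.125,
                    nrows=3, ncols=3)


@pytest.fixture
def small_recipe(fine_spec, coarse_spec):
    """A fast synthetic world: tiny grids, one warm bump, a few June days."""
    return SceneRecipe(
        fine=fine_spec,
        coarse=coarse_spec,
        urban_centers=[UrbanCenter(10, 12, 3.0, 4.0)],
        dates=pd.date_range("2009-06-01", "2009-06-05", freq="D"),
        n_scenes=7,
        seed=11,
    )


@pytest.fixture
def clean_recipe(small_recipe):
    """The same world with no noise, no clouds, no contamination."""
    import dataclasses

    return dataclasses.replace(
        small_recipe,
        noise_sd_c=0.0,
        cloud_fraction=0.0,
        contam_fraction=0.0,
        obs_noise_sd_c=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20090712)
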