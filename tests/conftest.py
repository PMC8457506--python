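import numpy as np
import pytest

from squigglevote import simulate
from squigglevote.squiggle_io import Ensemble, GoldModel, Squiggle


@pytest.fixture(scope="session")
def small_gold() -> GoldModel:
    return simulate.simulate_gold(300, seed=7)


@pytest.fixture(scope="session")
def small_ensemble(small_gold) -> Ensemble:
    """32 distorted reads of a 300-event gold, no leaders or corrupt reads:
    the minimal setting for exercising averaging and voting."""
    recipe = simulate.EnsembleRecipe(
        n_reads=32,
        chimera_fraction=0.0,
        short_fraction=0.0,
        global_outlier_fraction=0.0,
        leader=simulate.LeaderParams(length_mean=1, length_sd=0.0),
        seed=7,
    )
    ens = simulate.make_ensemble(small_gold, recipe)
    # strip the 1-event stub leader so reads are pure distorted gold
    return Ensemble(
        [Squiggle(s.read_id, s.levels[1:], truth=s.truth) for s in ens],
        label=ens.label,
    )


def toy_ensemble(series: list[list[float]]) -> Ensemble:
    return Ensemble(
        [Squiggle(f"r{i}", np.array(s, dtype=float)) for i, s in enumerate(series)]
    )
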