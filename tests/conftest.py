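from __future__ import annotations

import numpy as np
import pytest

from ibpp import EvolutionConfig, TrainingSet, evolve
from ibpp.synthetic import SynthConfig, generate_dataset

#: the scaled-down study conditions used for end-to-end checks: 50+50
#: training windows with planted motifs, a 500-seed library replenished
#: in batches of 100 below 50 members, 30 generations.
SCALED_SYNTH = dict(n_promoters=50, n_nonpromoters=50, n_long=3)
SCALED_EVO = dict(
    initial_library_size=500,
    replenish_batch=100,
    replenish_threshold=50,
    generations=30,
)


def scaled_run(seed: int):
    """One scaled evolution run on planted-motif data (fresh data per seed)."""
    data = generate_dataset(SynthConfig(rng_seed=seed + 1000, **SCALED_SYNTH))
    train = TrainingSet(
        promoters=tuple(data.promoters), non_promoters=tuple(data.non_promoters)
    )
    config = EvolutionConfig(rng_seed=seed, **SCALED_EVO)
    best, history = evolve(train, config)
    return best, history, data


@pytest.fixture(scope="session")
def scaled_runs():
    """Five scaled runs (seeds 0..4), for trend checks averaged over seeds."""
    return [scaled_run(s) for s in range(5)]


@pytest.fixture(scope="session")
def scaled_evolution(scaled_runs):
    """The seed-0 scaled run, shared by several end-to-end tests."""
    return scaled_runs[0]


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(
        SynthConfig(n_promoters=40, n_nonpromoters=40, n_long=2, rng_seed=7)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
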