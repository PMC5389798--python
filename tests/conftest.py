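"""Shared fixtures.

The two expensive Hindmarsh-Rose computations (the full-budget
single-neuron Lyapunov run and the desk-scale extensivity experiment) are
session-scoped so every test interrogating them shares one computation.
"""

import numpy as np
import pytest

from hksnet import evolve, hrnet, netgen


@pytest.fixture(scope="session")
def c4():
    return netgen.circulant_layer(4, 2)


@pytest.fixture(scope="session")
def hr_params():
    return hrnet.HRParams()


@pytest.fixture(scope="session")
def single_neuron_layer():
    return netgen.LayerGraph.from_adjacency(np.zeros((1, 1), dtype=int), label="single-neuron")


@pytest.fixture(scope="session")
def single_neuron_full(single_neuron_layer, hr_params):
    """Full-budget Lyapunov spectrum of one isolated HR neuron."""
    cfg = hrnet.BenettinConfig(seed=2)
    return hrnet.benettin_spectrum(None, single_neuron_layer, hr_params, 0.0, 0.0, cfg)


def small_world_pair_factory(k: int = 2, p: float = 0.2):
    """Two same-size, differently wired small-world layers per call."""

    def factory(n1: int, seed: int):
        return (
            netgen.small_world_layer(n1, k, p, seed),
            netgen.small_world_layer(n1, k, p, seed + 1000),
        )

    return factory


@pytest.fixture(scope="session")
def hr_extensivity():
    """Desk-scale HR evolution experiment: sizes N in {8, 12, 16}, fixed
    near-optimal couplings eps=0.005 << gamma=0.1, reduced screening budget
    and a fuller final evaluation of each evolved network."""
    screen = hrnet.BenettinConfig(dt=0.02, t_transient=200.0, t_total=1500.0, seed=11)
    final = hrnet.BenettinConfig(dt=0.01, t_transient=500.0, t_total=5000.0, seed=11)
    estimator = evolve.make_hr_estimator(cfg=screen, n_exponents_fn=lambda n: n + 2)
    final_estimator = evolve.make_hr_estimator(cfg=final)
    return evolve.extensivity_experiment(
        sizes=[8, 12, 16],
        layer_factory=small_world_pair_factory(),
        epsilon=0.005,
        gamma=0.1,
        estimator=estimator,
        seed=5,
        final_estimator=final_estimator,
    )
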