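import numpy as np
import pytest

from tmca import synthetic_data as sd


@pytest.fixture(scope="session")
def oracle_system():
    """Small atomistic three-helix system (≤500 atoms) with planted
    interactions at intermediate occupancies and sizable jitter, so every
    classifier's decision flips between frames."""
    seq_a = "LKAFWELVYH"
    seq_b = "ADVLRYFEWK"
    spec = sd.SyntheticSpec(
        sequences=(seq_a, seq_b, seq_b),
        first_resids=(1, 1, 1),
        resolution="aa-lite",
        n_frames=100,
        jitter_sigma=0.7,
        states=[sd.StateSpec(xy_separation=9.0, tilt_deg=0.0)],
        interactions=[
            sd.PlantedInteraction("saltbridge", res_a=("A", 2), res_b=("B", 8),
                                  occupancy=0.5),
            sd.PlantedInteraction("hbond", res_a=("A", 2), res_b=("B", 2),
                                  occupancy=0.5),
            sd.PlantedInteraction("pipi", res_a=("A", 9), res_b=("B", 7),
                                  fractions=(0.4, 0.3, 0.3)),
            sd.PlantedInteraction("hydrophobic", res_a=("A", 1), res_b=("B", 4),
                                  occupancy=0.5),
        ],
        seed=101,
        box=(60.0, 60.0, 60.0),
    )
    top, traj, truth = sd.simulate(spec)
    assert top.n_atoms <= 500
    return top, traj, truth


@pytest.fixture(scope="session")
def showcase():
    """Canonical planted-interaction system, jitter-free: schedules are
    exact ground truth."""
    spec = sd.interaction_showcase(n_frames=200, seed=11, jitter_sigma=0.0)
    return sd.simulate(spec)


@pytest.fixture(scope="session")
def cg_two_state():
    """Coarse-grained two-state system for contact/geometry/feature tests."""
    spec = sd.clustering_scenario(k=2, n_frames=300, seed=5)
    return sd.simulate(spec)


@pytest.fixture(scope="session")
def static_system():
    """Single state, zero jitter: every frame identical."""
    spec = sd.SyntheticSpec(n_frames=10, jitter_sigma=0.0,
                            states=[sd.StateSpec()], seed=1)
    return sd.simulate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
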