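import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from socialspike.behavior import behavior_table
from socialspike.io import FOCAL_ID
from socialspike.social_states import StateConfig, count_within_contact
from socialspike.synthetic import SimConfig, simulate_colony


@pytest.fixture(scope="session")
def fidelity_sim():
    """Noise-free planted-episode colony: the focal bee moves only when
    scripted, so every detectable event is a planted one."""
    cfg = SimConfig(
        duration_s=400.0,
        seed=3,
        n_passive_events=4,
        n_active_events=4,
        n_onset_events=3,
        focal_free_locomotion=False,
    )
    tracks, truth = simulate_colony(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def main_sim():
    """Default-condition colony (free focal locomotion, planted contacts)."""
    cfg = SimConfig(duration_s=600.0, seed=5)
    tracks, truth = simulate_colony(cfg)
    return cfg, tracks, truth


@pytest.fixture(scope="session")
def main_behavior(main_sim):
    cfg, tracks, _ = main_sim
    behav = behavior_table(tracks)
    behav["n_within_contact"] = count_within_contact(tracks, FOCAL_ID, StateConfig())
    return behav


@pytest.fixture(scope="session")
def fidelity_behavior(fidelity_sim):
    cfg, tracks, _ = fidelity_sim
    behav = behavior_table(tracks)
    behav["n_within_contact"] = count_within_contact(tracks, FOCAL_ID, StateConfig())
    return behav


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
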