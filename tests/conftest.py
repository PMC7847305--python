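import numpy as np
import pytest

from kisspulse import SceneParams, simulate_exm_scene

# planting plan used throughout: margins of every planted gap/overlap are well
# clear of the 0.95/1.75 um synapse thresholds and the 1 um contact cut
MIXED_PLAN = [
    (-1.6, 0.30, "side", 2.0),
    (0.4, 0.20, "side", 2.0),
    (2.5, 0.15, "side", 2.0),
    (-3.2, 0.15, "face", 3.5),
    (0.4, 0.10, "face", 2.0),
    (2.5, 0.10, "face", 2.0),
]


def mixed_scene_params(seed: int = 42, n_dendrons: int = 3, n_boutons: int = 30) -> SceneParams:
    return SceneParams(
        n_dendrons=n_dendrons,
        dendron_length=72.0,
        n_boutons=n_boutons,
        gap_distribution=list(MIXED_PLAN),
        noise_snr=5.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mixed_scene():
    """One rendered scene with side/face synapses, close contacts and separates."""
    scene, gt = simulate_exm_scene(mixed_scene_params())
    return scene, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
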