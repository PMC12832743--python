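import numpy as np
import pytest

from sonopupil import PLRWaveform, SceneConfig, render_cine


@pytest.fixture(scope="session")
def std_waveform() -> PLRWaveform:
    """Reference reflex: 4.0 -> 3.0 mm, 0.3 s latency, 1 s constriction,
    half the amplitude regained over 1 s."""
    return PLRWaveform(
        baseline_diameter=4.0, min_diameter=3.0, latency=0.3,
        constriction_duration=1.0, recovery_fraction=0.5, recovery_duration=1.0,
    )


@pytest.fixture(scope="session")
def noise_free_scene() -> SceneConfig:
    return SceneConfig(stimulus_onset=0.5, speckle_shape=None, blur_sigma_px=0.0)


@pytest.fixture(scope="session")
def noise_free_loop(std_waveform, noise_free_scene):
    loop, gt = render_cine(std_waveform, noise_free_scene)
    return loop, gt


@pytest.fixture(scope="session")
def speckle_loop(std_waveform):
    scene = SceneConfig(stimulus_onset=1.0, rng_seed=11)
    loop, gt = render_cine(std_waveform, scene)
    return loop, gt


def exact_moment_sample(rng: np.random.Generator, n: int, mean: float, sd: float):
    """Random sample standardised to have exactly the requested mean and
    (n-1)-denominator SD."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
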