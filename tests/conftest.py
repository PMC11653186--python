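import numpy as np
import pytest

from evocnn import GAConfig, SynthSpec, generate, stratified_split


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """Tiny search space used by most GA mechanics tests."""
    return GAConfig(
        population_size=10,
        max_generations=20,
        max_layers=3,
        max_filters=16,
        max_filter_size=5,
        seed=0,
    )


@pytest.fixture(scope="session")
def easy_task():
    """Separable synthetic task: lift 0.5, 200/class, 32x32, split 70/15/15."""
    spec = SynthSpec(
        n_per_class=200, image_size=(32, 32), intensity_lift=0.5, noise_sd=0.05, seed=11
    )
    train, test, val = stratified_split(generate(spec), (0.7, 0.15, 0.15), seed=11)
    return {"train": train, "test": test, "val": val}


@pytest.fixture(scope="session")
def null_task():
    """Zero-lift control: the two classes are distributionally identical."""
    spec = SynthSpec(
        n_per_class=100, image_size=(16, 16), intensity_lift=0.0, noise_sd=0.05, seed=11
    )
    train, test, val = stratified_split(generate(spec), (0.7, 0.15, 0.15), seed=11)
    return {"train": train, "test": test, "val": val}
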