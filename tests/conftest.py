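import numpy as np
import pytest

import ftirq
from ftirq import DirichletConfig, NoiseConfig, SplitPlan, WavenumberAxis

# Canonical seeded study fixture: 8 concentration classes x 10 replicates of
# melamine-spiked matrix under the default noise model, Dirichlet-expanded to
# 8 x 169 = 1352 artificial samples.  Seeds are fixed so every test sees the
# same data.
STUDY_SEEDS = {"simulate": 11, "augment": 12, "split": 13, "cv": 14, "cnn": 15}


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis()


@pytest.fixture(scope="session")
def band_library():
    return ftirq.load_band_library()


@pytest.fixture(scope="session")
def replicate_set():
    """The raw replicate design: 80 noisy melamine spectra."""
    return ftirq.generate_dataset(
        "melamine", noise=NoiseConfig(seed=STUDY_SEEDS["simulate"])
    )


@pytest.fixture(scope="session")
def augmented_set(replicate_set):
    """The 1352-sample Dirichlet-augmented study set."""
    return ftirq.dirichlet_augment(
        replicate_set, DirichletConfig(seed=STUDY_SEEDS["augment"])
    )


@pytest.fixture(scope="session")
def chemometric_split(augmented_set):
    """800/552 calibration/validation split (100/69 per class)."""
    return ftirq.stratified_split(
        augmented_set, SplitPlan(scheme="chemometric_800_552", seed=STUDY_SEEDS["split"])
    )


@pytest.fixture(scope="session")
def cnn_split(augmented_set):
    """1148/204 calibration/prediction split for the network."""
    return ftirq.stratified_split(
        augmented_set, SplitPlan(scheme="cnn_1148_204", seed=STUDY_SEEDS["split"])
    )


def make_two_component_mixtures(n=24, p=60, seed=3, noise_sd=0.0):
    """Noiseless (or noisy) Beer-Lambert mixtures of two linearly
    independent pure spectra; returns (X, y, pure_analyte, pure_background).

    y is the analyte fraction in percent, spanning 0-4 like the study grid.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, p)
    analyte = np.exp(-0.5 * ((t - 0.3) / 0.05) ** 2) + 0.4 * np.exp(
        -0.5 * ((t - 0.8) / 0.03) ** 2
    )
    background = 0.8 * np.exp(-0.5 * ((t - 0.55) / 0.15) ** 2) + 0.2
    y = rng.uniform(0.0, 4.0, size=n)
    # background amplitude varies independently of the analyte level, so the
    # centered spectra have rank 2 and concentration is not a 1-factor fit
    b = rng.uniform(0.8, 1.2, size=n)
    X = b[:, None] * background + (y[:, None] / 100) * analyte
    if noise_sd > 0:
        X = X + rng.normal(0, noise_sd, size=X.shape)
    return X, y, analyte, background
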