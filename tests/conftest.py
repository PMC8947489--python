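"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import slideweak as sw


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """10-slide needle-biopsy-like cohort at 256 px (fast fixture).

    Splits (0.6, 0.2, 0.2) -> 6 train / 2 validation / 2 test slides,
    labels balanced per split.
    """
    out = tmp_path_factory.mktemp("small_cohort")
    params = sw.SynthParams(image_size=256, n_cores=3, lesion_fraction=0.3, seed=42)
    manifest = sw.generate_cohort(5, 5, params, out, split_fractions=(0.6, 0.2, 0.2))
    return manifest


@pytest.fixture(scope="session")
def positive_slide(tmp_path_factory):
    """One positive 512-px slide with its ground-truth masks."""
    out = tmp_path_factory.mktemp("one_slide")
    params = sw.SynthParams(image_size=512, lesion_fraction=0.3, seed=7)
    return sw.generate_slide(params, "adenocarcinoma", out, "pos000")


@pytest.fixture(scope="session")
def trained_pipeline(tmp_path_factory):
    """Full weakly-supervised run at study scale (shared across tests).

    70 slides (40 train / 10 validation / 20 test) of 1024 px with 30%
    lesion fraction, 128-px tiles, tiny CNN, random sampling -> hard mining
    -> early stopping.  Returns (manifest, fitted results).
    """
    from slideweak.model import WeakSlideClassifier

    out = tmp_path_factory.mktemp("e2e_cohort")
    params = sw.SynthParams(image_size=1024, lesion_fraction=0.3, seed=1)
    manifest = sw.generate_cohort(35, 35, params, out, split_fractions=(4 / 7, 1 / 7, 2 / 7))
    model = WeakSlideClassifier(
        manifest,
        tile_size=128,
        train_config=sw.TrainConfig(seed=1),
        mining_config=sw.MiningConfig(),
    )
    return manifest, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class ConstantModel:
    """Stub backbone emitting a fixed positive-class probability."""

    def __init__(self, p=0.5):
        self.p = p

    def predict_proba(self, x):
        return np.full(len(x), self.p)


@pytest.fixture()
def constant_model():
    return ConstantModel
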