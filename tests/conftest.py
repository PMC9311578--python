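"""Shared fixtures: small simulated cohorts and a quickly trained model."""

import numpy as np
import pytest

import rollgait as rg


@pytest.fixture(scope="session")
def study_cohort():
    """12 dogs (7 sound, 5 lame), 3 trials each — the study's training shape."""
    return rg.simulate_cohort(7, 5, 3, rg.GaitSimParams(seed=42))


@pytest.fixture(scope="session")
def study_dataset(study_cohort):
    return rg.build_dataset(study_cohort)


@pytest.fixture(scope="session")
def tiny_trained(tmp_path_factory):
    """A small model trained on a strongly separable cohort + its checkpoint.

    Used by prediction tests; deliberately easy (deep asymmetry, little
    noise) so a 16-unit single-layer model converges in seconds.
    """
    params = rg.GaitSimParams(
        asymmetry_ratio=0.3, noise_sd=0.3, artifact_rate=0.0, n_samples=300, seed=7
    )
    cohort = rg.simulate_cohort(4, 4, 2, params)
    dataset = rg.build_dataset(cohort)
    train_set, val_set = rg.split_by_dog(dataset, 0.25, seed=0)
    model = rg.init_model(
        rg.ModelConfig(
            num_recurrent_layers=1, hidden_units=16, dropout_fraction=0.2, seed=3
        )
    )
    config = rg.TrainConfig(
        learning_rate=0.02,
        epochs=60,
        batch_size=3,
        early_stopping_patience=10,
        seed=11,
    )
    model, history = rg.train(model, train_set, val_set, config)
    path = tmp_path_factory.mktemp("ckpt") / "tiny.ckpt"
    rg.save_model(model, path, preprocess=rg.PreprocessConfig())
    return {"model": model, "path": path, "sim_params": params, "history": history}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
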