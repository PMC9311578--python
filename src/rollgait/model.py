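"""The lameness classifier: a stacked LSTM with a sigmoid head.

Architecture (study configuration): one scalar input per time step — the
roll angle in degrees — fed through 2 LSTM layers of 256 units; the final
hidden state of the top layer passes through a single fully connected unit
and a sigmoid, yielding the probability that the dog is lame. Dropout (50%
in the initial configuration, 60% in the improved one) is active only during
training, on the sequence passed between the recurrent layers.

Checkpoints are single ``.npz`` files holding the configuration (as JSON)
together with every weight array, so a load reproduces predictions
bit-identically.
"""

from __future__ import annotations

import json
import os
import zipfile
from dataclasses import asdict, dataclass

import numpy as np

from . import _lstm
from .errors import FormatError, ParameterError, ShapeError

__all__ = [
    "ModelConfig",
    "ClassifierModel",
    "init_model",
    "classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults = the study configuration)."""

    input_size: int = 1
    num_recurrent_layers: int = 2
    hidden_units: int = 256
    dropout_fraction: float = 0.5
    sequence_length: int = 250
    classification_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.input_size != 1:
            raise ParameterError("input_size: fixed at 1 (one roll value per step)")
        if int(self.num_recurrent_layers) < 1:
            raise ParameterError("num_recurrent_layers: must be >= 1")
        if int(self.hidden_units) < 1:
            raise ParameterError("hidden_units: must be >= 1")
        if not (0 <= self.dropout_fraction < 1):
            raise ParameterError("dropout_fraction: must lie in [0, 1)")
        if int(self.sequence_length) < 1:
            raise ParameterError("sequence_length: must be >= 1")
        if not (0 <= self.classification_threshold <= 1):
            raise ParameterError("classification_threshold: must lie in [0, 1]")


class ClassifierModel:
    """A parameterized classifier instance.

    ``training_mode`` controls dropout: inference (the default) is fully
    deterministic; the trainer flips it on and supplies the dropout RNG.
    """

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.training_mode = False
        self.preprocess_config = None  # optionally attached by load_model

    def predict_proba(self, window) -> float:
        """Probability of lameness for one fixed-length window."""
        return float(self.predict_proba_batch(np.asarray(window, dtype=float)[None, :])[0])

    def predict_proba_batch(
        self,
        windows: np.ndarray,
        *,
        rng: np.random.Generator | None = None,
        want_cache: bool = False,
    ):
        """Vectorized inference over ``(n, sequence_length)`` windows.

        Dropout is applied only when ``training_mode`` is set and an RNG is
        supplied (the trainer's path); plain calls are deterministic.
        """
        windows = np.asarray(windows, dtype=float)
        if windows.ndim != 2 or windows.shape[1] != self.config.sequence_length:
            raise ShapeError(
                f"windows must have shape (n, {self.config.sequence_length}); "
                f"got {windows.shape}"
            )
        dropout = self.config.dropout_fraction if (self.training_mode and rng is not None) else 0.0
        probs, cache = _lstm.forward(
            self.params,
            windows,
            self.config.num_recurrent_layers,
            self.config.hidden_units,
            dropout=dropout,
            rng=rng,
            want_cache=want_cache,
        )
        return (probs, cache) if want_cache else probs

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def init_model(config: ModelConfig | None = None) -> ClassifierModel:
    """Build a model with deterministic initialization under ``config.seed``."""
    if config is None:
        config = ModelConfig()
    config.validate()
    params = _lstm.init_params(
        config.input_size, config.hidden_units, config.num_recurrent_layers, config.seed
    )
    return ClassifierModel(config, params)


def classify(p: float, threshold: float = 0.5) -> int:
    """Threshold a probability into a label; ties go to lame (screening bias)."""
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p: probability {p} outside [0, 1]")
    return 1 if p >= threshold else 0


def save_model(
    model: ClassifierModel, path: str | os.PathLike, *, preprocess=None
) -> None:
    """Serialize config + weights to a single self-describing ``.npz`` file.

    ``preprocess`` may carry the PreprocessConfig the model was trained
    with, so downstream prediction can clean raw traces the same way.
    """
    payload = dict(model.params)
    payload["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config), sort_keys=True).encode(), dtype=np.uint8
    )
    if preprocess is not None:
        payload["__preprocess__"] = np.frombuffer(
            json.dumps(asdict(preprocess), sort_keys=True).encode(), dtype=np.uint8
        )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path: str | os.PathLike) -> ClassifierModel:
    """Load a checkpoint written by :func:`save_model`."""
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (OSError, ValueError, zipfile.BadZipFile, EOFError) as exc:
        raise FormatError(f"{path}: not a readable model checkpoint ({exc})") from exc
    if "__config__" not in arrays:
        raise FormatError(f"{path}: checkpoint lacks embedded config")
    preprocess_config = None
    try:
        config = ModelConfig(**json.loads(bytes(arrays.pop("__config__")).decode()))
        config.validate()
        if "__preprocess__" in arrays:
            from .preprocess import PreprocessConfig

            preprocess_config = PreprocessConfig(
                **json.loads(bytes(arrays.pop("__preprocess__")).decode())
            )
    except (json.JSONDecodeError, TypeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: corrupt embedded config ({exc})") from exc
    expected = _lstm.init_params(
        config.input_size, config.hidden_units, config.num_recurrent_layers, config.seed
    )
    if set(arrays) != set(expected) or any(
        arrays[k].shape != expected[k].shape for k in expected
    ):
        raise FormatError(f"{path}: checkpoint weights do not match its config")
    params = {k: np.ascontiguousarray(v, dtype=_lstm.DTYPE) for k, v in arrays.items()}
    model = ClassifierModel(config, params)
    model.preprocess_config = preprocess_config
    return model
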