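"""Core data containers: single-trial roll traces and per-dog records.

A *roll trace* is the time series of lateral pelvic inclination (the IMU
gyroscope's roll channel, in degrees) recorded during one walking trial.
A *dog record* groups the trials of one subject together with its diagnosis
label: 0 = sound, 1 = unilateral hindlimb lameness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataIntegrityError, ParameterError

__all__ = ["RollTrace", "DogRecord"]


@dataclass
class RollTrace:
    """One trial's ordered roll-angle samples.

    Parameters
    ----------
    values
        Roll angles in degrees, one per sample, in recording order. Must be
        finite and within [-180, 180].
    sampling_rate
        Sampling frequency in Hz (the study sensor records at 100 Hz).
    dog_id, trial_id
        Identity of the subject and the walking pass.
    """

    values: np.ndarray
    sampling_rate: float = 100.0
    dog_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ParameterError("values: a trace needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("values: all samples must be finite")
        if np.any(np.abs(self.values) > 180.0):
            raise ParameterError("values: roll angles must lie in [-180, 180] degrees")
        if not (self.sampling_rate > 0):
            raise ParameterError("sampling_rate: must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    def replace_values(self, values: np.ndarray) -> "RollTrace":
        """A copy of this trace with new samples but the same identity."""
        return RollTrace(
            values=np.asarray(values, dtype=np.float64),
            sampling_rate=self.sampling_rate,
            dog_id=self.dog_id,
            trial_id=self.trial_id,
        )


@dataclass
class DogRecord:
    """A subject with its diagnosis label and one or more trial traces."""

    dog_id: str
    label: int
    traces: list[RollTrace] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ParameterError("label: must be 0 (sound) or 1 (lame)")
        for t in self.traces:
            if t.dog_id != self.dog_id:
                raise DataIntegrityError(
                    f"trace {t.trial_id!r} belongs to dog {t.dog_id!r}, "
                    f"not {self.dog_id!r}"
                )
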