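"""Parametric synthetic gait simulator.

At walk, the alternating hindlimb support phases rock the pelvis from side to
side, so the sacral roll angle oscillates quasi-periodically with a
peak-to-peak range of roughly 20 degrees in medium/large dogs. A unilateral
supporting-limb lameness unloads the painful limb, damping the lean toward
that side; the simulator models this as an amplitude scaling of one half-cycle
of the oscillation. Real recordings additionally contain sensor noise and
sparse large-magnitude artifacts from head shakes and distractions.

Model for one trial::

    base(t)  = A * sin(2*pi*f*t + phase)
    lame     : base(t) < 0 half-cycles scaled by asymmetry_ratio
    trace(t) = base(t) + N(0, noise_sd^2) + artifact(t)

where artifact(t) is, independently per sample with probability
``artifact_rate``, a draw from Uniform(-artifact_magnitude,
+artifact_magnitude), else 0.

Sign convention: positive roll = lean toward the right hindlimb; the lame side
is always the negative half-cycle. The classifier's labels are side-agnostic,
so this loses no generality.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .traces import DogRecord, RollTrace

__all__ = ["GaitSimParams", "simulate_trace", "simulate_cohort"]

#: Relative jitter applied per dog to stride frequency and amplitude so that
#: subjects are mutually distinguishable (splitting code cannot ignore dog
#: identity).
DOG_JITTER = 0.10


@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of the synthetic pelvic-roll generator.

    Defaults describe a medium-sized dog at walk: 1.5 Hz stride rate and a
    10-degree roll amplitude (about 20 degrees peak to peak), sampled at
    100 Hz for 4 s, with 1 degree of sensor noise and a 1% per-sample chance
    of an artifact of up to +/-15 degrees.
    """

    stride_frequency: float = 1.5
    base_amplitude: float = 10.0
    asymmetry_ratio: float = 0.6
    noise_sd: float = 1.0
    artifact_rate: float = 0.01
    artifact_magnitude: float = 15.0
    n_samples: int = 400
    sampling_rate: float = 100.0
    phase: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.stride_frequency > 0):
            raise ParameterError("stride_frequency: must be > 0 Hz")
        if self.base_amplitude < 0:
            raise ParameterError("base_amplitude: must be >= 0 degrees")
        if not (0 < self.asymmetry_ratio <= 1):
            raise ParameterError("asymmetry_ratio: must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd: must be >= 0 degrees")
        if not (0 <= self.artifact_rate <= 1):
            raise ParameterError("artifact_rate: must lie in [0, 1]")
        if self.artifact_magnitude < 0:
            raise ParameterError("artifact_magnitude: must be >= 0 degrees")
        if int(self.n_samples) < 1:
            raise ParameterError("n_samples: must be >= 1")
        if not (self.sampling_rate > 0):
            raise ParameterError("sampling_rate: must be > 0 Hz")


def simulate_trace(
    params: GaitSimParams,
    lame: bool,
    *,
    dog_id: str = "sim",
    trial_id: str = "t0",
    rng: np.random.Generator | None = None,
) -> RollTrace:
    """Simulate one walking trial.

    When ``lame`` is true, every negative half-cycle of the underlying
    sinusoid (the lean toward the lame side) is scaled by
    ``params.asymmetry_ratio``. The same seed always yields the identical
    trace.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = int(params.n_samples)
    t = np.arange(n) / params.sampling_rate
    base = params.base_amplitude * np.sin(
        2.0 * np.pi * params.stride_frequency * t + params.phase
    )
    if lame:
        base = np.where(base < 0, base * params.asymmetry_ratio, base)

    # Draw order is fixed (noise, artifact mask, artifact magnitudes) so a
    # given seed yields the same underlying stream regardless of which terms
    # are zeroed out.
    noise = rng.normal(0.0, params.noise_sd, n)
    mask = rng.random(n) < params.artifact_rate
    bursts = rng.uniform(-params.artifact_magnitude, params.artifact_magnitude, n)
    values = base + noise + np.where(mask, bursts, 0.0)
    np.clip(values, -180.0, 180.0, out=values)
    return RollTrace(values, params.sampling_rate, dog_id=dog_id, trial_id=trial_id)


def simulate_cohort(
    n_sound: int,
    n_lame: int,
    trials_per_dog: int,
    params: GaitSimParams | None = None,
) -> list[DogRecord]:
    """Simulate a labeled cohort: sound dogs first, then lame dogs.

    Each dog receives its own stride frequency and amplitude (uniform
    +/-10% jitter around the cohort parameters) so that trials of one dog
    resemble each other more than trials of different dogs. Randomness is
    hierarchical — cohort seed -> per-dog stream -> per-trial stream — so
    appending dogs to the cohort does not perturb earlier dogs.
    """
    if params is None:
        params = GaitSimParams()
    params.validate()
    if n_sound < 0 or n_lame < 0 or n_sound + n_lame < 1:
        raise ParameterError("n_sound/n_lame: need at least one dog, none negative")
    if trials_per_dog < 1:
        raise ParameterError("trials_per_dog: must be >= 1")

    labels = [0] * n_sound + [1] * n_lame
    dog_streams = np.random.SeedSequence(params.seed).spawn(len(labels))
    cohort: list[DogRecord] = []
    for idx, (label, stream) in enumerate(zip(labels, dog_streams)):
        dog_id = f"dog{idx:03d}"
        dog_rng = np.random.default_rng(stream)
        freq = params.stride_frequency * (1 + dog_rng.uniform(-DOG_JITTER, DOG_JITTER))
        amp = params.base_amplitude * (1 + dog_rng.uniform(-DOG_JITTER, DOG_JITTER))
        dog_params = replace(params, stride_frequency=freq, base_amplitude=amp)
        trial_streams = stream.spawn(trials_per_dog)
        traces = [
            simulate_trace(
                dog_params,
                lame=bool(label),
                dog_id=dog_id,
                trial_id=f"t{k}",
                rng=np.random.default_rng(trial_streams[k]),
            )
            for k in range(trials_per_dog)
        ]
        cohort.append(DogRecord(dog_id=dog_id, label=label, traces=traces))
    return cohort
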