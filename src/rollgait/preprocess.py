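"""Trace cleaning and fixed-length windowing.

Raw roll traces contain sparse large-magnitude outliers (head shakes,
distractions) that would bias training. Cleaning keeps only the samples whose
value lies inside the central percentile band of that trial (10th-90th by
default, i.e. the inner ~80% of the empirical distribution), preserving
sample order. Cleaned traces are then cut into fixed-length windows of 250
samples (2.5 s at 100 Hz): long traces yield one window per stride offset,
short traces are padded with leading zeros — as if the dog stood still before
the recording — so every window has exactly the model's sequence length.

Percentile convention: the nearest-rank order statistic. ``percentile(v, q)``
is the ceil(q/100 * n)-th smallest value. For the outlier cut the *lower*
bound mirrors the upper one (counted from the top), which lands on the
floor(low/100 * n) + 1-th smallest value; this trims the two tails
symmetrically and keeps exactly ~(high - low)% of tie-free data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ProcessingError
from .traces import DogRecord, RollTrace

__all__ = [
    "PreprocessConfig",
    "WindowedDataset",
    "percentile",
    "remove_outliers",
    "window_and_pad",
    "build_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning and windowing parameters.

    Defaults follow the study protocol: keep values between the 10th and
    90th percentile of each trial, window length 250 samples, non-overlapping
    windows, zero padding.
    """

    low_percentile: float = 10.0
    high_percentile: float = 90.0
    window_length: int = 250
    stride: int = 250
    pad_value: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.low_percentile < 100):
            raise ParameterError("low_percentile: must lie in [0, 100)")
        if not (0 < self.high_percentile <= 100):
            raise ParameterError("high_percentile: must lie in (0, 100]")
        if not (self.low_percentile < self.high_percentile):
            raise ParameterError("low_percentile must be < high_percentile")
        if int(self.window_length) < 1:
            raise ParameterError("window_length: must be >= 1")
        if int(self.stride) < 1:
            raise ParameterError("stride: must be >= 1")


@dataclass
class WindowedDataset:
    """Fixed-length windows with labels and subject identity.

    ``group_ids`` carries each window's dog so splits can be made at the
    subject level (no dog contributes windows to both partitions).
    """

    windows: np.ndarray          # (n_windows, window_length) float64
    labels: np.ndarray           # (n_windows,) int, 0 sound / 1 lame
    group_ids: np.ndarray        # (n_windows,) str dog ids
    trial_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    offsets: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.group_ids = np.asarray(self.group_ids)
        n = len(self.windows)
        if self.trial_ids is None:
            self.trial_ids = np.asarray([""] * n)
        if self.offsets is None:
            self.offsets = np.zeros(n, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if not (len(self.labels) == len(self.group_ids) == n == len(self.trial_ids) == len(self.offsets)):
            raise ParameterError("windows, labels, group_ids must have equal counts")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ParameterError("labels: every label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, index: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.windows[index],
            self.labels[index],
            self.group_ids[index],
            self.trial_ids[index],
            self.offsets[index],
        )

    @property
    def dog_ids(self) -> list[str]:
        """Unique dogs in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.group_ids:
            seen.setdefault(str(g), None)
        return list(seen)


def percentile(values, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value.

    ``q = 0`` returns the minimum; no interpolation is performed, so the
    result is always an element of ``values``.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ParameterError("values: percentile of an empty sequence")
    if not (0 <= q <= 100):
        raise ParameterError("q: percentile rank must lie in [0, 100]")
    rank = max(1, math.ceil(q / 100.0 * v.size))  # 1-based
    return float(np.partition(v, rank - 1)[rank - 1])


def _cutoffs(values: np.ndarray, low: float, high: float) -> tuple[float, float]:
    """Lower/upper retention bounds for the percentile cut.

    Upper bound: nearest-rank ``high`` percentile. Lower bound: its mirror
    image counted from the maximum, equal to the floor(low/100 * n) + 1-th
    smallest value.
    """
    n = values.size
    lo_rank = math.floor(low / 100.0 * n) + 1  # 1-based
    srt = np.sort(values)
    return float(srt[lo_rank - 1]), percentile(values, high)


def remove_outliers(trace: RollTrace, config: PreprocessConfig | None = None) -> RollTrace:
    """Drop samples outside the trial's central percentile band.

    Retains, in original order, exactly the samples with
    ``P_low <= v <= P_high`` (bounds inclusive, so constant traces pass
    through unchanged). Percentiles are computed per trace.
    """
    if config is None:
        config = PreprocessConfig()
    config.validate()
    lo, hi = _cutoffs(trace.values, config.low_percentile, config.high_percentile)
    keep = (trace.values >= lo) & (trace.values <= hi)
    if not keep.any():
        raise ProcessingError(
            f"trace {trace.dog_id}/{trace.trial_id}: outlier filter removed every sample"
        )
    return trace.replace_values(trace.values[keep])


def window_and_pad(values, config: PreprocessConfig | None = None) -> np.ndarray:
    """Cut a sequence into fixed-length windows, zero-padding short inputs.

    Returns an array of shape ``(n_windows, window_length)``. A sequence
    shorter than the window is left-padded with ``pad_value`` into a single
    window; a longer one yields ``floor((L - W) / stride) + 1`` windows at
    offsets 0, stride, 2*stride, ...
    """
    if config is None:
        config = PreprocessConfig()
    config.validate()
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size == 0:
        raise ParameterError("values: need a non-empty 1-D sequence")
    w, s = int(config.window_length), int(config.stride)
    if v.size < w:
        out = np.full((1, w), float(config.pad_value))
        out[0, w - v.size:] = v
        return out
    n_win = (v.size - w) // s + 1
    out = np.empty((n_win, w))
    for k in range(n_win):
        out[k] = v[k * s : k * s + w]
    return out


def build_dataset(
    cohort: list[DogRecord], config: PreprocessConfig | None = None
) -> WindowedDataset:
    """Clean and window every trial of a cohort into one dataset.

    Window order is deterministic: dogs in cohort order, trials in record
    order, offsets ascending. Each window carries its dog's label and id.
    """
    if config is None:
        config = PreprocessConfig()
    config.validate()
    blocks, labels, groups, trials, offsets = [], [], [], [], []
    for rec in cohort:
        for trace in rec.traces:
            try:
                cleaned = remove_outliers(trace, config)
            except ProcessingError as exc:
                raise ProcessingError(
                    f"dog {rec.dog_id}, trial {trace.trial_id}: {exc}"
                ) from exc
            wins = window_and_pad(cleaned.values, config)
            blocks.append(wins)
            labels.extend([rec.label] * len(wins))
            groups.extend([rec.dog_id] * len(wins))
            trials.extend([trace.trial_id] * len(wins))
            offsets.extend(int(config.stride) * k for k in range(len(wins)))
    if not blocks:
        raise ProcessingError("empty cohort: no windows produced")
    return WindowedDataset(
        np.concatenate(blocks, axis=0),
        np.asarray(labels, dtype=int),
        np.asarray(groups),
        np.asarray(trials),
        np.asarray(offsets, dtype=int),
    )
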