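"""Shared data containers: continuous recordings and segmented epochs."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import SensorArray


class DataFormatError(ValueError):
    """Inconsistent recording/epoch structure."""


@dataclass
class Recording:
    """Continuous multichannel magnetometer record.

    data is channel-major (n_channels, n_samples) in tesla.  ``triggers``
    maps an integer trigger code to the sample indices of event onsets.
    ``flags`` marks samples where a channel railed (open loop beyond the
    dynamic range) or exceeded the closed-loop coil range; flagged samples
    hold clamped values rather than NaN so segment counting still works.
    ``aux`` carries non-magnetometer traces (e.g. the commanded background
    field in nT during a sweep).  ``ground_truth`` is only populated by the
    simulator and gives downstream stages an oracle.
    """

    data: np.ndarray
    sample_rate: float
    array: SensorArray | None = None
    triggers: dict[int, np.ndarray] = field(default_factory=dict)
    flags: np.ndarray | None = None
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise DataFormatError("data must be (n_channels, n_samples)")
        if self.array is not None and self.array.n_channels != self.n_channels:
            raise DataFormatError(
                f"channel table has {self.array.n_channels} rows for "
                f"{self.n_channels}-channel data"
            )
        for code, idx in self.triggers.items():
            idx = np.asarray(idx, int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
                raise DataFormatError(f"trigger {code} index out of bounds")
            self.triggers[code] = idx

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, data: np.ndarray, note: str | None = None) -> "Recording":
        """New Recording sharing metadata, with replacement data and a
        provenance note appended."""
        meta = dict(self.metadata)
        if note:
            meta.setdefault("provenance", [])
            meta["provenance"] = list(meta["provenance"]) + [note]
        return Recording(
            data=data,
            sample_rate=self.sample_rate,
            array=self.array,
            triggers={c: v.copy() for c, v in self.triggers.items()},
            flags=None if self.flags is None else self.flags.copy(),
            aux={k: v.copy() for k, v in self.aux.items()},
            metadata=meta,
            ground_truth=self.ground_truth,
        )


@dataclass
class Epochs:
    """Trials segmented around a trigger: (n_trials, n_channels, n_samples).

    ``window`` is the half-open interval [t0, t1) in seconds relative to the
    trigger, converted to samples with floor rounding.
    """

    data: np.ndarray
    sample_rate: float
    window: tuple[float, float]
    trigger_code: int | None = None
    retained_trial_ids: np.ndarray | None = None
    retained_channel_ids: np.ndarray | None = None
    array: SensorArray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise DataFormatError("epochs must be (n_trials, n_channels, n_samples)")
        if self.retained_trial_ids is None:
            self.retained_trial_ids = np.arange(self.data.shape[0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.sample_rate

    def sample_slice(self, interval: tuple[float, float]) -> slice:
        """Samples covering [a, b) in epoch-relative seconds (floor rounding)."""
        a, b = interval
        t0 = self.window[0]
        i0 = int(np.floor((a - t0) * self.sample_rate))
        i1 = int(np.floor((b - t0) * self.sample_rate))
        if i0 < 0 or i1 > self.n_samples:
            raise DataFormatError(f"interval {interval} outside epoch window {self.window}")
        return slice(i0, i1)
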