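"""Core domain types: signal segments and supervised shock records.

A :class:`SignalSegment` is a uniformly sampled slice of one physiologic
channel (ECG in mV, PetCO2 in mmHg) carrying its own sampling rate — the rate
is data, never assumed downstream.  A :class:`ShockRecord` bundles the
pre-countershock ECG (and optional PetCO2) with the binary defibrillation
outcome used as the supervised label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import DataError


class Channel(str, enum.Enum):
    ECG = "ECG"
    PETCO2 = "PETCO2"


class Outcome(enum.IntEnum):
    """Defibrillation outcome: ROSC-style success (1) vs failure (0)."""

    UNSUCCESSFUL = 0
    SUCCESSFUL = 1


#: physical units per channel
CHANNEL_UNITS = {Channel.ECG: "mV", Channel.PETCO2: "mmHg"}


@dataclass(frozen=True)
class SignalSegment:
    """Uniformly sampled single-channel signal slice.

    Parameters
    ----------
    samples :
        1-D float array; mV for ECG, mmHg for PetCO2. Must be finite.
    sampling_rate :
        Sampling rate in Hz, strictly positive.
    channel :
        Channel identity (ECG or PETCO2).
    start_time :
        Recording-clock time of the first sample, seconds.
    segment_id :
        Opaque identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: Channel = Channel.ECG
    start_time: float = 0.0
    segment_id: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size < 2:
            raise DataError("segment needs a 1-D array of length >= 2")
        if not np.all(np.isfinite(arr)):
            idx = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise DataError(f"non-finite sample at index {idx}")
        if not self.sampling_rate > 0:
            raise DataError("sampling_rate must be > 0")
        if not isinstance(self.channel, Channel):
            object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Window duration in seconds (n / rate)."""
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.sampling_rate

    @property
    def units(self) -> str:
        return CHANNEL_UNITS[self.channel]

    def with_samples(self, samples: np.ndarray, **meta) -> "SignalSegment":
        """Copy of this segment with new samples (same rate/identity)."""
        new = replace(self, samples=np.asarray(samples, dtype=float))
        if meta:
            merged = dict(self.meta)
            merged.update(meta)
            object.__setattr__(new, "meta", merged)
        return new


@dataclass
class ShockRecord:
    """One countershock instance: pre-shock signals plus outcome."""

    ecg: SignalSegment
    outcome: Outcome
    patient_id: str
    shock_id: str
    shock_time: float
    petco2: Optional[SignalSegment] = None

    def __post_init__(self) -> None:
        self.outcome = Outcome(self.outcome)
        end = self.ecg.start_time + self.ecg.n / self.ecg.sampling_rate
        if end > self.shock_time + 0.5 / self.ecg.sampling_rate:
            raise DataError(
                f"ECG segment of shock {self.shock_id!r} extends past the shock "
                f"time ({end:.4f} s > {self.shock_time:.4f} s)"
            )
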