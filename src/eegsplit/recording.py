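"""The in-memory recording container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .montage import ChannelMontage


@dataclass
class EEGRecording:
    """A multichannel EEG recording with its diagnosis label.

    Attributes
    ----------
    samples
        Array of shape ``(channels, timepoints)`` in microvolts, channel
        order matching ``montage``.
    fs
        Sampling rate in Hz.
    montage
        Channel montage; ``montage.size`` must equal ``samples.shape[0]``.
    subject_id
        Stable subject identifier.
    label
        Diagnosis: 0 = healthy control, 1 = MDD.
    """

    samples: np.ndarray
    fs: float
    montage: ChannelMontage
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise InputError("samples must be a 2-D (channels x timepoints) array")
        if self.samples.shape[0] != self.montage.size:
            raise InputError(
                f"channel count {self.samples.shape[0]} does not match "
                f"montage size {self.montage.size}"
            )
        if self.label not in (0, 1):
            raise InputError(f"label must be 0 (healthy) or 1 (MDD), got {self.label!r}")
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs
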