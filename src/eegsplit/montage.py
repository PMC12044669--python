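"""Channel montages and canonical EEG frequency bands."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: The 19 electrodes of the international 10-20 system, in the fixed order
#: used throughout the package. This ordering is preserved by every
#: downstream stage (filtering, epoching, feature layout).
STANDARD_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Frontal channels that carry ocular (blink) artifacts.
FRONTAL_CHANNELS = ("Fp1", "Fp2", "F7", "F8")

#: Canonical band edges in Hz. Gamma's upper edge is resolved to the Nyquist
#: frequency of the recording at use time.
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, None),
}

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered set of channel labels.

    Parameters
    ----------
    names
        Channel labels in acquisition order. Must be unique.
    """

    names: tuple[str, ...] = field(default=STANDARD_1020_19)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ConfigError("montage channel labels must be unique")
        if len(names) == 0:
            raise ConfigError("montage must contain at least one channel")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)


def default_montage() -> ChannelMontage:
    """The standard 19-channel 10-20 montage."""
    return ChannelMontage(STANDARD_1020_19)


def band_limits(band: str, fs: float) -> tuple[float, float]:
    """Resolve a named band to numeric (low, high) Hz edges for a given fs."""
    if band not in BAND_EDGES:
        raise ConfigError(f"unknown band {band!r}; expected one of {BAND_ORDER}")
    low, high = BAND_EDGES[band]
    if high is None:
        high = fs / 2.0
    return float(low), float(high)
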