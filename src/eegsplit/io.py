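"""EDF (European Data Format) interchange and cohort manifests.

Reading goes through MNE's EDF reader. Writing uses a minimal EDF writer
implemented here: plain 16-bit EDF with one data record per second, one
signal per channel, physical units in microvolts. Amplitudes outside the
declared physical range are clipped with a warning; the quantization step
is ``(phys_max - phys_min) / 65535`` (~0.015 µV at the ±500 µV default).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .errors import FileIOError, FormatError, InputError
from .montage import ChannelMontage
from .recording import EEGRecording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_recording(
    rec: EEGRecording,
    path: str | Path,
    phys_range: tuple[float, float] = (-500.0, 500.0),
) -> Path:
    """Write a recording as a 16-bit EDF file.

    The record duration is 1 s, so ``fs`` must be a positive integer and
    the recording is truncated to a whole number of seconds (our generator
    always produces whole seconds). Samples outside ``phys_range`` are
    clipped and a warning is logged.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise InputError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    phys_min, phys_max = phys_range
    if not phys_min < phys_max:
        raise InputError("phys_range must satisfy min < max")

    n_records = rec.n_times // fs
    if n_records == 0:
        raise InputError("recording shorter than one EDF record (1 s)")
    data = rec.samples[:, : n_records * fs]

    if np.any(data < phys_min) or np.any(data > phys_max):
        msg = (
            f"samples outside the declared physical range "
            f"[{phys_min}, {phys_max}] µV are clipped"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        data = np.clip(data, phys_min, phys_max)

    # Physical-to-digital mapping shared by all signals.
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + _DIG_MIN).astype("<i2")

    ns = rec.n_channels
    header = bytearray()
    header += _pad("0", 8)                                   # version
    header += _pad(f"subject {rec.subject_id} label {rec.label}", 80)
    header += _pad("eegsplit synthetic recording", 80)
    header += _pad("01.01.00", 8)                            # start date
    header += _pad("00.00.00", 8)                            # start time
    header += _pad(str(256 * (ns + 1)), 8)                   # header bytes
    header += _pad("", 44)                                   # reserved
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                                   # record duration s
    header += _pad(str(ns), 4)
    for name in rec.montage.names:
        header += _pad(f"EEG {name}", 16)
    header += b"".join(_pad("", 80) for _ in range(ns))      # transducer
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{phys_min:g}", 8) for _ in range(ns))
    header += b"".join(_pad(f"{phys_max:g}", 8) for _ in range(ns))
    header += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))      # prefiltering
    header += b"".join(_pad(str(fs), 8) for _ in range(ns))  # samples/record
    header += b"".join(_pad("", 32) for _ in range(ns))      # reserved

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            for r in range(n_records):
                # EDF interleaves by record: all of signal 0's samples for
                # this second, then signal 1's, ...
                fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    except OSError as exc:
        raise FileIOError(f"could not write EDF file {path}: {exc}") from exc
    return path


def read_recording(
    path: str | Path,
    montage: ChannelMontage,
    label: int,
    subject_id: str | None = None,
) -> EEGRecording:
    """Read an EDF file, selecting and reordering channels to ``montage``.

    Channel matching ignores an ``EEG `` prefix and case, so files written
    by this package and by common acquisition software both resolve.
    """
    import mne

    path = Path(path)
    if label not in (0, 1):
        raise InputError(f"label must be 0 or 1, got {label!r}")
    if not path.exists():
        raise FileIOError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except OSError as exc:
        raise FileIOError(f"could not read EDF file {path}: {exc}") from exc
    except Exception as exc:  # mne raises various types on malformed files
        raise FormatError(f"not a readable EDF file: {path}: {exc}") from exc

    def _norm(name: str) -> str:
        name = name.strip()
        if name.lower().startswith("eeg "):
            name = name[4:]
        return name.strip().lower()

    available = {_norm(ch): i for i, ch in enumerate(raw.ch_names)}
    indices = []
    for name in montage.names:
        key = _norm(name)
        if key not in available:
            raise FormatError(f"EDF file {path} lacks required channel {name!r}")
        indices.append(available[key])

    data = raw.get_data()[indices] * 1e6  # MNE loads EEG in volts
    return EEGRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        montage=montage,
        subject_id=subject_id or path.stem,
        label=int(label),
    )


def write_manifest(records: list[tuple[str, int, str]], path: str | Path) -> Path:
    """Write a cohort manifest CSV with columns subject_id,label,path."""
    import pandas as pd

    path = Path(path)
    frame = pd.DataFrame(records, columns=["subject_id", "label", "path"])
    frame.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a cohort manifest CSV back into (subject_id, label, path) rows."""
    import pandas as pd

    frame = pd.read_csv(path)
    expected = {"subject_id", "label", "path"}
    if not expected.issubset(frame.columns):
        raise FormatError(f"manifest {path} must have columns {sorted(expected)}")
    return [
        (str(r.subject_id), int(r.label), str(r.path))
        for r in frame.itertuples(index=False)
    ]
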