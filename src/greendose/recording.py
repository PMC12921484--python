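"""Multichannel EEG recording container and on-disk formats.

A :class:`RawRecording` is the unit every preprocessing transform consumes and
returns: a channels x samples matrix in microvolts with its sampling rate,
10-20 channel labels and session metadata (participant, environment, condition
and the stress/exposure phase boundaries).

Recordings round-trip to plain delimited text (first column time in seconds,
one column per channel in microvolts) with an optional JSON sidecar; EDF files
can be *read* when ``mne`` is installed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

#: The 14 scalp positions of the saline-electrode headset, 10-20 system order.
DEFAULT_CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Frontal channels on which ocular (blink) activity dominates.
FRONTAL_CHANNELS = ("AF3", "AF4", "F7", "F8")


@dataclasses.dataclass
class SessionMeta:
    """Session-level metadata attached to a recording."""

    participant: str = "P000"
    environment: str = "UP"   # UP / RF / WP
    condition: str = "OE"     # open eyes / blindfold
    stress_end_min: float = 4.0
    session_min: float = 20.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMeta":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})


@dataclasses.dataclass
class RawRecording:
    """Channels x samples EEG matrix in microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    meta: SessionMeta = dataclasses.field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.ndim}-D")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        """A new recording sharing this one's rate/labels/meta with new samples."""
        return RawRecording(
            data=np.asarray(data, dtype=float),
            sampling_rate=self.sampling_rate,
            channel_names=self.channel_names,
            meta=dataclasses.replace(self.meta),
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_delimited(rec: RawRecording, path: str | Path, fmt: str = "%.4f") -> Path:
    """Write ``time_s`` + one column per channel, tab-separated, with sidecar JSON."""
    path = Path(path)
    header = "time_s\t" + "\t".join(rec.channel_names)
    table = np.column_stack([rec.times_s(), rec.data.T])
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt=fmt)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"sampling_rate": rec.sampling_rate, "meta": rec.meta.to_dict()}, indent=2
    ))
    return path


def read_delimited(path: str | Path) -> RawRecording:
    path = Path(path)
    with open(path) as fh:
        names = fh.readline().strip().split("\t")
    if names[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s', got {names[0]!r}")
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    t, data = table[:, 0], table[:, 1:].T
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fs = float(info["sampling_rate"])
        meta = SessionMeta.from_dict(info.get("meta", {}))
    else:
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt))
        meta = SessionMeta(session_min=len(t) / fs / 60.0)
    return RawRecording(data=data, sampling_rate=fs, channel_names=tuple(names[1:]), meta=meta)


def read_edf(path: str | Path, meta: SessionMeta | None = None) -> RawRecording:
    """Read an EDF file via :mod:`mne` (optional dependency), returning microvolts."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne works in volts
    return RawRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        meta=meta or SessionMeta(session_min=data.shape[1] / raw.info["sfreq"] / 60.0),
    )


def read_recording(path: str | Path) -> RawRecording:
    """Dispatch on extension: ``.edf`` via mne, anything else as delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_delimited(path)
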