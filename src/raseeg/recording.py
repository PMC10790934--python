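"""Multichannel EEG recording container and I/O.

An :class:`EEGRecording` holds a (channels x samples) microvolt array at a
fixed sampling rate, together with named, labelled time segments. The study
design expects one ``baseline`` segment (resting recording made before the
tasks) followed by one or more ``task_*`` segments during which console
video exists.

On-disk formats: long-form CSV (columns ``timestamp_s, channel, value_uv``)
with a JSON sidecar for segments, and EDF reading through :mod:`mne`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EEGRecording:
    channels: tuple[str, ...]
    sfreq: float
    data: np.ndarray              # shape (n_channels, n_samples), microvolts
    t0: float = 0.0               # time of first sample, seconds
    segments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        for name, (a, b) in self.segments.items():
            if not a < b:
                raise ValueError(f"segment {name!r} has non-positive length")

    # ------------------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise ValueError(f"channel {label!r} not in montage "
                             f"{list(self.channels)}") from None

    def segment_bounds(self, name: str) -> tuple[float, float]:
        if name not in self.segments:
            raise KeyError(f"no segment {name!r}; have {list(self.segments)}")
        return self.segments[name]

    def segment_slice(self, name: str) -> slice:
        """Sample slice covering a named segment, half-open in time: a
        sample exactly on a segment boundary belongs to the later segment."""
        a, b = self.segment_bounds(name)
        i0 = int(np.ceil((a - self.t0) * self.sfreq - 1e-9))
        i1 = int(np.ceil((b - self.t0) * self.sfreq - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_samples))

    def task_segments(self) -> list[str]:
        return sorted(k for k in self.segments if k.startswith("task"))

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of the recording with new sample data, metadata preserved."""
        return replace(self, data=np.asarray(data, dtype=float))

    # ------------------------------------------------------------------
    # I/O
    def to_long_csv(self, path) -> None:
        """Write as long-form CSV plus a ``<stem>.segments.json`` sidecar."""
        path = Path(path)
        n = self.n_samples
        df = pd.DataFrame({
            "timestamp_s": np.tile(self.timestamps, self.n_channels),
            "channel": np.repeat(list(self.channels), n),
            "value_uv": self.data.ravel(),
        })
        df.to_csv(path, index=False, float_format="%.6f")
        sidecar = path.with_suffix(".segments.json")
        with open(sidecar, "w") as fh:
            json.dump({"sfreq": self.sfreq, "t0": self.t0,
                       "segments": {k: list(v) for k, v in self.segments.items()}},
                      fh, indent=1)

    @classmethod
    def from_long_csv(cls, path, sfreq: float | None = None,
                      segments: dict | None = None) -> "EEGRecording":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".segments.json")
        t0 = 0.0
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            sfreq = sfreq or meta["sfreq"]
            t0 = meta.get("t0", 0.0)
            segments = segments or {k: tuple(v)
                                    for k, v in meta["segments"].items()}
        channels = list(dict.fromkeys(df["channel"]))
        data = np.stack([df.loc[df["channel"] == c, "value_uv"].to_numpy()
                         for c in channels])
        if sfreq is None:
            ts = df.loc[df["channel"] == channels[0], "timestamp_s"].to_numpy()
            sfreq = 1.0 / float(np.median(np.diff(ts)))
            t0 = float(ts[0])
        return cls(tuple(channels), float(sfreq), data, t0=t0,
                   segments=segments or {})

    @classmethod
    def from_edf(cls, path, segments: dict | None = None) -> "EEGRecording":
        """Read an EDF file (requires :mod:`mne`); amplitudes converted to uV."""
        import mne  # deferred: only needed for EDF input

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        return cls(tuple(raw.ch_names), float(raw.info["sfreq"]), data,
                   segments=segments or {})
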