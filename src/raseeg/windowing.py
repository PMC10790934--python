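"""Frame-aligned EEG windowing, RMS band power, and baseline normalization.

Each console video frame defines one EEG analysis window: the window starts
at the EEG sample nearest the frame's timestamp (ties broken toward the
earlier sample) and ends at the next frame's start sample, so consecutive
windows are contiguous and non-overlapping and partition the task stream.
At the nominal 30 fps and 500 Hz this yields ~33 ms windows of 16 or 17
samples in the repeating pattern forced by 500/30.

Per window and per (channel, band) the root-mean-square amplitude of the
band-filtered signal is the power measure. Task powers are expressed
relative to the mean windowed RMS of the resting baseline, which has no
video: the baseline is cut at the nominal frame period so that baseline and
task powers are unit-compatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .preprocessing import BandDecomposition

log = logging.getLogger(__name__)


class WindowIndex(NamedTuple):
    frame_index: int
    start_sample: int
    end_sample: int          # exclusive
    start_time: float
    error_label: bool
    participant_id: str


@dataclass
class WindowSet:
    """Vectorized collection of contiguous, non-overlapping windows."""

    frame_index: np.ndarray
    start_sample: np.ndarray
    end_sample: np.ndarray
    start_time: np.ndarray
    error_label: np.ndarray
    participant_id: str = "p0"

    def __len__(self):
        return len(self.frame_index)

    def __getitem__(self, i) -> WindowIndex:
        return WindowIndex(int(self.frame_index[i]), int(self.start_sample[i]),
                           int(self.end_sample[i]), float(self.start_time[i]),
                           bool(self.error_label[i]), self.participant_id)

    @property
    def lengths(self) -> np.ndarray:
        return self.end_sample - self.start_sample


def nearest_sample(timestamps, t0: float, sfreq: float) -> np.ndarray:
    """Index of the EEG sample nearest each timestamp, ties -> earlier."""
    x = (np.asarray(timestamps, dtype=float) - t0) * sfreq
    return np.ceil(x - 0.5).astype(np.int64)


def align_frames(frames, eeg_like, segment: str | None = None,
                 error_labels=None, participant_id: str = "p0",
                 min_samples: int = 8) -> WindowSet:
    """Map frame timestamps onto contiguous EEG sample windows.

    ``frames`` is anything with ``.timestamps`` (an ``ErrorSchedule`` or
    ``FrameStream``) or a plain array of timestamps in seconds. ``eeg_like``
    is an :class:`~raseeg.recording.EEGRecording` or
    :class:`~raseeg.preprocessing.BandDecomposition`; ``segment`` names the
    task segment whose span must contain every frame (defaults to the only
    ``task*`` segment).

    The final frame's window extends to the segment end and is kept if it is
    at least half the nominal frame period; any window shorter than
    ``min_samples`` is dropped (logged).
    """
    ts = np.asarray(getattr(frames, "timestamps", frames), dtype=float)
    if ts.size == 0:
        return WindowSet(*(np.empty(0, dtype=np.int64) for _ in range(3)),
                         np.empty(0), np.empty(0, dtype=bool), participant_id)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("frame timestamps must be strictly increasing")
    if error_labels is None:
        error_labels = getattr(frames, "labels", None)
        if error_labels is None:
            error_labels = np.zeros(ts.size, dtype=bool)
    error_labels = np.asarray(error_labels, dtype=bool)
    if error_labels.size != ts.size:
        raise ValueError("label count must equal frame count")

    if segment is None:
        tasks = sorted(k for k in eeg_like.segments if k.startswith("task"))
        if len(tasks) != 1:
            raise ValueError("segment must be named when the recording has "
                             f"{len(tasks)} task segments")
        segment = tasks[0]
    sl = eeg_like.segment_slice(segment)
    sfreq, t0 = eeg_like.sfreq, eeg_like.t0
    seg_t = (t0 + sl.start / sfreq, t0 + (sl.stop - 1) / sfreq)
    bad = np.flatnonzero((ts < seg_t[0] - 0.5 / sfreq) |
                         (ts > seg_t[1] + 0.5 / sfreq))
    if bad.size:
        raise ValueError(
            f"{bad.size} frame timestamp(s) outside EEG segment "
            f"{segment!r} span {seg_t}: frame indices {bad[:10].tolist()}...")

    start = nearest_sample(ts, t0, sfreq)
    start = np.clip(start, sl.start, sl.stop - 1)
    end = np.empty_like(start)
    end[:-1] = start[1:]
    end[-1] = sl.stop

    frame_index = np.arange(ts.size, dtype=np.int64)
    lengths = end - start
    nominal = sfreq * np.median(np.diff(ts)) if ts.size > 1 else lengths[-1]
    keep = lengths >= min_samples
    if ts.size > 1 and lengths[-1] < nominal / 2:
        keep[-1] = False
    dropped = int((~keep).sum())
    if dropped:
        log.info("align_frames: dropped %d window(s) shorter than %d samples",
                 dropped, min_samples)
    return WindowSet(frame_index[keep], start[keep], end[keep],
                     t0 + start[keep] / sfreq, error_labels[keep],
                     participant_id)


# ----------------------------------------------------------------------
@dataclass
class BandPowerTable:
    """Per-window x per-(channel, band) RMS powers.

    ``values`` is indexed by (participant_id, frame_index) with one flat
    ``{channel}_{band}`` column per cell; ``meta`` carries timestamp and
    error label per row. ``normalized`` flags baseline-relative values.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    channels: tuple[str, ...]
    bands: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self):
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values/meta row misalignment")

    def column(self, channel: str, band: str) -> pd.Series:
        return self.values[f"{channel}_{band}"]

    @property
    def error(self) -> pd.Series:
        return self.meta["error"]

    @property
    def participant(self) -> pd.Series:
        return self.values.index.get_level_values("participant_id").to_series(
            index=self.values.index)

    @staticmethod
    def concat(tables: list["BandPowerTable"]) -> "BandPowerTable":
        first = tables[0]
        if any(t.normalized != first.normalized or t.channels != first.channels
               or t.bands != first.bands for t in tables):
            raise ValueError("cannot concat incompatible band-power tables")
        return BandPowerTable(pd.concat([t.values for t in tables]),
                              pd.concat([t.meta for t in tables]),
                              first.channels, first.bands, first.normalized)

    def to_csv(self, path) -> None:
        out = self.meta.join(self.values)
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, normalized: bool = True) -> "BandPowerTable":
        df = pd.read_csv(path).set_index(["participant_id", "frame_index"])
        meta_cols = [c for c in ("timestamp_s", "error") if c in df.columns]
        values = df.drop(columns=meta_cols)
        chans, bands = [], []
        for col in values.columns:
            ch, band = col.rsplit("_", 1)
            if ch not in chans:
                chans.append(ch)
            if band not in bands:
                bands.append(band)
        return cls(values, df[meta_cols], tuple(chans), tuple(bands),
                   normalized=normalized)


def window_rms(decomp: BandDecomposition, windows: WindowSet) -> BandPowerTable:
    """RMS amplitude of every (channel, band) stream in every window.

    Computed from cumulative sums of squares, equal to the direct
    element-wise definition to floating tolerance.
    """
    if len(windows) == 0:
        raise ValueError("empty window set")
    if windows.end_sample.max() > decomp.n_samples:
        raise ValueError("windows extend past decomposition length")
    s, e = windows.start_sample, windows.end_sample
    lengths = (e - s).astype(float)
    csq = np.concatenate(
        [np.zeros((len(decomp.channels), len(decomp.bands), 1)),
         np.cumsum(decomp.data ** 2, axis=2)], axis=2)
    ms = (csq[:, :, e] - csq[:, :, s]) / lengths        # (ch, band, win)
    rms = np.sqrt(np.maximum(ms, 0.0))
    cols = [f"{ch}_{b.name}" for ch in decomp.channels for b in decomp.bands]
    idx = pd.MultiIndex.from_arrays(
        [np.repeat(windows.participant_id, len(windows)), windows.frame_index],
        names=["participant_id", "frame_index"])
    values = pd.DataFrame(
        rms.reshape(len(decomp.channels) * len(decomp.bands), -1).T,
        index=idx, columns=cols)
    meta = pd.DataFrame({"timestamp_s": windows.start_time,
                         "error": windows.error_label}, index=idx)
    return BandPowerTable(values, meta, decomp.channels,
                          tuple(b.name for b in decomp.bands))


# ----------------------------------------------------------------------
@dataclass
class BaselineStats:
    """Per-(channel, band) mean windowed RMS over the resting baseline (uV)."""

    means: pd.Series            # index: "{channel}_{band}"

    def __post_init__(self):
        if (self.means <= 0).any():
            bad = list(self.means.index[self.means <= 0])
            raise ValueError(f"non-positive baseline mean for {bad}; "
                             "cannot be used as a normalization divisor")


def baseline_stats(decomp: BandDecomposition, segment: str = "baseline",
                   frame_period: float = 1.0 / 30.0) -> BaselineStats:
    """Cut the baseline at the nominal frame period and average window RMS."""
    sl = decomp.segment_slice(segment)
    n = sl.stop - sl.start
    if n <= 0:
        raise ValueError(f"baseline segment {segment!r} is empty")
    t_rel = np.arange(0.0, n / decomp.sfreq, frame_period)
    bounds = nearest_sample(t_rel, 0.0, decomp.sfreq) + sl.start
    bounds = bounds[bounds < sl.stop]
    windows = WindowSet(np.arange(len(bounds)), bounds,
                        np.append(bounds[1:], sl.stop),
                        decomp.t0 + bounds / decomp.sfreq,
                        np.zeros(len(bounds), dtype=bool))
    table = window_rms(decomp, windows)
    return BaselineStats(table.values.mean(axis=0))


def normalize(table: BandPowerTable, stats: BaselineStats,
              method: str = "ratio") -> BandPowerTable:
    """Express task powers relative to the baseline mean (ratio by default;
    ``method="log"`` gives the natural log-ratio)."""
    if table.normalized:
        raise ValueError("table is already baseline-normalized")
    missing = [c for c in table.values.columns if c not in stats.means.index]
    if missing:
        raise ValueError(f"baseline stats missing columns {missing}")
    ratio = table.values / stats.means[table.values.columns]
    if method == "log":
        ratio = np.log(ratio)
    elif method != "ratio":
        raise ValueError("method must be 'ratio' or 'log'")
    return BandPowerTable(ratio, table.meta.copy(), table.channels,
                          table.bands, normalized=True)


def heatmap_matrix(table_or_results, channels, bands) -> pd.DataFrame:
    """Arrange per-(channel, band) scalars as a channels x bands matrix
    (the 19 x 5 layout used for heat-map display)."""
    mat = pd.DataFrame(index=list(channels), columns=list(bands), dtype=float)
    for (ch, band), val in table_or_results.items():
        mat.loc[ch, band] = val
    return mat
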