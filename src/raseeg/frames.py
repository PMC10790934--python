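"""Console video frames: container, synthetic rendering, and PNG I/O.

The reference synthetic scene emulates a surgical-simulator console view at
desk scale: a dark field with a metallic ring and a curved wire (the
classic ring-and-wire transfer task). Frames whose error label is true
carry the simulator-style indicator the detector is tuned to: a saturated
red border around the frame plus a high-contrast red text box with white
glyph bars at the top centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter, disk

log = logging.getLogger(__name__)


@dataclass
class Frame:
    pixels: np.ndarray          # HxWx3 uint8
    frame_index: int
    timestamp: float


@dataclass(frozen=True)
class SceneParams:
    width: int = 640
    height: int = 360
    ring_radius: int = 60
    ring_drift: float = 0.12     # fraction of width the ring centre wanders
    border_px: int = 12
    textbox_size: tuple[int, int] = (160, 40)   # (width, height)
    background: int = 45
    overlay_color: tuple[int, int, int] = (230, 30, 25)


def render_frame(error: bool, frame_index: int,
                 params: SceneParams = SceneParams()) -> np.ndarray:
    """Render one RGB frame of the task scene, deterministically per index."""
    h, w = params.height, params.width
    img = np.full((h, w, 3), params.background, dtype=np.uint8)

    # curved wire
    xs = np.arange(w)
    ys = (0.70 * h + 0.08 * h * np.sin(2 * np.pi * xs / w * 1.5)).astype(int)
    for dy in (0, 1):
        img[np.clip(ys + dy, 0, h - 1), xs] = (160, 160, 170)

    # ring with slow deterministic drift
    cx = int(w / 2 + params.ring_drift * w * np.sin(2 * np.pi * frame_index / 400))
    cy = int(h / 2 + 0.08 * h * np.cos(2 * np.pi * frame_index / 400))
    for r in range(params.ring_radius - 1, params.ring_radius + 2):
        rr, cc = circle_perimeter(cy, cx, r, shape=(h, w))
        img[rr, cc] = (205, 205, 210)

    if error:
        b = params.border_px
        img[:b, :] = params.overlay_color
        img[-b:, :] = params.overlay_color
        img[:, :b] = params.overlay_color
        img[:, -b:] = params.overlay_color
        tw, th = params.textbox_size
        x0 = (w - tw) // 2
        y0 = b + 4
        img[y0:y0 + th, x0:x0 + tw] = params.overlay_color
        # white glyph bars standing in for indicator text
        for row in range(2):
            yy = y0 + 8 + row * (th - 16) // 2
            for seg in range(4):
                xx = x0 + 10 + seg * (tw - 20) // 4
                img[yy:yy + 6, xx:xx + (tw - 30) // 4] = (250, 250, 250)
    return img


class FrameStream:
    """Ordered timestamped frames with optional ground truth.

    Frames may live in memory, on disk (PNG sequence + ``frames.csv``), or
    be rendered lazily from an error schedule.
    """

    def __init__(self, timestamps, source: Callable[[int], np.ndarray | None],
                 truth=None):
        self.timestamps = np.asarray(timestamps, dtype=float)
        self.truth = None if truth is None else np.asarray(truth, dtype=bool)
        self._source = source

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def labels(self):
        return self.truth

    def frame(self, i: int) -> Frame:
        return Frame(self._source(i), i, float(self.timestamps[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self.frame(i)

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(cls, frames: list, timestamps, truth=None) -> "FrameStream":
        return cls(timestamps, lambda i: frames[i], truth=truth)

    @classmethod
    def from_schedule(cls, schedule, params: SceneParams = SceneParams()
                      ) -> "FrameStream":
        """Lazy rendering of a synthetic stream from an error schedule."""
        labels = schedule.labels
        return cls(schedule.timestamps,
                   lambda i: render_frame(bool(labels[i]), i, params),
                   truth=labels)

    @classmethod
    def from_directory(cls, directory) -> "FrameStream":
        """PNG sequence + ``frames.csv`` (frame_index, timestamp_s[, error_truth])."""
        import imageio.v3 as iio

        directory = Path(directory)
        df = pd.read_csv(directory / "frames.csv")
        truth = (df["error_truth"].to_numpy().astype(bool)
                 if "error_truth" in df.columns else None)
        indices = df["frame_index"].to_numpy()

        def load(i: int):
            path = directory / f"frame_{indices[i]:06d}.png"
            try:
                return np.asarray(iio.imread(path))[..., :3]
            except (FileNotFoundError, OSError) as exc:
                log.warning("missing/corrupt frame %s: %s", path, exc)
                return None

        return cls(df["timestamp_s"].to_numpy(), load, truth=truth)

    def write(self, directory) -> Path:
        """Materialize as zero-padded PNGs plus frames.csv."""
        import imageio.v3 as iio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for fr in self:
            iio.imwrite(directory / f"frame_{fr.frame_index:06d}.png",
                        fr.pixels)
            rows.append((fr.frame_index, fr.timestamp,
                         int(self.truth[fr.frame_index])
                         if self.truth is not None else ""))
        pd.DataFrame(rows, columns=["frame_index", "timestamp_s",
                                    "error_truth"]).to_csv(
            directory / "frames.csv", index=False)
        return directory


def render_frames(schedule, params: SceneParams = SceneParams()) -> FrameStream:
    """Render the synthetic task scene for every frame of a schedule."""
    return FrameStream.from_schedule(schedule, params)
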