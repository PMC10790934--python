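"""Frame-by-frame intraoperative error detection from console video.

The simulator flags errors with colour and text overlays on the console
feed, so classical computer vision suffices: a hue/saturation/value colour
mask for the saturated indicator colour, a text-region contrast score, 2-D
spectral high-frequency content, and Hough-transform circle geometry form
the feature representation; a thresholded decision rule over the colour
mask fraction (boundary closed: mask fraction exactly at threshold labels
error) gives the binary per-frame label at the video rate.

All thresholds live in :class:`DetectorParams` so the detector can be
re-tuned to other footage; the defaults are tuned to the synthetic
reference overlay rendered by :mod:`raseeg.frames`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import ErrorSchedule

log = logging.getLogger(__name__)


def _sat_val(pixels: np.ndarray):
    """Saturation and value planes in [0, 1] (float32), plus the channel
    planes. Standard HSV definitions computed channel-wise so a
    full-resolution stream can be classified at the video rate."""
    scale = np.float32(1.0 / 255.0) if pixels.dtype != np.float32 \
        and pixels.max() > 1.0 else np.float32(1.0)
    r = pixels[..., 0].astype(np.float32) * scale
    g = pixels[..., 1].astype(np.float32) * scale
    b = pixels[..., 2].astype(np.float32) * scale
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    s = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return (r, g, b), s, mx


def _hue(r, g, b) -> np.ndarray:
    """Hue in [0, 1) for flat channel arrays (HSV convention)."""
    mx = np.maximum(np.maximum(r, g), b)
    delta = mx - np.minimum(np.minimum(r, g), b)
    d = np.where(delta > 0, delta, 1.0)
    h = np.select([mx == r, mx == g],
                  [np.mod((g - b) / d, 6.0), (b - r) / d + 2.0],
                  default=(r - g) / d + 4.0) / 6.0
    return np.where(delta > 0, h, 0.0)


@dataclass(frozen=True)
class DetectorParams:
    # colour mask in HSV space: red hue wraps around 0
    hue_low: float = 0.95
    hue_high: float = 0.05
    min_saturation: float = 0.5
    min_value: float = 0.35
    mask_threshold: float = 0.01      # decision threshold on mask fraction
    # optional heavier features
    compute_circles: bool = False
    compute_spectral: bool = False
    canny_sigma: float = 2.0
    hough_radii: tuple[int, ...] = tuple(range(30, 121, 5))
    spectral_cutoff: float = 0.25     # fraction of Nyquist radius
    # text-region scoring (white glyphs inside the indicator box)
    text_min_value: float = 0.85
    text_max_saturation: float = 0.25


@dataclass
class FrameFeatures:
    color_mask_fraction: float
    edge_density: float
    hough_circles: list[tuple[tuple[float, float], float]]
    text_region_score: float
    highfreq_ratio: float = 0.0


def _red_mask(rgb, s, v, params: DetectorParams) -> np.ndarray:
    """Indicator colour mask in HSV space; hue is evaluated only on pixels
    already passing the saturation/value gates (the mask is unchanged)."""
    r, g, b = rgb
    cand = (s >= params.min_saturation) & (v >= params.min_value)
    mask = np.zeros(cand.shape, dtype=bool)
    idx = np.flatnonzero(cand.ravel())
    if idx.size:
        h = _hue(r.ravel()[idx], g.ravel()[idx], b.ravel()[idx])
        ok = (h >= params.hue_low) | (h <= params.hue_high)
        mask.ravel()[idx[ok]] = True
    return mask


def extract_features(frame, params: DetectorParams = DetectorParams()
                     ) -> FrameFeatures:
    """Deterministic feature vector for one frame.

    Degenerate (all-constant) images yield zero mask fraction and no
    circles rather than an exception.
    """
    pixels = getattr(frame, "pixels", frame)
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] < 3:
        raise ValueError("frame must have >= 3 colour channels")
    rgb, s, v = _sat_val(pixels[..., :3])
    mask = _red_mask(rgb, s, v, params)
    mask_fraction = float(mask.mean())

    # white glyphs inside the indicator's bounding box
    text_score = 0.0
    if mask.any():
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        white = ((v >= params.text_min_value)
                 & (s <= params.text_max_saturation))
        text_score = float(white[box].mean())

    edge_density = 0.0
    circles: list[tuple[tuple[float, float], float]] = []
    if params.compute_circles:
        from skimage.feature import canny
        from skimage.transform import hough_circle, hough_circle_peaks

        edges = canny(v, sigma=params.canny_sigma)
        edge_density = float(edges.mean())
        if edges.any():
            radii = np.asarray(params.hough_radii)
            accum = hough_circle(edges, radii)
            _, cx, cy, rad = hough_circle_peaks(accum, radii,
                                                total_num_peaks=3,
                                                threshold=0.5)
            circles = [((float(x), float(y)), float(r))
                       for x, y, r in zip(cx, cy, rad)]

    hf_ratio = 0.0
    if params.compute_spectral:
        gray = v
        spec = np.abs(np.fft.fftshift(np.fft.fft2(gray - gray.mean()))) ** 2
        hh, ww = spec.shape
        fy = np.fft.fftshift(np.fft.fftfreq(hh))[:, None]
        fx = np.fft.fftshift(np.fft.fftfreq(ww))[None, :]
        radial = np.hypot(fy / 0.5, fx / 0.5)
        total = spec.sum()
        hf_ratio = float(spec[radial > params.spectral_cutoff].sum() / total) \
            if total > 0 else 0.0

    return FrameFeatures(mask_fraction, edge_density, circles, text_score,
                         hf_ratio)


def classify_frame(features: FrameFeatures,
                   params: DetectorParams = DetectorParams()) -> bool:
    """Thresholded decision rule; pure function of the feature vector."""
    return features.color_mask_fraction >= params.mask_threshold


def label_stream(frames, params: DetectorParams = DetectorParams()
                 ) -> ErrorSchedule:
    """Label every frame of a stream; timestamps copied through unchanged.

    Missing/corrupt frames (loader returned ``None``) are logged, labelled
    False and flagged invalid so downstream stages can exclude them.
    """
    ts = np.asarray(frames.timestamps, dtype=float)
    if len(ts) > 1 and np.any(np.diff(ts) <= 0):
        raise ValueError("frames must be ordered by timestamp")
    labels = np.zeros(len(ts), dtype=bool)
    valid = np.ones(len(ts), dtype=bool)
    for i, fr in enumerate(frames):
        if fr.pixels is None:
            log.warning("frame %d missing; excluded downstream", i)
            valid[i] = False
            continue
        labels[i] = classify_frame(extract_features(fr, params), params)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("label_stream: %d/%d frames missing", n_bad, len(ts))
    sched = ErrorSchedule(np.arange(len(ts)), ts, labels)
    sched.valid = valid
    return sched


# ----------------------------------------------------------------------
@dataclass
class DetectionMetrics:
    n_frames: int
    true_positive: int
    false_positive: int
    false_negative: int
    true_negative: int
    accuracy: float
    precision: float
    recall: float

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def evaluate_detector(predicted: ErrorSchedule,
                      truth: ErrorSchedule) -> DetectionMetrics:
    """Confusion counts and accuracy/precision/recall.

    Zero-denominator precision or recall is reported as NaN with a warning
    (an all-negative prediction has no meaningful precision).
    """
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs "
                         f"{len(truth)} truth labels")
    if not np.array_equal(predicted.frame_index, truth.frame_index):
        raise ValueError("frame indices do not match")
    keep = np.ones(len(truth), dtype=bool)
    for sched in (predicted, truth):
        if sched.valid is not None:
            keep &= sched.valid
    p = predicted.labels[keep]
    t = truth.labels[keep]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n if n else float("nan")

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    return DetectionMetrics(n, tp, fp, fn, tn, accuracy, precision, recall)
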