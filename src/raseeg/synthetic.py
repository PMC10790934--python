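"""Synthetic cohort generation with known ground truth.

Real recordings from the operating room are protected health data, so the
package ships a generator that emulates the study design: a cohort of
participants, each with a resting baseline followed by simulation tasks
whose console video runs at a nominal 30 fps while 19-channel EEG is
sampled at 500 Hz. Intraoperative errors occur in multi-frame runs at a
controlled prevalence, and error-locked band-power effects of known
standardized size can be injected per channel/region and band.

Signal model
------------
Each channel is a sum over the five bands of band-limited Gaussian noise
(white noise through the band's own zero-phase Butterworth filter) with
amplitudes proportional to 1/(band centre frequency), giving a realistic
1/f-like spectrum with controllable per-band power. Participant-level
variation and error effects are injected as multiplicative amplitude gains
on individual band components, applied only during task segments (the
baseline is never modulated, so baseline normalization stays well defined).

Effect calibration
------------------
The study's effects live on the *standardized baseline-normalized window
power* scale, not on raw amplitude. The generator closes that loop with a
one-off per-band calibration run: it synthesizes a long stretch of the
mixture, pushes it through the exact downstream chain (bandpass, band
decomposition, frame-period windowing, RMS), and measures (a) the
coefficient of variation of window RMS and (b) the response slope of mean
band RMS to an amplitude gain on that band's component (slightly below 1
because of leakage from neighbouring bands). From these the gain that
produces a requested standardized fixed effect follows in closed form;
RMS scales linearly with amplitude over the small gains involved.

An :class:`EffectSpec` naming a multi-channel region targets the
*regional-mean feature* on that region: averaging k channels with
independent noise shrinks the feature's standard deviation by sqrt(k), so
the per-channel gain is scaled accordingly (each individual channel then
carries effect_size/sqrt(k)).
"""

from __future__ import annotations

import functools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BAND_NAMES, DEFAULT_BANDS, band_by_name
from .montage import MONTAGE_1020, resolve_channels
from .preprocessing import band_sos, bandpass_filter
from .recording import EEGRecording
from .windowing import nearest_sample

log = logging.getLogger(__name__)

_CAL_SEED = 0x5EED  # fixed internal seed: calibration is a design constant


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class EffectSpec:
    """Target standardized error effect for one channel/region and band."""

    channel: str            # electrode label, "O1+O2", or region keyword
    band: str
    effect_size: float      # standardized units on the named target

    def __post_init__(self):
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        resolve_channels(self.channel)  # raises for unknown channels/regions


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults reproduce the study conditions: 20 participants x 3 tasks,
    368,040 frames in total at 30 fps (equal split), 500 Hz EEG, a 4-minute
    baseline, 17.1% error frames in ~1 s runs, and participant
    random-intercept SD 0.3 on the standardized power scale.
    """

    n_participants: int = 20
    tasks_per_participant: int = 3
    frames_per_task: int = 6134
    frame_rate: float = 30.0
    eeg_rate: float = 500.0
    baseline_duration: float = 240.0
    target_error_rate: float = 0.171
    mean_error_run: float = 30.0
    effect_specs: tuple[EffectSpec, ...] = ()
    intercept_sd: float = 0.3
    seed: int = 0
    montage: tuple[str, ...] = MONTAGE_1020
    amplitude_uv: float = 30.0   # per-band amplitude scale before 1/f weighting

    def __post_init__(self):
        if min(self.n_participants, self.tasks_per_participant,
               self.frames_per_task) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.target_error_rate < 1:
            raise ValueError("target_error_rate must be in [0, 1)")
        if self.frame_rate <= 0 or self.eeg_rate <= 0:
            raise ValueError("frame_rate and eeg_rate must be positive")
        if self.mean_error_run < 1:
            raise ValueError("mean_error_run must be >= 1 frame")
        if not 0 <= self.intercept_sd < 1:
            raise ValueError("intercept_sd must be in [0, 1) on the "
                             "standardized scale")

    @property
    def task_duration(self) -> float:
        return self.frames_per_task / self.frame_rate


# ----------------------------------------------------------------------
@dataclass
class ErrorSchedule:
    """Per-frame boolean error labels with timestamps."""

    frame_index: np.ndarray
    timestamps: np.ndarray
    labels: np.ndarray
    valid: np.ndarray | None = None   # False for missing/corrupt frames

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.frame_index) == len(self.timestamps)
                == len(self.labels)):
            raise ValueError("label count must equal frame count")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.labels)

    @property
    def error_fraction(self) -> float:
        return float(self.labels.mean()) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_index": self.frame_index,
                             "timestamp_s": self.timestamps,
                             "error_truth": self.labels.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, label_col: str | None = None) -> "ErrorSchedule":
        df = pd.read_csv(path)
        if label_col is None:
            label_col = ("error_truth" if "error_truth" in df.columns
                         else "error_pred")
        return cls(df["frame_index"].to_numpy(),
                   df["timestamp_s"].to_numpy(),
                   df[label_col].to_numpy().astype(bool))


def generate_error_schedule(n_frames: int, target_error_rate: float,
                            mean_error_run: float, seed,
                            frame_rate: float = 30.0,
                            t_start: float = 0.0) -> ErrorSchedule:
    """Alternating error/non-error runs with geometric run lengths.

    Error runs have mean length ``mean_error_run`` frames; non-error run
    lengths are set so the stationary marginal error fraction equals
    ``target_error_rate``. The initial state is drawn from the stationary
    distribution.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= target_error_rate < 1:
        raise ValueError("target_error_rate must be in [0, 1)")
    if mean_error_run < 1:
        raise ValueError("mean_error_run must be >= 1 frame")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ts = t_start + np.arange(n_frames) / frame_rate
    idx = np.arange(n_frames)
    labels = np.zeros(n_frames, dtype=bool)
    r = target_error_rate
    if r > 0:
        mean_nonerror_run = mean_error_run * (1 - r) / r
        state = bool(rng.random() < r)
        pos = 0
        while pos < n_frames:
            mean_run = mean_error_run if state else mean_nonerror_run
            p = min(max(1.0 / mean_run, 1e-12), 1.0)  # guard tiny rates
            run = int(rng.geometric(p))
            labels[pos:pos + run] = state
            pos += run
            state = not state
    return ErrorSchedule(idx, ts, labels)


# ----------------------------------------------------------------------
# per-band pilot calibration
#
# Three constants per band, measured once through the real downstream chain
# (bandpass, band filter, frame-period windows, RMS) on a long synthetic
# stretch and cached:
#   cv          coefficient of variation of window RMS (sets the
#               standardized scale);
#   slope_global response of mean window RMS to a sustained amplitude gain
#               on the band's component (slightly < 1 from neighbour-band
#               leakage) — used for participant intercepts, which span
#               whole task segments;
#   slope_pulse response of the error/non-error window-RMS *separation* to
#               an amplitude gain applied only inside error runs. The band
#               filter smears gain pulses over its impulse-response width
#               (~0.3 s for delta against ~1 s runs), so the effective
#               separation is well below slope_global for slow bands; it is
#               measured with the gained and ungained stream sharing one
#               noise realization, so sampling noise cancels.
@functools.lru_cache(maxsize=16)
def _band_calibration(eeg_rate: float, frame_rate: float,
                      amplitude_uv: float, error_rate: float = 0.171,
                      mean_error_run: float = 30.0,
                      duration: float = 240.0
                      ) -> dict[str, tuple[float, float, float]]:
    """Return ``{band: (cv, slope_global, slope_pulse)}``."""
    rng = np.random.default_rng(_CAL_SEED)
    n = int(round(duration * eeg_rate))
    weights = {b.name: amplitude_uv / b.center for b in DEFAULT_BANDS}
    comps = {}
    for b in DEFAULT_BANDS:
        white = rng.standard_normal(n)
        comps[b.name] = signal.sosfiltfilt(
            band_sos(b, eeg_rate), white) * weights[b.name]
    mix = sum(comps.values())

    # error-like pulse pattern matching the study's run structure
    n_frames = int(duration * frame_rate)
    sched = generate_error_schedule(n_frames, max(error_rate, 0.05),
                                    mean_error_run, rng,
                                    frame_rate=frame_rate)
    bounds = nearest_sample(sched.timestamps, 0.0, eeg_rate)
    bounds = bounds[bounds < n]
    labels = sched.labels[:len(bounds)]
    ends = np.append(bounds[1:], n)
    pulse = np.zeros(n, dtype=bool)
    for s, e in zip(bounds[labels], ends[labels]):
        pulse[s:e] = True

    def _windowed_rms(x: np.ndarray, band) -> np.ndarray:
        rec = EEGRecording(("cal",), eeg_rate, x[None, :])
        rec = bandpass_filter(rec)
        filt = signal.sosfiltfilt(band_sos(band, eeg_rate), rec.data[0])
        csq = np.concatenate([[0.0], np.cumsum(filt ** 2)])
        ms = (csq[ends] - csq[bounds]) / (ends - bounds)
        return np.sqrt(ms)

    out = {}
    for b in DEFAULT_BANDS:
        rms0 = _windowed_rms(mix, b)
        m0 = float(rms0.mean())
        cv = float(rms0.std(ddof=1)) / m0
        bumped = mix + 0.2 * comps[b.name]       # sustained x1.2 gain
        m_global = float(_windowed_rms(bumped, b).mean())
        slope_global = (m_global / m0 - 1.0) / 0.2
        pulsed = mix + 0.2 * comps[b.name] * pulse
        rms1 = _windowed_rms(pulsed, b)
        sep1 = float(rms1[labels].mean() - rms1[~labels].mean())
        sep0 = float(rms0[labels].mean() - rms0[~labels].mean())
        slope_pulse = (sep1 - sep0) / (0.2 * m0)
        out[b.name] = (cv, slope_global, slope_pulse)
    return out


def effect_gain(effect_size: float, band: str, n_channels: int,
                intercept_sd: float, eeg_rate: float = 500.0,
                frame_rate: float = 30.0, amplitude_uv: float = 30.0,
                error_rate: float = 0.171,
                mean_error_run: float = 30.0) -> float:
    """Amplitude gain applied during error frames so the downstream pipeline
    recovers ``effect_size`` on the standardized regional-mean power."""
    cv, _, slope_pulse = _band_calibration(
        eeg_rate, frame_rate, amplitude_uv, error_rate, mean_error_run)[band]
    sigma_x = cv / np.sqrt(1.0 - intercept_sd ** 2)
    g = 1.0 + effect_size * sigma_x / (slope_pulse * np.sqrt(n_channels))
    if g <= 0.05:
        raise ValueError(f"effect_size {effect_size} too large for band "
                         f"{band} (gain {g:.3f})")
    return float(g)


def _intercept_gain(z_standardized: float, band: str, intercept_sd: float,
                    eeg_rate: float, frame_rate: float,
                    amplitude_uv: float, error_rate: float,
                    mean_error_run: float) -> float:
    """Task-segment amplitude gain realizing a participant intercept of
    ``z_standardized`` standardized units on one (channel, band) cell."""
    cv, slope_global, _ = _band_calibration(
        eeg_rate, frame_rate, amplitude_uv, error_rate, mean_error_run)[band]
    sigma_x = cv / np.sqrt(1.0 - intercept_sd ** 2)
    return float(max(1.0 + z_standardized * sigma_x / slope_global, 0.05))


# ----------------------------------------------------------------------
def synthesize_eeg(config: SimulationConfig,
                   schedules: "ErrorSchedule | dict[str, ErrorSchedule]",
                   participant_intercepts: dict | None = None,
                   rng=None) -> EEGRecording:
    """Synthesize one participant's full recording (baseline + tasks).

    ``schedules`` maps task segment names to error schedules whose
    timestamps must fall inside the corresponding task segment; a single
    schedule is treated as ``task_1``. ``participant_intercepts`` maps
    ``(channel, band)`` to standardized intercept offsets (applied to task
    segments only). Error-locked gains follow ``config.effect_specs``. The
    baseline carries no modulation of any kind.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(config.seed if rng is None else rng)
    if isinstance(schedules, ErrorSchedule):
        schedules = {"task_1": schedules}
    fs = config.eeg_rate
    segments = {"baseline": (0.0, config.baseline_duration)}
    t = config.baseline_duration
    for name in sorted(schedules):
        segments[name] = (t, t + config.task_duration)
        t += config.task_duration
    n_total = int(round(t * fs))

    # resolve effect specs to per-(channel, band) gains; overlaps multiply
    gains: dict[tuple[str, str], float] = {}
    for spec in config.effect_specs:
        chans = resolve_channels(spec.channel, config.montage)
        g = effect_gain(spec.effect_size, spec.band, len(chans),
                        config.intercept_sd, fs, config.frame_rate,
                        config.amplitude_uv, config.target_error_rate,
                        config.mean_error_run)
        for ch in chans:
            key = (ch, spec.band)
            gains[key] = gains.get(key, 1.0) * g

    # per-task sample spans and error-sample masks
    task_masks = {}
    for name, sched in schedules.items():
        a, b = segments[name]
        if (sched.timestamps[0] < a - 0.5 / fs
                or sched.timestamps[-1] > b + 0.5 / fs):
            raise ValueError(f"schedule for {name!r} falls outside its task "
                             f"segment {a}-{b} s")
        start = np.clip(nearest_sample(sched.timestamps, 0.0, fs),
                        int(round(a * fs)), int(round(b * fs)) - 1)
        end = np.append(start[1:], int(round(b * fs)))
        mask = np.zeros(n_total, dtype=bool)
        for s, e in zip(start[sched.labels], end[sched.labels]):
            mask[s:e] = True
        task_masks[name] = mask
    error_mask = np.logical_or.reduce(list(task_masks.values())) \
        if task_masks else np.zeros(n_total, dtype=bool)
    task_mask = np.zeros(n_total, dtype=bool)
    task_mask[int(round(config.baseline_duration * fs)):] = True

    weights = {b.name: config.amplitude_uv / b.center for b in DEFAULT_BANDS}
    data = np.zeros((len(config.montage), n_total))
    for ci, ch in enumerate(config.montage):
        for b in DEFAULT_BANDS:
            white = rng.standard_normal(n_total)
            comp = signal.sosfiltfilt(band_sos(b, fs), white) * weights[b.name]
            h = 1.0
            if participant_intercepts:
                z = participant_intercepts.get((ch, b.name), 0.0)
                if z:
                    h = _intercept_gain(z, b.name, config.intercept_sd, fs,
                                        config.frame_rate, config.amplitude_uv,
                                        config.target_error_rate,
                                        config.mean_error_run)
            g = gains.get((ch, b.name), 1.0)
            if h != 1.0 or g != 1.0:
                gain_vec = np.ones(n_total)
                if h != 1.0:
                    gain_vec[task_mask] *= h
                if g != 1.0:
                    gain_vec[error_mask] *= g
                comp = comp * gain_vec
            data[ci] += comp
    return EEGRecording(config.montage, fs, data, segments=segments)


# ----------------------------------------------------------------------
@dataclass
class ParticipantData:
    participant_id: str
    recording: EEGRecording
    schedules: dict[str, ErrorSchedule]
    intercepts: dict[tuple[str, str], float]


@dataclass
class CohortBundle:
    """Synthetic cohort: per-participant recordings, schedules, and truth."""

    config: SimulationConfig
    participants: list[ParticipantData]
    effect_map: dict[tuple[str, str], float]  # per-cell standardized effects

    @property
    def n_task_recordings(self) -> int:
        return sum(len(p.schedules) for p in self.participants)


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the full cohort deterministically from ``config.seed``.

    Participant intercepts are independent Normal(0, intercept_sd^2) draws
    per (channel, band) on the standardized scale.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)
    effect_map: dict[tuple[str, str], float] = {}
    for spec in config.effect_specs:
        chans = resolve_channels(spec.channel, config.montage)
        for ch in chans:
            key = (ch, spec.band)
            effect_map[key] = effect_map.get(key, 0.0) + \
                spec.effect_size / np.sqrt(len(chans))
    participants = []
    for pi, child in enumerate(children):
        rng = np.random.default_rng(child)
        intercepts = {
            (ch, b): float(rng.normal(0.0, config.intercept_sd))
            for ch in config.montage for b in BAND_NAMES}
        schedules = {}
        t = config.baseline_duration
        for k in range(config.tasks_per_participant):
            schedules[f"task_{k + 1}"] = generate_error_schedule(
                config.frames_per_task, config.target_error_rate,
                config.mean_error_run, rng, config.frame_rate, t_start=t)
            t += config.task_duration
        rec = synthesize_eeg(config, schedules, intercepts, rng=rng)
        participants.append(ParticipantData(f"p{pi:02d}", rec, schedules,
                                            intercepts))
    return CohortBundle(config, participants, effect_map)


def write_cohort(bundle: CohortBundle, outdir) -> Path:
    """Persist a cohort as long-form EEG CSVs, per-task frames.csv files and
    a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"n_participants": len(bundle.participants),
                "seed": bundle.config.seed,
                "effect_specs": [
                    {"channel": s.channel, "band": s.band,
                     "effect_size": s.effect_size}
                    for s in bundle.config.effect_specs],
                "participants": {}}
    for p in bundle.participants:
        pdir = outdir / p.participant_id
        pdir.mkdir(exist_ok=True)
        p.recording.to_long_csv(pdir / "eeg.csv")
        files = {"eeg": str(pdir / "eeg.csv")}
        for task, sched in p.schedules.items():
            f = pdir / f"frames_{task}.csv"
            sched.to_csv(f)
            files[task] = str(f)
        manifest["participants"][p.participant_id] = files
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
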