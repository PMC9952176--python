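"""Gunshot detection by spectrogram template matching.

The detector emulates a data-template workflow: an exemplar spectrogram
patch (averaged over annotated gunshot clips, mean-centred and
unit-normed) is slid along the recording's log-magnitude spectrogram;
each alignment is scored by Pearson correlation between the template
and the equally-shaped spectrogram window, clipped below at 0 so scores
live in [0, 1]. Local score maxima above an operating threshold
(default 0.4) become detections; maxima closer together than a
separation gap merge into one selection window whose gunshot count is
the number of merged peaks — field review windows hold 1-12 shots.

Selection tables are read and written in the tab-separated format used
by the Raven annotation tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.signal import fftconvolve, find_peaks, get_window

from pamharvest.audio import AudioRecording

__all__ = [
    "StftParams",
    "Spectrogram",
    "Template",
    "DetectionEvent",
    "SelectionTableError",
    "compute_spectrogram",
    "build_template",
    "score_series",
    "detect",
    "read_selection_table",
    "write_selection_table",
    "detect_recording",
]

DEFAULT_THRESHOLD = 0.4
LOG_POWER_EPS = 1e-12  # power floor; silence maps to a flat -120 dB


@dataclass(frozen=True)
class StftParams:
    """Analysis STFT settings.

    The default 256-sample window (32 ms at 8 kHz) with hop 64 resolves
    impulsive sub-second events; review-display spectrograms use much
    longer windows, which are too coarse for scoring.
    """

    window_samples: int = 256
    hop_samples: int = 64
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0 < self.hop_samples <= self.window_samples:
            raise ValueError("require window_samples >= hop_samples > 0")


@dataclass
class Spectrogram:
    """Log-magnitude STFT: frames x frequency bins, in dB."""

    magnitude: np.ndarray  # shape (n_frames, n_bins)
    frame_times_s: np.ndarray
    freqs_hz: np.ndarray
    stft_params: StftParams

    def __post_init__(self) -> None:
        if self.magnitude.shape != (self.frame_times_s.size, self.freqs_hz.size):
            raise ValueError("axis lengths do not match magnitude shape")
        if self.frame_times_s.size > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    def band_slice(self, low_hz: float, high_hz: float) -> np.ndarray:
        """Column indices of bins within [low_hz, high_hz]."""
        idx = np.nonzero((self.freqs_hz >= low_hz) & (self.freqs_hz <= high_hz))[0]
        if idx.size == 0:
            raise ValueError(f"no frequency bins within [{low_hz}, {high_hz}] Hz")
        return idx


@dataclass(frozen=True)
class Template:
    """Exemplar spectrogram patch, mean 0 and unit Frobenius norm."""

    patch: np.ndarray  # shape (n_frames, n_bins)
    duration_s: float
    band: tuple  # (low_hz, high_hz)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if abs(float(self.patch.mean())) > 1e-9:
            raise ValueError("template patch must have zero mean")
        if abs(float(np.linalg.norm(self.patch)) - 1.0) > 1e-9:
            raise ValueError("template patch must have unit norm")


@dataclass(frozen=True)
class DetectionEvent:
    """A scored putative gunshot selection window."""

    sensor_id: str
    begin_s: float
    end_s: float
    peak_score: float
    n_gunshots: int = 1
    low_hz: float = 0.0
    high_hz: float = 4000.0

    def __post_init__(self) -> None:
        if not self.begin_s < self.end_s:
            raise ValueError("require begin_s < end_s")
        if self.n_gunshots < 1:
            raise ValueError("n_gunshots must be >= 1")
        if not 0.0 <= self.peak_score <= 1.0:
            raise ValueError("peak_score must lie in [0, 1]")


class SelectionTableError(ValueError):
    """Malformed selection table."""


def compute_spectrogram(audio: AudioRecording, params: StftParams = StftParams()) -> Spectrogram:
    """Log-magnitude STFT with an exact frame count.

    Frames are hop-spaced windows fully inside the signal:
    n_frames = floor((n_samples - window) / hop) + 1. Magnitude is
    10*log10(power + eps), so silence sits at a constant floor.
    """
    n = len(audio)
    w, h = params.window_samples, params.hop_samples
    if n < w:
        raise ValueError(f"audio ({n} samples) shorter than one analysis window ({w})")
    n_frames = (n - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    frames = audio.samples[idx] * get_window(params.window, w, fftbins=True)
    spec = sp_fft.rfft(frames, axis=1)
    power = np.abs(spec) ** 2
    magnitude = 10.0 * np.log10(power + LOG_POWER_EPS)
    frame_times = (np.arange(n_frames) * h + w / 2) / audio.sample_rate_hz
    freqs = sp_fft.rfftfreq(w, d=1.0 / audio.sample_rate_hz)
    return Spectrogram(magnitude=magnitude, frame_times_s=frame_times,
                       freqs_hz=freqs, stft_params=params)


def _normalize_patch(patch: np.ndarray) -> np.ndarray:
    centred = patch - patch.mean()
    norm = np.linalg.norm(centred)
    if norm == 0:
        raise ValueError("degenerate (constant) template patch")
    return centred / norm


def build_template(
    clips: list,
    sample_rate_hz: int = 8000,
    duration_s: float = 0.4,
    band: tuple = (200.0, 3000.0),
    params: StftParams = StftParams(),
) -> Template:
    """Average annotated gunshot clips into a matched template.

    Each clip is a waveform starting at its annotated onset. Per-clip
    spectrogram patches covering ``duration_s`` and the frequency band
    are averaged element-wise, then mean-centred and scaled to unit
    norm.
    """
    if not clips:
        raise ValueError("build_template requires at least one clip")
    n_needed = int(round(duration_s * sample_rate_hz))
    patches = []
    for k, clip in enumerate(clips):
        clip = np.asarray(clip, dtype=float)
        if clip.size < n_needed:
            raise ValueError(f"clip {k} shorter than the template duration")
        rec = AudioRecording(samples=clip[:n_needed], sample_rate_hz=sample_rate_hz,
                             sensor_id="template-clip")
        spec = compute_spectrogram(rec, params)
        cols = spec.band_slice(*band)
        patches.append(spec.magnitude[:, cols])
    mean_patch = np.mean(patches, axis=0)
    n_frames = mean_patch.shape[0]
    return Template(
        patch=_normalize_patch(mean_patch),
        duration_s=(n_frames - 1) * params.hop_samples / sample_rate_hz
        + params.window_samples / sample_rate_hz,
        band=(float(band[0]), float(band[1])),
    )


def score_series(spec: Spectrogram, template: Template) -> np.ndarray:
    """Correlation score of the template at every alignment.

    At alignment k the score is the Pearson correlation between the
    template patch and the spectrogram window starting at frame k
    (restricted to the template's band), clipped below at 0. Windows
    with zero variance score 0 rather than NaN. Output has
    n_frames - template_frames + 1 entries; scores align with
    ``spec.frame_times_s[k]`` at the window start.
    """
    cols = spec.band_slice(*template.band)
    if cols.size != template.patch.shape[1]:
        raise ValueError(
            f"band mismatch: template has {template.patch.shape[1]} bins, "
            f"spectrogram band [{template.band[0]}, {template.band[1]}] Hz has {cols.size}"
        )
    S = spec.magnitude[:, cols]
    T = template.patch
    tf, nb = T.shape
    if spec.n_frames < tf:
        raise ValueError("spectrogram shorter than the template")

    # template sums to zero, so numerator = raw dot product with each window
    num = fftconvolve(S, T[::-1, ::-1], mode="valid")[:, 0]
    # windowed sums for the centred-window norm: ||w - mean|| = sqrt(sum w^2 - (sum w)^2 / N)
    ones = np.ones(tf)
    row_sum = S.sum(axis=1)
    row_sq = (S * S).sum(axis=1)
    win_sum = np.convolve(row_sum, ones, mode="valid")
    win_sq = np.convolve(row_sq, ones, mode="valid")
    var = np.maximum(win_sq - win_sum**2 / (tf * nb), 0.0)
    denom = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 1e-12, num / denom, 0.0)
    return np.clip(scores, 0.0, 1.0)


def detect(
    scores: np.ndarray,
    frame_times_s: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation_s: float = 0.5,
    template_duration_s: float = 0.4,
    peak_refractory_s: float | None = None,
    sensor_id: str = "unknown",
    band: tuple = (200.0, 3000.0),
) -> list[DetectionEvent]:
    """Pick score peaks above the threshold and group them into events.

    Local maxima with score > ``threshold`` are accepted after
    non-maximum suppression within ``peak_refractory_s`` (default half
    the template duration — one shot produces one accepted peak).
    Accepted peaks closer together than ``min_separation_s`` merge into
    one selection window spanning the template duration around the
    outermost peaks; ``n_gunshots`` counts the merged peaks, so the sum
    of counts over events equals the number of accepted peaks.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    frame_times_s = np.asarray(frame_times_s, dtype=float)[: scores.size]
    if scores.size == 0:
        return []
    if peak_refractory_s is None:
        peak_refractory_s = template_duration_s / 2
    dt = frame_times_s[1] - frame_times_s[0] if frame_times_s.size > 1 else 1.0
    distance = max(int(round(peak_refractory_s / dt)), 1)

    peak_idx, _ = find_peaks(scores, distance=distance)
    # an everywhere-decaying or single-frame series: allow boundary maxima
    if scores.size == 1 or (peak_idx.size == 0 and scores.max() > threshold):
        peak_idx = np.array([int(np.argmax(scores))])
    peak_idx = peak_idx[scores[peak_idx] > threshold]
    if peak_idx.size == 0:
        return []

    peak_times = frame_times_s[peak_idx]
    half = template_duration_s / 2
    events: list[DetectionEvent] = []
    cluster = [0]
    for i in range(1, peak_idx.size):
        if peak_times[i] - peak_times[cluster[-1]] < min_separation_s:
            cluster.append(i)
        else:
            events.append(_cluster_event(cluster, peak_idx, peak_times, scores,
                                         half, sensor_id, band))
            cluster = [i]
    events.append(_cluster_event(cluster, peak_idx, peak_times, scores,
                                 half, sensor_id, band))
    return events


def _cluster_event(cluster, peak_idx, peak_times, scores, half, sensor_id, band):
    members = np.asarray(cluster)
    t0 = peak_times[members[0]] - half
    t1 = peak_times[members[-1]] + half
    return DetectionEvent(
        sensor_id=sensor_id,
        begin_s=float(max(t0, 0.0)),
        end_s=float(t1),
        peak_score=float(scores[peak_idx[members]].max()),
        n_gunshots=int(members.size),
        low_hz=float(band[0]),
        high_hz=float(band[1]),
    )


def detect_recording(
    audio: AudioRecording,
    template: Template,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation_s: float = 0.5,
    params: StftParams = StftParams(),
    chunk_s: float = 600.0,
) -> list[DetectionEvent]:
    """End-to-end detection on one recording, chunked to bound memory.

    Chunks overlap by one template duration so events at chunk seams are
    not lost; duplicate events from the overlap are de-duplicated by
    onset proximity.
    """
    sr = audio.sample_rate_hz
    chunk = max(int(chunk_s * sr), params.window_samples * 4)
    overlap = int(template.duration_s * sr) + params.window_samples
    events: list[DetectionEvent] = []
    start = 0
    while start < len(audio):
        stop = min(start + chunk + overlap, len(audio))
        piece = AudioRecording(samples=audio.samples[start:stop], sample_rate_hz=sr,
                               sensor_id=audio.sensor_id)
        if len(piece) < params.window_samples:
            break
        spec = compute_spectrogram(piece, params)
        if spec.n_frames >= template.patch.shape[0]:
            scores = score_series(spec, template)
            offset = start / sr
            for ev in detect(scores, spec.frame_times_s, threshold, min_separation_s,
                             template.duration_s, sensor_id=audio.sensor_id,
                             band=template.band):
                events.append(DetectionEvent(
                    sensor_id=ev.sensor_id,
                    begin_s=ev.begin_s + offset,
                    end_s=ev.end_s + offset,
                    peak_score=ev.peak_score,
                    n_gunshots=ev.n_gunshots,
                    low_hz=ev.low_hz,
                    high_hz=ev.high_hz,
                ))
        start += chunk
    # drop overlap duplicates: same onset within half a separation gap
    events.sort(key=lambda e: e.begin_s)
    deduped: list[DetectionEvent] = []
    for ev in events:
        if deduped and abs(ev.begin_s - deduped[-1].begin_s) < min_separation_s / 2:
            if ev.peak_score > deduped[-1].peak_score:
                deduped[-1] = ev
            continue
        deduped.append(ev)
    return deduped


# ---------------------------------------------------------------------------
# Raven-style selection tables

MANDATORY_COLUMNS = [
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
]
ANNOTATION_COLUMNS = ["Score", "N Gunshots", "Sensor ID"]


def write_selection_table(events: list[DetectionEvent], path: str | Path) -> None:
    """Write events as a tab-separated Raven-style selection table."""
    rows = [
        {
            "Selection": i + 1,
            "View": "Spectrogram 1",
            "Channel": 1,
            "Begin Time (s)": ev.begin_s,
            "End Time (s)": ev.end_s,
            "Low Freq (Hz)": ev.low_hz,
            "High Freq (Hz)": ev.high_hz,
            "Score": ev.peak_score,
            "N Gunshots": ev.n_gunshots,
            "Sensor ID": ev.sensor_id,
        }
        for i, ev in enumerate(events)
    ]
    df = pd.DataFrame(rows, columns=["Selection", "View", "Channel"] + MANDATORY_COLUMNS[1:] + ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_selection_table(path: str | Path) -> list[DetectionEvent]:
    """Read a Raven-style selection table back into events.

    Raises :class:`SelectionTableError` naming the first missing
    mandatory column, and rejects non-numeric time/frequency fields
    (e.g. comma decimal separators).
    """
    df = pd.read_csv(path, sep="\t")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SelectionTableError(f"selection table {path} is missing column {col!r}")
    numeric = ["Begin Time (s)", "End Time (s)", "Low Freq (Hz)", "High Freq (Hz)"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SelectionTableError(
                f"selection table {path}: column {col!r} is not numeric "
                "(comma decimal separators are not supported)"
            ) from exc
    events = []
    for _, row in df.iterrows():
        events.append(DetectionEvent(
            sensor_id=str(row.get("Sensor ID", "unknown")),
            begin_s=float(row["Begin Time (s)"]),
            end_s=float(row["End Time (s)"]),
            peak_score=float(row.get("Score", 1.0)),
            n_gunshots=int(row.get("N Gunshots", 1)),
            low_hz=float(row["Low Freq (Hz)"]),
            high_hz=float(row["High Freq (Hz)"]),
        ))
    return events
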