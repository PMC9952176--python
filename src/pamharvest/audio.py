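"""Timestamped mono recordings and PCM-16 WAV input/output.

Field sensors (SWIFT units) record mono PCM at 8 kHz; everything in the
package works on float waveforms in [-1, 1] and converts to and from
16-bit integers only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.io import wavfile

PCM16_FULL_SCALE = 32767.0


@dataclass
class AudioRecording:
    """A mono waveform tied to a sensor deployment.

    Parameters
    ----------
    samples
        Linear amplitudes, 1-D float array; values are expected in
        [-1, 1] (enforced when writing WAV).
    sample_rate_hz
        Sampling rate in Hz (field deployments use 8000).
    start_time
        Wall-clock time of the first sample, or None for fixture audio.
    sensor_id
        Deployment identifier.
    """

    samples: np.ndarray
    sample_rate_hz: int
    start_time: datetime | None = None
    sensor_id: str = field(default="unknown")

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecording requires a 1-D mono waveform")
        if self.samples.size == 0:
            raise ValueError("AudioRecording requires a non-empty waveform")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.size


def write_wav(path: str | Path, recording: AudioRecording) -> None:
    """Write a recording as RIFF WAV, PCM 16-bit mono."""
    x = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(x * PCM16_FULL_SCALE).astype(np.int16)
    wavfile.write(str(path), recording.sample_rate_hz, pcm)


def read_wav(
    path: str | Path,
    start_time: datetime | None = None,
    sensor_id: str = "unknown",
) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer PCM is rescaled to floats in [-1, 1]; float WAVs pass
    through unchanged. Multi-channel audio is rejected (sensors record
    mono).
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    return AudioRecording(
        samples=samples,
        sample_rate_hz=int(rate),
        start_time=start_time,
        sensor_id=sensor_id,
    )
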