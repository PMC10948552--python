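"""Mono audio container and WAV I/O (PCM 16-bit and float32)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioBuffer:
    """Mono audio: float samples in [-1, 1] plus a sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1:
            raise ValueError(f"audio must be mono (1-D), got shape {s.shape}")
        if not np.all(np.isfinite(s)):
            raise ValueError("audio contains non-finite samples")
        if s.size and np.max(np.abs(s)) > 1.0 + 1e-9:
            raise ValueError("audio samples must lie in [-1, 1]")
        object.__setattr__(self, "samples", s)
        if self.sample_rate_hz < 1:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path) -> AudioBuffer:
    """Read a mono WAV file (PCM16, PCM32, or float)."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = np.asarray(data, dtype=np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioBuffer(np.clip(samples, -1.0, 1.0), int(rate))


def write_wav(path, audio: AudioBuffer) -> None:
    """Write PCM 16-bit mono WAV."""
    pcm = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, audio.sample_rate_hz, (pcm * 32767.0).astype(np.int16))
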