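"""Minimal mono 16-bit PCM WAV I/O on top of the stdlib ``wave`` module.

Samples are exchanged as floats in [-1, 1]; on write they are scaled by
32767 and rounded, so the round-trip error is bounded by half an LSB.
"""

from __future__ import annotations

import wave
import warnings

import numpy as np

_SCALE = 32767


def write_wav(path, samples: np.ndarray, fs: int = 4000) -> None:
    """Write samples as mono PCM-16 WAV; out-of-range values are clipped."""
    samples = np.asarray(samples, dtype=float)
    if np.any(np.abs(samples) > 1.0):
        warnings.warn("samples outside [-1, 1] clipped on WAV write", stacklevel=2)
        samples = np.clip(samples, -1.0, 1.0)
    ints = np.round(samples * _SCALE).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(fs)
        fh.writeframes(ints.tobytes())


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM-16 WAV; returns (float samples in [-1, 1], fs)."""
    with wave.open(str(path), "rb") as fh:
        if fh.getnchannels() != 1 or fh.getsampwidth() != 2:
            raise ValueError("expected mono 16-bit PCM WAV")
        fs = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    return np.frombuffer(raw, dtype="<i2").astype(float) / _SCALE, fs
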