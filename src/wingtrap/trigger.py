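"""Streaming event detection.

The trap's microcontroller copies the ADC output into a 16 K-sample
circular buffer while monitoring the root-mean-square of a sliding
128-sample window (16 ms at 4 kHz).  When the window RMS exceeds a
predefined threshold an event is declared and a 1024-sample snippet is cut:
200 samples before and up to the triggering point plus 824 samples after
it, so the onset of the wingbeat is never lost even when it precedes the
threshold crossing.

This module reproduces that behaviour on in-memory streams: an explicit
:class:`RingBuffer` with wrap-around extraction, a sliding-RMS scan, a
refractory interval so one transit yields one event, and zero-padding for
triggers that occur before enough pre-context has accumulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WINDOW_LEN = 128
PRE_SAMPLES = 200
POST_SAMPLES = 824
SNIPPET_LEN = PRE_SAMPLES + POST_SAMPLES
RING_CAPACITY = 16384


class BufferOverrunError(RuntimeError):
    """Requested span has already been overwritten in the circular buffer."""


@dataclass
class RingBuffer:
    """Fixed-capacity circular sample buffer with absolute-index reads.

    ``write`` appends a block, overwriting the oldest samples once the
    buffer is full; ``read`` retrieves a span by absolute stream index and
    raises :class:`BufferOverrunError` if the span is no longer resident.
    """

    capacity: int = RING_CAPACITY
    storage: np.ndarray = field(init=False)
    total_written: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.capacity < SNIPPET_LEN:
            raise ValueError(f"capacity must be at least {SNIPPET_LEN} samples")
        self.storage = np.zeros(self.capacity)

    @property
    def write_index(self) -> int:
        return self.total_written % self.capacity

    def write(self, block: np.ndarray) -> None:
        block = np.asarray(block, dtype=float)
        if len(block) >= self.capacity:
            # Only the trailing `capacity` samples survive; place them so the
            # absolute-index modular arithmetic in `read` still holds.
            tail = block[-self.capacity :]
            start = (self.total_written + len(block) - self.capacity) % self.capacity
            self.storage[start:] = tail[: self.capacity - start]
            self.storage[:start] = tail[self.capacity - start :]
            self.total_written += len(block)
            return
        start = self.write_index
        end = start + len(block)
        if end <= self.capacity:
            self.storage[start:end] = block
        else:
            split = self.capacity - start
            self.storage[start:] = block[:split]
            self.storage[: end - self.capacity] = block[split:]
        self.total_written += len(block)

    def read(self, start: int, length: int) -> np.ndarray:
        """Copy ``length`` samples starting at absolute index ``start``."""
        if start < 0 or start + length > self.total_written:
            raise IndexError("requested span outside written history")
        if start < self.total_written - self.capacity:
            raise BufferOverrunError(
                f"samples [{start}, {start + length}) were overwritten "
                f"(only the last {self.capacity} of {self.total_written} remain)"
            )
        idx = (np.arange(start, start + length)) % self.capacity
        return self.storage[idx].copy()


@dataclass(frozen=True)
class TriggerConfig:
    """Detector settings.

    ``pre_samples + post_samples`` is pinned to the 1024-sample snippet; the
    refractory interval (default: the post-trigger window) suppresses
    re-triggering on the tail of the transit that caused the event.
    ``hop`` > 1 evaluates the RMS window every ``hop`` samples instead of
    every sample.
    """

    threshold: float
    window_len: int = WINDOW_LEN
    pre_samples: int = PRE_SAMPLES
    post_samples: int = POST_SAMPLES
    refractory: int = POST_SAMPLES
    hop: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.pre_samples + self.post_samples != SNIPPET_LEN:
            raise ValueError(
                f"pre_samples + post_samples must equal {SNIPPET_LEN}"
            )
        if self.window_len > self.pre_samples:
            raise ValueError("window_len must not exceed pre_samples")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")


@dataclass(frozen=True)
class DetectionEvent:
    """One detected transit: trigger position, snippet and trigger RMS."""

    trigger_index: int
    snippet: np.ndarray
    rms_at_trigger: float
    padded_head: int = 0
    padded_tail: int = 0

    def __post_init__(self) -> None:
        if len(self.snippet) != SNIPPET_LEN:
            raise ValueError(f"snippet must hold {SNIPPET_LEN} samples")


def rms(window: np.ndarray) -> float:
    """Root-mean-square of a sample window."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("RMS of an empty window is undefined")
    return float(np.sqrt(np.mean(window**2)))


def sliding_rms(samples: np.ndarray, window_len: int = WINDOW_LEN) -> np.ndarray:
    """RMS of every ``window_len`` window; entry i is the window ending at i.

    The first ``window_len - 1`` entries are NaN (no complete window yet).
    """
    samples = np.asarray(samples, dtype=float)
    out = np.full(len(samples), np.nan)
    if len(samples) < window_len:
        return out
    csum = np.concatenate([[0.0], np.cumsum(samples**2)])
    mean_sq = (csum[window_len:] - csum[:-window_len]) / window_len
    out[window_len - 1 :] = np.sqrt(np.maximum(mean_sq, 0.0))
    return out


def extract_snippet(
    buffer: RingBuffer,
    trigger_index: int,
    pre_samples: int = PRE_SAMPLES,
    post_samples: int = POST_SAMPLES,
) -> tuple[np.ndarray, int, int]:
    """Cut the snippet around a trigger from the circular buffer.

    The snippet spans absolute indices ``[trigger - pre + 1, trigger + post]``
    inclusive.  A trigger earlier than ``pre_samples - 1`` into the stream is
    head-padded with zeros; a post-window extending past the written history
    is tail-padded.  Returns ``(snippet, padded_head, padded_tail)``.
    """
    start = trigger_index - pre_samples + 1
    stop = trigger_index + post_samples + 1  # exclusive
    padded_head = max(0, -start)
    padded_tail = max(0, stop - buffer.total_written)
    body = buffer.read(start + padded_head, stop - padded_tail - (start + padded_head))
    snippet = np.concatenate(
        [np.zeros(padded_head), body, np.zeros(padded_tail)]
    )
    return snippet, padded_head, padded_tail


def process_stream(
    samples: np.ndarray, config: TriggerConfig
) -> list[DetectionEvent]:
    """Scan a stream and return one :class:`DetectionEvent` per transit.

    The trigger index is the last sample of the first window whose RMS
    reaches the threshold; no new trigger is accepted within ``refractory``
    samples of the previous one.  Snippets are extracted through a
    :class:`RingBuffer` exactly as the embedded implementation would.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < config.window_len:
        return []

    series = sliding_rms(samples, config.window_len)
    if config.hop > 1:
        mask = np.zeros(len(series), dtype=bool)
        mask[config.window_len - 1 :: config.hop] = True
        series = np.where(mask, series, np.nan)
    candidates = np.flatnonzero(series >= config.threshold)

    ring = RingBuffer()
    written = 0
    events: list[DetectionEvent] = []
    last_trigger: int | None = None
    for t in candidates:
        if last_trigger is not None and t - last_trigger <= config.refractory:
            continue
        # Feed the ring up to the end of the post-window before extracting.
        need = min(t + config.post_samples + 1, len(samples))
        if need > written:
            ring.write(samples[written:need])
            written = need
        snippet, head, tail = extract_snippet(
            ring, int(t), config.pre_samples, config.post_samples
        )
        events.append(
            DetectionEvent(
                trigger_index=int(t),
                snippet=snippet,
                rms_at_trigger=float(series[t]),
                padded_head=head,
                padded_tail=tail,
            )
        )
        last_trigger = int(t)
    return events


def calibrate_noise_threshold(
    samples: np.ndarray, fs: int = 4000, seconds: float = 1.0, margin_db: float = 12.0
) -> float:
    """Trigger threshold from a signal-free stretch of stream.

    Estimates the noise-floor RMS from the first ``seconds`` of the stream
    and places the threshold ``margin_db`` above it.
    """
    n = int(round(seconds * fs))
    head = np.asarray(samples, dtype=float)[:n]
    if head.size == 0:
        raise ValueError("stream too short to calibrate")
    return rms(head) * 10.0 ** (margin_db / 20.0)


def default_threshold(noise_floor_db: float = -75.0, margin_db: float = 12.0) -> float:
    """Threshold ``margin_db`` above a known noise floor (dB full scale)."""
    return 10.0 ** ((noise_floor_db + margin_db) / 20.0)
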