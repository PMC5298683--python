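"""Synthetic optical wingbeat signals.

An insect crossing the infrared beam of an optoelectronic trap sensor
modulates the received light intensity in two ways: a slow, almost
non-oscillatory excursion caused by the body occluding the beam (near-DC
content), and a fast oscillation at the wingbeat fundamental plus several
harmonics.  This module synthesises 1024-sample snippets at 4 kHz with that
structure, continuous sensor streams with a calibrated noise floor, and
labelled corpora, so that the trigger, spectral, rule and ML stages can be
exercised without field recordings.

The waveform model for a single transit of duration ``T`` is

    x(t) = e(t) * [ A_body + A_wing * sum_k a_k sin(2*pi*k*f0*(1+d_k)*t + phi_k) ]

where ``e(t)`` is a raised-cosine bell over the transit, ``a_k`` is a
geometric per-harmonic decay, and ``d_k`` is a small fractional detuning
applied to partials k >= 3.  White Gaussian noise is added and scaled so
that 20*log10(clean_rms / noise_rms) equals the requested SNR exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

FS = 4000
"""Sampling rate in Hz (one sample per 250 us emitter pulse)."""

SNIPPET_LEN = 1024
"""Snippet length in samples (256 ms at 4 kHz)."""

POSITIVE_LABEL = "B. oleae"


@dataclass(frozen=True)
class SpeciesPreset:
    """Generative parameters for one species' wingbeat signature.

    Parameters
    ----------
    name : str
        Species label attached to generated snippets.
    f0_range : (float, float)
        Closed interval of wingbeat fundamental frequencies, Hz.  The
        fundamental of an individual transit is drawn uniformly from it.
    n_harmonics : int
        Number of partials in the harmonic stack (partials falling at or
        above the Nyquist frequency are silently dropped).
    harmonic_decay : float
        Geometric amplitude ratio between successive partials, in (0, 1).
    detune_max : float
        Fractional detuning bound for partials k >= 3; each such partial is
        shifted by a uniform factor in [-detune_max, detune_max].
    wing_amplitude_range : (float, float)
        Peak amplitude of the wingbeat modulation, normalised full-scale
        units in (0, 1].
    body_amplitude_range : (float, float)
        Peak amplitude of the slow body-occlusion component.
    transit_ms_range : (float, float)
        Transit (field-of-view crossing) duration interval, ms, in (0, 256].
    """

    name: str
    f0_range: tuple[float, float]
    n_harmonics: int = 5
    harmonic_decay: float = 0.6
    detune_max: float = 0.01
    wing_amplitude_range: tuple[float, float] = (0.15, 0.5)
    body_amplitude_range: tuple[float, float] = (0.05, 0.2)
    transit_ms_range: tuple[float, float] = (60.0, 140.0)

    def __post_init__(self) -> None:
        if not (0 < self.f0_range[0] <= self.f0_range[1]):
            raise ValueError(f"f0_range must be positive and ordered: {self.f0_range}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be a positive integer")
        if not (0 < self.harmonic_decay < 1):
            raise ValueError("harmonic_decay must lie in (0, 1)")
        lo, hi = self.wing_amplitude_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("wing_amplitude_range must lie within (0, 1]")
        lo, hi = self.transit_ms_range
        if not (0 < lo <= hi <= 256):
            raise ValueError("transit_ms_range must lie within (0, 256] ms")


@dataclass(frozen=True)
class GenConfig:
    """Global generation settings.

    ``fs`` and ``snippet_len`` are fixed by the acquisition design (4 kHz,
    1024 samples); ``snr_db`` is the per-snippet signal-to-noise ratio in the
    20*log10(signal_rms/noise_rms) sense; ``noise_floor_db`` the stream
    background level relative to full scale.
    """

    fs: int = FS
    snippet_len: int = SNIPPET_LEN
    snr_db: float = 50.0
    noise_floor_db: float = -75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs != FS:
            raise ValueError(f"fs is fixed at {FS} Hz")
        if self.snippet_len != SNIPPET_LEN:
            raise ValueError(f"snippet_len is fixed at {SNIPPET_LEN} samples")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")

    @property
    def noise_floor_rms(self) -> float:
        return 10.0 ** (self.noise_floor_db / 20.0)


@dataclass(frozen=True)
class LabeledSnippet:
    """A 1024-sample waveform with generation ground truth."""

    samples: np.ndarray
    label: str
    f0_true: float
    body_component_peak: float
    clean_rms: float
    noise_rms: float
    onset_index: int
    transit_samples: int
    below_floor: bool = False

    def __post_init__(self) -> None:
        if len(self.samples) != SNIPPET_LEN:
            raise ValueError(f"snippet must hold exactly {SNIPPET_LEN} samples")

    @property
    def snr_db(self) -> float:
        """Realised SNR, 20*log10(clean_rms / noise_rms)."""
        return 20.0 * np.log10(self.clean_rms / self.noise_rms)


# Default corpus composition: the lab corpus mix of the four fruit-fly
# species the verifier is evaluated against.
DEFAULT_COMPOSITION: dict[str, int] = {
    "B. oleae": 913,
    "C. capitata": 623,
    "Drosophila": 166,
    "L. aristella": 771,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Composition (species -> snippet count) and seed for a corpus."""

    composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, count in self.composition.items():
            if count < 0:
                raise ValueError(f"negative count for {name!r}")
            make_preset(name)  # raises on unknown species


@dataclass(frozen=True)
class Corpus:
    snippets: list[LabeledSnippet]
    labels: np.ndarray  # 1 for the target species, 0 otherwise

    def __len__(self) -> int:
        return len(self.snippets)


_PRESETS: dict[str, SpeciesPreset] = {
    # Olive fruit fly: fundamental 170-230 Hz (15-35 degC activity range),
    # at least five resolved harmonics.
    "B. oleae": SpeciesPreset(name="B. oleae", f0_range=(170.0, 230.0)),
    # Medfly: spectrum overlaps B. oleae's almost completely; slightly
    # different body occlusion and harmonic roll-off.
    "C. capitata": SpeciesPreset(
        name="C. capitata",
        f0_range=(170.0, 230.0),
        harmonic_decay=0.55,
        body_amplitude_range=(0.06, 0.22),
    ),
    # Black fig fly: spectrum also overlapping the target band.
    "L. aristella": SpeciesPreset(
        name="L. aristella",
        f0_range=(170.0, 230.0),
        harmonic_decay=0.65,
        body_amplitude_range=(0.04, 0.18),
    ),
    # Smaller insect, higher fundamental (260-310 Hz), roughly half the
    # optical modulation amplitude of the fruit flies.
    "Drosophila": SpeciesPreset(
        name="Drosophila",
        f0_range=(260.0, 310.0),
        wing_amplitude_range=(0.075, 0.25),
        body_amplitude_range=(0.025, 0.1),
    ),
    # Mosquitoes: much smaller still, fundamental well above the fruit-fly
    # band.
    "mosquito": SpeciesPreset(
        name="mosquito",
        f0_range=(350.0, 700.0),
        wing_amplitude_range=(0.02, 0.08),
        body_amplitude_range=(0.01, 0.04),
    ),
}


def make_preset(name: str) -> SpeciesPreset:
    """Return the default :class:`SpeciesPreset` for a known species.

    Raises
    ------
    ValueError
        If ``name`` is not one of the documented presets; the message lists
        the valid options.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(_PRESETS))
        raise ValueError(f"unknown species {name!r}; valid options: {valid}") from None


def species_names() -> list[str]:
    return sorted(_PRESETS)


def f0_at_temperature(
    preset: SpeciesPreset,
    temperature: float,
    jitter_hz: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Wingbeat fundamental at a given ambient temperature.

    The species is active between 15 and 35 degC and its fundamental varies
    linearly across ``preset.f0_range`` over that span.  Optional zero-mean
    Gaussian jitter (``jitter_hz`` standard deviation) models individual
    variation; with ``jitter_hz=0`` the map is deterministic.
    """
    if not (15.0 <= temperature <= 35.0):
        raise ValueError(
            f"temperature {temperature} degC outside the 15-35 degC activity range"
        )
    lo, hi = preset.f0_range
    f0 = lo + (hi - lo) * (temperature - 15.0) / 20.0
    if jitter_hz > 0:
        if rng is None:
            rng = np.random.default_rng()
        f0 += jitter_hz * rng.standard_normal()
    return f0


def _as_rng(rng: np.random.Generator | int | None, fallback_seed: int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        return np.random.default_rng(fallback_seed)
    return np.random.default_rng(rng)


def _raised_cosine(n: int) -> np.ndarray:
    # Smooth bell rising from and returning to zero over the transit.
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def _transit(
    preset: SpeciesPreset, rng: np.random.Generator, fs: int
) -> tuple[np.ndarray, float, float]:
    """Draw one clean (noise-free) transit waveform.

    Returns ``(waveform, f0, body_amplitude)``.  The waveform is the
    envelope-gated body component plus harmonic stack, with the stack
    normalised so its peak weight is 1 before scaling by the wing amplitude.
    """
    f0 = rng.uniform(*preset.f0_range)
    transit_ms = rng.uniform(*preset.transit_ms_range)
    n = int(round(transit_ms * fs / 1000.0))
    wing_amp = rng.uniform(*preset.wing_amplitude_range)
    body_amp = rng.uniform(*preset.body_amplitude_range)

    t = np.arange(n) / fs
    weights = preset.harmonic_decay ** np.arange(preset.n_harmonics)
    stack = np.zeros(n)
    for k in range(1, preset.n_harmonics + 1):
        delta = (
            rng.uniform(-preset.detune_max, preset.detune_max)
            if (k >= 3 and preset.detune_max > 0)
            else 0.0
        )
        phi = rng.uniform(0.0, 2.0 * np.pi)
        fk = k * f0 * (1.0 + delta)
        if fk >= fs / 2:  # band-limit: drop aliasing partials
            continue
        stack += weights[k - 1] * np.sin(2.0 * np.pi * fk * t + phi)
    stack /= weights.sum()

    env = _raised_cosine(n)
    return env * (body_amp + wing_amp * stack), f0, body_amp


def synth_snippet(
    preset: SpeciesPreset,
    config: GenConfig = GenConfig(),
    rng: np.random.Generator | int | None = None,
) -> LabeledSnippet:
    """Synthesise one labelled 1024-sample snippet.

    The transit is embedded at a random position (leaving room for the
    pre-trigger context a real capture would carry), and white Gaussian
    noise is scaled so the realised clean/noise RMS ratio matches
    ``config.snr_db`` exactly.
    """
    rng = _as_rng(rng, config.seed)
    clean_transit, f0, body_amp = _transit(preset, rng, config.fs)
    n = len(clean_transit)
    lo = min(100, max(0, config.snippet_len - n))
    hi = max(lo + 1, config.snippet_len - n - 19)
    onset = int(rng.integers(lo, hi))

    clean = np.zeros(config.snippet_len)
    clean[onset : onset + n] = clean_transit
    clean_rms = float(np.sqrt(np.mean(clean**2)))

    noise = rng.standard_normal(config.snippet_len)
    target_noise_rms = clean_rms * 10.0 ** (-config.snr_db / 20.0)
    noise *= target_noise_rms / np.sqrt(np.mean(noise**2))

    return LabeledSnippet(
        samples=np.clip(clean + noise, -1.0, 1.0),
        label=preset.name,
        f0_true=f0,
        body_component_peak=body_amp,
        clean_rms=clean_rms,
        noise_rms=target_noise_rms,
        onset_index=onset,
        transit_samples=n,
        below_floor=clean_rms < config.noise_floor_rms,
    )


def synth_stream(
    events: Sequence[tuple[float, SpeciesPreset]],
    duration: float,
    config: GenConfig = GenConfig(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Continuous 4 kHz sensor stream with transits at given onsets.

    Parameters
    ----------
    events : sequence of (onset_seconds, preset)
        Transit onsets within [0, duration).  Transits may not overlap (the
        trap's physical shields preclude simultaneous entries).
    duration : float
        Stream length in seconds.

    Returns
    -------
    (stream, truth)
        The sample stream (background white noise at the configured floor
        level with events added in) and a ground-truth table with columns
        ``onset_index``, ``label``, ``f0_hz``, ``n_samples``.
    """
    rng = _as_rng(rng, config.seed)
    n_total = int(round(duration * config.fs))
    stream = rng.standard_normal(n_total) * config.noise_floor_rms

    records = []
    last_end = -1
    for onset_s, preset in sorted(events, key=lambda e: e[0]):
        if not (0.0 <= onset_s < duration):
            raise ValueError(f"event onset {onset_s}s outside [0, {duration})")
        onset = int(round(onset_s * config.fs))
        clean, f0, _ = _transit(preset, rng, config.fs)
        if onset <= last_end:
            raise ValueError("overlapping transits are not supported")
        end = min(onset + len(clean), n_total)
        stream[onset:end] += clean[: end - onset]
        last_end = onset + len(clean) - 1
        records.append(
            {
                "onset_index": onset,
                "label": preset.name,
                "f0_hz": f0,
                "n_samples": len(clean),
            }
        )

    truth = pd.DataFrame(records, columns=["onset_index", "label", "f0_hz", "n_samples"])
    return np.clip(stream, -1.0, 1.0), truth


def synth_corpus(
    spec: CorpusSpec = CorpusSpec(), config: GenConfig = GenConfig()
) -> Corpus:
    """Generate a labelled corpus with exactly the requested composition.

    Binary labels are 1 for the target species (B. oleae) and 0 for every
    other species.  Identical specs and configs yield bit-identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    snippets: list[LabeledSnippet] = []
    labels: list[int] = []
    for name, count in spec.composition.items():
        preset = make_preset(name)
        for _ in range(count):
            snippets.append(synth_snippet(preset, config, rng))
            labels.append(1 if name == POSITIVE_LABEL else 0)
    return Corpus(snippets=snippets, labels=np.asarray(labels, dtype=int))


def preset_without_detune(preset: SpeciesPreset) -> SpeciesPreset:
    """Convenience: the same preset with partial detuning disabled."""
    return replace(preset, detune_max=0.0)
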