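"""In-situ two-rule species verifier.

Once a transit triggers the trap, a cheap on-board check decides whether
the insect was the target species (the olive fruit fly).  Two rules must
hold simultaneously:

* **Rule 1 — amplitude.**  The time-domain amplitude of the snippet lies
  within limits derived from a large set of positive recordings.  Larger
  insects modulate the light more strongly, much smaller ones (midges,
  mosquitoes) far less.
* **Rule 2 — band energy.**  The spectral energy between 170 and 230 Hz,
  where the target's wingbeat fundamental lies across its whole 15-35 degC
  activity range, exceeds a threshold derived from positives.

The conjunction rejects mosquitoes and most Drosophila but cannot, by
construction, separate the target from other fruit flies whose spectra
overlap the same band (C. capitata, L. aristella).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml

from . import spectral
from .synth import LabeledSnippet

MIN_POSITIVES = 50

# Calibration percentiles and widening margins.  The 1st/99th amplitude
# percentiles are widened by 10 % on each side; the band-energy floor is the
# 5th percentile of the positives' band energy relaxed by 3 dB (factor 0.5
# in linear power), so a held-out positive of the same population passes
# both rules with high probability.
AMP_PCT = (1.0, 99.0)
AMP_WIDEN = 0.10
BAND_PCT = 5.0
BAND_MARGIN = 0.5


@dataclass(frozen=True)
class RuleThresholds:
    """Calibrated amplitude limits and band-energy floor."""

    amp_lo: float
    amp_hi: float
    band_energy_min: float
    band: tuple[float, float] = spectral.OLEAE_BAND
    calibration_n: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.amp_lo < self.amp_hi):
            raise ValueError("require 0 <= amp_lo < amp_hi")
        if self.band_energy_min <= 0:
            raise ValueError("band_energy_min must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["band"] = list(d["band"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RuleThresholds":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["band"] = tuple(d["band"])
        return cls(**d)


def peak_amplitude(samples: np.ndarray) -> float:
    """Amplitude statistic: peak absolute value of the mean-removed snippet."""
    samples = np.asarray(samples, dtype=float)
    return float(np.max(np.abs(samples - samples.mean())))


def _snippet_samples(snippet) -> np.ndarray:
    return snippet.samples if isinstance(snippet, LabeledSnippet) else np.asarray(snippet)


def calibrate(positives: Sequence[LabeledSnippet]) -> RuleThresholds:
    """Derive rule thresholds from positive (target-species) examples.

    Requires at least ``MIN_POSITIVES`` snippets, all carrying the same
    label.  Amplitude limits are the 1st/99th percentiles of per-snippet
    peak amplitude widened by 10 %; the band-energy floor is the relaxed
    5th percentile of the positives' 170-230 Hz energy.  A zero-spread
    amplitude distribution is flagged as degenerate.
    """
    if len(positives) < MIN_POSITIVES:
        raise ValueError(
            f"calibration needs at least {MIN_POSITIVES} positive snippets, "
            f"got {len(positives)}"
        )
    labels = {s.label for s in positives}
    if len(labels) > 1:
        raise ValueError(f"calibration requires single-label positives, got {sorted(labels)}")

    amps = np.array([peak_amplitude(s.samples) for s in positives])
    energies = np.array(
        [spectral.band_energy(spectral.welch_log_psd(s.samples)) for s in positives]
    )
    p_lo, p_hi = np.percentile(amps, AMP_PCT)
    return RuleThresholds(
        amp_lo=float(p_lo) * (1.0 - AMP_WIDEN),
        amp_hi=float(p_hi) * (1.0 + AMP_WIDEN),
        band_energy_min=float(np.percentile(energies, BAND_PCT)) * BAND_MARGIN,
        calibration_n=len(positives),
        degenerate=bool(p_lo == p_hi),
    )


def rule1_amplitude(snippet, thresholds: RuleThresholds) -> bool:
    """Time-domain amplitude within the calibrated limits."""
    amp = peak_amplitude(_snippet_samples(snippet))
    return thresholds.amp_lo <= amp <= thresholds.amp_hi


def rule2_band(snippet, thresholds: RuleThresholds) -> bool:
    """170-230 Hz band energy at or above the calibrated floor."""
    psd = spectral.welch_log_psd(_snippet_samples(snippet))
    return spectral.band_energy(psd, thresholds.band) >= thresholds.band_energy_min


def verify(snippet, thresholds: RuleThresholds) -> bool:
    """Verified detection: Rule 1 AND Rule 2."""
    return rule1_amplitude(snippet, thresholds) and rule2_band(snippet, thresholds)
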