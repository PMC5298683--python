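"""Welch log-PSD estimation, SNR and band-energy utilities.

Feature extraction follows the trap's on-board procedure: the 1024-sample
snippet is split into 256-sample chunks, each windowed with a Hamming
window, transformed with a 256-point DFT, and the modified periodograms are
averaged and expressed as 10*log10 power.  On the 4 kHz grid this yields
129 one-sided bins from 0 to 2000 Hz in steps of 15.625 Hz.

Two overlap settings are meaningful: 0 (four independent chunks, the
4-segment worked example) and 192 (75 % overlap, 13 segments, the setting
used for classifier features).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import FS, SNIPPET_LEN

NPERSEG = 256
NFFT = 256
N_BINS = NFFT // 2 + 1  # 129
BIN_HZ = FS / NFFT  # 15.625
OLEAE_BAND = (170.0, 230.0)
"""Fundamental-frequency band of the target species, Hz."""


@dataclass(frozen=True)
class WelchParams:
    """Averaged-periodogram settings (Hamming window, 256-point DFT)."""

    nperseg: int = NPERSEG
    noverlap: int = 192
    nfft: int = NFFT
    fs: int = FS
    window_shape: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 <= self.noverlap < self.nperseg):
            raise ValueError("noverlap must lie in [0, nperseg)")
        if self.nfft < self.nperseg:
            raise ValueError("nfft must be >= nperseg")

    def n_segments(self, n_samples: int = SNIPPET_LEN) -> int:
        step = self.nperseg - self.noverlap
        return (n_samples - self.nperseg) // step + 1


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided log-PSD: 129 bins spanning 0-2000 Hz.

    ``values`` holds 10*log10 power density; ``power`` the same on the
    linear scale (kept so band energies sum exactly).
    """

    freqs: np.ndarray
    values: np.ndarray
    power: np.ndarray
    params: WelchParams
    n_segments: int

    def __post_init__(self) -> None:
        if not (len(self.freqs) == len(self.values) == len(self.power)):
            raise ValueError("freqs/values/power length mismatch")


@dataclass(frozen=True)
class SnrInputs:
    signal_rms: float
    noise_rms: float

    def __post_init__(self) -> None:
        if self.signal_rms <= 0 or self.noise_rms <= 0:
            raise ValueError("RMS values must be positive")


@dataclass(frozen=True)
class F0Estimate:
    """Peak-picked fundamental with a confidence flag.

    ``confident`` is False when the peak's prominence over the in-band
    median power falls below the floor margin (noise-only snippets).
    """

    f0_hz: float
    peak_db: float
    prominence_db: float
    confident: bool


def welch_log_psd(snippet: np.ndarray, params: WelchParams = WelchParams()) -> PsdEstimate:
    """Averaged modified-periodogram PSD of a 1024-sample snippet, in dB.

    One-sided density scaling with Hamming-window power normalisation
    (interior bins doubled, DC and Nyquist not), matching the usual
    ``pwelch`` convention.
    """
    snippet = np.asarray(snippet, dtype=float)
    if len(snippet) != SNIPPET_LEN:
        raise ValueError(f"snippet must hold exactly {SNIPPET_LEN} samples")
    if params.window_shape != "hamming":
        raise ValueError("only the Hamming window is supported")
    # Symmetric Hamming taper (the classical modified-periodogram choice;
    # scipy's name-based lookup would yield the periodic variant).
    window = np.hamming(params.nperseg)
    freqs, pxx = sps.welch(
        snippet,
        fs=params.fs,
        window=window,
        nperseg=params.nperseg,
        noverlap=params.noverlap,
        nfft=params.nfft,
        detrend=False,
        scaling="density",
        average="mean",
    )
    with np.errstate(divide="ignore"):
        values = 10.0 * np.log10(pxx)
    return PsdEstimate(
        freqs=freqs,
        values=values,
        power=pxx,
        params=params,
        n_segments=params.n_segments(len(snippet)),
    )


def snr_db(inputs: SnrInputs) -> float:
    """Signal-to-noise ratio: 20*log10(signal_rms / noise_rms), dB."""
    return 20.0 * np.log10(inputs.signal_rms / inputs.noise_rms)


def adc_theoretical_snr(bits: int) -> float:
    """Theoretical full-scale SNR of an ideal ``bits``-bit ADC: 6.02 b + 1.76 dB."""
    if bits < 1:
        raise ValueError("bits must be a positive integer")
    return 6.02 * bits + 1.76


def band_bins(psd: PsdEstimate, band: tuple[float, float]) -> np.ndarray:
    """Indices of PSD bins whose centres fall inside ``band`` (inclusive)."""
    lo, hi = band
    if not (0 <= lo < hi):
        raise ValueError(f"invalid band {band}")
    idx = np.flatnonzero((psd.freqs >= lo) & (psd.freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"band {band} contains no PSD bins")
    return idx


def band_energy(psd: PsdEstimate, band: tuple[float, float] = OLEAE_BAND) -> float:
    """Linear-scale power summed over the bins inside ``band``."""
    return float(psd.power[band_bins(psd, band)].sum())


def estimate_f0(
    psd: PsdEstimate,
    search_band: tuple[float, float] = OLEAE_BAND,
    interpolate: bool = False,
    prominence_margin_db: float = 10.0,
) -> F0Estimate:
    """Fundamental frequency as the strongest PSD bin within a band.

    With ``interpolate=True`` a parabola through the three log-power points
    around the peak refines the estimate by up to half a bin.  The estimate
    is flagged low-confidence when the peak rises less than
    ``prominence_margin_db`` above the spectrum's median level (near-DC
    region excluded), as happens on noise-only snippets.
    """
    idx = band_bins(psd, search_band)
    k = idx[np.argmax(psd.values[idx])]
    peak_db = float(psd.values[k])
    floor_db = float(np.median(psd.values[3:]))  # skip the body-movement bins
    prominence = peak_db - floor_db
    f0 = float(psd.freqs[k])
    if interpolate and 0 < k < len(psd.values) - 1:
        a, b, c = psd.values[k - 1], psd.values[k], psd.values[k + 1]
        denom = a - 2 * b + c
        if denom < 0:  # genuine local maximum
            delta = 0.5 * (a - c) / denom
            f0 += float(np.clip(delta, -0.5, 0.5)) * BIN_HZ
    return F0Estimate(
        f0_hz=f0,
        peak_db=peak_db,
        prominence_db=prominence,
        confident=prominence >= prominence_margin_db,
    )
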